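"""Per-A-line strut candidate detection.

A metal strut reflects most of the light, so along its A-line the
intensity profile shows a high peak followed by an abrupt fall into the
trailing shadow, while tissue attenuates gradually.  Because strut
brightness varies too much for a global intensity cut, candidates are
selected on the *slope* between the A-line peak and the first pixel of
the trailing shadow: ``slope = (I(shadow_start) - I(peak)) / dist``.
The shadow itself is a run of continuously-low pixels (at most the
shadow-intensity threshold, the 89th percentile of the ROI histogram of
the whole pullback run by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from octstrut.preprocess import RoiBoundary, _order_statistic
from octstrut.pullback_io import Frame, Pullback


@dataclass(frozen=True)
class CandidatePixel:
    """A per-A-line detection, at most one per row.

    ``dist`` is the peak-to-shadow distance; ``slope`` the (negative)
    intensity change per depth pixel between the peak and the shadow
    start.
    """

    frame_index: int
    aline: int
    peak_depth: int
    peak_intensity: float
    shadow_start_depth: int
    dist: int
    slope: float

    def __post_init__(self) -> None:
        if self.shadow_start_depth <= self.peak_depth:
            raise ValueError("shadow must start behind the peak")
        if self.dist != self.shadow_start_depth - self.peak_depth:
            raise ValueError("dist must equal shadow_start_depth - peak_depth")
        if self.slope > 0:
            raise ValueError("slope must be <= 0")


def compute_shadow_intensity_threshold(
    pullback: Pullback, roi: RoiBoundary, percentile: float = 0.89
) -> int:
    """Maximum intensity of a shadow pixel.

    The order statistic at rank ``ceil(p * N)`` over all ROI pixels
    (columns >= the catheter boundary) of every frame, same percentile
    convention as the noise floor.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must lie in (0, 1)")
    roi_pixels = pullback.stack[:, :, roi.catheter_column :]
    if roi_pixels.size == 0:
        raise ValueError("ROI is empty")
    return _order_statistic(roi_pixels, percentile)


def find_aline_peak(
    frame: Frame, aline: int, roi: RoiBoundary
) -> tuple[int, int] | None:
    """Maximum-intensity pixel of one A-line inside the ROI.

    Ties break toward the smallest depth (the strut front edge is the
    quantity of interest).  Returns ``None`` when the whole row is 0.
    """
    row = frame.pixels[aline, roi.catheter_column :]
    if row.size == 0:
        return None
    peak_offset = int(np.argmax(row))  # argmax takes the first maximum
    peak_val = int(row[peak_offset])
    if peak_val == 0:
        return None
    return peak_offset + roi.catheter_column, peak_val


def find_shadow_start(
    frame: Frame,
    aline: int,
    from_depth: int,
    shadow_threshold: float,
    window: int,
) -> int | None:
    """First pixel of the trailing shadow behind ``from_depth``.

    The smallest column ``d > from_depth`` such that all pixels in
    ``[d, d + window)`` are at most ``shadow_threshold``.  At the far
    image edge the window may be truncated, but only if at least half
    of it remains — otherwise deep struts near the border would never
    cast a detectable shadow.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    row = frame.pixels[aline]
    n = row.size
    low = row <= shadow_threshold
    # run[d] = length of the consecutive low-run starting at d, computed
    # from the next position where `low` is False
    idx = np.arange(n)
    false_pos = np.flatnonzero(~low)
    if false_pos.size:
        j = np.searchsorted(false_pos, idx)
        next_false = np.where(j < false_pos.size, false_pos[np.minimum(j, false_pos.size - 1)], n)
    else:
        next_false = np.full(n, n)
    run = np.where(low, next_false - idx, 0)
    remaining = n - idx
    needed = np.minimum(window, remaining)
    ok = (idx > from_depth) & (remaining >= window / 2) & (run >= needed)
    hits = np.flatnonzero(ok)
    return int(hits[0]) if hits.size else None


def detect_candidates(
    frame: Frame,
    roi: RoiBoundary,
    shadow_threshold: float,
    slope_threshold: float,
    window: int,
) -> list[CandidatePixel]:
    """One candidate per A-line whose peak-to-shadow slope is steep enough.

    Assumes a single strut per A-line (overlapping stents are out of
    scope), so each row contributes at most one candidate: the row
    maximum, kept iff a trailing shadow exists behind it and
    ``slope <= slope_threshold``.
    """
    out: list[CandidatePixel] = []
    for aline in range(frame.n_alines):
        peak = find_aline_peak(frame, aline, roi)
        if peak is None:
            continue
        peak_depth, peak_intensity = peak
        start = find_shadow_start(frame, aline, peak_depth, shadow_threshold, window)
        if start is None:
            continue
        dist = start - peak_depth
        slope = (float(frame.pixels[aline, start]) - peak_intensity) / dist
        if slope <= slope_threshold:
            out.append(
                CandidatePixel(
                    frame_index=frame.frame_index,
                    aline=aline,
                    peak_depth=peak_depth,
                    peak_intensity=peak_intensity,
                    shadow_start_depth=start,
                    dist=dist,
                    slope=slope,
                )
            )
    return out
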