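"""Noise-floor removal and catheter-artifact ROI definition.

The noise floor comes from the global intensity histogram of the whole
pullback: the lowest fraction (default 5%) of pixel values is treated as
noise and zeroed.  Catheter ring artifacts — constant bright vertical
lines near depth 0 in every frame — are found on the z-minimum image
(minimum over frames), where moving tissue is suppressed but
frame-constant artifacts survive; the ROI is everything to the right of
the rightmost artifact line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from octstrut.pullback_io import DetectionParameters, Frame, Pullback


@dataclass(frozen=True)
class RoiBoundary:
    """ROI = depth columns >= ``catheter_column``, for every A-line and frame."""

    catheter_column: int

    def __post_init__(self) -> None:
        if self.catheter_column < 0:
            raise ValueError("catheter_column must be >= 0")


def _order_statistic(values: np.ndarray, p: float) -> int:
    # Rank-based percentile on the integer pixel multiset: the order
    # statistic at rank ceil(p * N), no interpolation.
    n = values.size
    if n == 0:
        raise ValueError("cannot take a percentile of an empty pixel set")
    rank = math.ceil(p * n)  # 1-based; p in (0,1) so 1 <= rank <= n
    flat = values.ravel()
    return int(np.partition(flat, rank - 1)[rank - 1])


def compute_noise_floor(pullback: Pullback, noise_percentile: float = 0.05) -> int:
    """Intensity threshold below which pixels are considered noise.

    Returns the order statistic at rank ``ceil(p * N)`` of the sorted
    pixel multiset of the entire pullback, so that the fraction of
    pixels strictly below the threshold is the largest fraction <= p.
    """
    if not 0.0 < noise_percentile < 1.0:
        raise ValueError("noise_percentile must lie in (0, 1)")
    return _order_statistic(pullback.stack, noise_percentile)


def apply_noise_floor(pullback: Pullback, threshold: int) -> Pullback:
    """Zero every pixel with intensity strictly below ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = pullback.stack.copy()
    out[out < threshold] = 0
    return Pullback(out, pixel_size_mm=pullback.pixel_size_mm)


def compute_catheter_boundary(
    pullback: Pullback,
    noise_floor: int | None = None,
    params: DetectionParameters | None = None,
) -> RoiBoundary:
    """Locate the catheter ring artifacts and return the ROI boundary.

    A depth column of the z-minimum image counts as an artifact line
    when at least ``line_row_fraction`` of its rows stay above the
    noise floor in *every* frame; only the leftmost
    ``line_search_fraction`` of columns are searched, since the
    artifacts sit next to the catheter.  The boundary is one column
    right of the rightmost line, or 0 when no line is found.
    """
    params = params or DetectionParameters()
    if noise_floor is None:
        noise_floor = compute_noise_floor(pullback, params.noise_percentile)
    zmin = pullback.stack.min(axis=0)  # (n_alines, n_depth)
    above = zmin > noise_floor
    col_fraction = above.mean(axis=0)
    window = max(1, int(round(params.line_search_fraction * pullback.n_depth)))
    line_cols = np.flatnonzero(col_fraction[:window] >= params.line_row_fraction)
    if line_cols.size == 0:
        return RoiBoundary(0)
    return RoiBoundary(int(line_cols[-1]) + 1)


def apply_roi(frame: Frame, roi: RoiBoundary) -> Frame:
    """Zero the columns left of the catheter boundary."""
    if roi.catheter_column == 0:
        return frame
    out = frame.pixels.copy()
    out[:, : roi.catheter_column] = 0
    return Frame(out, frame_index=frame.frame_index)
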