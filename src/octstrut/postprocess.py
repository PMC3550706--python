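"""3D false-positive removal: guide wire and non-stented frames.

A guide wire reflects like a strut and casts the same trailing shadow,
but it has two tell-tale spatial properties: it sits closer to the
imaging catheter than any strut, and its position is continuous from
frame to frame throughout the whole pullback.  The filter chains the
closest-to-catheter detection of each frame and accepts the chain as a
guide wire only if it covers most of the pullback; pullbacks acquired
without a guide wire are left untouched.

The pullback is normally much longer than the stent, so frames outside
the stented segment hold no true struts.  The segment is recovered from
the per-frame strut counts (smoothed, thresholded); detections outside
are re-flagged rather than deleted, keeping the audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from octstrut.pullback_io import DetectionParameters, StrutRecord, wrap_distance


@dataclass(frozen=True)
class GuideWireTrack:
    """Per-frame guide-wire positions forming a continuous chain."""

    entries: dict[int, tuple[int, int]]  # frame -> (aline, depth)

    @property
    def n_frames_covered(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class StentedSegment:
    """Inclusive frame range [first_frame, last_frame] containing the stent."""

    first_frame: int
    last_frame: int

    def __post_init__(self) -> None:
        if self.first_frame > self.last_frame:
            raise ValueError("first_frame must be <= last_frame")

    def contains(self, frame: int) -> bool:
        return self.first_frame <= frame <= self.last_frame


def detect_guide_wire(
    per_frame_struts: dict[int, list[StrutRecord]],
    n_frames: int,
    n_alines: int,
    params: DetectionParameters | None = None,
) -> GuideWireTrack | None:
    """Search for a continuous closest-to-catheter track across frames.

    Per frame the active detection with minimal depth is the track
    candidate; candidates in consecutive frames link when their
    wrap-aware distance is at most the guide-wire distance threshold.
    The longest consecutive linked run must cover at least
    ``min_track_fraction`` of the frames, otherwise there is no guide
    wire and nothing will be removed.
    """
    params = params or DetectionParameters()
    if n_frames < 2:
        return None
    closest: dict[int, tuple[int, int]] = {}
    for f in range(n_frames):
        active = [r for r in per_frame_struts.get(f, []) if r.active]
        if active:
            best = min(active, key=lambda r: (r.depth, r.aline))
            closest[f] = (best.aline, best.depth)
    if not closest:
        return None
    # longest run of consecutive frames whose candidates chain
    best_run: tuple[int, int] | None = None  # (start, end) inclusive
    start: int | None = None
    prev: tuple[int, int] | None = None

    def close_run(end: int) -> None:
        nonlocal best_run
        if start is not None and (
            best_run is None or end - start > best_run[1] - best_run[0]
        ):
            best_run = (start, end)

    for f in range(n_frames):
        cur = closest.get(f)
        if cur is None:
            close_run(f - 1)
            start, prev = None, None
        elif start is None:
            start, prev = f, cur
        elif (
            wrap_distance(cur, prev, n_alines)
            <= params.guide_wire_distance_threshold
        ):
            prev = cur
        else:
            close_run(f - 1)
            start, prev = f, cur
    close_run(n_frames - 1)
    if best_run is None:
        return None
    coverage = (best_run[1] - best_run[0] + 1) / n_frames
    if coverage < params.min_track_fraction:
        return None
    entries = {f: closest[f] for f in range(best_run[0], best_run[1] + 1)}
    return GuideWireTrack(entries=entries)


def remove_guide_wire(
    per_frame_struts: dict[int, list[StrutRecord]],
    track: GuideWireTrack | None,
    n_alines: int,
    params: DetectionParameters | None = None,
) -> dict[int, list[StrutRecord]]:
    """Re-flag the detection on the guide-wire track in each frame.

    At most one detection per frame is flagged (the nearest one within
    the acceptance distance of the track entry); with no track this is
    the identity.
    """
    params = params or DetectionParameters()
    if track is None:
        return {f: list(rs) for f, rs in per_frame_struts.items()}
    out: dict[int, list[StrutRecord]] = {}
    for f, records in per_frame_struts.items():
        entry = track.entries.get(f)
        if entry is None:
            out[f] = list(records)
            continue
        best_i, best_d = None, None
        for i, r in enumerate(records):
            if not r.active:
                continue
            d = wrap_distance((r.aline, r.depth), entry, n_alines)
            if d <= params.acceptance_distance and (best_d is None or d < best_d):
                best_i, best_d = i, d
        new = list(records)
        if best_i is not None:
            new[best_i] = replace(records[best_i], kind="guide_wire_removed")
        out[f] = new
    return out


def detect_stented_segment(
    per_frame_struts: dict[int, list[StrutRecord]],
    n_frames: int,
    params: DetectionParameters | None = None,
) -> tuple[StentedSegment | None, dict[int, list[StrutRecord]]]:
    """Find the stented frame range and re-flag detections outside it.

    The per-frame active strut counts are smoothed with a moving
    average; the segment is the longest contiguous run of frames whose
    smoothed count reaches ``segment_min_count``.  Returns the segment
    (``None`` when no frame qualifies — every detection is then
    flagged) and the updated per-frame records.
    """
    params = params or DetectionParameters()
    counts = np.zeros(n_frames, dtype=float)
    for f in range(n_frames):
        counts[f] = sum(1 for r in per_frame_struts.get(f, []) if r.active)
    smoothed = uniform_filter1d(
        counts, size=max(1, int(params.segment_smooth_window)), mode="nearest"
    )
    inside = smoothed >= params.segment_min_count
    segment = None
    best_len = 0
    start = None
    for f in range(n_frames + 1):
        if f < n_frames and inside[f]:
            if start is None:
                start = f
        elif start is not None:
            if f - start > best_len:
                best_len = f - start
                segment = StentedSegment(start, f - 1)
            start = None
    out: dict[int, list[StrutRecord]] = {}
    for f in range(n_frames):
        records = list(per_frame_struts.get(f, []))
        if segment is None or not segment.contains(f):
            records = [
                replace(r, kind="outside_segment_removed") if r.active else r
                for r in records
            ]
        out[f] = records
    return segment, out
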