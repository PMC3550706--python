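"""Trailing-shadow edge detection with directional Prewitt compass kernels.

Trailing shadows align with the imaging beam, so in the polar frame they
run almost horizontally (along depth).  After Gaussian smoothing, two
3x3 horizontal Prewitt kernels pick up their boundaries: the *top*
kernel responds where the row above is brighter than the row below
(bright-to-dark going down), the *bottom* kernel is its negation.  Edges
are connected supra-threshold runs along the depth axis; only edges
longer than a minimum depth extent are kept, which discards the short
false edges of e.g. an eccentric lumen boundary.  A paired top and
bottom edge delimit one shadow's angular interval, the clustering region
for the strut that casts it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from octstrut.pullback_io import Frame


@dataclass(frozen=True)
class ShadowEdge:
    """A horizontal bright<->dark transition bounding a trailing shadow."""

    kind: str  # "top" | "bottom"
    aline: int
    depth_start: int
    depth_end: int

    def __post_init__(self) -> None:
        if self.kind not in ("top", "bottom"):
            raise ValueError(f"edge kind must be top|bottom, got {self.kind!r}")
        if self.depth_end < self.depth_start:
            raise ValueError("depth_end must be >= depth_start")

    @property
    def length(self) -> int:
        return self.depth_end - self.depth_start + 1


@dataclass(frozen=True)
class EdgeInterval:
    """The angular span between a paired top and bottom shadow edge.

    One of the edges may be missing (blurred or too short); the span then
    collapses onto the surviving edge's row.  ``row_lo`` precedes
    ``row_hi`` in wrap-aware angular order.
    """

    top_edge: ShadowEdge | None
    bottom_edge: ShadowEdge | None
    row_lo: int
    row_hi: int

    def __post_init__(self) -> None:
        if self.top_edge is None and self.bottom_edge is None:
            raise ValueError("an interval needs at least one edge")

    @property
    def two_sided(self) -> bool:
        return self.top_edge is not None and self.bottom_edge is not None

    def rows(self, n_alines: int) -> list[int]:
        """All A-line rows of the interval in wrap-aware order."""
        span = (self.row_hi - self.row_lo) % n_alines
        return [(self.row_lo + k) % n_alines for k in range(span + 1)]


def smooth_frame(frame: Frame, sigma: float) -> Frame:
    """Gaussian smoothing; the angular axis wraps, the depth axis reflects."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    out = ndimage.gaussian_filter(
        frame.pixels.astype(np.float64), sigma=sigma, mode=("wrap", "reflect")
    )
    return Frame(out, frame_index=frame.frame_index)


def _prewitt_horizontal(pixels: np.ndarray) -> np.ndarray:
    # Correlation with [[1,1,1],[0,0,0],[-1,-1,-1]]: row above minus row
    # below, summed over a 3-column neighbourhood.  Rows wrap (polar
    # angle), columns reflect.
    p = np.asarray(pixels, dtype=np.float64)
    padded = np.pad(p, ((0, 0), (1, 1)), mode="reflect")
    diff = np.roll(padded, 1, axis=0) - np.roll(padded, -1, axis=0)
    return diff[:, :-2] + diff[:, 1:-1] + diff[:, 2:]


def compass_response(frame: Frame, kind: str) -> np.ndarray:
    """Signed response of the top or bottom horizontal Prewitt kernel."""
    resp = _prewitt_horizontal(frame.pixels)
    if kind == "top":
        return resp
    if kind == "bottom":
        return -resp
    raise ValueError(f"edge kind must be top|bottom, got {kind!r}")


def _merge_wrap_labels(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Union labels that touch across the angular seam (rows 0 and n-1)."""
    n_rows, n_cols = mask.shape
    if n_rows < 2:
        return labels
    parent = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    top_row, bot_row = labels[0], labels[n_rows - 1]
    for c in range(n_cols):
        if not mask[n_rows - 1, c]:
            continue
        for dc in (-1, 0, 1):
            cc = c + dc
            if 0 <= cc < n_cols and mask[0, cc]:
                union(int(bot_row[c]), int(top_row[cc]))
    if not parent:
        return labels
    out = labels.copy()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        root = find(int(lab))
        if root != lab:
            out[labels == lab] = root
    return out


def _edge_has_shadow_contrast(
    intensity: np.ndarray,
    kind: str,
    row: int,
    depth_start: int,
    depth_end: int,
    contrast_ratio: float,
) -> bool:
    # A trailing-shadow edge must actually separate tissue from shadow:
    # the bright side has to outshine the dark side over the edge's span.
    # This rejects the spurious long runs an automatic response threshold
    # produces on frames without any shadow.
    n_rows = intensity.shape[0]
    sign = -1 if kind == "top" else 1  # direction of the bright side
    span = slice(depth_start, depth_end + 1)
    # the edge row can sit 1-2 rows off the true boundary and the shadow
    # band may be narrow, so compare the brightest nearby row on the
    # bright side with the darkest nearby row on the dark side
    bright = max(
        float(intensity[(row + sign * k) % n_rows, span].mean()) for k in (0, 1, 2, 3)
    )
    dark = min(
        float(intensity[(row - sign * k) % n_rows, span].mean()) for k in (1, 2, 3, 4)
    )
    return bright >= contrast_ratio * (dark + 1e-6)


def extract_edges(
    response: np.ndarray,
    kind: str,
    length_threshold: int,
    response_threshold: float | None = None,
    intensity: np.ndarray | None = None,
    contrast_ratio: float = 2.0,
) -> list[ShadowEdge]:
    """Threshold a compass response and keep the long connected edges.

    Supra-threshold pixels are grouped into per-row runs along the depth
    axis; runs on adjacent rows (including across the angular seam) are
    merged into one edge, which keeps the span of its longest row.  With
    ``response_threshold=None`` the threshold is Otsu's on the positive
    responses of this frame.  When the (smoothed) ``intensity`` image is
    given, an edge is additionally required to separate a bright side
    from a side darker by ``contrast_ratio`` — a trailing shadow — which
    guards against threshold artefacts on shadow-free frames.
    """
    if length_threshold < 1:
        raise ValueError("length_threshold must be >= 1")
    resp = np.asarray(response, dtype=np.float64)
    if response_threshold is None:
        positive = resp[resp > 0]
        if positive.size == 0 or np.all(positive == positive.flat[0]):
            return []
        # Otsu in the log domain: edge strength spans orders of magnitude
        # (strut-blob transitions dwarf the tissue/shadow boundary), and a
        # linear-domain Otsu would lock onto the blobs only.
        response_threshold = float(np.exp(threshold_otsu(np.log(positive))))
    mask = resp > response_threshold
    if not mask.any():
        return []
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    labels = _merge_wrap_labels(labels, mask)
    edges: list[ShadowEdge] = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rows, cols = np.nonzero(labels == lab)
        best = None  # (run_length, row, start, end)
        for r in np.unique(rows):
            cs = np.sort(cols[rows == r])
            # longest contiguous run within this row
            breaks = np.flatnonzero(np.diff(cs) > 1)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [cs.size - 1]))
            k = int(np.argmax(ends - starts))
            run = (
                int(ends[k] - starts[k] + 1),
                int(r),
                int(cs[starts[k]]),
                int(cs[ends[k]]),
            )
            if best is None or run[0] > best[0]:
                best = run
        length, row, start, end = best
        if length < length_threshold:
            continue
        if intensity is not None and not _edge_has_shadow_contrast(
            intensity, kind, row, start, end, contrast_ratio
        ):
            continue
        edges.append(ShadowEdge(kind=kind, aline=row, depth_start=start, depth_end=end))
    edges.sort(key=lambda e: (e.aline, e.depth_start))
    return edges


def pair_edges(
    tops: list[ShadowEdge], bottoms: list[ShadowEdge], n_alines: int
) -> list[EdgeInterval]:
    """Pair each top edge with the nearest bottom edge below it (wrap-aware).

    Pairs are claimed greedily in order of increasing forward angular
    distance (top -> bottom modulo ``n_alines``), so the result does not
    depend on input order.  Edges left unpaired become one-sided
    intervals — often the other shadow edge is too short or blurred.
    """
    pairs = []
    for i, t in enumerate(tops):
        for j, b in enumerate(bottoms):
            fwd = (b.aline - t.aline) % n_alines
            pairs.append((fwd, t.aline, b.aline, i, j))
    pairs.sort()
    used_t: set[int] = set()
    used_b: set[int] = set()
    intervals: list[EdgeInterval] = []
    for fwd, _, _, i, j in pairs:
        if i in used_t or j in used_b:
            continue
        used_t.add(i)
        used_b.add(j)
        intervals.append(
            EdgeInterval(
                top_edge=tops[i],
                bottom_edge=bottoms[j],
                row_lo=tops[i].aline,
                row_hi=bottoms[j].aline,
            )
        )
    for i, t in enumerate(tops):
        if i not in used_t:
            intervals.append(EdgeInterval(t, None, t.aline, t.aline))
    for j, b in enumerate(bottoms):
        if j not in used_b:
            intervals.append(EdgeInterval(None, b, b.aline, b.aline))
    intervals.sort(key=lambda iv: iv.row_lo)
    return intervals
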