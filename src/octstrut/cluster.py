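"""Clustering of candidate pixels into struts, guided by shadow edges.

Candidate pixels agglomerate by single linkage: two clusters merge while
the minimal member distance is shorter than the clustering threshold
(wrap-aware Euclidean, 4 pixels at clinical scale).  The shadow edges
then arbitrate: the strut sits right below its shadow's top edge and
right above its bottom edge, so for each top edge the first cluster
below it, and for each bottom edge the first cluster above it, are
selected; everything else (tissue false positives, seam artifacts) is
dropped.  Shadows with both edges but no candidate inside may hide a
non-bright strut — a dim strut far from the catheter or under thick
neointima — recovered from the brightest per-A-line pixels near the
shadow start.  A cluster's strut position is the (wrap-aware) average
of its members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from octstrut.candidate_detect import CandidatePixel
from octstrut.pullback_io import DetectionParameters, Frame, StrutRecord
from octstrut.shadow_edges import EdgeInterval


@dataclass(frozen=True)
class NonBrightPixel:
    """A recovered dim-strut pixel (the per-A-line maximum in the shadow)."""

    aline: int
    depth: int
    intensity: float

    @property
    def peak_depth(self) -> int:  # same coordinate accessor as CandidatePixel
        return self.depth


@dataclass
class StrutCluster:
    members: list
    kind: str = "bright"  # bright | non_bright
    interval: EdgeInterval | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a cluster needs at least one member")

    def centroid(self, n_alines: int) -> tuple[float, float]:
        """(circular-mean row, mean depth) of the members."""
        rows = np.array([m.aline for m in self.members], dtype=float)
        depths = np.array([m.peak_depth for m in self.members], dtype=float)
        ang = rows * (2.0 * math.pi / n_alines)
        mean_ang = math.atan2(np.sin(ang).sum(), np.cos(ang).sum())
        row = (mean_ang * n_alines / (2.0 * math.pi)) % n_alines
        return row, float(depths.mean())


def agglomerate(
    candidates: list[CandidatePixel], merge_distance: float, n_alines: int
) -> list[StrutCluster]:
    """Single-linkage agglomeration of candidate pixels.

    Starts from singleton clusters and merges while the minimal
    inter-cluster distance is strictly below ``merge_distance``; this is
    exactly the connected components of the graph whose edges join
    candidates closer than the threshold.  The row axis wraps, so
    candidates at the top and bottom of the polar frame can belong to
    the same strut.  The partition is independent of input order.
    """
    n = len(candidates)
    if n == 0:
        return []
    rows = np.array([c.aline for c in candidates], dtype=float)
    depths = np.array([c.peak_depth for c in candidates], dtype=float)
    dr = np.abs(rows[:, None] - rows[None, :])
    dr = np.minimum(dr, n_alines - dr)
    dist = np.hypot(dr, depths[:, None] - depths[None, :])
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in zip(*np.nonzero(np.triu(dist < merge_distance, k=1))):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[CandidatePixel]] = {}
    for i, c in enumerate(candidates):
        groups.setdefault(find(i), []).append(c)
    clusters = [StrutCluster(members=sorted(ms, key=lambda m: (m.aline, m.peak_depth)))
                for ms in groups.values()]
    clusters.sort(key=lambda cl: (cl.members[0].aline, cl.members[0].peak_depth))
    return clusters


def _forward(a: float, b: float, n: int) -> float:
    return (b - a) % n


def select_clusters(
    clusters: list[StrutCluster],
    intervals: list[EdgeInterval],
    n_alines: int,
) -> list[StrutCluster]:
    """Keep only clusters adjacent to a shadow edge.

    For each top edge the first cluster below it (smallest forward
    angular distance from the edge row to the cluster centroid), for
    each bottom edge the first cluster above it; the union of the
    selections survives, each cluster at most once even when both edges
    of its interval pick it.  With no edges everything is removed.
    """
    if not clusters or not intervals:
        return []
    centroids = [cl.centroid(n_alines) for cl in clusters]
    selected: dict[int, StrutCluster] = {}
    for iv in intervals:
        for edge, below in ((iv.top_edge, True), (iv.bottom_edge, False)):
            if edge is None:
                continue
            if below:
                dists = [_forward(edge.aline, c[0], n_alines) for c in centroids]
            else:
                dists = [_forward(c[0], edge.aline, n_alines) for c in centroids]
            k = int(np.argmin(dists))
            if k not in selected:
                cl = clusters[k]
                cl.interval = iv
                selected[k] = cl
    return [selected[k] for k in sorted(selected)]


def interval_has_cluster(
    interval: EdgeInterval, clusters: list[StrutCluster], n_alines: int
) -> bool:
    """True when some cluster centroid lies within the interval's rows."""
    span = (interval.row_hi - interval.row_lo) % n_alines
    for cl in clusters:
        row, _ = cl.centroid(n_alines)
        if _forward(interval.row_lo, row, n_alines) <= span + 0.5:
            return True
    return False


def recover_non_bright(
    frame: Frame,
    interval: EdgeInterval,
    shadow_threshold: float,
    params: DetectionParameters | None = None,
) -> StrutCluster | None:
    """Look for a non-bright strut inside a two-edged but empty shadow.

    The search range spans the interval's rows and a depth window
    around the edges' start columns; per row the maximum-intensity
    pixel is taken and kept when it exceeds the shadow-intensity
    threshold.  Enough surviving pixels form a cluster flagged
    ``non_bright``.
    """
    params = params or DetectionParameters()
    if not interval.two_sided:
        return None
    n_alines, n_depth = frame.n_alines, frame.n_depth
    # anchor on the deeper of the two edge starts: an edge run can begin
    # shallow of the strut where tissue contrast already exists, and a
    # window anchored there would let foreground tissue win the per-row
    # maximum instead of the dim strut
    start = max(interval.top_edge.depth_start, interval.bottom_edge.depth_start)
    lo = max(0, start - params.non_bright_depth_back)
    hi = min(n_depth, start + params.non_bright_depth_forward + 1)
    if hi <= lo:
        return None
    members: list[NonBrightPixel] = []
    for row in interval.rows(n_alines):
        segment = frame.pixels[row, lo:hi]
        k = int(np.argmax(segment))
        val = float(segment[k])
        if val > shadow_threshold:
            members.append(NonBrightPixel(aline=row, depth=lo + k, intensity=val))
    if len(members) < params.min_non_bright_pixels:
        return None
    return StrutCluster(members=members, kind="non_bright", interval=interval)


def cluster_to_strut(
    cluster: StrutCluster, n_alines: int, frame_index: int
) -> StrutRecord:
    """Strut position = rounded wrap-aware mean of the member pixels."""
    row, depth = cluster.centroid(n_alines)
    return StrutRecord(
        frame=frame_index,
        aline=int(np.round(row)) % n_alines,
        depth=int(np.round(depth)),
        kind=cluster.kind,
    )
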