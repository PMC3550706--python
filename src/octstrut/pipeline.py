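"""End-to-end detection pipeline in the fixed stage order.

preprocess -> candidate pixels -> shadow edges -> clustering ->
3D false-positive removal.  The whole pipeline is deterministic:
identical input and parameters give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from octstrut import candidate_detect, cluster, postprocess, preprocess, shadow_edges
from octstrut.postprocess import GuideWireTrack, StentedSegment
from octstrut.preprocess import RoiBoundary
from octstrut.pullback_io import DetectionParameters, Pullback, StrutRecord


@dataclass
class DetectionResult:
    """Everything a detection run produced, including the audit trail.

    ``records`` holds every detection with its final ``kind``; filtered
    detections stay in the list flagged ``guide_wire_removed`` or
    ``outside_segment_removed``.  ``stage_log`` has one entry per stage
    with the counts a run log reports.
    """

    records: list[StrutRecord]
    per_frame: dict[int, list[StrutRecord]]
    noise_floor: int
    shadow_threshold: float
    roi: RoiBoundary
    guide_wire_track: GuideWireTrack | None
    stented_segment: StentedSegment | None
    params: DetectionParameters
    stage_log: list[dict] = field(default_factory=list)

    @property
    def struts(self) -> list[StrutRecord]:
        """Only the detections that still count as struts."""
        return [r for r in self.records if r.active]


def detect_pullback(
    pullback: Pullback,
    params: DetectionParameters | None = None,
    guide_wire_filter: bool = True,
    segment_filter: bool = True,
    shadow_threshold_override: float | None = None,
) -> DetectionResult:
    """Run the full strut detection pipeline on one pullback.

    With ``params=None`` the clinical-scale defaults are rescaled to the
    pullback's frame size.  ``shadow_threshold_override`` replaces the
    histogram-derived shadow-intensity threshold (used by the parameter
    sweep).  The guide-wire and stented-segment filters can be disabled
    individually; disabled filters flag nothing.
    """
    if params is None:
        params = DetectionParameters().scaled_for(pullback.n_alines, pullback.n_depth)
    log: list[dict] = []

    # --- preprocessing: noise floor + catheter ROI
    noise_floor = preprocess.compute_noise_floor(pullback, params.noise_percentile)
    floored = preprocess.apply_noise_floor(pullback, noise_floor)
    roi = preprocess.compute_catheter_boundary(floored, noise_floor, params)
    log.append(
        {"stage": "preprocess", "noise_floor": noise_floor, "catheter_column": roi.catheter_column}
    )

    if shadow_threshold_override is not None:
        shadow_thr = float(shadow_threshold_override)
    else:
        shadow_thr = float(
            candidate_detect.compute_shadow_intensity_threshold(
                floored, roi, params.shadow_intensity_percentile
            )
        )

    n_alines = pullback.n_alines
    per_frame: dict[int, list[StrutRecord]] = {}
    n_candidates = n_edges = n_clusters = n_recovered = 0

    for f in range(pullback.n_frames):
        frame = preprocess.apply_roi(floored.frame(f), roi)

        candidates = candidate_detect.detect_candidates(
            frame, roi, shadow_thr, params.slope_threshold, params.sliding_shadow_size
        )
        n_candidates += len(candidates)

        smoothed = shadow_edges.smooth_frame(frame, params.gaussian_sigma)
        top_resp = shadow_edges.compass_response(smoothed, "top")
        tops = shadow_edges.extract_edges(
            top_resp, "top", params.edge_length_threshold,
            params.edge_response_threshold, smoothed.pixels, params.edge_contrast_ratio,
        )
        bottoms = shadow_edges.extract_edges(
            -top_resp, "bottom", params.edge_length_threshold,
            params.edge_response_threshold, smoothed.pixels, params.edge_contrast_ratio,
        )
        intervals = shadow_edges.pair_edges(tops, bottoms, n_alines)
        n_edges += len(tops) + len(bottoms)

        clusters = cluster.agglomerate(
            candidates, params.clustering_distance_threshold, n_alines
        )
        selected = cluster.select_clusters(clusters, intervals, n_alines)
        n_clusters += len(selected)

        recovered = []
        for iv in intervals:
            if not iv.two_sided:
                continue
            if cluster.interval_has_cluster(iv, clusters, n_alines):
                continue
            rec = cluster.recover_non_bright(frame, iv, shadow_thr, params)
            if rec is not None:
                recovered.append(rec)
        n_recovered += len(recovered)

        per_frame[f] = [
            cluster.cluster_to_strut(cl, n_alines, f) for cl in selected + recovered
        ]

    log.append({"stage": "candidate_detect", "shadow_threshold": shadow_thr, "candidates": n_candidates})
    log.append({"stage": "shadow_edges", "edges": n_edges})
    log.append({"stage": "cluster", "selected_clusters": n_clusters, "non_bright_recovered": n_recovered})

    # --- 3D false-positive removal (guide wire first, then segment)
    track = None
    if guide_wire_filter:
        track = postprocess.detect_guide_wire(per_frame, pullback.n_frames, n_alines, params)
    per_frame = postprocess.remove_guide_wire(per_frame, track, n_alines, params)
    segment = None
    if segment_filter:
        segment, per_frame = postprocess.detect_stented_segment(
            per_frame, pullback.n_frames, params
        )
    log.append(
        {
            "stage": "postprocess",
            "guide_wire_frames": track.n_frames_covered if track else 0,
            "segment": (segment.first_frame, segment.last_frame) if segment else None,
        }
    )

    records = sorted(
        (r for rs in per_frame.values() for r in rs),
        key=lambda r: (r.frame, r.aline, r.depth),
    )
    return DetectionResult(
        records=records,
        per_frame=per_frame,
        noise_floor=noise_floor,
        shadow_threshold=shadow_thr,
        roi=roi,
        guide_wire_track=track,
        stented_segment=segment,
        params=params,
        stage_log=log,
    )
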