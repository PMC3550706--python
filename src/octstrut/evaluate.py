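"""Validation protocol: tolerance matching, sensitivity, FP ratio, sweep.

Detections and reference annotations are matched per frame, one-to-one,
by optimal assignment on the wrap-aware pixel distance; only pairs
within the acceptance distance (10 pixels, about 0.05 mm, at clinical
scale) count.  Sensitivity is true positives over reference struts; the
false-positive ratio is unmatched detections over reference struts.
Distance statistics are computed over matched pairs only.  The same
matcher in inter-observer mode scores two annotation sets against each
other (agreements over the mean of the two counts).

``parameter_sweep`` reruns the whole pipeline with each of the five
main parameters at its recommended value and +/-20%, reporting
sensitivity, FP ratio and distance error per cell.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from octstrut.pullback_io import (
    DetectionParameters,
    Pullback,
    StrutRecord,
    wrap_distance,
)

_UNMATCHABLE = 1e9


@dataclass
class MatchResult:
    pairs: list[tuple[StrutRecord, StrutRecord, float]]  # (detected, truth, dist)
    unmatched_detected: list[StrutRecord]
    unmatched_truth: list[StrutRecord]


@dataclass
class EvaluationReport:
    n_truth: int
    n_detected: int
    n_true_positive: int
    n_false_positive: int
    sensitivity: float
    fp_ratio: float
    distance_mean_px: float
    distance_sd_px: float
    by_category: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def match_detections(
    detected: list[StrutRecord],
    truth: list[StrutRecord],
    acceptance_distance: float,
    n_alines: int,
) -> MatchResult:
    """Optimal one-to-one matching within the acceptance distance.

    Frames are matched independently.  The assignment maximises the
    number of within-tolerance pairs and, among those, minimises the
    total distance; each detection and each reference strut is used at
    most once.  Order-independent by construction.
    """
    frames = sorted({r.frame for r in detected} | {r.frame for r in truth})
    pairs: list[tuple[StrutRecord, StrutRecord, float]] = []
    un_det: list[StrutRecord] = []
    un_tru: list[StrutRecord] = []
    for f in frames:
        dets = sorted(
            (r for r in detected if r.frame == f), key=lambda r: (r.aline, r.depth)
        )
        trus = sorted(
            (r for r in truth if r.frame == f), key=lambda r: (r.aline, r.depth)
        )
        if not dets or not trus:
            un_det.extend(dets)
            un_tru.extend(trus)
            continue
        cost = np.full((len(dets), len(trus)), _UNMATCHABLE)
        for i, d in enumerate(dets):
            for j, t in enumerate(trus):
                dist = wrap_distance((d.aline, d.depth), (t.aline, t.depth), n_alines)
                if dist <= acceptance_distance:
                    cost[i, j] = dist
        rows, cols = linear_sum_assignment(cost)
        matched_i, matched_j = set(), set()
        for i, j in zip(rows, cols):
            if cost[i, j] < _UNMATCHABLE:
                pairs.append((dets[i], trus[j], float(cost[i, j])))
                matched_i.add(i)
                matched_j.add(j)
        un_det.extend(d for i, d in enumerate(dets) if i not in matched_i)
        un_tru.extend(t for j, t in enumerate(trus) if j not in matched_j)
    return MatchResult(pairs=pairs, unmatched_detected=un_det, unmatched_truth=un_tru)


def summarize(
    match: MatchResult,
    truth: list[StrutRecord],
    detected: list[StrutRecord],
    categories: dict[tuple[int, int, int], str] | None = None,
) -> EvaluationReport:
    """Sensitivity, FP ratio and distance-error statistics.

    ``categories`` optionally maps ``(frame, aline, depth)`` of a
    reference strut to a label (e.g. strut status or image quality) for
    per-category sensitivity breakdowns.
    """
    n_truth = len(truth)
    n_detected = len(detected)
    tp = len(match.pairs)
    fp = len(match.unmatched_detected)
    dists = np.array([d for _, _, d in match.pairs])
    report = EvaluationReport(
        n_truth=n_truth,
        n_detected=n_detected,
        n_true_positive=tp,
        n_false_positive=fp,
        sensitivity=tp / n_truth if n_truth else 0.0,
        fp_ratio=fp / n_truth if n_truth else 0.0,
        distance_mean_px=float(dists.mean()) if dists.size else float("nan"),
        distance_sd_px=float(dists.std(ddof=1)) if dists.size > 1 else float("nan"),
    )
    if categories:
        matched_keys = {(t.frame, t.aline, t.depth) for _, t, _ in match.pairs}
        by: dict[str, dict[str, float]] = {}
        for t in truth:
            key = (t.frame, t.aline, t.depth)
            label = categories.get(key)
            if label is None:
                continue
            entry = by.setdefault(label, {"n_truth": 0, "n_true_positive": 0})
            entry["n_truth"] += 1
            entry["n_true_positive"] += key in matched_keys
        for label, entry in by.items():
            entry["sensitivity"] = (
                entry["n_true_positive"] / entry["n_truth"] if entry["n_truth"] else 0.0
            )
        report.by_category = by
    return report


def interobserver_agreement(
    observer_a: list[StrutRecord],
    observer_b: list[StrutRecord],
    acceptance_distance: float,
    n_alines: int,
) -> float:
    """Agreements divided by the average strut count of the two observers."""
    if not observer_a and not observer_b:
        return float("nan")
    match = match_detections(observer_a, observer_b, acceptance_distance, n_alines)
    return len(match.pairs) / (0.5 * (len(observer_a) + len(observer_b)))


#: The five main parameters of the robustness sweep.
SWEEP_PARAMETERS = (
    "max_shadow_intensity_threshold",
    "sliding_shadow_size",
    "slope_threshold",
    "shadow_edge_length_threshold",
    "clustering_distance_threshold",
)


def parameter_sweep(
    pullback: Pullback,
    truth: list[StrutRecord],
    params: DetectionParameters,
    deltas: tuple[float, ...] = (-0.2, 0.0, 0.2),
    guide_wire_filter: bool = True,
) -> pd.DataFrame:
    """Rerun detection with each main parameter varied by the given deltas.

    The shadow-intensity threshold is a derived intensity value (a
    histogram percentile), so its variation is applied to the computed
    threshold rather than the percentile.  Integer-valued windows are
    rounded after scaling.  Returns one row per (parameter, delta) with
    sensitivity, FP ratio and distance statistics.
    """
    from octstrut.pipeline import detect_pullback  # deferred: avoid cycle

    baseline = detect_pullback(pullback, params, guide_wire_filter=guide_wire_filter)
    base_shadow_thr = baseline.shadow_threshold
    rows = []
    for name in SWEEP_PARAMETERS:
        for delta in deltas:
            scale = 1.0 + delta
            p = params
            override = None
            if name == "max_shadow_intensity_threshold":
                override = base_shadow_thr * scale
            elif name == "sliding_shadow_size":
                p = params.replace(
                    sliding_shadow_size=max(1, round(params.sliding_shadow_size * scale))
                )
            elif name == "slope_threshold":
                p = params.replace(slope_threshold=params.slope_threshold * scale)
            elif name == "shadow_edge_length_threshold":
                p = params.replace(
                    edge_length_threshold=max(1, round(params.edge_length_threshold * scale))
                )
            elif name == "clustering_distance_threshold":
                p = params.replace(
                    clustering_distance_threshold=params.clustering_distance_threshold * scale
                )
            result = detect_pullback(
                pullback,
                p,
                guide_wire_filter=guide_wire_filter,
                shadow_threshold_override=override,
            )
            active = [r for r in result.records if r.active]
            match = match_detections(active, truth, params.acceptance_distance, pullback.n_alines)
            report = summarize(match, truth, active)
            rows.append(
                {
                    "parameter": name,
                    "delta": delta,
                    "sensitivity": report.sensitivity,
                    "fp_ratio": report.fp_ratio,
                    "distance_mean_px": report.distance_mean_px,
                    "distance_sd_px": report.distance_sd_px,
                }
            )
    return pd.DataFrame(rows)
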