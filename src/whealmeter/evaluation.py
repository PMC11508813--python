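"""Scoring of predicted masks against reference masks.

Detection is scored by greedy one-to-one IoU matching of wheal clusters,
unmatched predictions counting as type I errors (spurious wheals) and
unmatched references as type II errors (missed wheals).  Segmentation
quality of each matched pair is scored on a confusion matrix restricted to
a padded window around the pair, so per-wheal metrics are not swamped by
distant background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from whealmeter.geometry import WhealCluster, cluster_pixels
from whealmeter.palette import CLASS_WHEAL


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for these inputs."""


@dataclass(frozen=True)
class DetectionOutcome:
    matched_pairs: tuple[tuple[int, int], ...]  # (predicted id, expected id)
    correct_detection: int
    expected_detection: int
    type1_errors: int  # predicted clusters with no expected match
    type2_errors: int  # expected clusters with no predicted match


@dataclass(frozen=True)
class ClusterMetrics:
    """Confusion-matrix scores for one matched wheal, within its window.

    Accuracy/sensitivity/specificity are percentages; DSC and IoU are 0-1.
    """

    predicted_id: int
    expected_id: int
    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    dsc: float
    iou: float
    window: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    pad_px: int


def _iou_of(a: WhealCluster, b: WhealCluster) -> float:
    sa = {(int(r), int(c)) for r, c in a.pixels}
    sb = {(int(r), int(c)) for r, c in b.pixels}
    inter = len(sa & sb)
    if inter == 0:
        return 0.0
    return inter / len(sa | sb)


def match_detections(
    predicted: list[WhealCluster], expected: list[WhealCluster]
) -> DetectionOutcome:
    """Greedy one-to-one matching by descending pairwise IoU (overlap > 0)."""
    pairs = [
        (iou, p.id, e.id)
        for p in predicted
        for e in expected
        if (iou := _iou_of(p, e)) > 0.0
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_e: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, pid, eid in pairs:
        if pid in used_p or eid in used_e:
            continue
        used_p.add(pid)
        used_e.add(eid)
        matched.append((pid, eid))
    return DetectionOutcome(
        matched_pairs=tuple(matched),
        correct_detection=len(matched),
        expected_detection=len(expected),
        type1_errors=len(predicted) - len(matched),
        type2_errors=len(expected) - len(matched),
    )


def detection_accuracy(outcome: DetectionOutcome) -> float:
    """Percent of correct detections among expected wheals plus spurious ones."""
    denom = outcome.expected_detection + outcome.type1_errors
    if denom <= 0:
        raise UndefinedMetricError("expected_detection + type1_errors is zero")
    return 100.0 * outcome.correct_detection / denom


def cluster_confusion_metrics(
    predicted_mask: np.ndarray,
    expected_mask: np.ndarray,
    predicted: WhealCluster,
    expected: WhealCluster,
    pad_px: int = 5,
) -> ClusterMetrics:
    """Per-wheal confusion metrics inside the padded union bounding box."""
    predicted_mask = np.asarray(predicted_mask)
    expected_mask = np.asarray(expected_mask)
    if predicted_mask.shape != expected_mask.shape:
        raise ValueError("masks must share dimensions")
    h, w = predicted_mask.shape
    pts = np.vstack([predicted.pixels, expected.pixels])
    r0 = max(0, int(pts[:, 0].min()) - pad_px)
    r1 = min(h, int(pts[:, 0].max()) + pad_px + 1)
    c0 = max(0, int(pts[:, 1].min()) - pad_px)
    c1 = min(w, int(pts[:, 1].max()) + pad_px + 1)
    if r0 >= r1 or c0 >= c1:
        raise UndefinedMetricError("evaluation window is empty")

    pred = predicted_mask[r0:r1, c0:c1] == CLASS_WHEAL
    exp = expected_mask[r0:r1, c0:c1] == CLASS_WHEAL
    tp = int(np.sum(pred & exp))
    fp = int(np.sum(pred & ~exp))
    fn = int(np.sum(~pred & exp))
    tn = int(np.sum(~pred & ~exp))
    total = tp + fp + fn + tn

    def ratio(num: int, den: int) -> float:
        if den == 0:
            raise UndefinedMetricError("metric denominator is zero in this window")
        return num / den

    return ClusterMetrics(
        predicted_id=predicted.id,
        expected_id=expected.id,
        accuracy_pct=100.0 * ratio(tp + tn, total),
        sensitivity_pct=100.0 * ratio(tp, tp + fn),
        specificity_pct=100.0 * ratio(tn, tn + fp),
        dsc=ratio(2 * tp, 2 * tp + fp + fn),
        iou=ratio(tp, tp + fp + fn),
        window=(r0, r1, c0, c1),
        pad_px=pad_px,
    )


def evaluate_masks(
    predicted_mask: np.ndarray,
    expected_mask: np.ndarray,
    min_size: int = 10,
    pad_px: int = 5,
) -> dict:
    """Full scoring of one predicted/reference mask pair.

    Returns a JSON-ready dict: detection counts, Eq.-style detection accuracy
    when defined, the per-wheal metric table and its unweighted means.
    """
    pred_clusters = cluster_pixels(predicted_mask, min_size=min_size)
    exp_clusters = cluster_pixels(expected_mask, min_size=min_size)
    outcome = match_detections(pred_clusters, exp_clusters)
    by_id_p = {c.id: c for c in pred_clusters}
    by_id_e = {c.id: c for c in exp_clusters}
    rows = [
        cluster_confusion_metrics(
            predicted_mask, expected_mask, by_id_p[pid], by_id_e[eid], pad_px=pad_px
        )
        for pid, eid in outcome.matched_pairs
    ]
    report: dict = {
        "parameters": {"min_size": min_size, "pad_px": pad_px},
        "detection": {
            "correct_detection": outcome.correct_detection,
            "expected_detection": outcome.expected_detection,
            "type1_errors": outcome.type1_errors,
            "type2_errors": outcome.type2_errors,
            "matched_pairs": [list(p) for p in outcome.matched_pairs],
        },
        "per_wheal": [
            {
                "predicted_id": m.predicted_id,
                "expected_id": m.expected_id,
                "accuracy_pct": m.accuracy_pct,
                "sensitivity_pct": m.sensitivity_pct,
                "specificity_pct": m.specificity_pct,
                "dsc": m.dsc,
                "iou": m.iou,
            }
            for m in rows
        ],
    }
    if outcome.expected_detection + outcome.type1_errors > 0:
        report["detection"]["detection_accuracy_pct"] = detection_accuracy(outcome)
    if rows:
        report["means"] = {
            key: float(np.mean([getattr(m, attr) for m in rows]))
            for key, attr in [
                ("accuracy_pct", "accuracy_pct"),
                ("sensitivity_pct", "sensitivity_pct"),
                ("specificity_pct", "specificity_pct"),
                ("dsc", "dsc"),
                ("iou", "iou"),
            ]
        }
    return report
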