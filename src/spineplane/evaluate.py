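"""Detection, classification, localization and orientation metrics.

Predictions and ground truths are :class:`VertebraAnnotation` lists in
world millimetres.  A prediction matches a ground-truth vertebra when
its center lies inside the ground-truth box; matching is greedy
one-to-one by ascending center distance.  Localization and orientation
errors are computed over matched ("correctly detected") vertebrae only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import PLANE_NAMES, VertebraAnnotation, plane_angle_error, point_to_plane_distance

logger = logging.getLogger(__name__)

__all__ = [
    "MatchResult",
    "EvaluationReport",
    "match_predictions",
    "detection_metrics",
    "classification_metrics",
    "localization_errors",
    "orientation_errors",
    "evaluate_pairs",
]


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]  # (prediction index, ground-truth index)
    false_positives: list[int]
    false_negatives: list[int]

    @property
    def tp(self) -> int:
        return len(self.pairs)


def match_predictions(
    preds: list[VertebraAnnotation], gts: list[VertebraAnnotation]
) -> MatchResult:
    """Greedy one-to-one matching by ascending center distance.

    A (pred, gt) pair is admissible iff the predicted center lies inside
    the ground-truth box.
    """
    cand = []
    for pi, p in enumerate(preds):
        for gi, g in enumerate(gts):
            if np.all(np.abs(p.box.center - g.box.center) <= g.box.extents / 2.0):
                cand.append((float(np.linalg.norm(p.box.center - g.box.center)), pi, gi))
    cand.sort(key=lambda t: (t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    pairs = []
    for _, pi, gi in cand:
        if pi in used_p or gi in used_g:
            continue
        pairs.append((pi, gi))
        used_p.add(pi)
        used_g.add(gi)
    fp = [i for i in range(len(preds)) if i not in used_p]
    fn = [i for i in range(len(gts)) if i not in used_g]
    return MatchResult(pairs=pairs, false_positives=fp, false_negatives=fn)


def detection_metrics(m: MatchResult) -> dict:
    """Accuracy, error rate, recall and precision of vertebra detection.

    Detection has no true negatives, so accuracy = TP / (TP + FP + FN).
    An entirely empty evaluation reports 1 by convention.
    """
    tp, fp, fn = m.tp, len(m.false_positives), len(m.false_negatives)
    if tp + fp + fn == 0:
        logger.info("empty match result; detection metrics defined as 1")
        return {"accuracy": 1.0, "error_rate": 0.0, "recall": 1.0, "precision": 1.0}
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    accuracy = tp / (tp + fp + fn)
    return {
        "accuracy": accuracy,
        "error_rate": 1.0 - accuracy,
        "recall": recall,
        "precision": precision,
    }


def classification_metrics(
    m: MatchResult, preds: list[VertebraAnnotation], gts: list[VertebraAnnotation]
) -> dict:
    """3x3 confusion over matched pairs; macro recall/precision."""
    conf = np.zeros((3, 3), dtype=int)  # rows: ground truth, cols: prediction
    for pi, gi in m.pairs:
        conf[gts[gi].class_id - 1, preds[pi].class_id - 1] += 1
    total = conf.sum()
    if total == 0:
        logger.info("no matched pairs; classification metrics defined as 0")
        return {"confusion": conf, "accuracy": 0.0, "error_rate": 0.0, "recall": 0.0, "precision": 0.0}
    acc = float(np.trace(conf)) / total
    recalls, precisions = [], []
    for k in range(3):
        if conf[k].sum():
            recalls.append(conf[k, k] / conf[k].sum())
        if conf[:, k].sum():
            precisions.append(conf[k, k] / conf[:, k].sum())
    return {
        "confusion": conf,
        "accuracy": acc,
        "error_rate": 1.0 - acc,
        "recall": float(np.mean(recalls)) if recalls else 0.0,
        "precision": float(np.mean(precisions)) if precisions else 0.0,
    }


def localization_errors(
    m: MatchResult, preds: list[VertebraAnnotation], gts: list[VertebraAnnotation]
) -> dict:
    """Center-to-center and center-to-plane distances (mm) per matched pair.

    ``d_sp_bar`` averages the coronal and sagittal center-to-plane
    distances per pair.
    """
    out = {k: [] for k in ("d_cc", "d_asp", "d_csp", "d_ssp", "d_sp_bar")}
    for pi, gi in m.pairs:
        p, g = preds[pi], gts[gi]
        out["d_cc"].append(float(np.linalg.norm(p.box.center - g.box.center)))
        dists = {}
        for plane in PLANE_NAMES:
            dists[plane] = point_to_plane_distance(
                p.box.center, g.box.center, g.planes.normal(plane)
            )
        out["d_asp"].append(dists["axial"])
        out["d_csp"].append(dists["coronal"])
        out["d_ssp"].append(dists["sagittal"])
        out["d_sp_bar"].append((dists["coronal"] + dists["sagittal"]) / 2.0)
    return {k: np.asarray(v) for k, v in out.items()}


def orientation_errors(
    m: MatchResult, preds: list[VertebraAnnotation], gts: list[VertebraAnnotation]
) -> dict:
    """Unoriented normal angle errors (deg) per plane per matched pair."""
    out = {k: [] for k in ("ang_asp", "ang_csp", "ang_ssp", "ang_sp_bar")}
    for pi, gi in m.pairs:
        p, g = preds[pi], gts[gi]
        angs = [
            plane_angle_error(p.planes.normal(plane), g.planes.normal(plane))
            for plane in PLANE_NAMES
        ]
        out["ang_asp"].append(angs[0])
        out["ang_csp"].append(angs[1])
        out["ang_ssp"].append(angs[2])
        out["ang_sp_bar"].append(float(np.mean(angs)))
    return {k: np.asarray(v) for k, v in out.items()}


def _mean_sd(x: np.ndarray) -> dict:
    if x.size == 0:
        return {"mean": float("nan"), "sd": float("nan"), "n": 0}
    return {"mean": float(np.mean(x)), "sd": float(np.std(x)), "n": int(x.size)}


@dataclass
class EvaluationReport:
    detection: dict
    classification: dict
    localization: dict
    orientation: dict

    def summary(self) -> dict:
        return {
            "detection": self.detection,
            "classification": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.classification.items()
            },
            "localization": {k: _mean_sd(v) for k, v in self.localization.items()},
            "orientation": {k: _mean_sd(v) for k, v in self.orientation.items()},
        }


def evaluate_pairs(volume_pairs: list[tuple[list, list]]) -> EvaluationReport:
    """Aggregate metrics over (predictions, ground-truths) per volume."""
    tp = fp = fn = 0
    all_pairs_metrics = {"loc": [], "ori": []}
    conf = np.zeros((3, 3), dtype=int)
    loc_acc = {k: [] for k in ("d_cc", "d_asp", "d_csp", "d_ssp", "d_sp_bar")}
    ori_acc = {k: [] for k in ("ang_asp", "ang_csp", "ang_ssp", "ang_sp_bar")}
    for preds, gts in volume_pairs:
        m = match_predictions(preds, gts)
        tp += m.tp
        fp += len(m.false_positives)
        fn += len(m.false_negatives)
        cm = classification_metrics(m, preds, gts)
        conf += cm["confusion"]
        for k, v in localization_errors(m, preds, gts).items():
            loc_acc[k].append(v)
        for k, v in orientation_errors(m, preds, gts).items():
            ori_acc[k].append(v)
    agg = MatchResult(pairs=[(0, 0)] * tp, false_positives=[0] * fp, false_negatives=[0] * fn)
    det = detection_metrics(agg)
    total = conf.sum()
    cls = {
        "confusion": conf,
        "accuracy": float(np.trace(conf)) / total if total else 0.0,
        "error_rate": 1.0 - float(np.trace(conf)) / total if total else 0.0,
    }
    loc = {k: np.concatenate(v) if v else np.array([]) for k, v in loc_acc.items()}
    ori = {k: np.concatenate(v) if v else np.array([]) for k, v in ori_acc.items()}
    return EvaluationReport(detection=det, classification=cls, localization=loc, orientation=ori)
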