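"""Evaluation metrics: keyframe frame error, rotated-box detection mAP/mP/mR,
gain-classification metrics with one-vs-rest ROC/AUC, and Cohen's kappa for
score agreement."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .lvvc import KeyframeLabel, Phase
from .obb import Detection, rotated_iou

__all__ = [
    "FrameErrorStats",
    "DetectionEval",
    "frame_error",
    "frame_error_stats",
    "detection_map",
    "cohens_kappa",
    "classification_report",
]


# ---------------------------------------------------------------------------
# Keyframe frame error


@dataclass
class FrameErrorStats:
    fe_ed_mean: float
    fe_ed_std: float
    fe_es_mean: float
    fe_es_std: float
    n_videos: int
    misses: int


def frame_error(
    pred: Sequence[KeyframeLabel], gt: Sequence[KeyframeLabel]
) -> dict[Phase, list[int]] | dict:
    """Per-phase absolute frame errors with greedy one-to-one matching.

    Each ground-truth keyframe is matched to the nearest unused prediction of
    the same phase (globally greedy by distance; ties resolve to the earlier
    prediction).  Unmatched ground truth is counted under ``"misses"``.
    """
    errors: dict = {Phase.ED: [], Phase.ES: [], "misses": 0}
    for phase in (Phase.ED, Phase.ES):
        gt_idx = sorted(k.frame_index for k in gt if k.phase is phase)
        pr_idx = sorted(k.frame_index for k in pred if k.phase is phase)
        pairs = sorted(
            ((abs(g - p), pi, gi) for gi, g in enumerate(gt_idx)
             for pi, p in enumerate(pr_idx)),
            key=lambda t: (t[0], t[1], t[2]),
        )
        used_g: set[int] = set()
        used_p: set[int] = set()
        for dist, pi, gi in pairs:
            if gi in used_g or pi in used_p:
                continue
            used_g.add(gi)
            used_p.add(pi)
            errors[phase].append(int(dist))
        errors["misses"] += len(gt_idx) - len(used_g)
    return errors


def frame_error_stats(per_video: Sequence[dict]) -> FrameErrorStats:
    """Aggregate :func:`frame_error` outputs over videos."""
    ed = np.concatenate([np.asarray(e[Phase.ED], dtype=float) for e in per_video]) \
        if per_video else np.array([])
    es = np.concatenate([np.asarray(e[Phase.ES], dtype=float) for e in per_video]) \
        if per_video else np.array([])
    return FrameErrorStats(
        fe_ed_mean=float(ed.mean()) if ed.size else float("nan"),
        fe_ed_std=float(ed.std()) if ed.size else float("nan"),
        fe_es_mean=float(es.mean()) if es.size else float("nan"),
        fe_es_std=float(es.std()) if es.size else float("nan"),
        n_videos=len(per_video),
        misses=int(sum(e["misses"] for e in per_video)),
    )


# ---------------------------------------------------------------------------
# Rotated-box detection mAP


@dataclass
class DetectionEval:
    map: float
    mp: float
    mr: float
    per_class_ap: dict = field(default_factory=dict)


def _average_precision(recalls: np.ndarray, precisions: np.ndarray) -> float:
    """All-point interpolated AP (area under the monotone PR envelope)."""
    r = np.concatenate([[0.0], recalls, [1.0]])
    p = np.concatenate([[0.0], precisions, [0.0]])
    for i in range(p.size - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    changes = np.nonzero(r[1:] != r[:-1])[0]
    return float(np.sum((r[changes + 1] - r[changes]) * p[changes + 1]))


def detection_map(
    preds: Sequence[Sequence[Detection]],
    gts: Sequence[Sequence[Detection]],
    iou_thresh: float = 0.5,
    conf_thresh: float = 0.25,
) -> DetectionEval:
    """Per-class all-point AP at rotated IoU >= ``iou_thresh``.

    ``preds[i]``/``gts[i]`` are the detections of image i.  Matching is
    greedy by descending confidence, at most one prediction per ground-truth
    box.  mP/mR are precision/recall pooled over classes at ``conf_thresh``.
    """
    if len(preds) != len(gts):
        raise ValueError("preds and gts must have equal length")
    labels = sorted({d.label for frame in gts for d in frame}, key=lambda s: s.value)
    per_class_ap: dict = {}
    precisions_at_t: list[float] = []
    recalls_at_t: list[float] = []
    for label in labels:
        records = []  # (confidence, image, detection)
        n_gt = 0
        for img, (p_frame, g_frame) in enumerate(zip(preds, gts)):
            n_gt += sum(1 for g in g_frame if g.label == label)
            for order, d in enumerate(p_frame):
                if d.label == label:
                    records.append((d.confidence, img, order, d))
        records.sort(key=lambda r: (-r[0], r[1], r[2]))
        matched: set = set()
        tp = np.zeros(len(records))
        for k, (_conf, img, _order, det) in enumerate(records):
            candidates = [
                (gi, g) for gi, g in enumerate(gts[img])
                if g.label == label and (img, gi) not in matched
            ]
            best_iou, best_gi = 0.0, None
            for gi, g in candidates:
                iou = rotated_iou(det.box, g.box)
                if iou > best_iou:
                    best_iou, best_gi = iou, gi
            if best_gi is not None and best_iou >= iou_thresh:
                matched.add((img, best_gi))
                tp[k] = 1.0
        if n_gt == 0:
            continue
        cum_tp = np.cumsum(tp)
        precisions = cum_tp / np.arange(1, len(records) + 1) if records else np.array([])
        recalls = cum_tp / n_gt if records else np.array([])
        per_class_ap[label] = (
            _average_precision(recalls, precisions) if records else 0.0
        )
        keep = np.array([r[0] >= conf_thresh for r in records], dtype=bool)
        n_kept = int(keep.sum())
        tp_kept = float(tp[keep].sum())
        precisions_at_t.append(tp_kept / n_kept if n_kept else 0.0)
        recalls_at_t.append(tp_kept / n_gt)
    if not per_class_ap:
        return DetectionEval(map=0.0, mp=0.0, mr=0.0, per_class_ap={})
    return DetectionEval(
        map=float(np.mean(list(per_class_ap.values()))),
        mp=float(np.mean(precisions_at_t)),
        mr=float(np.mean(recalls_at_t)),
        per_class_ap=per_class_ap,
    )


# ---------------------------------------------------------------------------
# Agreement and classification metrics


def cohens_kappa(a: Sequence[int], b: Sequence[int]) -> float:
    """Unweighted Cohen's kappa with marginal-product expected agreement.

    The degenerate case p_e == 1 (both raters constant) is defined as 0 with
    a warning.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score lists must be 1-D and of equal length")
    if a.size == 0:
        raise ValueError("score lists must be non-empty")
    cats = np.union1d(a, b)
    n = a.size
    p_o = float(np.mean(a == b))
    p_e = float(
        sum((np.sum(a == c) / n) * (np.sum(b == c) / n) for c in cats)
    )
    if abs(1.0 - p_e) < 1e-12:
        warnings.warn("kappa undefined (expected agreement = 1); returning 0")
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def _binary_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Rank-statistic (Mann-Whitney) AUC with tie correction."""
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    n_pos = int(positives.sum())
    n_neg = positives.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    return float((ranks[positives].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def classification_report(
    pred_probs: np.ndarray, labels: Sequence[int], n_classes: int | None = None
) -> dict:
    """Accuracy, macro precision/recall, one-vs-rest ROC AUC and confusion
    matrix for a multi-class classifier.

    ``pred_probs`` rows must sum to 1.  Classes absent from ``labels`` get
    no AUC and are excluded from the macro average with a warning.
    """
    from sklearn.metrics import confusion_matrix, precision_score, recall_score

    pred_probs = np.asarray(pred_probs, dtype=float)
    labels = np.asarray(labels)
    if pred_probs.ndim != 2 or pred_probs.shape[0] != labels.shape[0]:
        raise ValueError("pred_probs must be (n_samples, n_classes) matching labels")
    if not np.allclose(pred_probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    k = pred_probs.shape[1] if n_classes is None else n_classes
    preds = pred_probs.argmax(axis=1)
    all_classes = list(range(k))
    auc: dict[int, float] = {}
    for c in all_classes:
        positives = labels == c
        if positives.all() or not positives.any():
            warnings.warn(f"class {c} absent from labels; AUC undefined")
            continue
        auc[c] = _binary_auc(pred_probs[:, c], positives)
    macro_auc = float(np.mean(list(auc.values()))) if auc else float("nan")
    return {
        "accuracy": float(np.mean(preds == labels)),
        "macro_precision": float(
            precision_score(labels, preds, labels=all_classes, average="macro",
                            zero_division=0)
        ),
        "macro_recall": float(
            recall_score(labels, preds, labels=all_classes, average="macro",
                         zero_division=0)
        ),
        "auc_per_class": auc,
        "macro_auc": macro_auc,
        "confusion_matrix": confusion_matrix(labels, preds, labels=all_classes),
    }
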