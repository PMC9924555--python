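"""Pixel-wise and object-wise segmentation metrics plus status accuracy.

Pixel metrics are the usual confusion-matrix quantities per class
(precision, recall, Dice); object metrics match predicted and true
instances greedily by descending IoU with a configurable acceptance
threshold (default 0.3 — the matching criterion is a package choice, not a
clinical standard). Undefined ratios (zero denominators) are reported as 0.0
with an explicit ``defined`` flag instead of NaN so CSV reports stay stable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ClassMask, InstanceLabels, ValidationError


def pixel_metrics(pred: ClassMask, truth: ClassMask) -> pd.DataFrame:
    """Per-class precision/recall/Dice between two masks.

    Classes absent from both masks are reported with ``defined=False`` and
    should be excluded from averages.
    """
    if pred.class_set is not truth.class_set:
        raise ValidationError("masks use different class sets")
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch {pred.shape} vs {truth.shape}")
    n = pred.class_set.n_classes
    p = pred.labels.ravel()
    t = truth.labels.ravel()
    confusion = np.bincount(t * n + p, minlength=n * n).reshape(n, n)
    rows = []
    for c in range(n):
        tp = confusion[c, c]
        fp = confusion[:, c].sum() - tp
        fn = confusion[c, :].sum() - tp
        present = (tp + fp + fn) > 0
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        dice = 2 * tp / (2 * tp + fp + fn) if present else 0.0
        rows.append(
            {
                "class_id": c,
                "class_name": pred.class_set.class_names[c],
                "precision": float(precision),
                "recall": float(recall),
                "dice": float(dice),
                "support": int(tp + fn),
                "defined": bool(present),
            }
        )
    return pd.DataFrame(rows)


def mean_foreground_dice(pred: ClassMask, truth: ClassMask) -> float:
    """Mean Dice over foreground classes present in prediction or truth."""
    df = pixel_metrics(pred, truth)
    fg = df[(df.class_id > 0) & df.defined]
    if fg.empty:
        return 0.0
    return float(fg.dice.mean())


def _instance_sets(instances: InstanceLabels) -> dict[int, list[np.ndarray]]:
    """Flat pixel-index arrays per class for each instance."""
    flat = instances.labels.ravel()
    out: dict[int, list[np.ndarray]] = {}
    for inst_id, class_id in instances.instance_class.items():
        out.setdefault(class_id, []).append(np.flatnonzero(flat == inst_id))
    return out


def object_metrics(
    pred: InstanceLabels, truth: InstanceLabels, iou_threshold: float = 0.3
) -> pd.DataFrame:
    """Greedy one-to-one IoU matching per class.

    Pairs are accepted in descending IoU order while IoU >= ``iou_threshold``;
    precision = matched/predicted and recall = matched/truth. Classes with
    zero predictions or zero truth get 0.0 with ``defined=False`` on the
    affected ratio.
    """
    if pred.labels.shape != truth.labels.shape:
        raise ValidationError("instance maps must share a grid")
    pred_sets = _instance_sets(pred)
    truth_sets = _instance_sets(truth)
    classes = sorted(set(pred_sets) | set(truth_sets))
    rows = []
    for c in classes:
        p_list = pred_sets.get(c, [])
        t_list = truth_sets.get(c, [])
        pairs = []
        for i, p_pix in enumerate(p_list):
            p_set = set(p_pix.tolist())
            for j, t_pix in enumerate(t_list):
                inter = len(p_set.intersection(t_pix.tolist()))
                if inter == 0:
                    continue
                union = len(p_pix) + len(t_pix) - inter
                iou = inter / union
                if iou >= iou_threshold:
                    pairs.append((iou, i, j))
        pairs.sort(reverse=True)
        used_p: set[int] = set()
        used_t: set[int] = set()
        matched = 0
        for iou, i, j in pairs:
            if i in used_p or j in used_t:
                continue
            used_p.add(i)
            used_t.add(j)
            matched += 1
        precision = matched / len(p_list) if p_list else 0.0
        recall = matched / len(t_list) if t_list else 0.0
        rows.append(
            {
                "class_id": c,
                "n_pred": len(p_list),
                "n_truth": len(t_list),
                "matched": matched,
                "precision": float(precision),
                "recall": float(recall),
                "precision_defined": bool(p_list),
                "recall_defined": bool(t_list),
            }
        )
    return pd.DataFrame(rows)


def _aligned(pred: pd.DataFrame, truth: pd.DataFrame, key: str) -> pd.DataFrame:
    if key not in pred.columns or key not in truth.columns:
        raise ValidationError(f"both tables need a {key!r} column")
    merged = pred.merge(truth, on=key, suffixes=("_pred", "_true"))
    if merged.empty:
        raise ValidationError("prediction and truth tables share no ids")
    return merged


def status_accuracy(
    pred: pd.DataFrame,
    truth: pd.DataFrame,
    columns: list[str],
    key: str = "patient_id",
) -> dict[str, float]:
    """Exact-match fraction per status column over aligned ids."""
    merged = _aligned(pred, truth, key)
    out = {}
    for col in columns:
        out[col] = float(
            (merged[f"{col}_pred"].astype(str) == merged[f"{col}_true"].astype(str)).mean()
        )
    return out


def subtype_accuracy(
    pred: pd.DataFrame, truth: pd.DataFrame, key: str = "patient_id"
) -> float:
    """Exact-match fraction of the final subtype call."""
    return status_accuracy(pred, truth, ["subtype"], key)["subtype"]
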