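"""Compound segmentation objective: cross-entropy plus two focal Tversky terms.

The training loss is

    L = w_cce * CCE + w_ftl * (FTL1 + FTL2)
    FTL_k = (1 - TI_k) ** gamma
    TI_1  = TP / (TP + 0.75 FP + 0.25 FN)   (penalizes false positives)
    TI_2  = TP / (TP + 0.25 FP + 0.75 FN)   (penalizes false negatives)

with default weights w_cce = 0.2 and w_ftl = 0.4 and 0 < gamma < 1, which
raises the gradient for well-segmented samples (TI > 0.5) and counteracts the
heavy background/foreground class imbalance of IHC slides. TP/FP/FN are soft
counts accumulated per class over the whole batch from predicted
probabilities against one-hot truth; the Tversky index is computed per class
and averaged over foreground classes (background excluded) by default.

Both the loss value and its analytic gradient with respect to the predicted
probabilities are provided, so the segmentation network backpropagates
through its softmax output without numerical differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SoftConfusion:
    """Soft true/false positive/negative mass for one class."""

    tp: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        if self.tp < 0 or self.fp < 0 or self.fn < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class LossConfig:
    cce_weight: float = 0.2
    ftl_weight: float = 0.4
    alpha_fp_1: float = 0.75
    alpha_fn_1: float = 0.25
    alpha_fp_2: float = 0.25
    alpha_fn_2: float = 0.75
    gamma: float = 0.75
    class_aggregation: str = "mean_over_foreground"  # or "mean_over_all"
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if min(self.cce_weight, self.ftl_weight) < 0:
            raise ValueError("loss weights must be non-negative")
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.class_aggregation not in ("mean_over_foreground", "mean_over_all"):
            raise ValueError(f"unknown aggregation {self.class_aggregation!r}")


def soft_confusion(pred: np.ndarray, truth: np.ndarray, class_idx: int) -> SoftConfusion:
    """Accumulate soft confusion counts for one class over a batch.

    ``pred`` holds channel-last probabilities and ``truth`` the matching
    one-hot encoding.
    """
    p = pred[..., class_idx].astype(np.float64)
    t = truth[..., class_idx].astype(np.float64)
    return SoftConfusion(
        tp=float((p * t).sum()),
        fp=float((p * (1.0 - t)).sum()),
        fn=float(((1.0 - p) * t).sum()),
    )


def tversky_index(
    conf: SoftConfusion, fp_weight: float, fn_weight: float, epsilon: float = 1e-6
) -> float:
    """Smoothed Tversky similarity TI = (TP+eps)/(TP + a*FP + b*FN + eps)."""
    denom = conf.tp + fp_weight * conf.fp + fn_weight * conf.fn + epsilon
    return float((conf.tp + epsilon) / denom)


def focal_tversky(ti: float, gamma: float) -> float:
    """Focal transform (1 - TI)**gamma of a Tversky index."""
    if not (0.0 <= ti <= 1.0):
        raise ValueError(f"Tversky index {ti} outside [0, 1]")
    return float((1.0 - ti) ** gamma)


def _check_shapes(pred: np.ndarray, truth: np.ndarray) -> None:
    if pred.shape != truth.shape:
        raise ValueError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    if pred.ndim < 2:
        raise ValueError("pred must be at least (pixels, classes)")


def _loss_classes(n_classes: int, config: LossConfig) -> list[int]:
    if config.class_aggregation == "mean_over_foreground" and n_classes > 1:
        return list(range(1, n_classes))
    return list(range(n_classes))


def categorical_cross_entropy(
    pred: np.ndarray, truth: np.ndarray, epsilon: float = 1e-6
) -> float:
    """Mean per-pixel categorical cross-entropy with probability clipping."""
    _check_shapes(pred, truth)
    p = np.clip(pred.astype(np.float64), epsilon, 1.0 - epsilon)
    n_pixels = pred.size // pred.shape[-1]
    return float(-(truth * np.log(p)).sum() / n_pixels)


def focal_tversky_terms(
    pred: np.ndarray, truth: np.ndarray, config: LossConfig | None = None
) -> tuple[float, float]:
    """The two focal Tversky components (FP-penalizing, FN-penalizing)."""
    config = config or LossConfig()
    _check_shapes(pred, truth)
    classes = _loss_classes(pred.shape[-1], config)
    ftl1 = ftl2 = 0.0
    for c in classes:
        conf = soft_confusion(pred, truth, c)
        ftl1 += focal_tversky(
            tversky_index(conf, config.alpha_fp_1, config.alpha_fn_1, config.epsilon),
            config.gamma,
        )
        ftl2 += focal_tversky(
            tversky_index(conf, config.alpha_fp_2, config.alpha_fn_2, config.epsilon),
            config.gamma,
        )
    return ftl1 / len(classes), ftl2 / len(classes)


def combined_loss(
    pred: np.ndarray, truth: np.ndarray, config: LossConfig | None = None
) -> float:
    """w_cce * CCE + w_ftl * (FTL1 + FTL2) on a batch of probability maps."""
    config = config or LossConfig()
    _check_shapes(pred, truth)
    cce = categorical_cross_entropy(pred, truth, config.epsilon)
    ftl1, ftl2 = focal_tversky_terms(pred, truth, config)
    return config.cce_weight * cce + config.ftl_weight * (ftl1 + ftl2)


def combined_loss_and_grad(
    pred: np.ndarray, truth: np.ndarray, config: LossConfig | None = None
) -> tuple[float, np.ndarray]:
    """Loss value plus its analytic gradient w.r.t. the probabilities.

    The gradient of each focal term uses d(1-TI)^g/dTI = -g (1-TI)^(g-1) with
    (1-TI) floored at a tiny constant, since the exponent g-1 is negative and
    the derivative diverges as the prediction approaches perfection.
    """
    config = config or LossConfig()
    _check_shapes(pred, truth)
    p64 = pred.astype(np.float64)
    t64 = truth.astype(np.float64)
    eps = config.epsilon
    n_pixels = pred.size // pred.shape[-1]

    # cross-entropy part; gradient vanishes where the clip is active
    p_clip = np.clip(p64, eps, 1.0 - eps)
    cce = float(-(t64 * np.log(p_clip)).sum() / n_pixels)
    inside = (p64 > eps) & (p64 < 1.0 - eps)
    grad = np.where(inside, -t64 / p_clip, 0.0) * (config.cce_weight / n_pixels)

    classes = _loss_classes(pred.shape[-1], config)
    ftl_sum = 0.0
    for a_fp, a_fn in (
        (config.alpha_fp_1, config.alpha_fn_1),
        (config.alpha_fp_2, config.alpha_fn_2),
    ):
        for c in classes:
            p = p64[..., c]
            t = t64[..., c]
            tp = (p * t).sum()
            fp = (p * (1.0 - t)).sum()
            fn = ((1.0 - p) * t).sum()
            num = tp + eps
            den = tp + a_fp * fp + a_fn * fn + eps
            ti = num / den
            one_minus = max(1.0 - ti, 1e-12)
            ftl_sum += one_minus**config.gamma
            # dTI/dp_i = (dnum * den - num * dden) / den^2
            dnum = t
            dden = t + a_fp * (1.0 - t) - a_fn * t
            dti = (dnum * den - num * dden) / (den * den)
            dftl_dti = -config.gamma * one_minus ** (config.gamma - 1.0)
            grad[..., c] += (
                config.ftl_weight / len(classes)
            ) * dftl_dti * dti
    loss = config.cce_weight * cce + config.ftl_weight * (ftl_sum / len(classes))
    return loss, grad.astype(np.float32)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """One-hot encode integer labels along a trailing class axis."""
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("labels outside class range")
    return np.eye(n_classes, dtype=np.float32)[labels]
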