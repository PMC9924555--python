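"""Training harness: patient-wise leave-one-out CV and the Adam loop.

One model per biomarker, trained from scratch per fold with Adam
(learning rate 0.001), batch size 4, dropout 0.1 in the decoder, L2 weight
regularization and the compound cross-entropy + focal-Tversky objective.
Folds hold out all slides of one patient, so no patient's pixels ever
appear on both sides of a split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imgio
from .evaluate import mean_foreground_dice
from .losses import LossConfig, combined_loss_and_grad, one_hot
from .net import NetConfig, SegModel, build_model
from .nn import Adam, collect_batchnorm_stats
from .types import Biomarker, ClassMask, ClassSet, ValidationError


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 4
    epochs: int = 50
    l2_coefficient: float = 1e-5
    patch_size: int = 480
    model_size: int = 240
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    held_out_patient: str
    train_slide_ids: tuple[str, ...]
    test_slide_ids: tuple[str, ...]


def loocv_splits(manifest: pd.DataFrame, biomarker: Biomarker | str) -> list[FoldSplit]:
    """One fold per patient; the held-out patient supplies all test slides."""
    biomarker = Biomarker(biomarker)
    sub = manifest[manifest["biomarker"] == biomarker.value]
    patients = sorted(sub["patient_id"].astype(str).unique())
    if len(patients) < 2:
        raise ValidationError(
            f"LOOCV needs >= 2 patients for {biomarker.value}, found {len(patients)}"
        )
    id_col = "slide_id" if "slide_id" in sub.columns else "slide_path"
    folds = []
    for k, held_out in enumerate(patients):
        test = sub[sub["patient_id"].astype(str) == held_out]
        train = sub[sub["patient_id"].astype(str) != held_out]
        folds.append(
            FoldSplit(
                fold_id=k,
                held_out_patient=held_out,
                train_slide_ids=tuple(train[id_col].astype(str)),
                test_slide_ids=tuple(test[id_col].astype(str)),
            )
        )
    return folds


def patches_per_slide(image_shape: tuple[int, int], patch_size: int = 480) -> int:
    """Patch count bookkeeping: floor(H/p) * floor(W/p)."""
    return (image_shape[0] // patch_size) * (image_shape[1] // patch_size)


def build_patch_dataset(
    rows: pd.DataFrame,
    class_set: ClassSet,
    patch_size: int = 480,
    model_size: int = 240,
) -> tuple[np.ndarray, np.ndarray]:
    """Load manifest rows into (patches, one-hot masks) training arrays."""
    xs, ys = [], []
    for row in rows.itertuples():
        image = imgio.load_slide(
            row.slide_path, patient_id=str(row.patient_id), biomarker=row.biomarker
        )
        mask = imgio.load_mask(row.mask_path, class_set)
        patches, _ = imgio.slice_patches(image, patch_size, model_size)
        mask_patches, _ = imgio.slice_mask(mask, patch_size, model_size)
        xs.extend(p.astype(np.float32) / 255.0 for p in patches)
        ys.extend(one_hot(m.labels, class_set.n_classes) for m in mask_patches)
    if not xs:
        raise ValidationError("empty training set")
    return np.stack(xs), np.stack(ys)


def train_model(
    x_train: np.ndarray,
    y_train: np.ndarray,
    net_config: NetConfig,
    train_config: TrainConfig | None = None,
) -> tuple[SegModel, list[float]]:
    """Train a freshly initialized model; returns it with per-epoch losses."""
    train_config = train_config or TrainConfig()
    if len(x_train) == 0:
        raise ValidationError("empty training set")
    model = build_model(net_config, seed=train_config.seed)
    optimizer = Adam(
        model.network.parameters(),
        lr=train_config.learning_rate,
        l2=train_config.l2_coefficient,
    )
    rng = np.random.default_rng(train_config.seed)
    history: list[float] = []
    n = len(x_train)
    for _epoch in range(train_config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            probs = model.forward(x_train[idx], training=True)
            loss, grad = combined_loss_and_grad(
                probs.data, y_train[idx], train_config.loss
            )
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {_epoch}")
            optimizer.zero_grad()
            probs.backward(grad)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
            del probs
        history.append(epoch_loss / n_batches)
    # replace the lagging exponential batch-norm averages with population
    # statistics over the training set, so inference matches the converged
    # network
    collect_batchnorm_stats(
        model.network,
        lambda b: model.forward(b, training=True),
        (
            x_train[i : i + train_config.batch_size]
            for i in range(0, n, train_config.batch_size)
        ),
    )
    return model, history


def train_fold(
    fold: FoldSplit,
    manifest: pd.DataFrame,
    biomarker: Biomarker | str,
    net_config: NetConfig,
    train_config: TrainConfig | None = None,
) -> tuple[SegModel, list[float]]:
    """Train on the fold's training slides only (manifest-driven)."""
    train_config = train_config or TrainConfig()
    biomarker = Biomarker(biomarker)
    class_set = ClassSet.for_biomarker(biomarker)
    sub = manifest[manifest["biomarker"] == biomarker.value]
    id_col = "slide_id" if "slide_id" in sub.columns else "slide_path"
    rows = sub[sub[id_col].astype(str).isin(fold.train_slide_ids)]
    x_train, y_train = build_patch_dataset(
        rows, class_set, train_config.patch_size, train_config.model_size
    )
    return train_model(x_train, y_train, net_config, train_config)


def evaluate_fold(
    model: SegModel,
    fold: FoldSplit,
    manifest: pd.DataFrame,
    biomarker: Biomarker | str,
    train_config: TrainConfig | None = None,
) -> dict[str, float]:
    """Stitched whole-slide foreground Dice on the held-out patient."""
    train_config = train_config or TrainConfig()
    biomarker = Biomarker(biomarker)
    class_set = ClassSet.for_biomarker(biomarker)
    sub = manifest[manifest["biomarker"] == biomarker.value]
    id_col = "slide_id" if "slide_id" in sub.columns else "slide_path"
    rows = sub[sub[id_col].astype(str).isin(fold.test_slide_ids)]
    dices = []
    for row in rows.itertuples():
        image = imgio.load_slide(
            row.slide_path, patient_id=str(row.patient_id), biomarker=row.biomarker
        )
        truth = imgio.load_mask(row.mask_path, class_set)
        pred = predict_slide(model, image, class_set, train_config)
        h = min(pred.shape[0], truth.shape[0])
        w = min(pred.shape[1], truth.shape[1])
        dices.append(
            mean_foreground_dice(
                ClassMask(pred.labels[:h, :w], class_set),
                ClassMask(truth.labels[:h, :w], class_set),
            )
        )
    return {
        "fold_id": float(fold.fold_id),
        "n_test_slides": float(len(dices)),
        "mean_foreground_dice": float(np.mean(dices)) if dices else 0.0,
    }


def predict_slide(
    model: SegModel,
    image,
    class_set: ClassSet,
    train_config: TrainConfig | None = None,
) -> ClassMask:
    """Patch -> predict -> argmax -> stitch for one slide."""
    train_config = train_config or TrainConfig()
    patches, grid = imgio.slice_patches(
        image, train_config.patch_size, train_config.model_size
    )
    probs = model.predict_probs(np.stack(patches), batch_size=train_config.batch_size)
    patch_masks = [
        ClassMask(np.argmax(p, axis=-1).astype(np.int64), class_set) for p in probs
    ]
    return imgio.stitch_masks(patch_masks, grid)


def run_cross_validation(
    manifest: pd.DataFrame,
    biomarker: Biomarker | str,
    net_config: NetConfig,
    train_config: TrainConfig | None = None,
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Full LOOCV: per-fold training + held-out metrics and their mean."""
    train_config = train_config or TrainConfig()
    folds = loocv_splits(manifest, biomarker)
    records = []
    for fold in folds:
        model, history = train_fold(
            fold, manifest, biomarker, net_config, train_config
        )
        metrics = evaluate_fold(model, fold, manifest, biomarker, train_config)
        metrics["final_train_loss"] = history[-1]
        metrics["held_out_patient"] = fold.held_out_patient
        records.append(metrics)
        if outdir is not None:
            fold_dir = Path(outdir) / f"fold_{fold.fold_id}"
            fold_dir.mkdir(parents=True, exist_ok=True)
            model.save(fold_dir / "model.npz")
    results = pd.DataFrame(records)
    mean_row = results.mean(numeric_only=True).to_dict()
    mean_row["held_out_patient"] = "MEAN"
    results = pd.concat([results, pd.DataFrame([mean_row])], ignore_index=True)
    if outdir is not None:
        results.to_csv(Path(outdir) / "cv_results.csv", index=False)
    return results
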