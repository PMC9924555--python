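"""LOOCV split bookkeeping and the training loop on tiny problems."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ihcsubtype import synth
from ihcsubtype.losses import one_hot
from ihcsubtype.net import NetConfig
from ihcsubtype.train import (
    TrainConfig,
    build_patch_dataset,
    loocv_splits,
    patches_per_slide,
    train_model,
)
from ihcsubtype.types import ClassSet, ValidationError


def _manifest(n_patients, slides_each, biomarker="KI67"):
    rows = []
    for p in range(n_patients):
        for s in range(slides_each):
            rows.append(
                {
                    "slide_path": f"p{p}_s{s}.png",
                    "mask_path": f"p{p}_s{s}_mask.png",
                    "patient_id": f"P{p:02d}",
                    "biomarker": biomarker,
                    "slide_id": f"P{p:02d}_s{s}",
                }
            )
    return pd.DataFrame(rows)


class TestLOOCV:
    def test_fifteen_patients_give_fifteen_folds_of_140_train_slides(self):
        manifest = _manifest(15, 10)
        folds = loocv_splits(manifest, "KI67")
        assert len(folds) == 15
        for fold in folds:
            assert len(fold.train_slide_ids) == 140
            assert len(fold.test_slide_ids) == 10

    def test_two_patients_give_two_folds(self):
        folds = loocv_splits(_manifest(2, 3), "KI67")
        assert len(folds) == 2

    def test_test_sets_partition_all_slides(self):
        manifest = _manifest(5, 4)
        folds = loocv_splits(manifest, "KI67")
        seen = [sid for fold in folds for sid in fold.test_slide_ids]
        assert sorted(seen) == sorted(manifest["slide_id"])

    def test_no_patient_leakage(self):
        for fold in loocv_splits(_manifest(6, 2), "KI67"):
            train_patients = {s.split("_")[0] for s in fold.train_slide_ids}
            test_patients = {s.split("_")[0] for s in fold.test_slide_ids}
            assert train_patients.isdisjoint(test_patients)
            assert test_patients == {fold.held_out_patient}

    def test_single_patient_rejected(self):
        with pytest.raises(ValidationError):
            loocv_splits(_manifest(1, 10), "KI67")


class TestPatchBookkeeping:
    def test_training_fold_patch_count(self):
        """140 slides of 1920x1440 sliced at 480 px give 1680 patches."""
        per_slide = patches_per_slide((1440, 1920), 480)
        assert per_slide == 12
        assert 140 * per_slide == 1680
        assert 150 * per_slide == 1800

    def test_patch_dataset_from_disk(self, small_cohort):
        outdir, manifest, _ = small_cohort
        rows = manifest[manifest["biomarker"] == "KI67"]
        x, y = build_patch_dataset(rows, ClassSet.KI67_3CLASS, 96, 48)
        assert x.shape == (rows.shape[0] * 2 * 2, 48, 48, 3)
        assert y.shape == x.shape[:3] + (3,)
        assert x.min() >= 0.0 and x.max() <= 1.0


@pytest.fixture(scope="module")
def tiny_dataset():
    xs, ys = [], []
    for i in range(8):
        config = synth.default_slide_config("KI67", image_shape=(48, 48), seed=50 + i)
        config.nuclei_counts = {1: 4, 2: 2}
        config.nucleus_radius_range = (4.0, 6.0)
        image, mask, _ = synth.generate_slide(config)
        xs.append(image.pixels.astype(np.float32) / 255.0)
        ys.append(one_hot(mask.labels, 3))
    return np.stack(xs), np.stack(ys)


class TestTrainModel:
    def test_loss_decreases_and_stays_finite(self, tiny_dataset):
        x, y = tiny_dataset
        net = NetConfig(depth=2, base_filters=8, n_classes=3, input_shape=(48, 48, 3))
        config = TrainConfig(epochs=5, batch_size=4, seed=0)
        _, history = train_model(x, y, net, config)
        assert len(history) == 5
        assert all(np.isfinite(history))
        assert history[-1] < history[0]

    def test_training_is_seed_reproducible(self, tiny_dataset):
        x, y = tiny_dataset
        net = NetConfig(depth=2, base_filters=4, n_classes=3, input_shape=(48, 48, 3))
        config = TrainConfig(epochs=2, batch_size=4, seed=1)
        _, h1 = train_model(x, y, net, config)
        _, h2 = train_model(x, y, net, config)
        assert h1 == h2

    def test_empty_training_set_rejected(self):
        net = NetConfig(depth=2, base_filters=4, n_classes=3, input_shape=(48, 48, 3))
        with pytest.raises(ValidationError):
            train_model(np.zeros((0, 48, 48, 3)), np.zeros((0, 48, 48, 3)), net)


@pytest.fixture(scope="module")
def two_patient_manifest(tmp_path_factory):
    """Two patients x two tiny Ki67 slides written to disk."""
    from ihcsubtype import imgio

    outdir = tmp_path_factory.mktemp("cv")
    rows = []
    for p in range(2):
        for s in range(2):
            config = synth.default_slide_config(
                "KI67", image_shape=(48, 48), seed=70 + 10 * p + s
            )
            config.nuclei_counts = {1: 4, 2: 2}
            config.nucleus_radius_range = (4.0, 6.0)
            image, mask, _ = synth.generate_slide(config)
            slide_id = f"P{p:02d}_s{s}"
            slide_path = outdir / f"{slide_id}.png"
            mask_path = outdir / f"{slide_id}_mask.png"
            imgio.save_slide(image, slide_path)
            imgio.save_mask(mask, mask_path)
            rows.append(
                {
                    "slide_path": str(slide_path),
                    "mask_path": str(mask_path),
                    "patient_id": f"P{p:02d}",
                    "biomarker": "KI67",
                    "slide_id": slide_id,
                }
            )
    return pd.DataFrame(rows)


class TestRunCrossValidation:
    def test_two_patient_cv_results_table(self, two_patient_manifest, tmp_path):
        """Two folds plus a mean row; the mean equals the fold average and a
        reseeded rerun reproduces the table."""
        from ihcsubtype.train import run_cross_validation

        net = NetConfig(depth=2, base_filters=4, n_classes=3, input_shape=(48, 48, 3))
        config = TrainConfig(epochs=2, batch_size=2, patch_size=48, model_size=48, seed=0)
        results = run_cross_validation(
            two_patient_manifest, "KI67", net, config, outdir=tmp_path
        )
        assert len(results) == 3
        folds = results[results["held_out_patient"] != "MEAN"]
        mean_row = results[results["held_out_patient"] == "MEAN"].iloc[0]
        assert mean_row["mean_foreground_dice"] == pytest.approx(
            folds["mean_foreground_dice"].mean()
        )
        assert (tmp_path / "cv_results.csv").exists()
        assert (tmp_path / "fold_0" / "model.npz").exists()
        again = run_cross_validation(two_patient_manifest, "KI67", net, config)
        pd.testing.assert_frame_equal(results, again)
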