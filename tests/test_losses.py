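"""Tversky/focal-Tversky arithmetic, the compound loss, and its gradient."""

from __future__ import annotations

import numpy as np
import pytest

from ihcsubtype.losses import (
    LossConfig,
    SoftConfusion,
    categorical_cross_entropy,
    combined_loss,
    combined_loss_and_grad,
    focal_tversky,
    focal_tversky_terms,
    one_hot,
    soft_confusion,
    tversky_index,
)


def _random_batch(seed, shape=(2, 4, 4, 3)):
    """Probabilities away from 0/1 so clipping never bites gradient checks."""
    rng = np.random.default_rng(seed)
    logits = rng.normal(scale=0.7, size=shape)
    p = np.exp(logits)
    p /= p.sum(axis=-1, keepdims=True)
    t = one_hot(rng.integers(0, shape[-1], size=shape[:-1]), shape[-1])
    return p, t


class TestTverskyIndex:
    @pytest.mark.parametrize(
        "conf,weights,expected",
        [
            (SoftConfusion(10, 0, 0), (0.75, 0.25), 1.0),
            (SoftConfusion(1, 1, 0), (0.75, 0.25), 1 / 1.75),
            (SoftConfusion(1, 1, 0), (0.25, 0.75), 1 / 1.25),
        ],
    )
    def test_arithmetic(self, conf, weights, expected):
        assert tversky_index(conf, *weights, epsilon=0.0) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SoftConfusion(-1, 0, 0)

    def test_soft_confusion_bounded_by_truth_mass(self):
        p, t = _random_batch(0)
        for c in range(3):
            conf = soft_confusion(p, t, c)
            assert conf.tp <= t[..., c].sum() + 1e-9


class TestFocalTversky:
    @pytest.mark.parametrize(
        "ti,gamma,expected",
        [(1.0, 0.75, 0.0), (0.0, 0.75, 1.0), (0.5, 0.75, 0.5**0.75)],
    )
    def test_limits_and_arithmetic(self, ti, gamma, expected):
        assert focal_tversky(ti, gamma) == pytest.approx(expected)

    def test_out_of_range_ti_rejected(self):
        with pytest.raises(ValueError):
            focal_tversky(1.2, 0.75)

    def test_gamma_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(gamma=1.5)


class TestCombinedLoss:
    def test_perfect_prediction_gives_near_zero_loss(self):
        t = one_hot(np.array([[0, 1], [2, 1]]), 3)
        assert combined_loss(t.copy(), t) == pytest.approx(0.0, abs=1e-4)

    def test_all_wrong_prediction_hits_ftl_ceiling(self):
        """Total misclassification: both focal terms saturate at 1, so the
        loss equals 0.2*CCE + 0.8."""
        truth = one_hot(np.full((4, 4), 1), 3)
        pred = one_hot(np.full((4, 4), 2), 3).astype(np.float64)
        config = LossConfig()
        cce = categorical_cross_entropy(pred, truth, config.epsilon)
        assert combined_loss(pred, truth, config) == pytest.approx(
            0.2 * cce + 0.8, abs=1e-4
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_hand_composed_terms(self, seed):
        """The one-shot loss equals 0.2*CCE + 0.4*(FTL1+FTL2) recomposed
        independently from tversky_index/focal_tversky per class."""
        p, t = _random_batch(seed)
        config = LossConfig()
        cce = categorical_cross_entropy(p, t, config.epsilon)
        ftl1 = ftl2 = 0.0
        classes = range(1, 3)
        for c in classes:
            conf = soft_confusion(p, t, c)
            ti1 = tversky_index(conf, 0.75, 0.25, config.epsilon)
            ti2 = tversky_index(conf, 0.25, 0.75, config.epsilon)
            ftl1 += focal_tversky(ti1, config.gamma)
            ftl2 += focal_tversky(ti2, config.gamma)
        expected = 0.2 * cce + 0.4 * (ftl1 / 2 + ftl2 / 2)
        assert combined_loss(p, t, config) == pytest.approx(expected, abs=1e-6)
        value, _ = combined_loss_and_grad(p, t, config)
        assert value == pytest.approx(expected, abs=1e-6)

    def test_monotone_in_soft_true_positives(self):
        """Moving probability mass onto the true class never raises the
        focal-Tversky part of the loss."""
        p, t = _random_batch(7)
        config = LossConfig()
        base = sum(focal_tversky_terms(p, t, config))
        for step in (0.05, 0.15, 0.3):
            better = p + step * (t - p)  # convex shift toward the truth
            improved = sum(focal_tversky_terms(better, t, config))
            assert improved <= base + 1e-12
            base = improved

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradient_matches_finite_differences(self, seed):
        p, t = _random_batch(seed)
        config = LossConfig()
        _, grad = combined_loss_and_grad(p, t, config)
        rng = np.random.default_rng(seed + 100)
        eps = 1e-6
        for _ in range(12):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            plus = p.copy()
            plus[idx] += eps
            minus = p.copy()
            minus[idx] -= eps
            fd = (combined_loss(plus, t, config) - combined_loss(minus, t, config)) / (
                2 * eps
            )
            denom = max(abs(fd), abs(grad[idx]), 1e-8)
            assert abs(fd - grad[idx]) / denom < 1e-3

    def test_directional_sensitivity_of_fp_vs_fn_terms(self):
        """The FP-weighted term reacts more to added false positives; the
        FN-weighted term reacts more to removed true mass."""
        p, t = _random_batch(9)
        config = LossConfig()
        base1, base2 = focal_tversky_terms(p, t, config)
        # add false-positive mass on class 1 where truth is 0
        fp = p.copy()
        bump = 0.2 * (1 - t[..., 1]) * p[..., 0]
        fp[..., 1] += bump
        fp[..., 0] -= bump
        d1_fp = focal_tversky_terms(fp, t, config)[0] - base1
        d2_fp = focal_tversky_terms(fp, t, config)[1] - base2
        assert d1_fp > d2_fp > 0
        # remove true-positive mass from class 1 (creates false negatives)
        fn = p.copy()
        drop = 0.2 * t[..., 1] * p[..., 1]
        fn[..., 1] -= drop
        fn[..., 0] += drop
        d1_fn = focal_tversky_terms(fn, t, config)[0] - base1
        d2_fn = focal_tversky_terms(fn, t, config)[1] - base2
        assert d2_fn > d1_fn > 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combined_loss(np.ones((2, 3)) / 3, np.ones((3, 3)) / 3)
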