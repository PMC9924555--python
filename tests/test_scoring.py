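"""Guideline scoring rules: Allred, Ki67 bands, HER2 membranes, subtype."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from ihcsubtype import scoring
from ihcsubtype.scoring import (
    HER2CellFeatures,
    NucleiCounts,
    ScoringConfig,
    allred_intensity_score,
    allred_proportion_score,
    allred_score,
    decide_subtype,
    er_pr_status,
    her2_intensity_class,
    her2_membrane_completeness,
    her2_score,
    ki67_proliferation_index,
    ki67_status,
    majority_vote,
)
from ihcsubtype.types import (
    AllredScore,
    BiomarkerStatus,
    ER_PR_CATEGORIES,
    HER2_SCORE_CATEGORIES,
    KI67_CATEGORIES,
    Subtype,
)


class TestAllred:
    @pytest.mark.parametrize(
        "positive,total,expected_ps",
        [
            (0, 100, 0),
            (1, 100, 1),
            (5, 100, 2),
            (25, 100, 3),
            (50, 100, 4),  # 0.5 in (1/3, 2/3]
            (100, 100, 5),
        ],
    )
    def test_proportion_bins(self, positive, total, expected_ps):
        counts = NucleiCounts(
            negative=total - positive, weak_pos=0, strong_pos=positive
        )
        assert allred_proportion_score(counts) == expected_ps

    def test_empty_slide_has_no_score(self):
        with pytest.raises(scoring.UndefinedScoreError):
            allred_proportion_score(NucleiCounts(0, 0, 0))

    @pytest.mark.parametrize(
        "weak,strong,expected_is",
        [(0, 0, 0), (10, 0, 1), (0, 10, 3), (10, 10, 2)],
    )
    def test_intensity_from_weak_strong_mixture(self, weak, strong, expected_is):
        counts = NucleiCounts(negative=50, weak_pos=weak, strong_pos=strong)
        assert allred_intensity_score(counts) == expected_is

    @pytest.mark.parametrize(
        "ts,expected", [(0, "neg"), (2, "neg"), (3, "pos"), (8, "pos")]
    )
    def test_status_boundary_at_total_score_three(self, ts, expected):
        ps = min(ts, 5)
        is_ = ts - ps
        if ps == 0 and is_ > 0:
            pytest.skip("invalid combination")
        assert er_pr_status(AllredScore(proportion=ps, intensity=is_)) == expected

    def test_adding_strong_positives_never_flips_pos_to_neg(self):
        """Monotonicity: more stain can only move the call toward positive."""
        counts = NucleiCounts(negative=90, weak_pos=0, strong_pos=2)
        previous = er_pr_status(allred_score(counts))
        for extra in range(1, 80, 7):
            more = NucleiCounts(negative=90, weak_pos=0, strong_pos=2 + extra)
            current = er_pr_status(allred_score(more))
            assert not (previous == "pos" and current == "neg")
            previous = current


class TestKi67:
    @pytest.mark.parametrize(
        "np_,nn,expected",
        [(0, 50, 0.0), (50, 50, 50.0), (30, 70, 30.0), (21, 79, 21.0)],
    )
    def test_proliferation_index_arithmetic(self, np_, nn, expected):
        assert ki67_proliferation_index(np_, nn) == pytest.approx(expected)

    def test_empty_slide_has_no_index(self):
        with pytest.raises(scoring.UndefinedScoreError):
            ki67_proliferation_index(0, 0)

    @pytest.mark.parametrize(
        "pi,expected",
        [
            (13.999, "low"),
            (14.0, "intermediate"),
            (21.0, "intermediate"),
            (21.001, "high"),
            (0.0, "low"),
            (100.0, "high"),
        ],
    )
    def test_band_boundaries(self, pi, expected):
        assert ki67_status(pi) == expected

    def test_bands_partition_the_index_range(self):
        """Every PI in [0, 100] falls in exactly one band."""
        for pi in np.linspace(0, 100, 2001):
            assert ki67_status(float(pi)) in KI67_CATEGORIES


def _ring(shape=(64, 64), center=(32, 32), r_in=10, r_out=13, span_deg=360):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    rho = np.hypot(dy, dx)
    ring = (rho > r_in) & (rho <= r_out)
    if span_deg < 360:
        phi = np.degrees(np.arctan2(dy, dx)) % 360
        ring &= phi <= span_deg
    return ring


class TestHER2Membrane:
    def test_full_ring_is_complete(self):
        nucleus = _ring(r_in=-1, r_out=9)  # solid disk
        membrane = _ring(r_in=10, r_out=13)
        c = her2_membrane_completeness(nucleus, membrane, radius=5)
        assert c == pytest.approx(1.0, abs=0.02)

    def test_half_ring_is_half_complete(self):
        nucleus = _ring(r_in=-1, r_out=9)
        membrane = _ring(r_in=10, r_out=13, span_deg=180)
        c = her2_membrane_completeness(nucleus, membrane, radius=5)
        assert c == pytest.approx(0.5, abs=0.05)

    def test_no_membrane_is_zero(self):
        nucleus = _ring(r_in=-1, r_out=9)
        membrane = np.zeros_like(nucleus)
        assert her2_membrane_completeness(nucleus, membrane, radius=5) == 0.0

    def test_degenerate_nucleus_rejected(self):
        with pytest.raises(ValueError):
            her2_membrane_completeness(
                np.zeros((16, 16), bool), np.zeros((16, 16), bool)
            )

    def test_intensity_fallback_is_deterministic_and_separates_colors(self):
        rng = np.random.default_rng(0)
        membrane = _ring()
        dark = np.full((64, 64, 3), 235, np.uint8)
        dark[membrane] = (90, 55, 30)
        faint = np.full((64, 64, 3), 235, np.uint8)
        faint[membrane] = (190, 160, 130)
        assert her2_intensity_class(dark, membrane) == "intense"
        assert her2_intensity_class(faint, membrane) == "faint"
        assert her2_intensity_class(dark, membrane) == her2_intensity_class(
            dark, membrane
        )

    def test_intensity_needs_membrane_pixels(self):
        with pytest.raises(scoring.UndefinedScoreError):
            her2_intensity_class(
                np.zeros((8, 8, 3), np.uint8), np.zeros((8, 8), bool)
            )


class TestIntensityClassifier:
    def test_shallow_cnn_learns_faint_vs_intense(self):
        """The learned intensity path separates generator faint/intense
        HER2 slides after a short fit."""
        from ihcsubtype import synth
        from ihcsubtype.intensity import train_intensity_classifier

        images, labels = [], []
        for i in range(8):
            intensity = "intense" if i % 2 == 0 else "faint"
            config = synth.default_slide_config(
                "HER2", image_shape=(96, 128), seed=60 + i
            )
            config.nuclei_counts = {1: 4}
            config.nucleus_radius_range = (5.0, 7.0)
            config.membrane_intensity = intensity
            image, _, _ = synth.generate_slide(config)
            images.append(image.pixels)
            labels.append(intensity)
        clf = train_intensity_classifier(
            images[:6], labels[:6], epochs=25, seed=0
        )
        assert [clf.predict(im) for im in images[6:]] == labels[6:]


class TestHER2Score:
    def test_complete_intense_is_3plus_positive(self):
        f = HER2CellFeatures(completeness=(0.95,) * 10, intensity_class="intense")
        assert her2_score(f) == ("3+", "pos")

    def test_complete_faint_is_2plus_equivocal(self):
        f = HER2CellFeatures(completeness=(0.95,) * 10, intensity_class="faint")
        assert her2_score(f) == ("2+", "equivocal")

    def test_incomplete_faint_is_1plus_negative(self):
        f = HER2CellFeatures(completeness=(0.4,) * 10, intensity_class="faint")
        assert her2_score(f) == ("1+", "neg")

    def test_no_membrane_is_0_negative(self):
        f = HER2CellFeatures(completeness=(0.0,) * 10, intensity_class="faint")
        assert her2_score(f) == ("0", "neg")

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            her2_score(HER2CellFeatures(completeness=(), intensity_class="faint"))


class TestMajorityVote:
    @pytest.mark.parametrize(
        "statuses,kind,expected",
        [
            (["pos", "pos", "neg"], "er", "pos"),
            (["low", "low", "high"], "ki67", "low"),
            (["pos", "neg"], "er", "pos"),  # tie broken toward pos
            (["low", "high"], "ki67", "high"),  # tie broken toward high
            (["0", "3+"], "her2_score", "3+"),  # higher score wins ties
        ],
    )
    def test_modal_and_tie_break(self, statuses, kind, expected):
        assert majority_vote(statuses, kind) == expected

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([], "er")


class TestDecideSubtype:
    @pytest.mark.parametrize(
        "er,pr,ki67,her2_score_,expected",
        [
            ("neg", "neg", "low", "0", Subtype.TRIPLE_NEGATIVE),
            ("neg", "neg", "high", "1+", Subtype.TRIPLE_NEGATIVE),
            ("pos", "pos", "low", "0", Subtype.LUMINAL_A),
            ("pos", "pos", "intermediate", "0", Subtype.LUMINAL_A),
            ("pos", "neg", "high", "0", Subtype.LUMINAL_B),
            ("pos", "pos", "low", "3+", Subtype.LUMINAL_B),
            ("neg", "neg", "high", "3+", Subtype.HER2_ENRICHED),
        ],
    )
    def test_decision_table(self, er, pr, ki67, her2_score_, expected):
        status = BiomarkerStatus(
            er=er,
            pr=pr,
            ki67=ki67,
            her2_score=her2_score_,
            her2=scoring.her2_status_from_score(her2_score_),
        )
        assert decide_subtype(status).subtype is expected

    def test_total_over_all_status_combinations(self):
        """Every ER x PR x Ki67 x HER2 combination yields a subtype or an
        explicit indeterminate flag, and equivocal coercion removes the
        indeterminates."""
        for er, pr, ki67, hs in itertools.product(
            ER_PR_CATEGORIES, ER_PR_CATEGORIES, KI67_CATEGORIES, HER2_SCORE_CATEGORIES
        ):
            status = BiomarkerStatus(
                er=er,
                pr=pr,
                ki67=ki67,
                her2_score=hs,
                her2=scoring.her2_status_from_score(hs),
            )
            call = decide_subtype(status)
            if hs == "2+":
                assert call.indeterminate and call.subtype is None
                coerced = decide_subtype(status, coerce_equivocal="neg")
                assert coerced.subtype is not None
            else:
                assert call.subtype is not None


class TestTruthObjectScoring:
    def test_truth_counts_reproduce_cohort_status(self, ki67_slide):
        _, _, objects = ki67_slide
        # 20 positive of 100 nuclei -> PI 20% -> intermediate band
        assert scoring.score_truth_objects(objects, "KI67") == "intermediate"

    def test_her2_truth_scoring(self, her2_slide):
        _, _, objects = her2_slide
        score, status = scoring.score_truth_her2(objects, "intense")
        assert (score, status) == ("3+", "pos")
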