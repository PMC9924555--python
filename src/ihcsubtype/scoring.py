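"""Guideline-based biomarker scoring and the molecular-subtype decision.

ER/PR slides are scored with the Allred system: a proportion score PS in 0-5
from the fraction of positively stained tumor nuclei, an intensity score IS
in 0-3 from the staining strength, and total score TS = PS + IS with TS >= 3
called positive. Ki67 uses the proliferation index PI = 100*Np/(Np+Nn) with
bands low (PI < 14), intermediate (14 <= PI <= 21) and high (PI > 21). HER2
combines membrane-staining completeness (fraction of the cell perimeter
covered) and intensity (faint/intense) into the clinical 0/1+/2+/3+ score;
3+ is positive, 2+ equivocal, otherwise negative. Slide-level statuses are
combined per patient by majority vote, and the four patient-level statuses
map to one of the four intrinsic subtypes (Luminal A, Luminal B,
HER2-enriched, Triple-negative) via an editable decision table.

Because clinical centers use slightly different cut-offs, every threshold
(Allred bins, completeness cut-off, 10%-of-cells rule, intensity optical
density) lives in a config dataclass and can be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import (
    AllredScore,
    BiomarkerStatus,
    ER_PR_CATEGORIES,
    HER2_SCORE_CATEGORIES,
    KI67_CATEGORIES,
    Subtype,
    SubtypeCall,
    ValidationError,
)


class UndefinedScoreError(ValueError):
    """Raised when a score is requested for an empty slide."""


@dataclass(frozen=True)
class NucleiCounts:
    """Per-slide ER/PR nucleus counts by staining class."""

    negative: int
    weak_pos: int
    strong_pos: int

    def __post_init__(self) -> None:
        if min(self.negative, self.weak_pos, self.strong_pos) < 0:
            raise ValidationError("nucleus counts must be non-negative")

    @property
    def positive(self) -> int:
        return self.weak_pos + self.strong_pos

    @property
    def total(self) -> int:
        return self.negative + self.positive


@dataclass(frozen=True)
class HER2CellFeatures:
    """Per-slide HER2 evidence: membrane completeness per cell + intensity."""

    completeness: tuple[float, ...]
    intensity_class: str  # "faint" or "intense"

    def __post_init__(self) -> None:
        if any(not (0.0 <= c <= 1.0) for c in self.completeness):
            raise ValidationError("completeness values must lie in [0, 1]")
        if self.intensity_class not in ("faint", "intense"):
            raise ValidationError("intensity_class must be faint or intense")


@dataclass
class ScoringConfig:
    """All scoring thresholds in one editable place."""

    # Allred proportion bins: upper bounds of PS 1..4 (PS 0 at exactly zero,
    # PS 5 above the last bound)
    allred_proportion_bounds: tuple[float, ...] = (0.01, 0.10, 1 / 3, 2 / 3)
    allred_positive_min_ts: int = 3
    ki67_low_max: float = 14.0  # PI < low_max  -> low
    ki67_high_min: float = 21.0  # PI > high_min -> high
    her2_complete_threshold: float = 0.9
    her2_fraction_threshold: float = 0.10
    her2_weak_min_completeness: float = 0.10
    her2_intensity_od_threshold: float = 0.40
    her2_membrane_radius: int = 5
    # Ki67 "intermediate" groups with "low" for the Luminal A/B split
    ki67_high_statuses: tuple[str, ...] = ("high",)
    coerce_equivocal: str | None = None  # map HER2 2+ to "neg" when set


@dataclass(frozen=True)
class PatientTruth:
    """A ground-truth biomarker tuple for one (synthetic) patient."""

    er: str
    pr: str
    ki67: str
    her2_score: str

    def __post_init__(self) -> None:
        if self.er not in ER_PR_CATEGORIES or self.pr not in ER_PR_CATEGORIES:
            raise ValidationError("ER/PR truth must be pos/neg")
        if self.ki67 not in KI67_CATEGORIES:
            raise ValidationError(f"unknown Ki67 category {self.ki67!r}")
        if self.her2_score not in HER2_SCORE_CATEGORIES:
            raise ValidationError(f"unknown HER2 score {self.her2_score!r}")

    def to_status(self) -> BiomarkerStatus:
        return BiomarkerStatus(
            er=self.er,
            pr=self.pr,
            ki67=self.ki67,
            her2_score=self.her2_score,
            her2=her2_status_from_score(self.her2_score),
        )


# ---------------------------------------------------------------------------
# Allred (ER/PR)
# ---------------------------------------------------------------------------


def allred_proportion_score(
    counts: NucleiCounts, config: ScoringConfig | None = None
) -> int:
    """Allred PS: 0 for no positives, then 1..5 by positive fraction bins."""
    config = config or ScoringConfig()
    if counts.total == 0:
        raise UndefinedScoreError("no nuclei on slide; proportion undefined")
    f = counts.positive / counts.total
    if f == 0.0:
        return 0
    for score, bound in enumerate(config.allred_proportion_bounds, start=1):
        if f <= bound:
            return score
    return 5


def allred_intensity_score(counts: NucleiCounts) -> int:
    """Allred IS from the weak/strong mixture.

    Weak nuclei score 1 and strong nuclei 3; the count-weighted mean is
    rounded half-up to the nearest of {1, 2, 3}. No positives -> 0.
    """
    if counts.positive == 0:
        return 0
    mean = (1.0 * counts.weak_pos + 3.0 * counts.strong_pos) / counts.positive
    return int(min(3, max(1, math.floor(mean + 0.5))))


def allred_score(counts: NucleiCounts, config: ScoringConfig | None = None) -> AllredScore:
    ps = allred_proportion_score(counts, config)
    is_ = allred_intensity_score(counts) if ps > 0 else 0
    return AllredScore(proportion=ps, intensity=is_)


def er_pr_status(score: AllredScore, config: ScoringConfig | None = None) -> str:
    """Positive iff total score reaches the configured minimum (TS >= 3)."""
    config = config or ScoringConfig()
    return "pos" if score.total >= config.allred_positive_min_ts else "neg"


# ---------------------------------------------------------------------------
# Ki67
# ---------------------------------------------------------------------------


def ki67_proliferation_index(n_positive: int, n_negative: int) -> float:
    """PI = 100 * Np / (Np + Nn), in percent."""
    if min(n_positive, n_negative) < 0:
        raise ValidationError("counts must be non-negative")
    total = n_positive + n_negative
    if total == 0:
        raise UndefinedScoreError("no nuclei; proliferation index undefined")
    return 100.0 * n_positive / total


def ki67_status(pi: float, config: ScoringConfig | None = None) -> str:
    """low (PI < 14), intermediate (14 <= PI <= 21), high (PI > 21)."""
    config = config or ScoringConfig()
    if not (0.0 <= pi <= 100.0):
        raise ValidationError(f"proliferation index {pi} outside [0, 100]")
    if pi < config.ki67_low_max:
        return "low"
    if pi <= config.ki67_high_min:
        return "intermediate"
    return "high"


# ---------------------------------------------------------------------------
# HER2
# ---------------------------------------------------------------------------


def her2_membrane_completeness(
    nucleus_mask: np.ndarray, membrane_mask: np.ndarray, radius: int = 5
) -> float:
    """Fraction of directions around a nucleus showing membrane stain.

    Casts a ray from the nucleus centroid at each of 360 one-degree steps,
    finds the nucleus boundary along the ray, and checks for any membrane
    pixel within ``radius`` pixels beyond it.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    membrane_mask = np.asarray(membrane_mask, dtype=bool)
    if nucleus_mask.shape != membrane_mask.shape:
        raise ValidationError("nucleus and membrane masks must share a grid")
    ys, xs = np.nonzero(nucleus_mask)
    if len(ys) == 0:
        raise ValidationError("degenerate nucleus: no pixels")
    cy, cx = float(ys.mean()), float(xs.mean())
    h, w = nucleus_mask.shape
    max_extent = int(math.hypot(ys.max() - ys.min(), xs.max() - xs.min())) + radius + 3

    hits = 0
    for deg in range(360):
        theta = math.radians(deg)
        dy, dx = math.sin(theta), math.cos(theta)
        # walk outwards to find the last nucleus pixel on this ray
        boundary = 0.0
        misses = 0
        r = 0.0
        while r <= max_extent and misses < 3:
            y, x = int(round(cy + r * dy)), int(round(cx + r * dx))
            if 0 <= y < h and 0 <= x < w and nucleus_mask[y, x]:
                boundary = r
                misses = 0
            else:
                misses += 1
            r += 1.0
        found = False
        r = boundary + 1.0
        while r <= boundary + radius:
            y, x = int(round(cy + r * dy)), int(round(cx + r * dx))
            if 0 <= y < h and 0 <= x < w and membrane_mask[y, x]:
                found = True
                break
            r += 1.0
        hits += found
    return hits / 360.0


def her2_intensity_class(
    image: np.ndarray,
    membrane_mask: np.ndarray,
    config: ScoringConfig | None = None,
    classifier=None,
) -> str:
    """Classify membrane staining as faint or intense.

    The primary path is a trained shallow CNN classifier (see
    :mod:`ihcsubtype.intensity`); the default fallback thresholds the mean
    optical density OD = -log10(I/255) of the membrane pixels, which is
    deterministic and needs no training.
    """
    config = config or ScoringConfig()
    membrane_mask = np.asarray(membrane_mask, dtype=bool)
    if not membrane_mask.any():
        raise UndefinedScoreError("no membrane pixels; intensity undefined")
    if classifier is not None:
        return classifier.predict(image)
    pixels = np.asarray(image, dtype=np.float64)[membrane_mask]
    od = -np.log10(np.clip(pixels, 1.0, 255.0) / 255.0)
    return "intense" if od.mean() >= config.her2_intensity_od_threshold else "faint"


def her2_score(
    features: HER2CellFeatures, config: ScoringConfig | None = None
) -> tuple[str, str]:
    """Map per-cell completeness + slide intensity to (score, status).

    Complete (completeness >= 0.9) intense membrane in >= 10% of cells gives
    3+; complete but faint gives 2+; incomplete faint staining in >= 10% of
    cells gives 1+; anything less gives 0. Status: 3+ -> pos, 2+ ->
    equivocal, 0/1+ -> neg.
    """
    config = config or ScoringConfig()
    comp = np.asarray(features.completeness, dtype=float)
    if comp.size == 0:
        raise ValidationError("HER2 scoring needs at least one cell")
    frac_complete = float((comp >= config.her2_complete_threshold).mean())
    frac_any = float((comp >= config.her2_weak_min_completeness).mean())
    if frac_complete >= config.her2_fraction_threshold:
        score = "3+" if features.intensity_class == "intense" else "2+"
    elif frac_any >= config.her2_fraction_threshold:
        score = "1+"
    else:
        score = "0"
    return score, her2_status_from_score(score)


def her2_status_from_score(score: str) -> str:
    if score not in HER2_SCORE_CATEGORIES:
        raise ValidationError(f"unknown HER2 score {score!r}")
    return {"0": "neg", "1+": "neg", "2+": "equivocal", "3+": "pos"}[score]


# ---------------------------------------------------------------------------
# Patient-level aggregation
# ---------------------------------------------------------------------------

_TIE_PRIORITIES: dict[str, tuple[str, ...]] = {
    "er": ("pos", "neg"),
    "pr": ("pos", "neg"),
    "ki67": ("high", "intermediate", "low"),
    "her2_score": ("3+", "2+", "1+", "0"),
    "her2": ("pos", "equivocal", "neg"),
}


def majority_vote(statuses: list[str], kind: str = "er") -> str:
    """Modal category; ties broken by a fixed clinical-priority order.

    Priorities: pos > neg, high > intermediate > low, higher HER2 score wins.
    """
    if not statuses:
        raise ValidationError("cannot vote over an empty status list")
    priority = _TIE_PRIORITIES.get(kind)
    if priority is None:
        raise ValidationError(f"unknown vote kind {kind!r}")
    unknown = set(statuses) - set(priority)
    if unknown:
        raise ValidationError(f"unknown categories for {kind}: {sorted(unknown)}")
    counts = {c: statuses.count(c) for c in set(statuses)}
    best = max(counts.values())
    tied = [c for c, n in counts.items() if n == best]
    return min(tied, key=priority.index)


def decide_subtype(
    status: BiomarkerStatus, coerce_equivocal: str | None = None
) -> SubtypeCall:
    """St Gallen-style decision table over the four biomarker statuses.

    Hormone-receptor positive (ER+ and/or PR+) tumors are Luminal A when
    HER2-negative and Ki67 is not high, Luminal B when HER2-positive or Ki67
    high; hormone-receptor negative tumors are HER2-enriched when HER2+ and
    Triple-negative when HER2-. An equivocal HER2 (2+) yields an
    indeterminate call ("reflex testing advised") unless ``coerce_equivocal``
    maps it to ``"neg"``.
    """
    her2 = status.her2
    if her2 == "equivocal":
        if coerce_equivocal is None:
            return SubtypeCall(
                subtype=None,
                indeterminate=True,
                reason="HER2 2+ equivocal; reflex testing advised",
            )
        if coerce_equivocal != "neg":
            raise ValidationError("coerce_equivocal must be None or 'neg'")
        her2 = "neg"
    hr_positive = status.er == "pos" or status.pr == "pos"
    ki67_high = status.ki67 == "high"
    if hr_positive:
        if her2 == "pos" or ki67_high:
            return SubtypeCall(subtype=Subtype.LUMINAL_B)
        return SubtypeCall(subtype=Subtype.LUMINAL_A)
    if her2 == "pos":
        return SubtypeCall(subtype=Subtype.HER2_ENRICHED)
    return SubtypeCall(subtype=Subtype.TRIPLE_NEGATIVE)


# ---------------------------------------------------------------------------
# Scoring straight from generator ground truth (oracle bypass)
# ---------------------------------------------------------------------------


def score_truth_objects(
    objects, biomarker, config: ScoringConfig | None = None
) -> str:
    """Slide status from a ground-truth object list, bypassing segmentation.

    Closes the loop for end-to-end testing: counting the generator's objects
    and pushing the counts through the same scoring rules must reproduce the
    cohort truth table exactly.
    """
    from .types import Biomarker  # local import to keep module load light

    config = config or ScoringConfig()
    biomarker = Biomarker(biomarker)
    classes = [o.class_id for o in objects]
    if biomarker in (Biomarker.ER, Biomarker.PR):
        counts = NucleiCounts(
            negative=classes.count(1),
            weak_pos=classes.count(2),
            strong_pos=classes.count(3),
        )
        return er_pr_status(allred_score(counts, config), config)
    if biomarker is Biomarker.KI67:
        pi = ki67_proliferation_index(classes.count(2), classes.count(1))
        return ki67_status(pi, config)
    raise ValidationError(
        "HER2 truth scoring needs slide intensity; use score_truth_her2"
    )


def score_truth_her2(
    objects, intensity_class: str, config: ScoringConfig | None = None
) -> tuple[str, str]:
    """(score, status) for a HER2 slide from ground-truth completeness."""
    features = HER2CellFeatures(
        completeness=tuple(o.completeness or 0.0 for o in objects),
        intensity_class=intensity_class,
    )
    return her2_score(features, config)
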