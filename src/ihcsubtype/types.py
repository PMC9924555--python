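"""Core domain types shared across the pipeline.

The pipeline works on brightfield immunohistochemistry (IHC) slides of four
biomarkers — estrogen receptor (ER), progesterone receptor (PR), the
proliferation antigen Ki67, and the membrane receptor HER2 — each segmented
into a biomarker-specific set of pixel classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Biomarker(str, Enum):
    ER = "ER"
    PR = "PR"
    KI67 = "KI67"
    HER2 = "HER2"


class ClassSet(Enum):
    """Pixel-class vocabulary of a segmentation mask.

    ERPR_4CLASS: 0 background, 1 immunonegative, 2 weak-positive, 3 strong-positive.
    KI67_3CLASS: 0 background, 1 immunonegative, 2 immunopositive.
    HER2_3CLASS: 0 background, 1 nucleus, 2 membrane.
    """

    ERPR_4CLASS = ("background", "immunonegative", "weak_positive", "strong_positive")
    KI67_3CLASS = ("background", "immunonegative", "immunopositive")
    HER2_3CLASS = ("background", "nucleus", "membrane")

    @property
    def class_names(self) -> tuple[str, ...]:
        return self.value

    @property
    def n_classes(self) -> int:
        return len(self.value)

    @property
    def foreground_classes(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_classes))

    @classmethod
    def for_biomarker(cls, biomarker: Biomarker | str) -> "ClassSet":
        biomarker = Biomarker(biomarker)
        if biomarker in (Biomarker.ER, Biomarker.PR):
            return cls.ERPR_4CLASS
        if biomarker is Biomarker.KI67:
            return cls.KI67_3CLASS
        return cls.HER2_3CLASS


class FormatError(ValueError):
    """Raised for files or arrays that violate an I/O contract."""


class DimensionError(ValueError):
    """Raised when spatial dimensions violate an operation's precondition."""


class ValidationError(ValueError):
    """Raised for inconsistent manifests, configs, or truth tables."""


class CapacityError(RuntimeError):
    """Raised when requested synthetic objects cannot be placed."""


@dataclass
class SlideImage:
    """One RGB IHC slide with patient/biomarker provenance."""

    pixels: np.ndarray  # H x W x 3, uint8
    patient_id: str
    biomarker: Biomarker
    slide_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.biomarker = Biomarker(self.biomarker)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(f"slide pixels must be HxWx3, got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise DimensionError("slide must have positive height and width")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise FormatError("slide intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class ClassMask:
    """Per-pixel integer class labels aligned with a :class:`SlideImage`."""

    labels: np.ndarray  # H x W integer
    class_set: ClassSet

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError(f"mask labels must be HxW, got {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("mask labels must be integers")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.class_set.n_classes
        ):
            raise ValidationError(
                f"labels outside [0, {self.class_set.n_classes - 1}] for {self.class_set}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class PatchGrid:
    """Row-major tiling bookkeeping for non-overlapping patch extraction."""

    rows: int
    cols: int
    patch_size: int
    model_size: int
    origin_shape: tuple[int, int]

    @property
    def n_patches(self) -> int:
        return self.rows * self.cols


@dataclass
class InstanceLabels:
    """Connected objects after watershed splitting.

    ``labels`` uses 0 for background and ids 1..K for instances;
    ``instance_class`` maps each id to its pixel class.
    """

    labels: np.ndarray  # H x W int32
    instance_class: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        ids = np.unique(self.labels)
        ids = ids[ids > 0]
        if len(ids) and (set(ids.tolist()) != set(range(1, len(ids) + 1))):
            raise ValidationError("instance ids must be contiguous from 1")
        missing = set(ids.tolist()) - set(self.instance_class)
        if missing:
            raise ValidationError(f"instances without a class: {sorted(missing)}")

    @property
    def n_instances(self) -> int:
        return len(self.instance_class)


@dataclass(frozen=True)
class AllredScore:
    """Allred proportion + intensity score for ER/PR slides."""

    proportion: int  # 0-5
    intensity: int  # 0-3

    def __post_init__(self) -> None:
        if not (0 <= self.proportion <= 5):
            raise ValidationError("proportion score must be in 0..5")
        if not (0 <= self.intensity <= 3):
            raise ValidationError("intensity score must be in 0..3")
        if self.proportion == 0 and self.intensity != 0:
            raise ValidationError("zero proportion implies zero intensity")

    @property
    def total(self) -> int:
        return self.proportion + self.intensity


class Subtype(str, Enum):
    LUMINAL_A = "LuminalA"
    LUMINAL_B = "LuminalB"
    HER2_ENRICHED = "HER2Enriched"
    TRIPLE_NEGATIVE = "TripleNegative"


ER_PR_CATEGORIES = ("pos", "neg")
KI67_CATEGORIES = ("low", "intermediate", "high")
HER2_SCORE_CATEGORIES = ("0", "1+", "2+", "3+")
HER2_STATUS_CATEGORIES = ("pos", "neg", "equivocal")


@dataclass(frozen=True)
class BiomarkerStatus:
    """Patient- or slide-level categorical calls for the four biomarkers."""

    er: str
    pr: str
    ki67: str
    her2_score: str
    her2: str

    def __post_init__(self) -> None:
        for value, allowed, name in (
            (self.er, ER_PR_CATEGORIES, "er"),
            (self.pr, ER_PR_CATEGORIES, "pr"),
            (self.ki67, KI67_CATEGORIES, "ki67"),
            (self.her2_score, HER2_SCORE_CATEGORIES, "her2_score"),
            (self.her2, HER2_STATUS_CATEGORIES, "her2"),
        ):
            if value not in allowed:
                raise ValidationError(f"{name}={value!r} not in {allowed}")


@dataclass(frozen=True)
class SubtypeCall:
    """Molecular-subtype decision; ``indeterminate`` flags an equivocal HER2."""

    subtype: Subtype | None
    indeterminate: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if (self.subtype is None) != self.indeterminate:
            raise ValidationError("exactly one of subtype / indeterminate must hold")
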