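"""Synthetic IHC slide generator with pixel-perfect ground truth.

Emulates the appearance of DAB/hematoxylin-stained breast-biopsy slides well
enough to exercise every pipeline stage: violet immunonegative nuclei, solid
dark-brown strongly positive nuclei, granular faint-brown weakly positive
nuclei, whitish background, and — for HER2 — brown membrane rings of
configurable completeness and intensity around blue-violet nuclei. Nuclei
are rotated ellipses with mild eccentricity; the class-pixel imbalance of
real ER slides (background:strong:negative:weak ≈ 141:14:6:1) is reproduced
by the default ER/PR configuration.

Every slide comes with its exact class mask and a ground-truth object list
(center, radii, class, per-cell membrane completeness), so segmentation,
counting and scoring can each be validated against construction truth.
Cohort generation assigns each synthetic patient a biomarker-status tuple
and samples per-slide nuclei mixtures that sit safely inside the scoring
bins for that status, which lets end-to-end tests demand exact recovery of
the truth table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import imgio, scoring
from .types import (
    Biomarker,
    CapacityError,
    ClassMask,
    ClassSet,
    SlideImage,
    ValidationError,
)

# Nominal slide geometry of the emulated dataset (40x magnification).
FULL_SLIDE_SHAPE = (1440, 1920)

# Stain color models (mean RGB): hematoxylin violet, solid and faint DAB brown.
VIOLET = (120.0, 90.0, 170.0)
DARK_BROWN = (110.0, 70.0, 40.0)
FAINT_BROWN = (170.0, 130.0, 90.0)
BACKGROUND = (235.0, 230.0, 225.0)
MEMBRANE_INTENSE = (90.0, 55.0, 30.0)
MEMBRANE_FAINT = (170.0, 130.0, 95.0)

# Average pixel parts per class on ER slides: background, strong-positive,
# immunonegative, weak-positive.
ERPR_PIXEL_PARTS = {0: 141.0, 3: 14.0, 1: 6.0, 2: 1.0}

_HER2_SCORE_PARAMS: dict[str, tuple[tuple[float, float], str]] = {
    "0": ((0.0, 0.05), "faint"),
    "1+": ((0.25, 0.60), "faint"),
    "2+": ((0.95, 1.0), "faint"),
    "3+": ((0.95, 1.0), "intense"),
}


@dataclass(frozen=True)
class NucleusTruth:
    """Ground truth for one painted nucleus."""

    center: tuple[float, float]  # (row, col)
    radii: tuple[float, float]  # (row-axis, col-axis) before rotation
    angle: float  # radians
    class_id: int
    completeness: float | None = None  # HER2 membrane arc fraction

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SynthSlideConfig:
    biomarker: Biomarker
    image_shape: tuple[int, int] = FULL_SLIDE_SHAPE
    nuclei_counts: dict[int, int] = field(default_factory=dict)
    nucleus_radius_range: tuple[float, float] = (8.0, 12.0)
    color_model: dict[int, tuple[tuple[float, float, float], float]] = field(
        default_factory=dict
    )
    membrane_thickness: float = 3.0
    membrane_gap: float = 1.0
    membrane_completeness_range: tuple[float, float] = (0.95, 1.0)
    membrane_intensity: str = "intense"  # "faint" or "intense"
    background_color: tuple[float, float, float] = BACKGROUND
    noise_std: float = 5.0
    overlap_fraction: float = 0.0
    min_separation: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.biomarker = Biomarker(self.biomarker)
        if any(c < 0 for c in self.nuclei_counts.values()):
            raise ValidationError("nuclei counts must be non-negative")
        if self.nucleus_radius_range[0] < 1:
            raise ValidationError("nucleus radii must be >= 1 px")
        lo, hi = self.membrane_completeness_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("completeness range must lie within [0, 1]")
        if self.membrane_intensity not in ("faint", "intense"):
            raise ValidationError("membrane_intensity must be faint or intense")
        for mean, _std in self.color_model.values():
            if min(mean) < 0 or max(mean) > 255:
                raise ValidationError("color means must lie in [0, 255]")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValidationError("overlap_fraction must lie in [0, 1]")

    @property
    def class_set(self) -> ClassSet:
        return ClassSet.for_biomarker(self.biomarker)


def _default_colors(biomarker: Biomarker) -> dict[int, tuple[tuple[float, float, float], float]]:
    if biomarker in (Biomarker.ER, Biomarker.PR):
        return {1: (VIOLET, 8.0), 2: (FAINT_BROWN, 10.0), 3: (DARK_BROWN, 8.0)}
    if biomarker is Biomarker.KI67:
        return {1: (VIOLET, 8.0), 2: (DARK_BROWN, 8.0)}
    return {1: (VIOLET, 8.0)}  # HER2 nuclei; membrane color set by intensity


def mean_nucleus_area(radius_range: tuple[float, float]) -> float:
    """Expected painted ellipse area for radii drawn uniformly per axis."""
    mid = 0.5 * (radius_range[0] + radius_range[1])
    return math.pi * mid * mid


def erpr_ratio_counts(
    image_shape: tuple[int, int],
    radius_range: tuple[float, float] = (8.0, 12.0),
) -> dict[int, int]:
    """Nuclei counts reproducing the 141:14:6:1 ER class-pixel imbalance."""
    area = image_shape[0] * image_shape[1]
    total_parts = sum(ERPR_PIXEL_PARTS.values())
    mean_area = mean_nucleus_area(radius_range)
    counts = {}
    for class_id, parts in ERPR_PIXEL_PARTS.items():
        if class_id == 0:
            continue
        counts[class_id] = max(1, round(parts / total_parts * area / mean_area))
    return counts


def default_slide_config(
    biomarker: Biomarker | str,
    image_shape: tuple[int, int] = FULL_SLIDE_SHAPE,
    seed: int = 0,
    **overrides,
) -> SynthSlideConfig:
    """Study-condition defaults per biomarker at the given slide size."""
    biomarker = Biomarker(biomarker)
    area = image_shape[0] * image_shape[1]
    if biomarker in (Biomarker.ER, Biomarker.PR):
        counts = erpr_ratio_counts(image_shape)
    elif biomarker is Biomarker.KI67:
        total = max(20, round(area / 3500))
        n_pos = round(0.3 * total)
        counts = {1: total - n_pos, 2: n_pos}
    else:
        counts = {1: max(6, round(area / 9000))}
    config = SynthSlideConfig(
        biomarker=biomarker,
        image_shape=tuple(image_shape),
        nuclei_counts=counts,
        color_model=_default_colors(biomarker),
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(config, key, value)
    config.__post_init__()
    return config


# ---------------------------------------------------------------------------
# Rasterization helpers
# ---------------------------------------------------------------------------


def _ellipse_mask(
    shape: tuple[int, int],
    cy: float,
    cx: float,
    ry: float,
    rx: float,
    angle: float,
    scale_out: float = 1.0,
    scale_in: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates inside a rotated ellipse (or annulus).

    ``scale_out``/``scale_in`` multiply the radii, so an annulus is the set
    with normalized radius in (scale_in, scale_out].
    """
    rmax = max(ry, rx) * scale_out + 2
    y0, y1 = max(0, int(cy - rmax)), min(shape[0], int(cy + rmax) + 1)
    x0, x1 = max(0, int(cx - rmax)), min(shape[1], int(cx + rmax) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ca, sa = math.cos(angle), math.sin(angle)
    u = dy * ca + dx * sa
    v = -dy * sa + dx * ca
    rho2 = (u / ry) ** 2 + (v / rx) ** 2
    keep = rho2 <= scale_out**2
    if scale_in is not None:
        keep &= rho2 > scale_in**2
    return yy[keep], xx[keep]


def _arc_filter(
    yy: np.ndarray, xx: np.ndarray, cy: float, cx: float, start: float, span: float
) -> np.ndarray:
    """Keep annulus pixels whose polar angle lies within [start, start+span)."""
    phi = np.arctan2(yy - cy, xx - cx)
    rel = np.mod(phi - start, 2 * math.pi)
    return rel <= span


# ---------------------------------------------------------------------------
# Slide generation
# ---------------------------------------------------------------------------


def generate_slide(
    config: SynthSlideConfig,
) -> tuple[SlideImage, ClassMask, list[NucleusTruth]]:
    """Paint one synthetic slide and its exact class mask.

    Nuclei are placed by rejection sampling with a per-slide attempt budget;
    a :class:`CapacityError` is raised when the requested counts do not fit.
    ``overlap_fraction`` bounds the share of nuclei allowed to overlap an
    earlier one (used to exercise watershed splitting).
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    class_set = config.class_set
    n_cls = class_set.n_classes
    for class_id in config.nuclei_counts:
        if not (1 <= class_id < n_cls):
            raise ValidationError(
                f"class {class_id} invalid for {class_set.name}"
            )
        if class_set is ClassSet.HER2_3CLASS and class_id == 2:
            raise ValidationError("HER2 membrane pixels are generated, not counted")

    canvas = np.empty((h, w, 3), dtype=np.float32)
    canvas[:] = config.background_color
    mask = np.zeros((h, w), dtype=np.int64)

    is_her2 = config.biomarker is Biomarker.HER2
    extra = (
        config.membrane_gap + config.membrane_thickness + 1 if is_her2 else 0.0
    )
    total = sum(config.nuclei_counts.values())
    overlap_budget = int(config.overlap_fraction * total)
    placed: list[tuple[float, float, float]] = []  # (cy, cx, reserve radius)
    truth: list[NucleusTruth] = []
    attempts_left = 400 * max(total, 1)

    membrane_color = (
        MEMBRANE_INTENSE if config.membrane_intensity == "intense" else MEMBRANE_FAINT
    )

    for class_id in sorted(config.nuclei_counts):
        for _ in range(config.nuclei_counts[class_id]):
            while True:
                if attempts_left <= 0:
                    raise CapacityError(
                        f"could not place {total} nuclei on a {h}x{w} slide"
                    )
                attempts_left -= 1
                ry, rx = rng.uniform(*config.nucleus_radius_range, size=2)
                angle = rng.uniform(0.0, math.pi)
                reserve = max(ry, rx) + extra + config.min_separation
                if 2 * reserve >= min(h, w):
                    raise CapacityError("nucleus larger than the slide")
                cy = rng.uniform(reserve, h - reserve)
                cx = rng.uniform(reserve, w - reserve)
                overlapping = any(
                    math.hypot(cy - py, cx - px) < reserve + pr
                    for py, px, pr in placed
                )
                if overlapping:
                    # allow a mild overlap while the configured budget lasts
                    near = min(
                        (math.hypot(cy - py, cx - px) / (reserve + pr)
                         for py, px, pr in placed),
                        default=1.0,
                    )
                    if overlap_budget > 0 and near > 0.6:
                        overlap_budget -= 1
                    else:
                        continue
                placed.append((cy, cx, max(ry, rx) + extra))
                break

            yy, xx = _ellipse_mask((h, w), cy, cx, ry, rx, angle)
            mask[yy, xx] = class_id
            mean, std = config.color_model.get(class_id, (VIOLET, 8.0))
            color = np.clip(rng.normal(mean, std), 0, 255)
            canvas[yy, xx] = color

            completeness: float | None = None
            if is_her2:
                completeness = float(
                    rng.uniform(*config.membrane_completeness_range)
                )
                if completeness > 0:
                    g, t = config.membrane_gap, config.membrane_thickness
                    rmin = min(ry, rx)
                    yy_r, xx_r = _ellipse_mask(
                        (h, w),
                        cy,
                        cx,
                        ry,
                        rx,
                        angle,
                        scale_out=1.0 + (g + t) / rmin,
                        scale_in=1.0 + g / rmin,
                    )
                    start = rng.uniform(0.0, 2 * math.pi)
                    keep = _arc_filter(
                        yy_r, xx_r, cy, cx, start, completeness * 2 * math.pi
                    )
                    yy_r, xx_r = yy_r[keep], xx_r[keep]
                    free = mask[yy_r, xx_r] == 0
                    yy_r, xx_r = yy_r[free], xx_r[free]
                    mask[yy_r, xx_r] = 2
                    canvas[yy_r, xx_r] = np.clip(
                        rng.normal(membrane_color, 8.0), 0, 255
                    )
            truth.append(
                NucleusTruth(
                    center=(float(cy), float(cx)),
                    radii=(float(ry), float(rx)),
                    angle=float(angle),
                    class_id=class_id,
                    completeness=completeness,
                )
            )

    canvas += rng.normal(0.0, config.noise_std, size=canvas.shape)
    image = SlideImage(
        pixels=np.clip(canvas, 0, 255).astype(np.uint8),
        patient_id="",
        biomarker=config.biomarker,
        slide_id=f"synthetic-{config.seed}",
    )
    return image, ClassMask(mask, class_set), truth


# ---------------------------------------------------------------------------
# Status-consistent nuclei mixtures
# ---------------------------------------------------------------------------


def _allred_counts(total: int, status: str, rng: np.random.Generator) -> dict[int, int]:
    """Negative/weak/strong counts landing safely inside an Allred bin."""
    if total < 8:
        raise ValidationError("need at least 8 nuclei for an ER/PR slide")
    if status == "pos":
        n_pos = round(rng.uniform(0.45, 0.62) * total)
        n_strong = max(1, round(rng.uniform(0.78, 0.90) * n_pos))
        n_weak = n_pos - n_strong
    elif status == "neg":
        n_pos = n_strong = n_weak = 0
    else:
        raise ValidationError(f"unknown ER/PR status {status!r}")
    return {1: total - n_pos, 2: n_weak, 3: n_strong}


def _ki67_counts(total: int, status: str, rng: np.random.Generator) -> dict[int, int]:
    """Positive/negative counts whose proliferation index lands in the band."""
    if total < 15:
        raise ValidationError("need at least 15 nuclei for a Ki67 slide")
    low_max = math.ceil(0.14 * total) - 1
    mid_lo, mid_hi = math.ceil(0.14 * total), math.floor(0.21 * total)
    if status == "low":
        n_pos = int(rng.integers(max(0, low_max // 2), low_max + 1))
    elif status == "intermediate":
        if mid_hi < mid_lo:
            raise ValidationError(
                f"{total} nuclei cannot realize an intermediate proliferation index"
            )
        n_pos = int(rng.integers(mid_lo, mid_hi + 1))
    elif status == "high":
        n_pos = int(rng.integers(mid_hi + 1, max(mid_hi + 2, round(0.42 * total) + 1)))
    else:
        raise ValidationError(f"unknown Ki67 status {status!r}")
    return {1: total - n_pos, 2: n_pos}


def slide_config_for_status(
    biomarker: Biomarker | str,
    status: "scoring.PatientTruth | None" = None,
    image_shape: tuple[int, int] = FULL_SLIDE_SHAPE,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    **overrides,
) -> SynthSlideConfig:
    """A slide config whose expected scoring outcome matches ``status``."""
    biomarker = Biomarker(biomarker)
    rng = rng if rng is not None else np.random.default_rng(seed)
    config = default_slide_config(biomarker, image_shape, seed=seed, **overrides)
    if status is None:
        return config
    total = sum(config.nuclei_counts.values())
    if biomarker in (Biomarker.ER, Biomarker.PR):
        marker = status.er if biomarker is Biomarker.ER else status.pr
        config.nuclei_counts = _allred_counts(total, marker, rng)
    elif biomarker is Biomarker.KI67:
        config.nuclei_counts = _ki67_counts(total, status.ki67, rng)
    else:
        comp_range, intensity = _HER2_SCORE_PARAMS[status.her2_score]
        config.membrane_completeness_range = comp_range
        config.membrane_intensity = intensity
    return config


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    n_patients: int = 15
    slides_per_patient: int = 10  # per biomarker
    image_shape: tuple[int, int] = FULL_SLIDE_SHAPE
    truth_statuses: dict[str, "scoring.PatientTruth"] | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValidationError("a cohort needs at least 2 patients")
        if self.slides_per_patient < 1:
            raise ValidationError("need at least one slide per patient")


def default_cohort_statuses(n_patients: int) -> list["scoring.PatientTruth"]:
    """Representative biomarker-status tuples cycled across patients."""
    combos = [
        ("pos", "pos", "low", "0"),
        ("pos", "neg", "high", "1+"),
        ("pos", "pos", "intermediate", "3+"),
        ("neg", "neg", "high", "3+"),
        ("neg", "neg", "high", "0"),
        ("neg", "neg", "low", "1+"),
        ("pos", "pos", "intermediate", "0"),
        ("pos", "neg", "low", "0"),
        ("neg", "neg", "intermediate", "3+"),
        ("pos", "pos", "high", "3+"),
    ]
    return [
        scoring.PatientTruth(*combos[i % len(combos)]) for i in range(n_patients)
    ]


def generate_cohort(
    spec: CohortSpec, outdir: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write a full synthetic cohort to disk.

    Produces PNG slides, indexed-PNG masks, per-slide truth-object JSONs, a
    dataset manifest CSV and a patient truth table CSV. Returns the manifest
    and truth table as DataFrames. Fully deterministic in ``master_seed``.
    """
    outdir = Path(outdir)
    for sub in ("images", "masks", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    patient_ids = [f"P{i + 1:02d}" for i in range(spec.n_patients)]
    if spec.truth_statuses is None:
        statuses = dict(zip(patient_ids, default_cohort_statuses(spec.n_patients)))
    else:
        statuses = {str(k): v for k, v in spec.truth_statuses.items()}
        missing = [p for p in patient_ids if p not in statuses]
        if missing:
            raise ValidationError(f"truth table missing patients {missing}")

    seed_rng = np.random.default_rng(spec.master_seed)
    mix_rng = np.random.default_rng(spec.master_seed + 1)
    rows = []
    for patient_id in patient_ids:
        truth_status = statuses[patient_id]
        for biomarker in Biomarker:
            for s in range(spec.slides_per_patient):
                slide_seed = int(seed_rng.integers(0, 2**31 - 1))
                config = slide_config_for_status(
                    biomarker,
                    truth_status,
                    image_shape=spec.image_shape,
                    seed=slide_seed,
                    rng=mix_rng,
                )
                image, mask, objects = generate_slide(config)
                slide_id = f"{patient_id}_{biomarker.value}_s{s:02d}"
                image.patient_id = patient_id
                image.slide_id = slide_id
                slide_path = outdir / "images" / f"{slide_id}.png"
                mask_path = outdir / "masks" / f"{slide_id}.png"
                truth_path = outdir / "truth" / f"{slide_id}.json"
                imgio.save_slide(image, slide_path)
                imgio.save_mask(mask, mask_path)
                truth_path.write_text(
                    json.dumps([o.to_dict() for o in objects], indent=0)
                )
                rows.append(
                    {
                        "slide_path": str(slide_path),
                        "mask_path": str(mask_path),
                        "patient_id": patient_id,
                        "biomarker": biomarker.value,
                        "slide_id": slide_id,
                        "truth_path": str(truth_path),
                    }
                )
    manifest = pd.DataFrame(rows)
    imgio.write_manifest(manifest, outdir / "manifest.csv")

    truth_rows = []
    for patient_id in patient_ids:
        t = statuses[patient_id]
        call = scoring.decide_subtype(t.to_status(), coerce_equivocal="neg")
        truth_rows.append(
            {
                "patient_id": patient_id,
                "er": t.er,
                "pr": t.pr,
                "ki67": t.ki67,
                "her2_score": t.her2_score,
                "her2": scoring.her2_status_from_score(t.her2_score),
                "subtype": call.subtype.value if call.subtype else "indeterminate",
            }
        )
    truth_table = pd.DataFrame(truth_rows)
    truth_table.to_csv(outdir / "truth.csv", index=False)
    return manifest, truth_table


def load_truth_objects(path: str | Path) -> list[NucleusTruth]:
    data = json.loads(Path(path).read_text())
    return [
        NucleusTruth(
            center=tuple(d["center"]),
            radii=tuple(d["radii"]),
            angle=d["angle"],
            class_id=d["class_id"],
            completeness=d["completeness"],
        )
        for d in data
    ]
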