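"""End-to-end orchestration: segment -> post-process -> score -> subtype.

For every slide in a manifest the pipeline obtains a class mask (from a
per-biomarker trained model, or directly from the reference masks when
``use_truth_masks`` is set — the oracle-bypass mode used for validation),
cleans it, splits instances, counts objects and computes the slide-level
biomarker status. Slide statuses are majority-voted per patient and
biomarker, and the four patient-level statuses are combined into the
molecular subtype. Patients lacking any of the four biomarkers are reported
as incomplete and excluded from the subtype table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imgio
from .net import SegModel
from .postproc import PostprocConfig, process_mask
from .scoring import (
    HER2CellFeatures,
    NucleiCounts,
    ScoringConfig,
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
from .train import TrainConfig, predict_slide
from .types import Biomarker, BiomarkerStatus, ClassMask, ClassSet, ValidationError

log = logging.getLogger("ihcsubtype")


@dataclass
class RunConfig:
    manifest_path: str | Path
    model_paths: dict[str, str | Path] = field(default_factory=dict)
    use_truth_masks: bool = False
    outdir: str | Path | None = None
    postproc: PostprocConfig = field(default_factory=PostprocConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0


def her2_slide_features(
    image_pixels: np.ndarray,
    cleaned: ClassMask,
    instances,
    scoring_config: ScoringConfig,
) -> HER2CellFeatures:
    """Per-nucleus membrane completeness + slide intensity for HER2.

    Completeness is measured in a local window around each nucleus so large
    slides stay cheap.
    """
    membrane = cleaned.labels == 2
    completeness = []
    radius = scoring_config.her2_membrane_radius
    for inst_id, class_id in instances.instance_class.items():
        if class_id != 1:
            continue
        nucleus = instances.labels == inst_id
        ys, xs = np.nonzero(nucleus)
        pad = radius + 8
        y0, y1 = max(0, ys.min() - pad), min(nucleus.shape[0], ys.max() + pad + 1)
        x0, x1 = max(0, xs.min() - pad), min(nucleus.shape[1], xs.max() + pad + 1)
        completeness.append(
            her2_membrane_completeness(
                nucleus[y0:y1, x0:x1], membrane[y0:y1, x0:x1], radius
            )
        )
    if membrane.any():
        intensity = her2_intensity_class(image_pixels, membrane, scoring_config)
    else:
        intensity = "faint"
    return HER2CellFeatures(
        completeness=tuple(completeness), intensity_class=intensity
    )


def score_slide(
    image_pixels: np.ndarray | None,
    mask: ClassMask,
    biomarker: Biomarker | str,
    postproc_config: PostprocConfig | None = None,
    scoring_config: ScoringConfig | None = None,
) -> dict:
    """Slide-level counts, scores, and status from a segmentation mask."""
    biomarker = Biomarker(biomarker)
    postproc_config = postproc_config or PostprocConfig()
    scoring_config = scoring_config or ScoringConfig()
    cleaned, instances, counts = process_mask(mask, postproc_config)
    row: dict = {"biomarker": biomarker.value}
    if biomarker in (Biomarker.ER, Biomarker.PR):
        nuclei = NucleiCounts(
            negative=counts.get(1, 0),
            weak_pos=counts.get(2, 0),
            strong_pos=counts.get(3, 0),
        )
        score = allred_score(nuclei, scoring_config)
        row.update(
            n_negative=nuclei.negative,
            n_weak=nuclei.weak_pos,
            n_strong=nuclei.strong_pos,
            proportion_score=score.proportion,
            intensity_score=score.intensity,
            total_score=score.total,
            status=er_pr_status(score, scoring_config),
        )
    elif biomarker is Biomarker.KI67:
        n_pos, n_neg = counts.get(2, 0), counts.get(1, 0)
        pi = ki67_proliferation_index(n_pos, n_neg)
        row.update(
            n_positive=n_pos,
            n_negative=n_neg,
            proliferation_index=pi,
            status=ki67_status(pi, scoring_config),
        )
    else:
        if image_pixels is None:
            raise ValidationError("HER2 scoring needs the slide image")
        features = her2_slide_features(
            image_pixels, cleaned, instances, scoring_config
        )
        score, status = her2_score(features, scoring_config)
        row.update(
            n_cells=len(features.completeness),
            mean_completeness=(
                float(np.mean(features.completeness)) if features.completeness else 0.0
            ),
            intensity=features.intensity_class,
            her2_score=score,
            status=status,
        )
    return row


def run_subtyping(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Run the full pipeline over a manifest.

    Returns (per-slide report, per-patient subtype report, incomplete
    patients). Deterministic in inference mode for a fixed checkpoint set.
    """
    manifest = imgio.read_manifest(config.manifest_path)
    models: dict[str, SegModel] = {}
    if not config.use_truth_masks:
        for biomarker in Biomarker:
            path = config.model_paths.get(biomarker.value)
            if path is None:
                raise ValidationError(
                    f"no model checkpoint for {biomarker.value}; "
                    "either provide one or set use_truth_masks"
                )
            models[biomarker.value] = SegModel.load(path)

    slide_rows = []
    for row in manifest.itertuples():
        biomarker = Biomarker(row.biomarker)
        class_set = ClassSet.for_biomarker(biomarker)
        image = imgio.load_slide(
            row.slide_path, patient_id=str(row.patient_id), biomarker=biomarker
        )
        if config.use_truth_masks:
            mask = imgio.load_mask(row.mask_path, class_set)
        else:
            mask = predict_slide(
                models[biomarker.value], image, class_set, config.train
            )
            h = min(mask.shape[0], image.shape[0])
            w = min(mask.shape[1], image.shape[1])
            mask = ClassMask(mask.labels[:h, :w], class_set)
        scored = score_slide(
            image.pixels[: mask.shape[0], : mask.shape[1]],
            mask,
            biomarker,
            config.postproc,
            config.scoring,
        )
        scored["patient_id"] = str(row.patient_id)
        scored["slide_id"] = getattr(row, "slide_id", Path(row.slide_path).stem)
        log.info(
            "scored slide %s (%s): status=%s",
            scored["slide_id"],
            biomarker.value,
            scored["status"],
        )
        slide_rows.append(scored)
    per_slide = pd.DataFrame(slide_rows)

    patient_rows = []
    incomplete: list[str] = []
    for patient_id, group in per_slide.groupby("patient_id", sort=True):
        have = set(group["biomarker"])
        if have != {b.value for b in Biomarker}:
            log.warning(
                "patient %s missing biomarkers %s; excluded from subtyping",
                patient_id,
                sorted({b.value for b in Biomarker} - have),
            )
            incomplete.append(str(patient_id))
            continue

        def vote(marker: str, kind: str) -> str:
            statuses = group[group["biomarker"] == marker]["status"].tolist()
            return majority_vote(statuses, kind)

        her2_scores = group[group["biomarker"] == "HER2"]["her2_score"].tolist()
        her2_score_vote = majority_vote(her2_scores, "her2_score")
        status = BiomarkerStatus(
            er=vote("ER", "er"),
            pr=vote("PR", "pr"),
            ki67=vote("KI67", "ki67"),
            her2_score=her2_score_vote,
            her2=vote("HER2", "her2"),
        )
        call = decide_subtype(status, config.scoring.coerce_equivocal)
        patient_rows.append(
            {
                "patient_id": str(patient_id),
                "er": status.er,
                "pr": status.pr,
                "ki67": status.ki67,
                "her2_score": status.her2_score,
                "her2": status.her2,
                "subtype": call.subtype.value if call.subtype else "indeterminate",
            }
        )
    per_patient = pd.DataFrame(patient_rows)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        per_slide.to_csv(outdir / "slide_report.csv", index=False)
        per_patient.to_csv(outdir / "patient_report.csv", index=False)
        if incomplete:
            (outdir / "incomplete_patients.txt").write_text("\n".join(incomplete))
    return per_slide, per_patient, incomplete
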