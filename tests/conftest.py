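"""Shared fixtures: small synthetic slides and cohorts built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from ihcsubtype import synth
from ihcsubtype.types import Biomarker


@pytest.fixture(scope="session")
def ki67_slide():
    """A 320x400 Ki67 slide with 80 negative / 20 positive nuclei."""
    config = synth.default_slide_config(
        Biomarker.KI67, image_shape=(320, 400), seed=11
    )
    config.nuclei_counts = {1: 80, 2: 20}
    image, mask, objects = synth.generate_slide(config)
    return image, mask, objects


@pytest.fixture(scope="session")
def her2_slide():
    """A 240x320 HER2 slide with complete intense membranes."""
    config = synth.default_slide_config(
        Biomarker.HER2, image_shape=(240, 320), seed=13
    )
    image, mask, objects = synth.generate_slide(config)
    return image, mask, objects


@pytest.fixture(scope="session")
def erpr_slide():
    """A 240x320 ER slide with a mixed weak/strong/negative population."""
    config = synth.default_slide_config(Biomarker.ER, image_shape=(240, 320), seed=17)
    config.nuclei_counts = {1: 30, 2: 5, 3: 15}
    image, mask, objects = synth.generate_slide(config)
    return image, mask, objects


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 4-patient cohort written to disk (1 slide per biomarker each)."""
    outdir = tmp_path_factory.mktemp("cohort")
    spec = synth.CohortSpec(
        n_patients=4,
        slides_per_patient=1,
        image_shape=(192, 256),
        master_seed=23,
    )
    manifest, truth = synth.generate_cohort(spec, outdir)
    return outdir, manifest, truth
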