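"""Shared fixtures: small phantoms and a miniature cohort with features."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from radstab import preprocess, synthgen
from radstab.features import FeatureConfig
from radstab.features.extract import extract_all


@pytest.fixture(scope="session")
def disk_case():
    """Noise-free disk phantom, radius 10 mm at 1 mm spacing."""
    return synthgen.make_phantom(
        synthgen.PhantomSpec(axes_mm=(10.0, 10.0), image_size=48, seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort (8 patients, 12 variants) shared by integration tests."""
    spec = synthgen.CohortSpec(
        n_patients=8, k_manual=1, manual_amplitude_mm=0.0,
        perturbation=synthgen.PerturbationSpec(n_variants=12, amplitude_mm=1.0))
    return synthgen.make_cohort(spec, master_seed=7)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    """Patient-indexed wide feature table of the tiny cohort."""
    kept, _ = preprocess.crop_cohort(small_cohort.cases,
                                     preprocess.CropRule(box_size=40))
    table = extract_all(kept, FeatureConfig())
    l2p = {c.lesion_id: c.patient_id for c in small_cohort.cases}
    table.index = pd.MultiIndex.from_tuples(
        [(l2p[l], s) for l, s in table.index],
        names=["patient_id", "segmentation_id"])
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
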