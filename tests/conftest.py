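"""Shared fixtures: a small phantom cohort and its fused volumes.

Everything is generated programmatically and seeded; the session scope
keeps the expensive preprocessing to a single run.
"""

from __future__ import annotations

import numpy as np
import pytest

from msknet.pipeline import fuse_cohort
from msknet.synthetic_phantom import PhantomConfig, generate_cohort

#: Fixture cohort: 10 exams, every task has both classes in both splits.
COHORT_CONFIG = PhantomConfig(
    n_exams=10,
    prevalence_abnormal=0.75,
    prevalence_meniscus=0.5,
    prevalence_edema=0.5,
    co_occurrence_rate=0.5,
    slice_range=(14, 15),
    image_size=64,
    seed=0,
    test_fraction=0.3,
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(COHORT_CONFIG)


@pytest.fixture(scope="session")
def small_volumes(small_cohort):
    exams, manifest = small_cohort
    volumes, stats = fuse_cohort(exams, manifest)
    return volumes, stats


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
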