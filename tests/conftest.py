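"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ari_profiles.cohort import (
    ClinicalSimConfig,
    CohortConfig,
    generate_clinical,
    generate_expression,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort with planted signal (300 genes, 4 subjects/group)."""
    config = CohortConfig(
        n_genes=300, n_subjects_per_group=4,
        n_core_d2=20, n_shared_d6=20, n_distinct_d6=20,
        seed=11,
    )
    expr, annot, truth = generate_expression(config)
    return config, expr, annot, truth


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted effects (500 genes, 4 subjects/group)."""
    config = CohortConfig(
        n_genes=500, n_subjects_per_group=4,
        n_core_d2=0, n_shared_d6=0, n_distinct_d6=0,
        seed=23,
    )
    expr, annot, truth = generate_expression(config)
    return config, expr, annot, truth


@pytest.fixture(scope="session")
def clinical_series(small_cohort):
    config, _, annot, _ = small_cohort
    return generate_clinical(ClinicalSimConfig(seed=config.seed), annot)


@pytest.fixture()
def paired_toy_annotation():
    """One group, two subjects, BL and D2 each (hand-checkable GLS)."""
    return pd.DataFrame(
        {
            "subject_id": ["s1", "s1", "s2", "s2"],
            "group": ["Healthy"] * 4,
            "timepoint": ["BL", "D2", "BL", "D2"],
        },
        index=pd.Index(["s1_BL", "s1_D2", "s2_BL", "s2_D2"],
                       name="sample_id"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
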