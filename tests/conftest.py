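"""Shared fixtures: small hand-built cohorts and a seeded simulated pair."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gbmsubtypes import (
    Cohort,
    SimulationConfig,
    score_cohort,
    select_pgs,
    simulate_cohort_pair,
)


def make_cohort(expression: np.ndarray, os_months, event, gene_ids=None,
                sample_ids=None, name="test", **extra) -> Cohort:
    """Build a cohort from raw arrays with auto-generated identifiers."""
    n_genes, n_samples = np.asarray(expression).shape
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{i:03d}" for i in range(n_samples)]
    clinical = pd.DataFrame(
        {"os_months": np.asarray(os_months, float), "event": np.asarray(event, int),
         **extra},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    expr = pd.DataFrame(np.asarray(expression, float),
                        index=pd.Index(gene_ids, name="gene_id"),
                        columns=sample_ids)
    return Cohort(expression=expr, clinical=clinical, name=name)


@pytest.fixture(scope="session")
def pair7():
    """Default-condition simulated cohort pair (seed 7): 500 genes, 200
    samples per cohort, 20 poor + 20 favorable planted genes, beta = 1."""
    config = SimulationConfig(seed=7)
    cohort_a, cohort_b, truth = simulate_cohort_pair(config)
    return cohort_a, cohort_b, truth


@pytest.fixture(scope="session")
def selection7(pair7):
    cohort_a, cohort_b, _ = pair7
    return select_pgs(cohort_a, cohort_b, k=20)


@pytest.fixture(scope="session")
def scores7(pair7, selection7):
    cohort_a, _, _ = pair7
    poor_set, fav_set = selection7.gene_sets()
    return score_cohort(cohort_a, poor_set, fav_set)
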