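"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

from hierde.synthetic import (
    CohortDesign,
    SimulationParams,
    generate_metadata,
    simulate_expression,
)


@pytest.fixture(scope="session")
def cohort_meta():
    """Default 15 case / 30 control cohort over four regions, no missingness."""
    return generate_metadata(CohortDesign(seed=11, missing_rate=0.0))


@pytest.fixture(scope="session")
def small_meta():
    """Small cohort for fast unit tests: 4 case / 6 control, two regions."""
    design = CohortDesign(n_case=4, n_control=6, regions=("HIP", "TCx"),
                          missing_rate=0.0, seed=7)
    return generate_metadata(design)


@pytest.fixture(scope="session")
def null_cohort(cohort_meta):
    """300-gene null cohort (no DE genes) with the default trend."""
    params = SimulationParams(n_genes=300, de_fraction=0.0)
    matrix, truth = simulate_expression(cohort_meta, params, seed=23)
    return matrix, truth, cohort_meta


def model_scale_cohort(meta, n_genes, tau, sigma, logfc=0.0, seed=0):
    """Simulate directly from the random-intercept model (no FPKM transform).

    Used where a test needs exact control of τ and σ on the log2 scale.
    """
    rng = np.random.default_rng(seed)
    subjects, codes = np.unique(meta["subject_id"], return_inverse=True)
    n = len(meta)
    is_ad = (meta["diagnosis"] == "AD").to_numpy(dtype=float)
    u = rng.normal(0.0, tau, (n_genes, len(subjects)))
    eps = rng.normal(0.0, sigma, (n_genes, n))
    Y = logfc * is_ad[None, :] + u[:, codes] + eps
    return pd.DataFrame(Y, index=[f"g{i:04d}" for i in range(n_genes)],
                        columns=meta["sample_id"].to_numpy())
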