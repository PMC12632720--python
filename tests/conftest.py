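import numpy as np
import pandas as pd
import pytest

from dynbag import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """Tiny cohort used across modules: 24 subjects, 10 components."""
    return CohortSpec(n_subjects=24, n_components=10, n_timepoints=100, seed=5)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_cohort(small_spec)


@pytest.fixture(scope="session")
def assoc_pheno() -> pd.DataFrame:
    """Deterministic phenotype table for association-model tests."""
    rng = np.random.default_rng(11)
    n = 80
    return pd.DataFrame({
        "id": [f"S{k:03d}" for k in range(n)],
        "age": rng.uniform(40, 80, n),
        "sex": np.where(rng.random(n) < 0.5, "F", "M"),
        "site": np.where(rng.random(n) < 0.5, "siteA", "siteB"),
        "dx": np.where(rng.random(n) < 0.5, "SZ", "HC"),
        "attention": rng.normal(50, 1, n),
        "working_memory": rng.normal(50, 1, n),
    })
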