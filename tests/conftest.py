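import numpy as np
import pandas as pd
import pytest

from microshift.core_io import AbundanceTable, CohortMetadata
from microshift.synthetic import ArmEffect, SyntheticConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table(rng):
    """6 features x 4 samples, positive relative abundances."""
    raw = rng.lognormal(0, 1, (6, 4))
    rel = raw / raw.sum(axis=0)
    return AbundanceTable(
        pd.DataFrame(rel, index=[f"sp{i}" for i in range(6)],
                     columns=[f"s{i}" for i in range(4)]),
        kind="relative_abundance",
    )


@pytest.fixture
def paired_meta():
    """4 subjects x 2 timepoints in one arm."""
    rows = []
    for i in range(4):
        for d in (0, 90):
            rows.append({"sample_id": f"S{i}_d{d}", "subject_id": f"S{i}",
                         "arm": "drug", "timepoint_day": d})
    return CohortMetadata(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture(scope="session")
def null_cohort():
    """Null-effect cohort at the fingerprint-premise settings."""
    cfg = SyntheticConfig(n_subjects=50, n_species=100, seed=1,
                          arm_effects={"placebo": ArmEffect(0.0, 0.0)})
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def strong_cohort():
    """Strongly perturbed single-arm cohort (30% species, effect scale 2)."""
    cfg = SyntheticConfig(n_subjects=50, n_species=100, seed=1,
                          arm_effects={"drug": ArmEffect(0.3, 2.0)})
    return simulate_cohort(cfg)
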