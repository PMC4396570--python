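"""Shared fixtures: synthetic cohorts at the study's design scale.

All fixtures are seeded and session-scoped; nothing is read from disk.
"""

import numpy as np
import pandas as pd
import pytest

from methylodrift import (SimulationConfig, estimate_prior, fit_probe_models,
                          generate_dataset, moderated_t)

STANDARD_SEED = 42


@pytest.fixture(scope="session")
def standard_config():
    """10 individuals x 7 timepoints, 2000 probes, planted dM = 2,
    sigma_resid = sigma_individual = 0.5 — the reference study conditions."""
    return SimulationConfig(seed=STANDARD_SEED)


@pytest.fixture(scope="session")
def standard_cohort(standard_config):
    return generate_dataset(standard_config)


@pytest.fixture(scope="session")
def standard_m_dataset(standard_cohort):
    return standard_cohort.dataset.normalized().to_m()


@pytest.fixture(scope="session")
def standard_diffmeth(standard_m_dataset):
    fits = fit_probe_models(standard_m_dataset)
    prior = estimate_prior(fits)
    return moderated_t(fits, prior, alpha=0.01)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects of any kind: pure individual offsets + noise."""
    cfg = SimulationConfig(frac_age_methylated=0.0, frac_age_demethylated=0.0,
                           frac_snp_probes=0.0, frac_celltype_probes=0.0,
                           seed=STANDARD_SEED + 1)
    return generate_dataset(cfg)


@pytest.fixture
def tiny_m_dataset():
    """4 individuals x 3 timepoints, 20 probes, hand-scale for OLS oracles."""
    rng = np.random.default_rng(7)
    rows = []
    for i in range(4):
        for a in (3.0, 12.0, 60.0):
            rows.append((f"c{i}_m{a:g}", f"c{i}", a))
    samples = pd.DataFrame(rows, columns=["sample_id", "individual_id", "age_months"])
    values = pd.DataFrame(rng.normal(0, 1, size=(20, len(samples))),
                          index=[f"cg{p:08d}" for p in range(20)],
                          columns=samples["sample_id"])
    from methylodrift import MethylationDataset
    return MethylationDataset(values, samples, scale="M")
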