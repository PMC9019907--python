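import numpy as np
import pandas as pd
import pytest

from fatsig import SimulationConfig, simulate_multi_cohort


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7, n_cohorts=2)


@pytest.fixture(scope="session")
def cohort_pair(default_config):
    """Training + one platform-shifted validation cohort, generator defaults."""
    return simulate_multi_cohort(default_config)


@pytest.fixture(scope="session")
def training_cohort(cohort_pair):
    return cohort_pair[0]


def null_config(seed: int, **overrides) -> SimulationConfig:
    """All planted effects switched off."""
    kwargs = dict(
        seed=seed, delta_log2=0.0, group_delta_log2=0.0, anchor_mut_delta=0.0,
        rho=0.0, hr_hazard_ratio=1.0, rt_hazard_ratio=1.0,
        interaction_effect=1.0, platform_shift_sd=0.0, platform_scale_sd=0.0,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def random_expression(rng: np.random.Generator, n_genes: int = 10,
                      n_samples: int = 6) -> pd.DataFrame:
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"S{i}" for i in range(n_samples)]
    return pd.DataFrame(rng.normal(8.0, 1.0, size=(n_genes, n_samples)),
                        index=pd.Index(genes, name="gene_id"), columns=samples)
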