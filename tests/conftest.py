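import numpy as np
import pandas as pd
import pytest

from mitotick import (
    BetaMatrix,
    SimulationConfig,
    simulate_cell_profiles,
    simulate_purified_panel,
    simulate_whole_blood_cohort,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Reduced-size study conditions for fast unit tests (the generator's
    scientific defaults — rates, shifts, noise — are untouched)."""
    return SimulationConfig(
        seed=11,
        n_cpgs_total=1200,
        n_clock_cpgs=100,
        n_reference_cpgs_per_type=20,
        n_age_cpgs=20,
        n_cases=120,
        n_controls=120,
        n_control_probes=60,
        n_progression_patients=50,
    )


@pytest.fixture(scope="session")
def panel(small_cfg):
    return simulate_purified_panel(small_cfg)


@pytest.fixture(scope="session")
def cohort(small_cfg):
    return simulate_whole_blood_cohort(small_cfg)


@pytest.fixture(scope="session")
def profiles(small_cfg):
    return simulate_cell_profiles(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2021)


def random_beta_matrix(
    rng: np.random.Generator,
    n_cpgs: int = 8,
    n_samples: int = 5,
    missing_rate: float = 0.0,
) -> BetaMatrix:
    vals = rng.uniform(0, 1, size=(n_cpgs, n_samples))
    if missing_rate:
        vals[rng.uniform(size=vals.shape) < missing_rate] = np.nan
    return BetaMatrix(pd.DataFrame(
        vals,
        index=[f"cg{i:05d}" for i in range(n_cpgs)],
        columns=[f"S{j}" for j in range(n_samples)],
    ))
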