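import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phitrend import synthetic_data as syn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_design():
    """A 21-year, 30-species frame small enough for per-test fits."""
    return syn.SimulationDesign(
        n_obs=300, n_species=30, n_families=6, year_start=1990, year_end=2010
    )


@pytest.fixture(scope="session")
def small_trend_dataset(small_design):
    data, table, truth = syn.simulate_trend_dataset(small_design, seed=7)
    return data, table, truth


@pytest.fixture(scope="session")
def small_pglmm_dataset(small_design):
    table, tree, truth = syn.simulate_pglmm_dataset(small_design, seed=7)
    return table, tree, truth


@pytest.fixture()
def clean_obs_table():
    """Ten valid growth-curve rows in the raw input schema."""
    rng = np.random.default_rng(42)
    n = 10
    return pd.DataFrame(
        {
            "species": [f"sp{i:02d}" for i in range(n)],
            "family": ["fam1"] * 5 + ["fam2"] * 5,
            "L_inf_cm": rng.uniform(20, 120, n).round(1),
            "K_per_year": rng.uniform(0.1, 0.9, n).round(3),
            "length_measure": ["TL"] * n,
            "aging_method": ["otolith"] * 6 + ["length_frequency"] * 4,
            "year": rng.integers(1950, 2020, n),
            "latitude": rng.uniform(-50, 50, n).round(2),
            "longitude": rng.uniform(-170, 170, n).round(2),
        }
    )
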