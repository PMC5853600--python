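import numpy as np
import pandas as pd
import pytest

from lightresponse import FitConfig, default_scenario, generate, run_mcmc
from lightresponse.bayes import PosteriorChain


@pytest.fixture(scope="session")
def phi_dataset():
    """Default-scenario phi_II dataset: 8 treatments x 6 reps x 8 intensities."""
    return generate(default_scenario(), kinds=("phi_ii",), seed=1234)


@pytest.fixture(scope="session")
def wt_sl_air(phi_dataset):
    return phi_dataset[phi_dataset["treatment"] == "WT_SL_air"]


@pytest.fixture(scope="session")
def pyr_sl_air(phi_dataset):
    return phi_dataset[phi_dataset["treatment"] == "pyr_SL_air"]


@pytest.fixture(scope="session")
def wt_chain(wt_sl_air):
    """Moderate-length chain reused across posterior-summary tests."""
    return run_mcmc(wt_sl_air, "phi_ii", FitConfig(n_samples=20_000, burn_in=1_000, seed=7))


@pytest.fixture(scope="session")
def pyr_chain(pyr_sl_air):
    return run_mcmc(pyr_sl_air, "phi_ii", FitConfig(n_samples=20_000, burn_in=1_000, seed=8))


def synthetic_chain(draws_natural: np.ndarray, kind: str = "phi_ii") -> PosteriorChain:
    """Wrap hand-made natural-scale draws (n, 2) as a PosteriorChain.

    Columns are (etr_max-like, i_k-like) plus an appended unit sigma column.
    """
    draws = np.column_stack([np.log(draws_natural), np.zeros(len(draws_natural))])
    names = {
        "phi_ii": ("log_etr_max", "log_i_k", "log_sigma"),
        "tef": ("log_tef_max", "log_i_k", "log_sigma"),
    }[kind]
    return PosteriorChain(kind=kind, param_names=names, draws=draws, acceptance_rate=0.3)


@pytest.fixture()
def make_chain():
    return synthetic_chain


@pytest.fixture()
def small_dataset():
    """Tiny noiseless-ish phi_II dataset for cheap fits."""
    rng = np.random.default_rng(0)
    grid = np.array([22.0, 46.0, 106.0, 170.0, 251.0, 356.0, 509.0, 679.0])
    i = np.tile(grid, 3)
    mu = 25.0 / (0.42 * i) * -np.expm1(-i / 140.0)
    return pd.DataFrame(
        {"intensity": i, "response": mu + rng.normal(0, 0.01, i.size)}
    )
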