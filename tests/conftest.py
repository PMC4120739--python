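import numpy as np
import pandas as pd
import pytest

from mixboost import GbmParams, SimulationConfig, fit_ensemble, simulate_study


@pytest.fixture(scope="session")
def interaction_xy():
    """Small dataset with a product interaction and a smooth main effect."""
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.standard_normal((80, 5)), columns=list("abcde"))
    y = (X["a"] * X["b"] + np.sin(X["c"]) + 0.2 * rng.standard_normal(80)).to_numpy()
    return X, y


@pytest.fixture(scope="session")
def small_fit(interaction_xy):
    X, y = interaction_xy
    params = GbmParams(
        n_trees=40, depth=3, shrinkage=0.2, subsample=1.0,
        min_obs_per_leaf=5, seed=3,
    )
    return fit_ensemble(X, y, params), X, y


@pytest.fixture(scope="session")
def snr2_study():
    """One simulated mixture study at SNR = 2 (the strong-signal scenario)."""
    data, outcome = simulate_study(SimulationConfig(snr=2.0, seed=1))
    return data, outcome
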