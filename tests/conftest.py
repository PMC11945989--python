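import numpy as np
import pandas as pd
import pytest

from casim.simulate import (
    CovariateSpec,
    SimulationTruth,
    default_truth,
    geometric_weights,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_truth():
    """Compact two-covariate study with an excluded window, fast to fit."""
    specs = [
        CovariateSpec(
            "pm", "pollutant", 3, mean=55.0, sd=25.0, rho=0.7,
            amplitude=0.30, g_scale=50.0,
        ),
        CovariateSpec(
            "temp", "weather", 2, mean=23.0, sd=5.0, rho=0.85,
            amplitude=0.15, g_scale=5.0, g_center=23.0,
        ),
    ]
    return SimulationTruth(
        n=700, covariates=specs, noise_sd=0.05, seed=11, window_days=(320, 427)
    )


@pytest.fixture
def small_dataset(small_truth):
    return simulate_dataset(small_truth)


@pytest.fixture
def single_block_truth():
    """One pollutant-like covariate, no intervention window (fast fits)."""
    spec = CovariateSpec(
        "pm", "pollutant", 2, mean=55.0, sd=25.0, rho=0.6,
        amplitude=0.30, g_scale=50.0,
    )
    return SimulationTruth(n=450, covariates=[spec], noise_sd=0.05, seed=5, window_days=None)


def make_lag_truth(seed: int, lag: int = 6, n: int = 800) -> SimulationTruth:
    """Truth for lag-identification studies: slow weight decay keeps the
    last lag's weight large enough to matter."""
    spec = CovariateSpec(
        "pm", "pollutant", lag, mean=55.0, sd=25.0, rho=0.7,
        theta=geometric_weights(lag, 0.8), amplitude=0.30, g_scale=50.0,
    )
    return SimulationTruth(
        n=n, covariates=[spec], noise_sd=0.05, seed=seed,
        window_days=(int(0.45 * n), int(0.45 * n) + 107),
    )
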