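import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from atacmix import SimulationParams, simulate_mixture_experiment, tmm_normalize
from atacmix.pipeline import run_mixture_benchmark

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_benchmark():
    """Full benchmark at the study's default conditions (seed 42)."""
    return run_mixture_benchmark(SimulationParams())


@pytest.fixture(scope="session")
def small_params():
    """Small, cheap simulation used by unit tests."""
    return SimulationParams(
        n_peaks=400,
        frac_specific=0.2,
        depths=1_000_000,
        nb_dispersion=0.01,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_params):
    return simulate_mixture_experiment(small_params)


@pytest.fixture(scope="session")
def small_norm(small_experiment):
    return tmm_normalize(small_experiment.counts)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
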