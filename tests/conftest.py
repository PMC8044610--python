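import warnings

import pandas as pd
import pytest
from hypothesis import settings

import echosdt as es

# arviz emits a refactor FutureWarning on import; irrelevant to these tests
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_design() -> es.ExperimentDesign:
    return es.make_design()


@pytest.fixture(scope="session")
def small_design() -> es.ExperimentDesign:
    """Three distances, 2 days (day 1 practice): 50 analysis trials/cell."""
    return es.make_design(
        distances_m=(1.0, 2.5, 4.0), days=2, sessions_per_day=5,
        reps_per_distance_per_session=10,
    )


@pytest.fixture(scope="session")
def truth_observer() -> es.ObserverParams:
    """Exponential observer used throughout: moderate sensitivity decaying
    with distance, small opposite biases in the two tasks."""
    return es.ObserverParams.exponential(
        alpha0=3.0, alpha1=-0.4, beta0=2.0, beta1=-0.6, c0=0.1, c1=-0.2
    )


@pytest.fixture(scope="session")
def fast_sampler() -> es.SamplerConfig:
    """Reduced-draw settings for tests that check estimates, not diagnostics."""
    return es.SamplerConfig(walkers=16, warmup=400, draws=800, seed=0)


@pytest.fixture(scope="session")
def small_trials(small_design, truth_observer) -> pd.DataFrame:
    """One simulated participant, both tasks, practice day removed."""
    table = es.simulate_experiment(small_design, truth_observer, ["p01"], seed=11)
    return es.analysis_subset(table, small_design)
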