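import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import jumpland as jl

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def vertical_clean():
    """One noise-free vertical-treatment jump with its ground truth."""
    return jl.simulate_jump(jl.preset_config("vertical", noise_sd=0.0), rng=1)


@pytest.fixture(scope="session")
def vertical_noisy():
    """One vertical jump with the default 0.5 mm digitization noise."""
    return jl.simulate_jump(jl.preset_config("vertical"), rng=1)


@pytest.fixture(scope="session")
def vertical_study():
    """12 vertical-preset trials (4 individuals x 3 trials, seed 1)."""
    return jl.simulate_study(treatments=["vertical"], n_individuals=4, n_trials=3, seed=1)


@pytest.fixture(scope="session")
def vertical_study_summaries(vertical_study):
    return [jl.analyze_trial(t, g) for t, _, g in vertical_study]


@pytest.fixture(scope="session")
def horizontal_study():
    """12 horizontal-preset trials (4 individuals x 3 trials, seed 1)."""
    return jl.simulate_study(
        treatments=["horizontal"], n_individuals=4, n_trials=3, seed=1
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
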