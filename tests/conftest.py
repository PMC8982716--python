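import numpy as np
import pytest

from cgmdrnn import SimScenario, make_windows, simulate_subject


@pytest.fixture(scope="session")
def small_series():
    """Four defect-free simulated days, fixed seed."""
    return simulate_subject(SimScenario(n_days=4, seed=11), subject_id="fix-a")


@pytest.fixture(scope="session")
def quiet_series():
    """One noise-free day with a single meal and no boluses."""
    scen = SimScenario(
        n_days=1,
        meals_per_day=1,
        meal_size_mean=50.0,
        meal_size_cv=0.0,
        meal_time_std=1e-6,
        boluses_per_day_range=(0, 0),
        sensor_noise_sd=0.0,
        seed=1,
    )
    return simulate_subject(scen, subject_id="fix-quiet")


@pytest.fixture(scope="session")
def small_windows(small_series):
    return make_windows(small_series)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
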