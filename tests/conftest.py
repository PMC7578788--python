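import numpy as np
import pytest

from betaadapt.synth import (
    AdaptationParams,
    TaskConfig,
    default_human_neural_config,
    simulate_behavior,
)


@pytest.fixture
def task_600():
    """The standard 200/200/200 human session layout."""
    return TaskConfig()


@pytest.fixture
def small_task():
    """A short session for fast tests (epochs of 20 trials)."""
    return TaskConfig(n_baseline=60, n_adaptation=60, n_washout=60, epoch_len=20)


@pytest.fixture
def noise_free_params():
    return AdaptationParams(motor_noise_sd_deg=0.0, rt_sd_ms=0.0, dur_sd_ms=0.0)


@pytest.fixture
def fast_neural():
    """Reduced-rate neural config for quick end-to-end tests."""
    return default_human_neural_config(fs_raw=1000.0)


@pytest.fixture(scope="session")
def session_600():
    """One full default behavioural session, shared across tests."""
    trials, truth = simulate_behavior(TaskConfig(), AdaptationParams(), 123)
    return trials, truth


def angle_to_xy(angle_deg: float, radius: float) -> tuple[float, float]:
    """Point at a given angle (deg counterclockwise from vertical)."""
    a = np.deg2rad(angle_deg)
    return (-radius * np.sin(a), radius * np.cos(a))
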