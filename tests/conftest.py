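import numpy as np
import pytest

from odestep import get_model, solve_trajectory
from odestep.experiments import Dataset


@pytest.fixture(scope="session")
def linear_model():
    return get_model("linear")


@pytest.fixture(scope="session")
def lv_model():
    return get_model("lotka_volterra")


@pytest.fixture(scope="session")
def lv_truth():
    # initial values (1, 0.5), rates (0.5, 0.5, 0.5, 0.5)
    return np.array([1.0, 0.5, 0.5, 0.5, 0.5, 0.5])


def make_dataset(model, eta, times, sigma=0.0, seed=0, observed=None):
    """Noisy observations of a model trajectory (sigma may be scalar or per-state)."""
    traj = solve_trajectory(model, eta, times)
    rng = np.random.default_rng(seed)
    Y = traj.states + rng.standard_normal(traj.states.shape) * sigma
    obs = np.ones(model.d, bool) if observed is None else np.asarray(observed, bool)
    Y[:, ~obs] = np.nan
    return Dataset(times=times, Y=Y, observed_mask=obs)


@pytest.fixture(scope="session")
def lv_dataset(lv_model, lv_truth):
    """Noisy Lotka-Volterra data, n=51 equidistant on [0, 10], sigma=0.05."""
    return make_dataset(lv_model, lv_truth, np.linspace(0, 10, 51),
                        sigma=0.05, seed=7)
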