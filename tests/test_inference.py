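import numpy as np
import pytest

from odestep import get_model
from odestep.errors import InputError, SingularInformationError
from odestep.experiments import Dataset
from odestep.inference import (
    confidence_intervals,
    estimate_noise_variance,
    fisher_information,
    invert_information,
    nls_fit,
    summarize,
)
from odestep.ode_models import ODEModel
from odestep.one_step import one_step_update, score, step_matrix
from .conftest import make_dataset


def closed_form_linear_information(xi, theta, sigma, T):
    """Exact I for x = xi e^{theta t} with F_T uniform on [0, T].

    Entries are integrals of e^{2 theta t}, xi t e^{2 theta t} and
    xi^2 t^2 e^{2 theta t} divided by T and sigma^2.
    """
    a = 2 * theta
    e = np.exp(a * T)
    i0 = (e - 1) / a
    i1 = (T * e / a) - (e - 1) / a ** 2
    i2 = (T ** 2 * e / a) - 2 * T * e / a ** 2 + 2 * (e - 1) / a ** 3
    M = np.array([[i0, xi * i1], [xi * i1, xi ** 2 * i2]]) / T
    return M / sigma ** 2


def test_noise_variance_zero_residuals(linear_model):
    ds = make_dataset(linear_model, [1.0, -1.0], np.linspace(0, 10, 21))
    assert estimate_noise_variance(linear_model, [1.0, -1.0], ds) == \
        pytest.approx(0.0, abs=1e-12)


def test_noise_variance_formula(linear_model):
    """d=1, n=3, residuals (1,1,1) give 3 / (1 * 2) = 1.5."""
    times = np.array([0.0, 1.0, 2.0])
    x = np.exp(-times)
    ds = Dataset(times=times, Y=(x + 1.0)[:, None], observed_mask=[True])
    assert estimate_noise_variance(linear_model, [1.0, -1.0], ds) == \
        pytest.approx(1.5, rel=1e-9)
    with pytest.raises(InputError):
        estimate_noise_variance(
            linear_model, [1.0, -1.0],
            Dataset(times=[0.0], Y=[[1.0]], observed_mask=[True]))


def test_noise_variance_per_state(lv_model, lv_truth):
    ds = make_dataset(lv_model, lv_truth, np.linspace(0, 10, 41),
                      sigma=[0.2, 0.02], seed=3)
    s2 = estimate_noise_variance(lv_model, lv_truth, ds, per_state=True)
    assert s2[0] == pytest.approx(0.04, rel=0.5)
    assert s2[1] == pytest.approx(4e-4, rel=0.5)


def test_fisher_matches_closed_form(linear_model):
    """Uniform-design information agrees with analytic integrals to 1e-6."""
    I = fisher_information(linear_model, [1.0, 1.0], 0.01,
                           np.array([0.0, 10.0]), design="uniform",
                           grid_size=20001)
    expected = closed_form_linear_information(1.0, 1.0, 0.1, 10.0)
    np.testing.assert_allclose(I, expected, rtol=1e-6)


def test_fisher_symmetric_psd_registry():
    cases = {
        "linear": [0.5, -1.0],
        "lotka_volterra": [1, 0.5, 0.5, 0.5, 0.5, 0.5],
        "nitrogen_oxide": [0.0, 4.577e-06, 2.797e-04],
    }
    for name, eta in cases.items():
        model = get_model(name)
        I = fisher_information(model, eta, 0.0025, np.linspace(0, 10, 21))
        np.testing.assert_allclose(I, I.T, atol=1e-8)
        assert np.all(np.linalg.eigvalsh(I) > -1e-6)


def test_information_independent_of_xi(linear_model):
    """(I^{-1})_xixi does not depend on the value of xi at fixed theta."""
    times = np.array([0.0, 10.0])
    inv = {}
    for xi in (0.5, 1.0):
        I = fisher_information(linear_model, [xi, -1.0], 0.0025, times,
                               design="uniform")
        inv[xi] = invert_information(I)[0, 0]
    assert inv[0.5] == pytest.approx(inv[1.0], abs=1e-10)


def test_ci_multiplier_and_scaling(linear_model):
    """alpha=0.05 gives the 1.959964 multiplier; widths shrink as n^{-1/2}."""
    I = fisher_information(linear_model, [1.0, -1.0], 0.0025,
                           np.array([0.0, 10.0]), design="uniform")
    ci100 = confidence_intervals([1.0, -1.0], I, 100)
    ci400 = confidence_intervals([1.0, -1.0], I, 400)
    w100 = ci100[:, 1] - ci100[:, 0]
    w400 = ci400[:, 1] - ci400[:, 0]
    np.testing.assert_allclose(w400 / w100, 0.5, rtol=1e-12)
    se = np.sqrt(np.diag(invert_information(I)) / 100)
    np.testing.assert_allclose(w100, 2 * 1.959964 * se, rtol=1e-6)


def test_ci_duality(linear_model):
    """eta0 outside the CI iff the standardized distance exceeds z."""
    rng = np.random.default_rng(12)
    I = fisher_information(linear_model, [1.0, -1.0], 0.0025,
                           np.linspace(0, 10, 21))
    n = 21
    se = np.sqrt(np.diag(invert_information(I)) / n)
    z = 1.959964
    for _ in range(50):
        eta_bar = np.array([1.0, -1.0]) + rng.standard_normal(2) * se * 2
        ci = confidence_intervals(eta_bar, I, n)
        inside = (ci[:, 0] <= [1.0, -1.0]) & ([1.0, -1.0] <= ci[:, 1])
        dist = np.abs(eta_bar - [1.0, -1.0]) / se
        np.testing.assert_array_equal(inside, dist <= z + 1e-12)


def test_singular_information_raises():
    with pytest.raises(SingularInformationError):
        invert_information(np.zeros((2, 2)))


def test_nls_noise_free_from_truth(lv_model, lv_truth):
    ds = make_dataset(lv_model, lv_truth, np.linspace(0, 10, 21))
    res = nls_fit(lv_model, ds, lv_truth)
    assert res.converged
    np.testing.assert_allclose(res.eta, lv_truth, atol=1e-8)


def test_nls_linear_in_eta_matches_normal_equations():
    """x(t) = xi + theta t: NLS equals closed-form linear least squares."""
    toy = ODEModel(name="ramp", d=1, p=1,
                   rhs=lambda x, th, t: np.array([th[0]]),
                   jac_x=lambda x, th, t: np.zeros((1, 1)),
                   jac_theta=lambda x, th, t: np.ones((1, 1)))
    times = np.linspace(0, 5, 21)
    rng = np.random.default_rng(4)
    y = 1.5 + 0.7 * times + 0.1 * rng.standard_normal(21)
    ds = Dataset(times=times, Y=y[:, None], observed_mask=[True])
    res = nls_fit(toy, ds, [0.0, 0.0])
    A = np.column_stack([np.ones(21), times])
    expected, *_ = np.linalg.lstsq(A, y, rcond=None)
    np.testing.assert_allclose(res.eta, expected, atol=1e-8)


def test_nls_accepted_steps_never_increase_rss(lv_model, lv_truth,
                                               lv_dataset):
    start = lv_truth * 1.3
    from odestep.one_step import residual_sum_of_squares
    rss0 = residual_sum_of_squares(lv_model, start, lv_dataset)
    res = nls_fit(lv_model, lv_dataset, start, max_iter=30)
    assert res.rss <= rss0
    np.testing.assert_allclose(res.eta, lv_truth, atol=0.1)


def test_one_lm_iteration_equals_damped_update(lv_model, lv_truth,
                                               lv_dataset):
    """nls_fit's first accepted step is the damped one-step update."""
    eta0 = lv_truth * 1.02
    lam = 0.01
    res = nls_fit(lv_model, lv_dataset, eta0, max_iter=1, lambda0=lam,
                  gtol=0.0)
    psi = score(lv_model, eta0, lv_dataset)
    M = step_matrix(lv_model, eta0, lv_dataset, variant="damped", lam=lam)
    expected = one_step_update(eta0, psi, M)
    np.testing.assert_allclose(res.eta, expected, atol=1e-12)


def test_summarize_intervals_contain_estimate(lv_model, lv_truth, lv_dataset):
    s = summarize(lv_model, lv_truth, lv_dataset)
    center = lv_truth
    assert np.all(s.intervals[:, 0] <= center)
    assert np.all(center <= s.intervals[:, 1])
    assert s.fisher.shape == (6, 6)
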