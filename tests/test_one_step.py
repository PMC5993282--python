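import numpy as np
import pytest

from odestep import get_model, solve_trajectory
from odestep.one_step import (
    integrate_sensitivities,
    integrate_variational,
    one_step_update,
    residual_sum_of_squares,
    score,
    select_estimate,
    step_matrix,
    _scaled_solve,
)
from odestep.smoothing import bandwidth_grid
from .conftest import make_dataset


def test_sensitivity_initial_condition(lv_model, lv_truth):
    sol = integrate_sensitivities(lv_model, lv_truth, np.linspace(0, 5, 11))
    expected = np.zeros((2, 6))
    expected[:, :2] = np.eye(2)
    np.testing.assert_allclose(sol.s[0], expected, atol=1e-12)


def test_sensitivities_linear_closed_form(linear_model):
    """s = (e^{theta t}, xi t e^{theta t}) for the scalar linear model."""
    times = np.linspace(0, 10, 21)
    xi, theta = 0.5, -1.0
    sol = integrate_sensitivities(linear_model, [xi, theta], times,
                                  rtol=1e-11, atol=1e-13)
    np.testing.assert_allclose(sol.s[:, 0, 0], np.exp(theta * times), rtol=1e-7)
    np.testing.assert_allclose(sol.s[:, 0, 1], xi * times * np.exp(theta * times),
                               rtol=1e-7, atol=1e-12)


def test_sensitivities_match_finite_differences(lv_model, lv_truth):
    """Central finite differences of the trajectory over eta match s."""
    times = np.linspace(0, 10, 11)
    sol = integrate_sensitivities(lv_model, lv_truth, times)
    h = 1e-6
    for a in range(6):
        ep, em = lv_truth.copy(), lv_truth.copy()
        ep[a] += h
        em[a] -= h
        fd = (solve_trajectory(lv_model, ep, times).states
              - solve_trajectory(lv_model, em, times).states) / (2 * h)
        scale = np.maximum(np.abs(sol.s[:, :, a]), 1e-3)
        assert np.max(np.abs(sol.s[:, :, a] - fd) / scale) < 1e-5


def test_variational_initial_condition_and_closed_form(linear_model):
    """z(0)=0; z_xixi=0, z_xitheta=t e^{theta t}, z_thth=xi t^2 e^{theta t}."""
    times = np.linspace(0, 5, 11)
    xi, theta = 1.2, 0.4
    sens = integrate_sensitivities(linear_model, [xi, theta], times)
    sol = integrate_variational(linear_model, [xi, theta], sens)
    np.testing.assert_allclose(sol.z[0], 0.0, atol=1e-12)
    e = np.exp(theta * times)
    np.testing.assert_allclose(sol.z[:, 0, 0, 0], 0.0, atol=1e-8)
    np.testing.assert_allclose(sol.z[:, 0, 0, 1], times * e, rtol=1e-6,
                               atol=1e-10)
    np.testing.assert_allclose(sol.z[:, 0, 1, 1], xi * times ** 2 * e,
                               rtol=1e-6, atol=1e-10)


def test_variational_matches_fd_of_sensitivities():
    """z agrees with finite differences of s over eta (NO kinetics)."""
    model = get_model("nitrogen_oxide")
    eta = np.array([0.0, 4.577e-06, 2.797e-04])
    times = np.linspace(0, 40, 9)
    kw = {"rtol": 1e-10, "atol": 1e-12}
    sens = integrate_sensitivities(model, eta, times, **kw)
    sol = integrate_variational(model, eta, sens, **kw)
    h = np.array([1e-3, 4.577e-09, 2.797e-07])  # ~1e-3 relative per coordinate
    for a in range(3):
        ep, em = eta.copy(), eta.copy()
        ep[a] += h[a]
        em[a] -= h[a]
        fd = (integrate_sensitivities(model, ep, times, **kw).s
              - integrate_sensitivities(model, em, times, **kw).s) / (2 * h[a])
        scale = np.maximum(np.abs(sol.z[:, :, :, a]), np.abs(fd).max() * 1e-3)
        assert np.max(np.abs(sol.z[:, :, :, a] - fd) / scale) < 1e-4


def test_score_zero_on_noise_free_data(lv_model, lv_truth):
    ds = make_dataset(lv_model, lv_truth, np.linspace(0, 10, 21))
    psi = score(lv_model, lv_truth, ds)
    np.testing.assert_allclose(psi, 0.0, atol=1e-6)


def test_score_single_observation_pattern(linear_model):
    """One observation, s=2, residual 0.5 contributes s * r = 1 per entry."""
    from odestep.experiments import Dataset
    from odestep.one_step import SensitivitySolution
    ds = Dataset(times=[1.0], Y=np.array([[2.5]]), observed_mask=[True])
    sens = SensitivitySolution(times=np.array([1.0]),
                               x=np.array([[2.0]]),
                               s=np.full((1, 1, 2), 2.0))
    psi = score(linear_model, [1.0, 0.7], ds, sens=sens)
    np.testing.assert_allclose(psi, [1.0, 1.0])


def test_score_is_half_negative_gradient_of_rss(lv_model, lv_truth,
                                                lv_dataset):
    """Psi_n equals -1/2 times the gradient of R_n (finite differences)."""
    eta = lv_truth * 1.03
    psi = score(lv_model, eta, lv_dataset)
    h = 1e-6
    grad = np.empty(6)
    for a in range(6):
        ep, em = eta.copy(), eta.copy()
        ep[a] += h
        em[a] -= h
        grad[a] = (residual_sum_of_squares(lv_model, ep, lv_dataset)
                   - residual_sum_of_squares(lv_model, em, lv_dataset)) / (2 * h)
    np.testing.assert_allclose(psi, -0.5 * grad, rtol=1e-4, atol=1e-4)


def test_step_matrix_variants(lv_model, lv_truth):
    ds = make_dataset(lv_model, lv_truth, np.linspace(0, 10, 21))
    newton = step_matrix(lv_model, lv_truth, ds, variant="newton")
    gn = step_matrix(lv_model, lv_truth, ds, variant="gauss_newton")
    # zero residuals: the z-term vanishes
    np.testing.assert_allclose(newton, gn, atol=1e-5)
    np.testing.assert_allclose(gn, gn.T, atol=1e-10)
    assert np.all(np.linalg.eigvalsh(gn) <= 1e-10)  # negative semidefinite
    damped = step_matrix(lv_model, lv_truth, ds, variant="damped", lam=0.5)
    assert np.all(np.linalg.eigvalsh(damped) < 0)  # negative definite


def test_newton_matrix_matches_score_jacobian(linear_model):
    """dPsi/deta by finite differences equals the newton matrix."""
    ds = make_dataset(linear_model, [0.5, -1.0], np.linspace(0, 10, 21),
                      sigma=0.05, seed=9)
    eta = np.array([0.52, -0.97])
    M = step_matrix(linear_model, eta, ds, variant="newton")
    h = 1e-6
    fd = np.empty((2, 2))
    for a in range(2):
        ep, em = eta.copy(), eta.copy()
        ep[a] += h
        em[a] -= h
        fd[:, a] = (score(linear_model, ep, ds) - score(linear_model, em, ds)) / (2 * h)
    np.testing.assert_allclose(M, fd, rtol=1e-4, atol=1e-6)


def test_update_identity_at_zero_score():
    eta = np.array([1.0, 2.0])
    out = one_step_update(eta, np.zeros(2), -np.eye(2))
    np.testing.assert_allclose(out, eta)


def test_damped_update_equals_lm_iteration(lv_model, lv_truth, lv_dataset):
    """One damped update reproduces a hand-rolled LM step at equal lambda."""
    eta = lv_truth * 1.02
    lam = 0.01
    psi = score(lv_model, eta, lv_dataset)
    M = step_matrix(lv_model, eta, lv_dataset, variant="damped", lam=lam)
    ours = one_step_update(eta, psi, M)
    # hand-rolled LM: eta + (J'J + lam I)^{-1} J'r with the same linear solve
    sens = integrate_sensitivities(lv_model, eta, lv_dataset.times)
    S = sens.s.reshape(-1, 6)
    r = (lv_dataset.Y - sens.x).reshape(-1)
    lm = eta + _scaled_solve(S.T @ S + lam * np.eye(6), S.T @ r)
    np.testing.assert_allclose(ours, lm, atol=1e-10)


def test_fixed_components_pass_through(lv_model, lv_truth, lv_dataset):
    free = np.array([True, True, False, True, True, True])
    eta = lv_truth * 1.01
    psi = score(lv_model, eta, lv_dataset, free_mask=free)
    M = step_matrix(lv_model, eta, lv_dataset, variant="damped",
                    free_mask=free)
    out = one_step_update(eta, psi, M, free_mask=free)
    assert out[2] == eta[2]
    assert not np.allclose(out[free], eta[free])


def test_select_single_candidate(lv_model, lv_dataset):
    res = select_estimate(lv_model, lv_dataset, [0.6], max_steps=1)
    assert res.bandwidth == pytest.approx(0.6)
    assert len(res.candidates) == 1


def test_select_returns_minimum_rss(lv_model, lv_dataset):
    res = select_estimate(lv_model, lv_dataset,
                          bandwidth_grid(51, N=6, c_min=0.3, c_max=3.0),
                          max_steps=1)
    finite = [c.rss for c in res.candidates if np.isfinite(c.rss)]
    assert res.rss == pytest.approx(min(finite))


def test_one_step_reduces_error_over_preliminary(linear_model):
    """The correction improves on the preliminary on average (setup A)."""
    bw = bandwidth_grid(21, N=10, c_min=0.02, c_max=3.0)
    truth = np.array([0.5, -1.0])
    gains = []
    for r in range(60):
        ds = make_dataset(linear_model, truth, np.linspace(0, 10, 21),
                          sigma=0.05, seed=1000 + r)
        res = select_estimate(linear_model, ds, bw, max_steps=1)
        gains.append((np.linalg.norm(res.eta_hat - truth),
                      np.linalg.norm(res.eta_bar - truth)))
    gains = np.array(gains)
    assert gains[:, 1].mean() <= gains[:, 0].mean()


def test_all_candidates_failing_raises(lv_model, lv_truth):
    from odestep.errors import EstimationError
    ds = make_dataset(lv_model, lv_truth, np.linspace(0, 10, 8), sigma=0.05)
    # absurdly large bandwidths force the correction to work, so instead
    # use a dataset too small for any degree-2 window
    from odestep.experiments import Dataset
    tiny = Dataset(times=[0.0, 1.0], Y=np.ones((2, 2)),
                   observed_mask=[True, True])
    with pytest.raises(EstimationError):
        select_estimate(lv_model, tiny, [0.1, 0.5])
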