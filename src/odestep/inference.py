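"""Noise-variance estimation, Fisher information, confidence intervals,
and the Levenberg-Marquardt nonlinear least squares baseline.

Under i.i.d. additive Gaussian noise with variance sigma^2 and design
distribution F_T, the efficient asymptotic covariance of an estimator
of eta is I(eta)^{-1} / n with Fisher information

    I(eta) = sigma^{-2} sum_i int_0^T (dx_i/deta)^T (dx_i/deta) dF_T(t),

the sum running over the observed states.  Plug-in confidence
intervals use the estimated eta, the residual-based sigma^2 estimate,
and the empirical design for F_T (trapezoid rule on a dense grid).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm

from .errors import InputError, IntegrationError, SingularInformationError
from .ode_models import ODEModel, solve_trajectory
from .one_step import integrate_sensitivities, _scaled_solve

__all__ = ["InferenceSummary", "estimate_noise_variance", "fisher_information",
           "invert_information", "confidence_intervals", "nls_fit", "NLSResult",
           "summarize"]

FISHER_GRID_SIZE = 1001


@dataclass
class InferenceSummary:
    """Plug-in inference at an estimate: noise level, information, CIs."""

    sigma2_hat: float | np.ndarray
    fisher: np.ndarray
    cov: np.ndarray  # inverse information / n
    intervals: np.ndarray  # (n_free, 2)
    n: int
    alpha: float
    free_mask: np.ndarray

    def to_dict(self):
        s2 = self.sigma2_hat
        return {
            "sigma2_hat": s2.tolist() if isinstance(s2, np.ndarray) else s2,
            "cov": self.cov.tolist(),
            "intervals": self.intervals.tolist(),
            "n": self.n,
            "alpha": self.alpha,
        }


def estimate_noise_variance(model: ODEModel, eta_bar, dataset, per_state=False,
                            rtol=1e-8, atol=1e-10):
    """Residual-based noise-variance estimate at the fitted parameters.

    Pooled: ``sigma2 = sum_ij r_ij^2 / (d_obs (n - 1))`` over observed
    states.  With ``per_state=True`` returns a length-d array with the
    per-state version ``sum_j r_ij^2 / (n - 1)`` (NaN for unobserved
    states), for heteroscedastic error models.
    """
    times = np.asarray(dataset.times, dtype=float)
    n = times.size
    if n < 2:
        raise InputError("need at least 2 observations to estimate the noise variance")
    traj = solve_trajectory(model, eta_bar, times, rtol=rtol, atol=atol)
    obs = np.asarray(dataset.observed_mask, dtype=bool)
    r = np.asarray(dataset.Y, dtype=float) - traj.states
    r[:, ~obs] = 0.0
    r = np.nan_to_num(r, nan=0.0)
    if per_state:
        out = np.full(model.d, np.nan)
        out[obs] = np.sum(r[:, obs] ** 2, axis=0) / (n - 1)
        return out
    d_obs = int(obs.sum())
    return float(np.sum(r ** 2) / (d_obs * (n - 1)))


def fisher_information(model: ODEModel, eta, sigma2, times, free_mask=None,
                       grid_size=FISHER_GRID_SIZE, rtol=1e-8, atol=1e-10,
                       observed_mask=None, design="points") -> np.ndarray:
    """Fisher information per observation at eta.

    ``design`` chooses the approximation of the design distribution
    F_T: ``"points"`` places mass 1/n on each supplied design time
    (the standard nonlinear-regression plug-in, sigma^2 (J'J/n)^{-1}
    asymptotics), while ``"uniform"`` integrates with the trapezoid
    rule over a dense ``grid_size``-point grid spanning
    ``[times[0], times[-1]]`` — the limiting information of a uniform
    random design, used for true-asymptotic-variance computations.
    ``sigma2`` may be a scalar (homoscedastic) or a length-d array of
    per-state variances.  Rows/columns of fixed parameters are removed.
    """
    eta = np.asarray(eta, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    q = model.d + model.p
    if free_mask is None:
        free_mask = np.ones(q, dtype=bool)
    free_mask = np.asarray(free_mask, dtype=bool)
    if observed_mask is None:
        observed_mask = np.ones(model.d, dtype=bool)
    observed_mask = np.asarray(observed_mask, dtype=bool)
    if design == "points":
        grid = times
        w = np.full(grid.size, 1.0 / grid.size)
    elif design == "uniform":
        grid = np.linspace(times[0], times[-1], grid_size)
        w = np.empty_like(grid)
        w[1:-1] = 0.5 * (grid[2:] - grid[:-2])
        w[0] = 0.5 * (grid[1] - grid[0])
        w[-1] = 0.5 * (grid[-1] - grid[-2])
        w = w / w.sum()  # F_T is a probability distribution
    else:
        raise InputError(f"unknown design approximation '{design}'")
    sens = integrate_sensitivities(model, eta, grid, rtol=rtol, atol=atol)
    s2 = np.asarray(sigma2, dtype=float)
    if s2.ndim == 0:
        inv_s2 = np.full(model.d, 1.0 / float(s2))
    else:
        inv_s2 = np.where(np.isfinite(s2) & (s2 > 0), 1.0 / s2, 0.0)
    S = sens.s[:, :, free_mask]  # (m, d, f)
    coeff = w[:, None] * (inv_s2[None, :] * observed_mask)
    info = np.einsum("mi,mia,mib->ab", coeff, S, S)
    return 0.5 * (info + info.T)


def invert_information(fisher) -> np.ndarray:
    """Invert I with diagonal equilibration; raise on singularity."""
    fisher = np.asarray(fisher, dtype=float)
    dscale = np.sqrt(np.abs(np.diag(fisher)))
    if np.any(dscale == 0):
        raise SingularInformationError(
            "Fisher information has a zero diagonal entry")
    D = 1.0 / dscale
    Ms = fisher * D[:, None] * D[None, :]
    cond = np.linalg.cond(Ms)
    try:
        inv = np.linalg.inv(Ms)
    except np.linalg.LinAlgError:
        raise SingularInformationError(
            f"Fisher information singular (equilibrated cond={cond:.3g})",
            cond=cond) from None
    return inv * D[:, None] * D[None, :]


def confidence_intervals(eta_bar, fisher, n, alpha=0.05, free_mask=None):
    """Wald intervals eta_j +/- z_{1-alpha/2} sqrt((I^{-1})_jj / n).

    Returns an ``(n_free, 2)`` array of lower/upper limits for the free
    components of eta_bar.
    """
    eta_bar = np.asarray(eta_bar, dtype=float).ravel()
    if free_mask is None:
        free_mask = np.ones(eta_bar.size, dtype=bool)
    free_mask = np.asarray(free_mask, dtype=bool)
    inv = invert_information(fisher)
    se = np.sqrt(np.diag(inv) / n)
    z = norm.ppf(1.0 - alpha / 2.0)
    center = eta_bar[free_mask]
    return np.column_stack([center - z * se, center + z * se])


def summarize(model: ODEModel, eta_bar, dataset, free_mask=None, alpha=0.05,
              per_state_sigma=False, rtol=1e-8, atol=1e-10,
              grid_size=FISHER_GRID_SIZE, design="points") -> InferenceSummary:
    """Full plug-in inference at an estimate (sigma^2, I, covariance, CIs)."""
    times = np.asarray(dataset.times, dtype=float)
    n = times.size
    q = model.d + model.p
    if free_mask is None:
        free_mask = np.ones(q, dtype=bool)
    free_mask = np.asarray(free_mask, dtype=bool)
    sigma2 = estimate_noise_variance(model, eta_bar, dataset,
                                     per_state=per_state_sigma,
                                     rtol=rtol, atol=atol)
    fisher = fisher_information(model, eta_bar, sigma2, times,
                                free_mask=free_mask, grid_size=grid_size,
                                rtol=rtol, atol=atol,
                                observed_mask=dataset.observed_mask,
                                design=design)
    cov = invert_information(fisher) / n
    z = norm.ppf(1.0 - alpha / 2.0)
    se = np.sqrt(np.diag(cov))
    center = np.asarray(eta_bar, float)[free_mask]
    intervals = np.column_stack([center - z * se, center + z * se])
    return InferenceSummary(sigma2_hat=sigma2, fisher=fisher, cov=cov,
                            intervals=intervals, n=n, alpha=alpha,
                            free_mask=free_mask)


@dataclass
class NLSResult:
    """Levenberg-Marquardt fit outcome."""

    eta: np.ndarray
    rss: float
    n_iter: int
    n_accepted: int
    converged: bool
    message: str
    lam: float


def nls_fit(model: ODEModel, dataset, eta_init, free_mask=None, max_iter=100,
            lambda0=0.01, gtol=1e-8, xtol=1e-10, ftol=1e-12,
            rtol=1e-8, atol=1e-10) -> NLSResult:
    """Nonlinear least squares by Levenberg-Marquardt.

    Minimizes R_n(eta) using sensitivity-equation Jacobians; the
    damping parameter is divided by 10 on an accepted step and
    multiplied by 10 on a rejected one (integrator failures at a
    proposal count as rejections).  Non-convergence is reported, not
    raised.
    """
    eta = np.asarray(eta_init, dtype=float).ravel().copy()
    q = model.d + model.p
    if free_mask is None:
        free_mask = np.ones(q, dtype=bool)
    free_mask = np.asarray(free_mask, dtype=bool)
    times = np.asarray(dataset.times, dtype=float)
    obs = np.asarray(dataset.observed_mask, dtype=bool)
    Y = np.nan_to_num(np.asarray(dataset.Y, dtype=float), nan=0.0)

    def cost_and_grad(eta_cur):
        sens = integrate_sensitivities(model, eta_cur, times, rtol=rtol, atol=atol)
        r = Y - sens.x
        r[:, ~obs] = 0.0
        S = sens.s[:, obs][:, :, free_mask]
        g = np.einsum("jia,ji->a", S, r[:, obs])
        H = np.einsum("jia,jib->ab", S, S)
        return float(np.sum(r[:, obs] ** 2)), g, H

    def cost_only(eta_cur):
        from .one_step import residual_sum_of_squares
        return residual_sum_of_squares(model, eta_cur, dataset, rtol=rtol, atol=atol)

    lam = lambda0
    cost, g, H = cost_and_grad(eta)
    n_accepted = 0
    message = "max_iter reached"
    converged = False
    for it in range(1, max_iter + 1):
        if np.linalg.norm(g) < gtol * (1.0 + cost):
            message, converged = "gradient tolerance reached", True
            return NLSResult(eta, cost, it - 1, n_accepted, converged, message, lam)
        accepted = False
        while lam <= 1e10:
            try:
                step = _scaled_solve(H + lam * np.eye(H.shape[0]), g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial = eta.copy()
            trial[free_mask] = eta[free_mask] + step
            try:
                trial_cost = cost_only(trial)
            except IntegrationError:
                lam *= 10.0
                continue
            if np.isfinite(trial_cost) and trial_cost < cost:
                accepted = True
                n_accepted += 1
                step_small = bool(np.max(np.abs(step) / (1.0 + np.abs(eta[free_mask])))
                                  < xtol)
                cost_small = (cost - trial_cost) < ftol * (1.0 + cost)
                eta = trial
                old_cost = cost
                cost, g, H = cost_and_grad(eta)
                lam = max(lam / 10.0, 1e-12)
                if step_small:
                    message, converged = "step tolerance reached", True
                    return NLSResult(eta, cost, it, n_accepted, converged, message, lam)
                if cost_small:
                    message, converged = "criterion tolerance reached", True
                    return NLSResult(eta, cost, it, n_accepted, converged, message, lam)
                break
            lam *= 10.0
        if not accepted:
            message = f"no acceptable step found (lambda > 1e10) at iteration {it}"
            return NLSResult(eta, cost, it, n_accepted, False, message, lam)
    return NLSResult(eta, cost, max_iter, n_accepted, converged, message, lam)
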