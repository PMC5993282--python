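"""Sensitivity integration and the one-step (Le Cam) correction.

Given a root-n-consistent preliminary estimate eta_hat = (xi, theta),
one Newton-type step

    eta_bar = eta_hat - M(eta_hat)^{-1} Psi_n(eta_hat)

turns it into an asymptotic equivalent of the nonlinear least squares
estimator.  Psi_n is the score of the least squares criterion,

    Psi_n(eta) = sum_j s(t_j)^T (Y_j - x(eta, t_j)),

with s(t) = dx/deta obtained from the sensitivity equations; M is
either the full derivative of Psi_n (using second-order sensitivities
from the variational equations), its Gauss-Newton surrogate
-sum_j s_j^T s_j, or the damped Levenberg-Marquardt version
-sum_j s_j^T s_j - lambda I.  A candidate set of bandwidths is scanned
and the estimate whose integrated trajectory best fits the raw data
(smallest residual sum of squares) is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .errors import EstimationError, InputError, IntegrationError, OdestepError
from .ode_models import ODEModel, second_derivatives, solve_trajectory
from .preliminary import integral_estimate, sme_estimate
from .smoothing import BandwidthGrid, smooth_dataset

logger = logging.getLogger(__name__)

__all__ = ["SensitivitySolution", "OneStepResult", "CandidateDiagnostics",
           "integrate_sensitivities", "integrate_variational", "score",
           "step_matrix", "one_step_update", "residual_sum_of_squares",
           "select_estimate", "MAX_LAMBDA"]

MAX_LAMBDA = 1e6


@dataclass
class SensitivitySolution:
    """States and their derivatives with respect to eta = (xi, theta).

    ``s`` has shape (n, d, d+p) with s(t0) = [I_d | 0]; the optional
    second-order block ``z`` has shape (n, d, d+p, d+p) with z(t0) = 0.
    """

    times: np.ndarray
    x: np.ndarray
    s: np.ndarray
    z: Optional[np.ndarray] = None


@dataclass
class CandidateDiagnostics:
    """Per-bandwidth record kept by the data-driven selector."""

    bandwidth: float
    eta_hat: Optional[np.ndarray] = None
    eta_bar: Optional[np.ndarray] = None
    rss: float = np.inf
    rss_prelim: float = np.inf
    lam: float = 0.0
    error: Optional[str] = None


@dataclass
class OneStepResult:
    """Outcome of the data-driven one-step estimation."""

    eta_bar: np.ndarray
    eta_hat: np.ndarray
    psi: np.ndarray
    step_matrix: np.ndarray
    variant: str
    lam: float
    bandwidth: float
    rss: float
    free_mask: np.ndarray
    candidates: list = field(default_factory=list)

    @property
    def prelim_selected(self) -> np.ndarray:
        """Preliminary estimate whose own integrated fit is best.

        Falls back to the preliminary of the selected one-step
        candidate when preliminary fits were not scored.
        """
        best = min(self.candidates, key=lambda c: c.rss_prelim)
        if np.isfinite(best.rss_prelim) and best.eta_hat is not None:
            return best.eta_hat
        return self.eta_hat

    def to_dict(self):
        return {
            "eta_bar": self.eta_bar.tolist(),
            "eta_hat": self.eta_hat.tolist(),
            "variant": self.variant,
            "lambda": self.lam,
            "bandwidth": self.bandwidth,
            "rss": self.rss,
            "free_mask": self.free_mask.astype(bool).tolist(),
            "candidates": [
                {"bandwidth": c.bandwidth, "rss": c.rss, "lambda": c.lam,
                 "error": c.error}
                for c in self.candidates
            ],
        }


def integrate_sensitivities(model: ODEModel, eta, times, rtol=1e-8,
                            atol=1e-10, method=None) -> SensitivitySolution:
    """Integrate the state jointly with its first-order sensitivities.

    The sensitivity system s' = F_x s + [0 | F_theta] is linear in s
    and shares the state trajectory, so both are integrated together.
    """
    eta = np.asarray(eta, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    d, p = model.d, model.p
    q = d + p
    if eta.size != q:
        raise InputError(f"eta has length {eta.size}, expected {q}")
    xi, theta = eta[:d], eta[d:]
    if method is None:
        method = "BDF" if model.stiff else "DOP853"

    def f(t, y):
        x = y[:d]
        s = y[d:].reshape(d, q)
        jx = np.asarray(model.jac_x(x, theta, t))
        jt = np.asarray(model.jac_theta(x, theta, t))
        ds = jx @ s
        ds[:, d:] += jt
        return np.concatenate([model.rhs(x, theta, t), ds.ravel()])

    s0 = np.zeros((d, q))
    s0[:, :d] = np.eye(d)
    y0 = np.concatenate([xi, s0.ravel()])
    if times.size == 1:
        return SensitivitySolution(times=times, x=xi[None], s=s0[None].copy())
    sol = solve_ivp(f, (times[0], times[-1]), y0, t_eval=times, method=method,
                    rtol=rtol, atol=atol)
    if not sol.success or sol.y.shape[1] != times.size:
        t_fail = sol.t[-1] if sol.t.size else times[0]
        raise IntegrationError(
            f"sensitivity integration of '{model.name}' failed near "
            f"t={t_fail:.6g}: {sol.message}", t_fail=t_fail)
    Y = sol.y.T
    return SensitivitySolution(times=times, x=Y[:, :d].copy(),
                               s=Y[:, d:].reshape(-1, d, q).copy())


def integrate_variational(model: ODEModel, eta, sens: SensitivitySolution,
                          rtol=1e-8, atol=1e-10, method=None,
                          allow_fd=True) -> SensitivitySolution:
    """Add second-order sensitivities z = d^2 x / deta^2.

    The variational system is linear in z with coefficients depending
    on x(t) and s(t); state, first- and second-order sensitivities are
    integrated jointly for accuracy.  z(t0) = 0.
    """
    eta = np.asarray(eta, dtype=float).ravel()
    times = sens.times
    d, p = model.d, model.p
    q = d + p
    xi, theta = eta[:d], eta[d:]
    if method is None:
        method = "BDF" if model.stiff else "DOP853"
    n_x, n_s = d, d * q
    # probe second derivatives once to fail fast if unavailable
    second_derivatives(model, xi, theta, times[0], allow_fd=allow_fd)

    def f(t, y):
        x = y[:n_x]
        s = y[n_x:n_x + n_s].reshape(d, q)
        z = y[n_x + n_s:].reshape(d, q, q)
        jx = np.asarray(model.jac_x(x, theta, t))
        jt = np.asarray(model.jac_theta(x, theta, t))
        hxx, hxt, htt = second_derivatives(model, x, theta, t, allow_fd=allow_fd)
        ds = jx @ s
        ds[:, d:] += jt
        # Hxeta: direct eta-dependence enters only through theta
        hxe = np.zeros((d, d, q))
        hxe[:, :, d:] = hxt
        hee = np.zeros((d, q, q))
        hee[:, d:, d:] = htt
        dz = np.einsum("ik,kab->iab", jx, z)
        dz += np.einsum("ikl,ka,lb->iab", hxx, s, s)
        dz += np.einsum("ikb,ka->iab", hxe, s)
        dz += np.einsum("ika,kb->iab", hxe, s)
        dz += hee
        return np.concatenate([model.rhs(x, theta, t), ds.ravel(), dz.ravel()])

    s0 = np.zeros((d, q))
    s0[:, :d] = np.eye(d)
    y0 = np.concatenate([xi, s0.ravel(), np.zeros(d * q * q)])
    sol = solve_ivp(f, (times[0], times[-1]), y0, t_eval=times, method=method,
                    rtol=rtol, atol=atol)
    if not sol.success or sol.y.shape[1] != times.size:
        t_fail = sol.t[-1] if sol.t.size else times[0]
        raise IntegrationError(
            f"variational integration of '{model.name}' failed near "
            f"t={t_fail:.6g}: {sol.message}", t_fail=t_fail)
    Y = sol.y.T
    return SensitivitySolution(
        times=times,
        x=Y[:, :n_x].copy(),
        s=Y[:, n_x:n_x + n_s].reshape(-1, d, q).copy(),
        z=Y[:, n_x + n_s:].reshape(-1, d, q, q).copy(),
    )


def _residuals(dataset, x):
    """Observed-coordinate residual matrix Y - x with NaN -> 0."""
    r = np.asarray(dataset.Y, dtype=float) - x
    mask = np.asarray(dataset.observed_mask, dtype=bool)
    r[:, ~mask] = 0.0
    r = np.nan_to_num(r, nan=0.0)
    return r


def score(model: ODEModel, eta_hat, dataset, free_mask=None, sens=None,
          rtol=1e-8, atol=1e-10) -> np.ndarray:
    """Least squares score Psi_n at eta_hat, reduced to free components.

    Observations of unobserved states contribute nothing; rows of the
    sensitivity matrix belonging to fixed parameters are dropped.
    """
    eta_hat = np.asarray(eta_hat, dtype=float).ravel()
    q = model.d + model.p
    if free_mask is None:
        free_mask = np.ones(q, dtype=bool)
    free_mask = np.asarray(free_mask, dtype=bool)
    if sens is None:
        sens = integrate_sensitivities(model, eta_hat, np.asarray(dataset.times),
                                       rtol=rtol, atol=atol)
    r = _residuals(dataset, sens.x)
    # Psi = sum_j s_j[:, free]^T r_j over observed coordinates
    return np.einsum("jif,ji->f", sens.s[:, :, free_mask], r)


def step_matrix(model: ODEModel, eta_hat, dataset, variant="damped",
                lam=0.01, free_mask=None, sens=None, var=None,
                rtol=1e-8, atol=1e-10) -> np.ndarray:
    """Derivative matrix of the Newton step for the requested variant.

    ``newton``       : sum_j [ z_j^T (Y_j - x_j) - s_j^T s_j ]
    ``gauss_newton`` : -sum_j s_j^T s_j
    ``damped``       : -sum_j s_j^T s_j - lambda I
    """
    if variant not in ("newton", "gauss_newton", "damped"):
        raise InputError(f"unknown variant '{variant}'")
    eta_hat = np.asarray(eta_hat, dtype=float).ravel()
    q = model.d + model.p
    if free_mask is None:
        free_mask = np.ones(q, dtype=bool)
    free_mask = np.asarray(free_mask, dtype=bool)
    times = np.asarray(dataset.times)
    if sens is None:
        sens = integrate_sensitivities(model, eta_hat, times, rtol=rtol, atol=atol)
    obs = np.asarray(dataset.observed_mask, dtype=bool)
    S = sens.s[:, obs][:, :, free_mask]  # (n, d_obs, f)
    M = -np.einsum("jia,jib->ab", S, S)
    if variant == "newton":
        if var is None or var.z is None:
            var = integrate_variational(model, eta_hat, sens, rtol=rtol, atol=atol)
        r = _residuals(dataset, var.x)
        Z = var.z[:, :, free_mask][:, :, :, free_mask]
        M = M + np.einsum("jiab,ji->ab", Z, r)
    elif variant == "damped":
        if lam <= 0:
            raise InputError("damped variant requires lambda > 0")
        M = M - lam * np.eye(M.shape[0])
    return M


def _scaled_solve(M, b):
    """Solve M x = b with Jacobi equilibration for wide parameter scales."""
    dscale = np.sqrt(np.abs(np.diag(M)))
    dscale[dscale == 0] = 1.0
    D = 1.0 / dscale
    Ms = M * D[:, None] * D[None, :]
    x = np.linalg.solve(Ms, b * D)
    return x * D


def one_step_update(eta_hat, psi, matrix, free_mask=None) -> np.ndarray:
    """Apply eta_bar = eta_hat - M^{-1} Psi on the free components."""
    eta_hat = np.asarray(eta_hat, dtype=float).ravel()
    if free_mask is None:
        free_mask = np.ones(eta_hat.size, dtype=bool)
    free_mask = np.asarray(free_mask, dtype=bool)
    step = _scaled_solve(np.asarray(matrix, float), np.asarray(psi, float))
    eta_bar = eta_hat.copy()
    eta_bar[free_mask] = eta_hat[free_mask] - step
    return eta_bar


def residual_sum_of_squares(model: ODEModel, eta, dataset, rtol=1e-8,
                            atol=1e-10) -> float:
    """Least squares criterion R_n(eta) over observed coordinates."""
    traj = solve_trajectory(model, eta, np.asarray(dataset.times),
                            rtol=rtol, atol=atol)
    r = _residuals(dataset, traj.states)
    return float(np.sum(r ** 2))


def _correct(model, dataset, eta_hat, free_mask, variant, lam, rtol, atol):
    """One escalating-damping correction; returns (eta_bar, psi, M, lam)."""
    times = np.asarray(dataset.times)
    sens = integrate_sensitivities(model, eta_hat, times, rtol=rtol, atol=atol)
    psi = score(model, eta_hat, dataset, free_mask=free_mask, sens=sens)
    lam_cur = lam
    var = None
    use_variant = variant
    while True:
        try:
            M = step_matrix(model, eta_hat, dataset, variant=use_variant,
                            lam=lam_cur, free_mask=free_mask, sens=sens,
                            var=var, rtol=rtol, atol=atol)
            eta_bar = one_step_update(eta_hat, psi, M, free_mask=free_mask)
            if np.all(np.isfinite(eta_bar)):
                return eta_bar, psi, M, (lam_cur if use_variant == "damped" else 0.0)
        except (np.linalg.LinAlgError, IntegrationError):
            pass
        # escalate: fall back to damping and increase lambda tenfold
        if use_variant != "damped":
            use_variant = "damped"
            lam_cur = max(lam, 0.01)
        else:
            lam_cur *= 10.0
        if lam_cur > MAX_LAMBDA:
            raise EstimationError(
                f"one-step update singular even at lambda={MAX_LAMBDA:g}")


def _lm_refine(model, dataset, eta, free_mask, lam, max_accepts, rtol, atol,
               gtol=1e-10, ftol=1e-10):
    """Polish an estimate with further damped (LM) corrections.

    Accepts at most ``max_accepts`` residual-decreasing steps, with the
    standard damping dynamics (divide by 10 on acceptance, multiply by
    10 on rejection).  Returns the polished estimate and its residual
    sum of squares.
    """
    times = np.asarray(dataset.times)
    rss = residual_sum_of_squares(model, eta, dataset, rtol=rtol, atol=atol)
    for _ in range(max_accepts):
        sens = integrate_sensitivities(model, eta, times, rtol=rtol, atol=atol)
        psi = score(model, eta, dataset, free_mask=free_mask, sens=sens)
        if np.linalg.norm(psi) < gtol * (1.0 + rss):
            break
        accepted = False
        lam_cur = lam
        while lam_cur <= MAX_LAMBDA:
            try:
                M = step_matrix(model, eta, dataset, variant="damped",
                                lam=lam_cur, free_mask=free_mask, sens=sens)
                trial = one_step_update(eta, psi, M, free_mask=free_mask)
                trial_rss = residual_sum_of_squares(model, trial, dataset,
                                                    rtol=rtol, atol=atol)
            except (np.linalg.LinAlgError, IntegrationError, OdestepError):
                lam_cur *= 10.0
                continue
            if np.isfinite(trial_rss) and trial_rss < rss:
                improved = (rss - trial_rss) > ftol * (1.0 + rss)
                # component-wise relative step size (parameter scales differ
                # by many orders of magnitude in kinetic models)
                rel_step = np.max(np.abs(trial - eta) / (1.0 + np.abs(eta)))
                eta, rss = trial, trial_rss
                lam = max(lam_cur / 10.0, 1e-12)
                accepted = True
                if not improved or rel_step < 1e-12:
                    return eta, rss
                break
            lam_cur *= 10.0
        if not accepted:
            break
    return eta, rss


def select_estimate(model: ODEModel, dataset, bandwidths, variant="damped",
                    lam=0.01, preliminary="integral", known_xi=None,
                    known_theta=None, theta0=None, degree=2, grid=None,
                    max_steps=8, score_preliminary=False,
                    free_xi_prelim=False, rtol=1e-8, atol=1e-10) -> OneStepResult:
    """Data-driven one-step estimation over a bandwidth candidate set.

    For each candidate bandwidth: smooth the data, compute the
    preliminary estimate, apply the one-step correction, integrate the
    model at the corrected estimate and score it by the residual sum
    of squares against the raw observations.  The candidate with the
    smallest criterion wins; exact ties go to the smallest bandwidth.
    Candidates that fail anywhere along the way (singular smoothing
    window, degenerate design, integrator blow-up) are skipped with a
    logged warning.

    ``max_steps`` is the total budget of accepted damped corrections:
    the defining one-step update per candidate, plus up to
    ``max_steps - 1`` further Levenberg-Marquardt polishing steps
    applied to the selected candidate only (the capped-budget practical
    scheme; set ``max_steps=1`` for the bare one-step estimator).

    ``free_xi_prelim=True`` lets the integral preliminary estimate a
    free intercept per state even when initial values are declared
    known (they are reset to their known values before the
    correction).  This shields the rate estimates from accumulated
    early-time smoothing error when the trajectory has a transient
    that the design cannot resolve (e.g. stiff kinetics sampled after
    an initial boundary layer).
    """
    if isinstance(bandwidths, BandwidthGrid):
        bandwidths = bandwidths.values
    bandwidths = np.sort(np.asarray(bandwidths, dtype=float))
    d, p = model.d, model.p
    kx = np.full(d, np.nan) if known_xi is None else np.asarray(known_xi, float)
    kt = np.full(p, np.nan) if known_theta is None else np.asarray(known_theta, float)
    free_mask = np.concatenate([np.isnan(kx), np.isnan(kt)])

    estimator = integral_estimate if preliminary == "integral" else sme_estimate
    candidates = []
    best = None
    best_payload = None
    for bw in bandwidths:
        cand = CandidateDiagnostics(bandwidth=float(bw))
        candidates.append(cand)
        try:
            fit = smooth_dataset(dataset, bw, degree=degree, grid=grid)
            if preliminary == "integral":
                kx_pre = None if free_xi_prelim else kx
                prelim = estimator(model, fit, known_theta=kt, known_xi=kx_pre)
            else:
                prelim = estimator(model, fit, known_theta=kt, known_xi=kx,
                                   theta0=theta0)
            eta_hat = prelim.eta_hat
            fixed_xi = ~np.isnan(kx)
            eta_hat[:d][fixed_xi] = kx[fixed_xi]
            eta_bar, psi, M, lam_used = _correct(
                model, dataset, eta_hat, free_mask, variant, lam, rtol, atol)
            rss = residual_sum_of_squares(model, eta_bar, dataset,
                                          rtol=rtol, atol=atol)
        except OdestepError as exc:
            cand.error = f"{type(exc).__name__}: {exc}"
            logger.warning("bandwidth %.4g skipped: %s", bw, cand.error)
            continue
        cand.eta_hat = eta_hat
        cand.eta_bar = eta_bar
        cand.rss = rss
        cand.lam = lam_used
        if score_preliminary:
            try:
                cand.rss_prelim = residual_sum_of_squares(
                    model, eta_hat, dataset, rtol=rtol, atol=atol)
            except OdestepError:
                cand.rss_prelim = np.inf
        if best is None or rss < best.rss:
            best = cand
            best_payload = (psi, M)
    if best is None:
        raise EstimationError(
            "all bandwidth candidates failed",
            causes=[c.error for c in candidates])
    psi, M = best_payload
    eta_bar, rss = best.eta_bar, best.rss
    if max_steps > 1:
        eta_bar, rss = _lm_refine(model, dataset, eta_bar, free_mask,
                                  max(best.lam, lam), max_steps - 1,
                                  rtol, atol)
    return OneStepResult(
        eta_bar=eta_bar, eta_hat=best.eta_hat, psi=psi, step_matrix=M,
        variant=variant, lam=best.lam, bandwidth=best.bandwidth,
        rss=rss, free_mask=free_mask, candidates=candidates)
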