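"""Root-n-consistent preliminary estimators based on smoothing.

Two estimators are provided, both driven by a :class:`SmoothFit`:

* the smooth-and-match estimator (SME), which matches the smoothed
  derivative x'(t) to the model right-hand side F(x(t); theta) in
  weighted L2, and
* the direct integral estimator, which matches the smoothed trajectory
  x(t) to xi + int_0^t F(x(s); theta) ds, avoiding derivative
  estimation altogether.

When the model declares a parameter-linear decomposition
F(x) = G(x) theta + g0(x), both criteria reduce to weighted linear
least squares and are solved in closed form.  Initial values are always
recovered from the integral-matching criterion, which is linear in xi.

Partially observed systems are supported for the Goodwin oscillator
via cascade reconstruction: the unobserved third state is rebuilt by
integrating its own (linear) equation driven by the smoothed observed
states, and the integral criterion is profiled over the linear
parameter and minimized over the nonlinear one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares, minimize_scalar

from .errors import (
    DegenerateDesignError,
    InputError,
    UnsupportedObservationPatternError,
)
from .ode_models import ODEModel
from .smoothing import SmoothFit

__all__ = ["PreliminaryEstimate", "sme_estimate", "integral_estimate",
           "estimate_initial_values", "interior_weight"]


@dataclass
class PreliminaryEstimate:
    """Preliminary parameter and initial-value estimate.

    Known (fixed) components are passed through at their declared
    values; ``method`` records which criterion produced the estimate.
    """

    theta_hat: np.ndarray
    xi_hat: np.ndarray
    bandwidth: float
    method: str
    criterion_value: float

    @property
    def eta_hat(self) -> np.ndarray:
        return np.concatenate([self.xi_hat, self.theta_hat])


def _resolve_known(known, size, label):
    """Normalize a known-components spec to an array with NaN = free."""
    if known is None:
        return np.full(size, np.nan)
    known = np.asarray(known, dtype=float).ravel()
    if known.size != size:
        raise InputError(f"known {label} mask has length {known.size}, expected {size}")
    return known


def interior_weight(grid, trim=0.05):
    """Indicator weight of the interior of the grid span.

    Trims ``trim`` of the span at each end, removing boundary bias of
    the smoothed derivative from the matching criterion.
    """
    span = grid[-1] - grid[0]
    lo, hi = grid[0] + trim * span, grid[-1] - trim * span
    return ((grid >= lo) & (grid <= hi)).astype(float)


def _trapezoid_weights(grid):
    w = np.empty_like(grid)
    w[1:-1] = 0.5 * (grid[2:] - grid[:-2])
    w[0] = 0.5 * (grid[1] - grid[0])
    w[-1] = 0.5 * (grid[-1] - grid[-2])
    return w


def _require_fully_observed(model, fit):
    if not np.all(fit.observed_mask[: model.d]):
        if model.name == "goodwin":
            return False
        raise UnsupportedObservationPatternError(
            f"model '{model.name}' needs all states observed for the "
            "preliminary estimators; only the Goodwin cascade pattern is supported"
        )
    return True


def _solve_lstsq(A, b):
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < A.shape[1]:
        raise DegenerateDesignError(
            f"normal equations rank {rank} < {A.shape[1]} unknowns"
        )
    return sol


def sme_estimate(model: ODEModel, fit: SmoothFit, weight=None,
                 known_theta=None, known_xi=None, theta0=None,
                 trim=0.05) -> PreliminaryEstimate:
    """Smooth-and-match estimator of the rate parameters.

    Minimizes the trapezoid approximation of
    ``int || x'(t) - F(x(t); theta) ||^2 w(t) dt`` over the free
    parameters, then recovers free initial values from the integral
    criterion at the fitted theta.

    ``weight`` is an optional vector of criterion weights on the fit
    grid; the default trims 5% of the span at each boundary.
    """
    if not _require_fully_observed(model, fit):
        return _goodwin_cascade(model, fit, known_theta, known_xi, method="sme")
    grid = fit.grid
    kt = _resolve_known(known_theta, model.p, "theta")
    free_t = np.isnan(kt)
    w = interior_weight(grid, trim) if weight is None else np.asarray(weight, float)
    wq = _trapezoid_weights(grid) * w
    X = fit.xhat[:, : model.d]
    Xp = fit.xhat_prime[:, : model.d]

    if model.theta_linear is not None:
        Gfun, g0fun = model.theta_linear
        m = grid.size
        Gs = np.empty((m, model.d, model.p))
        g0s = np.empty((m, model.d))
        for k in range(m):
            Gs[k] = Gfun(X[k], grid[k])
            g0s[k] = g0fun(X[k], grid[k])
        target = Xp - g0s
        if np.any(~free_t):
            target = target - Gs[:, :, ~free_t] @ kt[~free_t]
        sw = np.sqrt(wq)[:, None]
        A = (Gs[:, :, free_t] * sw[:, :, None]).reshape(-1, int(free_t.sum()))
        b = (target * sw).reshape(-1)
        theta_free = _solve_lstsq(A, b)
        crit = float(np.sum((A @ theta_free - b) ** 2))
    else:
        nf = int(free_t.sum())
        x0 = np.ones(nf) if theta0 is None else np.asarray(theta0, float)[free_t]
        sw = np.sqrt(wq)

        def resid(tf):
            th = kt.copy()
            th[free_t] = tf
            F = np.stack([model.rhs(X[k], th, grid[k]) for k in range(grid.size)])
            return ((Xp - F) * sw[:, None]).ravel()

        sol = least_squares(resid, x0, method="lm")
        theta_free = sol.x
        crit = float(2 * sol.cost)

    theta = kt.copy()
    theta[free_t] = theta_free
    xi = estimate_initial_values(model, fit, theta, known_xi=known_xi)
    return PreliminaryEstimate(theta_hat=theta, xi_hat=xi,
                               bandwidth=fit.bandwidth, method="sme",
                               criterion_value=crit)


def integral_estimate(model: ODEModel, fit: SmoothFit, known_theta=None,
                      known_xi=None) -> PreliminaryEstimate:
    """Direct integral estimator of (xi, theta), jointly.

    Minimizes the quadrature approximation of
    ``int || x(t) - xi - int_{t1}^t F(x(s); theta) ds ||^2 dt`` over
    the free components; with a parameter-linear model this is a linear
    least squares problem solved in closed form.  Inner integrals use
    the cumulative trapezoid rule on the fit grid.
    """
    if not _require_fully_observed(model, fit):
        return _goodwin_cascade(model, fit, known_theta, known_xi, method="integral")
    if model.theta_linear is None:
        raise InputError(
            f"integral estimator needs a theta-linear model; '{model.name}' "
            "does not declare one"
        )
    grid = fit.grid
    m = grid.size
    d, p = model.d, model.p
    kt = _resolve_known(known_theta, p, "theta")
    kx = _resolve_known(known_xi, d, "xi")
    free_t = np.isnan(kt)
    free_x = np.isnan(kx)
    X = fit.xhat[:, :d]

    Gfun, g0fun = model.theta_linear
    Gs = np.empty((m, d, p))
    g0s = np.empty((m, d))
    for k in range(m):
        Gs[k] = Gfun(X[k], grid[k])
        g0s[k] = g0fun(X[k], grid[k])
    CG = cumulative_trapezoid(Gs, grid, axis=0, initial=0.0)  # (m, d, p)
    cg0 = cumulative_trapezoid(g0s, grid, axis=0, initial=0.0)  # (m, d)

    target = X - cg0
    if np.any(~free_t):
        target = target - CG[:, :, ~free_t] @ kt[~free_t]
    if np.any(~free_x):
        target[:, ~free_x] -= kx[~free_x]

    n_xi, n_th = int(free_x.sum()), int(free_t.sum())
    sw = np.sqrt(_trapezoid_weights(grid))
    rows = []
    rhs = []
    xi_cols = np.flatnonzero(free_x)
    for i in range(d):
        A = np.zeros((m, n_xi + n_th))
        pos = np.searchsorted(xi_cols, i)
        if free_x[i]:
            A[:, pos] = 1.0
        A[:, n_xi:] = CG[:, i, free_t]
        rows.append(A * sw[:, None])
        rhs.append(target[:, i] * sw)
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    sol = _solve_lstsq(A, b)
    crit = float(np.sum((A @ sol - b) ** 2))

    xi = kx.copy()
    xi[free_x] = sol[:n_xi]
    theta = kt.copy()
    theta[free_t] = sol[n_xi:]
    return PreliminaryEstimate(theta_hat=theta, xi_hat=xi,
                               bandwidth=fit.bandwidth, method="integral",
                               criterion_value=crit)


def estimate_initial_values(model: ODEModel, fit: SmoothFit, theta_hat,
                            known_xi=None) -> np.ndarray:
    """Closed-form initial-value estimator at a given theta.

    Minimizing ``int || x(t) - xi - int_{t1}^t F(x(s); theta) ds ||^2 dt``
    over xi gives the quadrature-weighted time average of
    ``x(t) - int_{t1}^t F(x(s); theta) ds`` per coordinate.
    """
    theta_hat = np.asarray(theta_hat, dtype=float).ravel()
    kx = _resolve_known(known_xi, model.d, "xi")
    grid = fit.grid
    X = fit.xhat[:, : model.d]
    F = np.stack([model.rhs(X[k], theta_hat, grid[k]) for k in range(grid.size)])
    CF = cumulative_trapezoid(F, grid, axis=0, initial=0.0)
    wq = _trapezoid_weights(grid)
    xi = np.average(X - CF, axis=0, weights=wq)
    fixed = ~np.isnan(kx)
    xi[fixed] = kx[fixed]
    return xi


# ---------------------------------------------------------------------------
# Goodwin cascade (partially observed: x3 never measured)


def _goodwin_x3(grid, x2hat, theta4, theta5):
    """Reconstruct x3(t) = int_0^t exp(-theta5 (t-s)) theta4 x2(s) ds.

    Stable interval recursion: over each grid step the integrating
    factor is applied exactly and the source term by the trapezoid rule.
    """
    x3 = np.zeros_like(grid)
    src = theta4 * x2hat
    for k in range(grid.size - 1):
        dt = grid[k + 1] - grid[k]
        decay = np.exp(-theta5 * dt)
        x3[k + 1] = decay * x3[k] + 0.5 * dt * (decay * src[k] + src[k + 1])
    return x3


def _goodwin_cascade(model, fit, known_theta, known_xi, method):
    """Integral estimator for the Goodwin oscillator with x3 unobserved.

    Free parameters are (theta1, theta5); theta2..theta4 and the zero
    initial conditions are fixed.  Given theta5, x3 is reconstructed
    from the smoothed x2 and the criterion is linear in theta1; the
    resulting profile is minimized over theta5 on a coarse grid refined
    by bounded scalar minimization.
    """
    kt = _resolve_known(known_theta, model.p, "theta")
    kx = _resolve_known(known_xi, model.d, "xi")
    free_t = np.isnan(kt)
    if not (fit.observed_mask[0] and fit.observed_mask[1]
            and not fit.observed_mask[2]):
        raise UnsupportedObservationPatternError(
            "Goodwin cascade expects x1, x2 observed and x3 unobserved"
        )
    if not (free_t[0] and free_t[4] and not np.any(free_t[1:4])):
        raise UnsupportedObservationPatternError(
            "Goodwin cascade estimates (theta1, theta5) with theta2..theta4 fixed"
        )
    th2, th3, th4 = kt[1], kt[2], kt[3]
    xi = np.where(np.isnan(kx), 0.0, kx)
    grid = fit.grid
    x1h, x2h = fit.xhat[:, 0], fit.xhat[:, 1]
    wq = _trapezoid_weights(grid)
    B1 = cumulative_trapezoid(x1h, grid, initial=0.0)
    B2 = cumulative_trapezoid(x2h, grid, initial=0.0)

    def profile(theta5):
        x3 = _goodwin_x3(grid, x2h, th4, theta5)
        A = cumulative_trapezoid(1.0 / (1.0 + th2 * x3 ** 10), grid, initial=0.0)
        # state 1: x1h ~ xi1 + theta1 * A - theta5 * B1
        y1 = x1h - xi[0] + theta5 * B1
        denom = np.sum(wq * A * A)
        theta1 = np.sum(wq * A * y1) / denom if denom > 0 else 0.0
        r1 = y1 - theta1 * A
        # state 2: x2h ~ xi2 + theta3 * B1 - theta5 * B2 (no free parameter)
        r2 = x2h - xi[1] - th3 * B1 + theta5 * B2
        crit = float(np.sum(wq * (r1 ** 2 + r2 ** 2)))
        return crit, theta1

    t5_grid = np.linspace(0.02, 2.0, 60)
    crits = np.array([profile(t5)[0] for t5 in t5_grid])
    k = int(np.argmin(crits))
    lo = t5_grid[max(k - 1, 0)]
    hi = t5_grid[min(k + 1, t5_grid.size - 1)]
    res = minimize_scalar(lambda t5: profile(t5)[0], bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-8})
    theta5 = float(res.x)
    crit, theta1 = profile(theta5)
    theta = kt.copy()
    theta[0] = theta1
    theta[4] = theta5
    return PreliminaryEstimate(theta_hat=theta, xi_hat=xi,
                               bandwidth=fit.bandwidth, method=method,
                               criterion_value=crit)
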