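"""ODE model abstraction, registry of standard test systems, integration.

A model is the autonomous initial value problem

    x'(t) = F(x(t); theta),   x(t0) = xi,

with state dimension ``d`` and parameter dimension ``p``.  The combined
vector ``eta = (xi, theta)`` of length ``d + p`` collects initial values
and rate parameters.  Models carry analytic Jacobians and, where cheap,
a parameter-linearity decomposition ``F(x; theta) = G(x) theta + g0(x)``
which the preliminary estimators exploit for closed-form fits.

Registry systems: a scalar exponential-growth/decay model, the
Lotka-Volterra predator-prey system, the Robertson stiff chemical
kinetics benchmark, the Goodwin gene-regulation oscillator, the
nitrogen-oxide gas-phase reaction, and the alpha-pinene thermal
isomerization network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, InputError, IntegrationError

__all__ = [
    "ODEModel",
    "Trajectory",
    "get_model",
    "list_models",
    "solve_trajectory",
    "evaluate_rhs",
    "evaluate_jacobians",
    "second_derivatives",
    "wrap_nonautonomous",
]

_FD_STEP = 1e-5


@dataclass
class ODEModel:
    """An autonomous ODE system with derivative information.

    Parameters
    ----------
    name : str
        Registry identifier.
    d, p : int
        State and parameter dimensions.
    rhs : callable ``(x, theta, t) -> (d,)``
        Right-hand side F.
    jac_x : callable ``(x, theta, t) -> (d, d)``
        State Jacobian dF/dx.
    jac_theta : callable ``(x, theta, t) -> (d, p)``
        Parameter Jacobian dF/dtheta.
    hess_xx, hess_xtheta, hess_thetatheta : callables, optional
        Second-derivative tensors with shapes ``(d, d, d)``,
        ``(d, d, p)`` and ``(d, p, p)``; finite differences of the
        Jacobians are used when absent.
    theta_linear : (G, g0), optional
        Decomposition ``F(x) = G(x) theta + g0(x)`` with
        ``G(x, t) -> (d, p)`` and ``g0(x, t) -> (d,)``.
    stiff : bool
        Hint that an implicit integrator should be used.
    """

    name: str
    d: int
    p: int
    rhs: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    jac_x: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    jac_theta: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    hess_xx: Optional[Callable] = None
    hess_xtheta: Optional[Callable] = None
    hess_thetatheta: Optional[Callable] = None
    theta_linear: Optional[tuple] = None
    stiff: bool = False
    param_names: Sequence[str] = field(default_factory=list)
    state_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.param_names:
            self.param_names = [f"theta{i + 1}" for i in range(self.p)]
        if not self.state_names:
            self.state_names = [f"x{i + 1}" for i in range(self.d)]

    @property
    def eta_names(self):
        return [f"xi{i + 1}" for i in range(self.d)] + list(self.param_names)


@dataclass
class Trajectory:
    """Solution x(eta, t) of a model evaluated at the requested times."""

    times: np.ndarray
    states: np.ndarray  # (n, d)
    eta: np.ndarray  # (d + p,), concatenation (xi, theta)

    @property
    def xi(self):
        return self.eta[: self.states.shape[1]]

    @property
    def theta(self):
        return self.eta[self.states.shape[1]:]


def _check_xt(model: ODEModel, x, theta):
    x = np.asarray(x, dtype=float).ravel()
    theta = np.asarray(theta, dtype=float).ravel()
    if x.size != model.d:
        raise InputError(f"state has length {x.size}, expected d={model.d}")
    if theta.size != model.p:
        raise InputError(f"theta has length {theta.size}, expected p={model.p}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(theta))):
        raise InputError("non-finite state or parameter values")
    return x, theta


def evaluate_rhs(model: ODEModel, x, theta, t=0.0) -> np.ndarray:
    """Evaluate F(x; theta) with input validation."""
    x, theta = _check_xt(model, x, theta)
    out = np.asarray(model.rhs(x, theta, t), dtype=float).ravel()
    if out.size != model.d:
        raise InputError(f"rhs returned length {out.size}, expected {model.d}")
    return out


def evaluate_jacobians(model: ODEModel, x, theta, t=0.0):
    """Return (dF/dx, dF/dtheta) at (x, theta, t)."""
    x, theta = _check_xt(model, x, theta)
    jx = np.asarray(model.jac_x(x, theta, t), dtype=float).reshape(model.d, model.d)
    jt = np.asarray(model.jac_theta(x, theta, t), dtype=float).reshape(model.d, model.p)
    return jx, jt


def _fd_hessians(model: ODEModel, x, theta, t):
    """Central finite differences of the analytic Jacobians.

    Step is scaled per coordinate as ``1e-5 * (1 + |value|)``.
    """
    d, p = model.d, model.p
    hxx = np.zeros((d, d, d))
    hxt = np.zeros((d, d, p))
    htt = np.zeros((d, p, p))
    for k in range(d):
        h = _FD_STEP * (1.0 + abs(x[k]))
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        jxp, jtp = evaluate_jacobians(model, xp, theta, t)
        jxm, jtm = evaluate_jacobians(model, xm, theta, t)
        hxx[:, :, k] = (jxp - jxm) / (2 * h)
        hxt[:, k, :] = (jtp - jtm) / (2 * h)
    for b in range(p):
        h = _FD_STEP * (1.0 + abs(theta[b]))
        tp, tm = theta.copy(), theta.copy()
        tp[b] += h
        tm[b] -= h
        _, jtp = evaluate_jacobians(model, x, tp, t)
        _, jtm = evaluate_jacobians(model, x, tm, t)
        htt[:, :, b] = (jtp - jtm) / (2 * h)
    # symmetrize hxx in its last two indices (d/dx of dF/dx)
    hxx = 0.5 * (hxx + np.transpose(hxx, (0, 2, 1)))
    htt = 0.5 * (htt + np.transpose(htt, (0, 2, 1)))
    return hxx, hxt, htt


def second_derivatives(model: ODEModel, x, theta, t=0.0, allow_fd=True):
    """Second-derivative tensors (Hxx, Hxtheta, Hthetatheta).

    Shapes ``(d,d,d)``, ``(d,d,p)``, ``(d,p,p)``; index order is
    ``[output state, first deriv, second deriv]``.
    """
    x, theta = _check_xt(model, x, theta)
    if model.hess_xx is not None:
        return (
            np.asarray(model.hess_xx(x, theta, t), dtype=float),
            np.asarray(model.hess_xtheta(x, theta, t), dtype=float),
            np.asarray(model.hess_thetatheta(x, theta, t), dtype=float),
        )
    if not allow_fd:
        raise ConfigurationError(
            f"model '{model.name}' has no analytic second derivatives "
            "and finite differences are disabled"
        )
    return _fd_hessians(model, x, theta, t)


def solve_trajectory(model: ODEModel, eta, times, rtol=1e-8, atol=1e-10,
                     method=None) -> Trajectory:
    """Integrate the model at eta = (xi, theta) over the given times.

    The initial condition ``xi`` is attached to ``times[0]``.  Stiff
    models default to BDF; all others to an adaptive explicit
    Runge-Kutta scheme.
    """
    eta = np.asarray(eta, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    if eta.size != model.d + model.p:
        raise InputError(f"eta has length {eta.size}, expected {model.d + model.p}")
    if times.size < 1 or np.any(np.diff(times) <= 0):
        raise InputError("times must be strictly increasing")
    xi, theta = eta[: model.d], eta[model.d:]
    if method is None:
        method = "BDF" if model.stiff else "DOP853"

    def f(t, x):
        return model.rhs(x, theta, t)

    def jac(t, x):
        return model.jac_x(x, theta, t)

    kwargs = {"jac": jac} if method in ("BDF", "Radau", "LSODA") else {}
    if times.size == 1:
        return Trajectory(times=times, states=xi[None, :].copy(), eta=eta)
    sol = solve_ivp(f, (times[0], times[-1]), xi, t_eval=times,
                    method=method, rtol=rtol, atol=atol, **kwargs)
    if not sol.success or sol.y.shape[1] != times.size:
        t_fail = sol.t[-1] if sol.t.size else times[0]
        raise IntegrationError(
            f"integration of '{model.name}' failed near t={t_fail:.6g}: {sol.message}",
            t_fail=t_fail,
        )
    if not np.all(np.isfinite(sol.y)):
        raise IntegrationError(f"integration of '{model.name}' produced non-finite states")
    return Trajectory(times=times, states=sol.y.T.copy(), eta=eta)


def wrap_nonautonomous(name, d, p, rhs_t, jac_x_t=None, jac_theta_t=None,
                       stiff=False) -> ODEModel:
    """Reduce a non-autonomous system x' = F(x, t; theta) to autonomous form.

    Appends time as an extra state with unit derivative, so every
    downstream routine (sensitivities, estimators) sees an autonomous
    model of dimension ``d + 1``.  Missing Jacobians are filled by
    central finite differences of ``rhs_t``.
    """

    def rhs(x, theta, t):
        tau = x[d]
        out = np.empty(d + 1)
        out[:d] = rhs_t(x[:d], theta, tau)
        out[d] = 1.0
        return out

    def _fd_jac_x(x, theta, tau):
        J = np.zeros((d, d))
        for k in range(d):
            h = _FD_STEP * (1 + abs(x[k]))
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            J[:, k] = (np.asarray(rhs_t(xp, theta, tau)) -
                       np.asarray(rhs_t(xm, theta, tau))) / (2 * h)
        return J

    def _fd_jac_theta(x, theta, tau):
        J = np.zeros((d, p))
        for b in range(p):
            h = _FD_STEP * (1 + abs(theta[b]))
            tp, tm = theta.copy(), theta.copy()
            tp[b] += h
            tm[b] -= h
            J[:, b] = (np.asarray(rhs_t(x, tp, tau)) -
                       np.asarray(rhs_t(x, tm, tau))) / (2 * h)
        return J

    jxt = jac_x_t or _fd_jac_x
    jtt = jac_theta_t or _fd_jac_theta

    def jac_x(x, theta, t):
        tau = x[d]
        J = np.zeros((d + 1, d + 1))
        J[:d, :d] = jxt(x[:d], theta, tau)
        # dF/dtau column via finite difference in time
        h = _FD_STEP * (1 + abs(tau))
        J[:d, d] = (np.asarray(rhs_t(x[:d], theta, tau + h)) -
                    np.asarray(rhs_t(x[:d], theta, tau - h))) / (2 * h)
        return J

    def jac_theta(x, theta, t):
        J = np.zeros((d + 1, p))
        J[:d, :] = jtt(x[:d], theta, x[d])
        return J

    return ODEModel(name=name, d=d + 1, p=p, rhs=rhs, jac_x=jac_x,
                    jac_theta=jac_theta, stiff=stiff)


# ---------------------------------------------------------------------------
# Registry


def _linear_model() -> ODEModel:
    # x' = theta * x; closed-form solution xi * exp(theta * t)
    def rhs(x, th, t):
        return np.array([th[0] * x[0]])

    return ODEModel(
        name="linear", d=1, p=1,
        rhs=rhs,
        jac_x=lambda x, th, t: np.array([[th[0]]]),
        jac_theta=lambda x, th, t: np.array([[x[0]]]),
        hess_xx=lambda x, th, t: np.zeros((1, 1, 1)),
        hess_xtheta=lambda x, th, t: np.ones((1, 1, 1)),
        hess_thetatheta=lambda x, th, t: np.zeros((1, 1, 1)),
        theta_linear=(lambda x, t: np.array([[x[0]]]),
                      lambda x, t: np.zeros(1)),
    )


def _lotka_volterra() -> ODEModel:
    # x1' = th1 x1 - th2 x1 x2 ; x2' = -th3 x2 + th4 x1 x2
    def rhs(x, th, t):
        return np.array([
            th[0] * x[0] - th[1] * x[0] * x[1],
            -th[2] * x[1] + th[3] * x[0] * x[1],
        ])

    def jac_x(x, th, t):
        return np.array([
            [th[0] - th[1] * x[1], -th[1] * x[0]],
            [th[3] * x[1], -th[2] + th[3] * x[0]],
        ])

    def G(x, t):
        return np.array([
            [x[0], -x[0] * x[1], 0.0, 0.0],
            [0.0, 0.0, -x[1], x[0] * x[1]],
        ])

    return ODEModel(
        name="lotka_volterra", d=2, p=4,
        rhs=rhs, jac_x=jac_x,
        jac_theta=lambda x, th, t: G(x, t),
        theta_linear=(G, lambda x, t: np.zeros(2)),
        state_names=["prey", "predator"],
    )


def _robertson() -> ODEModel:
    # x1' = th1 x2 x3 - th2 x1
    # x2' = th2 x1 - th1 x2 x3 - th3 x2^2
    # x3' = th3 x2^2
    def rhs(x, th, t):
        a = th[0] * x[1] * x[2]
        b = th[1] * x[0]
        c = th[2] * x[1] ** 2
        return np.array([a - b, b - a - c, c])

    def jac_x(x, th, t):
        return np.array([
            [-th[1], th[0] * x[2], th[0] * x[1]],
            [th[1], -th[0] * x[2] - 2 * th[2] * x[1], -th[0] * x[1]],
            [0.0, 2 * th[2] * x[1], 0.0],
        ])

    def G(x, t):
        return np.array([
            [x[1] * x[2], -x[0], 0.0],
            [-x[1] * x[2], x[0], -x[1] ** 2],
            [0.0, 0.0, x[1] ** 2],
        ])

    return ODEModel(
        name="robertson", d=3, p=3,
        rhs=rhs, jac_x=jac_x,
        jac_theta=lambda x, th, t: G(x, t),
        theta_linear=(G, lambda x, t: np.zeros(3)),
        stiff=True,
    )


def _goodwin() -> ODEModel:
    # x1' = th1 / (1 + th2 x3^10) - th5 x1
    # x2' = th3 x1 - th5 x2
    # x3' = th4 x2 - th5 x3
    def rhs(x, th, t):
        denom = 1.0 + th[1] * x[2] ** 10
        return np.array([
            th[0] / denom - th[4] * x[0],
            th[2] * x[0] - th[4] * x[1],
            th[3] * x[1] - th[4] * x[2],
        ])

    def jac_x(x, th, t):
        denom = 1.0 + th[1] * x[2] ** 10
        return np.array([
            [-th[4], 0.0, -th[0] * th[1] * 10 * x[2] ** 9 / denom ** 2],
            [th[2], -th[4], 0.0],
            [0.0, th[3], -th[4]],
        ])

    def jac_theta(x, th, t):
        denom = 1.0 + th[1] * x[2] ** 10
        return np.array([
            [1.0 / denom, -th[0] * x[2] ** 10 / denom ** 2, 0.0, 0.0, -x[0]],
            [0.0, 0.0, x[0], 0.0, -x[1]],
            [0.0, 0.0, 0.0, x[1], -x[2]],
        ])

    return ODEModel(name="goodwin", d=3, p=5, rhs=rhs,
                    jac_x=jac_x, jac_theta=jac_theta)


_NO_A = 126.2
_NO_B = 91.9


def _nitrogen_oxide() -> ODEModel:
    # x' = th1 (126.2 - x)(91.9 - x)^2 - th2 x^2 ; reversible 2NO + O2 <-> 2NO2
    def rhs(x, th, t):
        return np.array([
            th[0] * (_NO_A - x[0]) * (_NO_B - x[0]) ** 2 - th[1] * x[0] ** 2
        ])

    def jac_x(x, th, t):
        u = x[0]
        d1 = -(_NO_B - u) ** 2 - 2 * (_NO_A - u) * (_NO_B - u)
        return np.array([[th[0] * d1 - 2 * th[1] * u]])

    def G(x, t):
        u = x[0]
        return np.array([[(_NO_A - u) * (_NO_B - u) ** 2, -u ** 2]])

    def hess_xx(x, th, t):
        u = x[0]
        return np.array([[[th[0] * (4 * (_NO_B - u) + 2 * (_NO_A - u)) - 2 * th[1]]]])

    def hess_xtheta(x, th, t):
        u = x[0]
        return np.array([[[-(_NO_B - u) ** 2 - 2 * (_NO_A - u) * (_NO_B - u),
                           -2 * u]]])

    return ODEModel(
        name="nitrogen_oxide", d=1, p=2,
        rhs=rhs, jac_x=jac_x,
        jac_theta=lambda x, th, t: G(x, t),
        hess_xx=hess_xx, hess_xtheta=hess_xtheta,
        hess_thetatheta=lambda x, th, t: np.zeros((1, 2, 2)),
        theta_linear=(G, lambda x, t: np.zeros(1)),
    )


def _alpha_pinene() -> ODEModel:
    # Thermal isomerization network, 5 states, 5 rate parameters:
    # x1' = -(th1 + th2) x1
    # x2' = th1 x1
    # x3' = th2 x1 - (th3 + th4) x3 + th5 x5
    # x4' = th3 x3
    # x5' = th4 x3 - th5 x5
    def rhs(x, th, t):
        return np.array([
            -(th[0] + th[1]) * x[0],
            th[0] * x[0],
            th[1] * x[0] - (th[2] + th[3]) * x[2] + th[4] * x[4],
            th[2] * x[2],
            th[3] * x[2] - th[4] * x[4],
        ])

    def jac_x(x, th, t):
        J = np.zeros((5, 5))
        J[0, 0] = -(th[0] + th[1])
        J[1, 0] = th[0]
        J[2, 0] = th[1]
        J[2, 2] = -(th[2] + th[3])
        J[2, 4] = th[4]
        J[3, 2] = th[2]
        J[4, 2] = th[3]
        J[4, 4] = -th[4]
        return J

    def G(x, t):
        Gm = np.zeros((5, 5))
        Gm[0, 0] = -x[0]
        Gm[0, 1] = -x[0]
        Gm[1, 0] = x[0]
        Gm[2, 1] = x[0]
        Gm[2, 2] = -x[2]
        Gm[2, 3] = -x[2]
        Gm[2, 4] = x[4]
        Gm[3, 2] = x[2]
        Gm[4, 3] = x[2]
        Gm[4, 4] = -x[4]
        return Gm

    return ODEModel(
        name="alpha_pinene", d=5, p=5,
        rhs=rhs, jac_x=jac_x,
        jac_theta=lambda x, th, t: G(x, t),
        theta_linear=(G, lambda x, t: np.zeros(5)),
    )


_REGISTRY = {
    "linear": _linear_model,
    "lotka_volterra": _lotka_volterra,
    "robertson": _robertson,
    "goodwin": _goodwin,
    "nitrogen_oxide": _nitrogen_oxide,
    "alpha_pinene": _alpha_pinene,
}


def list_models():
    """Names of the built-in model registry."""
    return sorted(_REGISTRY)


def get_model(name: str) -> ODEModel:
    """Instantiate a registry model by name."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise InputError(
            f"unknown model '{name}'; available: {', '.join(list_models())}"
        ) from None
    return factory()
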