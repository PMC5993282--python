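"""Local-polynomial trajectory smoothing and bandwidth grids.

Noisy observations of each observed state are smoothed by a local
polynomial fit of degree 2 with the Epanechnikov kernel; the intercept
coefficient estimates the trajectory x(t) and the slope coefficient its
derivative x'(t).  A candidate set of bandwidths proportional to
n^(-1/3) feeds the data-driven selection performed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, SingularWindowError

__all__ = ["SmoothFit", "BandwidthGrid", "local_poly_fit", "bandwidth_grid",
           "smooth_dataset", "DEFAULT_DEGREE", "DEFAULT_GRID_SIZE"]

DEFAULT_DEGREE = 2
DEFAULT_GRID_SIZE = 101
#: time-axis span the published bandwidth multipliers were built for
_REFERENCE_SPAN = 10.0


@dataclass
class SmoothFit:
    """Smoothed trajectory and derivative on an evaluation grid.

    Columns of unobserved states are NaN and flagged in
    ``observed_mask``.
    """

    grid: np.ndarray  # (m,)
    xhat: np.ndarray  # (m, d)
    xhat_prime: np.ndarray  # (m, d)
    bandwidth: float
    degree: int
    observed_mask: np.ndarray  # (d,) bool

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (grid plus value/derivative per state)."""
        data = {"t": self.grid}
        for i in range(self.xhat.shape[1]):
            data[f"x{i + 1}"] = self.xhat[:, i]
            data[f"dx{i + 1}"] = self.xhat_prime[:, i]
        return pd.DataFrame(data)


@dataclass
class BandwidthGrid:
    """Candidate bandwidths ``n**(-1/3) * c`` for data-driven selection."""

    values: np.ndarray
    n: int
    c: np.ndarray


def bandwidth_grid(n: int, N: int = 10, c_min: float = 0.02,
                   c_max: float = 3.0, span: float = _REFERENCE_SPAN) -> BandwidthGrid:
    """Equispaced multipliers c_min..c_max scaled by n^(-1/3).

    ``span`` is the length of the observation window; multipliers are
    interpreted on a 10-unit time axis and rescaled by span/10 so the
    same grid transfers across horizons.
    """
    if N < 1:
        raise InputError("bandwidth grid size N must be >= 1")
    if not (0 < c_min <= c_max):
        raise InputError("need 0 < c_min <= c_max")
    if n < 1:
        raise InputError("sample size must be positive")
    c = np.linspace(c_min, c_max, N)
    values = n ** (-1.0 / 3.0) * c * (span / _REFERENCE_SPAN)
    return BandwidthGrid(values=values, n=n, c=c)


def _epanechnikov(u):
    return np.where(np.abs(u) < 1.0, 0.75 * (1.0 - u ** 2), 0.0)


def local_poly_fit(times, y, bandwidth, degree=DEFAULT_DEGREE, grid=None,
                   widen=False):
    """Weighted local polynomial regression of y on times.

    Returns ``(values, derivatives)`` on the evaluation grid: the
    fitted intercept and slope coefficients of the local expansion
    around each grid point.  Windows near the boundary are asymmetric;
    no reflection is applied.

    With ``widen=True`` a window containing fewer than ``degree + 1``
    observations is enlarged, at that evaluation point only, to 1.1x
    the distance of the (degree+1)-th nearest observation — a
    nearest-neighbor floor that keeps every local system determined,
    so small candidate bandwidths act as near-interpolants instead of
    failing.

    Raises
    ------
    SingularWindowError
        If ``widen=False`` and fewer than ``degree + 1`` observations
        receive positive kernel weight at some grid point, or the
        local design is numerically singular there.
    """
    times = np.asarray(times, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if times.size != y.size:
        raise InputError("times and y must have equal length")
    if np.any(np.diff(times) <= 0):
        raise InputError("times must be strictly increasing")
    if bandwidth <= 0:
        raise InputError("bandwidth must be positive")
    if grid is None:
        grid = times
    grid = np.asarray(grid, dtype=float).ravel()
    n, m, q = times.size, grid.size, degree + 1
    if n < q:
        raise SingularWindowError(
            f"only {n} observations for a degree-{degree} fit")

    # (m,) per-evaluation-point bandwidths
    h = np.full(m, float(bandwidth))
    if widen:
        # distance to the (degree+1)-th nearest observation, from the
        # 2q sorted neighbours around each grid point (deduplicated at
        # the boundaries)
        j = np.searchsorted(times, grid)
        cand = np.clip(j[:, None] + np.arange(-q, q)[None, :], 0, n - 1)
        dist = np.abs(times[cand] - grid[:, None])
        dist[:, 1:][cand[:, 1:] == cand[:, :-1]] = np.inf
        dist.sort(axis=1)
        h = np.maximum(h, 1.1 * dist[:, degree])

    # gather only the observations inside each window
    lo = np.searchsorted(times, grid - h, side="left")
    hi = np.searchsorted(times, grid + h, side="right")
    K = int(np.max(hi - lo))
    idx = np.minimum(lo[:, None] + np.arange(K)[None, :], n - 1)
    valid = lo[:, None] + np.arange(K)[None, :] < hi[:, None]
    D = times[idx] - grid[:, None]  # (m, K)
    W = _epanechnikov(D / h[:, None]) * valid
    counts = np.count_nonzero(W > 0, axis=1)
    if np.any(counts < q):
        k = int(np.argmax(counts < q))
        raise SingularWindowError(
            f"window at t={grid[k]:.6g} holds {counts[k]} observations, "
            f"need at least {q}; increase the bandwidth",
            grid_point=grid[k],
        )

    # design powers (t - g)^p, p = 0..degree, on the gathered windows
    P = D[:, :, None] ** np.arange(q)[None, None, :]
    WP = W[:, :, None] * P
    A = np.einsum("mkq,mkr->mqr", WP, P)  # (m, q, q) normal matrices
    b = np.einsum("mkq,mk->mq", WP, y[idx])
    try:
        beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        # find the offending grid point for the error message
        for k in range(grid.size):
            try:
                np.linalg.solve(A[k], b[k])
            except np.linalg.LinAlgError:
                raise SingularWindowError(
                    f"singular local design at t={grid[k]:.6g}",
                    grid_point=grid[k],
                ) from None
        raise
    if not np.all(np.isfinite(beta)):
        k = int(np.argmax(~np.all(np.isfinite(beta), axis=1)))
        raise SingularWindowError(
            f"ill-conditioned local design at t={grid[k]:.6g}",
            grid_point=grid[k],
        )
    values = beta[:, 0]
    derivs = beta[:, 1] if degree >= 1 else np.zeros_like(values)
    return values, derivs


def smooth_dataset(dataset, bandwidth, degree=DEFAULT_DEGREE, grid=None,
                   widen=True) -> SmoothFit:
    """Smooth every observed state of a dataset on a shared grid.

    ``dataset`` needs attributes ``times`` (n,), ``Y`` (n, d) and
    ``observed_mask`` (d,).  The default evaluation grid is
    ``max(n, 101)`` equispaced points spanning the design.  Deficient
    windows are widened by default (see :func:`local_poly_fit`) so
    that every candidate bandwidth yields a usable fit.
    """
    times = np.asarray(dataset.times, dtype=float)
    Y = np.asarray(dataset.Y, dtype=float)
    mask = np.asarray(dataset.observed_mask, dtype=bool)
    if not mask.any():
        raise InputError("dataset has no observed states")
    if grid is None:
        m = max(times.size, DEFAULT_GRID_SIZE)
        grid = np.linspace(times[0], times[-1], m)
    grid = np.asarray(grid, dtype=float)
    d = Y.shape[1]
    xhat = np.full((grid.size, d), np.nan)
    xhat_prime = np.full((grid.size, d), np.nan)
    for i in range(d):
        if not mask[i]:
            continue
        xhat[:, i], xhat_prime[:, i] = local_poly_fit(
            times, Y[:, i], bandwidth, degree=degree, grid=grid, widen=widen)
    return SmoothFit(grid=grid, xhat=xhat, xhat_prime=xhat_prime,
                     bandwidth=float(bandwidth), degree=degree,
                     observed_mask=mask.copy())
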