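"""Synthetic data generation, scenario registry and Monte-Carlo driver.

Observations follow the additive measurement-error model

    Y_ij = x_i(eta0, t_j) + eps_ij,    eps_ij ~ N(0, sigma_i^2) i.i.d.,

on a fixed design (equidistant, explicit, or i.i.d.-uniform times).
The scenario registry encodes the standard simulation setups used to
benchmark the one-step estimator: the scalar linear model at four
parameter configurations, the Lotka-Volterra system, the true-variance
study for the linear model, the nitrogen-oxide reaction, the
alpha-pinene network with known initial values and heteroscedastic
noise, the Robertson stiff kinetics benchmark, and the partially
observed Goodwin oscillator.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import EstimationError, InputError, OdestepError
from .inference import summarize
from .ode_models import get_model, solve_trajectory
from .one_step import select_estimate
from .smoothing import bandwidth_grid

logger = logging.getLogger(__name__)

__all__ = ["Dataset", "Scenario", "MCSummary", "generate_dataset",
           "run_monte_carlo", "load_scenario", "list_scenarios",
           "dataset_to_csv", "dataset_from_csv"]


@dataclass
class Dataset:
    """Noisy time-course observations of an ODE system.

    ``Y`` is n x d with NaN columns for unobserved states; missingness
    is whole-state (a state is measured at every time or never).
    """

    times: np.ndarray
    Y: np.ndarray
    observed_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.Y = np.asarray(self.Y, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if self.Y.shape[0] != self.times.size:
            raise InputError("Y row count must match times length")
        if not self.observed_mask.any():
            raise InputError("at least one state must be observed")


def dataset_to_csv(dataset: Dataset, path):
    """Write a dataset as ``time,y1..yd`` CSV; missing entries empty."""
    d = dataset.Y.shape[1]
    df = pd.DataFrame({"time": dataset.times})
    for i in range(d):
        df[f"y{i + 1}"] = dataset.Y[:, i]
    df.to_csv(path, index=False)


def dataset_from_csv(path) -> Dataset:
    """Read a ``time,y1..yd`` CSV; fully-empty columns become unobserved."""
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise InputError("CSV must have a 'time' column")
    ycols = [c for c in df.columns if c != "time"]
    Y = df[ycols].to_numpy(dtype=float)
    observed = ~np.all(np.isnan(Y), axis=0)
    return Dataset(times=df["time"].to_numpy(dtype=float), Y=Y,
                   observed_mask=observed, meta={"source": str(path)})


@dataclass
class Scenario:
    """A fully specified simulation experiment."""

    name: str
    model_name: str
    xi0: np.ndarray
    theta0: np.ndarray
    known_xi: Optional[np.ndarray] = None  # NaN = free
    known_theta: Optional[np.ndarray] = None
    design: dict = field(default_factory=dict)  # kind: equidistant|explicit|uniform
    noise_sd: np.ndarray = None  # per-state SDs
    observed: np.ndarray = None  # per-state booleans
    estimation: dict = field(default_factory=dict)
    reps: int = 500
    base_seed: int = 0

    def __post_init__(self):
        self.xi0 = np.asarray(self.xi0, dtype=float).ravel()
        self.theta0 = np.asarray(self.theta0, dtype=float).ravel()
        d = self.xi0.size
        if self.noise_sd is None:
            raise InputError("scenario needs per-state noise SDs")
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (d,)).copy()
        if np.any(self.noise_sd[self.observed_arr] <= 0):
            raise InputError("noise SDs of observed states must be positive")
        if self.known_xi is not None:
            self.known_xi = np.asarray(self.known_xi, dtype=float).ravel()
        if self.known_theta is not None:
            self.known_theta = np.asarray(self.known_theta, dtype=float).ravel()

    @property
    def observed_arr(self):
        if self.observed is None:
            return np.ones(self.xi0.size, dtype=bool)
        return np.asarray(self.observed, dtype=bool)

    @property
    def eta0(self):
        return np.concatenate([self.xi0, self.theta0])

    @property
    def free_mask(self):
        d, p = self.xi0.size, self.theta0.size
        kx = np.full(d, np.nan) if self.known_xi is None else self.known_xi
        kt = np.full(p, np.nan) if self.known_theta is None else self.known_theta
        return np.concatenate([np.isnan(kx), np.isnan(kt)])

    def design_times(self, rng=None) -> np.ndarray:
        kind = self.design.get("kind", "equidistant")
        if kind == "equidistant":
            return np.linspace(self.design.get("t0", 0.0), self.design["T"],
                               self.design["n"])
        if kind == "explicit":
            return np.asarray(self.design["times"], dtype=float)
        if kind == "uniform":
            if rng is None:
                raise InputError("uniform design needs an RNG")
            t = np.sort(rng.uniform(self.design.get("t0", 0.0),
                                    self.design["T"], self.design["n"]))
            # guard against coincident draws
            while np.any(np.diff(t) <= 0):
                t = np.sort(rng.uniform(self.design.get("t0", 0.0),
                                        self.design["T"], self.design["n"]))
            return t
        raise InputError(f"unknown design kind '{kind}'")

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a, float).tolist()

        return {
            "name": self.name,
            "model_name": self.model_name,
            "xi0": arr(self.xi0),
            "theta0": arr(self.theta0),
            "known_xi": arr(self.known_xi),
            "known_theta": arr(self.known_theta),
            "design": {k: (arr(v) if isinstance(v, np.ndarray) else v)
                       for k, v in self.design.items()},
            "noise_sd": arr(self.noise_sd),
            "observed": None if self.observed is None
            else np.asarray(self.observed, bool).tolist(),
            "estimation": dict(self.estimation),
            "reps": self.reps,
            "base_seed": self.base_seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        data = dict(data)
        for key in ("xi0", "theta0", "known_xi", "known_theta", "noise_sd"):
            if data.get(key) is not None:
                data[key] = np.asarray(data[key], dtype=float)
        if data.get("observed") is not None:
            data["observed"] = np.asarray(data["observed"], dtype=bool)
        return cls(**data)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _replicate_rng(scenario: Scenario, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate stream, stable in the scenario name."""
    tag = zlib.crc32(scenario.name.encode() or scenario.model_name.encode())
    ss = np.random.SeedSequence([int(scenario.base_seed), int(tag), int(replicate)])
    return np.random.default_rng(ss)


def generate_dataset(scenario: Scenario, replicate: int = 0) -> Dataset:
    """Simulate one noisy dataset for the scenario's replicate index."""
    if replicate < 0:
        raise InputError("replicate index must be >= 0")
    model = get_model(scenario.model_name)
    rng = _replicate_rng(scenario, replicate)
    times = scenario.design_times(rng=rng)
    opts = scenario.estimation
    traj = solve_trajectory(model, scenario.eta0, times,
                            rtol=opts.get("rtol", 1e-8),
                            atol=opts.get("atol", 1e-10))
    obs = scenario.observed_arr
    eps = rng.standard_normal(traj.states.shape) * scenario.noise_sd[None, :]
    Y = traj.states + eps
    Y[:, ~obs] = np.nan
    return Dataset(times=times, Y=Y, observed_mask=obs,
                   meta={"scenario": scenario.name, "seed": scenario.base_seed,
                         "replicate": replicate})


@dataclass
class MCSummary:
    """Aggregated Monte-Carlo results for the free parameters.

    ``table`` columns: parameter, truth, mean, ste (empirical SD of the
    point estimates), asym (square root of the mean estimated
    asymptotic variance), coverage.  Per-replicate arrays are retained
    for downstream analysis of both the corrected and the preliminary
    estimators.
    """

    table: pd.DataFrame
    estimates: np.ndarray  # (R_ok, n_free) one-step estimates
    prelim: np.ndarray  # (R_ok, n_free) preliminary estimates
    asym_var: np.ndarray  # (R_ok, n_free)
    cover: np.ndarray  # (R_ok, n_free) bool
    n_success: int
    n_fail: int
    failures: list

    @property
    def coverage(self):
        return self.table.set_index("parameter")["coverage"]


def run_replicate(scenario: Scenario, replicate: int):
    """Generate one dataset and run the full pipeline on it.

    Returns ``(eta_bar_free, eta_hat_free, asym_var, cover)`` for the
    free parameters.
    """
    model = get_model(scenario.model_name)
    dataset = generate_dataset(scenario, replicate)
    opts = dict(scenario.estimation)
    n = dataset.times.size
    span = dataset.times[-1] - dataset.times[0]
    bw = bandwidth_grid(n, N=opts.get("N", 10), c_min=opts.get("c_min", 0.02),
                        c_max=opts.get("c_max", 3.0), span=span)
    result = select_estimate(
        model, dataset, bw,
        variant=opts.get("variant", "damped"),
        lam=opts.get("lambda", 0.01),
        preliminary=opts.get("preliminary", "integral"),
        known_xi=scenario.known_xi, known_theta=scenario.known_theta,
        max_steps=opts.get("max_steps", 8), score_preliminary=True,
        free_xi_prelim=opts.get("free_xi_prelim", False),
        rtol=opts.get("rtol", 1e-8), atol=opts.get("atol", 1e-10))
    summary = summarize(
        model, result.eta_bar, dataset, free_mask=result.free_mask,
        alpha=opts.get("alpha", 0.05),
        per_state_sigma=opts.get("per_state_sigma", False),
        design=opts.get("fisher_design", "points"),
        rtol=opts.get("rtol", 1e-8), atol=opts.get("atol", 1e-10),
        grid_size=opts.get("fisher_grid", 1001))
    free = result.free_mask
    eta_bar_f = result.eta_bar[free]
    eta_hat_f = result.prelim_selected[free]
    truth = scenario.eta0[free]
    lo, hi = summary.intervals[:, 0], summary.intervals[:, 1]
    cover = (lo <= truth) & (truth <= hi)
    asym_var = np.diag(summary.cov)
    return eta_bar_f, eta_hat_f, asym_var, cover


def run_monte_carlo(scenario: Scenario, reps=None, base_seed=None,
                    progress=False) -> MCSummary:
    """Replicate the scenario and aggregate estimator statistics.

    Replicate-level failures (all bandwidth candidates failing,
    integrator blow-up) are recorded and excluded from the summaries;
    the run only aborts if every replicate fails.
    """
    if base_seed is not None:
        scenario = Scenario.from_dict({**scenario.to_dict(),
                                       "base_seed": int(base_seed)})
    reps = scenario.reps if reps is None else int(reps)
    if reps < 1:
        raise InputError("reps must be >= 1")
    model = get_model(scenario.model_name)
    free = scenario.free_mask
    names = [nm for nm, f in zip(model.eta_names, free) if f]
    truth = scenario.eta0[free]

    est, pre, avar, cov = [], [], [], []
    failures = []
    for r in range(reps):
        try:
            eb, eh, av, cv = run_replicate(scenario, r)
        except OdestepError as exc:
            failures.append((r, f"{type(exc).__name__}: {exc}"))
            logger.warning("replicate %d failed: %s", r, exc)
            continue
        est.append(eb)
        pre.append(eh)
        avar.append(av)
        cov.append(cv)
        if progress and (r + 1) % 50 == 0:
            logger.info("%s: %d/%d replicates done", scenario.name, r + 1, reps)
    if not est:
        raise EstimationError(
            f"all {reps} replicates of '{scenario.name}' failed",
            causes=[msg for _, msg in failures])
    est = np.asarray(est)
    pre = np.asarray(pre)
    avar = np.asarray(avar)
    cov = np.asarray(cov, dtype=bool)
    R = est.shape[0]
    table = pd.DataFrame({
        "parameter": names,
        "truth": truth,
        "mean": est.mean(axis=0),
        "ste": est.std(axis=0, ddof=1) if R > 1 else np.full(len(names), np.nan),
        "asym": np.sqrt(avar.mean(axis=0)),
        "coverage": cov.mean(axis=0),
    })
    return MCSummary(table=table, estimates=est, prelim=pre, asym_var=avar,
                     cover=cov, n_success=R, n_fail=len(failures),
                     failures=failures)


# ---------------------------------------------------------------------------
# Scenario registry


def _linear_scenario(name, xi0, theta0, n, sigma=0.05, reps=500, T=10.0):
    return Scenario(
        name=name, model_name="linear", xi0=[xi0], theta0=[theta0],
        design={"kind": "equidistant", "t0": 0.0, "T": T, "n": n},
        noise_sd=[sigma], reps=reps,
        estimation={},
    )


_ALPHA_PINENE_TIMES = [1230.0, 3060.0, 4920.0, 7800.0, 10680.0, 15030.0,
                       22620.0, 36420.0]
_ALPHA_PINENE_XI = [88.35, 7.3, 2.3, 0.4, 1.75]
_ALPHA_PINENE_THETA = [5.926e-05, 2.963e-05, 2.047e-05, 2.744e-04, 3.997e-05]
_ALPHA_PINENE_SD_BASE = np.array([44.6833, 36.4111, 4.9570, 1.6339, 12.4147])


def _alpha_pinene_scenario(name, a, reps=500):
    return Scenario(
        name=name,
        model_name="alpha_pinene",
        xi0=_ALPHA_PINENE_XI, theta0=_ALPHA_PINENE_THETA,
        known_xi=np.asarray(_ALPHA_PINENE_XI, dtype=float),
        design={"kind": "explicit", "times": list(_ALPHA_PINENE_TIMES)},
        noise_sd=a * _ALPHA_PINENE_SD_BASE, reps=reps,
        estimation={"preliminary": "integral"},
    )


def _robertson_noise_sd():
    """Per-state SD: 0.01 x the time-mean of the true state."""
    model = get_model("robertson")
    times = np.linspace(0.0, 10.0, 201)
    traj = solve_trajectory(model, np.array([1.0, 0.0, 0.0, 1e4, 0.04, 3e7]),
                            times)
    means = traj.states.mean(axis=0)
    return 0.01 * np.abs(means)


def _robertson_scenario():
    return Scenario(
        name="robertson", model_name="robertson",
        xi0=[1.0, 0.0, 0.0], theta0=[1e4, 0.04, 3e7],
        known_xi=np.array([1.0, 0.0, 0.0]),
        design={"kind": "equidistant", "t0": 0.0, "T": 10.0, "n": 21},
        noise_sd=_robertson_noise_sd(), reps=100,
        estimation={"preliminary": "integral", "free_xi_prelim": True},
    )


def _goodwin_scenario(name, sigma, reps=100):
    return Scenario(
        name=name, model_name="goodwin",
        xi0=[0.0, 0.0, 0.0], theta0=[1.0, 3.0, 2.0, 1.0, 0.5],
        known_xi=np.zeros(3),
        known_theta=np.array([np.nan, 3.0, 2.0, 1.0, np.nan]),
        design={"kind": "equidistant", "t0": 0.0, "T": 80.0, "n": 50},
        noise_sd=[sigma, sigma, sigma],
        observed=np.array([True, True, False]), reps=reps,
        estimation={"preliminary": "integral"},
    )


def _build_registry():
    reg = {}
    setups = {"A": (0.5, -1.0), "B": (0.5, 1.0), "C": (1.0, -1.0),
              "D": (1.0, 1.0)}
    for tag, (xi0, th0) in setups.items():
        for n in (21, 51):
            name = f"table1_{tag}_n{n}"
            reg[name] = (lambda name=name, xi0=xi0, th0=th0, n=n:
                         _linear_scenario(name, xi0, th0, n))
    for n in (21, 51):
        name = f"table2_n{n}"
        reg[name] = (lambda name=name, n=n: Scenario(
            name=name, model_name="lotka_volterra",
            xi0=[1.0, 0.5], theta0=[0.5, 0.5, 0.5, 0.5],
            design={"kind": "equidistant", "t0": 0.0, "T": 10.0, "n": n},
            noise_sd=[0.05, 0.05], reps=500,
            estimation={}))
    for n in (250, 500, 1000):
        for k, s in ((1, 0.1), (2, 0.2), (3, 0.3)):
            name = f"table4_n{n}_s{k:02d}"
            reg[name] = (lambda name=name, n=n, s=s:
                         _linear_scenario(name, 1.0, 1.0, n, sigma=s,
                                          reps=1000, T=1.0))
    reg["table6"] = lambda: Scenario(
        name="table6", model_name="nitrogen_oxide",
        xi0=[0.0], theta0=[4.577e-06, 2.797e-04],
        design={"kind": "equidistant", "t0": 0.0, "T": 40.0, "n": 21},
        noise_sd=[0.5], reps=500,
        estimation={})
    reg["table9_a002"] = lambda: _alpha_pinene_scenario("table9_a002", 0.02)
    reg["table9_a010"] = lambda: _alpha_pinene_scenario("table9_a010", 0.10)
    reg["robertson"] = _robertson_scenario
    reg["goodwin_s001"] = lambda: _goodwin_scenario("goodwin_s001", 0.01)
    reg["goodwin_s015"] = lambda: _goodwin_scenario("goodwin_s015", 0.15)
    reg["goodwin_s025"] = lambda: _goodwin_scenario("goodwin_s025", 0.25)
    return reg


_SCENARIOS = _build_registry()


def list_scenarios():
    """Names of the built-in scenario registry."""
    return sorted(_SCENARIOS)


def load_scenario(name: str) -> Scenario:
    """Instantiate a registry scenario by name."""
    try:
        factory = _SCENARIOS[name]
    except KeyError:
        raise InputError(
            f"unknown scenario '{name}'; available: {', '.join(list_scenarios())}"
        ) from None
    scenario = factory()
    scenario.name = name
    return scenario
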