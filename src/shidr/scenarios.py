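"""Benchmark parameter schemes and packaged simulation experiments.

Three parameter schemes exercise the qualitatively distinct regimes: a
slow-turnover extinction regime (Scheme 1, mu = 0.01), a persistent regime
with weak recovery (Scheme 2, mu = 0.1), and a fast-turnover extinction
regime with strong media exposure (Scheme 3, mu = 0.3).  In every scheme
pi = mu, so the carrying level pi/mu is 1 and the default initial state
(which sums to 1) keeps N(t) identically 1.

``run_experiment`` packages the standard experiment grid: the effect of the
pulse proportion phi, the pulse period T, the delay tau, the saturation
factors rho1 = rho2, and the (phi, rho) threshold surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .diagnostics import classify_long_run, sweep_thresholds
from .model import ModelParameters, PulseSchedule, StateVector
from .solver import SolverConfig, Trajectory, integrate
from .thresholds import ThresholdReport, compute_thresholds

__all__ = [
    "Scheme",
    "SCHEME_NAMES",
    "get_scheme",
    "default_initial_state",
    "run_experiment",
    "EXPERIMENT_IDS",
    "random_valid_parameters",
]

#: shared initial condition for all packaged experiments
_INITIAL = (0.92, 0.03, 0.02, 0.02, 0.01)

_SCHEME_TABLE = {
    # name: (alpha1, alpha2, rho1, rho2, gamma1, gamma2, theta, k, mu, pi)
    "scheme1": (0.8, 0.9, 0.02, 0.03, 0.2, 0.5, 0.5, 0.5, 0.01, 0.01),
    "scheme2": (0.8, 0.9, 0.02, 0.03, 0.09, 0.08, 0.5, 0.5, 0.1, 0.1),
    "scheme3": (0.8, 0.4, 0.08, 0.1, 0.8, 0.1, 0.5, 0.7, 0.3, 0.3),
}

_SCHEME_NOTES = {
    "scheme1": "slow turnover (mu=0.01); rumor-free regime under moderate pulsing",
    "scheme2": "weak recovery (gamma1=0.09, gamma2=0.08); persistent regime",
    "scheme3": "fast turnover (mu=0.3), strong media exposure (gamma1=0.8)",
}

SCHEME_NAMES = tuple(_SCHEME_TABLE)

#: default horizons: the slow scheme needs a long window to settle
_DEFAULT_T_END = {"scheme1": 600.0, "scheme2": 200.0, "scheme3": 200.0}


@dataclass(frozen=True)
class Scheme:
    name: str
    params: ModelParameters
    initial_state: StateVector
    t_end: float
    notes: str


def default_initial_state() -> StateVector:
    """S=0.92, H=0.03, I=0.02, D=0.02, R=0.01 (sums to 1)."""
    return StateVector(*_INITIAL)


def get_scheme(name: str) -> Scheme:
    """Return one of the benchmark schemes by name (scheme1/2/3)."""
    try:
        row = _SCHEME_TABLE[name]
    except KeyError:
        raise KeyError(f"unknown scheme {name!r}; choose from {SCHEME_NAMES}") from None
    a1, a2, r1, r2, g1, g2, theta, k, mu, pi = row
    params = ModelParameters(pi=pi, mu=mu, alpha1=a1, alpha2=a2, rho1=r1,
                             rho2=r2, gamma1=g1, gamma2=g2, theta=theta, k=k)
    return Scheme(name=name, params=params, initial_state=default_initial_state(),
                  t_end=_DEFAULT_T_END[name], notes=_SCHEME_NOTES[name])


# ---------------------------------------------------------------------------
# packaged experiments

#: experiment id -> (scheme, schedule settings, varied quantity)
_EXPERIMENTS = {
    # pulse proportion phi
    "6.1a": dict(scheme="scheme1", T=2.0, tau=1.0, phis=(0.2, 0.5)),
    "6.1b": dict(scheme="scheme2", T=2.0, tau=1.0, phis=(0.2, 0.3)),
    # pulse period T
    "6.2a": dict(scheme="scheme1", phi=0.3, tau=1.0, Ts=(1.0, 3.0)),
    "6.2b": dict(scheme="scheme2", phi=0.3, tau=1.0, Ts=(2.0, 4.0)),
    # delay tau
    "6.3a": dict(scheme="scheme3", phi=0.3, T=2.0, taus=(2.0, 4.0, 6.0, 8.0, 10.0)),
    "6.3b": dict(scheme="scheme2", phi=0.3, T=2.0, taus=(0.5, 1.0, 1.5)),
    # saturation factors rho1 = rho2 at the 6.1a/phi=0.2 base
    "6.4": dict(scheme="scheme1", phi=0.2, T=2.0, tau=1.0,
                rhos=(0.0, 0.05, 0.2, 0.4, 0.6, 0.8)),
    # (phi, rho) threshold surface at the scheme1 base
    "6.5": dict(scheme="scheme1", T=2.0, tau=1.0,
                phi_grid=tuple(np.linspace(0.0, 0.4, 9)),
                rho_grid=tuple(np.linspace(0.0, 0.4, 9))),
}

EXPERIMENT_IDS = tuple(_EXPERIMENTS)


@dataclass(frozen=True)
class ExperimentRun:
    """One simulated setting inside an experiment."""

    label: str
    params: ModelParameters
    schedule: PulseSchedule
    thresholds: ThresholdReport
    trajectory: Trajectory
    report: "object"  # LongRunReport


def _simulate(params: ModelParameters, schedule: PulseSchedule,
              initial: StateVector, t_end: float, dt_target: float):
    config = SolverConfig(dt_target=dt_target, t_end=t_end)
    traj = integrate(params, schedule, history=initial.as_tuple(), config=config)
    report = classify_long_run(traj, schedule, params=params)
    return traj, report


def run_experiment(experiment_id: str, overrides: Optional[dict] = None,
                   dt_target: float = 0.01) -> dict:
    """Run one packaged experiment and return its structured results.

    Returns a dict with keys ``id``, ``scheme`` and ``runs`` (a list of
    ``ExperimentRun``), or for the surface experiment ``6.5`` the grids and
    the two threshold matrices.  ``overrides`` may replace scalar settings
    (``t_end``, ``phi``, ``T``, ``tau``, ``dt_target``); unknown keys are
    rejected.
    """
    if experiment_id not in _EXPERIMENTS:
        raise KeyError(f"unknown experiment {experiment_id!r}; "
                       f"choose from {EXPERIMENT_IDS}")
    defn = dict(_EXPERIMENTS[experiment_id])
    scheme = get_scheme(defn.pop("scheme"))
    settings = dict(defn)
    t_end = scheme.t_end
    if overrides:
        allowed = {"t_end", "phi", "T", "tau", "dt_target"}
        bad = set(overrides) - allowed
        if bad:
            raise KeyError(f"invalid override keys: {sorted(bad)}")
        t_end = float(overrides.get("t_end", t_end))
        dt_target = float(overrides.get("dt_target", dt_target))
        for key in ("phi", "T", "tau"):
            if key in overrides and key in settings:
                settings[key] = float(overrides[key])

    if experiment_id == "6.5":
        r1, r2 = sweep_thresholds(scheme.params, settings["phi_grid"],
                                  settings["rho_grid"], settings["T"],
                                  settings["tau"])
        return {"id": experiment_id, "scheme": scheme.name,
                "phi_grid": np.asarray(settings["phi_grid"]),
                "rho_grid": np.asarray(settings["rho_grid"]),
                "R1": r1, "R2": r2}

    runs = []
    if "phis" in settings:
        grid = [("phi=%g" % v,
                 scheme.params,
                 PulseSchedule(phi=v, T=settings["T"], tau=settings["tau"]))
                for v in settings["phis"]]
    elif "Ts" in settings:
        grid = [("T=%g" % v,
                 scheme.params,
                 PulseSchedule(phi=settings["phi"], T=v, tau=settings["tau"]))
                for v in settings["Ts"]]
    elif "taus" in settings:
        grid = [("tau=%g" % v,
                 scheme.params,
                 PulseSchedule(phi=settings["phi"], T=settings["T"], tau=v))
                for v in settings["taus"]]
    else:  # rho sweep
        grid = [("rho=%g" % v,
                 replace(scheme.params, rho1=v, rho2=v),
                 PulseSchedule(phi=settings["phi"], T=settings["T"],
                               tau=settings["tau"]))
                for v in settings["rhos"]]

    for label, params, schedule in grid:
        traj, report = _simulate(params, schedule, scheme.initial_state,
                                 t_end, dt_target)
        runs.append(ExperimentRun(label=label, params=params, schedule=schedule,
                                  thresholds=compute_thresholds(params, schedule),
                                  trajectory=traj, report=report))
    return {"id": experiment_id, "scheme": scheme.name, "runs": runs}


# ---------------------------------------------------------------------------
# random parameter generator for property tests

_DEFAULT_RANGES = {
    "pi": (0.01, 0.5), "mu": (0.01, 0.5),
    "alpha1": (0.05, 1.5), "alpha2": (0.05, 1.5),
    "rho1": (0.0, 1.0), "rho2": (0.0, 1.0),
    "gamma1": (0.01, 1.0), "gamma2": (0.01, 1.0),
    "theta": (0.0, 1.0), "k": (0.0, 1.0),
    "phi": (0.0, 0.95), "T": (0.5, 5.0), "tau": (0.0, 3.0),
}


def random_valid_parameters(seed: int, ranges: Optional[dict] = None
                            ) -> tuple[ModelParameters, PulseSchedule]:
    """Draw one valid (parameters, schedule) pair, reproducibly by seed."""
    rng = np.random.default_rng(seed)
    r = dict(_DEFAULT_RANGES)
    if ranges:
        bad = set(ranges) - set(r)
        if bad:
            raise KeyError(f"unknown range keys: {sorted(bad)}")
        r.update(ranges)
    draw = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in r.items()}
    params = ModelParameters(**{k: draw[k] for k in
                                ("pi", "mu", "alpha1", "alpha2", "rho1", "rho2",
                                 "gamma1", "gamma2", "theta", "k")})
    schedule = PulseSchedule(phi=draw["phi"], T=draw["T"], tau=draw["tau"])
    return params, schedule
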