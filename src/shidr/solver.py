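"""Fixed-step method-of-steps integrator with periodic proportional impulses.

The delay system is advanced with classical 4th-order Runge-Kutta on a
uniform grid whose step divides both the delay tau and the pulse period T
(``resolve_step``).  Delay lookups at grid nodes are then exact; the
delayed values needed at Runge-Kutta half-steps are obtained by cubic
Hermite interpolation of stored (state, derivative) node pairs, which
preserves the 4th-order accuracy of the scheme.  Impulses fire exactly at
the nodes t = nT, n >= 1, where both the left limit (pre-pulse) and the
right limit (post-pulse) are recorded; the solution is continued from the
right limit.  Grid alignment also guarantees that every discontinuity of a
derivative (the pulse instants and their tau-translates) is a grid node, so
every Runge-Kutta step works on a smooth segment and no event handling is
needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (COMPARTMENTS, ModelParameters, PulseSchedule,
                    apply_impulse, make_rhs)

__all__ = [
    "IntegrationError",
    "SolverConfig",
    "HistoryGrid",
    "Trajectory",
    "resolve_step",
    "integrate",
]


class IntegrationError(RuntimeError):
    """Raised when the integration produces invalid states."""


def _as_fraction(x: float) -> Fraction:
    # str() gives the shortest decimal that round-trips, so decimal inputs
    # like 0.1 or 1.5 become exact rationals (1/10, 3/2).
    return Fraction(str(float(x)))


def resolve_step(tau: float, T: float, t_end: float, dt_target: float) -> float:
    """Largest dt <= dt_target such that T/dt (and tau/dt when tau > 0) are
    integers, so impulses and delay lookups land exactly on grid nodes.

    tau and T are interpreted as the decimal rationals they were written
    as.  Raises if they are incommensurable beyond a reasonable rational
    tolerance (pass an explicit dt by adjusting tau/T in that case).
    """
    if dt_target <= 0:
        raise ValueError("dt_target must be > 0")
    if T <= 0 or tau < 0 or t_end <= 0:
        raise ValueError("require T > 0, tau >= 0, t_end > 0")
    Tf = _as_fraction(T)
    if tau == 0:
        g = Tf
    else:
        tf = _as_fraction(tau)
        g = Fraction(math.gcd(Tf.numerator * tf.denominator,
                              tf.numerator * Tf.denominator),
                     Tf.denominator * tf.denominator)
    if g < _as_fraction(dt_target) / 1_000_000:
        raise ValueError(
            f"tau={tau} and T={T} are incommensurable beyond rational "
            "tolerance; choose commensurate decimal values")
    n = math.ceil(g / _as_fraction(dt_target))
    return float(g / n)


@dataclass(frozen=True)
class SolverConfig:
    """Integration request: target step, horizon, and guard tolerances."""

    dt_target: float = 0.01
    t_end: float = 100.0
    #: components below -neg_tol abort the run (silent clipping would hide
    #: integrator misconfiguration)
    neg_tol: float = 1e-9
    enforce_nonneg: bool = True
    #: labels exempt from the guard.  H tracks the delayed-incidence
    #: integral only when the initial data are consistent with the history;
    #: with point initial values it may legitimately dip below zero.
    nonneg_exempt: tuple[str, ...] = ("H",)

    def __post_init__(self) -> None:
        if self.dt_target <= 0 or self.t_end <= 0:
            raise ValueError("dt_target and t_end must be > 0")


@dataclass(frozen=True)
class HistoryGrid:
    """State samples on [-tau, 0] at uniform spacing dt, with derivative
    samples of the history function for dense (Hermite) evaluation."""

    values: np.ndarray   # (m+1, d), row 0 at t = -tau, row m at t = 0
    derivs: np.ndarray   # (m+1, d) derivatives of the history function
    tau: float
    dt: float

    def __post_init__(self) -> None:
        if self.values.shape != self.derivs.shape:
            raise ValueError("values and derivs must have the same shape")
        if np.any(self.values < 0):
            raise ValueError("history values must be non-negative")

    @classmethod
    def constant(cls, y0: Sequence[float], tau: float, dt: float) -> "HistoryGrid":
        """Constant history equal to the t = 0 state (derivative zero)."""
        y = np.asarray(y0, dtype=float).reshape(1, -1)
        m = round(tau / dt) if tau > 0 else 0
        vals = np.repeat(y, m + 1, axis=0)
        return cls(values=vals, derivs=np.zeros_like(vals), tau=tau, dt=dt)

    @classmethod
    def from_function(cls, fn: Callable[[float], Sequence[float]],
                      tau: float, dt: float) -> "HistoryGrid":
        """Sample a history function theta -> state on the grid; derivatives
        by central finite differences of the samples."""
        m = round(tau / dt) if tau > 0 else 0
        ts = np.array([-tau + i * dt for i in range(m + 1)])
        ts[-1] = 0.0
        vals = np.array([fn(t) for t in ts], dtype=float)
        if m == 0:
            derivs = np.zeros_like(vals)
        else:
            derivs = np.gradient(vals, dt, axis=0)
        return cls(values=vals, derivs=derivs, tau=tau, dt=dt)


@dataclass
class Trajectory:
    """Solution on the uniform grid, with both limits at impulse nodes.

    ``states`` holds the right limits (the values the solution continues
    from); ``states_left`` differs from it only at impulse nodes, where it
    holds the pre-pulse value.  ``derivs``/``derivs_left`` are the matching
    vector-field evaluations, stored for dense output.
    """

    times: np.ndarray           # (n,)
    states: np.ndarray          # (n, d) right limits
    states_left: np.ndarray     # (n, d) left limits
    derivs: np.ndarray          # (n, d)
    derivs_left: np.ndarray     # (n, d)
    impulse_indices: np.ndarray  # indices into times of impulse nodes
    dt: float
    labels: tuple[str, ...] = COMPARTMENTS
    schedule: Optional[PulseSchedule] = None

    def __len__(self) -> int:
        return len(self.times)

    @property
    def impulse_times(self) -> np.ndarray:
        return self.times[self.impulse_indices]

    def column(self, label: str) -> np.ndarray:
        return self.states[:, self.labels.index(label)]

    @property
    def N(self) -> np.ndarray:
        """Total density on the grid (right limits; impulses conserve N)."""
        return self.states.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per regular node, two rows (left limit
        then right limit) per impulse node.  Columns are t, the components,
        N, and event (0 regular, 1 impulse-left, 2 impulse-right)."""
        imp = set(self.impulse_indices.tolist())
        rows = []
        for i, t in enumerate(self.times):
            if i in imp:
                rows.append((t, *self.states_left[i], self.states_left[i].sum(), 1))
                rows.append((t, *self.states[i], self.states[i].sum(), 2))
            else:
                rows.append((t, *self.states[i], self.states[i].sum(), 0))
        cols = ["t", *self.labels, "N", "event"]
        frame = pd.DataFrame(rows, columns=cols)
        frame["event"] = frame["event"].astype(int)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_state(y: tuple, t: float, neg_tol: float, enforce: bool,
                 checked: tuple[int, ...]) -> None:
    for v in y:
        if not math.isfinite(v):
            raise IntegrationError(f"non-finite state at t={t:.6g}: {y}")
    if enforce:
        for i in checked:
            if y[i] < -neg_tol:
                raise IntegrationError(
                    f"component {y[i]:.3e} < -{neg_tol:.0e} at t={t:.6g}; "
                    "reduce the step size")


def integrate(params: ModelParameters,
              schedule: PulseSchedule,
              history=None,
              config: Optional[SolverConfig] = None,
              *,
              rhs: Optional[Callable] = None,
              impulse_map: Optional[Callable] = None,
              labels: tuple[str, ...] = COMPARTMENTS) -> Trajectory:
    """Integrate the pulsed delay system by the method of steps.

    Parameters
    ----------
    params, schedule
        Model constants and the pulse/delay schedule.
    history
        Initial data on [-tau, 0]: a state sequence (constant history equal
        to the t = 0 value), a callable theta -> state, or a prebuilt
        ``HistoryGrid`` (its dt must match the resolved step).
    config
        Step-size request and horizon; defaults to ``SolverConfig()``.
    rhs, impulse_map
        Override the vector field ``f(now, delayed) -> tuple`` and the jump
        ``g(state, phi) -> state``; defaults are the full SHIDR model.  This
        is how the scalar comparison system dx/dt = pi - mu x with
        x(nT+) = (1-phi) x(nT) is integrated for oracle checks.
    """
    config = config or SolverConfig()
    dt = resolve_step(schedule.tau, schedule.T, config.t_end, config.dt_target)
    m = round(schedule.tau / dt) if schedule.tau > 0 else 0
    n_steps = math.ceil(config.t_end / dt - 1e-9)
    spp = round(schedule.T / dt)  # steps per pulse period, exact by construction

    if rhs is None:
        rhs = make_rhs(params, schedule)
    if impulse_map is None:
        impulse_map = apply_impulse

    if history is None:
        raise ValueError("history is required (state sequence, callable, or HistoryGrid)")
    if isinstance(history, HistoryGrid):
        if m and (abs(history.dt - dt) > 1e-12 or history.values.shape[0] != m + 1):
            raise ValueError(
                f"HistoryGrid spacing {history.dt} does not match resolved dt {dt}")
        hist = history
    elif callable(history):
        hist = HistoryGrid.from_function(history, schedule.tau, dt)
    else:
        hist = HistoryGrid.constant(history, schedule.tau, dt)

    d = hist.values.shape[1]
    eff_labels = labels if d == len(labels) else tuple(f"x{i}" for i in range(d))
    checked = tuple(i for i, lab in enumerate(eff_labels)
                    if lab not in config.nonneg_exempt)
    total = m + n_steps + 1
    # right-limit and left-limit node storage as python lists of tuples
    Y: list = [tuple(map(float, row)) for row in hist.values]
    Yl: list = list(Y)
    F: list = [tuple(map(float, row)) for row in hist.derivs]
    Fl: list = list(F)
    # replace the derivative at t=0 with the model's own (the history slope
    # need not match the vector field there; the solution is only C^0 at 0)
    F[m] = rhs(Y[m], Y[0] if m else Y[m])

    half = 0.5 * dt
    sixth = dt / 6.0
    eighth = dt / 8.0
    impulse_nodes: list[int] = []
    zeros = (0.0,) * d

    for step in range(n_steps):
        i = m + step
        t = step * dt
        y = Y[i]
        if m:
            j = i - m
            d0 = Y[j]
            d1 = Yl[j + 1]
            f0, f1 = F[j], Fl[j + 1]
            # cubic Hermite at the segment midpoint
            dmid = tuple(0.5 * (a + b) + eighth * (fa - fb)
                         for a, b, fa, fb in zip(d0, d1, f0, f1))
            k1 = rhs(y, d0)
            y2 = tuple(a + half * b for a, b in zip(y, k1))
            k2 = rhs(y2, dmid)
            y3 = tuple(a + half * b for a, b in zip(y, k2))
            k3 = rhs(y3, dmid)
            y4 = tuple(a + dt * b for a, b in zip(y, k3))
            k4 = rhs(y4, d1)
        else:
            # no delay: ordinary RK4, delayed argument is the stage state
            k1 = rhs(y, y)
            y2 = tuple(a + half * b for a, b in zip(y, k1))
            k2 = rhs(y2, y2)
            y3 = tuple(a + half * b for a, b in zip(y, k2))
            k3 = rhs(y3, y3)
            y4 = tuple(a + dt * b for a, b in zip(y, k3))
            k4 = rhs(y4, y4)
        y_next = tuple(a + sixth * (p + 2.0 * (q + r) + s)
                       for a, p, q, r, s in zip(y, k1, k2, k3, k4))
        t_next = t + dt
        _check_state(y_next, t_next, config.neg_tol, config.enforce_nonneg,
                     checked)

        i_next = i + 1
        Yl.append(y_next)
        dl_next = Yl[i_next - m] if m else y_next
        Fl.append(rhs(y_next, dl_next))
        if (step + 1) % spp == 0:
            # impulse at t = nT: continue from the right limit
            y_right = impulse_map(y_next, schedule.phi)
            impulse_nodes.append(step + 1)
            Y.append(tuple(y_right))
            dr_next = Y[i_next - m] if m else tuple(y_right)
            F.append(rhs(tuple(y_right), dr_next))
        else:
            Y.append(y_next)
            # the right derivative differs from the left one when the
            # delayed argument t - tau is itself a pulse instant (the
            # vector field jumps there): use the delayed right limit
            g_delayed = step + 1 - m
            if m and g_delayed >= spp and g_delayed % spp == 0:
                F.append(rhs(y_next, Y[i_next - m]))
            else:
                F.append(Fl[i_next])
    assert len(Y) == total

    times = np.arange(n_steps + 1) * dt
    return Trajectory(
        times=times,
        states=np.array(Y[m:], dtype=float),
        states_left=np.array(Yl[m:], dtype=float),
        derivs=np.array(F[m:], dtype=float),
        derivs_left=np.array(Fl[m:], dtype=float),
        impulse_indices=np.array(impulse_nodes, dtype=int),
        dt=dt,
        labels=eff_labels,
        schedule=schedule,
    )
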