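"""Long-run classification and threshold-surface sweeps.

Extinction means the spreading classes I + D vanish and S settles onto the
rumor-free periodic solution; permanence means lim inf (I + D) stays above
a positive constant.  Both are judged from the tail of a simulated
trajectory over whole pulse periods, after discarding a burn-in that
absorbs the transient from the (arbitrary) constant history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict
from typing import Optional, Sequence

import numpy as np

from .model import ModelParameters, PulseSchedule
from .solver import Trajectory
from .thresholds import (basic_reproduction_R1, basic_reproduction_R2,
                         vaccinated_fixed_point_S_star)

__all__ = [
    "LongRunReport",
    "classify_long_run",
    "sup_distance_to_rumor_free",
    "sweep_thresholds",
    "peak_infected",
]

VERDICT_EXTINCT = "extinct"
VERDICT_PERSISTENT = "persistent"
VERDICT_UNDETERMINED = "undetermined"

#: fraction of the horizon discarded before windowed statistics
BURN_IN_FRACTION = 0.5


@dataclass(frozen=True)
class LongRunReport:
    """Windowed tail statistics and the resulting verdict."""

    verdict: str
    sup_ID_last_window: float
    inf_ID_last_window: float
    sup_S_distance: float  # nan when no reference comparison was requested
    windows_used: int

    def to_dict(self) -> dict:
        return asdict(self)


def _window_slice(traj: Trajectory, schedule: PulseSchedule,
                  n_windows: int) -> slice:
    """Grid slice covering the final ``n_windows`` whole pulse periods,
    required to start after the burn-in."""
    spp = round(schedule.T / traj.dt)
    n = len(traj.times) - 1
    need = n_windows * spp
    start = n - need
    if start < 0 or traj.times[start] < BURN_IN_FRACTION * traj.times[-1] - 1e-9:
        raise ValueError(
            f"horizon too short: need {n_windows} pulse periods after a "
            f"{BURN_IN_FRACTION:.0%} burn-in (t_end={traj.times[-1]:.6g}, T={schedule.T})")
    return slice(start, n + 1)


def classify_long_run(traj: Trajectory,
                      schedule: PulseSchedule,
                      tol_extinct: float = 1e-6,
                      tol_persist: float = 1e-4,
                      n_windows: int = 5,
                      params: Optional[ModelParameters] = None) -> LongRunReport:
    """Classify the tail of a trajectory as extinct / persistent.

    Over the final ``n_windows`` pulse periods, F(t) = I(t) + D(t) is
    extinct if its maximum stays below ``tol_extinct`` and persistent if
    its minimum stays above ``tol_persist``; anything in between (or a mix)
    is undetermined.  When ``params`` is given, the report also carries the
    sup distance of S to the rumor-free periodic solution over the window.
    """
    sl = _window_slice(traj, schedule, n_windows)
    i_col = traj.labels.index("I")
    d_col = traj.labels.index("D")
    F = traj.states[sl, i_col] + traj.states[sl, d_col]
    sup_f, inf_f = float(F.max()), float(F.min())
    if sup_f < tol_extinct:
        verdict = VERDICT_EXTINCT
    elif inf_f > tol_persist:
        verdict = VERDICT_PERSISTENT
    else:
        verdict = VERDICT_UNDETERMINED
    sup_s = math.nan
    if params is not None:
        sup_s = sup_distance_to_rumor_free(traj, params, schedule, n_windows)
    return LongRunReport(verdict=verdict, sup_ID_last_window=sup_f,
                         inf_ID_last_window=inf_f, sup_S_distance=sup_s,
                         windows_used=n_windows)


def sup_distance_to_rumor_free(traj: Trajectory, params: ModelParameters,
                               schedule: PulseSchedule,
                               n_windows: int = 1) -> float:
    """sup |S(t) - S~e(t)| over the final ``n_windows`` pulse periods.

    The reference is phase-aligned on the impulse-epoch grid: at a pulse
    node the trajectory's right limit is compared with S* and its left
    limit with the end-of-period value of S~e, avoiding off-by-one-node
    artifacts.
    """
    sl = _window_slice(traj, schedule, n_windows)
    spp = round(schedule.T / traj.dt)
    idx = np.arange(sl.start, sl.stop)
    s_col = traj.labels.index("S") if "S" in traj.labels else 0
    mu, pm = params.mu, params.pi / params.mu
    s_star = vaccinated_fixed_point_S_star(params, schedule)
    phase = (idx % spp) * traj.dt
    ref_right = pm + (s_star - pm) * np.exp(-mu * phase)
    err = np.abs(traj.states[sl, s_col] - ref_right).max()
    # left limits at pulse nodes against the pre-pulse end-of-period value
    pulse = idx[(idx % spp == 0) & (idx > 0)]
    if pulse.size:
        ref_left = pm + (s_star - pm) * math.exp(-mu * schedule.T)
        err = max(err, np.abs(traj.states_left[pulse, s_col] - ref_left).max())
    return float(err)


def sweep_thresholds(params: ModelParameters,
                     phi_grid: Sequence[float],
                     rho_grid: Sequence[float],
                     T: float, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """R1 and R2 matrices over a (phi, rho) grid with rho1 = rho2 = rho.

    Returns ``(R1, R2)`` of shape (len(phi_grid), len(rho_grid)); both are
    non-increasing along every row and column (stronger saturation and
    larger pulses both suppress spreading).
    """
    r1 = np.empty((len(phi_grid), len(rho_grid)))
    r2 = np.empty_like(r1)
    for i, phi in enumerate(phi_grid):
        schedule = PulseSchedule(phi=float(phi), T=T, tau=tau)
        for j, rho in enumerate(rho_grid):
            p = replace(params, rho1=float(rho), rho2=float(rho))
            r1[i, j] = basic_reproduction_R1(p, schedule)
            r2[i, j] = basic_reproduction_R2(p, schedule)
    return r1, r2


def peak_infected(traj: Trajectory) -> tuple[float, float]:
    """Maximum of I over the grid and the time of its first attainment."""
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    i_col = traj.labels.index("I")
    col = traj.states[:, i_col]
    k = int(np.argmax(col))
    return float(col[k]), float(traj.times[k])
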