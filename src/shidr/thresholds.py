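"""Closed-form threshold quantities for the pulsed SHIDR model.

Between impulses the pulsed susceptible class, in the absence of rumor,
relaxes toward pi/mu; each pulse multiplies it by (1-phi).  The resulting
T-periodic rumor-free solution S~e(t) starts each period at the fixed point
S* and its supremum is the depletion level B.  Two reproduction numbers
bracket the true threshold:

    R1 = alpha e^{-mu tau} B / ((1 + rho B) sigma)          (extinction)
    R2 = (alpha' e^{-mu tau} / sigma' - rho') S*            (permanence)

with alpha = max(alpha1, alpha2), rho = min(rho1, rho2),
sigma = min(theta*gamma1 + mu, gamma2 + mu) and the primed constants the
opposite extremes.  R1 < 1 implies global attraction to the rumor-free
periodic solution; R2 > 1 implies the rumor is permanent (I + D stays
bounded away from zero).  The gap between the two reflects the max/min
bounding used in the comparison arguments; R1 < 1 and R2 > 1 can never
hold together.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional

from .model import ModelParameters, PulseSchedule

__all__ = [
    "ThresholdReport",
    "depletion_level_B",
    "vaccinated_fixed_point_S_star",
    "rumor_free_solution",
    "basic_reproduction_R1",
    "basic_reproduction_R2",
    "critical_pulse_rate_phi_star",
    "permanence_floor",
    "compute_thresholds",
    "PHI_STAR_ROOT",
    "PHI_STAR_NOT_NEEDED",
    "PHI_STAR_UNATTAINABLE",
]

# status flags for the critical pulse rate
PHI_STAR_ROOT = "root"                  # R1(phi*) = 1 found in (0, 1)
PHI_STAR_NOT_NEEDED = "not_needed"      # R1(0) <= 1 already
PHI_STAR_UNATTAINABLE = "unattainable"  # R1 > 1 for every phi < 1


def _extremal_R1(params: ModelParameters) -> tuple[float, float, float]:
    alpha = max(params.alpha1, params.alpha2)
    rho = min(params.rho1, params.rho2)
    sigma = min(params.theta * params.gamma1 + params.mu,
                params.gamma2 + params.mu)
    return alpha, rho, sigma


def _extremal_R2(params: ModelParameters) -> tuple[float, float, float]:
    alpha = min(params.alpha1, params.alpha2)
    rho = max(params.rho1, params.rho2)
    sigma = max(params.theta * params.gamma1 + params.mu,
                params.gamma2 + params.mu)
    return alpha, rho, sigma


def depletion_level_B(params: ModelParameters, schedule: PulseSchedule) -> float:
    """Supremum of the rumor-free periodic susceptible level:
    B = pi (1 - e^{-mu T}) / (mu (1 - (1-phi) e^{-mu T})).  With phi = 0 the
    pulses are inert and B reduces to the carrying level pi/mu."""
    mu, T, phi = params.mu, schedule.T, schedule.phi
    E = math.exp(-mu * T)
    return params.pi * (1.0 - E) / (mu * (1.0 - (1.0 - phi) * E))


def vaccinated_fixed_point_S_star(params: ModelParameters,
                                  schedule: PulseSchedule) -> float:
    """Post-pulse fixed point S* = (1-phi) B: the unique value with
    (1-phi) * (pi/mu + (S* - pi/mu) e^{-mu T}) = S*."""
    return (1.0 - schedule.phi) * depletion_level_B(params, schedule)


def rumor_free_solution(t: float, params: ModelParameters,
                        schedule: PulseSchedule) -> float:
    """The T-periodic rumor-free susceptible trajectory
    S~e(t) = pi/mu + (S* - pi/mu) e^{-mu (t - nT)} on nT < t <= (n+1)T.

    At t = nT exactly, returns the right limit S* (the post-pulse value).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    mu, T = params.mu, schedule.T
    s_star = vaccinated_fixed_point_S_star(params, schedule)
    pm = params.pi / mu
    phase = math.fmod(t, T)
    return pm + (s_star - pm) * math.exp(-mu * phase)


def basic_reproduction_R1(params: ModelParameters,
                          schedule: PulseSchedule) -> float:
    """Extinction threshold R1 = alpha e^{-mu tau} B / ((1 + rho B) sigma).

    Strictly decreasing in phi (larger pulses deplete B) and in tau and
    rho.  R1 < 1 guarantees global attraction to the rumor-free periodic
    solution.
    """
    alpha, rho, sigma = _extremal_R1(params)
    B = depletion_level_B(params, schedule)
    return alpha * math.exp(-params.mu * schedule.tau) * B / ((1.0 + rho * B) * sigma)


def basic_reproduction_R2(params: ModelParameters,
                          schedule: PulseSchedule) -> float:
    """Permanence threshold R2 = (alpha' e^{-mu tau}/sigma' - rho') S*.

    R2 > 1 is algebraically equivalent to the saturated-incidence condition
    alpha' e^{-mu tau} S* / ((1 + rho' S*) sigma') > 1 and guarantees
    lim inf (I + D) > 0.
    """
    alpha, rho, sigma = _extremal_R2(params)
    s_star = vaccinated_fixed_point_S_star(params, schedule)
    return (alpha * math.exp(-params.mu * schedule.tau) / sigma - rho) * s_star


def critical_pulse_rate_phi_star(params: ModelParameters, T: float,
                                 tau: float, *, tol: float = 1e-10
                                 ) -> tuple[float, str]:
    """Critical pulse proportion phi* with R1(phi*) = 1.

    Returns ``(value, status)``: status ``"root"`` with phi* in (0, 1) when
    R1 crosses 1 on the interval (any phi > phi* then gives R1 < 1, by the
    strict monotonicity of R1 in phi); ``"not_needed"`` with value 0.0 when
    R1(0) <= 1 already; ``"unattainable"`` with value nan when R1 > 1 for
    every phi < 1.  Bisection until the residual |R1 - 1| <= tol;
    monotonicity makes the bracket safe.
    """
    def r1(phi: float) -> float:
        return basic_reproduction_R1(params, PulseSchedule(phi=phi, T=T, tau=tau))

    lo, hi = 0.0, 1.0 - 1e-12
    if r1(lo) <= 1.0:
        return 0.0, PHI_STAR_NOT_NEEDED
    if r1(hi) > 1.0:
        return math.nan, PHI_STAR_UNATTAINABLE
    mid = 0.5 * (lo + hi)
    while hi - lo > 1e-15:
        mid = 0.5 * (lo + hi)
        resid = r1(mid) - 1.0
        if abs(resid) <= tol:
            break
        if resid > 0.0:
            lo = mid
        else:
            hi = mid
    return mid, PHI_STAR_ROOT


def permanence_floor(params: ModelParameters,
                     schedule: PulseSchedule) -> tuple[Optional[float], Optional[float]]:
    """Analytic lower floor for I + D when the rumor is permanent.

    Returns ``(F_star, P)`` with F* = (mu/alpha)(R2 - 1), alpha the larger
    transmission rate, and P = min(F*/2, F* e^{-sigma' tau}).  Both are None
    when R2 <= 1 (no permanence guarantee).  P is a sufficient bound from
    the permanence argument, not a tight one.
    """
    r2 = basic_reproduction_R2(params, schedule)
    if r2 <= 1.0:
        return None, None
    alpha = max(params.alpha1, params.alpha2)
    _, _, sigma_p = _extremal_R2(params)
    f_star = params.mu / alpha * (r2 - 1.0)
    p = min(0.5 * f_star, f_star * math.exp(-sigma_p * schedule.tau))
    return f_star, p


@dataclass(frozen=True)
class ThresholdReport:
    """All closed-form threshold quantities for one (params, schedule)."""

    R1: float
    R2: float
    phi_star: Optional[float]
    phi_star_status: str
    B: float
    S_star: float
    alpha_max: float
    rho_min: float
    sigma_min: float
    alpha_min: float
    rho_max: float
    sigma_max: float
    F_star: Optional[float]
    P_floor: Optional[float]

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        if d["phi_star"] is not None and math.isnan(d["phi_star"]):
            d["phi_star"] = None
        return json.dumps(d, **kwargs)


def compute_thresholds(params: ModelParameters,
                       schedule: PulseSchedule) -> ThresholdReport:
    """Evaluate every threshold quantity for one parameter set."""
    alpha_max, rho_min, sigma_min = _extremal_R1(params)
    alpha_min, rho_max, sigma_max = _extremal_R2(params)
    phi_star, status = critical_pulse_rate_phi_star(params, schedule.T, schedule.tau)
    f_star, p_floor = permanence_floor(params, schedule)
    return ThresholdReport(
        R1=basic_reproduction_R1(params, schedule),
        R2=basic_reproduction_R2(params, schedule),
        phi_star=phi_star,
        phi_star_status=status,
        B=depletion_level_B(params, schedule),
        S_star=vaccinated_fixed_point_S_star(params, schedule),
        alpha_max=alpha_max, rho_min=rho_min, sigma_min=sigma_min,
        alpha_min=alpha_min, rho_max=rho_max, sigma_max=sigma_max,
        F_star=f_star, P_floor=p_floor,
    )
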