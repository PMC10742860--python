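"""Core SHIDR model: parameters, state, vector field, and the pulse map.

The model divides an online population into susceptible (S), hesitant (H),
infected/rumor-spreading (I), refuting (D) and recovered (R) classes.
Susceptibles meeting spreaders or refuters become hesitant; after a fixed
deliberation delay tau (discounted by the survival factor e^{-mu*tau}) a
fraction k of the resolving hesitants start spreading the rumor while the
rest refute it.  Contacts follow a saturated incidence alpha*S*X/(1+rho*S):
the psychological factor rho caps the per-capita contact rate as S grows.
Periodic "vaccination" (popular-science education) instantaneously moves a
fraction phi of susceptibles to the recovered class every T time units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ModelParameters",
    "PulseSchedule",
    "StateVector",
    "COMPARTMENTS",
    "incidence_infected",
    "incidence_refuting",
    "rhs_full",
    "make_rhs",
    "apply_impulse",
]

COMPARTMENTS = ("S", "H", "I", "D", "R")


@dataclass(frozen=True)
class ModelParameters:
    """The ten rate/probability constants of the SHIDR model.

    pi      inflow rate of susceptibles (density/time)
    mu      rate of leaving the network (1/time), > 0
    alpha1  susceptible-infected contact transmission rate
    alpha2  susceptible-refuting contact transmission rate
    rho1    psychological saturation factor for rumor contact
    rho2    psychological saturation factor for truth contact
    gamma1  infected -> (refuting/recovered) exit rate
    gamma2  refuting -> recovered exit rate
    theta   fraction of exiting infected that recover directly, in [0, 1]
    k       fraction of resolving hesitants that become infected, in [0, 1]

    gamma1 and gamma2 are treated strictly as rates (no cap at 1): the
    differential equations, not the parameter gloss, define the dynamics.
    """

    pi: float
    mu: float
    alpha1: float
    alpha2: float
    rho1: float
    rho2: float
    gamma1: float
    gamma2: float
    theta: float
    k: float

    def __post_init__(self) -> None:
        for name in ("pi", "mu", "alpha1", "alpha2", "rho1", "rho2",
                     "gamma1", "gamma2", "theta", "k"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.mu <= 0:
            raise ValueError(f"mu must be > 0, got {self.mu!r}")
        for name in ("theta", "k"):
            v = getattr(self, name)
            if v > 1:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")


@dataclass(frozen=True)
class PulseSchedule:
    """Pulse-vaccination control: proportion phi in [0,1), period T > 0,
    and the hesitation delay tau >= 0.  Impulses fire at t = nT, n >= 1."""

    phi: float
    T: float
    tau: float

    def __post_init__(self) -> None:
        if not (0 <= self.phi < 1):
            raise ValueError(f"phi must be in [0, 1), got {self.phi!r}")
        if not (self.T > 0):
            raise ValueError(f"T must be > 0, got {self.T!r}")
        if not (self.tau >= 0):
            raise ValueError(f"tau must be >= 0, got {self.tau!r}")


@dataclass(frozen=True)
class StateVector:
    """Compartment densities at one instant; N = S+H+I+D+R."""

    S: float
    H: float
    I: float
    D: float
    R: float

    #: constructor tolerance for slightly-negative solver output
    _NEG_TOL: float = field(default=1e-9, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in COMPARTMENTS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < -self._NEG_TOL:
                raise ValueError(f"component {name} must be >= 0, got {v!r}")

    @property
    def N(self) -> float:
        return self.S + self.H + self.I + self.D + self.R

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.S, self.H, self.I, self.D, self.R)

    @classmethod
    def from_sequence(cls, y) -> "StateVector":
        return cls(*map(float, y))


def incidence_infected(S: float, I: float, params: ModelParameters) -> float:
    """Saturated rumor incidence alpha1*S*I/(1+rho1*S)."""
    if S < 0 or I < 0:
        raise ValueError("incidence requires S >= 0 and I >= 0")
    return params.alpha1 * S * I / (1.0 + params.rho1 * S)


def incidence_refuting(S: float, D: float, params: ModelParameters) -> float:
    """Saturated truth incidence alpha2*S*D/(1+rho2*S)."""
    if S < 0 or D < 0:
        raise ValueError("incidence requires S >= 0 and D >= 0")
    return params.alpha2 * S * D / (1.0 + params.rho2 * S)


def make_rhs(params: ModelParameters, schedule: PulseSchedule):
    """Compile the continuous part of the vector field into a closure
    ``f(now, delayed) -> (dS, dH, dI, dD, dR)`` over plain floats.

    ``now`` and ``delayed`` are 5-sequences (S, H, I, D, R) at t and t-tau.
    The component sum is pi - mu*N(now) identically: incidence only moves
    mass between compartments, inflow and leaving are the only external
    flows.
    """
    pi, mu = params.pi, params.mu
    a1, a2 = params.alpha1, params.alpha2
    r1, r2 = params.rho1, params.rho2
    g1, g2 = params.gamma1, params.gamma2
    theta, k = params.theta, params.k
    disc = math.exp(-mu * schedule.tau)  # survival over the delay

    def rhs(now, delayed):
        S, H, I, D, R = now
        Sd, _, Id, Dd, _ = delayed
        inc1 = a1 * S * I / (1.0 + r1 * S)
        inc2 = a2 * S * D / (1.0 + r2 * S)
        dinc = disc * Sd * (a1 * Id / (1.0 + r1 * Sd) + a2 * Dd / (1.0 + r2 * Sd))
        dS = pi - inc1 - inc2 - mu * S
        dH = inc1 + inc2 - dinc - mu * H
        dI = k * dinc - (mu + g1) * I
        dD = (1.0 - k) * dinc - (g2 + mu) * D + (1.0 - theta) * g1 * I
        dR = theta * g1 * I + g2 * D - mu * R
        return (dS, dH, dI, dD, dR)

    return rhs


def rhs_full(now, delayed, params: ModelParameters,
             schedule: PulseSchedule) -> tuple[float, float, float, float, float]:
    """Continuous vector field of the full model at t != nT.

    ``now``/``delayed`` may be StateVector or any 5-sequence.
    """
    if isinstance(now, StateVector):
        now = now.as_tuple()
    if isinstance(delayed, StateVector):
        delayed = delayed.as_tuple()
    return make_rhs(params, schedule)(now, delayed)


def apply_impulse(state, phi: float):
    """Pulse-vaccination jump at t = nT: S -> (1-phi)S, R -> R + phi*S,
    H, I, D unchanged.  Conserves N exactly.

    Accepts a StateVector (returns StateVector) or a 5-tuple (returns tuple).
    """
    if not (0 <= phi < 1):
        raise ValueError(f"phi must be in [0, 1), got {phi!r}")
    if isinstance(state, StateVector):
        S, H, I, D, R = state.as_tuple()
        return StateVector((1.0 - phi) * S, H, I, D, R + phi * S)
    S, H, I, D, R = state
    return ((1.0 - phi) * S, H, I, D, R + phi * S)
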