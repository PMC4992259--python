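"""Planar competition model of PR-B transcriptional activity and inflammation.

The myometrium is modeled with two coupled logistic-competition equations:
PR-B activity ``B̂`` and inflammatory load ``Î`` each grow logistically toward
a critical level (``B_c``, ``I_c``) and deplete one another through mass-action
interaction terms (rates ``k1``, ``k2``).  Rescaling state by the critical
levels and time by ``k1*I_c`` reduces the six dimensional parameters to three
dimensionless ones:

    dB/dτ = b·B·(1−B) − B·I
    dI/dτ = i·I·(1−I) − k·B·I

with ``b = b̂/(k1·I_c)``, ``i = î/(k1·I_c)`` and ``k = k2·B_c/(k1·I_c)``.
The dimensionless phase space is the closed unit square; the corners (1,0)
and (0,1) are the quiescent and laboring equilibria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DimensionalParams",
    "DimensionalState",
    "DimensionlessParams",
    "PhaseState",
    "Trajectory",
    "LaborBasinError",
    "InvalidStateError",
    "ParameterDomainError",
    "IntegrationError",
    "rhs_dimensional",
    "rhs_dimensionless",
    "nondimensionalize",
    "integrate",
]

#: absolute clipping tolerance for excursions outside the unit square
CLIP_TOL = 1e-9

#: default integration horizon (dimensionless time); long because convergence
#: near the degenerate k = i equilibrium is algebraic, not exponential
DEFAULT_T_MAX = 500.0

#: default Euclidean capture radius around an equilibrium
DEFAULT_CAPTURE_TOL = 1e-3

#: solver tolerances (adaptive explicit Runge-Kutta 4/5)
RTOL = 1e-8
ATOL = 1e-10


class LaborBasinError(Exception):
    """Base class for all errors raised by this package."""


class InvalidStateError(LaborBasinError):
    """A phase-space state is non-finite or outside its domain."""


class ParameterDomainError(LaborBasinError):
    """Model parameters violate their domain constraints."""


class IntegrationError(LaborBasinError):
    """The ODE solver failed; carries the last valid state."""

    def __init__(self, message: str, last_state: "PhaseState | None" = None):
        super().__init__(message)
        self.last_state = last_state


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise InvalidStateError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class DimensionalParams:
    """Rates and critical levels of the dimensional model.

    Parameters
    ----------
    b_hat, i_hat : float
        PR-B and inflammation activation rates (1/weeks).
    k1 : float
        Depletion of PR-B per unit inflammation (1/(concentration*weeks)).
    k2 : float
        Depletion of inflammation per unit PR-B (1/(concentration*weeks)).
    B_c, I_c : float
        Critical (saturating) PR-B and inflammation levels (concentration).
    """

    b_hat: float
    i_hat: float
    k1: float
    k2: float
    B_c: float
    I_c: float

    def __post_init__(self):
        for name in ("b_hat", "i_hat", "k1", "k2", "B_c", "I_c"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ParameterDomainError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )


@dataclass(frozen=True)
class DimensionalState:
    """A point (B̂, Î) of the dimensional model at time ``t`` (weeks)."""

    B_hat: float
    I_hat: float
    t: float = 0.0

    def __post_init__(self):
        for name in ("B_hat", "I_hat", "t"):
            _require_finite(name, getattr(self, name))
        if self.B_hat < 0 or self.I_hat < 0:
            raise InvalidStateError(
                f"amounts must be nonnegative, got B_hat={self.B_hat}, I_hat={self.I_hat}"
            )


@dataclass(frozen=True)
class DimensionlessParams:
    """The dimensionless triple (b, i, k) governing the reduced model.

    ``b`` and ``i`` are the rescaled PR-B and inflammation growth rates and
    live in [0, 1] because they are assigned from min-max normalized surrogate
    gene expression; ``k`` is the rescaled anti-inflammatory strength of PR-B,
    in (0, 1].  The prediction convention additionally fixes ``k = 1``.
    """

    b: float
    i: float
    k: float = 1.0

    def __post_init__(self):
        for name in ("b", "i", "k"):
            _require_finite(name, getattr(self, name))
        if not (0.0 <= self.b <= 1.0):
            raise ParameterDomainError(f"b must lie in [0, 1], got {self.b}")
        if not (0.0 <= self.i <= 1.0):
            raise ParameterDomainError(f"i must lie in [0, 1], got {self.i}")
        if not (0.0 < self.k <= 1.0):
            raise ParameterDomainError(f"k must lie in (0, 1], got {self.k}")


@dataclass(frozen=True)
class PhaseState:
    """A point (B, I) of the dimensionless model at time ``tau``.

    The domain is the closed unit square: the rescaled levels cannot exceed
    their critical values.
    """

    B: float
    I: float
    tau: float = 0.0

    def __post_init__(self):
        for name in ("B", "I", "tau"):
            _require_finite(name, getattr(self, name))
        if not (-CLIP_TOL <= self.B <= 1 + CLIP_TOL and -CLIP_TOL <= self.I <= 1 + CLIP_TOL):
            raise InvalidStateError(
                f"(B, I)=({self.B}, {self.I}) lies outside the unit square"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.B, self.I], dtype=float)


#: labels a finished trajectory can carry
TERMINAL_LABELS = ("trivial", "quiescent", "laboring", "intermediate", "unresolved")


@dataclass
class Trajectory:
    """An integrated orbit of the dimensionless model.

    ``terminal_label`` names the equilibrium the orbit was captured by
    (within the capture radius), or ``"unresolved"`` if the horizon ran out.
    """

    states: list[PhaseState]
    params: DimensionlessParams
    terminal_label: str = "unresolved"

    def __post_init__(self):
        if self.terminal_label not in TERMINAL_LABELS:
            raise ValueError(f"unknown terminal label {self.terminal_label!r}")
        taus = [s.tau for s in self.states]
        if any(t1 >= t2 for t1, t2 in zip(taus, taus[1:])):
            raise ValueError("tau must be strictly increasing along a trajectory")

    @property
    def final(self) -> PhaseState:
        return self.states[-1]

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (tau, B, I) as flat arrays."""
        tau = np.array([s.tau for s in self.states])
        B = np.array([s.B for s in self.states])
        I = np.array([s.I for s in self.states])
        return tau, B, I


# ---------------------------------------------------------------------------
# Vector fields
# ---------------------------------------------------------------------------

def rhs_dimensional(state: DimensionalState, params: DimensionalParams) -> tuple[float, float]:
    """Rates (dB̂/dt, dÎ/dt) of the dimensional model at ``state``."""
    B, I = state.B_hat, state.I_hat
    dB = params.b_hat * B * (1.0 - B / params.B_c) - params.k1 * B * I
    dI = params.i_hat * I * (1.0 - I / params.I_c) - params.k2 * B * I
    return dB, dI


def rhs_dimensionless(state: PhaseState, params: DimensionlessParams) -> tuple[float, float]:
    """Rates (dB/dτ, dI/dτ) of the dimensionless model at ``state``."""
    B, I = state.B, state.I
    dB = params.b * B * (1.0 - B) - B * I
    dI = params.i * I * (1.0 - I) - params.k * B * I
    return dB, dI


def _rhs_array(y: np.ndarray, b: float, i: float, k: float) -> np.ndarray:
    """Vectorized right-hand side; ``y`` has shape (2, ...) stacking (B, I)."""
    B, I = y[0], y[1]
    return np.stack([b * B * (1.0 - B) - B * I, i * I * (1.0 - I) - k * B * I])


# ---------------------------------------------------------------------------
# Nondimensionalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleFactors:
    """Factors mapping dimensionless trajectories back to dimensional ones:
    ``B̂ = B_scale·B``, ``Î = I_scale·I``, ``t = t_scale·τ``."""

    B_scale: float
    I_scale: float
    t_scale: float


def nondimensionalize(params: DimensionalParams) -> tuple[DimensionlessParams, ScaleFactors]:
    """Reduce the six dimensional parameters to (b, i, k) plus scale factors.

    ``b = b̂/(k1·I_c)``, ``i = î/(k1·I_c)``, ``k = k2·B_c/(k1·I_c)``; state
    scales are the critical levels and the time scale is ``1/(k1·I_c)``.
    """
    rate = params.k1 * params.I_c
    dimless = DimensionlessParams(
        b=params.b_hat / rate,
        i=params.i_hat / rate,
        k=params.k2 * params.B_c / rate,
    )
    scales = ScaleFactors(B_scale=params.B_c, I_scale=params.I_c, t_scale=1.0 / rate)
    return dimless, scales


# ---------------------------------------------------------------------------
# Trajectory integration
# ---------------------------------------------------------------------------

def _clip_square(y: np.ndarray) -> np.ndarray:
    return np.clip(y, 0.0, 1.0)


def integrate(
    start: PhaseState,
    params: DimensionlessParams,
    t_max: float = DEFAULT_T_MAX,
    tol: float = DEFAULT_CAPTURE_TOL,
) -> Trajectory:
    """Integrate the dimensionless flow from ``start`` until captured.

    Uses an adaptive explicit Runge-Kutta 4(5) scheme and stops early when the
    orbit comes within Euclidean distance ``tol`` of any equilibrium of the
    system, labeling the trajectory by that equilibrium.  If the horizon
    ``t_max`` is exhausted first the label is ``"unresolved"``.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if tol <= 0:
        raise ValueError("tol must be positive")

    from .stability import equilibria  # local import: stability builds on this module

    targets = [(rep.label, np.asarray(rep.location, dtype=float)) for rep in equilibria(params)]

    y0 = start.as_array()
    for label, loc in targets:
        if np.linalg.norm(y0 - loc) <= tol:
            return Trajectory(states=[start], params=params, terminal_label=label)

    def rhs(t, y):
        return _rhs_array(y, params.b, params.i, params.k)

    events = []
    for _, loc in targets:
        def make_event(target=loc):
            def event(t, y):
                return float(np.linalg.norm(y - target) - tol)
            event.terminal = True
            return event
        events.append(make_event())

    sol = solve_ivp(
        rhs, (start.tau, start.tau + t_max), y0,
        method="RK45", rtol=RTOL, atol=ATOL, events=events, dense_output=False,
    )
    if sol.status == -1:
        last = PhaseState(*_clip_square(sol.y[:, -1]), tau=float(sol.t[-1]))
        raise IntegrationError(f"solver failed: {sol.message}", last_state=last)

    label = "unresolved"
    if sol.status == 1:  # a capture event fired
        for idx, t_events in enumerate(sol.t_events):
            if len(t_events):
                label = targets[idx][0]
                break

    states = []
    prev_tau = -np.inf
    for tau, y in zip(sol.t, sol.y.T):
        if tau <= prev_tau:  # solve_ivp can repeat the event time
            continue
        B, I = _clip_square(y)
        states.append(PhaseState(B=float(B), I=float(I), tau=float(tau)))
        prev_tau = tau
    return Trajectory(states=states, params=params, terminal_label=label)


def integrate_dimensional(
    start: DimensionalState,
    params: DimensionalParams,
    t_max: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the dimensional model; returns (t, y) with y shape (2, n).

    Convenience used to verify that rescaling dimensional orbits reproduces
    the dimensionless flow; no equilibrium capture is attempted.
    """
    def rhs(t, y):
        s = DimensionalState(B_hat=max(y[0], 0.0), I_hat=max(y[1], 0.0), t=t)
        return rhs_dimensional(s, params)

    sol = solve_ivp(
        rhs, (start.t, start.t + t_max), [start.B_hat, start.I_hat],
        method="RK45", rtol=RTOL, atol=ATOL,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    return sol.t, sol.y
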