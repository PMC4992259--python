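"""Linear stability analysis of the dimensionless competition model.

The model has up to four equilibria: the trivial point (0,0), the quiescent
point (1,0), the laboring point (0,1) and an interior intermediate point

    ( i(1-b)/(k-ib), b(k-i)/(k-ib) )

which exists inside the unit square only for some (b, i, k) and is a saddle
whose stable manifold separates the quiescent and laboring basins.
Eigenvalues are taken from the characteristic polynomial λ² + βλ + γ of the
Jacobian, with

    β = 2(bB* + iI*) + kB* + I* − (i + b)
    γ = ib(1 − 2I* − 2B* + 4B*I*) + bB*(−k + 2kB*) + iI*(2I* − 1) + I*B*(k − 1)

Three parameter-driven bifurcations move the intermediate point onto a corner
equilibrium and flip its stability: pro-labor (collision with the quiescent
point when i reaches k, or i = 1, or b or k vanish), pro-pregnancy (collision
with the laboring point when b = 1 or i = 0) and the trivial collision
(b = i = 0).  At k = b·i the intermediate expression is singular.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np

from .ode_model import (
    DimensionlessParams,
    LaborBasinError,
    PhaseState,
    rhs_dimensionless,
)

__all__ = [
    "EquilibriumReport",
    "BifurcationReport",
    "SingularIntermediateError",
    "ComplexEigenvaluesError",
    "equilibria",
    "intermediate_equilibrium",
    "jacobian",
    "characteristic_coefficients",
    "eigenvalues_at",
    "classify",
    "detect_bifurcations",
]

#: residual bound certifying that a reported location is an equilibrium
RESIDUAL_TOL = 1e-10

#: absolute tolerance of all equality-to-bifurcation tests; normalized
#: expression produces exact 0/1 parameter values by construction
BIFURCATION_TOL = 1e-9

#: eigenvalues with |λ| below this are treated as zero (degenerate)
ZERO_EIG_TOL = 1e-12


class SingularIntermediateError(LaborBasinError):
    """k = b·i: the intermediate equilibrium expression is a singularity."""


class ComplexEigenvaluesError(LaborBasinError):
    """Complex eigenvalues fall outside the modeled (real-node) regime."""


@dataclass(frozen=True)
class EquilibriumReport:
    """Location, eigenvalues and stability class of one equilibrium.

    Eigenvalues are reported in descending order (λ₁ ≥ λ₂) when real; a
    complex-conjugate pair is stored as-is with ``complex_pair=True``.
    """

    label: str  # trivial | quiescent | laboring | intermediate
    location: tuple[float, float]
    eigenvalues: tuple[complex, complex]
    beta: float
    gamma: float
    stability: str  # source | sink | saddle | degenerate
    complex_pair: bool = False


@dataclass(frozen=True)
class BifurcationReport:
    """Which of the model's parameter-driven degeneracies hold at (b, i, k)."""

    pro_labor: bool
    pro_pregnancy: bool
    trivial_collision: bool
    singular_intermediate: bool


def intermediate_equilibrium(params: DimensionlessParams) -> tuple[float, float] | None:
    """Interior equilibrium location, or None when it leaves the unit square.

    Both printed algebraic forms of the point are evaluated and required to
    agree to 1e-12 wherever both are defined; k = b·i raises
    :class:`SingularIntermediateError`.
    """
    b, i, k = params.b, params.i, params.k
    denom = k - i * b
    if abs(denom) <= BIFURCATION_TOL:
        raise SingularIntermediateError(
            f"k = b*i (k={k}, b*i={b * i}): the intermediate equilibrium is a singularity"
        )
    B = i * (1.0 - b) / denom
    I = b * (k - i) / denom
    # Alternative substitution-order form; it coincides with the first form
    # exactly at k = 1 (the prediction convention) or i = 0, and is checked
    # there as an algebra guard.
    if abs(k - 1.0) <= BIFURCATION_TOL or abs(i) <= BIFURCATION_TOL:
        B2 = (i * i * b * (1.0 - k) - i * k * (1.0 - b)) / (k * (b * i - k))
        I2 = k * b * (i - 1.0) / (b * i - k)
        if not (math.isclose(B, B2, abs_tol=1e-12) and math.isclose(I, I2, abs_tol=1e-12)):
            raise LaborBasinError(
                f"intermediate-equilibrium forms disagree: ({B}, {I}) vs ({B2}, {I2})"
            )
    if -BIFURCATION_TOL <= B <= 1 + BIFURCATION_TOL and -BIFURCATION_TOL <= I <= 1 + BIFURCATION_TOL:
        return (min(max(B, 0.0), 1.0), min(max(I, 0.0), 1.0))
    return None


def jacobian(point: PhaseState, params: DimensionlessParams) -> np.ndarray:
    """Jacobian of the dimensionless vector field at ``point``."""
    b, i, k = params.b, params.i, params.k
    B, I = point.B, point.I
    return np.array(
        [
            [b - 2.0 * b * B - I, -B],
            [-I, i - 2.0 * i * I - k * B],
        ]
    )


def characteristic_coefficients(
    point: PhaseState, params: DimensionlessParams
) -> tuple[float, float]:
    """Coefficients (β, γ) of the characteristic polynomial λ² + βλ + γ."""
    b, i, k = params.b, params.i, params.k
    B, I = point.B, point.I
    beta = 2.0 * (b * B + i * I) + k * B + I - (i + b)
    gamma = (
        i * b * (1.0 - 2.0 * I - 2.0 * B + 4.0 * B * I)
        + b * B * (-k + 2.0 * k * B)
        + i * I * (2.0 * I - 1.0)
        + I * B * (k - 1.0)
    )
    return beta, gamma


def eigenvalues_at(
    point: PhaseState, params: DimensionlessParams
) -> tuple[tuple[complex, complex], float, float, bool]:
    """Eigenvalue pair at an equilibrium, from the (β, γ) quadratic.

    Returns ``((λ₁, λ₂), β, γ, complex_pair)``.  Real pairs are ordered
    descending; a negative discriminant yields a complex-conjugate pair that
    is flagged rather than raised (it falls outside the regime the four
    named equilibria occupy for valid parameters).
    """
    residual = rhs_dimensionless(point, params)
    if max(abs(residual[0]), abs(residual[1])) > RESIDUAL_TOL:
        raise LaborBasinError(
            f"point ({point.B}, {point.I}) is not an equilibrium (residual {residual})"
        )
    beta, gamma = characteristic_coefficients(point, params)
    disc = beta * beta - 4.0 * gamma
    if disc < 0:
        root = cmath.sqrt(disc)
        lam1 = (-beta + root) / 2.0
        lam2 = (-beta - root) / 2.0
        return (lam1, lam2), beta, gamma, True
    root = math.sqrt(disc)
    lam1 = (-beta + root) / 2.0
    lam2 = (-beta - root) / 2.0
    return (lam1, lam2), beta, gamma, False


def classify(eigenvalues: tuple[complex, complex], complex_pair: bool = False) -> str:
    """Stability class from a real eigenvalue pair.

    both > 0 → source; both < 0 → sink; opposite signs → saddle; any
    eigenvalue within 1e-12 of zero → degenerate.
    """
    if complex_pair:
        raise ComplexEigenvaluesError(
            "complex eigenvalues are outside the modeled regime; cannot classify"
        )
    lam1, lam2 = (float(eigenvalues[0].real), float(eigenvalues[1].real)) if isinstance(
        eigenvalues[0], complex
    ) else (float(eigenvalues[0]), float(eigenvalues[1]))
    if abs(lam1) < ZERO_EIG_TOL or abs(lam2) < ZERO_EIG_TOL:
        return "degenerate"
    if lam1 > 0 and lam2 > 0:
        return "source"
    if lam1 < 0 and lam2 < 0:
        return "sink"
    return "saddle"


def _report(label: str, location: tuple[float, float], params: DimensionlessParams) -> EquilibriumReport:
    point = PhaseState(B=location[0], I=location[1])
    (lam1, lam2), beta, gamma, is_complex = eigenvalues_at(point, params)
    try:
        stability = classify((lam1, lam2), complex_pair=is_complex)
    except ComplexEigenvaluesError:
        stability = "degenerate"
    return EquilibriumReport(
        label=label,
        location=location,
        eigenvalues=(lam1, lam2),
        beta=beta,
        gamma=gamma,
        stability=stability,
        complex_pair=is_complex,
    )


def equilibria(params: DimensionlessParams) -> list[EquilibriumReport]:
    """All equilibria of the model at ``params``, with stability reports.

    The three corner equilibria are always present; the intermediate point is
    included when it lies in the closed unit square (and omitted, not raised,
    when it exists but falls outside).  ``k = b·i`` raises
    :class:`SingularIntermediateError`.
    """
    reports = [
        _report("trivial", (0.0, 0.0), params),
        _report("quiescent", (1.0, 0.0), params),
        _report("laboring", (0.0, 1.0), params),
    ]
    interior = intermediate_equilibrium(params)
    if interior is not None:
        # skip when it coincides with a corner (bifurcation collision)
        if all(
            np.hypot(interior[0] - r.location[0], interior[1] - r.location[1]) > BIFURCATION_TOL
            for r in reports
        ):
            reports.append(_report("intermediate", interior, params))
    return reports


def detect_bifurcations(
    params: DimensionlessParams, tol: float = BIFURCATION_TOL
) -> BifurcationReport:
    """Flag the parameter degeneracies present at (b, i, k).

    pro-labor: the intermediate point has collided with the quiescent
    equilibrium (i ≥ k, or i = 1, or b = 0, or k = 0), destabilizing
    quiescence — probability of labor 1.  pro-pregnancy: collision with the
    laboring equilibrium (b = 1 or i = 0) — probability of labor 0.
    trivial collision: b = i = 0.  singular intermediate: k = b·i.
    All equality tests use absolute tolerance ``tol``.
    """
    b, i, k = params.b, params.i, params.k
    pro_labor = (
        i >= k - tol
        or abs(i - 1.0) <= tol
        or abs(b) <= tol
        or abs(k) <= tol
    )
    pro_pregnancy = abs(b - 1.0) <= tol or abs(i) <= tol
    trivial_collision = abs(b) <= tol and abs(i) <= tol
    singular_intermediate = abs(k - b * i) <= tol
    return BifurcationReport(
        pro_labor=bool(pro_labor),
        pro_pregnancy=bool(pro_pregnancy),
        trivial_collision=bool(trivial_collision),
        singular_intermediate=bool(singular_intermediate),
    )
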