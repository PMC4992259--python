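"""Probability of labor as the laboring equilibrium's basin-of-attraction area.

Under a uniform measure on initial states (B, I) in the unit square, the
probability of labor for a parameter triple (b, i, k) is the area of the set
of initial states whose orbits converge to the laboring equilibrium (0, 1),
divided by the domain area (1).  The reference estimator launches one orbit
from every cell center of a regular grid over the open square and counts the
fraction captured by the laboring equilibrium; a separatrix estimator traces
the interior saddle's stable manifold and integrates the area on the laboring
side, serving as a fast independent cross-check.

Analytic shortcut cases (applied before any integration unless disabled):
i ≥ k or b = 0 → probability 1 (quiescence destabilized); b = 1 with i < 1 →
probability 0 (labor destabilized).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .ode_model import (
    DEFAULT_CAPTURE_TOL,
    DEFAULT_T_MAX,
    ATOL,
    RTOL,
    DimensionlessParams,
    LaborBasinError,
    PhaseState,
    _rhs_array,
)
from .stability import BIFURCATION_TOL, SingularIntermediateError, equilibria, jacobian

__all__ = [
    "BasinGridSpec",
    "LaborProbability",
    "PrecisionError",
    "SeparatrixNotApplicableError",
    "basin_probability",
    "separatrix_probability",
    "probability_surface",
    "clear_cache",
]

QUIESCENT = np.array([1.0, 0.0])
LABORING = np.array([0.0, 1.0])

#: integration window between capture checks in the batch grid method
_WINDOW = 25.0


class PrecisionError(LaborBasinError):
    """Too many grid orbits unresolved; increase t_max."""


class SeparatrixNotApplicableError(LaborBasinError):
    """No interior saddle: the separatrix method does not apply."""


@dataclass(frozen=True)
class BasinGridSpec:
    """Discretization of the unit square for the grid estimator.

    ``resolution`` is the number of cells per axis and must be odd so the
    diagonal is sampled symmetrically; orbits start from cell centers, never
    from the invariant axes or corners.
    """

    resolution: int = 201
    t_max: float = DEFAULT_T_MAX
    tol: float = DEFAULT_CAPTURE_TOL

    def __post_init__(self):
        if self.resolution < 21:
            raise ValueError("resolution must be at least 21")
        if self.resolution % 2 == 0:
            raise ValueError("resolution must be odd")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class LaborProbability:
    """A basin-area probability together with bookkeeping counts.

    ``n_laboring``/``n_quiescent`` count grid orbits captured within the
    radius; ``n_unresolved`` counts orbits that ran out of horizon and were
    assigned by net drift.  ``value`` includes the drift-assigned orbits.
    """

    value: float
    params: DimensionlessParams
    n_unresolved: int = 0
    method: str = "grid"  # grid | separatrix | analytic-shortcut
    n_laboring: int = 0
    n_quiescent: int = 0
    n_total: int = 0
    n_frozen: int = 0

    def __post_init__(self):
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"probability must lie in [0, 1], got {self.value}")


_CACHE: dict[tuple, LaborProbability] = {}


def clear_cache() -> None:
    _CACHE.clear()


def _cache_key(params: DimensionlessParams, spec: BasinGridSpec, shortcuts: bool) -> tuple:
    return (
        round(params.b, 12),
        round(params.i, 12),
        round(params.k, 12),
        spec.resolution,
        round(spec.t_max, 12),
        round(spec.tol, 12),
        shortcuts,
    )


def _shortcut(params: DimensionlessParams) -> float | None:
    b, i, k = params.b, params.i, params.k
    if b >= 1.0 - BIFURCATION_TOL and i >= 1.0 - BIFURCATION_TOL:
        # doubly degenerate corner: both collisions at once; resolved by the
        # grid method (a line of rest states appears, handled as frozen orbits)
        return None
    if i >= k - BIFURCATION_TOL or b <= BIFURCATION_TOL:
        return 1.0
    if b >= 1.0 - BIFURCATION_TOL and i < 1.0 - BIFURCATION_TOL:
        return 0.0
    return None


def basin_probability(
    params: DimensionlessParams,
    spec: BasinGridSpec | None = None,
    shortcuts: bool = True,
) -> LaborProbability:
    """Laboring-basin area fraction by the grid-of-initial-conditions method.

    One orbit is launched from each cell center of the open unit square and
    integrated (vectorized, adaptive RK45) until captured within ``spec.tol``
    of the quiescent or laboring equilibrium.  Orbits still unresolved at
    ``spec.t_max`` are assigned to whichever attractor they drifted toward
    over the last integration window and are counted in ``n_unresolved``;
    if more than 1 % of orbits needed drift assignment a
    :class:`PrecisionError` advises a larger horizon.

    With ``shortcuts=True`` the analytic limit cases bypass integration.
    """
    spec = spec or BasinGridSpec()
    key = _cache_key(params, spec, shortcuts)
    if key in _CACHE:
        return _CACHE[key]

    if shortcuts:
        p = _shortcut(params)
        if p is not None:
            result = LaborProbability(value=p, params=params, method="analytic-shortcut")
            _CACHE[key] = result
            return result

    n = spec.resolution
    centers = (np.arange(n) + 0.5) / n
    Bg, Ig = np.meshgrid(centers, centers, indexing="ij")
    y = np.stack([Bg.ravel(), Ig.ravel()])  # (2, N)
    total = y.shape[1]

    b, i, k = params.b, params.i, params.k
    captured = np.zeros(total, dtype=np.int8)  # 0 active, 1 laboring, 2 quiescent
    active = np.arange(total)
    tau = 0.0
    n_frozen = 0
    drift_start = y.copy()

    while active.size and tau < spec.t_max:
        window = min(_WINDOW, spec.t_max - tau)
        ya = y[:, active]
        drift_start_a = ya.copy()

        def rhs(t, flat):
            return _rhs_array(flat.reshape(2, -1), b, i, k).ravel()

        sol = solve_ivp(
            rhs, (0.0, window), ya.ravel(), method="RK45", rtol=RTOL, atol=ATOL,
        )
        if not sol.success:
            raise LaborBasinError(f"batch integration failed: {sol.message}")
        ya = np.clip(sol.y[:, -1].reshape(2, -1), 0.0, 1.0)
        y[:, active] = ya
        drift_start[:, active] = drift_start_a

        d_lab = np.hypot(ya[0] - LABORING[0], ya[1] - LABORING[1])
        d_qui = np.hypot(ya[0] - QUIESCENT[0], ya[1] - QUIESCENT[1])
        lab_hit = d_lab <= spec.tol
        qui_hit = d_qui <= spec.tol
        # Orbits whose velocity has vanished away from both attractors have
        # converged to a degenerate rest point (a continuum of equilibria
        # appears at i = 0 and at the b = i = 1 corner).  They are assigned
        # to the nearest attractor, which is where an infinitesimal
        # perturbation of the degeneracy would send them.
        speed = np.hypot(*_rhs_array(ya, b, i, k))
        frozen = (speed < 1e-9) & ~(lab_hit | qui_hit)
        captured[active[lab_hit | (frozen & (d_lab < d_qui))]] = 1
        captured[active[qui_hit | (frozen & (d_lab >= d_qui))]] = 2
        n_frozen += int(np.count_nonzero(frozen))
        active = active[~(lab_hit | qui_hit | frozen)]
        tau += window

    n_unresolved = int(active.size)
    n_laboring = int(np.count_nonzero(captured == 1))
    n_quiescent = int(np.count_nonzero(captured == 2))

    value_count = n_laboring
    if n_unresolved:
        # assign leftovers by net drift toward (0,1) vs (1,0) over the last window
        ya = y[:, active]
        ys = drift_start[:, active]
        gain_lab = (
            np.hypot(ys[0] - LABORING[0], ys[1] - LABORING[1])
            - np.hypot(ya[0] - LABORING[0], ya[1] - LABORING[1])
        )
        gain_qui = (
            np.hypot(ys[0] - QUIESCENT[0], ys[1] - QUIESCENT[1])
            - np.hypot(ya[0] - QUIESCENT[0], ya[1] - QUIESCENT[1])
        )
        value_count += int(np.count_nonzero(gain_lab > gain_qui))

    if n_unresolved > 0.01 * total:
        raise PrecisionError(
            f"{n_unresolved}/{total} orbits unresolved after t_max={spec.t_max}; "
            "increase t_max"
        )

    result = LaborProbability(
        value=value_count / total,
        params=params,
        n_unresolved=n_unresolved,
        method="grid",
        n_laboring=n_laboring,
        n_quiescent=n_quiescent,
        n_total=total,
        n_frozen=n_frozen,
    )
    _CACHE[key] = result
    return result


# ---------------------------------------------------------------------------
# Separatrix quadrature (independent cross-check)
# ---------------------------------------------------------------------------

def _trace_manifold_branch(
    saddle: np.ndarray, direction: np.ndarray, params: DimensionlessParams,
    eps: float = 1e-7, t_max: float = 200.0,
) -> np.ndarray:
    """Backward-time orbit from ``saddle + eps*direction``; shape (n, 2).

    Integration stops on leaving the (slightly enlarged) unit square or on
    converging backward to the trivial source (0, 0).
    """
    b, i, k = params.b, params.i, params.k

    def rhs(t, y):
        return -_rhs_array(y, b, i, k)

    margin = 1e-6

    def exits(t, y):
        return min(y[0] + margin, y[1] + margin, 1.0 + margin - y[0], 1.0 + margin - y[1])
    exits.terminal = True
    exits.direction = -1

    def at_origin(t, y):
        return float(np.hypot(y[0], y[1]) - 1e-9)
    at_origin.terminal = True
    at_origin.direction = -1

    y0 = saddle + eps * direction
    sol = solve_ivp(
        rhs, (0.0, t_max), y0, method="RK45", rtol=1e-10, atol=1e-12,
        events=[exits, at_origin], max_step=0.5,
    )
    if not sol.success:
        raise LaborBasinError(f"manifold tracing failed: {sol.message}")
    pts = sol.y.T
    return pts


def _polygon_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def separatrix_probability(params: DimensionlessParams) -> LaborProbability:
    """Laboring-basin area by stable-manifold tracing and quadrature.

    The interior saddle's stable manifold (the separatrix) is traced by
    integrating the flow backward in time from two points offset along the
    stable eigenvector.  One branch closes on the trivial source (0, 0), the
    other leaves the square; together with the boundary arc through the
    laboring corner they bound a polygon whose area is the probability.
    Raises :class:`SeparatrixNotApplicableError` when no interior saddle
    exists (callers then fall back to the grid or shortcut path).
    """
    try:
        reports = equilibria(params)
    except SingularIntermediateError as exc:
        raise SeparatrixNotApplicableError(str(exc)) from exc
    saddle_report = next((r for r in reports if r.label == "intermediate"), None)
    if saddle_report is None or saddle_report.stability != "saddle":
        raise SeparatrixNotApplicableError(
            "no interior saddle equilibrium; separatrix method not applicable"
        )
    loc = np.asarray(saddle_report.location)
    if not (0 < loc[0] < 1 and 0 < loc[1] < 1):
        raise SeparatrixNotApplicableError("saddle lies on the domain boundary")

    J = jacobian(PhaseState(B=loc[0], I=loc[1]), params)
    eigvals, eigvecs = np.linalg.eig(J)
    stable_idx = int(np.argmin(eigvals.real))
    if eigvals[stable_idx].real >= 0:
        raise SeparatrixNotApplicableError("no stable eigendirection at the saddle")
    v = np.real(eigvecs[:, stable_idx])
    v = v / np.linalg.norm(v)

    branch_plus = _trace_manifold_branch(loc, v, params)
    branch_minus = _trace_manifold_branch(loc, -v, params)

    def ends_at_origin(branch: np.ndarray) -> bool:
        return bool(np.hypot(*branch[-1]) < 1e-3)

    if ends_at_origin(branch_plus) and not ends_at_origin(branch_minus):
        to_origin, to_boundary = branch_plus, branch_minus
    elif ends_at_origin(branch_minus) and not ends_at_origin(branch_plus):
        to_origin, to_boundary = branch_minus, branch_plus
    else:
        raise SeparatrixNotApplicableError(
            "could not orient the stable manifold branches"
        )

    # separatrix polyline from (0,0) through the saddle to the exit point
    curve = np.vstack(
        [np.array([[0.0, 0.0]]), to_origin[::-1], loc[None, :], to_boundary]
    )
    curve = np.clip(curve, 0.0, 1.0)

    exit_pt = curve[-1]
    # close the polygon along the boundary arc containing the laboring corner
    boundary: list[np.ndarray] = []
    if exit_pt[1] >= 1.0 - 1e-6:  # exits through the top edge I = 1
        boundary = [np.array([0.0, 1.0])]
    elif exit_pt[0] >= 1.0 - 1e-6:  # exits through the right edge B = 1
        boundary = [np.array([1.0, 1.0]), np.array([0.0, 1.0])]
    else:
        raise SeparatrixNotApplicableError(
            f"separatrix exits through an unexpected boundary point {exit_pt}"
        )
    polygon = np.vstack([curve, np.array(boundary)])
    area = _polygon_area(polygon)
    area = min(max(area, 0.0), 1.0)
    return LaborProbability(value=area, params=params, method="separatrix")


# ---------------------------------------------------------------------------
# Probability surface over (b, i)
# ---------------------------------------------------------------------------

def probability_surface(
    b_grid, i_grid, k: float = 1.0, spec: BasinGridSpec | None = None,
    shortcuts: bool = True,
):
    """Matrix of basin probabilities over a (b, i) grid at fixed ``k``.

    Returns a pandas DataFrame with ``b`` values as the row index and ``i``
    values as columns.  Per-cell failures are recorded as NaN without
    aborting the sweep.
    """
    import pandas as pd

    b_grid = np.asarray(list(b_grid), dtype=float)
    i_grid = np.asarray(list(i_grid), dtype=float)
    if ((b_grid < 0) | (b_grid > 1)).any() or ((i_grid < 0) | (i_grid > 1)).any():
        raise ValueError("b and i grids must lie within [0, 1]")
    out = np.full((b_grid.size, i_grid.size), np.nan)
    for r, b in enumerate(b_grid):
        for c, i in enumerate(i_grid):
            try:
                params = DimensionlessParams(b=float(b), i=float(i), k=float(k))
                out[r, c] = basin_probability(params, spec, shortcuts=shortcuts).value
            except LaborBasinError:
                pass
    return pd.DataFrame(out, index=b_grid, columns=i_grid)
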