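"""Phenotypic phase planes: the objective surface over paired flux constraints.

A phase plane fixes the fluxes of two chosen reactions on a 2-D grid and
re-optimizes the growth surrogate in every cell.  Slope-sign changes of the
resulting surface along an axis delimit metabolic phenotype regions (e.g.
the regime where *reducing* pyruvate dehydrogenase or fumarate hydratase
activity increases predicted growth, versus the regime past a threshold
where it collapses).

Cells may constrain the scanned fluxes by equality (classic construction,
default) or as upper bounds (``mode='inequality'``).  Infeasible cells are
reported as such and carry NaN, not zero, so they cannot masquerade as
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fba import LinearProblem, ObjectiveSpec
from .network import MetabolicNetwork

__all__ = [
    "PhasePlaneGrid",
    "compute_phase_plane",
    "detect_threshold",
    "oxidative_branch_asymmetry",
]


@dataclass
class PhasePlaneGrid:
    """Objective values over a grid of paired flux constraints.

    ``Z[i, j]`` is the optimal objective with the y-axis reaction at
    ``y_values[i]`` and the x-axis reaction at ``x_values[j]``; NaN where
    the constrained problem is infeasible (``status`` False).
    """

    axis_x: str
    axis_y: str
    x_values: np.ndarray
    y_values: np.ndarray
    Z: np.ndarray
    feasible: np.ndarray  # bool mask, same shape as Z
    mode: str

    def slice_along(self, axis: str, at: float) -> tuple[np.ndarray, np.ndarray]:
        """1-D slice of Z along one axis at the grid line nearest ``at``."""
        if axis == "x":
            i = int(np.argmin(np.abs(self.y_values - at)))
            return self.x_values, self.Z[i, :]
        if axis == "y":
            j = int(np.argmin(np.abs(self.x_values - at)))
            return self.y_values, self.Z[:, j]
        raise ValueError("axis must be 'x' or 'y'")


def compute_phase_plane(
    net: MetabolicNetwork,
    obj: ObjectiveSpec,
    rx: str,
    ry: str,
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
    n_points: int = 50,
    mode: str = "equality",
) -> PhasePlaneGrid:
    """Optimal objective over an ``n_points`` × ``n_points`` constraint grid.

    Default axis ranges span [0, 1.5 × wild-type flux] of each reaction
    (falling back to [0, 10] when the wild-type flux is ~0).
    """
    if mode not in ("equality", "inequality"):
        raise ValueError(f"unknown mode {mode!r}")
    lp = LinearProblem(net)
    for rid in (rx, ry):
        if rid not in lp.ridx:
            raise KeyError(f"unknown reaction id {rid!r}")
    c = obj.vector(net)
    jx, jy = lp.ridx[rx], lp.ridx[ry]

    if x_range is None or y_range is None:
        status, _, v = lp.maximize(c)
        if status != "optimal":
            raise ValueError(f"wild-type solve is {status}")
        if x_range is None:
            hi = 1.5 * abs(v[jx])
            x_range = (0.0, hi if hi > 1e-6 else 10.0)
        if y_range is None:
            hi = 1.5 * abs(v[jy])
            y_range = (0.0, hi if hi > 1e-6 else 10.0)

    xs = np.linspace(*x_range, n_points)
    ys = np.linspace(*y_range, n_points)
    Z = np.full((len(ys), len(xs)), np.nan)
    ok = np.zeros_like(Z, dtype=bool)
    lb0, ub0 = lp.lb, lp.ub
    for i, yv in enumerate(ys):
        for j, xv in enumerate(xs):
            lb = lb0.copy()
            ub = ub0.copy()
            if mode == "equality":
                lb[jx] = ub[jx] = xv
                lb[jy] = ub[jy] = yv
            else:
                ub[jx] = xv
                ub[jy] = yv
            status, val, _ = lp.maximize(c, lb=lb, ub=ub)
            if status == "optimal":
                Z[i, j] = val
                ok[i, j] = True
    return PhasePlaneGrid(
        axis_x=rx, axis_y=ry, x_values=xs, y_values=ys, Z=Z, feasible=ok, mode=mode
    )


def detect_threshold(
    grid: PhasePlaneGrid, along: str, at: float, rel_tol: float = 1e-6
) -> list[float]:
    """Flux values where the slope of Z changes sign along one axis.

    Scans the grid slice nearest ``at`` on the other axis and returns the
    axis values at which the discrete derivative flips sign (region
    boundaries).  Infeasible cells truncate the scanned slice.
    """
    xs, zs = grid.slice_along(along, at)
    mask = np.isfinite(zs)
    xs, zs = xs[mask], zs[mask]
    if len(xs) < 3:
        raise ValueError("need at least three finite grid points along the axis")
    dz = np.diff(zs)
    scale = max(np.max(np.abs(zs)), 1.0)
    sign = np.where(dz > rel_tol * scale, 1, np.where(dz < -rel_tol * scale, -1, 0))
    breaks: list[float] = []
    prev = 0
    for k, s in enumerate(sign):
        if s == 0:
            continue
        if prev != 0 and s != prev:
            breaks.append(float(xs[k]))
        prev = s
    return breaks


@dataclass
class BranchAsymmetryReport:
    """Growth with one pentose-phosphate branch closed and the other forced."""

    growth_oxidative_only: float   # TKT1 = 0, G6PDH free to carry flux
    growth_nonoxidative_only: float  # G6PDH = 0, TKT1 forced forward
    oxidative_supports_growth: bool
    nonoxidative_alone_supports_growth: bool


def oxidative_branch_asymmetry(
    net: MetabolicNetwork,
    obj: ObjectiveSpec,
    tkt: str = "TKT1",
    g6pdh: str = "G6PDH",
    forced_flux: float = 0.1,
) -> BranchAsymmetryReport:
    """Probe the asymmetry between the two ribose-5-phosphate routes.

    Regime A closes the non-oxidative entry (``TKT1 = 0``) and leaves the
    oxidative branch free; regime B closes the oxidative branch
    (``G6PDH = 0``) and forces a positive forward transketolase flux.  In
    the core network regime A grows while regime B cannot: forward
    transketolase consumes ribose 5-phosphate, so without the oxidative
    branch no net r5p supply exists.
    """
    lp = LinearProblem(net)
    for rid in (tkt, g6pdh):
        if rid not in lp.ridx:
            raise KeyError(f"unknown reaction id {rid!r}")
    c = obj.vector(net)

    def solve_with(overrides: dict[str, tuple[float, float]]) -> float:
        lb, ub = lp.lb.copy(), lp.ub.copy()
        for rid, (lo, hi) in overrides.items():
            j = lp.ridx[rid]
            lb[j], ub[j] = lo, hi
        status, val, _ = lp.maximize(c, lb=lb, ub=ub)
        return val if status == "optimal" else 0.0

    g_ox = solve_with({tkt: (0.0, 0.0)})
    g_nonox = solve_with({g6pdh: (0.0, 0.0), tkt: (forced_flux, lp.ub[lp.ridx[tkt]])})
    return BranchAsymmetryReport(
        growth_oxidative_only=g_ox,
        growth_nonoxidative_only=g_nonox,
        oxidative_supports_growth=g_ox > 0,
        nonoxidative_alone_supports_growth=g_nonox > 0,
    )
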