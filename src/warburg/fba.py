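"""Flux balance analysis: objectives, LP solves, reaction deletions.

FBA maximizes a linear growth surrogate ``c·v`` over the steady-state flux
polytope ``{v : S v = 0, lb <= v <= ub}``.  The growth surrogate used for the
cancer core network is a weighted sum of demand fluxes of growth-supporting
metabolites (lactate, cytosolic and mitochondrial ATP turnover, ribose
5-phosphate, NADPH, NAD⁺ regeneration, oxaloacetate, citrate) rather than a
calibrated biomass equation.

Solves use scipy's HiGHS interface.  Infeasible and unbounded problems are
reported as statuses, not exceptions, so large deletion screens never abort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .network import MetabolicNetwork

__all__ = [
    "ObjectiveSpec",
    "FluxSolution",
    "GROWTH_COMPONENTS",
    "FIG_PHASE_WEIGHTS",
    "equimolar_objective",
    "weighted_objective",
    "solve_fba",
    "delete_reaction",
    "LinearProblem",
]

#: Demand reactions whose fluxes make up the growth surrogate, in the
#: canonical 8-component form (the 5-metabolite shorthand — lactate, ATP,
#: r5p, oaa, citrate — is recovered by dropping the NADPH/NAD/ATPm terms).
GROWTH_COMPONENTS = (
    "DM_atp_c",    # cytosolic ATP turnover
    "DM_lac_e",    # lactate secretion (Warburg flux)
    "DM_nadph_c",  # reductive power for biosynthesis
    "DM_r5p_c",    # ribose 5-phosphate for nucleotides
    "DM_nad_c",    # NAD+ regeneration demand
    "DM_oaa_c",    # oxaloacetate for amino-acid synthesis
    "DM_atp_m",    # mitochondrial ATP turnover
    "DM_cit_c",    # cytosolic citrate for lipogenesis
)

#: Non-equimolar coefficient set used for the pyruvate-kinase phase-plane
#: variant of the growth surrogate (same 8 components, tuned weights).
FIG_PHASE_WEIGHTS = {
    "DM_atp_c": 12.47,
    "DM_lac_e": 0.13,
    "DM_nadph_c": 0.93,
    "DM_r5p_c": 0.6,
    "DM_nad_c": 0.89,
    "DM_oaa_c": 0.75,
    "DM_atp_m": 17.09,
    "DM_cit_c": 0.55,
}


class ObjectiveError(ValueError):
    """An objective references reactions missing from the network."""


@dataclass(frozen=True)
class ObjectiveSpec:
    """A weighted linear combination of reaction fluxes, ``sum_i c_i v_i``."""

    components: dict[str, float]

    def __post_init__(self) -> None:
        if not self.components or not any(w != 0 for w in self.components.values()):
            raise ObjectiveError("objective needs at least one non-zero weight")
        if any(w < 0 for w in self.components.values()):
            raise ObjectiveError("objective weights must be >= 0")

    def vector(self, net: MetabolicNetwork) -> np.ndarray:
        ridx = net.reaction_index()
        c = np.zeros(len(net.reactions))
        for rid, w in self.components.items():
            if rid not in ridx:
                raise ObjectiveError(f"objective component {rid!r} not in network")
            c[ridx[rid]] = w
        return c

    def scaled(self, k: float) -> "ObjectiveSpec":
        return ObjectiveSpec({r: k * w for r, w in self.components.items()})


@dataclass
class FluxSolution:
    """Result of one FBA solve."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux_vector(self, net: MetabolicNetwork) -> np.ndarray:
        return np.array([self.fluxes[r] for r in net.reaction_ids])


def equimolar_objective(net: MetabolicNetwork, components=GROWTH_COMPONENTS) -> ObjectiveSpec:
    """Unit weight on every growth-component demand reaction.

    Raises :class:`ObjectiveError` naming the first missing component.
    """
    ridx = net.reaction_index()
    for rid in components:
        if rid not in ridx:
            raise ObjectiveError(
                f"network lacks growth-component demand reaction {rid!r}"
            )
    return ObjectiveSpec({rid: 1.0 for rid in components})


def weighted_objective(weights: dict[str, float] | None = None) -> ObjectiveSpec:
    """The tuned 8-component growth surrogate (default: phase-plane weights)."""
    return ObjectiveSpec(dict(FIG_PHASE_WEIGHTS if weights is None else weights))


# ---------------------------------------------------------------------------
# LP machinery.  A LinearProblem caches S and bounds as arrays so screens
# (hundreds of thousands of solves) avoid rebuilding them per solve.
# ---------------------------------------------------------------------------

_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


class LinearProblem:
    """Reusable ``max c·v  s.t.  S v = 0, lb <= v <= ub`` solver."""

    def __init__(self, net: MetabolicNetwork):
        self.net = net
        self.S = net.S
        self.lb, self.ub = net.bounds
        self.rids = net.reaction_ids
        self.ridx = {r: j for j, r in enumerate(self.rids)}

    def solve(
        self,
        c: np.ndarray,
        sense: float = -1.0,
        lb: np.ndarray | None = None,
        ub: np.ndarray | None = None,
        extra_row: tuple[np.ndarray, float] | None = None,
    ) -> tuple[str, float, np.ndarray | None]:
        """Optimize ``sense * c·v`` (sense=-1 maximizes).

        ``extra_row`` appends one equality/inequality-free constraint of the
        form ``a·v >= rhs`` (used by FVA to pin the objective at optimum).
        """
        lo = self.lb if lb is None else lb
        hi = self.ub if ub is None else ub
        A_ub = b_ub = None
        if extra_row is not None:
            a, rhs = extra_row
            A_ub = -a[None, :]
            b_ub = np.array([-rhs])
        res = linprog(
            sense * c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=np.column_stack([lo, hi]),
            method="highs",
        )
        status = _STATUS.get(res.status, "infeasible")
        if status != "optimal":
            return status, float("nan"), None
        return "optimal", float(c @ res.x), res.x

    def maximize(self, c, lb=None, ub=None, extra_row=None):
        return self.solve(c, -1.0, lb, ub, extra_row)

    def minimize(self, c, lb=None, ub=None, extra_row=None):
        return self.solve(c, 1.0, lb, ub, extra_row)


def solve_fba(
    net: MetabolicNetwork,
    obj: ObjectiveSpec,
    overrides: dict[str, tuple[float, float]] | None = None,
) -> FluxSolution:
    """Maximize the objective over the steady-state flux polytope.

    ``overrides`` maps reaction id -> (lower, upper) bound replacements for
    this solve only; the network is not modified.
    """
    lp = LinearProblem(net)
    lb, ub = lp.lb.copy(), lp.ub.copy()
    if overrides:
        for rid, (lo, hi) in overrides.items():
            if rid not in lp.ridx:
                raise KeyError(f"unknown reaction id {rid!r}")
            j = lp.ridx[rid]
            lb[j], ub[j] = lo, hi
    c = obj.vector(net)
    status, value, x = lp.maximize(c, lb=lb, ub=ub)
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"))
    return FluxSolution(
        status="optimal",
        objective_value=value,
        fluxes=dict(zip(lp.rids, x.tolist())),
    )


def delete_reaction(net: MetabolicNetwork, rid: str) -> MetabolicNetwork:
    """A copy of the network with the reaction's flux pinned to zero."""
    if rid not in net.reaction_index():
        raise KeyError(f"unknown reaction id {rid!r}")
    return net.with_bounds({rid: (0.0, 0.0)})
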