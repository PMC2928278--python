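"""Flux variability, deletion essentiality, and target robustness screens.

A metabolic drug-target candidate is a reaction that combines *high
essentiality* (deleting it costs at least half of the optimal growth
surrogate; an infeasible deletion counts as total loss) with *low flux
variability* (its flux range at the optimum spans at most half of the
largest range observed across the analyzed reactions).  Exchange and sink
pseudo-reactions are excluded from the analysis; the target fraction is
reported against both the analyzed set and the complete reconstruction.

The robustness scan re-runs the screen under many random objective weightings
(components i.i.d. Uniform(0,1)) and reports, per reaction, the fraction of
realizations in which it met both criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fba import GROWTH_COMPONENTS, LinearProblem, ObjectiveSpec
from .network import MetabolicNetwork

__all__ = [
    "FvaRange",
    "TargetReport",
    "RobustnessResult",
    "flux_variability",
    "single_deletion_screen",
    "double_deletion",
    "random_objective",
    "robustness_scan",
    "ESSENTIALITY_THRESHOLD",
    "VARIABILITY_FRACTION",
]

#: a deletion retaining less than this fraction of the wild-type optimum is
#: classified essential
ESSENTIALITY_THRESHOLD = 0.5
#: low-variability cut: span <= this fraction of the maximal analyzed span
VARIABILITY_FRACTION = 0.5
#: reaction kinds excluded from the screen
DEFAULT_EXCLUDE_KINDS = frozenset({"exchange", "sink"})


@dataclass(frozen=True)
class FvaRange:
    reaction_id: str
    v_min: float
    v_max: float

    @property
    def span(self) -> float:
        return self.v_max - self.v_min


@dataclass
class TargetReport:
    """Per-reaction outcome of the combined variability/essentiality screen."""

    wild_type_objective: float
    analyzed_set: list[str]
    fva: dict[str, FvaRange]
    growth_ratio: dict[str, float]
    essential: dict[str, bool]
    low_variability: dict[str, bool]
    max_span: float
    n_reactions_total: int

    @property
    def targets(self) -> list[str]:
        return [
            r
            for r in self.analyzed_set
            if self.essential[r] and self.low_variability[r]
        ]

    @property
    def target_fraction_total(self) -> float:
        """Targets as a fraction of the complete reconstruction."""
        return len(self.targets) / self.n_reactions_total

    @property
    def target_fraction_analyzed(self) -> float:
        """Targets as a fraction of the analyzed (non-exchange/sink) set."""
        return len(self.targets) / len(self.analyzed_set)


@dataclass
class RobustnessResult:
    n_realizations: int
    n_feasible: int
    seed: int | None
    frequency: dict[str, float]
    threshold: float = 0.99
    skipped: int = 0

    @property
    def robust_set(self) -> list[str]:
        return [r for r, f in self.frequency.items() if f >= self.threshold]


def _analyzed_reactions(net: MetabolicNetwork, exclude_kinds) -> list[str]:
    return [r.id for r in net.reactions if r.kind not in exclude_kinds]


def flux_variability(
    net: MetabolicNetwork,
    obj: ObjectiveSpec,
    optimum_fraction: float = 1.0,
    reactions: list[str] | None = None,
    lp: LinearProblem | None = None,
) -> dict[str, FvaRange]:
    """Per-reaction min/max flux at (a fraction of) the optimal objective.

    Solves two LPs per reaction with the additional constraint
    ``c·v >= optimum_fraction * optimum``.
    """
    lp = lp or LinearProblem(net)
    c = obj.vector(net)
    status, opt, _ = lp.maximize(c)
    if status != "optimal":
        raise ValueError(f"wild-type FBA is {status}; cannot run FVA")
    pin = (c, optimum_fraction * opt)
    rids = reactions if reactions is not None else lp.rids
    out: dict[str, FvaRange] = {}
    e = np.zeros(len(lp.rids))
    for rid in rids:
        j = lp.ridx[rid]
        e[j] = 1.0
        s_lo, lo, _ = lp.minimize(e, extra_row=pin)
        s_hi, hi, _ = lp.maximize(e, extra_row=pin)
        e[j] = 0.0
        if s_lo != "optimal" or s_hi != "optimal":
            raise ValueError(f"FVA subproblem for {rid} was {s_lo}/{s_hi}")
        out[rid] = FvaRange(rid, min(lo, hi), max(lo, hi))
    return out


def _deletion_ratio(lp: LinearProblem, c: np.ndarray, j: int, wt: float) -> float:
    lb = lp.lb.copy()
    ub = lp.ub.copy()
    lb[j] = ub[j] = 0.0
    status, val, _ = lp.maximize(c, lb=lb, ub=ub)
    if status != "optimal":
        return 0.0  # lethal: no feasible flux state without this reaction
    if wt <= 0:
        raise ValueError("wild-type objective must be positive")
    # a demand deletion also removes its maintenance minimum, which can
    # slightly relax the problem; the ratio is reported on [0, 1]
    return min(1.0, max(0.0, val / wt))


def single_deletion_screen(
    net: MetabolicNetwork,
    obj: ObjectiveSpec,
    exclude_kinds=DEFAULT_EXCLUDE_KINDS,
    essentiality_threshold: float = ESSENTIALITY_THRESHOLD,
    variability_fraction: float = VARIABILITY_FRACTION,
    lp: LinearProblem | None = None,
) -> TargetReport:
    """Combined flux-variability / essentiality screen over all reactions.

    ``growth_ratio[r]`` is the deleted-over-wild-type objective ratio
    (0 when the deletion is infeasible).  A reaction is flagged a target when
    its ratio is at most ``essentiality_threshold`` and its FVA span is at
    most ``variability_fraction`` of the maximal span over the analyzed set.
    """
    lp = lp or LinearProblem(net)
    c = obj.vector(net)
    status, wt, _ = lp.maximize(c)
    if status != "optimal" or wt <= 0:
        raise ValueError(
            f"wild-type solve is {status} with objective {wt}; screen undefined"
        )
    analyzed = _analyzed_reactions(net, exclude_kinds)
    fva = flux_variability(net, obj, reactions=analyzed, lp=lp)
    max_span = max(r.span for r in fva.values())
    ratios = {
        rid: _deletion_ratio(lp, c, lp.ridx[rid], wt) for rid in analyzed
    }
    essential = {r: ratios[r] <= essentiality_threshold for r in analyzed}
    low_var = {
        r: fva[r].span <= variability_fraction * max_span for r in analyzed
    }
    return TargetReport(
        wild_type_objective=wt,
        analyzed_set=analyzed,
        fva=fva,
        growth_ratio=ratios,
        essential=essential,
        low_variability=low_var,
        max_span=max_span,
        n_reactions_total=len(net.reactions),
    )


def double_deletion(
    net: MetabolicNetwork, obj: ObjectiveSpec, pair: tuple[str, str]
) -> float:
    """Objective ratio with both reactions of ``pair`` deleted (0 = lethal)."""
    lp = LinearProblem(net)
    c = obj.vector(net)
    status, wt, _ = lp.maximize(c)
    if status != "optimal" or wt <= 0:
        raise ValueError("wild-type objective must be positive")
    lb, ub = lp.lb.copy(), lp.ub.copy()
    for rid in pair:
        if rid not in lp.ridx:
            raise KeyError(f"unknown reaction id {rid!r}")
        j = lp.ridx[rid]
        lb[j] = ub[j] = 0.0
    status, val, _ = lp.maximize(c, lb=lb, ub=ub)
    if status != "optimal":
        return 0.0
    return max(0.0, val / wt)


def random_objective(
    rng: np.random.Generator | int | None,
    components=GROWTH_COMPONENTS,
) -> ObjectiveSpec:
    """Objective with weights drawn i.i.d. Uniform(0,1) per component.

    An all-zero draw (numerically impossible in practice, but guarded) is
    resampled.
    """
    if not components:
        raise ValueError("component list must be non-empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    while True:
        w = rng.uniform(0.0, 1.0, size=len(components))
        if np.any(w > 0):
            return ObjectiveSpec(dict(zip(components, w.tolist())))


def robustness_scan(
    net: MetabolicNetwork,
    n: int = 1000,
    seed: int | None = None,
    components=GROWTH_COMPONENTS,
    threshold: float = 0.99,
    exclude_kinds=DEFAULT_EXCLUDE_KINDS,
    objective_factory=None,
) -> RobustnessResult:
    """Target frequency per reaction over ``n`` random objective weightings.

    Realizations whose wild-type problem is infeasible (or has zero optimum)
    are skipped and do not enter the frequency denominator.
    ``objective_factory(rng) -> ObjectiveSpec`` overrides the default
    uniform sampler (useful for reductions to a fixed weighting).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lp = LinearProblem(net)
    counts: dict[str, int] = {
        r: 0 for r in _analyzed_reactions(net, exclude_kinds)
    }
    feasible = 0
    skipped = 0
    for _ in range(n):
        obj = (
            objective_factory(rng)
            if objective_factory is not None
            else random_objective(rng, components)
        )
        try:
            report = single_deletion_screen(
                net, obj, exclude_kinds=exclude_kinds, lp=lp
            )
        except ValueError:
            skipped += 1
            continue
        feasible += 1
        for rid in report.targets:
            counts[rid] += 1
    if feasible == 0:
        raise ValueError("no feasible realization in robustness scan")
    freq = {r: counts[r] / feasible for r in counts}
    return RobustnessResult(
        n_realizations=n,
        n_feasible=feasible,
        seed=seed,
        frequency=freq,
        threshold=threshold,
        skipped=skipped,
    )
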