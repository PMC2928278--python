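"""Synthetic-data generators: growth replicates, toy networks, expression.

These generators stand in for inputs that cannot be shipped with the
repository: replicated absorbance-proxy growth measurements (the wet-lab
crystal-violet design they emulate: five daily time points, six replicates),
small analytically solvable oracle networks for testing the LP machinery,
and a tumor expression matrix with planted high-variability genes for the
variability filter.  Everything is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dfba import GrowthCurve, MeasurementMatrix
from .network import MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "GrowthNoiseModel",
    "ExpressionSimSpec",
    "generate_growth_measurements",
    "make_toy_network",
    "generate_expression_matrix",
]


@dataclass(frozen=True)
class GrowthNoiseModel:
    """Multiplicative measurement noise for replicated density readings.

    Five daily time points with six replicates at ~10% CV emulate a
    plate-based absorbance growth assay.
    """

    n_timepoints: int = 5
    n_replicates: int = 6
    cv: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_timepoints < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")


def generate_growth_measurements(
    curve: GrowthCurve, noise: GrowthNoiseModel = GrowthNoiseModel()
) -> MeasurementMatrix:
    """Sample a growth curve at 24 h intervals with multiplicative noise.

    ``g_ij = X(t_i) * (1 + eps)`` with ``eps ~ Normal(0, cv^2)`` truncated
    below at -0.9 so densities stay positive.
    """
    rng = np.random.default_rng(noise.seed)
    times = 24.0 * np.arange(1, noise.n_timepoints + 1)
    x = curve.density_at(times)
    eps = rng.normal(0.0, noise.cv, size=(noise.n_timepoints, noise.n_replicates))
    eps = np.maximum(eps, -0.9)
    G = x[:, None] * (1.0 + eps)
    return MeasurementMatrix(times=times, G=G)


def _toy(mets: list[str], rxns: list[tuple], name: str) -> MetabolicNetwork:
    metabolites = [Metabolite(id=m, name=m[:-3], compartment="c") for m in mets]
    reactions = [
        Reaction(id=rid, stoich=st, lower_bound=lo, upper_bound=hi, kind=kind)
        for rid, st, lo, hi, kind in rxns
    ]
    return MetabolicNetwork(metabolites, reactions, name=name)


def make_toy_network(kind: str) -> MetabolicNetwork:
    """Small fixtures with analytically known optima and flux geometry.

    chain
        source (<=10) -> A -> B -> sink; unique route: optimum 10, every FVA
        span 0, deleting any interior reaction is lethal.
    parallel
        source (<=10) -> A -> B via two equivalent branches -> sink; branch
        FVA ranges [0, 10]; single branch deletions are neutral, deleting
        both is lethal.
    box
        two uncoupled source->sink chains capped at 10: the flux polytope is
        the square [0,10]^2 (mean (5,5), independent coordinates).
    synthetic_lethal
        like parallel but each branch is a two-step path, so branch pairs
        across routes are synthetically lethal while all singles are neutral.
    """
    if kind == "chain":
        return _toy(
            ["a[c]", "b[c]", "c[c]"],
            [
                ("SRC", {"a[c]": 1.0}, 0, 10, "demand"),
                ("R1", {"a[c]": -1.0, "b[c]": 1.0}, 0, 1000, "internal"),
                ("R2", {"b[c]": -1.0, "c[c]": 1.0}, 0, 1000, "internal"),
                ("SNK", {"c[c]": -1.0}, 0, 1000, "demand"),
            ],
            "toy_chain",
        )
    if kind == "parallel":
        return _toy(
            ["a[c]", "b[c]"],
            [
                ("SRC", {"a[c]": 1.0}, 0, 10, "demand"),
                ("B1", {"a[c]": -1.0, "b[c]": 1.0}, 0, 1000, "internal"),
                ("B2", {"a[c]": -1.0, "b[c]": 1.0}, 0, 1000, "internal"),
                ("SNK", {"b[c]": -1.0}, 0, 1000, "demand"),
            ],
            "toy_parallel",
        )
    if kind == "box":
        return _toy(
            ["a[c]", "b[c]"],
            [
                ("SRC1", {"a[c]": 1.0}, 0, 10, "demand"),
                ("SNK1", {"a[c]": -1.0}, 0, 1000, "demand"),
                ("SRC2", {"b[c]": 1.0}, 0, 10, "demand"),
                ("SNK2", {"b[c]": -1.0}, 0, 1000, "demand"),
            ],
            "toy_box",
        )
    if kind == "synthetic_lethal":
        return _toy(
            ["a[c]", "b1[c]", "b2[c]", "c[c]"],
            [
                ("SRC", {"a[c]": 1.0}, 0, 10, "demand"),
                ("R1A", {"a[c]": -1.0, "b1[c]": 1.0}, 0, 1000, "internal"),
                ("R1B", {"b1[c]": -1.0, "c[c]": 1.0}, 0, 1000, "internal"),
                ("R2A", {"a[c]": -1.0, "b2[c]": 1.0}, 0, 1000, "internal"),
                ("R2B", {"b2[c]": -1.0, "c[c]": 1.0}, 0, 1000, "internal"),
                ("SNK", {"c[c]": -1.0}, 0, 1000, "demand"),
            ],
            "toy_synthetic_lethal",
        )
    raise ValueError(f"unknown toy network kind {kind!r}")


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Design of a synthetic log2 expression matrix with planted signal.

    Background genes are i.i.d. Normal(mu_g, sigma_bg^2) per sample around
    gene-specific baselines; each planted gene receives an additive shift of
    magnitude >= ``effect`` (random sign) in a random subset of samples.
    """

    n_genes: int = 500
    n_samples: int = 33
    n_variable: int = 25
    effect: float = 2.0
    sigma_bg: float = 0.2
    shifted_fraction: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_variable > self.n_genes:
            raise ValueError("n_variable must be <= n_genes")
        if self.n_samples < 3:
            raise ValueError("need at least three samples")
        if not 0 < self.shifted_fraction <= 1:
            raise ValueError("shifted_fraction must be in (0, 1]")


def generate_expression_matrix(
    spec: ExpressionSimSpec = ExpressionSimSpec(),
) -> tuple[np.ndarray, list[int]]:
    """Synthesize a (genes x samples) log2 expression matrix.

    Returns the matrix and the list of planted (truly variable) gene rows.
    """
    rng = np.random.default_rng(spec.seed)
    base = rng.uniform(4.0, 12.0, size=spec.n_genes)
    X = base[:, None] + rng.normal(
        0.0, spec.sigma_bg, size=(spec.n_genes, spec.n_samples)
    )
    planted = sorted(
        rng.choice(spec.n_genes, size=spec.n_variable, replace=False).tolist()
    )
    k = max(1, round(spec.shifted_fraction * spec.n_samples))
    for g in planted:
        cols = rng.choice(spec.n_samples, size=k, replace=False)
        sign = rng.choice([-1.0, 1.0])
        X[g, cols] += sign * spec.effect
    return X, planted
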