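"""Artificial-centering hit-and-run (ACHR) sampling of the flux polytope.

The steady-state flux space ``{v : S v = 0, lb <= v <= ub}`` is a bounded
convex polytope inside the null space of the stoichiometric matrix.  ACHR
explores it with a Markov chain whose step directions are differences
between stored points and the running centroid: because the polytope lives
in an affine subspace, any difference of two feasible points is an exact
null-space direction, so chain iterates stay on ``S v = 0`` by construction
(a periodic re-projection guards against floating-point drift).

Two direction rules are provided: the default, ergodic rule draws a stored
point ``w`` and moves along ``w - x_c`` (the span of stored differences
covers the polytope's affine hull once warm-up includes all coordinate
extrema); the ``centered`` variant moves along ``x_c - y`` from the current
point, which contracts toward the centroid and is kept only for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from .fba import LinearProblem
from .network import MetabolicNetwork

__all__ = [
    "ACHRState",
    "FluxSample",
    "CorrelationResult",
    "generate_warmup",
    "achr_sample",
    "flux_correlation",
]

_FEAS_TOL = 1e-8
_CHORD_TOL = 1e-9


@dataclass
class ACHRState:
    """Warm-up points (columns of ``W``) and the running centroid."""

    net: MetabolicNetwork
    W: np.ndarray          # (n_reactions, n_points)
    x_c: np.ndarray        # centroid of all points seen so far
    n_seen: int            # number of points the centroid averages over

    def __post_init__(self) -> None:
        if self.W.ndim != 2 or self.W.shape[0] != len(self.net.reactions):
            raise ValueError("W must be (n_reactions, n_points)")


@dataclass
class FluxSample:
    """Sampled flux points (rows) with reaction order and chain metadata."""

    points: np.ndarray      # (n_samples, n_reactions)
    reaction_ids: list[str]
    seed: int | None
    thin: int
    direction_rule: str

    def column(self, rid: str) -> np.ndarray:
        try:
            j = self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"reaction {rid!r} not in sample") from None
        return self.points[:, j]


def generate_warmup(
    net: MetabolicNetwork,
    n_warmup: int | None = None,
    seed: int | None = None,
) -> ACHRState:
    """Warm-up points by optimizing coordinate and random objectives.

    Always includes the per-reaction minimum and maximum vertices
    (2·n_reactions points, the coordinate extrema that span the polytope's
    affine hull); if ``n_warmup`` exceeds that, the remainder come from
    random +/-1 objective vectors.  Raises if the polytope is empty.
    """
    lp = LinearProblem(net)
    n = len(lp.rids)
    n_warmup = 2 * n if n_warmup is None else n_warmup
    rng = np.random.default_rng(seed)
    points = []
    e = np.zeros(n)
    for j in range(n):
        e[j] = 1.0
        for sense in ("maximize", "minimize"):
            status, _, x = getattr(lp, sense)(e)
            if status != "optimal":
                raise ValueError(
                    f"empty or unbounded flux polytope ({status} while "
                    f"optimizing {lp.rids[j]})"
                )
            points.append(x)
        e[j] = 0.0
    while len(points) < n_warmup:
        c = rng.choice([-1.0, 1.0], size=n) * rng.uniform(0, 1, size=n)
        status, _, x = lp.maximize(c)
        if status == "optimal":
            points.append(x)
    W = np.array(points[:max(n_warmup, 2 * n)]).T
    x_c = W.mean(axis=1)
    return ACHRState(net=net, W=W, x_c=x_c, n_seen=W.shape[1])


def _chord(y: np.ndarray, d: np.ndarray, lb: np.ndarray, ub: np.ndarray):
    """Feasible interval [lo, hi] for y + t d within the box bounds."""
    lo, hi = -np.inf, np.inf
    mask = np.abs(d) > _CHORD_TOL
    if not mask.any():
        return 0.0, 0.0
    dm = d[mask]
    span_lo = (lb[mask] - y[mask]) / dm
    span_hi = (ub[mask] - y[mask]) / dm
    t_lo = np.minimum(span_lo, span_hi)
    t_hi = np.maximum(span_lo, span_hi)
    lo = t_lo.max()
    hi = t_hi.min()
    return lo, hi


def achr_sample(
    state: ACHRState,
    n: int = 10000,
    seed: int | None = None,
    thin: int = 100,
    direction_rule: str = "mixed",
) -> FluxSample:
    """Run the sampling chain and return ``n`` (thinned) sample points.

    direction_rule:
        'mixed'    alternate (stored warm-up point - centroid) directions
                   with isotropic null-space directions, keeping the stored
                   set and centroid fixed: a time-homogeneous hit-and-run
                   chain whose stationary distribution is exactly uniform on
                   the polytope  [default]
        'adaptive' classic artificial centering: the accepted point replaces
                   the chosen stored point and the centroid is re-averaged
                   (approximately uniform; kept for comparison)
        'centered' the literal centering rule, moving along
                   (centroid - current point); contracts toward the centroid
                   and is not ergodic on its own

    If the chord degenerates repeatedly (point polytope), the sampler falls
    back to returning copies of the single feasible point with a warning.
    """
    if direction_rule not in ("mixed", "adaptive", "centered"):
        raise ValueError(f"unknown direction rule {direction_rule!r}")
    net = state.net
    lb, ub = net.bounds
    rng = np.random.default_rng(seed)
    W = state.W.copy()
    x_c = state.x_c.copy()
    n_seen = state.n_seen
    y = x_c.copy()

    # affine-subspace basis for periodic drift re-projection
    N = null_space(net.S)
    y0 = W[:, 0].copy()

    samples = np.empty((n, len(y)))
    collected = 0
    steps = 0
    degenerate_streak = 0
    max_steps = 50 * n * thin + 1000
    while collected < n and steps < max_steps:
        steps += 1
        k = rng.integers(W.shape[1])
        if direction_rule == "centered":
            d = x_c - y
        elif steps % 2 == 0:
            # centroid-anchored directions accelerate long moves along the
            # polytope's principal axes
            d = W[:, k] - x_c
        else:
            # isotropic null-space directions give the classical hit-and-run
            # uniformity guarantee
            d = rng.standard_normal(W.shape[0])
        # project onto ker(S): normalizing a near-zero difference would
        # otherwise amplify off-null rounding noise into real drift
        d = N @ (N.T @ d)
        norm = np.linalg.norm(d)
        if norm < 1e-7:
            degenerate_streak += 1
            if degenerate_streak > 100:
                break
            continue
        d = d / norm
        t_lo, t_hi = _chord(y, d, lb, ub)
        if not np.isfinite(t_lo) or not np.isfinite(t_hi) or t_hi - t_lo < _CHORD_TOL:
            degenerate_streak += 1
            if degenerate_streak > 100:
                break
            continue
        degenerate_streak = 0
        y = y + rng.uniform(t_lo, t_hi) * d
        if direction_rule in ("adaptive", "centered"):
            # artificial centering: the new point replaces the chosen stored
            # point and the running centroid is re-averaged (this adaptation
            # is what makes the classic scheme only approximately uniform)
            W[:, k] = y
            x_c = (n_seen * x_c + y) / (n_seen + 1)
            n_seen += 1
        if steps % 500 == 0:
            # guard against accumulated drift out of the null space
            y = y0 + N @ (N.T @ (y - y0))
        if steps % thin == 0:
            samples[collected] = y
            collected += 1

    if collected < n:
        warnings.warn(
            "flux polytope is degenerate (zero-volume); returning the "
            "single feasible point",
            RuntimeWarning,
            stacklevel=2,
        )
        samples[collected:] = y
    return FluxSample(
        points=samples,
        reaction_ids=list(net.reaction_ids),
        seed=seed,
        thin=thin,
        direction_rule=direction_rule,
    )


@dataclass
class CorrelationResult:
    reaction_a: str
    reaction_b: str
    r: float
    ci95: tuple[float, float]
    n: int
    defined: bool

    def __bool__(self) -> bool:  # truthy only when the correlation exists
        return self.defined


def flux_correlation(sample: FluxSample, rid_a: str, rid_b: str) -> CorrelationResult:
    """Pearson correlation between two sampled fluxes, with Fisher-z 95% CI.

    A zero-variance flux yields ``defined=False`` rather than NaN.
    """
    a = sample.column(rid_a)
    b = sample.column(rid_b)
    n = len(a)
    if np.std(a) < 1e-12 or np.std(b) < 1e-12 or n < 4:
        return CorrelationResult(rid_a, rid_b, float("nan"), (float("nan"),) * 2, n, False)
    r = float(np.corrcoef(a, b)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) >= 1.0:
        return CorrelationResult(rid_a, rid_b, r, (r, r), n, True)
    z = np.arctanh(r)
    half = 1.959963984540054 / np.sqrt(n - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    return CorrelationResult(rid_a, rid_b, r, (float(lo), float(hi)), n, True)
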