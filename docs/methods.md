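# Methods

## The model

The package analyzes a compartmentalized core reconstruction of cancer-cell
metabolism: glycolysis, the pentose phosphate pathway (PPP), the TCA cycle,
a lumped oxidative-phosphorylation chain, and glutaminolysis, across the
external environment `[e]`, cytosol `[c]` and mitochondrion `[m]` —
80 reactions over 66 metabolites. All flux analysis is constraint-based:
steady-state flux vectors satisfy `S v = 0` with per-reaction capacity
bounds `lb ≤ v ≤ ub` (mmol·gDW⁻¹·h⁻¹ convention), and FBA maximizes a
linear growth surrogate `c·v`.

### The growth surrogate

There is no calibrated biomass equation. Growth is represented by a
weighted sum of eight *demand* fluxes of growth-supporting metabolites:
lactate secretion, cytosolic and mitochondrial ATP turnover, ribose
5-phosphate, NADPH turnover, NAD⁺ regeneration, oxaloacetate, and cytosolic
citrate. Two weightings ship with the package: the **equimolar** objective
(all weights 1) used for the screens, and a **tuned** coefficient set
(`c_ATP[c]`=12.47, `c_lac`=0.13, `c_NADPH`=0.93, `c_r5p`=0.6, `c_NAD`=0.89,
`c_OAA`=0.75, `c_ATP[m]`=17.09, `c_cit`=0.55) used for the pyruvate-kinase
and pyruvate-dehydrogenase phase planes.

### Viability minima

Each growth demand carries a small positive lower bound — an obligatory
maintenance production (lactate 1.0, cytosolic ATP 1.0, mitochondrial ATP
0.2, r5p 0.2, NADPH 0.1, NAD⁺ 0.05, citrate 0.1; oxaloacetate 0). These
minima are the load-bearing modeling choice for the essentiality screen: a
deletion that makes any single requirement unreachable renders the LP
infeasible and is scored as total growth loss, *independently of the
objective weights*. This is why the core target set is robust in ~100% of
random objective weightings: lethality is a property of the network
topology plus the viability requirements, not of any particular weighting.
Demand upper bounds (12 for the carbon demands, 0.5 for NADPH, hypoxic 0.5
for the oxygen source) keep any single component from dominating the
surrogate and enforce the Warburg regime (glycolytic ATP ≫ oxidative ATP).

### Key curation choices

* **Hypoxia**: the oxygen source is capped at 0.5; the electron chain is
  lumped into complex I plus a combined CIII/CIV/ATP-synthase step at
  P/O 2.5 (proton-motive-force bookkeeping is out of scope).
* **Glutaminolysis** enters as a capped external 2-oxoglutarate source
  (0.3), the sole anaplerotic input — there is no pyruvate carboxylase, so
  mitochondrial malate dehydrogenase and the 2-oxoglutarate source itself
  are essential (glutamine addiction).
* **Redox valves**: bounded mitochondrial NADH/NAD⁺ sinks let the TCA cycle
  turn under hypoxia; the cytosolic glycerol-3-phosphate shuttle provides
  O₂-capped, LDH-independent NADH oxidation. The shuttle is what gives
  pyruvate dehydrogenase head-room above its optimum in the phase planes.
* **Isoform redundancy**: glucose (GLUT1/GLUT3) and lactate (MCT1/MCT4)
  each enter through duplicated transporters, so plasma-membrane transport
  steps are not spurious screen hits.
* **Reversibles** carry signed bounds; they are never split into
  forward/backward pairs.
* Each reaction's `note` field records its provenance: `pathway`
  (diagram-derived core chemistry), `biochem` (standard human
  central-metabolism steps used to complete a pathway), `boundary`
  (environment/maintenance pseudo-reactions).

## Target screening

`single_deletion_screen` combines two criteria over the analyzed set
(everything except exchange and sink pseudo-reactions):

* **essential**: deleted-over-wild-type objective ratio ≤ 0.5 (infeasible
  deletions count as 0);
* **low variability**: FVA span at 100% of the optimum ≤ 0.5 × the maximal
  span over the analyzed set.

A *target* satisfies both. The target fraction is reported against both
the complete 80-reaction reconstruction (22/80 = 27.5%) and the analyzed
set. Deletion ratios are clamped to [0, 1]: deleting a demand also removes
its maintenance minimum, which can relax the LP slightly (observed +0.3%
for the citrate demand); monotonicity of deletion therefore holds exactly
for every reaction whose bounds straddle zero (true flux restrictions) and
is tested on that set.

`robustness_scan` repeats the screen under objectives with components drawn
i.i.d. Uniform(0,1) (an all-zero draw is resampled; infeasible realizations
are skipped and excluded from the frequency denominator). The wording in
the source literature for this distribution is ambiguous ("from 0 to 1
around values estimated for other organisms"); plain Uniform(0,1) is used.

## Dynamic batch growth

The quasi-steady-state loop per step Δt (default 1 h): scale the medium
glucose to a specific availability `s_c = s_av/(X·Δt)`; cap the glucose
supply flux at `s_c` and solve FBA; convert the surrogate optimum to a
specific growth rate `mu = kappa·(c·v)`; advance `dX/dt = mu X`,
`dS/dt = -S_u X` analytically within the step (explicit Euler available for
cross-checks); shorten the final step to exact glucose exhaustion and stop
(the culture plateaus). `kappa` (default 0.0015 h⁻¹ per flux unit), X0
(0.005) and S0 (20 mmol·L⁻¹) are free parameters chosen so the default run
grows for ~3 days inside a 5-day observation window; all comparisons are
made on min-max normalized curves, in which `kappa` cancels.

In the batch medium the maintenance minima are dropped (a starved culture
stops growing rather than dying instantly; the glucose-free model must
admit the all-zero flux state) and the non-glucose source demands
(2-oxoglutarate, acetyl-CoA, O₂, ADP) are closed, making glucose the sole
dynamic substrate — consistent with terminating at glucose exhaustion.

`fit_growth_rate` estimates the exponential rate by OLS on log mean density
versus time over the pre-plateau window (trailing points whose log
increment falls below 10% of the median early increment are trimmed).
At the synthetic design's 10% replicate CV, the fitted rate lands within
15% of a known exponential truth in ≥95% of seeds.

## Flux sampling

The steady-state polytope is sampled by hit-and-run. Warm-up points are
the per-reaction minimum/maximum vertices (2n LP solves). The default
chain alternates directions of two kinds — (stored warm-up point −
centroid), which produces long moves along the polytope's principal axes,
and isotropic directions in `ker(S)` — while keeping the stored set and
centroid fixed. This chain is time-homogeneous with a provably uniform
stationary distribution; the classic adaptive artificial-centering update
(replace the stored point, re-average the centroid) is available as
`direction_rule="adaptive"` but is measurably non-uniform on a box
(χ² ≈ 70–130 versus a critical value of 20 at n=4000), and the literal
centroid-seeking rule (`"centered"`) contracts and is kept only for
comparison. Every direction is projected onto `ker(S)` before normalization
(normalizing a near-zero stored-point difference would otherwise amplify
rounding noise into constraint drift), iterates are re-projected onto the
affine subspace every 500 steps, and default thinning keeps every 100th
step. Degenerate (zero-volume) polytopes fall back to the single feasible
point with a warning.

## Phase planes

`compute_phase_plane` pins two reaction fluxes on a grid (equality
constraints by default; an upper-bound mode exists, under which the surface
is monotone in each axis) and re-optimizes per cell. Infeasible cells carry
NaN, never 0, so they cannot masquerade as thresholds. `detect_threshold`
reports the grid point at which the discrete slope of a slice changes sign
(relative tolerance 1e-6 of the slice's scale). In the core network the
pyruvate-dehydrogenase slice at fixed sub-saturating glucose rises to an
interior optimum where the hypoxic O₂ budget saturates and falls beyond
it — the two-region structure in which *reducing* oxidation first improves
and then collapses the growth surrogate.

## Synthetic data

* **Growth replicates**: the curve is sampled every 24 h (5 time points,
  6 replicates) with multiplicative Normal(0, cv²) noise (default cv=0.1,
  truncated at −0.9). This emulates plate-absorbance proxies of cell
  density: constant relative error, no plate/edge effects, no
  between-day drift — passing tests therefore validate the pipeline's
  statistics, not any specific instrument.
* **Toy networks** (`chain`, `parallel`, `box`, `synthetic_lethal`) have
  closed-form optima, FVA ranges and polytope geometry and serve as
  oracles for the LP, screen and sampler tests.
* **Expression panels**: 500 genes × 33 samples in log2 space, background
  Normal(base_g, 0.2²); each of 25 planted genes receives a ±2.0 shift in a
  random 30% of samples. Real tumor panels have correlated genes and
  batch structure; the generator does not emulate those, so filter results
  on it demonstrate calibration under independence only.

## Expression-variability filter

Per gene: deviations from the across-sample mean; the reported log-ratio
statistic is the maximal absolute deviation; significance comes from a
variance test of the gene's sample variance against the 20%-trimmed-mean
background variance pooled over genes (`(n−1)s²/σ₀² ~ χ²(n−1)` under the
null), with a one-sample-t-on-absolute-deviations variant for comparison.
A gene is flagged when log-ratio > 1.2 *and* p < 0.01, reported raw with no
multiple-testing correction. Constant genes get p = 1. Log base 2 is
assumed throughout (expression-array convention).

## Numerical choices

* LP solves use the HiGHS interface in scipy (`method="highs"`); screens
  reuse a cached matrix/bounds structure (~200 LP solves per screen
  realization, ~0.6 s). Feasibility is asserted at 1e-9 (scaled) in tests;
  sampler feasibility at 1e-8.
* FBA optima are generically degenerate; any optimal vertex is reported and
  no downstream analysis depends on which one the solver returns (FVA and
  sampling characterize the whole optimal set / polytope instead).
* Infeasible and unbounded solves are *statuses*, not exceptions, so
  deletion screens never abort.
* Default problem sizes: robustness scans run 200 random objectives
  (`analysis/04_robustness.py --n 1000` for the full-size scan); flux
  samples default to 10,000 points.

## Known limitations

* The reconstruction is a core model: no fatty-acid synthesis (cytosolic
  citrate exits through a demand rather than ATP-citrate lyase), no
  malate–aspartate shuttle, no proton-motive coupling, no gene–protein–
  reaction rules (the screen is over reactions, not genes).
* The 27.5% target fraction is sensitive to curation: it counts 22
  structurally forced reactions out of 80, and small changes to the
  boundary caps move individual borderline reactions in or out.
* Absolute growth rates are not calibrated — only normalized curve shapes
  are comparable to measurements.
* The sampled flux space uses the screening bounds (including viability
  minima); sampling under relaxed bounds will broaden marginals but, in
  this network, preserves the strong glycolytic flux coupling.
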