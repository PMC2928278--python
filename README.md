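# warburg — constraint-based analysis of core cancer metabolism

Cancer cells famously prefer glycolytic lactate production over oxidative
phosphorylation for ATP generation even when oxygen is available (the
Warburg effect). This package asks what that preference, and its weak
points, look like at the level of network stoichiometry: it builds a
curated core reconstruction of tumor metabolism — glycolysis, pentose
phosphate pathway, TCA cycle, oxidative phosphorylation and glutaminolysis
across external/cytosolic/mitochondrial compartments (80 reactions,
66 metabolites) — and analyzes it with the standard constraint-based
toolkit, implemented here from the linear program up:

* **FBA** with a multi-metabolite growth surrogate: maximize `c·v` subject
  to `S v = 0`, `lb ≤ v ≤ ub`, where the objective weights demand fluxes of
  lactate, ATP (cytosolic and mitochondrial), ribose 5-phosphate, NADPH,
  NAD⁺, oxaloacetate and citrate;
* **dynamic FBA** batch growth (`dX/dt = μX`, `dS/dt = −S_u X` with μ from
  a per-step FBA solve), compared to replicated growth measurements on
  min-max normalized curves;
* a **drug-target screen** combining flux-variability analysis (FVA) and
  single-reaction deletion essentiality at 50%/50% thresholds, plus a
  robustness scan over random objective weightings;
* **hit-and-run sampling** of the steady-state flux polytope and flux–flux
  correlations;
* **phenotypic phase planes** (objective surface over paired flux
  constraints) with slope-sign threshold detection;
* a per-gene **expression-variability filter** for tumor sample panels,
  with a synthetic-data module generating every input the pipeline needs.

Intended users: systems-biology researchers and students who want a small,
fully tested, self-contained cancer-metabolism model whose headline
behaviors (essential enzyme set, synthetic lethality in the pentose
phosphate pathway, hypoxia-limited oxidation thresholds) are reproducible
from first principles.

## Worked example

```python
from warburg import build_cancer_core_network, equimolar_objective, solve_fba
from warburg.screen import single_deletion_screen, double_deletion

net = build_cancer_core_network()        # 80 reactions, 66 metabolites
obj = equimolar_objective(net)           # unit weight on 8 growth demands

sol = solve_fba(net, obj)
print(round(sol.objective_value, 4))     # 31.5312
print(round(sol.fluxes["DM_lac_e"], 1),  # 12.0  lactate at its cap
      round(sol.fluxes["DM_o2_c"], 1))   # 0.5   hypoxic oxygen ceiling

report = single_deletion_screen(net, obj)
print(len(report.targets),                              # 22
      round(100 * report.target_fraction_total, 1))     # 27.5  (% of 80)
print(sorted(report.targets)[:5])  # ['AKGDm', 'CITtcm', 'CSm', 'DM_akg_m', 'DM_glc_e']

# pentose-phosphate branches: harmless alone, lethal together
print(round(report.growth_ratio["G6PDH"], 3),   # 0.991
      round(report.growth_ratio["TKT1"], 3),    # 0.913
      double_deletion(net, obj, ("G6PDH", "TKT1")))  # 0.0
```

The screen flags 22 of 80 reactions (27.5%) as joint low-variability /
high-essentiality targets, including the glycolytic backbone (GAPD, PGMT,
ENO, PYK, TPI, LDH), ribose-5-phosphate isomerase, and the TCA enzymes
(PDHm, CSm, AKGDm, SUCOAS, SUCD1m, FUMm, MDHm). Deleting either entry of
the pentose phosphate pathway is nearly harmless — the other branch still
supplies ribose 5-phosphate — but deleting both abolishes growth.

The numbered drivers under `analysis/` run the full study and write tables
under `results/`:

```bash
python analysis/01_build_network.py      # serialize the reconstruction
python analysis/02_growth_kinetics.py    # batch growth vs synthetic replicates
python analysis/03_target_screen.py      # FVA + deletion screen
python analysis/04_robustness.py         # random-objective robustness (--n 1000)
python analysis/05_ldh_and_ppp.py        # LDH sweeps, sampling correlation, PPP
python analysis/06_phase_planes.py       # PDHm / FUMm / SUCD1m / PYK surfaces
python analysis/07_expression_variability.py
```

## Layout

```
src/warburg/        library: network model + SBML/TSV I/O, cancer-core
                    fixture, FBA, dynamic FBA, screens, sampling, phase
                    planes, synthetic data, expression filter
analysis/           numbered study drivers (write results/)
tests/              pytest suite incl. end-to-end acceptance checks
scripts/            acceptance.py
docs/methods.md     model assumptions, parameters, numerical choices
```
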