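"""Curated core metabolic network of a proliferating cancer cell.

The fixture couples the five pathways with the strongest experimental support
in tumor metabolism — glycolysis, the pentose phosphate pathway (PPP), the
TCA cycle, oxidative phosphorylation and glutaminolysis — across three
compartments (external ``[e]``, cytosol ``[c]``, mitochondrion ``[m]``), with
transport reactions, boundary sinks for cofactor pools and demand reactions
that stand in for the metabolic requirements of biomass production.

Curation conventions
--------------------
* 66 metabolites, 80 reactions.  Reversibles carry signed bounds rather than
  being split into forward/backward pairs.
* Flux unit convention: mmol·gDW⁻¹·h⁻¹.
* The growth surrogate is the set of eight demand fluxes in
  :data:`warburg.fba.GROWTH_COMPONENTS`.  Each growth demand carries a small
  positive lower bound — an obligatory maintenance production for viability —
  so that a deletion that makes any single requirement unreachable is lethal
  (infeasible) rather than merely sub-optimal.  Demand upper bounds keep any
  single component from dominating the surrogate.
* Hypoxia: the oxygen source is capped low (0.5 by default), so ATP comes
  predominantly from glycolysis (Warburg regime).
* Glutamine consumption is represented by an external 2-oxoglutarate source
  feeding the TCA cycle, with mitochondrial malic enzyme closing the
  glutaminolysis-to-lactate route.
* Each reaction's ``note`` records its provenance: ``pathway`` (diagram-
  derived core chemistry), ``biochem`` (standard human central-metabolism
  stoichiometry used to complete the pathway), or ``boundary`` (environment
  / maintenance pseudo-reaction).
"""

from __future__ import annotations

from .network import MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "build_cancer_core_network",
    "GLUCOSE_SUPPLY",
    "GLUCOSE_TRANSPORTERS",
    "DEFAULT_OXYGEN_BOUND",
]

#: reaction id of the plasma glucose source; dynamic batch simulation caps it
GLUCOSE_SUPPLY = "DM_glc_e"
GLUCOSE_TRANSPORTERS = ("GLCt", "GLCt2")
DEFAULT_OXYGEN_BOUND = 0.5  # hypoxic oxygen supply cap, mmol·gDW⁻¹·h⁻¹

_BIG = 1000.0
_T = 100.0  # generic transporter capacity

# (id, name, compartment)
_METABOLITES = [
    # external environment
    ("glc[e]", "D-glucose", "e"),
    ("lac[e]", "L-lactate", "e"),
    ("co2[e]", "carbon dioxide", "e"),
    ("h2o[e]", "water", "e"),
    # cytosol: glycolysis intermediates
    ("glc[c]", "D-glucose", "c"),
    ("g6p[c]", "glucose 6-phosphate", "c"),
    ("f6p[c]", "fructose 6-phosphate", "c"),
    ("fdp[c]", "fructose 1,6-bisphosphate", "c"),
    ("dhap[c]", "dihydroxyacetone phosphate", "c"),
    ("g3p[c]", "glyceraldehyde 3-phosphate", "c"),
    ("13dpg[c]", "1,3-bisphosphoglycerate", "c"),
    ("3pg[c]", "3-phosphoglycerate", "c"),
    ("2pg[c]", "2-phosphoglycerate", "c"),
    ("pep[c]", "phosphoenolpyruvate", "c"),
    ("pyr[c]", "pyruvate", "c"),
    ("lac[c]", "L-lactate", "c"),
    ("glyc3p[c]", "glycerol 3-phosphate", "c"),
    # cytosol: energy and redox cofactors
    ("atp[c]", "ATP", "c"),
    ("adp[c]", "ADP", "c"),
    ("amp[c]", "AMP", "c"),
    ("pi[c]", "orthophosphate", "c"),
    ("h[c]", "proton", "c"),
    ("h2o[c]", "water", "c"),
    ("co2[c]", "carbon dioxide", "c"),
    ("o2[c]", "oxygen", "c"),
    ("nad[c]", "NAD+", "c"),
    ("nadh[c]", "NADH", "c"),
    ("nadp[c]", "NADP+", "c"),
    ("nadph[c]", "NADPH", "c"),
    # cytosol: pentose phosphate intermediates
    ("6pgl[c]", "6-phosphogluconolactone", "c"),
    ("6pgc[c]", "6-phosphogluconate", "c"),
    ("ru5p[c]", "ribulose 5-phosphate", "c"),
    ("r5p[c]", "ribose 5-phosphate", "c"),
    ("xu5p[c]", "xylulose 5-phosphate", "c"),
    ("s7p[c]", "sedoheptulose 7-phosphate", "c"),
    ("e4p[c]", "erythrose 4-phosphate", "c"),
    # cytosol: TCA-derived carbon skeletons
    ("cit[c]", "citrate", "c"),
    ("oaa[c]", "oxaloacetate", "c"),
    ("mal[c]", "L-malate", "c"),
    # mitochondrion: carbon skeletons
    ("pyr[m]", "pyruvate", "m"),
    ("accoa[m]", "acetyl-CoA", "m"),
    ("coa[m]", "coenzyme A", "m"),
    ("cit[m]", "citrate", "m"),
    ("icit[m]", "isocitrate", "m"),
    ("akg[m]", "2-oxoglutarate", "m"),
    ("succoa[m]", "succinyl-CoA", "m"),
    ("succ[m]", "succinate", "m"),
    ("fum[m]", "fumarate", "m"),
    ("mal[m]", "L-malate", "m"),
    ("oaa[m]", "oxaloacetate", "m"),
    # mitochondrion: cofactors
    ("nad[m]", "NAD+", "m"),
    ("nadh[m]", "NADH", "m"),
    ("fad[m]", "FAD", "m"),
    ("fadh2[m]", "FADH2", "m"),
    ("nadp[m]", "NADP+", "m"),
    ("nadph[m]", "NADPH", "m"),
    ("atp[m]", "ATP", "m"),
    ("adp[m]", "ADP", "m"),
    ("amp[m]", "AMP", "m"),
    ("pi[m]", "orthophosphate", "m"),
    ("h[m]", "proton", "m"),
    ("h2o[m]", "water", "m"),
    ("co2[m]", "carbon dioxide", "m"),
    ("o2[m]", "oxygen", "m"),
    ("q10[m]", "ubiquinone", "m"),
    ("q10h2[m]", "ubiquinol", "m"),
]

# (id, name, stoich, lb, ub, kind, note)
_REACTIONS = [
    # ---------------- glycolysis (cytosol) --------------------------------
    ("HEX1", "hexokinase",
     {"glc[c]": -1, "atp[c]": -1, "g6p[c]": 1, "adp[c]": 1, "h[c]": 1},
     0, _BIG, "internal", "pathway"),
    ("PGI", "glucose-6-phosphate isomerase",
     {"g6p[c]": -1, "f6p[c]": 1}, -_BIG, _BIG, "internal", "pathway"),
    ("PFK", "phosphofructokinase",
     {"f6p[c]": -1, "atp[c]": -1, "fdp[c]": 1, "adp[c]": 1, "h[c]": 1},
     0, _BIG, "internal", "pathway"),
    ("FBP", "fructose-1,6-bisphosphatase",
     {"fdp[c]": -1, "h2o[c]": -1, "f6p[c]": 1, "pi[c]": 1},
     0, _BIG, "internal", "biochem"),
    ("FBA", "fructose-bisphosphate aldolase",
     {"fdp[c]": -1, "dhap[c]": 1, "g3p[c]": 1}, -_BIG, _BIG, "internal", "pathway"),
    ("TPI", "triose-phosphate isomerase",
     {"dhap[c]": -1, "g3p[c]": 1}, -_BIG, _BIG, "internal", "pathway"),
    ("GAPD", "glyceraldehyde-3-phosphate dehydrogenase",
     {"g3p[c]": -1, "nad[c]": -1, "pi[c]": -1,
      "13dpg[c]": 1, "nadh[c]": 1, "h[c]": 1},
     -_BIG, _BIG, "internal", "pathway"),
    ("PGK", "phosphoglycerate kinase",
     {"13dpg[c]": -1, "adp[c]": -1, "3pg[c]": 1, "atp[c]": 1},
     -_BIG, _BIG, "internal", "pathway"),
    ("PGMT", "phosphoglucomutase (glycolytic mutase step)",
     {"3pg[c]": -1, "2pg[c]": 1}, -_BIG, _BIG, "internal", "pathway"),
    ("ENO", "enolase",
     {"2pg[c]": -1, "pep[c]": 1, "h2o[c]": 1}, -_BIG, _BIG, "internal", "pathway"),
    ("PYK", "pyruvate kinase",
     {"pep[c]": -1, "adp[c]": -1, "h[c]": -1, "pyr[c]": 1, "atp[c]": 1},
     0, _BIG, "internal", "pathway"),
    ("LDH", "lactate dehydrogenase",
     {"pyr[c]": -1, "nadh[c]": -1, "h[c]": -1, "lac[c]": 1, "nad[c]": 1},
     -_BIG, _BIG, "internal", "pathway"),
    ("ADK1", "adenylate kinase",
     {"amp[c]": -1, "atp[c]": -1, "adp[c]": 2}, -_BIG, _BIG, "internal", "biochem"),
    # ---------------- pentose phosphate pathway ---------------------------
    ("G6PDH", "glucose-6-phosphate dehydrogenase",
     {"g6p[c]": -1, "nadp[c]": -1, "6pgl[c]": 1, "nadph[c]": 1, "h[c]": 1},
     0, _BIG, "internal", "pathway"),
    ("PGL", "6-phosphogluconolactonase",
     {"6pgl[c]": -1, "h2o[c]": -1, "6pgc[c]": 1, "h[c]": 1},
     0, _BIG, "internal", "biochem"),
    ("GND", "6-phosphogluconate dehydrogenase",
     {"6pgc[c]": -1, "nadp[c]": -1, "ru5p[c]": 1, "co2[c]": 1, "nadph[c]": 1},
     0, _BIG, "internal", "pathway"),
    ("RPI", "ribose-5-phosphate isomerase",
     {"ru5p[c]": -1, "r5p[c]": 1}, -_BIG, _BIG, "internal", "pathway"),
    ("RPE", "ribulose-5-phosphate 3-epimerase",
     {"ru5p[c]": -1, "xu5p[c]": 1}, -_BIG, _BIG, "internal", "biochem"),
    ("TKT1", "transketolase 1",
     {"xu5p[c]": -1, "r5p[c]": -1, "s7p[c]": 1, "g3p[c]": 1},
     -_BIG, _BIG, "internal", "pathway"),
    ("TALA", "transaldolase",
     {"s7p[c]": -1, "g3p[c]": -1, "e4p[c]": 1, "f6p[c]": 1},
     -_BIG, _BIG, "internal", "biochem"),
    ("TKT2", "transketolase 2",
     {"xu5p[c]": -1, "e4p[c]": -1, "f6p[c]": 1, "g3p[c]": 1},
     -_BIG, _BIG, "internal", "biochem"),
    # ---------------- TCA cycle and anaplerosis (mitochondrion) -----------
    ("PDHm", "pyruvate dehydrogenase",
     {"pyr[m]": -1, "coa[m]": -1, "nad[m]": -1,
      "accoa[m]": 1, "co2[m]": 1, "nadh[m]": 1},
     0, _BIG, "internal", "pathway"),
    ("CSm", "citrate synthase",
     {"accoa[m]": -1, "oaa[m]": -1, "h2o[m]": -1,
      "cit[m]": 1, "coa[m]": 1, "h[m]": 1},
     0, _BIG, "internal", "pathway"),
    ("ACONTm", "aconitase",
     {"cit[m]": -1, "icit[m]": 1}, -_BIG, _BIG, "internal", "pathway"),
    ("ICDHxm", "isocitrate dehydrogenase (NAD)",
     {"icit[m]": -1, "nad[m]": -1, "akg[m]": 1, "co2[m]": 1, "nadh[m]": 1},
     0, _BIG, "internal", "pathway"),
    ("ICDHym", "isocitrate dehydrogenase (NADP)",
     {"icit[m]": -1, "nadp[m]": -1, "akg[m]": 1, "co2[m]": 1, "nadph[m]": 1},
     0, _BIG, "internal", "biochem"),
    ("AKGDm", "2-oxoglutarate dehydrogenase",
     {"akg[m]": -1, "coa[m]": -1, "nad[m]": -1,
      "succoa[m]": 1, "co2[m]": 1, "nadh[m]": 1},
     0, _BIG, "internal", "pathway"),
    ("SUCOAS", "succinyl-CoA synthetase",
     {"succoa[m]": -1, "adp[m]": -1, "pi[m]": -1,
      "succ[m]": 1, "atp[m]": 1, "coa[m]": 1},
     -_BIG, _BIG, "internal", "pathway"),
    ("SUCD1m", "succinate dehydrogenase",
     {"succ[m]": -1, "fad[m]": -1, "fum[m]": 1, "fadh2[m]": 1},
     0, _BIG, "internal", "pathway"),
    ("FUMm", "fumarate hydratase",
     {"fum[m]": -1, "h2o[m]": -1, "mal[m]": 1}, -_BIG, _BIG, "internal", "pathway"),
    ("MDHm", "malate dehydrogenase (mitochondrial)",
     {"mal[m]": -1, "nad[m]": -1, "oaa[m]": 1, "nadh[m]": 1, "h[m]": 1},
     -_BIG, _BIG, "internal", "pathway"),
    ("ME2m", "malic enzyme (NAD, mitochondrial)",
     {"mal[m]": -1, "nad[m]": -1, "pyr[m]": 1, "co2[m]": 1, "nadh[m]": 1},
     0, _BIG, "internal", "pathway"),
    # ---------------- oxidative phosphorylation ---------------------------
    ("NADH2q", "NADH dehydrogenase (complex I)",
     {"nadh[m]": -1, "h[m]": -1, "q10[m]": -1, "nad[m]": 1, "q10h2[m]": 1},
     0, _BIG, "internal", "pathway"),
    ("CYOOm", "ubiquinol oxidase + ATP synthase (lumped, P/O 2.5)",
     {"q10h2[m]": -1, "o2[m]": -0.5, "adp[m]": -2.5, "pi[m]": -2.5,
      "q10[m]": 1, "h2o[m]": 1, "atp[m]": 2.5},
     0, _BIG, "internal", "pathway"),
    # ---------------- cytosolic TCA-adjacent chemistry --------------------
    ("ME1", "malic enzyme (NADP, cytosolic)",
     {"mal[c]": -1, "nadp[c]": -1, "pyr[c]": 1, "co2[c]": 1, "nadph[c]": 1},
     0, _BIG, "internal", "pathway"),
    ("G3PD1", "glycerol-3-phosphate dehydrogenase (cytosolic)",
     {"dhap[c]": -1, "nadh[c]": -1, "h[c]": -1, "glyc3p[c]": 1, "nad[c]": 1},
     0, _BIG, "internal", "biochem"),
    ("G3PD2", "glycerol-3-phosphate dehydrogenase (mitochondrial, quinone-linked)",
     {"glyc3p[c]": -1, "q10[m]": -1, "dhap[c]": 1, "q10h2[m]": 1},
     0, _BIG, "internal", "biochem"),
    ("MDH", "malate dehydrogenase (cytosolic)",
     {"mal[c]": -1, "nad[c]": -1, "oaa[c]": 1, "nadh[c]": 1, "h[c]": 1},
     -_BIG, _BIG, "internal", "pathway"),
    ("ADK1m", "adenylate kinase (mitochondrial)",
     {"amp[m]": -1, "atp[m]": -1, "adp[m]": 2}, -_BIG, _BIG, "internal", "biochem"),
    # ---------------- transport -------------------------------------------
    ("GLCt", "glucose transport (GLUT1)",
     {"glc[e]": -1, "glc[c]": 1}, 0, _T, "transport", "pathway"),
    ("GLCt2", "glucose transport (GLUT3 isoform)",
     {"glc[e]": -1, "glc[c]": 1}, 0, _T, "transport", "biochem"),
    ("LACt", "lactate transport (MCT1)",
     {"lac[c]": -1, "lac[e]": 1}, -_T, _T, "transport", "pathway"),
    ("LACt2", "lactate transport (MCT4 isoform)",
     {"lac[c]": -1, "lac[e]": 1}, -_T, _T, "transport", "biochem"),
    ("PYRtm", "pyruvate carrier (mitochondrial)",
     {"pyr[c]": -1, "pyr[m]": 1}, -_T, _T, "transport", "pathway"),
    ("CITtcm", "citrate carrier (mitochondrion to cytosol)",
     {"cit[m]": -1, "cit[c]": 1}, 0, _T, "transport", "pathway"),
    ("MALtm", "malate carrier",
     {"mal[c]": -1, "mal[m]": 1}, -_T, _T, "transport", "pathway"),
    ("PItm", "phosphate carrier",
     {"pi[c]": -1, "pi[m]": 1}, -_T, _T, "transport", "biochem"),
    ("ANT", "adenine nucleotide translocase",
     {"adp[c]": -1, "atp[m]": -1, "adp[m]": 1, "atp[c]": 1},
     0, _T, "transport", "pathway"),
    ("O2tm", "oxygen diffusion (mitochondrial)",
     {"o2[c]": -1, "o2[m]": 1}, 0, _T, "transport", "biochem"),
    ("CO2tm", "CO2 diffusion (mitochondrial)",
     {"co2[m]": -1, "co2[c]": 1}, -_T, _T, "transport", "biochem"),
    ("CO2t", "CO2 diffusion (plasma membrane)",
     {"co2[c]": -1, "co2[e]": 1}, -_T, _T, "transport", "pathway"),
    ("H2Ot", "water diffusion (plasma membrane)",
     {"h2o[c]": -1, "h2o[e]": 1}, -_T, _T, "transport", "biochem"),
    ("H2Otm", "water diffusion (mitochondrial)",
     {"h2o[c]": -1, "h2o[m]": 1}, -_T, _T, "transport", "biochem"),
    ("Htm", "proton transport (mitochondrial)",
     {"h[c]": -1, "h[m]": 1}, -_T, _T, "transport", "biochem"),
    # ---------------- sinks (non-metabolic production/consumption) --------
    ("SK_nadh_c", "NADH sink (cytosolic, non-metabolic supply/consumption)",
     {"nadh[c]": -1}, -2, 0, "sink", "boundary"),
    ("SK_nadh_m", "NADH sink (mitochondrial)",
     {"nadh[m]": -1}, 0, 2, "sink", "boundary"),
    ("SK_nad_m", "NAD sink (mitochondrial)",
     {"nad[m]": -1}, -1, 0, "sink", "boundary"),
    ("SK_co2_m", "CO2 sink",
     {"co2[m]": -1}, 0, _BIG, "sink", "boundary"),
    ("SK_pi_c", "phosphate sink",
     {"pi[c]": -1}, -_BIG, _BIG, "sink", "boundary"),
    ("SK_h_c", "proton sink",
     {"h[c]": -1}, -_BIG, _BIG, "sink", "boundary"),
    ("SK_h2o_c", "water sink",
     {"h2o[c]": -1}, -_BIG, _BIG, "sink", "boundary"),
    ("SK_coa_m", "coenzyme A sink",
     {"coa[m]": -1}, -10, 10, "sink", "boundary"),
    ("SK_fad_m", "FAD sink",
     {"fad[m]": -1}, -10, 10, "sink", "boundary"),
    ("SK_fadh2_m", "FADH2 sink",
     {"fadh2[m]": -1}, 0, 2, "sink", "boundary"),
    # ---------------- demands: environment sources ------------------------
    ("DM_glc_e", "plasma glucose source",
     {"glc[e]": 1}, 0, 10, "demand", "boundary"),
    ("DM_akg_m", "2-oxoglutarate source (glutamine consumption)",
     {"akg[m]": 1}, 0, 0.3, "demand", "boundary"),
    ("DM_o2_c", "oxygen source (hypoxic cap)",
     {"o2[c]": 1}, 0, DEFAULT_OXYGEN_BOUND, "demand", "boundary"),
    ("DM_adp_c", "ADP source",
     {"adp[c]": 1}, 0, _BIG, "demand", "boundary"),
    ("DM_accoa_m", "acetyl-CoA source",
     {"accoa[m]": 1}, 0, 0.05, "demand", "boundary"),
    # ---------------- demands: growth surrogate components ----------------
    ("DM_atp_c", "ATP turnover demand (cytosolic)",
     {"atp[c]": -1, "h2o[c]": -1, "adp[c]": 1, "pi[c]": 1, "h[c]": 1},
     1.0, 12, "demand", "boundary"),
    ("DM_lac_e", "lactate production demand",
     {"lac[e]": -1}, 1.0, 12, "demand", "boundary"),
    ("DM_nadph_c", "NADPH turnover demand (biosynthetic reducing power)",
     {"nadph[c]": -1, "nadp[c]": 1}, 0.1, 0.5, "demand", "boundary"),
    ("DM_r5p_c", "ribose-5-phosphate demand (nucleotide synthesis)",
     {"r5p[c]": -1}, 0.2, 12, "demand", "boundary"),
    ("DM_nad_c", "NAD regeneration demand",
     {"nad[c]": -1}, 0.05, 12, "demand", "boundary"),
    ("DM_oaa_c", "oxaloacetate demand (amino-acid synthesis)",
     {"oaa[c]": -1}, 0, 12, "demand", "boundary"),
    ("DM_atp_m", "ATP turnover demand (mitochondrial)",
     {"atp[m]": -1, "h2o[m]": -1, "adp[m]": 1, "pi[m]": 1, "h[m]": 1},
     0.2, 12, "demand", "boundary"),
    ("DM_cit_c", "citrate demand (lipogenic precursor)",
     {"cit[c]": -1}, 0.1, 12, "demand", "boundary"),
    # ---------------- exchanges -------------------------------------------
    ("EX_lac_e", "lactate exchange",
     {"lac[e]": -1}, 0, _BIG, "exchange", "boundary"),
    ("EX_co2_e", "CO2 exchange",
     {"co2[e]": -1}, 0, _BIG, "exchange", "boundary"),
    ("EX_h2o_e", "water exchange",
     {"h2o[e]": -1}, -_BIG, _BIG, "exchange", "boundary"),
]


def build_cancer_core_network(
    oxygen_bound: float = DEFAULT_OXYGEN_BOUND,
    glucose_bound: float = 10.0,
) -> MetabolicNetwork:
    """Construct the curated cancer-core network.

    Parameters
    ----------
    oxygen_bound:
        Upper bound of the oxygen source (hypoxic default 0.5).
    glucose_bound:
        Upper bound of the plasma glucose source (default 10).
    """
    mets = [Metabolite(id=i, name=n, compartment=c) for i, n, c in _METABOLITES]
    rxns = []
    for rid, name, stoich, lb, ub, kind, note in _REACTIONS:
        if rid == "DM_o2_c":
            ub = oxygen_bound
        elif rid == GLUCOSE_SUPPLY:
            ub = glucose_bound
        rxns.append(
            Reaction(
                id=rid,
                name=name,
                stoich={k: float(v) for k, v in stoich.items()},
                lower_bound=float(lb),
                upper_bound=float(ub),
                kind=kind,
                note=note,
            )
        )
    return MetabolicNetwork(mets, rxns, name="cancer_core")
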