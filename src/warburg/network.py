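"""Compartmentalized stoichiometric network model and serialization.

A :class:`MetabolicNetwork` is an ordered collection of metabolites and
reactions together with the stoichiometric matrix ``S`` (rows = metabolites,
columns = reactions).  Steady-state flux analysis solves problems of the form
``S v = 0`` with per-reaction flux bounds ``lb_j <= v_j <= ub_j``
(mmol·gDW⁻¹·h⁻¹ convention).

Two on-disk formats are supported: SBML Level 3 (with flux bounds encoded as
reaction annotations readable by this package and by common constraint-based
tools) and a compact tab-separated reaction table using ``→`` / ``↔`` equation
syntax with compartment-suffixed metabolite ids (``glc[e]``, ``pyr[c]``,
``akg[m]``).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "NetworkValidationError",
    "NetworkParseError",
    "read_network",
    "write_network",
]

COMPARTMENTS = ("e", "c", "m")
REACTION_KINDS = ("internal", "transport", "exchange", "sink", "demand")

#: kinds whose mass balance is intentionally open (boundary pseudo-reactions)
BOUNDARY_KINDS = frozenset({"exchange", "sink", "demand"})

_MET_ID_RE = re.compile(r"^[A-Za-z0-9_]+\[(e|c|m)\]$")


class NetworkValidationError(ValueError):
    """Raised when a network violates a structural invariant."""


class NetworkParseError(ValueError):
    """Raised when an on-disk network file cannot be parsed."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species localized to one compartment.

    The id carries the compartment as a bracketed suffix (``pyr[c]``); the
    suffix must agree with the ``compartment`` field.
    """

    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not _MET_ID_RE.match(self.id):
            raise NetworkValidationError(
                f"metabolite id {self.id!r} must end in a [e]/[c]/[m] suffix"
            )
        if self.compartment not in COMPARTMENTS:
            raise NetworkValidationError(
                f"unknown compartment {self.compartment!r} for {self.id}"
            )
        suffix = self.id[self.id.rindex("[") + 1 : -1]
        if suffix != self.compartment:
            raise NetworkValidationError(
                f"metabolite {self.id}: suffix [{suffix}] != compartment "
                f"[{self.compartment}]"
            )


@dataclass(frozen=True)
class Reaction:
    """A (pseudo-)reaction with signed stoichiometry and flux bounds.

    ``stoich`` maps metabolite id -> signed coefficient (negative =
    substrate).  ``lower_bound``/``upper_bound`` are the flux capacity
    constraints; reversible reactions carry a negative lower bound rather
    than being split into directional pairs.  ``kind`` distinguishes mass-
    balanced chemistry (``internal``), membrane ``transport``, and the
    deliberately unbalanced boundary pseudo-reactions (``exchange``,
    ``sink``, ``demand``).
    """

    id: str
    stoich: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    kind: str = "internal"
    name: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if not self.stoich:
            raise NetworkValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.kind not in REACTION_KINDS:
            raise NetworkValidationError(
                f"reaction {self.id}: unknown kind {self.kind!r}"
            )
        if self.lower_bound > self.upper_bound:
            raise NetworkValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.kind in ("internal", "transport"):
            has_sub = any(v < 0 for v in self.stoich.values())
            has_prod = any(v > 0 for v in self.stoich.values())
            if not (has_sub and has_prod):
                raise NetworkValidationError(
                    f"reaction {self.id}: kind={self.kind} requires metabolites "
                    "on both sides"
                )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


@dataclass
class MetabolicNetwork:
    """Ordered metabolites + reactions with a derived stoichiometric matrix."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    name: str = "network"
    _S: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- indexing -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: j for j, r in enumerate(self.reactions)}

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self.reaction_index()[rid]]
        except KeyError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    # -- stoichiometric matrix ---------------------------------------------
    @property
    def S(self) -> np.ndarray:
        """Dense stoichiometric matrix, shape (n_metabolites, n_reactions)."""
        if self._S is None:
            midx = self.metabolite_index()
            S = np.zeros((len(self.metabolites), len(self.reactions)))
            for j, rxn in enumerate(self.reactions):
                for mid, coeff in rxn.stoich.items():
                    S[midx[mid], j] = coeff
            self._S = S
        return self._S

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        seen_m: set[str] = set()
        for m in self.metabolites:
            if m.id in seen_m:
                raise NetworkValidationError(f"duplicate metabolite id {m.id!r}")
            seen_m.add(m.id)
        seen_r: set[str] = set()
        for r in self.reactions:
            if r.id in seen_r:
                raise NetworkValidationError(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            for mid, coeff in r.stoich.items():
                if mid not in seen_m:
                    raise NetworkValidationError(
                        f"reaction {r.id} references undeclared metabolite {mid!r}"
                    )
                if coeff == 0 or not math.isfinite(coeff):
                    raise NetworkValidationError(
                        f"reaction {r.id}: bad coefficient {coeff} for {mid}"
                    )
        self._S = None

    # -- mutation helpers (copy-on-write) ------------------------------------
    def with_bounds(self, overrides: dict[str, tuple[float, float]]) -> "MetabolicNetwork":
        """A copy of the network with per-reaction bound overrides applied."""
        unknown = set(overrides) - set(self.reaction_ids)
        if unknown:
            raise KeyError(f"unknown reaction id(s) {sorted(unknown)}")
        new = [
            r.with_bounds(*overrides[r.id]) if r.id in overrides else r
            for r in self.reactions
        ]
        return MetabolicNetwork(self.metabolites, new, name=self.name)

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(list(self.metabolites), list(self.reactions), self.name)


# ---------------------------------------------------------------------------
# TSV reaction-table dialect
# ---------------------------------------------------------------------------

_ARROW_IRREV = "→"
_ARROW_REV = "↔"
_TSV_HEADER = ["reaction_id", "equation", "lower", "upper", "kind", "note"]
_MET_DECL = "#!metabolite"


def format_equation(rxn: Reaction) -> str:
    subs = sorted((mid, -c) for mid, c in rxn.stoich.items() if c < 0)
    prods = sorted((mid, c) for mid, c in rxn.stoich.items() if c > 0)

    def side(terms: list[tuple[str, float]]) -> str:
        parts = []
        for mid, c in terms:
            parts.append(mid if c == 1 else f"{c:g} {mid}")
        return " + ".join(parts)

    arrow = _ARROW_REV if rxn.reversible else _ARROW_IRREV
    return f"{side(subs)} {arrow} {side(prods)}".strip()


def parse_equation(eq: str, rid: str = "?") -> dict[str, float]:
    if _ARROW_REV in eq:
        lhs, rhs = eq.split(_ARROW_REV)
    elif _ARROW_IRREV in eq:
        lhs, rhs = eq.split(_ARROW_IRREV)
    else:
        raise NetworkParseError(f"reaction {rid}: equation lacks → or ↔: {eq!r}")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            bits = term.split()
            if len(bits) == 2:
                coeff, mid = float(bits[0]), bits[1]
            elif len(bits) == 1:
                coeff, mid = 1.0, bits[0]
            else:
                raise NetworkParseError(f"reaction {rid}: bad term {term!r}")
            stoich[mid] = stoich.get(mid, 0.0) + sign * coeff

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    return {m: c for m, c in stoich.items() if c != 0.0}


def _write_tsv(net: MetabolicNetwork, path: str) -> None:
    lines = []
    for m in net.metabolites:
        lines.append(f"{_MET_DECL}\t{m.id}\t{m.name}\t{m.compartment}")
    lines.append("\t".join(_TSV_HEADER))
    for r in net.reactions:
        lines.append(
            "\t".join(
                [
                    r.id,
                    format_equation(r),
                    f"{r.lower_bound:g}",
                    f"{r.upper_bound:g}",
                    r.kind,
                    r.note,
                ]
            )
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_tsv(path: str) -> MetabolicNetwork:
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(_MET_DECL):
                parts = line.split("\t")
                if len(parts) < 4:
                    raise NetworkParseError(
                        f"{path}:{lineno}: malformed metabolite declaration"
                    )
                metabolites.append(
                    Metabolite(id=parts[1], name=parts[2], compartment=parts[3])
                )
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if not header_seen:
                if parts[: len(_TSV_HEADER) - 1] != _TSV_HEADER[:-1]:
                    raise NetworkParseError(
                        f"{path}:{lineno}: expected header {_TSV_HEADER}, got {parts}"
                    )
                header_seen = True
                continue
            if len(parts) < 5:
                raise NetworkParseError(f"{path}:{lineno}: expected >=5 columns")
            rid, eq, lo, hi, kind = parts[:5]
            note = parts[5] if len(parts) > 5 else ""
            try:
                stoich = parse_equation(eq, rid)
                rxn = Reaction(
                    id=rid,
                    stoich=stoich,
                    lower_bound=float(lo),
                    upper_bound=float(hi),
                    kind=kind,
                    note=note,
                )
            except (ValueError, NetworkValidationError) as exc:
                raise NetworkParseError(f"{path}:{lineno}: {exc}") from exc
            reactions.append(rxn)
    if not header_seen:
        raise NetworkParseError(f"{path}: missing reaction-table header")
    try:
        return MetabolicNetwork(metabolites, reactions)
    except NetworkValidationError as exc:
        raise NetworkValidationError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# SBML Level 3 (fbc flux bounds)
# ---------------------------------------------------------------------------

def _sbml_safe(sid: str) -> str:
    return sid.replace("[", "__").replace("]", "")


def _sbml_unsafe(sid: str) -> str:
    # inverse of _sbml_safe for ids like M_glc__e
    m = re.match(r"^(.*)__([ecm])$", sid)
    if not m:
        raise NetworkParseError(f"cannot recover compartment from SBML id {sid!r}")
    return f"{m.group(1)}[{m.group(2)}]"


def _write_sbml(net: MetabolicNetwork, path: str) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(re.sub(r"\W", "_", net.name) or "model")
    mplug = model.getPlugin("fbc")
    mplug.setStrict(False)

    for comp in COMPARTMENTS:
        c = model.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met in net.metabolites:
        sp = model.createSpecies()
        sp.setId("M_" + _sbml_safe(met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    def bound_param(value: float) -> str:
        pid = ("b_" + f"{value:g}").replace("-", "m").replace(".", "p").replace("+", "")
        if model.getParameter(pid) is None:
            p = model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
        return pid

    for rxn in net.reactions:
        r = model.createReaction()
        r.setId("R_" + rxn.id)
        r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for mid, coeff in sorted(rxn.stoich.items()):
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies("M_" + _sbml_safe(mid))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.kind != "internal" or rxn.note:
            r.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>kind: {rxn.kind}</p><p>note: {rxn.note}</p></body>"
            )
    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise OSError(f"could not write SBML to {path}")


_KIND_NOTE_RE = re.compile(r"kind:\s*(\w+)")
_NOTE_NOTE_RE = re.compile(r"note:\s*([^<]*)")


def _read_sbml(path: str) -> MetabolicNetwork:
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise NetworkParseError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    model = doc.getModel()
    if model is None:
        raise NetworkParseError(f"{path}: no SBML model element")
    metabolites = []
    for sp in model.getListOfSpecies():
        mid = _sbml_unsafe(sp.getId()[2:] if sp.getId().startswith("M_") else sp.getId())
        metabolites.append(
            Metabolite(id=mid, name=sp.getName(), compartment=sp.getCompartment())
        )
    reactions = []
    for r in model.getListOfReactions():
        rid = r.getId()[2:] if r.getId().startswith("R_") else r.getId()
        stoich: dict[str, float] = {}
        for ref in r.getListOfReactants():
            mid = _sbml_unsafe(ref.getSpecies()[2:])
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for ref in r.getListOfProducts():
            mid = _sbml_unsafe(ref.getSpecies()[2:])
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = r.getPlugin("fbc")
        lo = model.getParameter(rplug.getLowerFluxBound()).getValue()
        hi = model.getParameter(rplug.getUpperFluxBound()).getValue()
        kind, note = "internal", ""
        if r.isSetNotes():
            text = r.getNotesString()
            mk = _KIND_NOTE_RE.search(text)
            if mk:
                kind = mk.group(1)
            mn = _NOTE_NOTE_RE.search(text)
            if mn:
                note = mn.group(1).strip()
        reactions.append(
            Reaction(
                id=rid,
                stoich=stoich,
                lower_bound=lo,
                upper_bound=hi,
                kind=kind,
                name=r.getName(),
                note=note,
            )
        )
    return MetabolicNetwork(metabolites, reactions, name=model.getId())


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def write_network(net: MetabolicNetwork, path: str, format: str = "tsv") -> None:
    """Serialize a network to ``tsv`` or ``sbml``.

    Refuses to serialize an empty network (no reactions): such a file would
    not round-trip into a meaningful model.
    """
    if not net.reactions or not net.metabolites:
        raise NetworkValidationError("refusing to serialize an empty network")
    if format == "tsv":
        _write_tsv(net, path)
    elif format == "sbml":
        _write_sbml(net, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network(path: str, format: str = "tsv") -> MetabolicNetwork:
    """Parse a network from ``tsv`` or ``sbml``; round-trips write_network."""
    if format == "tsv":
        return _read_tsv(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown format {format!r}")
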