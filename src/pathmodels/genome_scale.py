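"""Draft genome-scale metabolic reconstructions and their analysis.

A :class:`Reconstruction` is a stoichiometric network with flux bounds, an
objective and per-metabolite chemistry (formula, charge).  The build
pipeline mirrors an automated draft-reconstruction workflow:

1. extract per-source networks (:func:`from_pathway_graph`),
2. reconcile metabolite identifiers against a unification map that also
   supplies default formulas and charges at an assumed pH of 7.3
   (:func:`reconcile`),
3. merge the per-source networks (:func:`merge`),
4. add a minimal growth medium with its uptake machinery and universal
   export reactions (:func:`add_medium_and_transport`),
5. add a fixed 30-component biomass objective (:func:`add_biomass`),
6. write a COBRA-dialect SBML document (:func:`format_cobra`) and check
   which biomass components the network can synthesize from the medium by
   linear programming (:func:`synthesizability`).

Mass/charge balance of individual reactions is checked against Hill-style
formulas (:func:`check_balance`).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace

import libsbml

from .common import PathModelsError, StructuralError
from .kgml import PathwayGraph

log = logging.getLogger(__name__)

INTRACELLULAR = "intracellular"
EXTRACELLULAR = "extracellular"

DEFAULT_UPPER = 1000.0
PRODUCIBILITY_EPS = 1e-6


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: str | None = None
    charge: int | None = None
    compartment: str = INTRACELLULAR
    namespace: str = ""  # source identifier namespace, e.g. kegg.compound
    source_tags: list[str] = field(default_factory=list)


@dataclass
class ReconReaction:
    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower: float = 0.0
    upper: float = DEFAULT_UPPER
    gpr: str = ""
    source_tags: list[str] = field(default_factory=list)

    @property
    def reversible(self) -> bool:
        return self.lower < 0 < self.upper

    def substrates(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


@dataclass
class Reconstruction:
    id: str = "draft"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[ReconReaction] = field(default_factory=list)
    objective: str | None = None

    def metabolite_ids(self) -> set[str]:
        return {m.id for m in self.metabolites}

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction_ids(self) -> set[str]:
        return {r.id for r in self.reactions}

    def validate(self) -> None:
        mids = [m.id for m in self.metabolites]
        if len(mids) != len(set(mids)):
            raise StructuralError("duplicate metabolite ids")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            raise StructuralError("duplicate reaction ids")
        known = set(mids)
        for r in self.reactions:
            if r.lower > r.upper:
                raise StructuralError(f"reaction {r.id}: lower bound above upper bound")
            for mid in r.stoichiometry:
                if mid not in known:
                    raise StructuralError(f"reaction {r.id}: unknown metabolite {mid!r}")
        if self.objective is not None and self.objective not in set(rids):
            raise StructuralError(f"objective {self.objective!r} is not a reaction")


# ---------------------------------------------------------------------------
# the fixed medium and biomass specification

#: Minimal growth medium: id, name, formula, charge.  (The chlorate entry
#: follows the source medium specification verbatim.)
MEDIUM = (
    ("glc__aD", "alpha-D-Glucose", "C6H12O6", 0),
    ("glc__bD", "beta-D-Glucose", "C6H12O6", 0),
    ("nh4", "Ammonium", "H4N", 1),
    ("na1", "Sodium", "Na", 1),
    ("k", "Potassium", "K", 1),
    ("mg2", "Magnesium", "Mg", 2),
    ("ca2", "Calcium", "Ca", 2),
    ("so4", "Sulphate", "O4S", -2),
    ("clo3", "Chlorate", "ClO3", -1),
    ("pi", "Phosphate", "HO4P", -2),
    ("h", "Proton", "H", 1),
    ("h2o", "Water", "H2O", 0),
    ("co2", "Carbon dioxide", "CO2", 0),
    ("o2", "Oxygen", "O2", 0),
)

AMINO_ACIDS = (
    ("ala__L", "L-Alanine"),
    ("arg__L", "L-Arginine"),
    ("asn__L", "L-Asparagine"),
    ("asp__L", "L-Aspartate"),
    ("cys__L", "L-Cysteine"),
    ("gln__L", "L-Glutamine"),
    ("glu__L", "L-Glutamate"),
    ("gly", "Glycine"),
    ("his__L", "L-Histidine"),
    ("ile__L", "L-Isoleucine"),
    ("leu__L", "L-Leucine"),
    ("lys__L", "L-Lysine"),
    ("met__L", "L-Methionine"),
    ("phe__L", "L-Phenylalanine"),
    ("pro__L", "L-Proline"),
    ("ser__L", "L-Serine"),
    ("thr__L", "L-Threonine"),
    ("trp__L", "L-Tryptophan"),
    ("tyr__L", "L-Tyrosine"),
    ("val__L", "L-Valine"),
)

#: RNA precursors are represented as the four NMPs and DNA precursors as
#: the four dNMPs, keeping ATP a distinct 30th component.
RNA_PRECURSORS = (("amp", "AMP"), ("gmp", "GMP"), ("cmp", "CMP"), ("ump", "UMP"))
DNA_PRECURSORS = (("damp", "dAMP"), ("dgmp", "dGMP"), ("dcmp", "dCMP"), ("dtmp", "dTMP"))

#: Biomass components: id -> (name, category); 30 entries, 20 amino acids.
BIOMASS_COMPONENTS: dict[str, tuple[str, str]] = {
    **{mid: (name, "amino_acid") for mid, name in AMINO_ACIDS},
    **{mid: (name, "rna_precursor") for mid, name in RNA_PRECURSORS},
    **{mid: (name, "dna_precursor") for mid, name in DNA_PRECURSORS},
    "glycogen": ("Glycogen", "carbohydrate"),
    "atp": ("ATP", "energy"),
}

BIOMASS_REACTION_ID = "biomass"


# ---------------------------------------------------------------------------
# extraction / reconciliation / merging


def from_pathway_graph(graph: PathwayGraph, source: str = "kegg") -> Reconstruction:
    """Extract a per-source metabolic network from a pathway graph.

    Compound entries become intracellular metabolites identified by their
    first database accession; reactions keep direction (reversible spans
    both directions) and record their catalysts as a gene-protein-reaction
    (GPR) association."""
    net = Reconstruction(id=f"{source}_{graph.organism_code or 'net'}")
    mid_of: dict[str, str] = {}
    seen: set[str] = set()
    for e in graph.entries:
        if e.type != "compound":
            continue
        acc = e.names[0].split(":", 1)[-1] if e.names else e.id
        mid_of[e.id] = acc
        if acc in seen:
            continue
        seen.add(acc)
        net.metabolites.append(
            Metabolite(
                id=acc,
                name=acc,
                compartment=INTRACELLULAR,
                namespace="kegg.compound" if source == "kegg" else source,
                source_tags=[source],
            )
        )
    for r in graph.reactions:
        stoich: dict[str, float] = {}
        for eid, coeff in r.substrates:
            if eid in mid_of:
                stoich[mid_of[eid]] = stoich.get(mid_of[eid], 0.0) - coeff
        for eid, coeff in r.products:
            if eid in mid_of:
                stoich[mid_of[eid]] = stoich.get(mid_of[eid], 0.0) + coeff
        if not stoich:
            continue
        genes = []
        for eid in r.enzymes:
            e = graph.entry(eid)
            genes.extend(n for n in e.names if ":" in n)
        rid = r.name.split(":", 1)[-1].split()[0] if r.name else f"{source}_{r.id}"
        net.reactions.append(
            ReconReaction(
                id=rid,
                stoichiometry=stoich,
                lower=-DEFAULT_UPPER if r.reversible else 0.0,
                upper=DEFAULT_UPPER,
                gpr=" or ".join(genes),
                source_tags=[source],
            )
        )
    net.validate()
    return net


ReconMap = dict[tuple[str, str], tuple[str, str | None, int | None]]


def read_recon_map(path) -> ReconMap:
    """Read a 5-column identifier-unification table: source namespace,
    source id, unified id, formula, charge."""
    out: ReconMap = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ns, sid, uid, formula, charge = (line.split("\t") + [""] * 5)[:5]
            out[(ns, sid)] = (uid, formula or None, int(charge) if charge else None)
    return out


def reconcile(net: Reconstruction, recon_map: ReconMap) -> Reconstruction:
    """Replace source identifiers by unified identifiers.

    Metabolites that collide after mapping are merged; map-supplied
    formulas and charges override absent values (and win, with a warning,
    on contradiction).  Unmapped metabolites keep their source identifier
    and tags.  Reaction coefficients referring to merged metabolites are
    summed per unified id."""
    new_id: dict[str, str] = {}
    merged: dict[tuple[str, str], Metabolite] = {}
    order: list[Metabolite] = []
    for m in net.metabolites:
        row = recon_map.get((m.namespace, m.id))
        uid, formula, charge = row if row is not None else (m.id, None, None)
        new_id[m.id] = uid
        key = (uid, m.compartment)
        if key in merged:
            tgt = merged[key]
            tgt.source_tags = sorted(set(tgt.source_tags) | set(m.source_tags))
        else:
            tgt = replace(m, id=uid, source_tags=list(m.source_tags))
            merged[key] = tgt
            order.append(tgt)
        if formula is not None:
            if tgt.formula is not None and tgt.formula != formula:
                log.warning(
                    "metabolite %s: formula %s contradicts map value %s; map wins",
                    uid, tgt.formula, formula,
                )
            tgt.formula = formula
        if charge is not None:
            if tgt.charge is not None and tgt.charge != charge:
                log.warning(
                    "metabolite %s: charge %s contradicts map value %s; map wins",
                    uid, tgt.charge, charge,
                )
            tgt.charge = charge

    reactions = []
    for r in net.reactions:
        stoich: dict[str, float] = {}
        for mid, coeff in r.stoichiometry.items():
            uid = new_id.get(mid, mid)
            stoich[uid] = stoich.get(uid, 0.0) + coeff
        stoich = {mid: c for mid, c in stoich.items() if c != 0}
        reactions.append(replace(r, stoichiometry=stoich, source_tags=list(r.source_tags)))
    out = Reconstruction(id=net.id, metabolites=order, reactions=reactions, objective=net.objective)
    out.validate()
    return out


def _reaction_identity(r: ReconReaction) -> tuple:
    # participant multiset and direction class define reaction identity;
    # the same conversion written in opposite directions is kept twice
    return (tuple(sorted(r.stoichiometry.items())), r.reversible)


def merge(nets: list[Reconstruction]) -> Reconstruction:
    """Union of already-reconciled per-source networks.

    Metabolites are merged by (id, compartment); reactions equal up to
    participant multiset and direction class are deduplicated with their
    source tags concatenated."""
    out = Reconstruction(id="merged")
    mets: dict[tuple[str, str], Metabolite] = {}
    rxns: dict[tuple, ReconReaction] = {}
    for net in nets:
        for m in net.metabolites:
            key = (m.id, m.compartment)
            if key in mets:
                tgt = mets[key]
                tgt.source_tags = sorted(set(tgt.source_tags) | set(m.source_tags))
                tgt.formula = tgt.formula or m.formula
                tgt.charge = tgt.charge if tgt.charge is not None else m.charge
            else:
                tgt = replace(m, source_tags=list(m.source_tags))
                mets[key] = tgt
                out.metabolites.append(tgt)
        for r in net.reactions:
            key = _reaction_identity(r)
            if key in rxns:
                tgt = rxns[key]
                tgt.source_tags = sorted(set(tgt.source_tags) | set(r.source_tags))
                if r.gpr and r.gpr not in tgt.gpr:
                    tgt.gpr = f"{tgt.gpr} or {r.gpr}" if tgt.gpr else r.gpr
            else:
                tgt = replace(
                    r,
                    stoichiometry=dict(r.stoichiometry),
                    source_tags=list(r.source_tags),
                )
                if tgt.id in {x.id for x in out.reactions}:
                    tgt.id = f"{tgt.id}_{len(out.reactions)}"
                rxns[key] = tgt
                out.reactions.append(tgt)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# balance checking

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int] | None:
    """Element counts of a Hill-style formula, or None when unparseable
    (generic R groups, asterisks, lowercase fragments...)."""
    if not formula:
        return None
    pos = 0
    counts: dict[str, int] = {}
    while pos < len(formula):
        m = _FORMULA_RE.match(formula, pos)
        if m is None or m.end() == pos:
            return None
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if "R" in counts or "X" in counts:
        return None  # generic group placeholders
    return counts


@dataclass
class BalanceResult:
    status: str  # balanced | unbalanced | unknown
    element_diff: dict[str, float] = field(default_factory=dict)
    charge_diff: float | None = None
    detail: str = ""


def check_balance(reaction: ReconReaction, net: Reconstruction) -> BalanceResult:
    """Mass and charge balance of one reaction.

    Sums element counts and charges over the stoichiometry; a participant
    without a formula, or with an unparseable one, makes the result
    ``unknown``."""
    mets = {m.id: m for m in net.metabolites}
    elements: dict[str, float] = {}
    charge = 0.0
    for mid, coeff in reaction.stoichiometry.items():
        m = mets.get(mid)
        if m is None or m.formula is None:
            return BalanceResult("unknown", detail=f"{mid}: no formula")
        counts = parse_formula(m.formula)
        if counts is None:
            log.warning("reaction %s: unparseable formula %r on %s", reaction.id, m.formula, mid)
            return BalanceResult("unknown", detail=f"{mid}: unparseable formula {m.formula!r}")
        for el, n in counts.items():
            elements[el] = elements.get(el, 0.0) + coeff * n
        if m.charge is None:
            return BalanceResult("unknown", detail=f"{mid}: no charge")
        charge += coeff * m.charge
    elements = {el: d for el, d in elements.items() if d != 0}
    if not elements and charge == 0:
        return BalanceResult("balanced", charge_diff=0.0)
    detail = ", ".join(f"{el}: {d:+g}" for el, d in sorted(elements.items()))
    if charge != 0:
        detail = (detail + ", " if detail else "") + f"charge: {charge:+g}"
    return BalanceResult("unbalanced", element_diff=elements, charge_diff=charge, detail=detail)


# ---------------------------------------------------------------------------
# medium / transport / biomass


def _ensure_metabolite(net: Reconstruction, mid: str, compartment: str, name: str = "",
                       formula: str | None = None, charge: int | None = None) -> None:
    for m in net.metabolites:
        if m.id == mid:
            return
    net.metabolites.append(
        Metabolite(id=mid, name=name or mid, formula=formula, charge=charge,
                   compartment=compartment, source_tags=["default"])
    )


def add_medium_and_transport(net: Reconstruction) -> Reconstruction:
    """Add the minimal growth medium and default transport reactions.

    Each of the 14 medium metabolites gains an extracellular pool, an
    exchange reaction that permits uptake, and an uptake-directed transport
    into the cytosol; metabolites absent from the network are created.
    Every intracellular metabolite gains a secretion-only export transport
    and exchange, so nothing in the medium can be synthesized backwards
    through an exporter.  Idempotent: existing reactions are not
    duplicated."""
    rids = net.reaction_ids()
    for mid, name, formula, charge in MEDIUM:
        _ensure_metabolite(net, mid, INTRACELLULAR, name, formula, charge)
        _ensure_metabolite(net, f"{mid}_e", EXTRACELLULAR, name, formula, charge)
        ex = f"EX_{mid}_e"
        if ex not in rids:
            net.reactions.append(
                ReconReaction(id=ex, stoichiometry={f"{mid}_e": -1.0},
                              lower=-DEFAULT_UPPER, upper=DEFAULT_UPPER,
                              source_tags=["medium"])
            )
            rids.add(ex)
        tr = f"T_{mid}_uptake"
        if tr not in rids:
            net.reactions.append(
                ReconReaction(id=tr, stoichiometry={f"{mid}_e": -1.0, mid: 1.0},
                              lower=0.0, upper=DEFAULT_UPPER, source_tags=["transport"])
            )
            rids.add(tr)
    for m in sorted(net.metabolites, key=lambda m: m.id):
        if m.compartment != INTRACELLULAR:
            continue
        ext = f"{m.id}_e"
        tr = f"T_{m.id}_export"
        if tr not in rids:
            _ensure_metabolite(net, ext, EXTRACELLULAR, m.name, m.formula, m.charge)
            net.reactions.append(
                ReconReaction(id=tr, stoichiometry={m.id: -1.0, ext: 1.0},
                              lower=0.0, upper=DEFAULT_UPPER, source_tags=["transport"])
            )
            rids.add(tr)
        ex = f"EX_{m.id}_e"
        if ex not in rids:
            net.reactions.append(
                ReconReaction(id=ex, stoichiometry={ext: -1.0},
                              lower=0.0, upper=DEFAULT_UPPER, source_tags=["exchange"])
            )
            rids.add(ex)
    net.validate()
    return net


def add_biomass(net: Reconstruction) -> Reconstruction:
    """Add the default biomass reaction over the 30 fixed components
    (20 amino acids, 4 RNA and 4 DNA nucleotide precursors, glycogen and
    ATP), all with coefficient 1, and make it the objective."""
    for mid, (name, _category) in BIOMASS_COMPONENTS.items():
        _ensure_metabolite(net, mid, INTRACELLULAR, name)
    if BIOMASS_REACTION_ID not in net.reaction_ids():
        net.reactions.append(
            ReconReaction(
                id=BIOMASS_REACTION_ID,
                stoichiometry={mid: -1.0 for mid in BIOMASS_COMPONENTS},
                lower=0.0,
                upper=DEFAULT_UPPER,
                source_tags=["biomass"],
            )
        )
    net.objective = BIOMASS_REACTION_ID
    net.validate()
    return net


# ---------------------------------------------------------------------------
# synthesizability analysis


@dataclass
class SynthReport:
    components: dict[str, bool] = field(default_factory=dict)
    max_flux: dict[str, float] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)
    n_reactions: int = 0
    n_metabolites: int = 0
    n_makeable_metabolites: int = 0
    n_makeable_components: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "components": self.components,
                "max_flux": self.max_flux,
                "counts": {
                    "reactions": self.n_reactions,
                    "metabolites": self.n_metabolites,
                    "makeable_metabolites": self.n_makeable_metabolites,
                    "makeable_components": self.n_makeable_components,
                },
            },
            indent=2,
            sort_keys=True,
        )

    def to_tsv(self) -> str:
        lines = ["component\tproducible\tmax_flux"]
        for mid in self.components:
            lines.append(f"{mid}\t{int(self.components[mid])}\t{self.max_flux[mid]:.6g}")
        return "\n".join(lines) + "\n"


def to_cobra(net: Reconstruction):
    """Build a cobrapy model (deterministic element order)."""
    import cobra

    model = cobra.Model(net.id)
    comp_code = {INTRACELLULAR: "c", EXTRACELLULAR: "e"}
    mets = {}
    for m in net.metabolites:
        cm = cobra.Metabolite(
            m.id,
            name=m.name,
            formula=m.formula,
            charge=m.charge,
            compartment=comp_code[m.compartment],
        )
        mets[m.id] = cm
    model.add_metabolites(list(mets.values()))
    rxns = []
    for r in net.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower, upper_bound=r.upper)
        rxns.append(cr)
    model.add_reactions(rxns)
    for r in net.reactions:
        model.reactions.get_by_id(r.id).add_metabolites(
            {mets[mid]: c for mid, c in r.stoichiometry.items()}
        )
    return model


def synthesizability(net: Reconstruction, eps: float = PRODUCIBILITY_EPS) -> SynthReport:
    """Per-component biomass producibility by flux maximization.

    For each biomass component c a temporary demand reaction c -> (sink) is
    added and its flux maximized under steady state and the network bounds;
    the component is producible when the optimum exceeds ``eps``.  The same
    test over all intracellular metabolites yields the makeable-metabolite
    count."""
    if net.objective is None:
        raise PathModelsError("add_biomass must run before synthesizability")
    import cobra

    model = to_cobra(net)
    report = SynthReport()
    core_tags = {"medium", "transport", "exchange", "biomass"}
    report.n_reactions = sum(
        1 for r in net.reactions if not (set(r.source_tags) & core_tags)
    )
    intracellular = [m.id for m in net.metabolites if m.compartment == INTRACELLULAR]
    report.n_metabolites = len(intracellular)

    def max_demand(mid: str) -> tuple[float, str]:
        with model:
            dm = cobra.Reaction(f"DM_{mid}", lower_bound=0.0, upper_bound=DEFAULT_UPPER)
            model.add_reactions([dm])
            dm.add_metabolites({model.metabolites.get_by_id(mid): -1.0})
            model.objective = dm
            value = model.slim_optimize(error_value=float("nan"))
            status = model.solver.status
        if value != value:  # NaN: infeasible or unbounded
            return 0.0, status
        return float(value), status

    for mid in sorted(intracellular):
        flux, status = max_demand(mid)
        producible = flux > eps
        if producible:
            report.n_makeable_metabolites += 1
        if mid in BIOMASS_COMPONENTS:
            report.components[mid] = producible
            report.max_flux[mid] = flux
            report.status[mid] = status
    report.n_makeable_components = sum(report.components.values())
    # preserve the canonical component order in the report
    ordered = [mid for mid in BIOMASS_COMPONENTS if mid in report.components]
    report.components = {mid: report.components[mid] for mid in ordered}
    report.max_flux = {mid: report.max_flux[mid] for mid in ordered}
    report.status = {mid: report.status[mid] for mid in ordered}
    return report


# ---------------------------------------------------------------------------
# COBRA-dialect SBML


def format_cobra(net: Reconstruction) -> str:
    """Write the reconstruction as a COBRA-dialect SBML Level 2 document:
    FORMULA/CHARGE in species notes, GENE_ASSOCIATION in reaction notes,
    and LOWER_BOUND / UPPER_BOUND / OBJECTIVE_COEFFICIENT as kinetic-law
    parameters."""
    from .sbml_io import render_notes

    net.validate()
    doc = libsbml.SBMLDocument(2, 4)
    model = doc.createModel()
    model.setId(net.id)
    comp_code = {INTRACELLULAR: "c", EXTRACELLULAR: "e"}
    for cid, cname in (("c", "intracellular"), ("e", "extracellular")):
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setSize(1.0)
    for m in net.metabolites:
        sp = model.createSpecies()
        sp.setId(f"M_{m.id}")
        if m.name:
            sp.setName(m.name)
        sp.setCompartment(comp_code[m.compartment])
        sp.setInitialAmount(0.0)
        notes = {}
        if m.formula is not None:
            notes["FORMULA"] = m.formula
        if m.charge is not None:
            notes["CHARGE"] = str(m.charge)
        if m.namespace:
            notes["NAMESPACE"] = m.namespace
        if m.source_tags:
            notes["SOURCE"] = " ".join(m.source_tags)
        if notes:
            sp.setNotes(render_notes(notes))
    for r in net.reactions:
        rx = model.createReaction()
        rx.setId(f"R_{r.id}")
        rx.setReversible(r.reversible)
        for mid, coeff in sorted(r.stoichiometry.items()):
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(f"M_{mid}")
            ref.setStoichiometry(abs(coeff))
        notes = {}
        if r.gpr:
            notes["GENE_ASSOCIATION"] = r.gpr
        if r.source_tags:
            notes["SOURCE"] = " ".join(r.source_tags)
        if notes:
            rx.setNotes(render_notes(notes))
        kl = rx.createKineticLaw()
        kl.setMath(libsbml.parseFormula("FLUX_VALUE"))
        for pid, value in (
            ("LOWER_BOUND", r.lower),
            ("UPPER_BOUND", r.upper),
            ("FLUX_VALUE", 0.0),
            ("OBJECTIVE_COEFFICIENT", 1.0 if r.id == net.objective else 0.0),
        ):
            p = kl.createParameter()
            p.setId(pid)
            p.setValue(value)
    return libsbml.writeSBMLToString(doc)


def read_cobra(document: str) -> Reconstruction:
    """Parse a COBRA-dialect SBML document back into a Reconstruction."""
    from .sbml_io import parse_notes

    doc = libsbml.readSBMLFromString(document)
    model = doc.getModel()
    if model is None:
        raise StructuralError("document contains no model")
    net = Reconstruction(id=model.getId() or "draft")
    comp_name = {}
    for i in range(model.getNumCompartments()):
        c = model.getCompartment(i)
        comp_name[c.getId()] = c.getName() or c.getId()
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        notes = parse_notes(sp.getNotes())
        mid = sp.getId()
        mid = mid[2:] if mid.startswith("M_") else mid
        net.metabolites.append(
            Metabolite(
                id=mid,
                name=sp.getName(),
                formula=notes.get("FORMULA"),
                charge=int(notes["CHARGE"]) if "CHARGE" in notes else None,
                compartment=comp_name.get(sp.getCompartment(), INTRACELLULAR),
                namespace=notes.get("NAMESPACE", ""),
                source_tags=notes.get("SOURCE", "").split(),
            )
        )
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        rid = rx.getId()
        rid = rid[2:] if rid.startswith("R_") else rid
        notes = parse_notes(rx.getNotes())
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            mid = ref.getSpecies()
            mid = mid[2:] if mid.startswith("M_") else mid
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            mid = ref.getSpecies()
            mid = mid[2:] if mid.startswith("M_") else mid
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        lower, upper, obj = -DEFAULT_UPPER if rx.getReversible() else 0.0, DEFAULT_UPPER, 0.0
        if rx.isSetKineticLaw():
            kl = rx.getKineticLaw()
            for j in range(kl.getNumParameters()):
                p = kl.getParameter(j)
                if p.getId() == "LOWER_BOUND":
                    lower = p.getValue()
                elif p.getId() == "UPPER_BOUND":
                    upper = p.getValue()
                elif p.getId() == "OBJECTIVE_COEFFICIENT":
                    obj = p.getValue()
        net.reactions.append(
            ReconReaction(
                id=rid,
                stoichiometry=stoich,
                lower=lower,
                upper=upper,
                gpr=notes.get("GENE_ASSOCIATION", ""),
                source_tags=notes.get("SOURCE", "").split(),
            )
        )
        if obj:
            net.objective = rid
    net.validate()
    return net
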