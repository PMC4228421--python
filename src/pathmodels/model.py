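"""Process-description model document and the pathway-to-model translation.

A :class:`ProcessModel` is an in-memory species/reaction document that maps
one-to-one onto SBML Level 3 Core (plus the Layout package for entry boxes;
see :mod:`pathmodels.sbml_io`).  Every element carries

* an SBO term derived from the source entry type (:func:`assign_sbo`),
* MIRIAM-style cross-references as Identifiers.org URIs with biology
  qualifiers (``is`` for a unique identifier, ``hasVersion`` when several
  identifiers from the same database apply, ``isEncodedBy`` for the gene
  members of a complex), and
* the evidence code ECO:0000313 (information imported by an automatic
  assertion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .common import LayoutBox, StructuralError
from .kgml import PathwayGraph

log = logging.getLogger(__name__)

#: entry type -> SBO term
SBO_BY_ENTRY_TYPE = {
    "compound": "SBO:0000247",  # simple chemical
    "enzyme": "SBO:0000252",  # polypeptide chain
    "gene": "SBO:0000252",
    "ortholog": "SBO:0000252",
    "group": "SBO:0000253",  # non-covalent complex
    "map": "SBO:0000552",  # reference annotation
}

ECO_AUTOMATIC_ASSERTION = "ECO:0000313"

#: Cross-reference databases accepted without warning, and the prefix of
#: database identifiers (``cpd:C00031`` style) that selects each of them.
DATABASES = (
    "3dmet",
    "chebi",
    "drugbank",
    "ec-code",
    "ensembl",
    "go",
    "glycomedb",
    "hgnc",
    "kegg.compound",
    "kegg.drug",
    "kegg.genes",
    "kegg.glycan",
    "kegg.orthology",
    "kegg.pathway",
    "kegg.reaction",
    "lipidbank",
    "ncbigene",
    "omim",
    "pdbe-chem",
    "pubchem.compound",
    "taxonomy",
    "uniprot",
)

_NAME_PREFIXES = {
    "cpd": "kegg.compound",
    "gl": "kegg.glycan",
    "dr": "kegg.drug",
    "rn": "kegg.reaction",
    "ko": "kegg.orthology",
    "path": "kegg.pathway",
    "ec": "ec-code",
    "chebi": "chebi",
    "up": "uniprot",
    "ncbigene": "ncbigene",
}


def name_to_identifier(name: str, organism_code: str = "") -> tuple[str, str] | None:
    """Map a KGML database name like ``cpd:C00031`` to (database, accession).

    Organism-prefixed gene names (``hsa:1234``) map to ``kegg.genes`` with
    the prefixed accession retained, as Identifiers.org expects.
    """
    if ":" not in name:
        return None
    prefix, acc = name.split(":", 1)
    if prefix in _NAME_PREFIXES:
        return _NAME_PREFIXES[prefix], acc
    if organism_code and prefix == organism_code:
        return "kegg.genes", name
    if prefix.isalpha() and prefix.islower() and len(prefix) <= 4:
        return "kegg.genes", name  # other organism codes
    return None


@dataclass
class AnnotationSet:
    entries: list[tuple[str, str]] = field(default_factory=list)  # (qualifier, uri)
    evidence_code: str = ECO_AUTOMATIC_ASSERTION

    def uris(self, qualifier: str | None = None) -> list[str]:
        return [u for q, u in self.entries if qualifier is None or q == qualifier]

    def accessions(self) -> set[str]:
        """Trailing path components of all URIs (database accessions)."""
        return {u.rsplit("/", 1)[-1] for _, u in self.entries}


@dataclass
class Compartment:
    id: str
    size: float | None = None


@dataclass
class Parameter:
    """A model parameter.  Newly created parameters carry value 1.0; units
    are derived later (:func:`pathmodels.kinetics.init_and_unitize`)."""

    id: str
    value: float = 1.0
    unit: dict[str, object] | None = None  # unit symbol -> exponent
    imported: bool = False


@dataclass
class Species:
    id: str
    name: str = ""
    sbo_term: str = ""
    compartment: str = "default"
    boundary_condition: bool = False
    initial_quantity: float | None = None
    has_only_substance_units: bool = False
    is_concentration: bool = False
    entry_type: str = ""  # source entry type (compound/enzyme/gene/...)


@dataclass
class Modifier:
    species: str
    sbo_term: str = ""  # SBO:0000169 inhibitor / SBO:0000170 activator / else catalyst


@dataclass
class Reaction:
    id: str
    reversible: bool = False
    reactants: list[tuple[str, float]] = field(default_factory=list)
    products: list[tuple[str, float]] = field(default_factory=list)
    modifiers: list[Modifier] = field(default_factory=list)
    kinetic_law: object | None = None  # RateLawSpec, attached by pathmodels.kinetics


@dataclass
class ProcessModel:
    model_id: str
    compartments: list[Compartment] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    layout: dict[str, LayoutBox] = field(default_factory=dict)
    annotations: dict[str, AnnotationSet] = field(default_factory=dict)
    notes: dict[str, dict[str, str]] = field(default_factory=dict)
    substance_units: str | None = None
    time_units: str | None = None
    volume_units: str | None = None

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def validate(self) -> None:
        ids = (
            [c.id for c in self.compartments]
            + [s.id for s in self.species]
            + [r.id for r in self.reactions]
            + [p.id for p in self.parameters]
        )
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise StructuralError(f"duplicate element ids: {dupes}")
        sids = {s.id for s in self.species}
        for r in self.reactions:
            for sid, _ in r.reactants + r.products:
                if sid not in sids:
                    raise StructuralError(f"reaction {r.id}: unknown species {sid!r}")
            for m in r.modifiers:
                if m.species not in sids:
                    raise StructuralError(f"reaction {r.id}: unknown modifier {m.species!r}")
        for aset in self.annotations.values():
            for _, uri in aset.entries:
                if "://" not in uri and not uri.startswith("urn:"):
                    raise StructuralError(f"not a URI: {uri!r}")


def assign_sbo(entry_type: str) -> str:
    """SBO term for a source entry type (total over the closed type set)."""
    return SBO_BY_ENTRY_TYPE[entry_type]


def annotate(identifiers: list[tuple[str, str]]) -> AnnotationSet:
    """Build cross-references for one element.

    ``identifiers`` are (database, accession) pairs.  When two or more
    identifiers come from the same database, each of them is qualified
    ``hasVersion`` (the element matches several versions of the concept);
    a database contributing a single identifier yields an ``is`` qualifier.
    The ECO evidence code is always attached.
    """
    counts: dict[str, int] = {}
    for db, _ in identifiers:
        counts[db] = counts.get(db, 0) + 1
    aset = AnnotationSet()
    for db, acc in identifiers:
        if db in DATABASES:
            uri = f"http://identifiers.org/{db}/{acc}"
        else:
            log.warning("unknown cross-reference database %r", db)
            uri = f"urn:local:{db}:{acc}"
        qualifier = "hasVersion" if counts[db] >= 2 else "is"
        aset.entries.append((qualifier, uri))
    return aset


def sanitize_id(raw: str, prefix: str) -> str:
    """Turn an arbitrary source id into a valid SBML SId."""
    cleaned = "".join(c if c.isalnum() or c == "_" else "_" for c in raw)
    if not cleaned or not (cleaned[0].isalpha() or cleaned[0] == "_"):
        cleaned = prefix + cleaned
    return cleaned


def translate_metabolic(graph: PathwayGraph) -> ProcessModel:
    """Translate an organism-filtered metabolic pathway into a process model.

    Each surviving entry becomes one species (SBO per entry type); each
    source reaction becomes one reaction with its enzymes as modifiers.
    Entry layout boxes are copied onto the corresponding species.  Group
    entries become a single complex species whose members are listed in the
    notes and cross-referenced with the ``isEncodedBy`` qualifier; members
    are not instantiated as standalone species unless they also occur
    outside the group.

    The source provides no localization, so the model has a single
    compartment ``default``.
    """
    model = ProcessModel(
        model_id=sanitize_id(graph.pathway_id or "pathway", "m_"),
        compartments=[Compartment("default", 1.0)],
    )
    member_only = _group_member_only_ids(graph)
    sid_of: dict[str, str] = {}
    for e in graph.entries:
        if e.id in member_only:
            continue
        sid = sanitize_id(f"s{e.id}", "s_")
        sid_of[e.id] = sid
        sp = Species(
            id=sid,
            name=e.names[0] if e.names else sid,
            sbo_term=assign_sbo(e.type),
            compartment="default",
            entry_type=e.type,
        )
        model.species.append(sp)
        if e.box is not None:
            model.layout[sid] = e.box
        idents = _entry_identifiers(e, graph.organism_code)
        aset = annotate(idents)
        notes: dict[str, str] = {"FULL_NAME": sp.name}
        if len(e.names) > 1:
            notes["SYNONYMS"] = " ".join(e.names[1:])
        if e.type == "group":
            members = [graph.entry(m) for m in e.group_members]
            notes["COMPLEX_MEMBERS"] = " ".join(
                m.names[0] if m.names else m.id for m in members
            )
            for m in members:
                for name in m.names:
                    ident = name_to_identifier(name, graph.organism_code)
                    if ident is not None:
                        aset.entries.append(
                            ("isEncodedBy", f"http://identifiers.org/{ident[0]}/{ident[1]}")
                        )
        model.annotations[sid] = aset
        model.notes[sid] = notes

    for r in graph.reactions:
        rid = sanitize_id(f"r{r.id}", "r_")
        rxn = Reaction(id=rid, reversible=r.reversible)
        for eid, coeff in r.substrates:
            rxn.reactants.append(_resolve(sid_of, eid, r.id, coeff))
        for eid, coeff in r.products:
            rxn.products.append(_resolve(sid_of, eid, r.id, coeff))
        for eid in r.enzymes:
            if eid not in sid_of:
                raise StructuralError(f"reaction {r.id}: dangling enzyme {eid!r}")
            rxn.modifiers.append(Modifier(species=sid_of[eid]))
        model.reactions.append(rxn)
        idents = [
            ident
            for name in r.name.split()
            if (ident := name_to_identifier(name, graph.organism_code)) is not None
        ]
        model.annotations[rid] = annotate(idents)
    model.validate()
    return model


def _resolve(sid_of: dict[str, str], eid: str, rid: str, coeff: float) -> tuple[str, float]:
    if eid not in sid_of:
        raise StructuralError(f"reaction {rid}: dangling participant {eid!r}")
    return sid_of[eid], coeff


def _entry_identifiers(e, organism_code: str) -> list[tuple[str, str]]:
    idents = []
    for name in e.names:
        ident = name_to_identifier(name, organism_code)
        if ident is not None:
            idents.append(ident)
    return idents


def _group_member_only_ids(graph: PathwayGraph) -> set[str]:
    """Entries that occur only as members of a group."""
    members: set[str] = set()
    for e in graph.entries:
        members.update(e.group_members)
    used: set[str] = set()
    for r in graph.reactions:
        used.update(s for s, _ in r.substrates)
        used.update(p for p, _ in r.products)
        used.update(r.enzymes)
    for rel in graph.relations:
        used.add(rel.source)
        used.add(rel.target)
    return members - used
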