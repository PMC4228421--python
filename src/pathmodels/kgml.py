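"""Reading, filtering and completion of KGML pathway descriptions.

KGML (KEGG Markup Language, v0.7.x element/attribute names) describes a
pathway map as *entries* (compounds, gene products, references to other
maps), *reactions* (biochemical conversions with substrates, products and
catalysing enzymes) and *relations* (signed or unsigned influences between
gene products, used mainly by signaling maps).  Layout information (a pixel
box) is attached to entries only.

Organism-specific maps are derived from orthologous template maps; enzymes
of the template that have no instance in the organism are retained in the
file for display purposes.  :func:`filter_organism` removes them (and, for
metabolic translation, the pathway-reference nodes) so that downstream
models only contain physical instances.  :func:`complete_reactions` adds
participants that the map omits but a reaction definition table provides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from lxml import etree

from .common import KgmlParseError, KgmlValidationError, LayoutBox

log = logging.getLogger(__name__)

#: Closed set of entry types handled by this dialect.
ENTRY_TYPES = frozenset({"compound", "enzyme", "gene", "ortholog", "group", "map"})

#: The 14 relation subtypes of the dialect, in their canonical order.
RELATION_SUBTYPES = (
    "activation",
    "inhibition",
    "expression",
    "repression",
    "indirect effect",
    "state change",
    "binding/association",
    "dissociation",
    "missing interaction",
    "phosphorylation",
    "dephosphorylation",
    "glycosylation",
    "ubiquitination",
    "methylation",
)

#: Background colour that marks an instantiated enzyme in organism-specific
#: maps (the "green enzyme" convention).
INSTANTIATED_COLOR = "#bfffbf"

_KNOWN_ENTRY_ATTRS = {"id", "name", "type", "reaction", "link", "instantiated"}
_KNOWN_GRAPHICS_ATTRS = {"name", "x", "y", "width", "height", "type", "fgcolor", "bgcolor", "coords"}


@dataclass
class Entry:
    id: str
    type: str
    names: list[str] = field(default_factory=list)
    instantiated: bool = True
    group_members: list[str] = field(default_factory=list)
    box: LayoutBox | None = None
    #: value of the entry's ``reaction`` attribute, linking catalysts to
    #: the reactions they catalyse (empty when absent)
    reaction: str = ""


@dataclass
class KgmlReaction:
    id: str
    reversible: bool
    substrates: list[tuple[str, float]] = field(default_factory=list)
    products: list[tuple[str, float]] = field(default_factory=list)
    enzymes: list[str] = field(default_factory=list)
    #: database identifier(s) of the reaction, e.g. ``rn:R00710``
    name: str = ""


@dataclass
class KgmlRelation:
    source: str
    target: str
    subtypes: list[str] = field(default_factory=list)


@dataclass
class PathwayGraph:
    pathway_id: str
    organism_code: str
    entries: list[Entry] = field(default_factory=list)
    reactions: list[KgmlReaction] = field(default_factory=list)
    relations: list[KgmlRelation] = field(default_factory=list)

    def entry(self, entry_id: str) -> Entry:
        for e in self.entries:
            if e.id == entry_id:
                return e
        raise KeyError(entry_id)

    def entry_ids(self) -> set[str]:
        return {e.id for e in self.entries}

    def validate(self) -> None:
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise KgmlValidationError(f"duplicate entry ids: {dupes}")
        known = set(ids)
        for e in self.entries:
            if e.type not in ENTRY_TYPES:
                raise KgmlValidationError(f"entry {e.id}: unknown type {e.type!r}")
            if (e.type == "group") != bool(e.group_members):
                raise KgmlValidationError(
                    f"entry {e.id}: group_members nonempty iff type is group"
                )
            for m in e.group_members:
                if m not in known:
                    raise KgmlValidationError(f"group {e.id}: unknown member {m!r}")
        for r in self.reactions:
            if not r.substrates and not r.products:
                raise KgmlValidationError(f"reaction {r.id}: no participants")
            for sid, _ in r.substrates + r.products:
                if sid not in known:
                    raise KgmlValidationError(f"reaction {r.id}: unknown participant {sid!r}")
            for sid in r.enzymes:
                if sid not in known:
                    raise KgmlValidationError(f"reaction {r.id}: unknown enzyme {sid!r}")
        for rel in self.relations:
            if not rel.subtypes:
                raise KgmlValidationError(f"relation {rel.source}->{rel.target}: no subtypes")
            for st in rel.subtypes:
                if st not in RELATION_SUBTYPES:
                    raise KgmlValidationError(
                        f"relation {rel.source}->{rel.target}: unknown subtype {st!r}"
                    )
            for sid in (rel.source, rel.target):
                if sid not in known:
                    raise KgmlValidationError(f"relation references unknown entry {sid!r}")


def _parse_bool(text: str, what: str) -> bool:
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise KgmlValidationError(f"{what}: cannot interpret boolean {text!r}")


def parse_kgml(source, color_convention: bool = False) -> PathwayGraph:
    """Parse a KGML document into a :class:`PathwayGraph`.

    ``source`` may be a path, a file object, or XML bytes/str.  Entry boxes
    are converted from KGML's center anchoring to top-left anchoring.

    The ``instantiated`` flag of an entry is read from a dedicated
    ``instantiated`` attribute when present.  With ``color_convention=True``
    the background colour of the entry graphics is consulted instead
    (``#BFFFBF`` marks an instantiated gene product); entries without
    either indication default to instantiated.
    """
    try:
        if isinstance(source, (bytes, str)) and not _looks_like_path(source):
            data = source.encode() if isinstance(source, str) else source
            root = etree.fromstring(data)
        else:
            root = etree.parse(source).getroot()
    except etree.XMLSyntaxError as exc:
        raise KgmlParseError(f"malformed XML (line {exc.lineno}): {exc.msg}") from exc
    if root.tag != "pathway":
        raise KgmlParseError(f"root element is {root.tag!r}, expected 'pathway'")

    graph = PathwayGraph(
        pathway_id=root.get("name", ""),
        organism_code=root.get("org", ""),
    )
    for el in root.findall("entry"):
        graph.entries.append(_parse_entry(el, color_convention))
    for el in root.findall("reaction"):
        graph.reactions.append(_parse_reaction(el))
    # catalysts declared via the entry "reaction" attribute
    by_name: dict[str, list[KgmlReaction]] = {}
    for r in graph.reactions:
        if r.name:
            by_name.setdefault(r.name, []).append(r)
    for e in graph.entries:
        if e.reaction:
            for rname in e.reaction.split():
                for r in by_name.get(rname, ()):
                    if e.id not in r.enzymes:
                        r.enzymes.append(e.id)
    for el in root.findall("relation"):
        graph.relations.append(_parse_relation(el))
    graph.validate()
    return graph


def _looks_like_path(s) -> bool:
    if isinstance(s, bytes):
        return False
    return not s.lstrip().startswith("<")


def _parse_entry(el, color_convention: bool) -> Entry:
    for attr in el.attrib:
        if attr not in _KNOWN_ENTRY_ATTRS:
            log.warning("entry %s: ignoring unrecognized attribute %r", el.get("id"), attr)
    etype = el.get("type", "")
    if etype not in ENTRY_TYPES:
        raise KgmlValidationError(f"entry {el.get('id')!r}: unknown type {etype!r}")
    entry = Entry(
        id=el.get("id", ""),
        type=etype,
        names=el.get("name", "").split(),
        reaction=el.get("reaction", ""),
    )
    gfx = el.find("graphics")
    if gfx is not None:
        for attr in gfx.attrib:
            if attr not in _KNOWN_GRAPHICS_ATTRS:
                log.warning("entry %s: ignoring graphics attribute %r", entry.id, attr)
        if gfx.get("x") is not None and gfx.get("y") is not None:
            entry.box = LayoutBox.from_center(
                float(gfx.get("x")),
                float(gfx.get("y")),
                float(gfx.get("width", 46)),
                float(gfx.get("height", 17)),
            )
    if el.get("instantiated") is not None:
        entry.instantiated = _parse_bool(el.get("instantiated"), f"entry {entry.id}")
    elif color_convention and etype in ("enzyme", "gene", "ortholog"):
        bg = (gfx.get("bgcolor", "") if gfx is not None else "").lower()
        entry.instantiated = bg == INSTANTIATED_COLOR
    entry.group_members = [c.get("id", "") for c in el.findall("component")]
    return entry


def _parse_reaction(el) -> KgmlReaction:
    rtype = el.get("type", "")
    if rtype not in ("reversible", "irreversible"):
        raise KgmlValidationError(f"reaction {el.get('id')!r}: unknown type {rtype!r}")
    rxn = KgmlReaction(
        id=el.get("id", ""),
        reversible=(rtype == "reversible"),
        name=el.get("name", ""),
    )
    for role, target in (("substrate", rxn.substrates), ("product", rxn.products)):
        for c in el.findall(role):
            # KGML frequently omits coefficients; they default to 1
            coeff = float(c.get("stoichiometry", "1"))
            target.append((c.get("id", ""), coeff))
    for c in el.findall("enzyme"):
        rxn.enzymes.append(c.get("id", ""))
    return rxn


def _parse_relation(el) -> KgmlRelation:
    rel = KgmlRelation(source=el.get("entry1", ""), target=el.get("entry2", ""))
    for st in el.findall("subtype"):
        name = st.get("name", "")
        if name not in RELATION_SUBTYPES:
            raise KgmlValidationError(
                f"relation {rel.source}->{rel.target}: unknown subtype {name!r}"
            )
        rel.subtypes.append(name)
    if not rel.subtypes:
        raise KgmlValidationError(f"relation {rel.source}->{rel.target}: no subtypes")
    return rel


def write_kgml(graph: PathwayGraph) -> str:
    """Serialize a :class:`PathwayGraph` back to KGML text.

    Boxes are converted back to center anchoring so that
    ``parse_kgml(write_kgml(g))`` reproduces ``g`` exactly.
    """
    root = etree.Element("pathway", name=graph.pathway_id, org=graph.organism_code)
    for e in graph.entries:
        attrs = {"id": e.id, "name": " ".join(e.names), "type": e.type}
        if e.reaction:
            attrs["reaction"] = e.reaction
        attrs["instantiated"] = "true" if e.instantiated else "false"
        el = etree.SubElement(root, "entry", attrs)
        if e.box is not None:
            etree.SubElement(
                el,
                "graphics",
                {
                    "x": _num(e.box.cx),
                    "y": _num(e.box.cy),
                    "width": _num(e.box.width),
                    "height": _num(e.box.height),
                },
            )
        for m in e.group_members:
            etree.SubElement(el, "component", {"id": m})
    for r in graph.reactions:
        el = etree.SubElement(
            root,
            "reaction",
            {
                "id": r.id,
                "name": r.name,
                "type": "reversible" if r.reversible else "irreversible",
            },
        )
        for role, parts in (("substrate", r.substrates), ("product", r.products)):
            for sid, coeff in parts:
                attrs = {"id": sid}
                if coeff != 1:
                    attrs["stoichiometry"] = _num(coeff)
                etree.SubElement(el, role, attrs)
        for sid in r.enzymes:
            etree.SubElement(el, "enzyme", {"id": sid})
    for rel in graph.relations:
        el = etree.SubElement(root, "relation", {"entry1": rel.source, "entry2": rel.target})
        for st in rel.subtypes:
            etree.SubElement(el, "subtype", {"name": st})
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def _num(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(v)


def filter_organism(graph: PathwayGraph, mode: str) -> PathwayGraph:
    """Remove nodes without a physical instance in the organism.

    Non-instantiated ortholog entries (template enzymes without an instance
    in the organism) are dropped together with their catalysis links and
    relations.  In ``metabolic`` mode, pathway-reference nodes (entries of
    type ``map``) are removed as well; ``signaling`` mode keeps them, since
    links to other maps are meaningful influence targets there.

    Reactions survive the removal of their catalysts with an emptied enzyme
    list; a reaction is only dropped if it loses *all* substrates and
    products.  The operation is idempotent.
    """
    if mode not in ("metabolic", "signaling"):
        raise ValueError(f"unknown mode {mode!r}")
    removed: set[str] = set()
    for e in graph.entries:
        if e.type == "ortholog" and not e.instantiated:
            removed.add(e.id)
        elif mode == "metabolic" and e.type == "map":
            removed.add(e.id)

    entries = []
    for e in graph.entries:
        if e.id in removed:
            continue
        members = [m for m in e.group_members if m not in removed]
        if e.type == "group" and not members:
            removed.add(e.id)
            continue
        entries.append(replace(e, names=list(e.names), group_members=members))

    reactions = []
    for r in graph.reactions:
        subs = [(s, c) for s, c in r.substrates if s not in removed]
        prods = [(p, c) for p, c in r.products if p not in removed]
        if not subs and not prods:
            continue
        enzymes = [z for z in r.enzymes if z not in removed]
        reactions.append(replace(r, substrates=subs, products=prods, enzymes=enzymes))

    relations = [
        replace(rel, subtypes=list(rel.subtypes))
        for rel in graph.relations
        if rel.source not in removed and rel.target not in removed
    ]
    out = PathwayGraph(
        pathway_id=graph.pathway_id,
        organism_code=graph.organism_code,
        entries=entries,
        reactions=reactions,
        relations=relations,
    )
    out.validate()
    return out


ReactionDefs = dict[str, list[tuple[str, str, float]]]


def read_reaction_defs(path) -> ReactionDefs:
    """Read a reaction definition table.

    Tab-separated columns: reaction id, role (substrate|product|enzyme),
    species database id, coefficient (optional, default 1).
    """
    defs: ReactionDefs = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            rid, role, sid = parts[0], parts[1], parts[2]
            coeff = float(parts[3]) if len(parts) > 3 and parts[3] else 1.0
            if role not in ("substrate", "product", "enzyme"):
                raise KgmlValidationError(f"reaction_defs: unknown role {role!r}")
            defs.setdefault(rid, []).append((role, sid, coeff))
    return defs


def complete_reactions(graph: PathwayGraph, reaction_defs: ReactionDefs) -> PathwayGraph:
    """Add participants that a reaction's definition lists but the map omits.

    A participant of a definition is matched against the database names of
    the entries already taking part in the reaction; unmatched participants
    are appended, synthesizing a new entry (type compound for substrates and
    products, enzyme for catalysts) without a layout box.  Existing
    participants are never altered; a stoichiometry conflict between map and
    definition is logged and the map's value kept.
    """
    out = PathwayGraph(
        pathway_id=graph.pathway_id,
        organism_code=graph.organism_code,
        entries=[replace(e, names=list(e.names), group_members=list(e.group_members)) for e in graph.entries],
        reactions=[
            replace(r, substrates=list(r.substrates), products=list(r.products), enzymes=list(r.enzymes))
            for r in graph.reactions
        ],
        relations=[replace(rel, subtypes=list(rel.subtypes)) for rel in graph.relations],
    )
    if not reaction_defs:
        return out
    next_id = _next_numeric_id(out)
    # species-name -> entry-id index over *all* entries, so a compound shared
    # by two reactions is synthesized once
    name_index: dict[str, str] = {}
    for e in out.entries:
        for n in e.names:
            name_index.setdefault(n, e.id)

    for rxn in out.reactions:
        for role, sid, coeff in reaction_defs.get(rxn.id, ()):
            part_list = {"substrate": rxn.substrates, "product": rxn.products}.get(role)
            present = _find_participant(out, rxn, role, sid)
            if present is not None:
                if part_list is not None:
                    for i, (eid, c) in enumerate(part_list):
                        if eid == present and c != coeff:
                            log.warning(
                                "reaction %s: definition coefficient %s for %s conflicts "
                                "with map value %s; keeping map value",
                                rxn.id, coeff, sid, c,
                            )
                continue
            eid = name_index.get(sid)
            if eid is None:
                eid = str(next_id)
                next_id += 1
                out.entries.append(
                    Entry(
                        id=eid,
                        type="compound" if role != "enzyme" else "enzyme",
                        names=[sid],
                    )
                )
                name_index[sid] = eid
            if role == "enzyme":
                if eid not in rxn.enzymes:
                    rxn.enzymes.append(eid)
            else:
                part_list.append((eid, coeff))
    out.validate()
    return out


def _find_participant(graph: PathwayGraph, rxn: KgmlReaction, role: str, sid: str) -> str | None:
    ids = {
        "substrate": [s for s, _ in rxn.substrates],
        "product": [p for p, _ in rxn.products],
        "enzyme": list(rxn.enzymes),
    }[role]
    for eid in ids:
        if sid in graph.entry(eid).names:
            return eid
    return None


def _next_numeric_id(graph: PathwayGraph) -> int:
    mx = 0
    for e in graph.entries:
        try:
            mx = max(mx, int(e.id))
        except ValueError:
            pass
    return mx + 1
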