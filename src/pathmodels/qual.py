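"""Qualitative (signed-influence) models from signaling pathway relations.

Signaling maps carry *relations* between gene products rather than
mass-balanced reactions.  Each relation becomes a transition whose input
carries a sign — ``positive`` for activation/expression, ``negative`` for
inhibition/repression, ``dual`` when a relation is simultaneously
activating and inhibiting, and ``unknown`` for the purely mechanistic
subtypes (a phosphorylation may either activate or inactivate its target).
An input also carries an SBO term refining the mechanism.

The resulting models are scaffolds: they record topology and signs only,
with no logical rules, and every activity is Boolean (``max_level`` 1).
An external interaction-sign table (activating/inhibiting control types)
can be used to resolve ``unknown`` signs (:func:`enrich_signs`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import libsbml

from .common import KgmlValidationError, LayoutBox, StructuralError
from .kgml import PathwayGraph
from .model import AnnotationSet, annotate, assign_sbo, name_to_identifier, sanitize_id

log = logging.getLogger(__name__)

#: relation subtype -> (input sign, input SBO term)
SIGN_SBO_TABLE = {
    "activation": ("positive", "SBO:0000170"),  # stimulation
    "inhibition": ("negative", "SBO:0000169"),  # inhibition
    "expression": ("positive", "SBO:0000170"),
    "repression": ("negative", "SBO:0000169"),
    "indirect effect": ("unknown", "SBO:0000344"),  # molecular interaction
    "state change": ("unknown", "SBO:0000168"),  # control
    "binding/association": ("unknown", "SBO:0000177"),  # non-covalent binding
    "dissociation": ("unknown", "SBO:0000177"),
    "missing interaction": ("unknown", "SBO:0000396"),  # uncertain process
    "phosphorylation": ("unknown", "SBO:0000216"),
    "dephosphorylation": ("unknown", "SBO:0000330"),
    "glycosylation": ("unknown", "SBO:0000217"),
    "ubiquitination": ("unknown", "SBO:0000224"),
    "methylation": ("unknown", "SBO:0000214"),
}

_SIGNED = ("activation", "inhibition", "expression", "repression")


@dataclass
class QualSpecies:
    id: str
    name: str = ""
    sbo_term: str = ""
    max_level: int = 1
    compartment: str = "default"
    entry_type: str = ""


@dataclass
class TransitionInput:
    species: str
    sign: str = "unknown"  # positive | negative | dual | unknown
    sbo_term: str = ""


@dataclass
class Transition:
    id: str
    inputs: list[TransitionInput] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)


@dataclass
class QualModel:
    model_id: str
    qualitative_species: list[QualSpecies] = field(default_factory=list)
    transitions: list[Transition] = field(default_factory=list)
    layout: dict[str, LayoutBox] = field(default_factory=dict)
    annotations: dict[str, AnnotationSet] = field(default_factory=dict)
    notes: dict[str, dict[str, str]] = field(default_factory=dict)

    def validate(self) -> None:
        sids = {s.id for s in self.qualitative_species}
        if len(sids) != len(self.qualitative_species):
            raise StructuralError("duplicate qualitative species ids")
        for t in self.transitions:
            for i in t.inputs:
                if i.species not in sids:
                    raise StructuralError(f"transition {t.id}: unknown input {i.species!r}")
            for o in t.outputs:
                if o not in sids:
                    raise StructuralError(f"transition {t.id}: unknown output {o!r}")


def map_relation_sign(subtypes: list[str]) -> tuple[str, str]:
    """Sign and SBO term of a relation's input, from its subtype list.

    The sign is ``dual`` when both an activating and an inhibiting subtype
    are present.  The SBO term comes from the highest-priority subtype:
    the first listed subtype of the activation/inhibition class when one
    exists, the first listed subtype otherwise.
    """
    if not subtypes:
        raise KgmlValidationError("relation has no subtypes")
    for st in subtypes:
        if st not in SIGN_SBO_TABLE:
            raise KgmlValidationError(f"unknown relation subtype {st!r}")
    activating = any(st in ("activation", "expression") for st in subtypes)
    inhibiting = any(st in ("inhibition", "repression") for st in subtypes)
    if activating and inhibiting:
        sign = "dual"
    elif activating:
        sign = "positive"
    elif inhibiting:
        sign = "negative"
    else:
        sign = "unknown"
    chosen = next((st for st in subtypes if st in _SIGNED), subtypes[0])
    return sign, SIGN_SBO_TABLE[chosen][1]


def translate_signaling(graph: PathwayGraph) -> QualModel:
    """Translate an organism-filtered signaling pathway into a qualitative
    model: one Boolean qualitative species per entry, one transition per
    relation, input sign per :func:`map_relation_sign`, layout copied and
    automatic-assertion evidence attached."""
    model = QualModel(model_id=sanitize_id(graph.pathway_id or "pathway", "m_"))
    sid_of: dict[str, str] = {}
    for e in graph.entries:
        sid = sanitize_id(f"qs{e.id}", "qs_")
        sid_of[e.id] = sid
        model.qualitative_species.append(
            QualSpecies(
                id=sid,
                name=e.names[0] if e.names else sid,
                sbo_term=assign_sbo(e.type),
                entry_type=e.type,
            )
        )
        if e.box is not None:
            model.layout[sid] = e.box
        idents = [
            ident
            for name in e.names
            if (ident := name_to_identifier(name, graph.organism_code)) is not None
        ]
        model.annotations[sid] = annotate(idents)
    for i, rel in enumerate(graph.relations):
        sign, sbo = map_relation_sign(rel.subtypes)
        t = Transition(
            id=f"t{i}",
            inputs=[TransitionInput(species=sid_of[rel.source], sign=sign, sbo_term=sbo)],
            outputs=[sid_of[rel.target]],
        )
        model.transitions.append(t)
        model.annotations[t.id] = AnnotationSet()
        model.notes[t.id] = {"SUBTYPES": " ".join(rel.subtypes)}
    model.validate()
    return model


def read_sign_table(path) -> list[tuple[str, str, str]]:
    """Read a 3-column interaction-sign table: source accession, target
    accession, control type (activation|inhibition)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            src, tgt, control = line.split("\t")[:3]
            if control not in ("activation", "inhibition"):
                raise StructuralError(f"sign table: unknown control type {control!r}")
            rows.append((src, tgt, control))
    return rows


def enrich_signs(
    model: QualModel, sign_table: list[tuple[str, str, str]]
) -> tuple[QualModel, int]:
    """Resolve unknown signs from an external interaction-sign table.

    Rows are matched by annotation accession of the (source, target) pair,
    respecting direction.  Only inputs whose sign is ``unknown`` are
    rewritten (the source map's own signs take precedence); topology is
    never changed.  Returns the model and the number of rewritten inputs.
    """
    by_pair: dict[tuple[str, str], str] = {}
    for src, tgt, control in sign_table:
        by_pair.setdefault((src, tgt), control)

    def accessions(sid: str) -> set[str]:
        aset = model.annotations.get(sid)
        return aset.accessions() if aset is not None else set()

    matched = 0
    for t in model.transitions:
        for inp in t.inputs:
            if inp.sign != "unknown":
                continue
            src_accs = accessions(inp.species)
            for out in t.outputs:
                hit = next(
                    (
                        by_pair[(a, b)]
                        for a in sorted(src_accs)
                        for b in sorted(accessions(out))
                        if (a, b) in by_pair
                    ),
                    None,
                )
                if hit is not None:
                    inp.sign = "positive" if hit == "activation" else "negative"
                    inp.sbo_term = "SBO:0000170" if hit == "activation" else "SBO:0000169"
                    matched += 1
                    break
    return model, matched


# ---------------------------------------------------------------------------
# SBML qual read/write


def write_qual(model: QualModel) -> str:
    """Serialize to SBML L3V1 with the qual (and layout) packages."""
    from .sbml_io import _set_annotations, _set_notes  # shared helpers

    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("qual", 1)
    ns.addPackageNamespace("layout", 1)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("qual", True)
    doc.setPackageRequired("layout", False)
    sbml = doc.createModel()
    sbml.setId(model.model_id)
    comp = sbml.createCompartment()
    comp.setId("default")
    comp.setConstant(True)
    comp.setSize(1.0)
    qplug = sbml.getPlugin("qual")
    for s in model.qualitative_species:
        qs = qplug.createQualitativeSpecies()
        qs.setId(s.id)
        if s.name:
            qs.setName(s.name)
        qs.setCompartment(s.compartment)
        qs.setConstant(False)
        qs.setMaxLevel(s.max_level)
        if s.sbo_term:
            qs.setSBOTerm(s.sbo_term)
        notes = dict(model.notes.get(s.id, {}))
        if s.entry_type:
            notes.setdefault("KEGG_TYPE", s.entry_type)
        _set_notes(qs, notes)
        if s.id in model.annotations:
            _set_annotations(qs, model.annotations[s.id])
    for t in model.transitions:
        tr = qplug.createTransition()
        tr.setId(t.id)
        for k, inp in enumerate(t.inputs):
            i = tr.createInput()
            i.setId(f"{t.id}_in{k}")
            i.setQualitativeSpecies(inp.species)
            i.setSign(
                {
                    "positive": libsbml.INPUT_SIGN_POSITIVE,
                    "negative": libsbml.INPUT_SIGN_NEGATIVE,
                    "dual": libsbml.INPUT_SIGN_DUAL,
                    "unknown": libsbml.INPUT_SIGN_UNKNOWN,
                }[inp.sign]
            )
            i.setTransitionEffect(libsbml.INPUT_TRANSITION_EFFECT_NONE)
            if inp.sbo_term:
                i.setSBOTerm(inp.sbo_term)
        for k, out in enumerate(t.outputs):
            o = tr.createOutput()
            o.setId(f"{t.id}_out{k}")
            o.setQualitativeSpecies(out)
            o.setTransitionEffect(libsbml.OUTPUT_TRANSITION_EFFECT_ASSIGNMENT_LEVEL)
        _set_notes(tr, model.notes.get(t.id, {}))
        if t.id in model.annotations:
            _set_annotations(tr, model.annotations[t.id])
    if model.layout:
        _write_qual_layout(sbml, model)
    return libsbml.writeSBMLToString(doc)


def _write_qual_layout(sbml, model: QualModel) -> None:
    lplug = sbml.getPlugin("layout")
    layout = lplug.createLayout()
    layout.setId("layout0")
    dims = libsbml.Dimensions(layout.getLevel(), layout.getVersion(), 1)
    dims.setWidth(max(b.x2 for b in model.layout.values()) + 10)
    dims.setHeight(max(b.y2 for b in model.layout.values()) + 10)
    layout.setDimensions(dims)
    for sid in sorted(model.layout):
        box = model.layout[sid]
        glyph = layout.createGeneralGlyph()
        glyph.setId(f"gg_{sid}")
        glyph.setReferenceId(sid)
        bb = libsbml.BoundingBox(layout.getLevel(), layout.getVersion())
        bb.setX(box.x)
        bb.setY(box.y)
        bb.setWidth(box.width)
        bb.setHeight(box.height)
        glyph.setBoundingBox(bb)


def read_qual(document: str) -> QualModel:
    from .sbml_io import _get_annotations, parse_notes

    doc = libsbml.readSBMLFromString(document)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise StructuralError("invalid SBML: " + "; ".join(msgs))
    sbml = doc.getModel()
    qplug = sbml.getPlugin("qual")
    if qplug is None:
        raise StructuralError("document has no qual content")
    model = QualModel(model_id=sbml.getId() or "model")
    sign_names = {
        libsbml.INPUT_SIGN_POSITIVE: "positive",
        libsbml.INPUT_SIGN_NEGATIVE: "negative",
        libsbml.INPUT_SIGN_DUAL: "dual",
        libsbml.INPUT_SIGN_UNKNOWN: "unknown",
    }
    for i in range(qplug.getNumQualitativeSpecies()):
        qs = qplug.getQualitativeSpecies(i)
        notes = parse_notes(qs.getNotes())
        model.qualitative_species.append(
            QualSpecies(
                id=qs.getId(),
                name=qs.getName(),
                sbo_term=qs.getSBOTermID() if qs.isSetSBOTerm() else "",
                max_level=qs.getMaxLevel(),
                compartment=qs.getCompartment(),
                entry_type=notes.pop("KEGG_TYPE", ""),
            )
        )
        if notes:
            model.notes[qs.getId()] = notes
        aset = _get_annotations(qs)
        if aset is not None:
            model.annotations[qs.getId()] = aset
    for i in range(qplug.getNumTransitions()):
        tr = qplug.getTransition(i)
        t = Transition(id=tr.getId())
        for j in range(tr.getNumInputs()):
            inp = tr.getInput(j)
            t.inputs.append(
                TransitionInput(
                    species=inp.getQualitativeSpecies(),
                    sign=sign_names.get(inp.getSign(), "unknown"),
                    sbo_term=inp.getSBOTermID() if inp.isSetSBOTerm() else "",
                )
            )
        for j in range(tr.getNumOutputs()):
            t.outputs.append(tr.getOutput(j).getQualitativeSpecies())
        model.transitions.append(t)
        notes = parse_notes(tr.getNotes())
        if notes:
            model.notes[t.id] = notes
        aset = _get_annotations(tr)
        if aset is not None:
            model.annotations[t.id] = aset
    lplug = sbml.getPlugin("layout")
    if lplug is not None and lplug.getNumLayouts() > 0:
        layout = lplug.getLayout(0)
        for j in range(layout.getNumAdditionalGraphicalObjects()):
            g = layout.getAdditionalGraphicalObject(j)
            bb = g.getBoundingBox()
            ref = g.getReferenceId() if hasattr(g, "getReferenceId") else g.getId()[3:]
            model.layout[ref] = LayoutBox(bb.getX(), bb.getY(), bb.getWidth(), bb.getHeight())
    model.validate()
    return model
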