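"""SBML read/write for process models and qualitative models.

Process models are written as SBML Level 3 Version 1 Core documents with
the Layout package carrying the entry boxes; qualitative models use the
Qualitative Models ("qual") package.  Notes are stored as a canonical flat
key/value XHTML rendering so that write/read round trips are stable, and
cross-references become RDF CV terms with BioModels.net biology qualifiers.
"""

from __future__ import annotations

import sympy
import libsbml

from .common import LayoutBox, StructuralError
from .model import (
    AnnotationSet,
    Compartment,
    Modifier,
    Parameter,
    ProcessModel,
    Reaction,
    Species,
)
from .kinetics import RateLawSpec
from . import units as U

_QUALIFIERS = {
    "is": libsbml.BQB_IS,
    "hasVersion": libsbml.BQB_HAS_VERSION,
    "isEncodedBy": libsbml.BQB_IS_ENCODED_BY,
    "isDescribedBy": libsbml.BQB_IS_DESCRIBED_BY,
}
_QUALIFIER_NAMES = {v: k for k, v in _QUALIFIERS.items()}

_BASE_UNITS = {
    "mole": libsbml.UNIT_KIND_MOLE,
    "second": libsbml.UNIT_KIND_SECOND,
    "litre": libsbml.UNIT_KIND_LITRE,
    "gram": libsbml.UNIT_KIND_GRAM,
}
_BASE_UNIT_NAMES = {v: k for k, v in _BASE_UNITS.items()}


def _check(status, what: str) -> None:
    if status is None:
        raise StructuralError(f"libsbml failed: {what}")
    if isinstance(status, int) and status != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise StructuralError(f"libsbml error {status}: {what}")


# ---------------------------------------------------------------------------
# notes / annotations / math helpers

_XHTML = "http://www.w3.org/1999/xhtml"


def render_notes(notes: dict[str, str]) -> str:
    body = "".join(f"<p>{k}: {notes[k]}</p>" for k in sorted(notes))
    return f'<body xmlns="{_XHTML}">{body}</body>'


def parse_notes(node) -> dict[str, str]:
    out: dict[str, str] = {}
    if node is None:
        return out
    text = libsbml.XMLNode.convertXMLNodeToString(node)
    import re

    for m in re.finditer(r"<p>\s*([^<:]+?)\s*:\s*(.*?)\s*</p>", text, re.S):
        out[m.group(1)] = m.group(2)
    return out


def _set_notes(element, notes: dict[str, str]) -> None:
    if notes:
        _check(element.setNotes(render_notes(notes)), f"notes on {element.getId()}")


def _set_annotations(element, aset: AnnotationSet) -> None:
    element.setMetaId(f"meta_{element.getId()}")
    for qualifier, uri in aset.entries:
        cv = libsbml.CVTerm()
        cv.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
        cv.setBiologicalQualifierType(_QUALIFIERS[qualifier])
        cv.addResource(uri)
        _check(element.addCVTerm(cv), f"cvterm on {element.getId()}")
    if aset.evidence_code:
        cv = libsbml.CVTerm()
        cv.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
        cv.setBiologicalQualifierType(libsbml.BQB_IS_DESCRIBED_BY)
        cv.addResource(f"http://identifiers.org/eco/{aset.evidence_code}")
        _check(element.addCVTerm(cv), f"eco on {element.getId()}")


def _get_annotations(element) -> AnnotationSet | None:
    n = element.getNumCVTerms()
    if n == 0:
        return None
    aset = AnnotationSet(evidence_code="")
    for i in range(n):
        cv = element.getCVTerm(i)
        qualifier = _QUALIFIER_NAMES.get(cv.getBiologicalQualifierType(), "is")
        for j in range(cv.getNumResources()):
            uri = cv.getResourceURI(j)
            if qualifier == "isDescribedBy" and "/eco/" in uri:
                aset.evidence_code = uri.rsplit("/", 1)[-1]
            else:
                aset.entries.append((qualifier, uri))
    return aset


def expr_to_math(expr: sympy.Expr):
    formula = sympy.sstr(expr).replace("**", "^")
    ast = libsbml.parseL3Formula(formula)
    if ast is None:
        raise StructuralError(f"cannot encode formula {formula!r}")
    return ast


def math_to_expr(ast) -> sympy.Expr:
    formula = libsbml.formulaToL3String(ast)
    return sympy.sympify(formula.replace("^", "**"))


def _unit_def_id(unit: U.Unit) -> str:
    if not unit:
        return "dimensionless"
    parts = []
    for k in sorted(unit):
        e = sympy.nsimplify(unit[k])
        tag = k if e == 1 else f"{k}{str(e).replace('-', 'm').replace('/', '_')}"
        parts.append(tag)
    return "u_" + "_".join(parts)


# ---------------------------------------------------------------------------
# writing


def write_model(model: ProcessModel) -> str:
    """Serialize a process model to an SBML L3V1 (Core + Layout) string."""
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "layout", 1)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("layout", False)
    sbml = doc.createModel()
    _check(sbml.setId(model.model_id), "model id")
    if model.substance_units:
        sbml.setSubstanceUnits(model.substance_units)
        sbml.setExtentUnits(model.substance_units)
    if model.time_units:
        sbml.setTimeUnits(model.time_units)
    if model.volume_units:
        sbml.setVolumeUnits(model.volume_units)

    unit_ids: dict[str, U.Unit] = {}

    def ensure_unit(unit: U.Unit | None) -> str | None:
        if unit is None:
            return None
        uid = _unit_def_id(unit)
        if uid == "dimensionless":
            return uid
        if uid not in unit_ids:
            unit_ids[uid] = unit
            ud = sbml.createUnitDefinition()
            ud.setId(uid)
            for k in sorted(unit):
                u = ud.createUnit()
                u.setKind(_BASE_UNITS[k])
                e = sympy.nsimplify(unit[k])
                u.setExponent(float(e))
                u.setScale(0)
                u.setMultiplier(1.0)
        return uid

    for c in model.compartments:
        comp = sbml.createCompartment()
        comp.setId(c.id)
        comp.setConstant(True)
        comp.setSpatialDimensions(3)
        if c.size is not None:
            comp.setSize(c.size)

    for s in model.species:
        sp = sbml.createSpecies()
        sp.setId(s.id)
        if s.name:
            sp.setName(s.name)
        sp.setCompartment(s.compartment)
        sp.setBoundaryCondition(s.boundary_condition)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(s.has_only_substance_units)
        if s.sbo_term:
            sp.setSBOTerm(s.sbo_term)
        if s.initial_quantity is not None:
            if s.is_concentration:
                sp.setInitialConcentration(s.initial_quantity)
            else:
                sp.setInitialAmount(s.initial_quantity)
        notes = dict(model.notes.get(s.id, {}))
        if s.entry_type:
            notes.setdefault("KEGG_TYPE", s.entry_type)
        _set_notes(sp, notes)
        if s.id in model.annotations:
            _set_annotations(sp, model.annotations[s.id])

    for p in model.parameters:
        par = sbml.createParameter()
        par.setId(p.id)
        par.setValue(p.value)
        par.setConstant(True)
        uid = ensure_unit(p.unit)
        if uid:
            par.setUnits(uid)

    for r in model.reactions:
        rxn = sbml.createReaction()
        rxn.setId(r.id)
        rxn.setReversible(r.reversible)
        rxn.setFast(False)
        for sid, coeff in r.reactants:
            ref = rxn.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(coeff)
            ref.setConstant(True)
        for sid, coeff in r.products:
            ref = rxn.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(coeff)
            ref.setConstant(True)
        for m in r.modifiers:
            ref = rxn.createModifier()
            ref.setSpecies(m.species)
            if m.sbo_term:
                ref.setSBOTerm(m.sbo_term)
        _set_notes(rxn, model.notes.get(r.id, {}))
        if r.id in model.annotations:
            _set_annotations(rxn, model.annotations[r.id])
        law: RateLawSpec | None = r.kinetic_law
        if law is not None:
            kl = rxn.createKineticLaw()
            _check(kl.setMath(expr_to_math(law.expression)), f"math of {r.id}")
            for p in law.params:
                lp = kl.createLocalParameter()
                lp.setId(p.id)
                lp.setValue(p.value)
                uid = ensure_unit(p.unit)
                if uid:
                    lp.setUnits(uid)
            kl.setNotes(render_notes(_law_notes(law)))

    if model.layout:
        _write_layout(sbml, model)
    # no program name/version: libsbml would add a timestamped comment,
    # breaking byte-identical reruns
    return libsbml.writeSBMLToString(doc)


def _law_notes(law: RateLawSpec) -> dict[str, str]:
    notes = {"RATE_LAW_FORM": law.form}
    if law.thermo_mode:
        notes["THERMO_MODE"] = law.thermo_mode
    if law.pruned:
        notes["PRUNED"] = " ".join(law.pruned)
    if law.param_species:
        notes["PARAM_SPECIES"] = " ".join(
            f"{k}={v}" for k, v in sorted(law.param_species.items())
        )
    if law.reactant_index:
        notes["RATE_REACTANTS"] = " ".join(law.reactant_index)
    if law.product_index:
        notes["RATE_PRODUCTS"] = " ".join(law.product_index)
    return notes


def _write_layout(sbml, model: ProcessModel) -> None:
    lplug = sbml.getPlugin("layout")
    layout = lplug.createLayout()
    layout.setId("layout0")
    max_x = max(b.x2 for b in model.layout.values())
    max_y = max(b.y2 for b in model.layout.values())
    dims = libsbml.Dimensions(layout.getLevel(), layout.getVersion(), 1)
    dims.setWidth(max_x + 10)
    dims.setHeight(max_y + 10)
    layout.setDimensions(dims)
    species_ids = {s.id for s in model.species}
    reaction_ids = {r.id for r in model.reactions}
    for eid in sorted(model.layout):
        box = model.layout[eid]
        if eid in species_ids:
            glyph = layout.createSpeciesGlyph()
            glyph.setId(f"sg_{eid}")
            glyph.setSpeciesId(eid)
        elif eid in reaction_ids:
            glyph = layout.createReactionGlyph()
            glyph.setId(f"rg_{eid}")
            glyph.setReactionId(eid)
        else:
            continue
        bb = libsbml.BoundingBox(layout.getLevel(), layout.getVersion())
        bb.setX(box.x)
        bb.setY(box.y)
        bb.setWidth(box.width)
        bb.setHeight(box.height)
        glyph.setBoundingBox(bb)


# ---------------------------------------------------------------------------
# reading


def read_model(document: str) -> ProcessModel:
    """Parse an SBML document written by :func:`write_model` back into a
    :class:`ProcessModel`."""
    doc = libsbml.readSBMLFromString(document)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise StructuralError("invalid SBML: " + "; ".join(msgs))
    sbml = doc.getModel()
    if sbml is None:
        raise StructuralError("document contains no model")
    model = ProcessModel(model_id=sbml.getId() or "model")
    model.compartments = []
    if sbml.isSetSubstanceUnits():
        model.substance_units = sbml.getSubstanceUnits()
    if sbml.isSetTimeUnits():
        model.time_units = sbml.getTimeUnits()
    if sbml.isSetVolumeUnits():
        model.volume_units = sbml.getVolumeUnits()

    unit_defs: dict[str, U.Unit] = {}
    for i in range(sbml.getNumUnitDefinitions()):
        ud = sbml.getUnitDefinition(i)
        unit: U.Unit = {}
        for j in range(ud.getNumUnits()):
            u = ud.getUnit(j)
            name = _BASE_UNIT_NAMES.get(u.getKind())
            if name:
                unit = U.unit_mul(unit, {name: sympy.nsimplify(u.getExponent())})
        unit_defs[ud.getId()] = unit
    unit_defs["dimensionless"] = {}

    for i in range(sbml.getNumCompartments()):
        c = sbml.getCompartment(i)
        model.compartments.append(
            Compartment(c.getId(), c.getSize() if c.isSetSize() else None)
        )
    for i in range(sbml.getNumSpecies()):
        sp = sbml.getSpecies(i)
        notes = parse_notes(sp.getNotes())
        s = Species(
            id=sp.getId(),
            name=sp.getName(),
            sbo_term=sp.getSBOTermID() if sp.isSetSBOTerm() else "",
            compartment=sp.getCompartment(),
            boundary_condition=sp.getBoundaryCondition(),
            has_only_substance_units=sp.getHasOnlySubstanceUnits(),
            entry_type=notes.pop("KEGG_TYPE", ""),
        )
        if sp.isSetInitialAmount():
            s.initial_quantity = sp.getInitialAmount()
        elif sp.isSetInitialConcentration():
            s.initial_quantity = sp.getInitialConcentration()
            s.is_concentration = True
        model.species.append(s)
        if notes:
            model.notes[s.id] = notes
        aset = _get_annotations(sp)
        if aset is not None:
            model.annotations[s.id] = aset
    for i in range(sbml.getNumParameters()):
        p = sbml.getParameter(i)
        model.parameters.append(
            Parameter(
                id=p.getId(),
                value=p.getValue(),
                unit=unit_defs.get(p.getUnits()) if p.isSetUnits() else None,
            )
        )
    for i in range(sbml.getNumReactions()):
        rx = sbml.getReaction(i)
        r = Reaction(id=rx.getId(), reversible=rx.getReversible())
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            r.reactants.append((ref.getSpecies(), ref.getStoichiometry()))
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            r.products.append((ref.getSpecies(), ref.getStoichiometry()))
        for j in range(rx.getNumModifiers()):
            ref = rx.getModifier(j)
            r.modifiers.append(
                Modifier(
                    species=ref.getSpecies(),
                    sbo_term=ref.getSBOTermID() if ref.isSetSBOTerm() else "",
                )
            )
        model.reactions.append(r)
        notes = parse_notes(rx.getNotes())
        if notes:
            model.notes[r.id] = notes
        aset = _get_annotations(rx)
        if aset is not None:
            model.annotations[r.id] = aset
        if rx.isSetKineticLaw():
            kl = rx.getKineticLaw()
            law_notes = parse_notes(kl.getNotes())
            params = []
            for j in range(kl.getNumLocalParameters()):
                lp = kl.getLocalParameter(j)
                params.append(
                    Parameter(
                        id=lp.getId(),
                        value=lp.getValue(),
                        unit=unit_defs.get(lp.getUnits()) if lp.isSetUnits() else None,
                    )
                )
            param_species = dict(
                kv.split("=", 1)
                for kv in law_notes.get("PARAM_SPECIES", "").split()
                if "=" in kv
            )
            r.kinetic_law = RateLawSpec(
                form=law_notes.get("RATE_LAW_FORM", "imported"),
                expression=math_to_expr(kl.getMath()),
                params=params,
                reactant_index=law_notes.get("RATE_REACTANTS", "").split(),
                product_index=law_notes.get("RATE_PRODUCTS", "").split(),
                modifier_index=[m.species for m in r.modifiers],
                stoich={sid: abs(c) for sid, c in r.reactants + r.products},
                pruned=law_notes.get("PRUNED", "").split(),
                param_species=param_species,
                thermo_mode=law_notes.get("THERMO_MODE", ""),
            )

    lplug = sbml.getPlugin("layout")
    if lplug is not None and lplug.getNumLayouts() > 0:
        layout = lplug.getLayout(0)
        for j in range(layout.getNumSpeciesGlyphs()):
            g = layout.getSpeciesGlyph(j)
            bb = g.getBoundingBox()
            model.layout[g.getSpeciesId()] = LayoutBox(
                bb.getX(), bb.getY(), bb.getWidth(), bb.getHeight()
            )
        for j in range(layout.getNumReactionGlyphs()):
            g = layout.getReactionGlyph(j)
            bb = g.getBoundingBox()
            model.layout[g.getReactionId()] = LayoutBox(
                bb.getX(), bb.getY(), bb.getWidth(), bb.getHeight()
            )
    model.validate()
    return model
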