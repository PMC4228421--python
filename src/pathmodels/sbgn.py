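"""SBGN map generation: Process Description maps from process models and
Activity Flow maps from qualitative models, with SBGN-ML 0.2 export.

Glyph classes are derived from SBO terms.  Heavily connected pools are
*cloned* — drawn once per connection with the clone marker set — so every
clone glyph touches exactly one arc.  Initial positions come from the
source layout; glyphs without stored positions are placed by simple
heuristics (process glyphs at the centroid of their positioned partners or
in a strip at the top of the map, enzymes beside the substrate/product
midline, pruned secondary compounds beside their process).  A final
deterministic pass removes all box overlaps while preserving the original
left/right and above/below order of every positioned glyph pair; the full
constraint-based layout machinery of interactive editors (alignment and
containment constraints, orthogonal object-avoiding edge routing) is
intentionally out of scope — the contract here is map validity, not
aesthetic parity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from lxml import etree

from .common import LayoutBox, LayoutError, StructuralError
from .model import ProcessModel
from .qual import QualModel
from .kinetics import SMALL_MOLECULE_IDS, SBO_INHIBITION, SBO_STIMULATION

SBGN_NS = "http://sbgn.org/libsbgn/0.2"

#: SBO term -> SBGN PD glyph class
GLYPH_CLASS_BY_SBO = {
    "SBO:0000247": "simple chemical",
    "SBO:0000252": "macromolecule",
    "SBO:0000253": "complex",
    "SBO:0000552": "submap",
}

DEFAULT_SIZES = {
    "simple chemical": (40.0, 40.0),
    "macromolecule": (60.0, 30.0),
    "complex": (70.0, 40.0),
    "submap": (60.0, 40.0),
    "process": (20.0, 20.0),
    "biological activity": (60.0, 30.0),
}

SEPARATION_MARGIN = 5.0


@dataclass
class Glyph:
    id: str
    cls: str
    label: str = ""
    box: LayoutBox | None = None
    clone: bool = False


@dataclass
class Arc:
    id: str
    cls: str
    source: str
    target: str
    points: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class SbgnMap:
    language: str  # "process description" | "activity flow"
    glyphs: list[Glyph] = field(default_factory=list)
    arcs: list[Arc] = field(default_factory=list)

    def glyph(self, gid: str) -> Glyph:
        for g in self.glyphs:
            if g.id == gid:
                return g
        raise KeyError(gid)

    def degree(self, gid: str) -> int:
        return sum(1 for a in self.arcs if a.source == gid or a.target == gid)

    def validate(self) -> None:
        gids = {g.id for g in self.glyphs}
        if len(gids) != len(self.glyphs):
            raise StructuralError("duplicate glyph ids")
        for a in self.arcs:
            if a.source not in gids or a.target not in gids:
                raise StructuralError(f"arc {a.id}: dangling endpoint")


# ---------------------------------------------------------------------------
# PD generation


def to_pd(model: ProcessModel) -> SbgnMap:
    """Process Description map of a process model.

    Simple chemicals without a stored position or with more than one
    connection, and macromolecules with more than one connection, are
    cloned so each copy carries a single arc and the clone marker."""
    sbgn = SbgnMap(language="process description")
    # connection count per species over all reactions
    connections: dict[str, list[tuple[str, str, str]]] = {s.id: [] for s in model.species}
    for r in model.reactions:
        for sid, _ in r.reactants:
            connections[sid].append((r.id, "consumption", sid))
        for sid, _ in r.products:
            connections[sid].append((r.id, "production", sid))
        for m in r.modifiers:
            if m.sbo_term == SBO_INHIBITION:
                cls = "inhibition"
            elif m.sbo_term == SBO_STIMULATION:
                cls = "stimulation"
            else:
                cls = "catalysis"
            connections[m.species].append((r.id, cls, m.species))

    glyph_for_connection: dict[tuple[str, int], str] = {}
    for s in model.species:
        if not s.sbo_term:
            raise StructuralError(f"species {s.id} has no SBO term; cannot pick a glyph class")
        cls = GLYPH_CLASS_BY_SBO.get(s.sbo_term, "macromolecule")
        conns = connections[s.id]
        has_pos = s.id in model.layout
        wants_clone = (cls == "simple chemical" and (not has_pos or len(conns) > 1)) or (
            cls == "macromolecule" and len(conns) > 1
        )
        if wants_clone and conns:
            for i in range(len(conns)):
                gid = f"{s.id}_clone{i}"
                sbgn.glyphs.append(Glyph(id=gid, cls=cls, label=s.name, clone=True))
                glyph_for_connection[(s.id, i)] = gid
        else:
            sbgn.glyphs.append(Glyph(id=s.id, cls=cls, label=s.name))
            for i in range(len(conns)):
                glyph_for_connection[(s.id, i)] = s.id

    for r in model.reactions:
        sbgn.glyphs.append(Glyph(id=f"pr_{r.id}", cls="process"))

    counters: dict[str, int] = {}
    arc_n = itertools.count()
    for s in model.species:
        for i, (rid, cls, sid) in enumerate(connections[s.id]):
            gid = glyph_for_connection[(sid, i)]
            process = f"pr_{rid}"
            if cls in ("consumption",):
                src, tgt = gid, process
            elif cls == "production":
                src, tgt = process, gid
            else:
                src, tgt = gid, process
            sbgn.arcs.append(Arc(id=f"a{next(arc_n)}", cls=cls, source=src, target=tgt))
            counters[gid] = counters.get(gid, 0) + 1
    sbgn.validate()
    return sbgn


def place_initial(sbgn: SbgnMap, model: ProcessModel) -> SbgnMap:
    """Assign initial positions.

    Glyphs with a stored source position keep it (clones share their
    original's box).  Process glyphs go to the centroid of their positioned
    partners, or to a strip at the top of the map when no partner has a
    position.  Unpositioned enzyme glyphs sit above the midpoint of the
    substrate/product centroids; pruned secondary compounds are stacked on
    the substrate or product side of their process; anything left goes to
    the top strip.  Deterministic for identical input."""
    stored: dict[str, LayoutBox] = {}
    for g in sbgn.glyphs:
        base = g.id.split("_clone")[0]
        box = model.layout.get(base)
        if box is not None:
            stored[g.id] = box
            g.box = box

    pruned_ids: set[str] = set()
    enzyme_ids: set[str] = set()
    for r in model.reactions:
        law = getattr(r, "kinetic_law", None)
        if law is not None:
            pruned_ids.update(law.pruned)
        enzyme_ids.update(m.species for m in r.modifiers)

    top_x = itertools.count()
    top = lambda cls: _default_box(cls, 10.0 + 90.0 * next(top_x), 10.0)  # noqa: E731

    # process glyphs
    for r in model.reactions:
        g = sbgn.glyph(f"pr_{r.id}")
        partners = [sid for sid, _ in r.reactants + r.products]
        boxes = [model.layout[sid] for sid in partners if sid in model.layout]
        if boxes:
            cx = sum(b.cx for b in boxes) / len(boxes)
            cy = sum(b.cy for b in boxes) / len(boxes)
            g.box = _default_box("process", cx, cy, centered=True)
        else:
            g.box = top("process")

    # enzymes without stored position: offset from substrate/product midline
    for r in model.reactions:
        proc = sbgn.glyph(f"pr_{r.id}")
        sub_boxes = [model.layout[s] for s, _ in r.reactants if s in model.layout]
        prod_boxes = [model.layout[p] for p, _ in r.products if p in model.layout]
        for g in sbgn.glyphs:
            base = g.id.split("_clone")[0]
            if base not in {m.species for m in r.modifiers} or g.box is not None:
                continue
            if sub_boxes and prod_boxes:
                mx = (sum(b.cx for b in sub_boxes) / len(sub_boxes)
                      + sum(b.cx for b in prod_boxes) / len(prod_boxes)) / 2
                my = (sum(b.cy for b in sub_boxes) / len(sub_boxes)
                      + sum(b.cy for b in prod_boxes) / len(prod_boxes)) / 2
                g.box = _default_box(g.cls, mx, my - 40.0, centered=True)
            else:
                g.box = _default_box(g.cls, proc.box.cx, proc.box.cy - 40.0, centered=True)

    # secondary (pruned) compounds: group on the substrate/product side
    for r in model.reactions:
        proc = sbgn.glyph(f"pr_{r.id}")
        side_count = {"sub": itertools.count(), "prod": itertools.count()}
        for sid, _ in r.reactants + r.products:
            if sid not in pruned_ids:
                continue
            side = "sub" if any(s == sid for s, _ in r.reactants) else "prod"
            dx = -60.0 if side == "sub" else 60.0
            for g in sbgn.glyphs:
                if g.id.split("_clone")[0] == sid and g.box is None:
                    k = next(side_count[side])
                    g.box = _default_box(g.cls, proc.box.cx + dx, proc.box.cy + 30.0 * (k + 1), centered=True)
                    break

    for g in sbgn.glyphs:
        if g.box is None:
            g.box = top(g.cls)
    return sbgn


def _default_box(cls: str, x: float, y: float, centered: bool = False) -> LayoutBox:
    w, h = DEFAULT_SIZES.get(cls, (60.0, 30.0))
    if centered:
        return LayoutBox.from_center(x, y, w, h)
    return LayoutBox(x, y, w, h)


# ---------------------------------------------------------------------------
# AF generation


def to_af(model: QualModel) -> SbgnMap:
    """Activity Flow map of a qualitative model: one biological-activity
    glyph per qualitative species (when the source layout stores several
    positions, the first in document order is used) and one influence arc
    per transition input/output pair, classed by sign."""
    sbgn = SbgnMap(language="activity flow")
    for s in model.qualitative_species:
        box = model.layout.get(s.id)
        if isinstance(box, list):
            box = box[0] if box else None
        sbgn.glyphs.append(
            Glyph(
                id=s.id,
                cls="biological activity",
                label=s.name,
                box=box,
            )
        )
    arc_cls = {
        "positive": "stimulation",
        "negative": "inhibition",
        "dual": "unknown influence",
        "unknown": "unknown influence",
    }
    n = itertools.count()
    for t in model.transitions:
        for inp in t.inputs:
            for out in t.outputs:
                sbgn.arcs.append(
                    Arc(
                        id=f"a{next(n)}",
                        cls=arc_cls[inp.sign],
                        source=inp.species,
                        target=out,
                    )
                )
    for g in sbgn.glyphs:
        if g.box is None:
            g.box = _default_box(g.cls, 10.0, 10.0)
    sbgn.validate()
    return sbgn


# ---------------------------------------------------------------------------
# overlap removal

def layout(sbgn: SbgnMap, margin: float = SEPARATION_MARGIN, max_iter: int = 100000) -> SbgnMap:
    """Remove all box overlaps deterministically.

    Overlapping pairs are separated by opening a gap: every glyph on the
    far side of a split line is shifted rigidly along one axis.  The shift
    is a monotone map of that axis, so the relative left/right and
    above/below order of every pair of initially positioned glyphs is
    preserved, and existing separations can only grow — each move fixes at
    least one overlap for good, guaranteeing convergence.  Arcs are then
    routed as straight lines, with a single bend when that avoids crossing
    another glyph's interior."""
    order = sorted(range(len(sbgn.glyphs)), key=lambda i: sbgn.glyphs[i].id)
    for _ in range(max_iter):
        pair = _first_overlap(sbgn, order, margin)
        if pair is None:
            break
        _separate(sbgn, *pair, margin)
    else:
        residual = sum(
            1
            for i, j in itertools.combinations(range(len(sbgn.glyphs)), 2)
            if sbgn.glyphs[i].box.overlaps(sbgn.glyphs[j].box)
        )
        raise LayoutError(f"overlap removal did not converge; {residual} overlaps left")
    _route_arcs(sbgn)
    return sbgn


def _first_overlap(sbgn, order, margin):
    for a, b in itertools.combinations(order, 2):
        if sbgn.glyphs[a].box.overlaps(sbgn.glyphs[b].box, margin - 1e-9):
            return a, b
    return None


def _separate(sbgn: SbgnMap, i: int, j: int, margin: float) -> None:
    gi, gj = sbgn.glyphs[i], sbgn.glyphs[j]
    # put the glyph with the smaller (coordinate, id) first on each axis
    def axis_plan(coord: str):
        a, b = gi, gj
        ca, cb = getattr(a.box, coord), getattr(b.box, coord)
        if (ca, a.id) > (cb, b.id):
            a, b = b, a
            ca, cb = cb, ca
        if coord == "cx":
            delta = a.box.x2 + margin - b.box.x
        else:
            delta = a.box.y2 + margin - b.box.y
        return a, b, ca, cb, delta

    plans = {c: axis_plan(c) for c in ("cx", "cy")}
    # prefer the axis needing the smaller shift; x on ties
    coord = "cx" if plans["cx"][4] <= plans["cy"][4] else "cy"
    a, b, ca, cb, delta = plans[coord]
    # shift everything at or beyond b's center (id-tiebroken) by delta
    for g in sbgn.glyphs:
        c = getattr(g.box, coord)
        if (c, g.id) >= (cb, b.id):
            if coord == "cx":
                g.box = g.box.moved_to(g.box.x + delta, g.box.y)
            else:
                g.box = g.box.moved_to(g.box.x, g.box.y + delta)


def _route_arcs(sbgn: SbgnMap) -> None:
    boxes = {g.id: g.box for g in sbgn.glyphs}
    for arc in sbgn.arcs:
        s, t = boxes[arc.source], boxes[arc.target]
        blockers = [
            b for gid, b in boxes.items() if gid not in (arc.source, arc.target)
        ]
        if not _segment_blocked((s.cx, s.cy), (t.cx, t.cy), blockers):
            arc.points = []
            continue
        mid_x, mid_y = (s.cx + t.cx) / 2, (s.cy + t.cy) / 2
        lo_y = min(b.y for b in blockers) - 15.0
        hi_y = max(b.y2 for b in blockers) + 15.0
        lo_x = min(b.x for b in blockers) - 15.0
        hi_x = max(b.x2 for b in blockers) + 15.0
        candidates = (
            (s.cx, t.cy),
            (t.cx, s.cy),
            (mid_x, lo_y),
            (mid_x, hi_y),
            (lo_x, mid_y),
            (hi_x, mid_y),
        )
        for bend in candidates:
            if not _segment_blocked((s.cx, s.cy), bend, blockers) and not _segment_blocked(
                bend, (t.cx, t.cy), blockers
            ):
                arc.points = [bend]
                break
        else:
            arc.points = []


def _segment_blocked(p, q, boxes) -> bool:
    return any(_segment_hits_box(p, q, b) for b in boxes)


def _segment_hits_box(p, q, box: LayoutBox) -> bool:
    # Liang-Barsky clipping against the (open) box interior
    x0, y0 = p
    x1, y1 = q
    dx, dy = x1 - x0, y1 - y0
    t0, t1 = 0.0, 1.0
    for pcoef, qcoef in (
        (-dx, x0 - box.x),
        (dx, box.x2 - x0),
        (-dy, y0 - box.y),
        (dy, box.y2 - y0),
    ):
        if pcoef == 0:
            if qcoef < 0:
                return False
            continue
        r = qcoef / pcoef
        if pcoef < 0:
            t0 = max(t0, r)
        else:
            t1 = min(t1, r)
        if t0 >= t1:
            return False
    return True


# ---------------------------------------------------------------------------
# SBGN-ML io


def write_sbgnml(sbgn: SbgnMap) -> str:
    """Serialize to an SBGN-ML 0.2 document."""
    sbgn.validate()
    root = etree.Element(f"{{{SBGN_NS}}}sbgn", nsmap={None: SBGN_NS})
    m = etree.SubElement(root, f"{{{SBGN_NS}}}map", language=sbgn.language)
    for g in sbgn.glyphs:
        gl = etree.SubElement(m, f"{{{SBGN_NS}}}glyph", id=g.id)
        gl.set("class", g.cls)
        if g.label:
            etree.SubElement(gl, f"{{{SBGN_NS}}}label", text=g.label)
        if g.clone:
            etree.SubElement(gl, f"{{{SBGN_NS}}}clone")
        if g.box is not None:
            etree.SubElement(
                gl,
                f"{{{SBGN_NS}}}bbox",
                x=repr(g.box.x),
                y=repr(g.box.y),
                w=repr(g.box.width),
                h=repr(g.box.height),
            )
    for a in sbgn.arcs:
        ar = etree.SubElement(m, f"{{{SBGN_NS}}}arc", id=a.id, source=a.source, target=a.target)
        ar.set("class", a.cls)
        sbox = next(g.box for g in sbgn.glyphs if g.id == a.source)
        tbox = next(g.box for g in sbgn.glyphs if g.id == a.target)
        etree.SubElement(ar, f"{{{SBGN_NS}}}start", x=repr(sbox.cx), y=repr(sbox.cy))
        for px, py in a.points:
            etree.SubElement(ar, f"{{{SBGN_NS}}}next", x=repr(px), y=repr(py))
        etree.SubElement(ar, f"{{{SBGN_NS}}}end", x=repr(tbox.cx), y=repr(tbox.cy))
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8").decode()


def read_sbgnml(document: str | bytes) -> SbgnMap:
    if isinstance(document, str):
        document = document.encode()
    root = etree.fromstring(document)
    m = root.find(f"{{{SBGN_NS}}}map")
    if m is None:
        raise StructuralError("no map element in SBGN-ML document")
    sbgn = SbgnMap(language=m.get("language", ""))
    for gl in m.findall(f"{{{SBGN_NS}}}glyph"):
        label = gl.find(f"{{{SBGN_NS}}}label")
        bbox = gl.find(f"{{{SBGN_NS}}}bbox")
        sbgn.glyphs.append(
            Glyph(
                id=gl.get("id"),
                cls=gl.get("class", ""),
                label=label.get("text", "") if label is not None else "",
                clone=gl.find(f"{{{SBGN_NS}}}clone") is not None,
                box=LayoutBox(
                    float(bbox.get("x")),
                    float(bbox.get("y")),
                    float(bbox.get("w")),
                    float(bbox.get("h")),
                )
                if bbox is not None
                else None,
            )
        )
    for ar in m.findall(f"{{{SBGN_NS}}}arc"):
        points = [
            (float(n.get("x")), float(n.get("y")))
            for n in ar.findall(f"{{{SBGN_NS}}}next")
        ]
        sbgn.arcs.append(
            Arc(
                id=ar.get("id"),
                cls=ar.get("class", ""),
                source=ar.get("source"),
                target=ar.get("target"),
                points=points,
            )
        )
    sbgn.validate()
    return sbgn
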