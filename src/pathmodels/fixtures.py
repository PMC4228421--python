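"""Seeded generators for synthetic inputs.

Every generator is a pure function of its arguments and the seed, and
returns the generated artifact together with a ground-truth manifest
computed *by construction* (not by running the code under test).  The
generated dialects are exactly the ones the other modules consume: KGML
documents, reaction-definition / rate-law-provider / interaction-sign /
identifier-reconciliation tables, and toy reconstructions whose
producibility answer is known from an independent reachability oracle.
"""

from __future__ import annotations

import random

from .genome_scale import (
    BIOMASS_COMPONENTS,
    Metabolite,
    ReconReaction,
    Reconstruction,
    add_biomass,
    add_medium_and_transport,
    reconcile,
)

#: Independent ground-truth statement of the relation-subtype sign/SBO
#: mapping, used for fixture manifests (kept literal on purpose: the
#: translation table under test must reproduce it, so the two must not
#: share code).
EXPECTED_SIGN_SBO = {
    "activation": ("positive", "SBO:0000170"),
    "inhibition": ("negative", "SBO:0000169"),
    "expression": ("positive", "SBO:0000170"),
    "repression": ("negative", "SBO:0000169"),
    "indirect effect": ("unknown", "SBO:0000344"),
    "state change": ("unknown", "SBO:0000168"),
    "binding/association": ("unknown", "SBO:0000177"),
    "dissociation": ("unknown", "SBO:0000177"),
    "missing interaction": ("unknown", "SBO:0000396"),
    "phosphorylation": ("unknown", "SBO:0000216"),
    "dephosphorylation": ("unknown", "SBO:0000330"),
    "glycosylation": ("unknown", "SBO:0000217"),
    "ubiquitination": ("unknown", "SBO:0000224"),
    "methylation": ("unknown", "SBO:0000214"),
}

ALL_SUBTYPES = tuple(EXPECTED_SIGN_SBO)


# ---------------------------------------------------------------------------
# KGML documents


def gen_kgml(
    n_compounds: int = 8,
    n_reactions: int = 4,
    n_relations: int = 6,
    subtype_mix: tuple[str, ...] = ALL_SUBTYPES,
    reversible_fraction: float = 0.5,
    instantiated_fraction: float = 0.75,
    n_genes: int = 6,
    with_map_entry: bool = True,
    with_group: bool = True,
    small_molecule_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[str, dict]:
    """Generate a KGML document plus its ground-truth manifest.

    Compounds form a pool wired into random reactions, each catalysed by
    one ortholog entry (instantiated with probability
    ``instantiated_fraction``); gene entries are wired into relations whose
    subtypes cycle through ``subtype_mix``.  The manifest records the entry
    counts surviving organism filtering in both modes and the expected
    sign/SBO of every relation.
    """
    rng = random.Random(seed)
    lines = ['<pathway name="path:syn%05d" org="syn">' % (seed % 100000)]
    next_id = 1
    compounds: list[tuple[int, str]] = []
    small_pool = ["C00001", "C00080", "C00038", "C00282"]
    for i in range(n_compounds):
        if rng.random() < small_molecule_fraction and small_pool:
            acc = small_pool[i % len(small_pool)]
        else:
            acc = f"C{10000 + seed % 100:05d}"[:1] + f"{90000 + i:05d}"  # C9xxxx
        eid = next_id
        next_id += 1
        compounds.append((eid, acc))
        x, y = 60 + 110 * (i % 5), 80 + 90 * (i // 5)
        lines.append(
            f' <entry id="{eid}" name="cpd:{acc}" type="compound">'
            f'<graphics x="{x}" y="{y}" width="40" height="20"/></entry>'
        )
    orthologs: list[tuple[int, bool]] = []
    for i in range(n_reactions):
        eid = next_id
        next_id += 1
        inst = rng.random() < instantiated_fraction
        orthologs.append((eid, inst))
        x, y = 100 + 110 * (i % 5), 40 + 90 * (i // 5)
        lines.append(
            f' <entry id="{eid}" name="ko:K{10000 + i:05d}" type="ortholog"'
            f' instantiated="{"true" if inst else "false"}" reaction="rn:R9{i:04d}">'
            f'<graphics x="{x}" y="{y}" width="46" height="17"/></entry>'
        )
    genes: list[int] = []
    for i in range(n_genes):
        eid = next_id
        next_id += 1
        genes.append(eid)
        x, y = 60 + 110 * (i % 5), 300 + 60 * (i // 5)
        lines.append(
            f' <entry id="{eid}" name="syn:{1000 + i}" type="gene">'
            f'<graphics x="{x}" y="{y}" width="46" height="17"/></entry>'
        )
    map_entries = 0
    if with_map_entry:
        eid = next_id
        next_id += 1
        map_entries = 1
        lines.append(
            f' <entry id="{eid}" name="path:syn99999" type="map">'
            f'<graphics x="400" y="40" width="80" height="25"/></entry>'
        )
    group_entries = 0
    if with_group and len(genes) >= 2:
        eid = next_id
        next_id += 1
        group_entries = 1
        lines.append(
            f' <entry id="{eid}" name="undefined" type="group">'
            + "".join(f'<component id="{g}"/>' for g in genes[:2])
            + "</entry>"
        )

    n_reversible = 0
    for i in range(n_reactions):
        rid = 1000 + i
        rev = rng.random() < reversible_fraction
        n_reversible += rev
        subs = rng.sample(compounds, min(2, len(compounds)))
        prods = rng.sample([c for c in compounds if c not in subs], min(1, max(0, len(compounds) - 2)))
        if not prods:
            prods = [compounds[-1]]
        lines.append(
            f' <reaction id="{rid}" name="rn:R9{i:04d}" type="{"reversible" if rev else "irreversible"}">'
            + "".join(f'<substrate id="{e}"/>' for e, _ in subs)
            + "".join(f'<product id="{e}"/>' for e, _ in prods)
            + "</reaction>"
        )

    expected_signs = []
    for i in range(n_relations):
        src, tgt = rng.sample(genes, 2) if len(genes) >= 2 else (genes[0], genes[0])
        subtype = subtype_mix[i % len(subtype_mix)]
        expected_signs.append(
            {"source": src, "target": tgt, "subtypes": [subtype],
             "sign": EXPECTED_SIGN_SBO[subtype][0], "sbo": EXPECTED_SIGN_SBO[subtype][1]}
        )
        lines.append(
            f' <relation entry1="{src}" entry2="{tgt}">'
            f'<subtype name="{subtype}"/></relation>'
        )
    lines.append("</pathway>")

    n_instantiated_orthologs = sum(1 for _, inst in orthologs if inst)
    n_entries = n_compounds + n_reactions + n_genes + map_entries + group_entries
    manifest = {
        "seed": seed,
        "entries": n_entries,
        "reactions": n_reactions,
        "reversible_reactions": n_reversible,
        "relations": n_relations,
        "instantiated_orthologs": n_instantiated_orthologs,
        "entries_after_metabolic_filter": n_entries
        - (n_reactions - n_instantiated_orthologs)
        - map_entries,
        "entries_after_signaling_filter": n_entries
        - (n_reactions - n_instantiated_orthologs),
        "expected_signs": expected_signs,
        "subtypes_present": sorted({s["subtypes"][0] for s in expected_signs}),
    }
    return "\n".join(lines) + "\n", manifest


def gen_reaction_defs(seed: int = 0, n_missing: int = 2) -> tuple[str, dict]:
    """Reaction-definition rows adding missing products/enzymes to the
    reactions of :func:`gen_kgml` output (reaction ids 1000...)."""
    rng = random.Random(seed)
    rows = []
    added = []
    for i in range(n_missing):
        rid = 1000 + i
        acc = f"C{80000 + rng.randrange(100):05d}"
        rows.append(f"{rid}\tproduct\tcpd:{acc}\t1")
        added.append({"reaction": str(rid), "role": "product", "species": f"cpd:{acc}"})
    manifest = {"seed": seed, "added": added}
    return "\n".join(rows) + "\n", manifest


# ---------------------------------------------------------------------------
# provider tables


def gen_provider_table(
    reactions: list[tuple[str, list[str]]],
    fraction_covered: float = 0.5,
    seed: int = 0,
) -> tuple[str, dict]:
    """Rate-law-provider rows for ``reactions``: (reaction key, accessions
    of its participating species).

    Covered reactions receive 1-3 ranked candidates; with more than one
    candidate the first references an unmappable species, so the matching
    rule must fall through to the next rank.  The manifest names the
    winning rank per covered reaction.
    """
    rng = random.Random(seed)
    lines = []
    winners: dict[str, int] = {}
    for key, accs in reactions:
        if rng.random() >= fraction_covered or not accs:
            continue
        n_cand = rng.randrange(1, 4)
        winner = 1 if n_cand == 1 else 2
        for rank in range(1, n_cand + 1):
            if n_cand > 1 and rank == 1:
                expr = "vmax * UNKNOWN_SPECIES / (km + UNKNOWN_SPECIES)"
            else:
                expr = f"vmax * {accs[0]} / (km + {accs[0]})"
            lines.append(f"{key}\t{rank}\t{expr}\tvmax\t2.5\tmole/second")
            lines.append(f"{key}\t{rank}\t{expr}\tkm\t0.7\tmole")
        winners[key] = winner
    manifest = {"seed": seed, "winners": winners}
    return "\n".join(lines) + ("\n" if lines else ""), manifest


def gen_sign_table(
    pairs: list[tuple[str, str]], seed: int = 0
) -> tuple[str, dict]:
    """Interaction-sign rows (source accession, target accession, control
    type) for the given pairs, alternating activation/inhibition."""
    rows = []
    expected = {}
    for i, (src, tgt) in enumerate(pairs):
        control = "activation" if i % 2 == 0 else "inhibition"
        rows.append(f"{src}\t{tgt}\t{control}")
        expected[f"{src}->{tgt}"] = "positive" if control == "activation" else "negative"
    return "\n".join(rows) + ("\n" if rows else ""), {"seed": seed, "expected": expected}


# ---------------------------------------------------------------------------
# toy reconstructions with known producibility


def reachable_metabolites(net: Reconstruction) -> set[str]:
    """Metabolites reachable from the boundary by forward closure.

    A reaction direction is usable when its flux bound allows it and all
    metabolites it consumes in that direction are already reachable; its
    products then become reachable.  Directions that consume nothing
    (uptake exchanges) seed the closure.  On acyclic unit-stoichiometry
    networks this coincides with flux-based producibility, which is what
    the toy fixtures are designed to guarantee.
    """
    avail: set[str] = set()
    changed = True
    while changed:
        changed = False
        for r in net.reactions:
            if r.upper > 0 and set(r.substrates()) <= avail:
                new = set(r.products()) - avail
                if new:
                    avail |= new
                    changed = True
            if r.lower < 0 and set(r.products()) <= avail:
                new = set(r.substrates()) - avail
                if new:
                    avail |= new
                    changed = True
    return avail


def gen_toy_recon(
    n_chain: int = 4,
    producible_components: int = 3,
    seed: int = 0,
) -> tuple[Reconstruction, dict, dict]:
    """Toy draft reconstruction with a designed producibility answer.

    An acyclic unit-stoichiometry chain runs from glucose through
    ``n_chain`` intermediates; from the chain end one reaction produces
    each of ``producible_components`` randomly chosen biomass components.
    Two decoy metabolites are unreachable.  The raw network uses
    source-namespace identifiers; the returned reconciliation map unifies
    them (glucose is reachable only after reconciliation maps its source
    id onto the medium id).

    Returns (raw network, reconciliation map rows, expected report), the
    expectation computed with :func:`reachable_metabolites` on the
    completed network.
    """
    if not 0 <= producible_components <= len(BIOMASS_COMPONENTS):
        raise ValueError("producible_components out of range")
    rng = random.Random(seed)
    chosen = sorted(rng.sample(sorted(BIOMASS_COMPONENTS), producible_components))

    net = Reconstruction(id=f"toy{seed}")
    glc_src = "C00267"  # source id for alpha-D-glucose
    net.metabolites.append(
        Metabolite(id=glc_src, name="alpha-D-Glucose", namespace="kegg.compound",
                   source_tags=["kegg"])
    )
    prev = glc_src
    for i in range(n_chain):
        mid = f"I{i}"
        net.metabolites.append(Metabolite(id=mid, name=mid, source_tags=["kegg"]))
        net.reactions.append(
            ReconReaction(id=f"chain{i}", stoichiometry={prev: -1.0, mid: 1.0},
                          lower=0.0, upper=1000.0, gpr=f"syn:{i}", source_tags=["kegg"])
        )
        prev = mid
    for k, comp in enumerate(chosen):
        net.metabolites.append(Metabolite(id=comp, name=comp, source_tags=["kegg"]))
        net.reactions.append(
            ReconReaction(id=f"make_{comp}", stoichiometry={prev: -1.0, comp: 1.0},
                          lower=0.0, upper=1000.0, source_tags=["kegg"])
        )
    net.metabolites.append(Metabolite(id="X0", name="decoy", source_tags=["kegg"]))
    net.metabolites.append(Metabolite(id="X1", name="decoy", source_tags=["kegg"]))
    net.reactions.append(
        ReconReaction(id="decoy0", stoichiometry={"X0": -1.0, "X1": 1.0},
                      lower=0.0, upper=1000.0, source_tags=["kegg"])
    )
    net.validate()

    recon_map = {
        ("kegg.compound", glc_src): ("glc__aD", "C6H12O6", 0),
        ("metacyc.compound", "GLC"): ("glc__aD", "C6H12O6", 0),
    }
    completed = add_biomass(add_medium_and_transport(reconcile(net, recon_map)))
    reachable = reachable_metabolites(completed)
    intracellular = [m.id for m in completed.metabolites if m.compartment == "intracellular"]
    expected = {
        "components": {mid: (mid in reachable) for mid in BIOMASS_COMPONENTS},
        "makeable_components": sum(1 for mid in BIOMASS_COMPONENTS if mid in reachable),
        "makeable_metabolites": sum(1 for mid in intracellular if mid in reachable),
        "metabolites": len(intracellular),
        "chosen": chosen,
    }
    assert expected["makeable_components"] == producible_components
    return net, recon_map, expected


def gen_recon_map(accessions: list[str], seed: int = 0) -> tuple[str, dict]:
    """Reconciliation-table text mapping kegg.compound accessions onto
    unified ids with formulas/charges."""
    rng = random.Random(seed)
    lines = []
    mapping = {}
    for acc in accessions:
        uid = f"MNXM{rng.randrange(1, 99999):05d}"
        formula = rng.choice(["C6H12O6", "C3H4O3", "C5H8O4", "H2O"])
        charge = rng.choice([-2, -1, 0, 0, 1])
        lines.append(f"kegg.compound\t{acc}\t{uid}\t{formula}\t{charge}")
        mapping[acc] = uid
    return "\n".join(lines) + ("\n" if lines else ""), {"seed": seed, "mapping": mapping}
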