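"""Reconciliation, merging, balance checking, medium/biomass assembly and
flux-based synthesizability (checked against a graph-reachability oracle).
"""

import random

import pytest

from pathmodels import fixtures
from pathmodels import genome_scale as G


def mk_net(mets, rxns, **kw):
    net = G.Reconstruction(id=kw.get("id", "n"))
    for m in mets:
        net.metabolites.append(m if isinstance(m, G.Metabolite) else G.Metabolite(**m))
    for r in rxns:
        net.reactions.append(r if isinstance(r, G.ReconReaction) else G.ReconReaction(**r))
    net.validate()
    return net


class TestReconcile:
    def test_collision_merges_metabolites(self):
        net = mk_net(
            [
                dict(id="C00031", namespace="kegg.compound", source_tags=["kegg"]),
                dict(id="GLC", namespace="metacyc.compound", source_tags=["metacyc"]),
            ],
            [],
        )
        rmap = {
            ("kegg.compound", "C00031"): ("MNXM41", "C6H12O6", 0),
            ("metacyc.compound", "GLC"): ("MNXM41", "C6H12O6", 0),
        }
        out = G.reconcile(net, rmap)
        assert [m.id for m in out.metabolites] == ["MNXM41"]
        assert out.metabolites[0].source_tags == ["kegg", "metacyc"]
        assert out.metabolites[0].formula == "C6H12O6"

    def test_empty_map_is_identity(self):
        net = mk_net(
            [dict(id="A"), dict(id="B")],
            [dict(id="r", stoichiometry={"A": -1.0, "B": 1.0})],
        )
        assert G.reconcile(net, {}) == net

    def test_coefficients_summed_per_unified_id(self):
        # brute-force reaggregation: every source id's coefficient must land
        # on its unified id, summed
        rng = random.Random(5)
        src_ids = [f"S{i}" for i in range(6)]
        rmap = {("ns", s): (f"U{rng.randrange(3)}", None, None) for s in src_ids}
        stoich = {s: float(rng.choice([-2, -1, 1, 2])) for s in src_ids}
        net = mk_net(
            [dict(id=s, namespace="ns") for s in src_ids],
            [dict(id="r", stoichiometry=stoich, lower=-1000.0)],
        )
        out = G.reconcile(net, rmap)
        expected: dict[str, float] = {}
        for s, c in stoich.items():
            u = rmap[("ns", s)][0]
            expected[u] = expected.get(u, 0.0) + c
        expected = {k: v for k, v in expected.items() if v != 0}
        assert out.reactions[0].stoichiometry == expected

    def test_map_value_wins_on_contradiction(self, caplog):
        net = mk_net([dict(id="A", namespace="ns", formula="CH4")], [])
        with caplog.at_level("WARNING"):
            out = G.reconcile(net, {("ns", "A"): ("U", "CO2", 0)})
        assert out.metabolites[0].formula == "CO2"
        assert any("contradicts" in r.message for r in caplog.records)

    def test_unmapped_ids_keep_source_tag(self):
        net = mk_net([dict(id="A", namespace="ns", source_tags=["kegg"])], [])
        out = G.reconcile(net, {("ns", "other"): ("U", None, None)})
        assert out.metabolites[0].id == "A"
        assert out.metabolites[0].source_tags == ["kegg"]


class TestMerge:
    def n1(self):
        return mk_net(
            [dict(id="A", source_tags=["kegg"]), dict(id="B", source_tags=["kegg"])],
            [dict(id="r1", stoichiometry={"A": -1.0, "B": 1.0}, source_tags=["kegg"])],
        )

    def test_identical_nets_collapse(self):
        out = G.merge([self.n1(), self.n1()])
        assert len(out.metabolites) == 2 and len(out.reactions) == 1
        assert out.reactions[0].source_tags == ["kegg"]

    def test_disjoint_nets_add(self):
        other = mk_net(
            [dict(id="C"), dict(id="D")],
            [dict(id="r2", stoichiometry={"C": -1.0, "D": 1.0})],
        )
        out = G.merge([self.n1(), other])
        assert len(out.metabolites) == 4 and len(out.reactions) == 2

    def test_opposite_directions_both_kept(self):
        rev = mk_net(
            [dict(id="A"), dict(id="B")],
            [dict(id="r1b", stoichiometry={"A": 1.0, "B": -1.0})],
        )
        out = G.merge([self.n1(), rev])
        assert len(out.reactions) == 2

    def test_gpr_concatenated_on_dedup(self):
        a = self.n1()
        a.reactions[0].gpr = "g1"
        b = self.n1()
        b.reactions[0].gpr = "g2"
        b.reactions[0].source_tags = ["metacyc"]
        out = G.merge([a, b])
        assert out.reactions[0].gpr == "g1 or g2"
        assert out.reactions[0].source_tags == ["kegg", "metacyc"]

    def test_associative_and_commutative_up_to_order(self):
        def canon(net):
            return (
                sorted((m.id, m.compartment) for m in net.metabolites),
                sorted(
                    (tuple(sorted(r.stoichiometry.items())), r.lower, r.upper)
                    for r in net.reactions
                ),
            )

        a, b = self.n1(), mk_net(
            [dict(id="C"), dict(id="A")],
            [dict(id="rX", stoichiometry={"A": -1.0, "C": 1.0})],
        )
        c = mk_net([dict(id="D")], [])
        assert canon(G.merge([G.merge([a, b]), c])) == canon(G.merge([a, G.merge([b, c])]))
        assert canon(G.merge([a, b])) == canon(G.merge([b, a]))


# independent element-count oracle: character-walk parser, no regex
def oracle_formula(formula):
    counts = {}
    i = 0
    while i < len(formula):
        ch = formula[i]
        if not ch.isupper():
            return None
        el = ch
        i += 1
        if i < len(formula) and formula[i].islower():
            el += formula[i]
            i += 1
        digits = ""
        while i < len(formula) and formula[i].isdigit():
            digits += formula[i]
            i += 1
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
    if "R" in counts or "X" in counts:
        return None
    return counts


def oracle_balance(reaction, mets):
    total, charge = {}, 0.0
    for mid, coeff in reaction.stoichiometry.items():
        m = mets[mid]
        if m.formula is None or m.charge is None:
            return "unknown"
        counts = oracle_formula(m.formula)
        if counts is None:
            return "unknown"
        for el, n in counts.items():
            total[el] = total.get(el, 0.0) + coeff * n
        charge += coeff * m.charge
    return "balanced" if all(v == 0 for v in total.values()) and charge == 0 else "unbalanced"


class TestBalance:
    def hexo(self):
        return mk_net(
            [
                dict(id="glc", formula="C6H12O6", charge=0),
                dict(id="atp", formula="C10H12N5O13P3", charge=-4),
                dict(id="g6p", formula="C6H11O9P", charge=-2),
                dict(id="adp", formula="C10H12N5O10P2", charge=-3),
                dict(id="h", formula="H", charge=1),
                dict(id="h2o", formula="H2O", charge=0),
                dict(id="rgroup", formula="ROH", charge=0),
            ],
            [],
        )

    def test_hexokinase_balanced(self):
        net = self.hexo()
        rxn = G.ReconReaction(
            id="hex",
            stoichiometry={"glc": -1.0, "atp": -1.0, "g6p": 1.0, "adp": 1.0, "h": 1.0},
        )
        assert G.check_balance(rxn, net).status == "balanced"

    def test_omitted_water_reported(self):
        net = self.hexo()
        # ATP hydrolysis with the water omitted
        rxn = G.ReconReaction(
            id="atpase", stoichiometry={"atp": -1.0, "adp": 1.0, "h": 1.0}
        )
        res = G.check_balance(rxn, net)
        assert res.status == "unbalanced"
        assert res.element_diff.get("O") == -3.0  # phosphate's oxygens missing
        assert "O" in res.detail

    def test_generic_group_is_unknown(self):
        net = self.hexo()
        rxn = G.ReconReaction(id="r", stoichiometry={"rgroup": -1.0, "h2o": 1.0})
        assert G.check_balance(rxn, net).status == "unknown"

    def test_missing_formula_is_unknown(self):
        net = mk_net([dict(id="A")], [])
        rxn = G.ReconReaction(id="r", stoichiometry={"A": -1.0})
        assert G.check_balance(rxn, net).status == "unknown"

    def test_agreement_with_oracle_on_200_reactions(self):
        rng = random.Random(17)
        formulas = ["C6H12O6", "H2O", "CO2", "C3H4O3", "CH4", "O2", "H", "NH3",
                    "C5H9NO4", "ROH", None]
        mets = {}
        for i in range(40):
            mets[f"m{i}"] = G.Metabolite(
                id=f"m{i}",
                formula=rng.choice(formulas),
                charge=rng.choice([None, -2, -1, 0, 1, 2]),
            )
        net = mk_net(list(mets.values()), [])
        disagreements = 0
        for i in range(200):
            k = rng.randrange(2, 5)
            chosen = rng.sample(sorted(mets), k)
            stoich = {mid: float(rng.choice([-2, -1, 1, 2])) for mid in chosen}
            if rng.random() < 0.3:
                # build an exactly balanced reaction: A -> A copies
                mid = chosen[0]
                stoich = {mid: -1.0}
                other = chosen[1]
                mets[other].formula = mets[mid].formula
                mets[other].charge = mets[mid].charge
                stoich[other] = 1.0
            rxn = G.ReconReaction(id=f"r{i}", stoichiometry=stoich)
            if G.check_balance(rxn, net).status != oracle_balance(rxn, mets):
                disagreements += 1
        assert disagreements == 0


class TestMediumAndBiomass:
    def test_every_intracellular_metabolite_gains_export_path(self):
        net = mk_net([dict(id=f"m{i}") for i in range(5)], [])
        out = G.add_medium_and_transport(net)
        for i in range(5):
            assert f"T_m{i}_export" in out.reaction_ids()
            assert f"EX_m{i}_e" in out.reaction_ids()

    def test_medium_uptake_path_complete(self):
        out = G.add_medium_and_transport(mk_net([], []))
        for mid, *_ in G.MEDIUM:
            ex = next(r for r in out.reactions if r.id == f"EX_{mid}_e")
            assert ex.lower < 0  # uptake allowed
            tr = next(r for r in out.reactions if r.id == f"T_{mid}_uptake")
            assert tr.stoichiometry == {f"{mid}_e": -1.0, mid: 1.0}
            assert tr.lower == 0.0  # uptake-directed

    def test_exports_are_secretion_only(self):
        net = mk_net([dict(id="A")], [])
        out = G.add_medium_and_transport(net)
        ex = next(r for r in out.reactions if r.id == "EX_A_e")
        assert ex.lower == 0.0

    def test_idempotent(self):
        net = G.add_medium_and_transport(mk_net([dict(id="A")], []))
        again = G.add_medium_and_transport(net)
        assert len(again.reactions) == len(net.reactions)
        assert len(again.metabolites) == len(net.metabolites)

    def test_biomass_has_thirty_components(self):
        net = G.add_biomass(mk_net([], []))
        bm = next(r for r in net.reactions if r.id == G.BIOMASS_REACTION_ID)
        assert len(bm.stoichiometry) == 30
        assert all(c == -1.0 for c in bm.stoichiometry.values())

    def test_twenty_amino_acid_components(self):
        categories = [cat for _, cat in G.BIOMASS_COMPONENTS.values()]
        assert categories.count("amino_acid") == 20
        assert len(G.BIOMASS_COMPONENTS) == 30

    def test_objective_set_to_biomass(self):
        net = G.add_biomass(mk_net([], []))
        assert net.objective == G.BIOMASS_REACTION_ID


class TestSynthesizability:
    def completed(self, seed, k, n_chain=4):
        net, rmap, expected = fixtures.gen_toy_recon(
            n_chain=n_chain, producible_components=k, seed=seed
        )
        return (
            G.add_biomass(G.add_medium_and_transport(G.reconcile(net, rmap))),
            expected,
        )

    @pytest.mark.parametrize("k", [0, 3, 30])
    def test_designed_answers(self, k):
        net, expected = self.completed(seed=k + 1, k=k)
        report = G.synthesizability(net)
        assert report.n_makeable_components == k
        assert report.components == expected["components"]

    def test_component_without_producer_not_producible(self):
        net, _ = self.completed(seed=2, k=1)
        report = G.synthesizability(net)
        unproduced = [c for c, ok in report.components.items() if not ok]
        assert len(unproduced) == 29

    def test_agreement_with_reachability_oracle(self):
        for seed in range(6):
            net, expected = self.completed(seed=seed, k=seed % 5)
            report = G.synthesizability(net)
            assert report.components == expected["components"], seed
            assert report.n_makeable_metabolites == expected["makeable_metabolites"]

    def test_adding_a_reaction_never_shrinks_producible_set(self):
        net, _ = self.completed(seed=9, k=2)
        before = {c for c, ok in G.synthesizability(net).components.items() if ok}
        # connect the chain end to one more component
        chain_end = sorted(
            m.id for m in net.metabolites if m.id.startswith("I")
        )[-1]
        new_target = next(
            mid for mid in G.BIOMASS_COMPONENTS if mid not in before
        )
        net.reactions.append(
            G.ReconReaction(
                id="extra", stoichiometry={chain_end: -1.0, new_target: 1.0}
            )
        )
        after = {c for c, ok in G.synthesizability(net).components.items() if ok}
        assert before < after

    def test_report_counts_exclude_scaffolding(self):
        net, expected = self.completed(seed=4, k=1)
        report = G.synthesizability(net)
        core = [r for r in net.reactions
                if not (set(r.source_tags) & {"medium", "transport", "exchange", "biomass"})]
        assert report.n_reactions == len(core)
        assert report.n_metabolites == expected["metabolites"]


class TestCobraDialect:
    def test_round_trip_preserves_everything(self):
        net, rmap, _ = fixtures.gen_toy_recon(seed=3, producible_components=2)
        net = G.add_biomass(G.add_medium_and_transport(G.reconcile(net, rmap)))
        back = G.read_cobra(G.format_cobra(net))
        assert back == net

    def test_notes_carry_formula_and_gpr(self):
        net, rmap, _ = fixtures.gen_toy_recon(seed=3, producible_components=1)
        net = G.add_biomass(G.add_medium_and_transport(G.reconcile(net, rmap)))
        doc = G.format_cobra(net)
        assert "<p>FORMULA: C6H12O6</p>" in doc
        assert "<p>GENE_ASSOCIATION: " in doc

    def test_bounds_in_kinetic_law_parameters(self):
        net = G.add_biomass(G.add_medium_and_transport(mk_net([], [])))
        doc = G.format_cobra(net)
        assert 'id="LOWER_BOUND"' in doc and 'id="UPPER_BOUND"' in doc

    def test_objective_coefficient_only_on_biomass(self):
        net = G.add_biomass(G.add_medium_and_transport(mk_net([dict(id="A")], [])))
        back = G.read_cobra(G.format_cobra(net))
        assert back.objective == G.BIOMASS_REACTION_ID
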