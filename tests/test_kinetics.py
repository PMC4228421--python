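"""Rate-law classification, construction, initialization and units.

The generated common-modular (cat-form) law is checked against an
independent brute-force evaluator that substitutes numbers directly into
the law's defining formula, without any symbolic machinery.
"""

import math
import random

import pytest
import sympy

from pathmodels import kinetics as K
from pathmodels import units as U
from pathmodels.common import UnitDerivationError
from pathmodels.model import (
    AnnotationSet,
    Compartment,
    Modifier,
    ProcessModel,
    Reaction,
    Species,
)


def make_model(n_reactants=1, n_products=1, reversible=False, enzyme=True,
               stoich=None, gene=False, modifier_sbo="", annotations=None):
    """Assemble a one-reaction model with configurable shape."""
    model = ProcessModel(model_id="m", compartments=[Compartment("default", 1.0)])
    rxn = Reaction(id="r1", reversible=reversible)
    stoich = stoich or {}
    for i in range(n_reactants):
        sid = f"a{i}"
        model.species.append(Species(id=sid, sbo_term="SBO:0000247", entry_type="compound"))
        rxn.reactants.append((sid, stoich.get(sid, 1.0)))
    for i in range(n_products):
        sid = f"p{i}"
        model.species.append(Species(id=sid, sbo_term="SBO:0000247", entry_type="compound"))
        rxn.products.append((sid, stoich.get(sid, 1.0)))
    if enzyme:
        model.species.append(
            Species(id="enz", sbo_term="SBO:0000252",
                    entry_type="gene" if gene else "enzyme")
        )
        rxn.modifiers.append(Modifier(species="enz", sbo_term=modifier_sbo))
    for sid, accs in (annotations or {}).items():
        model.annotations[sid] = AnnotationSet(
            entries=[("is", f"http://identifiers.org/kegg.compound/{a}") for a in accs]
        )
    model.reactions.append(rxn)
    model.validate()
    return model


class TestClassification:
    @pytest.mark.parametrize(
        "kw,form",
        [
            (dict(n_reactants=1, n_products=1, enzyme=True), "michaelis_menten"),
            (dict(n_reactants=2, n_products=2, enzyme=True), "ternary_complex"),
            (dict(n_reactants=2, n_products=1, enzyme=True), "ternary_complex"),
            (dict(n_reactants=3, n_products=1, enzyme=True), "convenience"),
            (dict(n_reactants=1, n_products=1, enzyme=False), "gma"),
            (dict(n_reactants=2, n_products=2, reversible=True, enzyme=True), "cm_cat"),
            (dict(n_reactants=1, n_products=1, reversible=True, enzyme=True), "cm_cat"),
            (dict(n_reactants=1, n_products=1, reversible=True, enzyme=False), "gma_reversible"),
            (dict(n_reactants=0, n_products=1, enzyme=False), "gma_zeroth"),
            (dict(n_reactants=1, n_products=0, reversible=True, enzyme=True), "gma_zeroth"),
            (dict(n_reactants=1, n_products=1, enzyme=True, gene=True), "hill"),
        ],
    )
    def test_form_selection(self, kw, form):
        model = make_model(**kw)
        assert K.classify_reaction(model.reactions[0], model) == form

    def test_fully_pruned_reaction_is_zeroth_order(self):
        model = make_model(annotations={"a0": ["C00001"], "p0": ["C00080"]})
        assert K.classify_reaction(model.reactions[0], model) == "gma_zeroth"


class TestPruning:
    def test_water_excluded_from_index_sets(self):
        model = make_model(n_reactants=2, annotations={"a0": ["C00001"]})
        r, p, pruned = K.prune_small_molecules(model.reactions[0], model)
        assert "a0" not in r and pruned == ["a0"] and r == ["a1"]

    def test_reaction_without_listed_species_unchanged(self):
        model = make_model(n_reactants=2)
        r, p, pruned = K.prune_small_molecules(model.reactions[0], model)
        assert (r, p, pruned) == (["a0", "a1"], ["p0"], [])

    def test_stoichiometry_of_reaction_untouched(self):
        model = make_model(annotations={"a0": ["C00001"]})
        K.prune_small_molecules(model.reactions[0], model)
        assert model.reactions[0].reactants == [("a0", 1.0)]

    def test_ignore_list_has_thirteen_entries(self):
        assert len(K.SMALL_MOLECULES) == 13
        assert "C00001" in K.SMALL_MOLECULE_IDS


def cm_cat_brute_force(values, reactants, products, stoich, rid="r1", enzyme=None):
    """Direct numeric transliteration of the cat-form CM law."""
    h = values[f"h_{rid}"]
    num = values[f"kf_{rid}"]
    den_f = 1.0
    for sid in reactants:
        ratio = values[sid] / values[f"kM_{rid}_{sid}"]
        num *= ratio ** (h * stoich[sid])
        den_f *= (1.0 + ratio) ** (h * stoich[sid])
    num_r = values[f"kr_{rid}"]
    den_r = 1.0
    for sid in products:
        ratio = values[sid] / values[f"kM_{rid}_{sid}"]
        num_r *= ratio ** (h * stoich[sid])
        den_r *= (1.0 + ratio) ** (h * stoich[sid])
    f = values[enzyme] if enzyme else 1.0
    return f * (num - num_r) / (den_f + den_r - 1.0)


class TestCmCat:
    def test_zero_at_symmetric_point(self):
        model = make_model(reversible=True)
        law = K.build_rate_law("cm_cat", model.reactions[0], model)
        assert law.evaluate({"a0": 1.0, "p0": 1.0, "enz": 1.0}) == pytest.approx(0.0)

    def test_textbook_point_two_thirds(self):
        # A <-> B at S_A=2, S_B=0, all parameters 1: num=2, den=(1+2)+(1+0)-1=3
        model = make_model(reversible=True, enzyme=False)
        model.species.append(Species(id="enz", sbo_term="SBO:0000252", entry_type="enzyme"))
        model.reactions[0].modifiers.append(Modifier(species="enz"))
        law = K.build_rate_law("cm_cat", model.reactions[0], model)
        v = law.evaluate({"a0": 2.0, "p0": 0.0, "enz": 1.0})
        assert v == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_parameter_count_r_plus_p_plus_three(self):
        for n_r, n_p in [(1, 1), (2, 1), (2, 3)]:
            model = make_model(n_reactants=n_r, n_products=n_p, reversible=True)
            law = K.build_rate_law("cm_cat", model.reactions[0], model)
            assert len(law.params) == n_r + n_p + 3

    def test_rejected_for_irreversible_reaction(self):
        model = make_model(reversible=False)
        with pytest.raises(K.KineticsError):
            K.build_rate_law("cm_cat", model.reactions[0], model)

    def test_brute_force_agreement_on_random_instances(self):
        rng = random.Random(42)
        worst = 0.0
        for _ in range(100):
            n_r = rng.randrange(1, 4)
            n_p = rng.randrange(1, 4)
            stoich = {f"a{i}": float(rng.randrange(1, 3)) for i in range(n_r)}
            stoich.update({f"p{i}": float(rng.randrange(1, 3)) for i in range(n_p)})
            model = make_model(n_reactants=n_r, n_products=n_p,
                               reversible=True, stoich=stoich)
            rxn = model.reactions[0]
            law = K.build_rate_law("cm_cat", rxn, model)
            values = {p.id: rng.uniform(0.2, 4.0) for p in law.params}
            for sid in law.reactant_index + law.product_index + ["enz"]:
                values[sid] = rng.uniform(0.0, 5.0)
            expected = cm_cat_brute_force(
                values, law.reactant_index, law.product_index, law.stoich, enzyme="enz"
            )
            got = law.evaluate(values)
            worst = max(worst, abs(got - expected))
        assert worst < 1e-12

    def test_detailed_balance_zero_rate(self):
        # rate vanishes whenever kf*prod_R (S/K)^(hn) == kr*prod_P (S/K)^(hn)
        rng = random.Random(7)
        for _ in range(20):
            model = make_model(n_reactants=2, n_products=1, reversible=True)
            law = K.build_rate_law("cm_cat", model.reactions[0], model)
            values = {p.id: rng.uniform(0.5, 2.0) for p in law.params}
            values.update({sid: rng.uniform(0.5, 2.0) for sid in ("a0", "a1", "enz")})
            h = values["h_r1"]
            fwd = (values["a0"] / values["kM_r1_a0"]) ** h * (values["a1"] / values["kM_r1_a1"]) ** h
            # choose product quantity to hit the balance point exactly
            target = values["kf_r1"] * fwd / values["kr_r1"]
            values["p0"] = values["kM_r1_p0"] * target ** (1.0 / h)
            assert abs(law.evaluate(values)) < 1e-9

    def test_monotone_in_reactants_and_products(self):
        model = make_model(n_reactants=2, n_products=2, reversible=True)
        law = K.build_rate_law("cm_cat", model.reactions[0], model)
        base = {p.id: 1.0 for p in law.params}
        base.update({s: 1.0 for s in ("a0", "a1", "p0", "p1", "enz")})
        grid = [0.1, 0.5, 1.0, 2.0, 5.0]
        for sid, direction in [("a0", +1), ("a1", +1), ("p0", -1), ("p1", -1)]:
            rates = []
            for v in grid:
                point = dict(base)
                point[sid] = v
                rates.append(law.evaluate(point))
            diffs = [direction * (b - a) for a, b in zip(rates, rates[1:])]
            assert all(d >= -1e-12 for d in diffs), (sid, rates)


class TestOtherForms:
    def test_gma_is_mass_action(self):
        model = make_model(enzyme=False)
        law = K.build_rate_law("gma", model.reactions[0], model)
        assert sympy.simplify(
            law.expression - sympy.Symbol("kG_r1") * sympy.Symbol("a0")
        ) == 0

    def test_gma_zeroth_is_constant(self):
        model = make_model(n_reactants=0, enzyme=False)
        law = K.build_rate_law("gma_zeroth", model.reactions[0], model)
        assert law.expression == sympy.Symbol("kG_r1")

    def test_michaelis_menten_shape(self):
        model = make_model()
        law = K.build_rate_law("michaelis_menten", model.reactions[0], model)
        v = law.evaluate({"a0": 1.0, "enz": 2.0})
        assert v == pytest.approx(2.0 * 1.0 / (1.0 + 1.0))

    def test_ternary_complex_denominator(self):
        model = make_model(n_reactants=2, n_products=2)
        law = K.build_rate_law("ternary_complex", model.reactions[0], model)
        # all ones: v = E*kcat*1*1/(1+1+1+1)
        assert law.evaluate({"a0": 1, "a1": 1, "enz": 1}) == pytest.approx(0.25)

    def test_hill_shape(self):
        model = make_model(gene=True)
        law = K.build_rate_law("hill", model.reactions[0], model)
        assert law.evaluate({"a0": 3.0, "enz": 1.0}) == pytest.approx(3.0 / (1 + 3.0))

    def test_inhibitor_and_activator_prefactors(self):
        model = make_model()
        model.species.append(Species(id="inh", sbo_term="SBO:0000247", entry_type="compound"))
        model.species.append(Species(id="act", sbo_term="SBO:0000247", entry_type="compound"))
        model.reactions[0].modifiers.append(Modifier(species="inh", sbo_term=K.SBO_INHIBITION))
        model.reactions[0].modifiers.append(Modifier(species="act", sbo_term=K.SBO_STIMULATION))
        law = K.build_rate_law("michaelis_menten", model.reactions[0], model)
        # kI/(kI+S_I) = 1/2, S_A/(kA+S_A) = 1/2, saturation S/(kM+S) = 1/2
        v = law.evaluate({"a0": 1, "enz": 1, "inh": 1, "act": 1})
        assert v == pytest.approx(0.5 * 0.5 * 0.5)

    @pytest.mark.parametrize(
        "form,kw",
        [
            ("cm_cat", dict(reversible=True)),
            ("gma_reversible", dict(reversible=True, enzyme=False)),
            ("gma", dict(enzyme=False)),
            ("gma_zeroth", dict(n_reactants=0, enzyme=False)),
            ("michaelis_menten", dict()),
            ("ternary_complex", dict(n_reactants=2)),
            ("convenience", dict(n_reactants=3)),
            ("hill", dict(gene=True)),
        ],
    )
    def test_all_forms_finite_at_all_ones(self, form, kw):
        model = make_model(**kw)
        law = K.build_rate_law(form, model.reactions[0], model)
        point = {s.id: 1.0 for s in model.species}
        assert math.isfinite(law.evaluate(point))

    def test_symbolic_matches_recursive_substitution_oracle(self):
        """Every generated expression evaluates like a plain recursive
        substitution of the same tree."""

        def substitute(expr, env):
            if expr.is_Number:
                return float(expr)
            if expr.is_Symbol:
                return env[expr.name]
            vals = [substitute(a, env) for a in expr.args]
            if expr.is_Add:
                return math.fsum(vals)
            if expr.is_Mul:
                out = 1.0
                for v in vals:
                    out *= v
                return out
            if expr.is_Pow:
                return vals[0] ** vals[1]
            raise AssertionError(f"unexpected node {expr.func}")

        rng = random.Random(3)
        shapes = [
            ("cm_cat", dict(reversible=True, n_reactants=2)),
            ("convenience", dict(n_reactants=3)),
            ("ternary_complex", dict(n_reactants=2)),
            ("michaelis_menten", dict()),
            ("gma_reversible", dict(reversible=True, enzyme=False)),
            ("hill", dict(gene=True)),
        ]
        for form, kw in shapes:
            model = make_model(**kw)
            law = K.build_rate_law(form, model.reactions[0], model)
            for _ in range(100):
                env = {p.id: rng.uniform(0.3, 3.0) for p in law.params}
                env.update({s.id: rng.uniform(0.3, 3.0) for s in model.species})
                assert law.evaluate(env) == pytest.approx(
                    substitute(law.expression, env), abs=1e-12, rel=1e-12
                )


class TestProvider:
    def make_provider(self, rows):
        return {
            key: [
                K.ProviderCandidate(rank=r, expression=e, params=p)
                for r, e, p in cands
            ]
            for key, cands in rows.items()
        }

    def annotated_model(self):
        model = make_model(annotations={"a0": ["C00031"]})
        model.annotations["r1"] = AnnotationSet(
            entries=[("is", "http://identifiers.org/kegg.reaction/R00299")]
        )
        return model

    def test_matching_record_adopted_verbatim(self):
        model = self.annotated_model()
        prov = self.make_provider(
            {"R00299": [(1, "v * C00031 / (km + C00031)",
                         [("v", 2.5, "mole/second"), ("km", 0.7, "mole")])]}
        )
        law = K.provider_lookup(model.reactions[0], model, prov)
        assert law is not None and law.form == "imported"
        assert law.evaluate({"a0": 0.7}) == pytest.approx(2.5 / 2)
        assert law.param("v_r1").value == 2.5 and law.param("v_r1").imported

    def test_empty_provider_absent(self):
        model = self.annotated_model()
        assert K.provider_lookup(model.reactions[0], model, {}) is None

    def test_unmatchable_first_candidate_falls_through(self):
        model = self.annotated_model()
        prov = self.make_provider(
            {
                "R00299": [
                    (1, "v * NOPE / (km + NOPE)", [("v", 1.0, "mole/second"), ("km", 1.0, "mole")]),
                    (2, "v * C00031", [("v", 9.0, "1/second")]),
                ]
            }
        )
        law = K.provider_lookup(model.reactions[0], model, prov)
        assert law is not None
        assert law.param("v_r1").value == 9.0

    def test_imported_values_not_reset_by_initialization(self):
        model = self.annotated_model()
        prov = self.make_provider(
            {"R00299": [(1, "v * C00031", [("v", 9.0, "1/second")])]}
        )
        K.attach_rate_laws(model, prov)
        K.init_and_unitize(model)
        assert model.reactions[0].kinetic_law.param("v_r1").value == 9.0


class TestInitAndUnitize:
    def test_everything_initialized_to_one(self):
        model = make_model(n_reactants=2, reversible=True)
        K.attach_rate_laws(model)
        K.init_and_unitize(model)
        assert all(c.size == 1.0 for c in model.compartments)
        assert all(s.initial_quantity == 1.0 for s in model.species)
        law = model.reactions[0].kinetic_law
        assert all(p.value == 1.0 for p in law.params)
        assert (model.substance_units, model.time_units, model.volume_units) == (
            "mole", "second", "litre",
        )
        assert all(s.has_only_substance_units for s in model.species)

    def test_gma_rate_constant_per_second(self):
        # v = k * S with S in substance units: unit(k) solves mole/s = u * mole
        model = make_model(enzyme=False)
        K.attach_rate_laws(model)
        K.init_and_unitize(model)
        law = model.reactions[0].kinetic_law
        assert law.param("kG_r1").unit == {"second": -1}

    @pytest.mark.parametrize(
        "kw,form",
        [
            (dict(reversible=True, n_reactants=2, n_products=2), "cm_cat"),
            (dict(n_reactants=3), "convenience"),
            (dict(n_reactants=2), "ternary_complex"),
            (dict(gene=True), "hill"),
            (dict(reversible=True, enzyme=False, n_reactants=2), "gma_reversible"),
        ],
    )
    def test_dimensional_reduction_to_substance_per_time(self, kw, form):
        model = make_model(**kw)
        K.attach_rate_laws(model)
        law = model.reactions[0].kinetic_law
        assert law.form == form
        K.init_and_unitize(model)  # raises on dimensional inconsistency
        dims = {sympy.Symbol(s.id): {"mole": 1} for s in model.species}
        dims[sympy.Symbol("default")] = {"litre": 1}
        for p in law.params:
            dims[sympy.Symbol(p.id)] = p.unit
        assert U.unit_eq(U.dimension_of(law.expression, dims), U.SUBSTANCE_PER_TIME)

    def test_concentration_species_wrapped_by_compartment_size(self):
        model = make_model(enzyme=False)
        model.species_by_id("a0").is_concentration = True
        K.attach_rate_laws(model)
        K.init_and_unitize(model)
        expr = model.reactions[0].kinetic_law.expression
        assert sympy.Symbol("default") in expr.free_symbols

    def test_inconsistent_imported_units_raise_naming_parameter(self):
        model = make_model(enzyme=False)
        law = K.build_rate_law("gma", model.reactions[0], model)
        law.params[0].unit = {"litre": 3}  # nonsense unit for a rate constant
        model.reactions[0].kinetic_law = law
        with pytest.raises(UnitDerivationError, match="kG_r1"):
            K.init_and_unitize(model)


def test_mark_genes_sets_boundary_condition():
    model = make_model(gene=True)
    K.mark_genes(model)
    assert model.species_by_id("enz").boundary_condition is True
    assert model.species_by_id("a0").boundary_condition is False


def test_full_column_rank_switch_recorded():
    model = make_model(n_reactants=3)
    law = K.build_rate_law("convenience", model.reactions[0], model)
    assert law.thermo_mode in ("dependent", "independent")
    assert law.thermo_mode == (
        "dependent" if K.stoichiometric_full_column_rank(model) else "independent"
    )
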