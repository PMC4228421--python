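"""Rate-law generation, parameter initialization and unit derivation.

Every reaction of a process model receives a kinetic law: imported from a
file-backed provider of measured rate laws when a matching record exists,
otherwise generated ab initio from the reaction's structure:

====================================  =============================
reversible, enzyme-catalysed          common modular rate law, explicit
                                      catalytic (*cat*) form
reversible, non-enzymatic             reversible generalized mass action
no reactants (or reversible without   zeroth-order generalized mass
products)                             action (a bare constant)
irreversible, non-enzymatic           generalized mass action
irreversible uni-uni, enzyme          Henri-Michaelis-Menten
irreversible bi-uni / bi-bi, enzyme   random-order ternary-complex
other irreversible enzymatic          convenience kinetics
gene-regulatory                       generalized Hill equation
====================================  =============================

The *cat* form of the common modular (CM) rate law for reaction r is

    v_r = f * [ k+ * prod_{i in R}(S_i/K_i)^(h*n_i)
              - k- * prod_{i in P}(S_i/K_i)^(h*n_i) ]
            / [ prod_{i in R}(1+S_i/K_i)^(h*n_i)
              + prod_{i in P}(1+S_i/K_i)^(h*n_i) - 1 ]

with R/P the reactant/product index sets after pruning ubiquitous small
molecules, n_i the absolute stoichiometric coefficients, K_i Michaelis
constants, h the cooperativity, and f a modulation prefactor: the catalyst
quantity (when an enzyme modifier exists) times K_I/(K_I+S_I) for each
inhibitor and S_A/(K_A+S_A) for each activator.

All newly created parameters, compartment sizes and species quantities are
initialized to 1.0; parameter units are derived so that every rate reduces
dimensionally to substance/time (mole/second by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import sympy

from .common import PathModelsError, UnitDerivationError
from .model import Modifier, Parameter, ProcessModel, Reaction
from . import units as U

log = logging.getLogger(__name__)


class KineticsError(PathModelsError):
    pass


#: Ubiquitous small molecules and ions excluded from rate-law symbol sets
#: (name, formula, compound identifier).
SMALL_MOLECULES = (
    ("Water", "H2O", "C00001"),
    ("Zinc cation", "Zn", "C00038"),
    ("Copper(II)", "Cu", "C00070"),
    ("Calcium cation", "Ca", "C00076"),
    ("Hydron", "H", "C00080"),
    ("Cobalt ion(II)", "Co", "C00175"),
    ("Potassium cation", "K", "C00238"),
    ("Hydrogen", "H2", "C00282"),
    ("Nickel", "Ni", "C00291"),
    ("Hydrochloric acid", "HCl", "C01327"),
    ("Hydrogen selenide", "H2Se", "C01528"),
    ("Iron(II) ion", "Fe", "C14818"),
    ("Iron(III) ion", "Fe", "C14819"),
)

SMALL_MOLECULE_IDS = frozenset(row[2] for row in SMALL_MOLECULES)

SBO_INHIBITION = "SBO:0000169"
SBO_STIMULATION = "SBO:0000170"
_ENZYME_SBO = ("SBO:0000252", "SBO:0000253")

FORMS = (
    "cm_cat",
    "convenience",
    "gma",
    "gma_reversible",
    "gma_zeroth",
    "michaelis_menten",
    "ternary_complex",
    "hill",
    "imported",
)


@dataclass
class RateLawSpec:
    form: str
    expression: sympy.Expr
    params: list[Parameter] = field(default_factory=list)
    reactant_index: list[str] = field(default_factory=list)
    product_index: list[str] = field(default_factory=list)
    modifier_index: list[str] = field(default_factory=list)
    stoich: dict[str, float] = field(default_factory=dict)
    pruned: list[str] = field(default_factory=list)
    #: saturation/inhibition constants -> the species they refer to
    param_species: dict[str, str] = field(default_factory=dict)
    #: thermodynamic parameterization mode of the convenience law
    thermo_mode: str = ""

    def param(self, pid: str) -> Parameter:
        for p in self.params:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def evaluate(self, values: dict[str, float]) -> float:
        """Numeric value of the law; unspecified symbols default to the
        stored parameter values."""
        subs = {p.id: p.value for p in self.params}
        subs.update(values)
        return float(self.expression.evalf(subs={sympy.Symbol(k): v for k, v in subs.items()}))


def prune_small_molecules(
    reaction: Reaction, model: ProcessModel
) -> tuple[list[str], list[str], list[str]]:
    """Split participants into rate-law reactant/product index sets and the
    pruned small-molecule list.

    A participant is pruned when one of its annotation accessions is on the
    small-molecule ignore list.  The reaction's stoichiometry itself is
    untouched; only the symbol sets used by the generated law shrink.
    """
    pruned: list[str] = []

    def keep(sid: str) -> bool:
        aset = model.annotations.get(sid)
        accs = aset.accessions() if aset is not None else set()
        if accs & SMALL_MOLECULE_IDS:
            pruned.append(sid)
            return False
        return True

    reactants = [sid for sid, _ in reaction.reactants if keep(sid)]
    products = [sid for sid, _ in reaction.products if keep(sid)]
    return reactants, products, pruned


def _catalysts(reaction: Reaction, model: ProcessModel) -> list[str]:
    out = []
    for m in reaction.modifiers:
        if m.sbo_term in (SBO_INHIBITION, SBO_STIMULATION):
            continue
        if model.species_by_id(m.species).sbo_term in _ENZYME_SBO:
            out.append(m.species)
    return out


def is_gene_regulatory(reaction: Reaction, model: ProcessModel) -> bool:
    """A reaction is treated as gene-regulatory when a gene-type species
    takes part as reactant or modifier (the gene acts as a constant
    template driving expression)."""
    sids = [s for s, _ in reaction.reactants] + [m.species for m in reaction.modifiers]
    return any(model.species_by_id(s).entry_type == "gene" for s in sids)


def classify_reaction(reaction: Reaction, model: ProcessModel) -> str:
    """Select the generated rate-law form for a reaction."""
    if is_gene_regulatory(reaction, model):
        return "hill"
    reactants, products, _ = prune_small_molecules(reaction, model)
    if not reactants or (reaction.reversible and not products):
        return "gma_zeroth"
    enzymatic = bool(_catalysts(reaction, model))
    if reaction.reversible:
        return "cm_cat" if enzymatic else "gma_reversible"
    if not enzymatic:
        return "gma"
    n_r, n_p = len(reactants), len(products)
    if (n_r, n_p) == (1, 1):
        return "michaelis_menten"
    if n_r == 2 and n_p in (1, 2):
        return "ternary_complex"
    return "convenience"


def _sym(sid: str) -> sympy.Symbol:
    return sympy.Symbol(sid)


class _Builder:
    def __init__(self, reaction: Reaction, model: ProcessModel):
        self.rxn = reaction
        self.model = model
        self.params: list[Parameter] = []
        self.param_species: dict[str, str] = {}
        self.reactants, self.products, self.pruned = prune_small_molecules(reaction, model)
        self.stoich = {sid: abs(c) for sid, c in reaction.reactants + reaction.products}
        self.catalysts = _catalysts(reaction, model)

    def new_param(self, pid: str, species: str | None = None) -> sympy.Symbol:
        self.params.append(Parameter(id=pid))
        if species is not None:
            self.param_species[pid] = species
        return _sym(pid)

    def k_michaelis(self, sid: str) -> sympy.Symbol:
        return self.new_param(f"kM_{self.rxn.id}_{sid}", species=sid)

    def prefactor(self) -> sympy.Expr:
        """Modulation function f: catalyst quantity times inhibitor and
        activator hyperbolic prefactors."""
        f: sympy.Expr = sympy.Integer(1)
        if self.catalysts:
            f = sympy.Add(*[_sym(c) for c in self.catalysts]) if len(self.catalysts) > 1 else _sym(self.catalysts[0])
        for m in self.rxn.modifiers:
            s = _sym(m.species)
            if m.sbo_term == SBO_INHIBITION:
                kI = self.new_param(f"kI_{self.rxn.id}_{m.species}", species=m.species)
                f = f * kI / (kI + s)
            elif m.sbo_term == SBO_STIMULATION:
                kA = self.new_param(f"kA_{self.rxn.id}_{m.species}", species=m.species)
                f = f * s / (kA + s)
        return f

    @property
    def has_catalyst_factor(self) -> bool:
        return bool(self.catalysts)


def build_rate_law(form: str, reaction: Reaction, model: ProcessModel) -> RateLawSpec:
    """Construct the symbolic rate law of the given form for a reaction."""
    if form not in FORMS:
        raise KineticsError(f"unknown rate-law form {form!r}")
    b = _Builder(reaction, model)
    rid = reaction.id
    f = b.prefactor()

    if form == "cm_cat":
        if not reaction.reversible:
            raise KineticsError(f"reaction {rid}: CM rate law requires reversibility")
        h = b.new_param(f"h_{rid}")
        kf = b.new_param(f"kf_{rid}")
        kr = b.new_param(f"kr_{rid}")
        num_f = sympy.Integer(1)
        num_r = sympy.Integer(1)
        den_f = sympy.Integer(1)
        den_r = sympy.Integer(1)
        for sid in b.reactants:
            K = b.k_michaelis(sid)
            ratio = _sym(sid) / K
            e = h * sympy.nsimplify(b.stoich[sid])
            num_f *= ratio**e
            den_f *= (1 + ratio) ** e
        for sid in b.products:
            K = b.k_michaelis(sid)
            ratio = _sym(sid) / K
            e = h * sympy.nsimplify(b.stoich[sid])
            num_r *= ratio**e
            den_r *= (1 + ratio) ** e
        expr = f * (kf * num_f - kr * num_r) / (den_f + den_r - 1)

    elif form == "michaelis_menten":
        (sid,) = b.reactants
        kcat = b.new_param(f"kcat_{rid}")
        kM = b.k_michaelis(sid)
        expr = f * kcat * _sym(sid) / (kM + _sym(sid))

    elif form == "ternary_complex":
        sa, sb_ = b.reactants
        kcat = b.new_param(f"kcat_{rid}")
        kic = b.new_param(f"kic_{rid}_{sa}", species=sa)
        kMa = b.k_michaelis(sa)
        kMb = b.k_michaelis(sb_)
        A, B = _sym(sa), _sym(sb_)
        expr = f * kcat * A * B / (kic * kMb + kMb * A + kMa * B + A * B)

    elif form == "convenience":
        kcat = b.new_param(f"kcat_{rid}")
        num = sympy.Integer(1)
        den = sympy.Integer(1)
        for sid in b.reactants:
            K = b.k_michaelis(sid)
            ratio = _sym(sid) / K
            n = int(round(b.stoich[sid]))
            num *= ratio**n
            den *= sympy.Add(*[ratio**m for m in range(n + 1)])
        expr = f * kcat * num / den

    elif form == "gma":
        if reaction.reversible:
            raise KineticsError(f"reaction {rid}: irreversible mass action on reversible reaction")
        k = b.new_param(f"kG_{rid}")
        expr = f * k * _mass_action_product(b, b.reactants)

    elif form == "gma_reversible":
        kf = b.new_param(f"kf_{rid}")
        kr = b.new_param(f"kr_{rid}")
        expr = f * (
            kf * _mass_action_product(b, b.reactants)
            - kr * _mass_action_product(b, b.products)
        )

    elif form == "gma_zeroth":
        k = b.new_param(f"kG_{rid}")
        expr = f * k

    elif form == "hill":
        targets = b.reactants or [m.species for m in reaction.modifiers]
        if not targets:
            raise KineticsError(f"reaction {rid}: Hill law needs a reactant or modifier")
        sid = targets[0]
        V = b.new_param(f"vmax_{rid}")
        h = b.new_param(f"h_{rid}")
        K = b.k_michaelis(sid)
        S = _sym(sid)
        expr = f * V * S**h / (K**h + S**h)

    else:  # imported laws are built by provider_lookup
        raise KineticsError("imported laws come from provider_lookup")

    spec = RateLawSpec(
        form=form,
        expression=expr,
        params=b.params,
        reactant_index=b.reactants,
        product_index=b.products,
        modifier_index=[m.species for m in reaction.modifiers],
        stoich=b.stoich,
        pruned=b.pruned,
        param_species=b.param_species,
    )
    if form == "convenience":
        spec.thermo_mode = (
            "dependent" if stoichiometric_full_column_rank(model) else "independent"
        )
    return spec


def _mass_action_product(b: _Builder, sids: list[str]) -> sympy.Expr:
    out: sympy.Expr = sympy.Integer(1)
    for sid in sids:
        out *= _sym(sid) ** sympy.nsimplify(b.stoich[sid])
    return out


def stoichiometric_full_column_rank(model: ProcessModel) -> bool:
    """True when the model's stoichiometric matrix (species x reactions)
    has full column rank; used to pick the thermodynamic parameterization
    mode of the convenience law."""
    if not model.reactions:
        return True
    sids = {s.id: i for i, s in enumerate(model.species)}
    mat = np.zeros((len(sids), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for sid, c in r.reactants:
            mat[sids[sid], j] -= c
        for sid, c in r.products:
            mat[sids[sid], j] += c
    return int(np.linalg.matrix_rank(mat)) == len(model.reactions)


# ---------------------------------------------------------------------------
# provider records


@dataclass
class ProviderCandidate:
    rank: int
    expression: str
    params: list[tuple[str, float, str]]  # (name, value, unit string)


def load_provider(path) -> dict[str, list[ProviderCandidate]]:
    """Read a rate-law provider table.

    Tab-separated columns: reaction key, candidate rank, infix expression,
    parameter name, value, unit string.  Parameter rows of one candidate
    repeat the key/rank/expression columns.
    """
    table: dict[str, dict[int, ProviderCandidate]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            key, rank_s, expr, pname, value_s, unit_s = line.split("\t")[:6]
            rank = int(rank_s)
            cand = table.setdefault(key, {}).setdefault(
                rank, ProviderCandidate(rank=rank, expression=expr, params=[])
            )
            if pname:
                cand.params.append((pname, float(value_s), unit_s))
    return {
        key: [cands[r] for r in sorted(cands)] for key, cands in table.items()
    }


def reaction_key(reaction: Reaction, model: ProcessModel) -> str | None:
    """Unified reaction identifier used to query the provider (the
    reaction-database accession from the MIRIAM annotation)."""
    aset = model.annotations.get(reaction.id)
    if aset is None:
        return None
    for _, uri in aset.entries:
        if "/kegg.reaction/" in uri:
            return uri.rsplit("/", 1)[-1]
    return None


def provider_lookup(
    reaction: Reaction,
    model: ProcessModel,
    provider: dict[str, list[ProviderCandidate]],
) -> RateLawSpec | None:
    """Adopt the first provider candidate whose species all match.

    Candidates are scanned in provider (rank) order.  Expression symbols
    that are not declared parameters must each resolve to a participant or
    modifier of the reaction — by species id or by a shared annotation
    accession — or to a compartment id; the first fully matchable candidate
    is imported verbatim (expression, parameter values and units).
    """
    key = reaction_key(reaction, model)
    if key is None or key not in provider:
        return None
    local_sids = (
        [s for s, _ in reaction.reactants]
        + [p for p, _ in reaction.products]
        + [m.species for m in reaction.modifiers]
    )
    acc_to_sid: dict[str, str] = {}
    for sid in local_sids:
        aset = model.annotations.get(sid)
        if aset is not None:
            for acc in sorted(aset.accessions()):
                acc_to_sid.setdefault(acc, sid)
    compartment_ids = {c.id for c in model.compartments}

    for cand in provider[key]:
        try:
            expr = sympy.sympify(cand.expression.replace("^", "**"))
        except (sympy.SympifyError, SyntaxError) as exc:
            log.warning("provider %s rank %d: unparseable expression (%s)", key, cand.rank, exc)
            continue
        pnames = {p[0] for p in cand.params}
        subs: dict[sympy.Symbol, sympy.Symbol] = {}
        ok = True
        for sym in sorted(expr.free_symbols, key=lambda s: s.name):
            name = sym.name
            if name in pnames:
                subs[sym] = _sym(f"{name}_{reaction.id}")
            elif name in {s for s in local_sids}:
                continue
            elif name in acc_to_sid:
                subs[sym] = _sym(acc_to_sid[name])
            elif name in compartment_ids:
                continue
            else:
                log.warning(
                    "provider %s rank %d: symbol %r matches no species/compartment; skipping",
                    key, cand.rank, name,
                )
                ok = False
                break
        if not ok:
            continue
        expr = expr.subs(subs, simultaneous=True)
        params = [
            Parameter(
                id=f"{name}_{reaction.id}",
                value=value,
                unit=U.parse_unit(unit_s),
                imported=True,
            )
            for name, value, unit_s in cand.params
        ]
        reactants, products, pruned = prune_small_molecules(reaction, model)
        return RateLawSpec(
            form="imported",
            expression=expr,
            params=params,
            reactant_index=reactants,
            product_index=products,
            modifier_index=[m.species for m in reaction.modifiers],
            stoich={sid: abs(c) for sid, c in reaction.reactants + reaction.products},
            pruned=pruned,
        )
    return None


def attach_rate_laws(
    model: ProcessModel,
    provider: dict[str, list[ProviderCandidate]] | None = None,
) -> dict[str, int]:
    """Attach a rate law to every reaction; returns per-form counts."""
    counts: dict[str, int] = {}
    for rxn in model.reactions:
        law = None
        if provider:
            law = provider_lookup(rxn, model, provider)
        if law is None:
            form = classify_reaction(rxn, model)
            law = build_rate_law(form, rxn, model)
        rxn.kinetic_law = law
        counts[law.form] = counts.get(law.form, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# initialization and unit derivation

_K_PREFIXES = ("kM_", "kI_", "kA_", "kic_")
_VELOCITY_PREFIXES = ("kf_", "kr_", "kcat_", "vmax_")


def init_and_unitize(model: ProcessModel) -> ProcessModel:
    """Initialize quantities and derive consistent parameter units.

    Model defaults become mole / second / litre when unset; unset
    compartment sizes and species quantities become 1.0 (new parameters are
    created at 1.0 already; imported parameter values are kept).  Species
    are switched to substance units: quantities stated as concentrations
    are multiplied by their compartment size inside each kinetic equation.
    Units of generated parameters are then derived so that every rate law
    reduces to substance/time, which is verified by symbolic dimensional
    analysis.
    """
    model.substance_units = model.substance_units or "mole"
    model.time_units = model.time_units or "second"
    model.volume_units = model.volume_units or "litre"
    for c in model.compartments:
        if c.size is None:
            c.size = 1.0
    conc_species = {}
    for s in model.species:
        if s.initial_quantity is None:
            s.initial_quantity = 1.0
        if s.is_concentration:
            conc_species[s.id] = s.compartment
        s.has_only_substance_units = True

    species_dims: dict[sympy.Symbol, U.Unit] = {}
    for s in model.species:
        if s.id in conc_species:
            species_dims[_sym(s.id)] = {"mole": 1, "litre": -1}
        else:
            species_dims[_sym(s.id)] = dict(U.SUBSTANCE)
    for c in model.compartments:
        species_dims[_sym(c.id)] = {"litre": 1}

    for rxn in model.reactions:
        law = rxn.kinetic_law
        if law is None:
            continue
        for sid, comp in conc_species.items():
            s = _sym(sid)
            if s in law.expression.free_symbols:
                law.expression = law.expression.subs(s, s * _sym(comp))
        _derive_units(rxn, law, model, species_dims)
    return model


def _derive_units(rxn: Reaction, law: RateLawSpec, model: ProcessModel, species_dims) -> None:
    f_dim: U.Unit = {}
    catalysts = _catalysts(rxn, model)
    if catalysts and law.form != "imported":
        f_dim = dict(species_dims[_sym(catalysts[0])])

    sum_n = lambda sids: sum(law.stoich.get(s, 1) for s in sids)  # noqa: E731
    for p in law.params:
        if p.unit is not None:
            continue
        if p.id.startswith(_K_PREFIXES):
            # same dimension as the species the constant refers to
            sid = law.param_species.get(p.id, "")
            p.unit = dict(species_dims.get(_sym(sid), U.SUBSTANCE))
        elif p.id.startswith("h_"):
            p.unit = {}
        elif p.id.startswith("kG_"):
            if law.form == "gma_zeroth":
                consumed: U.Unit = {}
            else:
                consumed = U.unit_pow(U.SUBSTANCE, sympy.nsimplify(sum_n(law.reactant_index)))
            p.unit = U.unit_div(U.SUBSTANCE_PER_TIME, U.unit_mul(f_dim, consumed))
        elif p.id.startswith(_VELOCITY_PREFIXES):
            if law.form == "gma_reversible":
                side = law.reactant_index if p.id.startswith("kf_") else law.product_index
                consumed = U.unit_pow(U.SUBSTANCE, sympy.nsimplify(sum_n(side)))
            else:
                consumed = {}
            p.unit = U.unit_div(U.SUBSTANCE_PER_TIME, U.unit_mul(f_dim, consumed))
        else:
            raise UnitDerivationError(
                f"reaction {rxn.id}: no unit rule for parameter {p.id!r}"
            )

    dims = dict(species_dims)
    for p in law.params:
        dims[_sym(p.id)] = p.unit or {}
    try:
        dim = U.dimension_of(law.expression, dims)
    except UnitDerivationError as exc:
        raise UnitDerivationError(
            f"reaction {rxn.id}: rate law not unitizable "
            f"(parameters {[p.id for p in law.params]}): {exc}"
        ) from exc
    if not U.unit_eq(dim, U.SUBSTANCE_PER_TIME):
        raise UnitDerivationError(
            f"reaction {rxn.id}: rate law has dimension {U.format_unit(dim)}, "
            f"expected substance/time (parameters {[p.id for p in law.params]})"
        )


def mark_genes(model: ProcessModel) -> ProcessModel:
    """Fix gene species as boundary conditions: genes act as constant
    template pools that reactions cannot deplete."""
    for s in model.species:
        if s.entry_type == "gene":
            s.boundary_condition = True
    return model
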