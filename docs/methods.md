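# Methods

This note records the models and procedures implemented by `pathmodels`,
the defaults that matter, and the design choices made where the design was
genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Source dialect and filtering

The input dialect is KGML v0.7.x (entries / reactions / relations, with
center-anchored pixel boxes on entries only).  All internal layout is
top-left anchored; the conversion happens once at parse time.  Stoichiometric
coefficients default to 1 when the file omits them.  The relation-subtype
catalogue is closed at the 14 subtypes the translation table covers;
anything else is rejected at parse time rather than guessed.

Organism-specific maps retain template enzymes that have no instance in
the organism (they exist for display).  Filtering removes non-instantiated
ortholog entries together with their catalysis links; in metabolic mode it
also removes pathway-reference (`map`) nodes, which do not denote physical
species.  A reaction survives losing its catalysts (with an emptied
modifier list) and is dropped only when it loses all participants.
Instantiation is read from a dedicated boolean attribute in the synthetic
dialect; a compatibility switch accepts the background-colour convention
(`#BFFFBF` = instantiated) of real organism-specific files.  Entries
without either indication count as instantiated.

Reaction completion consults an external reaction-definition table and
appends participants the map omits, synthesizing compound/enzyme entries
without layout.  On a stoichiometry conflict the map value wins (the map
is the primary source; the definition is auxiliary), with a logged
warning.

## Kinetic model generation

Species SBO terms follow a fixed entry-type table (simple chemical,
polypeptide chain, non-covalent complex, reference annotation).  Group
entries become a single complex species; members are recorded in the notes
and as `isEncodedBy` cross-references, and are *not* instantiated as
standalone species unless they also occur outside the group — a deliberate
choice to keep group semantics local.  Cross-references use Identifiers.org
URIs; when one element collects several identifiers from the same database
each is qualified `hasVersion`, otherwise `is`.  Every species, reaction,
qualitative species and transition carries the ECO:0000313
automatic-assertion evidence code.

Rate-law selection, after pruning thirteen ubiquitous small molecules and
ions (water, protons, common metal cations, ...) from the symbol sets:

| reaction shape | law |
| --- | --- |
| gene-regulatory | generalized Hill, `f·V·S^h/(K^h+S^h)` |
| no reactants, or reversible without products | zeroth-order mass action (bare constant) |
| reversible, enzyme-catalysed | CM rate law, *cat* form |
| reversible, non-enzymatic | reversible generalized mass action |
| irreversible, non-enzymatic | generalized mass action |
| irreversible uni-uni, enzyme | Henri-Michaelis-Menten |
| irreversible bi-uni / bi-bi, enzyme | random-order ternary complex |
| other irreversible enzymatic | convenience kinetics |

A reaction counts as gene-regulatory when a gene-type species takes part
as reactant or modifier; gene species are additionally fixed as boundary
conditions (constant template pools).  A reaction counts as
enzyme-catalysed when a modifier species carries a polypeptide/complex SBO
term and the modifier link is not an inhibition/stimulation link.

The *cat* form of the CM law is implemented with `h·nᵢ` grouped as a
single exponent (following the law's standard formulation; the typeset
variants are ambiguous on this point).  The modulation prefactor f
multiplies the catalyst quantity (the sum of catalyst species when several
are attached), `K_I/(K_I+S_I)` per inhibitor, and `S_A/(K_A+S_A)` per
activator, with modifier roles read from the SBO term of the modifier
link.  The convenience law is emitted in its thermodynamically independent
form; a rank test on the stoichiometric matrix records (as metadata)
whether the dependent parameterization would apply.  Parameter names are
deterministic — `<tag>_<reaction>[_<species>]` — so documents are
reproducible byte for byte.

Initialization: all newly created parameters, compartment sizes and
species quantities are set to 1.0.  Imported (provider) parameter values
are kept, since they carry measured information.  Default units are
mole / second / litre; `hasOnlySubstanceUnits` is set on every species,
and concentration-mode species are multiplied by their compartment size
inside kinetic expressions.  Units of generated parameters are derived
per role (saturation constants take the species dimension, cooperativities
are dimensionless, velocity constants absorb whatever remains) and the
complete expression is then verified by symbolic dimensional analysis to
reduce to substance/time; exponents may be symbolic (`mole^h`) in
intermediate terms.

The rate-law provider is a file-backed table keyed by the unified
(reaction-database) accession of a reaction's annotation.  Candidates are
scanned in rank order; the first whose free symbols all resolve — by
species id, by shared annotation accession, or as a compartment id — is
imported verbatim (expression, values, units).  Unresolvable candidates
are skipped with a logged reason.

## Qualitative models

Each relation becomes one transition; the input sign is positive for
activation/expression, negative for inhibition/repression, dual when both
classes are present, unknown otherwise, and the input SBO term comes from
the first listed subtype of the activation/inhibition class, else the
first listed subtype.  Activities are Boolean (`maxLevel` 1) and no logic
terms are emitted: the source provides topology and signs only, so the
models are scaffolds for later parameterization.  Sign enrichment from an
external control-type table rewrites **only unknown** signs, matching
(source, target) annotation accessions with direction respected; when the
source map and the table disagree on an already-signed input the map wins.
Topology is never changed and the match count is returned alongside the
model.

## Genome-scale reconstructions

Identifier reconciliation replaces source ids by unified ids from a
5-column map that also supplies default formulas and charges (stated for
an assumed pH of 7.3; no pKa computation is performed — protonation enters
only through the supplied formulas).  Colliding metabolites merge;
reaction coefficients are re-aggregated per unified id, and exact
cancellations drop out.  Merging unions networks, deduplicating reactions
equal up to participant multiset and direction class — the same conversion
written in opposite directions is deliberately kept twice, since direction
is part of reaction identity in the sources.

The minimal medium contains 14 metabolites (α- and β-D-glucose as the
sole carbon sources, ammonium, sodium, potassium, magnesium, calcium,
sulphate, chlorate, phosphate, protons, water, CO₂, O₂; the chlorate
entry follows the source specification verbatim even though chloride would
be the chemically expected ion).  Each medium metabolite gets an exchange
reaction permitting uptake and an uptake-directed transporter; every
intracellular metabolite gets a secretion-only export transporter and
exchange, so the medium cannot be synthesized backwards through an
exporter.  The biomass reaction consumes 30 components with coefficient
1.0 each (no organism-specific tailoring, and no coefficients are given by
the sources): 20 amino acids, the RNA precursors represented as the four
NMPs and the DNA precursors as the four dNMPs — chosen so ATP remains a
distinct 30th component — plus glycogen and ATP.

Synthesizability: for each component a temporary demand reaction is added
and its flux maximized (cobrapy/GLPK) under steady state and bounds;
producible means optimum > 1e-6 (bounds are ±1000, so this threshold
separates numerical noise from genuine flux).  Variable order is
deterministic.  The same test over all intracellular metabolites yields
the makeable-metabolite count.  Default bounds are −1000..1000 for
reversible and 0..1000 for irreversible reactions.

Mass/charge balance sums Hill-notation element counts and charges over a
reaction's stoichiometry; any participant lacking a formula or charge, or
carrying a generic group (R/X), makes the verdict `unknown` rather than a
guess.

The COBRA-dialect document is SBML Level 2 with FORMULA/CHARGE in species
notes, GENE_ASSOCIATION in reaction notes, and LOWER_BOUND / UPPER_BOUND /
FLUX_VALUE / OBJECTIVE_COEFFICIENT as kinetic-law parameters.

## SBGN maps

PD glyph classes derive from SBO terms; one process glyph per reaction;
consumption/production/catalysis (or stimulation/inhibition) arcs by role.
Simple chemicals without a stored position or with more than one
connection, and macromolecules with more than one connection, are cloned:
one copy per connection, clone marker on every copy, so each clone touches
exactly one arc.  Initial placement: stored positions win; process glyphs
go to the centroid of their positioned partners, else to a strip at the
top of the map; unpositioned enzymes sit above the substrate/product
midline; pruned secondary compounds stack beside their process on the
matching side.

Overlap removal opens gaps: the overlapping pair defines a split line on
one axis (the axis needing the smaller shift; x on ties; identical centers
are ordered by glyph id) and every glyph at or beyond it shifts rigidly.
The shift is a monotone map of that axis, so the left/right and
above/below order of every positioned pair is preserved and existing
separations only grow — each move fixes at least one overlap permanently,
which guarantees convergence.  The default separation margin is 5 units.
Arcs are straight lines with at most one bend chosen from a small
deterministic candidate set when the direct route crosses a glyph
interior.  The full constraint-based layout machinery (alignment and
containment constraints, orthogonal object-avoiding routing, edge nudging)
is intentionally not reproduced: the testable contract is a valid,
overlap-free, order-preserving map, not aesthetic parity with interactive
editors.

AF maps draw one biological-activity glyph per qualitative species (first
stored position when several exist — "best fitting" is not defined by the
sources, so first-in-document-order is the recorded choice) and one
influence arc per input/output pair: stimulation for positive,
inhibition for negative, unknown influence otherwise.

SBGN-ML 0.2 is read and written directly (flat XML: map / glyph / label /
clone / bbox / arc with start, next, end points); write∘read is the
identity on all fixtures.

## Synthetic data

`pathmodels.fixtures` generates every input dialect from an explicit seed
and emits ground-truth manifests computed by construction, not by running
the code under test: expected entry counts after filtering, expected
relation signs (stated as an independent literal table), the winning
provider rank under the matching rule, and expected producibility reports
computed by a graph-reachability oracle.  Toy reconstructions are acyclic
unit-stoichiometry chains from glucose, built so reachability and
flux-based producibility provably coincide; designed answers cover 0, 3
and 30 makeable components.  Default shapes (8 compounds, 4 reactions,
6 relations, 75% instantiation, 50% reversibility) keep every rule
exercised while documents stay small.

What the synthetic data does **not** emulate: real pathway maps are far
larger, contain disconnected fragments, inconsistent annotations, glycan
and drug sub-dialects, and cyclic metabolism where producibility requires
cofactor regeneration and reachability overestimates flux-based answers.
Passing tests therefore demonstrate correctness of the translation rules
and analyses on well-formed inputs, not robustness to the full messiness
of production databases, and the reachability-equals-FBA identity is a
property of the fixture design, not of metabolism.

## Problem sizes and tolerances

The suites run 100 random CM-law instances against a brute-force
evaluator at 1e-12, 50 seeded toy reconstructions (about 35 LPs each)
against the reachability oracle, 200 random reactions against an
element-count balance oracle, and three 50-glyph random maps through the
layout pass; these sizes exercise every branch while keeping the whole
suite in the tens of seconds.  Byte-identical rerun checks cover the
SBML, SBML-qual, SBGN-ML and COBRA writers (libsbml's timestamped
creation comment is disabled for this reason).

## Known limitations

* Only the *cat* version of the modular rate laws is generated; the
  Haldane- and Wegscheider-compliant versions and the parameter
  transformation between them are out of scope, so thermodynamic
  consistency is not enforced.
* The convenience law's dependent/independent switch is recorded as
  metadata but both modes share the irreversible expression shape.
* Qualitative models carry no logical rules; they are scaffolds.
* No gap-filling or biomass tailoring is attempted in reconstructions;
  a draft with few source reactions will legitimately synthesize few or
  no biomass components.
* SBGN layout optimizes validity, not compactness; long maps grow to the
  right/bottom as gaps open.
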