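# pathmodels

Curated pathway databases describe biochemistry qualitatively: entries
(compounds, gene products), reactions, and signed or unsigned relations,
laid out for human viewing.  Turning such a map into something a modeler
can simulate — a kinetic model, a logical scaffold, or a constraint-based
reconstruction — is a mechanical but error-prone chore that every group
used to repeat by hand.  `pathmodels` automates that chore for
KGML-dialect pathway files, producing three kinds of standards-based model
documents plus graphical maps:

1. **Kinetic process models** (SBML Level 3 Core + Layout).  Every entry
   becomes an annotated species, every reaction an SBML reaction, and
   every reaction receives a rate law — imported from a file-backed
   provider of measured kinetics when a matching record exists, otherwise
   generated ab initio.  Reversible enzyme-catalysed reactions get the
   explicit catalytic (*cat*) form of the common modular (CM) rate law:

   ```
            k⁺ ∏_{i∈R} (Sᵢ/Kᵢ)^(h·nᵢ)  −  k⁻ ∏_{i∈P} (Sᵢ/Kᵢ)^(h·nᵢ)
   v = f · ─────────────────────────────────────────────────────────
           ∏_{i∈R} (1+Sᵢ/Kᵢ)^(h·nᵢ) + ∏_{i∈P} (1+Sᵢ/Kᵢ)^(h·nᵢ) − 1
   ```

   with R/P the reactant/product index sets (after pruning ubiquitous
   small molecules such as water and protons), nᵢ stoichiometric
   coefficients, Kᵢ Michaelis constants, h the cooperativity, and f a
   modulation prefactor (catalyst quantity × inhibitor/activator terms).
   Irreversible reactions get Henri-Michaelis-Menten, random-order
   ternary-complex, convenience or generalized mass-action kinetics by
   arity; gene regulation gets the generalized Hill equation.  All new
   parameters start at 1.0 with units derived so every rate reduces to
   substance/time.

2. **Qualitative signed-influence models** (SBML Level 3 qual).  Each
   relation becomes a transition whose input carries a sign — positive,
   negative, dual, or unknown — derived from the relation subtypes, with
   an SBO term refining the mechanism.  Unknown signs (phosphorylation,
   binding, ...) can be resolved from an external interaction-sign table.

3. **Draft genome-scale reconstructions** (COBRA-dialect SBML).
   Per-source networks are reconciled against an identifier-unification
   map, merged, equipped with a 14-metabolite minimal glucose medium,
   default transporters, and a 30-component biomass objective (20 amino
   acids, 8 nucleotide precursors, glycogen, ATP).  Flux balance analysis
   then reports which biomass components the network can synthesize from
   the medium.

SBGN Process Description and Activity Flow maps are derived from the
models and written as SBGN-ML, with clone markers for heavily connected
pools and a deterministic overlap-free layout.

All model elements carry Identifiers.org cross-references with
BioModels.net qualifiers and the ECO:0000313 automatic-assertion evidence
code.  Seeded synthetic inputs for every pipeline stage are generated by
`pathmodels.fixtures`.

## Worked example

Generate a seeded synthetic pathway and run all three pipelines:

```sh
pathmodels synthesize-fixtures --out fx --seed 11
pathmodels translate-metabolic --in fx/pathway.kgml --out model.xml --provider fx/provider.tsv
pathmodels translate-qual      --in fx/pathway.kgml --out qual.xml
pathmodels reconstruct         --in fx/pathway.kgml --out recon.xml
pathmodels sbgn                --in model.xml       --out model.sbgn
```

The metabolic translation prints

```json
{
  "command": "translate-metabolic",
  "out": "model.xml",
  "rate_law_forms": { "gma": 1, "imported": 2, "ternary_complex": 1 },
  "reactions": 4,
  "species": 18
}
```

— 18 species and 4 reactions survived organism filtering; two reactions
matched provider records and imported measured rate laws, one
non-enzymatic reaction received generalized mass action, and one bi-bi
enzymatic reaction a ternary-complex law.  The qualitative translation
reports 6 transitions (2 positive, 2 negative, 2 unknown signs), and the
reconstruction reports 52 metabolites with 14 makeable from the medium
and 0 of the 30 biomass components producible — expected for a 4-reaction
fragment that never reaches an amino acid.  The SBGN export prints 28
glyphs, 9 of them clones, each clone touching exactly one arc.

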