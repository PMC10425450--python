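# plm — constraint-based modeling of plant lipid metabolism

`plm` is a toolkit for studying leaf lipid metabolism with constraint-based
metabolic models. It targets the workflow in which a curated lipid-metabolism
module is merged into an existing *Arabidopsis thaliana* genome-scale model,
the merged model is constrained by measured lipidomes and biomass
composition, and the resulting accession- and condition-specific models are
interrogated with flux simulation, gene-essentiality screening,
flux–transcript comparison, and flux genome-wide association (fGWA).

It is written for systems biologists who have (a) a template model in SBML
(Level 3 + `fbc`) or the package's JSON dialect, (b) a lipid module in the
same formats, and (c) delimited tables of lipid profiles, biomass
composition, transcript abundances, mutant evidence, and genotypes. A seeded
fixture generator (`plm.fixtures`) emulates all of these at toy scale, so
the full pipeline runs and is tested without any external data.

## What it computes

**Module integration.** A four-step merge: consolidate compartments (exact
id → case-insensitive name → explicit override), consolidate metabolites
(match priority: shared KEGG id > shared ChEBI id > identical formula +
charge; template attributes win on conflict), rewrite and add module
reactions, and drop duplicates — a module reaction is a duplicate iff its
rewritten stoichiometry equals a template reaction's up to overall sign with
direction-consistent bounds, in which case the GPR rules are OR-merged.
Template content is otherwise untouched, so every template-feasible flux
vector stays feasible.

**SLIME lipid constraints.** Each measured lipid species gets a SLIME
(Split Lipids Into Measurable Entities) pseudo-reaction

    species → M_backbone · backbone_class [g] + Σ_j M_chain_j · chain_j [g]

whose product coefficients are the moiety molar masses (g/mmol), so they
sum exactly to the species mass. Pool pseudo-reactions then constrain the
mass distribution over lipid classes (coefficients = measured class totals
in g/gDW) and over acyl chains. Wax monomers and other single-moiety
lipids get a backbone-only split.

**Biomass.** Condition/accession-specific coefficients via the
ratio-to-absolute rule `absolute = control_absolute × rel_condition /
rel_control`, with cell wall and nucleic acids entering
condition-unspecifically, the lipid pool drained at the profile's total
lipid mass, and mass closure rescaled to exactly 1 g/gDW so the biomass
flux `v_bio` is a relative growth rate.

**Simulation.** FBA (`max c'v` s.t. `S v = 0`, `lb ≤ v ≤ ub`) and pFBA
(total |v| minimized at the fixed FBA optimum) via HiGHS; a RuBisCO
coupling constraint `v_carboxylation = 2.88 · v_oxygenation`; diel models
(light/dark copies joined by irreversible storage linkers, dark photon
influx fixed at zero) with control / 3-day / 6-day extended-darkness (3DD,
6DD) scenarios; per-subsystem activity and mean-centered mean-flux
summaries.

**Synthetic lethality (Fast-SL).** Single and double gene deletions that
abolish biomass (optimum < 10⁻³ × wild type by default), with exact
pFBA-support pruning that is provably identical to exhaustive screening
(and is tested against it), plus accuracy scoring against mutant-phenotype
evidence tables.

**Concordance.** Per-reaction transcript abundance via GPR rules (OR =
sum of isoenzymes, AND = min over complex subunits), log2 fold changes of
flux magnitude vs transcripts, sign-concordance classification, and a 2×2
chi-square test of independence (uncorrected, df = 1, φ = √(χ²/N)) to
compare datasets.

**fGWA.** Fluxes as quantitative traits: MAF > 0.05 filtering, three
principal-component covariates, a per-SNP fixed-effect scan (or externally
supplied p-values), the 1/n significance threshold, transitive 20-kb
clumping, candidate genes within ±10 kb of each lead SNP, classification
against the trait reaction's GPR neighborhood (exact > upstream >
downstream > transcription factor > unknown), expression categories
(0 / <0.3 / 0.3–0.6 / >0.6), and mutant lipid fold-change validation.

## Worked example

```bash
plm fixtures --preset mini --seed 7 --out fx
plm integrate --template fx/template.xml --module fx/lipid_module.xml \
    --out merged.json --report report.tsv
plm slime --model merged.json --profile fx/lipid_profile.tsv --out with_slime.json
plm simulate --model with_slime.json --pfba --out fluxes.tsv --summary subsystems.tsv
plm simulate --model with_slime.json --scenario 6DD \
    --diel "starch_h,sucrose_c,ala_c" EX_photon --storage-budget 2 \
    --pfba --out fluxes_6dd.tsv
plm lethality --model with_slime.json --out lethal.tsv
```

prints

```
fixtures written to fx
metabolites: 4 matched, 7 added; reactions: 9 added, 3 deduplicated
objective (control): 0.671141
objective (6DD): 1.22449
single lethal: 12; double lethal pairs: 3; non-lethal: 27
```

Reading: the 12-reaction toy lipid module shares three reactions with the
template (deduplicated, their GPRs OR-merged) and contributes nine new
ones; under illumination the merged model grows at 0.671 gDW gDW⁻¹
phase⁻¹ (limited by CO₂ uptake); after six days of simulated darkness the
diel model grows only on its pre-accumulated starch/sucrose/amino-acid
storage; and 12 genes are singly essential for growth while three gene
pairs are synthetic lethal. `subsystems.tsv` holds the per-subsystem
proportion of active reactions and mean-centered mean fluxes.

The same stages are available as library calls (`plm.integrate_module`,
`plm.add_slime_constraints`, `plm.assemble_biomass`, `plm.pfba`,
`plm.fastsl_lethals`, `plm.concordance_table`, `plm.run_fgwa`, ...); see
the module docstrings and `docs/methods.md`.

## Repository layout

- `src/plm/model_core.py` — data model, GPR logic, formulas, SBML/JSON IO,
  validation (`docs/model_format.md` documents the JSON dialect)
- `src/plm/integration.py`, `slime.py`, `biomass.py` — model construction
- `src/plm/simulation.py`, `lethality.py`, `concordance.py`, `fgwa.py` —
  analyses
- `src/plm/fixtures.py` — seeded synthetic inputs
- `docs/methods.md` — modeling assumptions, conventions and limitations
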