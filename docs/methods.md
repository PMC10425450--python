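# Methods

This note records the modeling conventions, numerical choices and known
limitations behind each stage of the toolkit. Everything quantitative
stated here is computed by the test suite or `scripts/acceptance.py`.

## Model representation

A model is compartments, metabolites (elemental formula, integer charge,
database annotations), reactions (stoichiometry, flux bounds in
mmol gDW⁻¹ phase⁻¹, a GPR rule, a subsystem label, and role flags), and a
linear objective. Charged and neutral formula variants are not reconciled
at read time: one formula string plus the integer charge field is stored,
and `validate_model` reports element/charge imbalances instead of guessing.
Exchange reactions are one-sided (no boundary species), so uptake is
negative flux; `exchange`, `demand`, `biomass` and `slime` flags exempt a
reaction from balance checking, and reactions touching a formula-less
metabolite are reported as unchecked rather than unbalanced.

GPR rules are Boolean trees (AND = protein complex, OR = isoenzymes).
Quantitatively, transcript abundance maps onto a rule with OR = sum and
AND = min; a gene absent from the abundance table contributes 0 under OR
and is skipped under AND, on the grounds that absent evidence should not
zero out a whole complex (a warning is logged when an AND node has no
measured subunit). An empty rule has no defined abundance and raises a
distinct signal rather than returning 0.

Molar masses use conventional standard atomic weights (H 1.00794,
C 12.0107, N 14.0067, O 15.9994, …), expressed in g/mmol to match the
mmol/gDW coefficient convention. SBML (Level 3 + `fbc`) is read and
written through COBRApy/libsbml; flags and subsystem travel in reaction
notes, metabolite annotations as identifiers.org CV terms. libsbml prints
doubles at 15 significant digits, so SBML round-trips are exact only to
that precision; the JSON dialect (`docs/model_format.md`) is lossless and
is the reference serialization.

## Module integration

Compartment consolidation: explicit overrides, then exact id, then
case-insensitive name; everything else becomes a new compartment.
Metabolite matching priority is KEGG > ChEBI > (formula, charge), because
curated database identifiers are more reliable than formulas, which
collide on isomers. Two template metabolites with the same KEGG/ChEBI id
in one compartment make a match ambiguous and abort with the candidate
list. On attribute conflicts the template wins and the conflict is logged
— the template is the curated reference being extended.

Duplicate detection compares sign-normalized stoichiometries with exact
coefficient equality (model coefficients are curated constants, not
measurements) and requires a common admissible flux direction: A→B vs B→A
both irreversible are *not* duplicates. Duplicates are dropped and their
GPR OR-merged into the template reaction (both gene sets independently
support catalysis); an empty GPR means "no gene requirement" and absorbs
the union. GPR/subsystem differences are deliberately ignored for
duplication purposes. Because template bounds and stoichiometry are never
modified, feasibility of template flux distributions is preserved by
construction, and integration is idempotent provided module metabolites
carry an identifier or formula to match on (metabolites with neither are
re-added, by the definition of the match bases).

## SLIME constraints

Moiety convention: a chain moiety is the acyl group (fatty acid minus
H₂O-equivalent), and the backbone moiety is the remainder of the species
formula, so moiety masses sum exactly to the species molar mass and every
SLIME reaction conserves mass (verified to 1e-6 relative, observed at
machine precision). Wax monomers and other single-moiety lipids get a
backbone-only split. Pseudo-metabolites carry gram units; the two pool
species are dimensionless bookkeeping units.

The backbone pool consumes each class's backbone pseudo-metabolite at the
measured class total (g/gDW, the sum of species abundances) and produces
one unit of the lipid pool, which the biomass reaction drains at one unit
per gDW — in mass terms, exactly the profile's total lipid content. Since
class totals are full-species masses while SLIME reactions deliver only
backbone-moiety mass, the chain totals are scaled by the backbone mass of
the carrying species:

    chain_total_j = Σ_i abundance_i · chain_mass_ij / backbone_mass_i .

With this scaling the flux assignment `s_i = abundance_i / backbone_mass_i`
per unit pool drain satisfies the class and chain constraints
simultaneously, so the two pools are mutually consistent at steady state.
The chain pool is drained by a free demand reaction rather than by the
biomass: it enforces the acyl-chain ratios without counting lipid mass
twice in the mass closure. Classes or chains with zero measured abundance
are omitted from the pool reactions; re-parameterizing by a new profile
touches only pool coefficients and requires the same class/chain sets, so
model topology is invariant.

Cofactor demand reactions (irreversible drains, flagged `demand`)
compensate the coenzyme pseudo-gap problem — cofactor byproducts with no
consumer would otherwise block their producing pathways; they are added
idempotently and excluded from lethality analysis by flag.

## Biomass

Each composition row declares its unit (`mmol/gDW`, `umol/gDW`, `g/gDW`,
`mg/gDW`) and molar mass; conversion to mmol/gDW happens once, at
assembly. Condition-specific components are scaled by
`control_absolute × rel_condition / rel_control`; rows whose control
relative abundance is zero are skipped with a warning rather than failing
the build. Cell wall and nucleic acids enter condition-unspecifically (no
condition-resolved measurements exist for them). Protein-bound and free
amino acids combine as `fraction × total_protein / molar_mass + free`.

Mass closure is rescaled to exactly 1 g/gDW. This is imposed (standard
practice) so that `v_bio` has units gDW gDW⁻¹ phase⁻¹ and accessions are
comparable; normalization is idempotent and scale-invariant, and with all
ratios equal to 1 the control coefficients are reproduced bit for bit.
Growth-associated ATP maintenance is not hard-wired into the biomass; it
can be supplied through the `invariant_components` argument.

## Simulation

LPs are solved with HiGHS (scipy.optimize.linprog); optimal solutions
satisfy ‖S·v‖∞ ≤ 1e-6 and all bounds, and infeasible/unbounded statuses
raise instead of returning zeros. pFBA fixes the objective with an exact
equality row (HiGHS returns vertex solutions, so the optimum is exactly
attainable; a 1e-9-relative slack inequality is the fallback) and
minimizes Σ|v| via the standard split `v = p − n`, `p, n ≥ 0`.

The RuBisCO constraint `v_carb = 2.88 · v_oxy` is a dimensionless coupling
pseudo-metabolite produced by carboxylation (+1) and consumed by
oxygenation (−2.88); steady state enforces the ratio exactly whenever
oxygenation carries flux.

Diel models duplicate every reaction and metabolite into `__light` and
`__dark` copies joined only by irreversible light→dark linkers for a
configured storage list (fixture default: starch, sucrose, free amino
acids). The dark-phase photon exchange is fixed to [0, 0]. Scenarios:
`control` opens the light-phase photon influx and maximizes the weighted
sum of the two phase biomass reactions (default 1:1; the day-length split
and phase-specific maintenance costs are configuration, not assertions);
`3DD`/`6DD` close photons in both phases and give each storage species a
bounded light-phase source representing pre-darkness accumulation, with
dark-phase biomass as the objective — nested budgets therefore give
monotone optima. A maltose-uptake cap is exposed in the scenario
configuration for sensitivity analysis.

Subsystem summaries: a reaction is active iff |v| > 1e-6; mean fluxes per
subsystem are computed on |v| after dropping physiologically meaningless
values (default cap 500 mmol gDW⁻¹ phase⁻¹, configurable — no published
cutoff exists) and are mean-centered across subsystems; a subsystem with
no surviving fluxes is reported missing, never as zero.

## Synthetic lethality

"Biomass abolished" is operationalized as optimum < cutoff_rel × wild type
with cutoff_rel = 1e-3 (pure zero tests are numerically fragile); support
means |v| > 1e-6. The scope excludes demand, exchange, maintenance and
SLIME reactions; the gene universe is the genes of the remaining GPRs.
Fast-SL pruning is exact: a knockout that closes no flux-carrying reaction
of a parsimonious reference solution leaves that solution optimal, so
single-deletion candidates are the genes supported in the wild-type pFBA
solution, and pair candidates combine a supported anchor with genes
supported in the anchor-knockout pFBA solution. Support is evaluated over
*all* GPR-bearing reactions (a universe gene may also close an
excluded-flag reaction). Enumeration is canonical (sorted gene ids).
Equality with exhaustive screening is asserted on 20 seeded random models.

Accuracy scoring builds the confusion matrix over evidence genes
classified single-lethal or non-lethal; genes in double-lethal pairs are
excluded (single-mutant phenotypes cannot validate a pair), and the
false-positive rate is reported as FP / scored genes.

## Concordance

Flux changes use |v| — LP fluxes are signed by an arbitrary reaction
orientation, and it is the activity level that transcript abundance
should track. log2 fold changes use a pseudocount (default 1e-6);
both-zero rows and |fold change| ≤ 1e-6 on either side are excluded.
Scoring is per reaction (one GPR may serve several reactions; the mapping
is reported). The dataset comparison is a Pearson chi-square test of
independence on the 2×2 concordant/outlier table, two-sided, df = 1, with
φ = √(χ²/N). No Yates continuity correction is applied by default: the
uncorrected statistic is the one consistent with the published worked
example (0.046 where Yates gives ≈0.011); the permutation
(margin-conditioned) null is instead matched by the corrected variant at
moderate N, as the tests document. Reconstructing that example's counts
assumes the two datasets contribute equally to N = 472 (236 each) — an
assumption inferred from numerical reproduction.

## fGWA

The association scan is fixed-effect OLS with the top three principal
components of the mean-imputed, column-centered dosage matrix as
population-structure covariates; the kinship linear mixed model of
standard GWAS engines is out of scope here, and externally computed
p-values can be injected so mixed-model results flow through the same
post-processing. Missing dosages are mean-imputed per SNP. Covariates are
projected out of trait and dosages (Frisch–Waugh–Lovell) and the dosage
coefficient tested two-sided with n − k − 2 degrees of freedom; constant
traits or SNPs yield p = 1 with a warning. Type-I calibration at the
nominal level is verified by simulation.

MAF filtering is strict (> 0.05). Significance is 1/n (n = number of
tested SNPs). Loci are formed by transitive merging of significant SNPs
at most 20 kb apart (a fixed-window alternative would be order-dependent);
the lead SNP is the locus minimum p, ties to the smaller position.
Candidate genes overlap ±10 kb around the lead SNP (total 20 kb, matching
the clumping interval). Classification precedence is exact GPR > GPR
upstream (genes of reactions able to produce a substrate of the trait
reaction, reversibility counted) > GPR downstream (consumers of a
product) > transcription factor (from the supplied list) > unknown.
Expression categories follow the published bounds on [0, 1]-normalized
levels: 0 → not expressed, (0, 0.3) → low, [0.3, 0.6] → intermediate,
(0.6, 1] → high. Mutant validation computes mutant/wild-type fold changes
over the lipids of the trait reaction (for TF candidates, over reactions
whose GPR genes are among the TF's binding targets) and flags support
when any |log2 FC| exceeds a configured threshold (default 1).

## Synthetic fixtures: what they emulate, and what they do not

The generators are pure functions of a root seed with per-generator
streams (fixed stream ids, so adding a generator never perturbs existing
fixtures). The template is a 26-reaction element-balanced photoautotroph
(photon/CO₂/O₂/H₂O/NH₃ exchanges, RuBisCO carboxylation/oxygenation,
photorespiratory salvage, sugar/starch/organic-acid/amino-acid chemistry,
maintenance respiration, biomass) plus seeded accessory branches; the
lipid module adds glycerolipid, galactolipid, storage-lipid and wax
synthesis/degradation in an ER-like compartment and shares three
reactions with the template through KEGG-annotated metabolites. The
accession panel (default n = 200, three conditions: control, 3DD, 6DD)
draws log-normal relative abundances around condition means chosen to
mimic extended darkness — sugars and starch depleted, free amino acids
elevated, membrane lipids (PC, MGDG) declining while TG accumulates.
Transcript tables plant an exact concordant-reaction quota (default rate
0.75); genotype panels have two diverged subpopulations, independent SNPs
on two chromosomes, 15-kb-tiled gene annotations, and one causal SNP
placed inside a lipid-gene interval whose dosage perturbs the CO₂ uptake
bound so the pFBA trait flux is linear in dosage with the configured
variance explained (default 0.25). Evidence tables flip truth labels at a
configured rate.

Problem sizes were chosen so the whole test suite runs in about a minute
and the acceptance script in about one minute on one CPU: 20 random
lethality models (≤40 genes, ≤60 reactions), 200 accessions, 5000 SNPs,
20 recovery seeds, 50 null scans.

What passing tests on these fixtures does *not* show: behavior on
genome-scale reconstructions (thousands of reactions, extensive GPR
redundancy), linkage disequilibrium and realistic population structure
beyond two subpopulations, measurement noise structure of real lipidomics
or transcriptomics, or the biology of any specific accession. The
fixtures certify the algorithms and their contracts, not biological
conclusions.

## Known limitations

- The LP stack is dense in the pFBA bound rows; fine for models up to a
  few thousand reactions, not tuned beyond that.
- Duplicate-reaction detection uses exact coefficient equality after sign
  normalization; numerically re-derived coefficients that differ in the
  last digit are treated as distinct reactions.
- Under the null, the 1/n significance threshold admits on the order of
  one false-positive SNP per scan by construction; the candidate lists of
  real scans should be read accordingly.
- The association scan is a fixed-effect approximation; confounding not
  captured by three PCs (e.g. cryptic relatedness) is the user's
  responsibility, or mixed-model p-values should be supplied.
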