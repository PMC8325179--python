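# Methods

## Scope and model

`limogem` implements a template-based reconstruction and comparison pipeline
for genome-scale metabolic models (GEMs) of lactic acid bacteria, of the kind
used to study *Limosilactobacillus reuteri* strain panels. A GEM here is a
stoichiometric network over two compartments (cytosol `c`, extracellular `e`)
with flux bounds in mmol/gDW/h, boolean gene–protein–reaction (GPR)
associations, and a biomass pseudo-reaction whose flux is the specific growth
rate (1/h). Flux balance analysis (FBA) maximizes a reaction flux subject to
steady state, S·v = 0, and the bounds; the LP is solved with SciPy's HiGHS
backend behind a single internal interface. Feasibility tolerance is 1e-9 and
numeric comparisons in tests use 1e-6.

## Orthology

Orthologs between a template genome and the target are called by reciprocal
(bidirectional) best hits over BLASTP-style tabular alignments, filtered
inclusively at E-value ≤ 1e-10, bit score ≥ 100 and percentage of positive
scoring matches ≥ 45. Standard 12-column BLAST tabular output omits the
positives column, so the package defines a 7-column dialect
(`qseqid sseqid pident ppos length evalue bitscore`, producible with
`-outfmt "6 qseqid sseqid pident ppos length evalue bitscore"`). Best hits
rank by bit score with ties broken by lower E-value, then lexicographically
smallest subject id — the ranking criterion beyond bit score is a
determinism choice, as is discarding self-hits (BBH compares distinct
genomes). Only the three stated filters are applied; no alignment-coverage
criterion is added.

## Reconstruction

The primary template contributes every non-exchange reaction whose GPR is
satisfied when exactly the ortholog-mapped template genes are present. GPR
leaves are rewritten to target gene ids; OR-branches with no mapped gene are
pruned, and a reaction whose whole GPR is unsatisfiable is excluded rather
than carried as an orphan (a flag restores orphan carry-over). Reactions with
no gene association — diffusion steps, maintenance, the biomass reaction —
count as satisfied and are carried: they have no gene evidence to lose.
Exchange reactions are never carried from templates; they are reintroduced by
the medium stage so boundary conditions always reflect the declared growth
condition.

Secondary templates are integrated one at a time in a fixed priority order.
Reactions are identified across templates by a direction-normalized
stoichiometric signature (sorted metabolite:coefficient pairs; a reversible
reaction and its reversed writing share a signature; GPR and id are excluded
from identity), assuming a shared BiGG-style metabolite namespace. A
signature already present is never overwritten, so earlier templates take
precedence and re-integration is a no-op. Conflicting metabolite definitions
(different formula or charge under one id) raise a reconciliation error
rather than being merged silently.

The medium stage gives every medium metabolite an exchange reaction with
lower bound −(max uptake rate), copies a transport reaction from the first
template that supplies a GPR-satisfiable one, or adds a plain diffusion
reaction for metabolites flagged diffusible; everything else extracellular
gets a secretion-only exchange. Medium concentrations (e.g. 111 mM glucose
in a chemically defined medium) are metadata only — FBA operates on rates,
and uptake bounds always come from measured or assumed rates (glucose
default 25 mmol/gDW/h).

Manual curation is expressed as declarative YAML patches (add/remove
reaction lists) applied after integration, so that curation decisions are
reproducible inputs rather than untracked edits.

### Biomass and DNA coefficients

The biomass reaction is adopted from the primary template. The DNA term is
recomputed from the target genome's GC content: mole fractions follow base
pairing (A = T = (1−gc)/2, G = C = gc/2) and each dNMP coefficient is

    c_i = 1000 · x_i · D / Σ_j x_j M_j   [mmol/gDW]

with D the DNA mass fraction (default 0.031 g per g dry weight) and M_j the
molar masses of the free-acid deoxyribonucleoside monophosphates, fixed in
one constants table (dAMP 331.22, dCMP 307.20, dGMP 347.22, dTMP 322.21
g/mol). The mass-weighted coefficient sum recovers D to better than 1e-12
for any GC. Protein and lipid fractions are exposed as multiplicative
overrides; no default recalculation is claimed.

## Gap-filling

Gap-filling finds an irreducible subset of a universal reaction pool whose
addition lifts the biomass objective to a growth floor (default 1e-6,
configurable; the floor is this package's choice). Pool reactions keep only
their directionality; bound magnitudes are opened to ±1000. The default
algorithm is LP rounding — minimize total absolute flux through pool
reactions subject to growth ≥ floor, take the support, prune to
irreducibility in lexicographic order — deliberately avoiding a MILP so the
solver dependency stays pure LP. For pools of ≤ 15 candidates an exhaustive
mode enumerates subsets by (cardinality, lexicographic order) and is provably
minimum-cardinality; it is the default at that size. Both modes are
deterministic. An unfillable instance raises an error naming the biomass
precursors that cannot be produced even with the full pool.

## Simulation protocols

* **Growth**: biomass FBA under a medium; a run is "growth" only if the LP is
  optimal and the rate is ≥ 1e-10 1/h — infeasible or smaller counts as no
  growth.
* **EMP capping**: upper bounds of phosphofructokinase (PFK) and
  fructose-1,6-bisphosphate aldolase are capped to throttle the
  Embden–Meyerhof–Parnas branch, forcing carbon through the phosphoketolase
  route; growth is monotone non-decreasing in the cap. The cap value is a
  free parameter.
* **Nutrient omission**: each amino acid's uptake is closed independently
  (exchange lower bound 0) and growth re-evaluated; the input model is left
  bit-identical.
* **Product capability**: the product's secretion flux is maximized; any
  rate above 1e-9 counts as synthesis capability. No minimum growth is
  imposed (the criterion is secretion > 0 alone); a flag can require a
  simultaneous growth floor. Only the objective value is contractually
  stable — individual fluxes of degenerate optima are reported but never
  asserted.

## Pan/core comparison

Across a strain panel grouped by host, the core model is the intersection of
reaction keys (first model's representative retained, bounds intersected)
and the pan model the union (first-seen representative). Elements — genes,
reactions or metabolites — are classified over the union of per-group pan
sets: `common` (in all groups), `specific` (in exactly one), `dispensable`
(in more than one but not all); percentages are relative to the union size.
Reaction identity defaults to the stoichiometric signature; an `id` mode
exists for panels built in one pipeline with a shared namespace, where it
reproduces id-level counts. Reported spreads are sample standard deviations
(n−1); a single-member group reports SD 0 by convention. Exchange reactions
are included in counts unless `internal_only` is set.

## Synthetic data: what it emulates, what it does not

The generator produces the study conditions end to end:

* **Template network** (~105 reactions): glucose uptake, both glycolytic
  branches (EMP through PFK/aldolase; PK through a lumped oxidative branch
  and phosphoketolase), lumped lower glycolysis, a water-forming NADH
  oxidase and a free ATP maintenance sink, 20 amino-acid uptake and
  (optionally absent) synthesis routes, dNMP synthesis, a GC-derived biomass
  reaction, and 1–3-reaction product modules: lactate, acetate, ethanol,
  histidine→histamine decarboxylation (hdcA/hdcB AND-GPR),
  glycerol→3-HPA→1,3-propanediol (a three-gene AND for the B12-dependent
  dehydratase), folate, cobalamin and 1-propanol stubs. ATP stoichiometry is
  fixed at 2 ATP/glucose via EMP and 1 via PK, so capping EMP halves growth
  but leaves it positive — the qualitative pattern of a phosphoketolase-
  dominant heterofermenter. Every generated model is validated and must grow
  on its reference medium (glucose 25, amino acids 5 mmol/gDW/h each).
* **Hit tables**: retained genes (default retention 0.6) get reciprocal
  above-threshold hits with scores drawn from documented uniform ranges;
  noise hits (default 50) each violate at least one threshold, so the
  planted ortholog map is recoverable exactly.
* **Strain panels**: default group layout 16 herbivore / 15 omnivore / 4
  sourdough. Carbohydrate modules have presence probability 1 in all groups;
  histamine 0.9/0.45/0.0 and the 1,3-propanediol route 0.9/0.8/0.0 across
  the three groups (sourdough forced to zero); the 1-propanol route is
  absent everywhere, mirroring the loss of methylglyoxal synthase in this
  clade. Amino-acid synthesis routes drop out with probability 0.25 per
  strain (lactobacilli are multiply auxotrophic). Acetate/ethanol modules
  are forced off without PK, and PK is forced on if both branches sample
  off, keeping planted capability flags consistent with the emitted network
  by construction.

The fixtures exercise pipeline logic — GPR evaluation, set algebra, LP
screens — not biochemistry: stoichiometry is abstracted (no protons,
phosphate or water bookkeeping; formulas mostly absent, so mass-balance
checks on synthetic models exercise the coverage path), gene content is
noiseless apart from planted dropout, and alignment scores are not derived
from sequences. Passing tests therefore demonstrate correctness of the
pipeline's algorithms under known ground truth, not predictive accuracy on
real genomes.

## Problem sizes and numerical choices

The acceptance run uses 100 random networks of ≤ 8 reactions for the
LP-versus-vertex-enumeration check (enumeration is exponential, 3^n basic
point candidates), 50 random gap-fill instances with pools ≤ 12, a
120-gene hit-table recovery, the full 35-strain panel for the omission and
capability screens, and 100 random panels for the set-algebra checks. These
sizes keep exhaustive oracles exact. Ties everywhere break
lexicographically; all randomness flows through explicit NumPy generators
seeded from a single seed.

## Known limitations

* The SBML writer targets Level 3 Version 1 + FBC v2 only; groups/layout
  packages and compartments beyond `{c, e}` are rejected by design.
* Cross-template metabolite reconciliation assumes a shared id namespace
  with an explicit synonym/patch mechanism; no automatic compound matching.
* The LP-rounding gap-fill heuristic guarantees irreducibility, not global
  minimality, beyond the exhaustive-mode pool size.
* Quantitative growth-rate reproduction for real strains requires measured
  uptake rates that are not part of this package's inputs; simulations on
  real models are qualitative (growth/no-growth, capability) unless rates
  are supplied.
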