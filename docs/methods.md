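# Methods

`fluxrestore` analyses a three-arm study design — control (`WT_VEH`),
disease (`AD_VEH`) and treated disease (`AD_NFP`) — and asks which parts
of metabolism are altered by disease and normalised again by treatment.
The chain is: differential proteome statistics → per-sample
context-specific metabolic model extraction → least-absolute-deviation
(LAD) flux estimation → per-metabolite flux-sum profiling → a two-test
restoration classification. This note documents the models, the
parameters that matter, and the choices made where the design was open.

## Proteome statistics

Protein abundances (proteins × samples, strictly positive intensities)
are analysed per protein with a one-way fixed-effects ANOVA over the
three groups, with Benjamini–Hochberg step-up q-values over all tested
proteins; a protein is differential at q < α (default α = 0.05).
Heatmap normalisation is the row-wise Z-score with *population* SD
(divide by n). Population SD matches the common heatmap convention;
constant rows are mapped to zero and flagged rather than dropped.

Differential proteins are clustered by agglomerative hierarchical
clustering (Euclidean distance, average linkage) on the Z-scored rows,
cut at k = 4. Raw cluster indices are arbitrary, so clusters are
relabelled to fixed response semantics by their centroid contrasts in
(AD−WT, NFP−WT) space: cluster 1 = disease-elevated/treatment-restored,
cluster 4 = disease-depressed/treatment-restored, clusters 2/3 =
disease-insensitive but treatment-shifted (up/down). The mapping
maximises the size-weighted cosine agreement between cluster contrast
vectors and the four archetype directions (a linear assignment problem);
weighting by size prevents an outlier singleton from claiming a label
that describes a large cluster.

Treatment-regulated proteins are the ANOVA-significant proteins whose
disease-vs-treated contrast is significant under the Tukey HSD procedure
(Tukey–Kramer studentized-range correction for unequal group sizes,
strict inequality at α), split by the sign of the treatment effect. The
ANOVA-then-Tukey chain is one defensible reading of a post-hoc
selection; the prefilter is an explicit argument so Tukey-only selection
is also available.

## Expression-driven model extraction

Reactions of the generic network are scored from one sample's protein
abundances through the gene–protein–reaction rules: AND (complex) takes
the minimum of its operands, OR (isozymes) the sum. The mapped reaction
expression e_j becomes an evidence weight

    w_j = clip( ln(e_j / τ), −w_max, +w_max ),

with τ defaulting to the sample's median reaction-level expression
(so roughly half the scored reactions carry positive evidence), w_max =
5, GPR-less reactions w = −0.1 (weak prior toward removal), exchanges
and biomass w = 0 (never evidence, always retained).

The context model solves a tINIT-style selection MILP: binary y_j per
internal reaction, split fluxes v⁺, v⁻ ≥ 0, and

    maximise Σ w_j y_j
    s.t.  S(v⁺ − v⁻) = 0
          v⁺_j ≤ M⁺_j y_j,  v⁻_j ≤ M⁻_j y_j     (internal j)
          v⁺_j + v⁻_j ≥ δ y_j                    (activation, δ = 1e-3)
          v_biomass ≥ v_min                      (growth task, 1e-3)

so every included reaction carries at least δ of flux in one common
steady-state distribution that grows. The big-M coefficients M± are the
FVA-computed attainable forward/reverse fluxes of each reaction on the
full medium-bounded network, not the raw bounds: MILP solvers accept
binaries within an integrality tolerance (~1e-6), and with bound-sized
big-M (10³) this lets ~1e-3 of flux leak through an "excluded" reaction
— enough to fake growth. Capacity-sized big-M (≈10–40 in the toy
network) makes the leak numerically irrelevant. Above 1,000 binaries the
exact mode falls back (with a warning) to a greedy prune: drop
negative-evidence reactions one at a time, most negative first, whenever
growth survives, then iteratively remove reactions left without flux
capacity.

The growth task is part of the selection program, so extracted models
grow by construction; `gapfill_growth` is nevertheless part of the
pipeline as a verified repair step. It adds a minimum-cardinality set of
parent-network reactions (exact MILP over the candidate set) whenever a
context model cannot reach v_min, and is idempotent.

Model quality is summarised MEMOTE-style: stoichiometric consistency
(largest metabolite subset admitting strictly positive conserved masses
m with S_intᵀ m = 0, found by the LP relaxation max Σ k, k ≤ m, 0 ≤ k ≤
1), mass and charge balance per reaction from formula/charge annotation,
and metabolite connectivity. Exchange and biomass pseudo-reactions are
exempt from balance and consistency checks — they are net drains by
design. Note that elemental imbalance does not imply stoichiometric
inconsistency: an abstract positive mass vector can exist even when the
declared formulas do not balance, and the two metrics are reported
independently.

## LAD flux fitting and flux-sums

Per context model, flux targets are derived for GPR-bearing internal
reactions by scaling mapped expression linearly so the most-expressed
reaction targets its upper bound: d_j = ub_j · e_j / max_k e_k. The flux
state solves the LP

    minimise Σ_j |v_j − d_j|   (split deviation variables)
    s.t. S v = 0, bounds, medium, v_biomass ≥ v_min,

and deviations are measured on the net (signed) flux — a negative net
flux against a positive target counts its full deviation. The target
normalisation is an artifact choice (the literature does not fix one);
it only needs to be monotone in expression and common to all samples,
because group comparisons use replicate distributions rather than single
flux vectors, which also absorbs degenerate alternate LP optima.

The flux-sum of metabolite i is its total production rate

    Φ_i = Σ_j max(S_ij v_j, 0),

equal at steady state to total consumption and to half the total
absolute turnover ½ Σ_j |S_ij v_j| — the identity is asserted to 1e-9 in
tests. Solver tolerances: steady-state residual accepted to 1e-6,
HiGHS defaults (≈1e-9 feasibility) underneath.

## Restoration classification

For each reaction (flux) and each compartment-qualified metabolite
(flux-sum), replicate values across the per-sample models are compared
with two two-sided Wilcoxon rank-sum tests: disease vs control, treated
vs disease. Group tendency uses medians (robust at n = 3). An entity
with median(disease) > median(control) and median(treated) <
median(disease) is labelled `decreased_flux_sum` ("the treatment
decreased it again"), promoted to `significantly_decreased_flux_sum`
when both tests reject at α = 0.05; the mirrored rule yields the
`increased` labels. No multiplicity correction is applied across
entities — the rule is per-entity by design (a BH option exists but is
off by default). Entities absent from a sample's model contribute value
0 and are flagged: absence means no capacity.

The rank-sum test is exact — full enumeration of the U null
distribution by dynamic programming — when min(n₁, n₂) ≤ 10 and there
are no ties (covering the study's (3,9) and (9,6) contrasts), and a
normal approximation with midrank tie correction and continuity
correction otherwise.

Caveat: the two tests share the disease-group replicates, so their
rejections are positively correlated and the null rate of significant
labels is slightly above the naive α² (measured ≈0.4% vs 0.25% nominal
at n = 3/9/6). The Monte-Carlo acceptance band (α² + 2·SE over 100
seeds) accommodates this.

Low-dimensional views use UMAP (fixed random state): samples × protein
abundances with `n_neighbors = 5`, or samples × binary reaction-presence
vectors of the context models with `n_neighbors = 11`. Embeddings are an
external dependency and are smoke-tested only.

## Synthetic study generator

The generator provides the study conditions end to end without external
data.

**Toy network** (default 40 reactions, 45 metabolites, compartments
e/c/m): a fatty-acid branch — uptake, cytosolic acyl-CoA activation,
carnitine shuttle (CPT1 / carnitine–acylcarnitine antiport / CPT2), and
a 3-round mitochondrial beta-oxidation cascade of a C8 chain down to
acetyl-CoA — next to a glucose branch (lumped glycolysis + pyruvate
dehydrogenase) that keeps biomass feasible when the fatty-acid branch is
absent, plus lumped NAD/FAD respiration and transport/exchange
reactions. Activation and shuttle steps carry OR rules of ≥2 synthetic
isozymes; each beta-oxidation step carries an AND rule of ≥2 synthetic
subunits with a shared trifunctional-protein subunit across steps,
mirroring the published rule structure (the real mouse gene lists are
kept separately as reference annotation in `pathway_annotations`).
Every internal reaction is elementally and charge balanced by
construction (asserted at build time); biomass (acetyl-CoA + N + P
drain) and exchanges are pseudo-reactions. Default bounds: uptakes 10,
internal 1000 flux units (arbitrary mmol/gDW/h scale).

**Proteome**: group sizes default to (3, 9, 6). Protein abundance is
log-normal around a per-protein group mean: baseline log2 intensity ~
N(20, 1) for unaffected proteins, replicate noise with CV 0.2 (log2 SD
≈ 0.29), a standard dispersion for LC-MS intensity data. Planted
structure: all fatty-acid-branch genes form cluster 1, with baseline
2 log2 below the housekeeping level and a +3 log2 disease elevation
(restored under treatment). The offset/effect pair places the branch
below the sample's median reaction expression in control/treated samples
and above it in disease samples — the planted premise that disease
up-regulates the pathway strongly enough for evidence-based extraction
to include it. Cluster 4 mirrors the pattern downward (−3 log2, 12
proteins); clusters 2/3 are disease-insensitive with ±1.5 log2
treatment-only shifts (12 proteins each, the "possible side-effect"
pattern); 60 background proteins and the housekeeping network genes have
no group effect. The planted restored metabolites are the cytosolic and
mitochondrial acylcarnitines, whose turnover is nonzero only when the
branch is active. Setting an effect to zero removes that cluster from
the planted truth (null generator).

What the generator does *not* emulate: missing values and
limit-of-detection censoring, peptide-level variance structure,
protein–protein abundance correlation beyond the planted clusters, and
a realistic genome-scale network (tens of reactions, not thousands).
Passing tests therefore demonstrate correctness and statistical power of
the machinery under clean planted conditions, not performance on real
LC-MS data or on genome-scale models.

## Problem sizes and determinism

Default analyses build 18 per-sample models (3+9+6); Monte-Carlo
properties use 20 independent studies (plant-and-recover, model-size
restoration) and 100 × 50 null draws (classification error rate) —
sizes chosen so exhaustive oracles and repeated pipeline runs stay
convenient on a laptop-class machine. All randomness flows through
`numpy.random.default_rng` seeds; identical (config, seed) reproduce
identical fixtures, models and tables. Ties in Tukey or Wilcoxon at
exactly α are non-significant (strict inequality).

## Known limitations

- One context model per sample; the alternative (one pooled model per
  group) is not implemented, though group-level models can be emulated
  by averaging expression before scoring.
- The metabolic task list is biomass production only; full
  curated task catalogues are out of scope.
- LAD targets derive from the same expression used for extraction;
  no cross-validation between the two stages.
- The exact extraction MILP is intended for networks up to ~1,000
  internal reactions; beyond that the greedy mode trades optimality
  guarantees for speed.
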