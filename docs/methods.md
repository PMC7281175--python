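# Methods

## Study design and data model

The package targets a matched three-group design: normal liver of
wild-type animals (W), precancerous liver of oncogene-bearing animals (P),
and tumor tissue (T), with n = 8 biological samples per group for
metabolite tables and n = 5 for gene tables. Inputs are analyte × sample
matrices (GC-MS peak intensities or FPKM) with a sample→group design, and
long-format isotopologue area tables (metabolite, mass shift, sample,
area). Group labels are arbitrary strings; W/P/T is only the default trio.
One column is one biological sample; technical-replicate averaging, if
any, is assumed to have happened upstream.

Missing cells stay missing until the explicit imputation step
(half-minimum per analyte, the standard treatment for left-censored GC-MS
missingness), because silent zero-filling biases fold changes.

## Peak screening

`iqr_denoise` drops analytes whose across-sample interquartile range is
exactly zero (no information) and, optionally, those below a chosen
quantile of the remaining IQR distribution. Quartiles are type-7
(linear interpolation), the numpy default and the most common convention;
the absolute threshold actually applied is recorded in the
`DenoiseReport`, which also makes the screen reproducible and idempotent
(re-running at `threshold_used` drops nothing). The quantile cut defaults
to 0 — how aggressively a given study screened is data-specific, and the
default refuses to discard nonconstant signal silently. Whether the IQR
rule should be global or per-group is genuinely open; this implementation
is global across samples and says so in the report rather than guessing.

## Differential calling and fold conventions

Pairwise comparisons use the two-sample t-test (pooled-variance Student by
default, Welch optionally) on linear intensities, matching the mean-ratio
presentation of GC-MS summary tables; a log-scale option exists but is off
by default. Fold change is `mean(first-named)/mean(second-named)` — the
orientation validated against the bundled metabolite summaries (e.g.
glucose-1-phosphate W vs P: 0.109/0.148 → 0.74). Published gene tables are
not always internally consistent in orientation; the package standardizes
on the metabolite convention throughout.

Differential metabolites are called at p < α (α = 0.05, strict
inequality); differential genes additionally need fold ≥ 1.5 or ≤ 0.67.
No multiple-testing correction is applied by default, mirroring the
per-comparison criterion these studies report; Benjamini–Hochberg is
available (`bh_correct=True`). VIP-based filtering is likewise available
but is not part of the differential criterion.

## Trajectory-pattern classification

Each analyte's triple of relations (T vs P, T vs W, P vs W) — where `=`
means *not significant at α*, never numerical equality — is classified by
exact lookup into the ten named (category, subtype) pairs listed in the
README, else unclassified. Exact matching is the only deterministic
reading of strict chains under noise: a chain subtype such as `T>W>P`
requires the implied outer inequality (T > P) to be significant as well.
Profiles whose adjacent links are significant while the outer one is not
(six of the 27 triples) are transitively inconsistent; they are left
unclassified and flagged `consistent=False`. All analytes are classified
regardless of differential status; reports can intersect with DEM lists
downstream.

## Multivariate QC

PCA is computed by SVD of the scaled sample × analyte matrix
(autoscaling default — unit variance is the GC-MS convention because
analyte intensities span orders of magnitude), with component signs fixed
so each loading vector's largest entry is positive. PLS-DA is NIPALS PLS1
against a centered ±1 response; VIP scores use the y-variance-weighted
squared weights (mean VIP² = 1 by construction). Q² = 1 − PRESS/TSS from
stratified k-fold cross-validation (7-fold default, the SIMCA convention),
re-estimating scaling inside each fold. The permutation test refits Q²
under label permutations and reports p = (1 + #{Q²_perm ≥ Q²_obs}) /
(1 + n_perm); with n_perm chosen so that α is an attainable p-value
quantile (e.g. 39 permutations for α = 0.05) the null rejection rate of
`p ≤ α` is exactly α in expectation. An optional single-component
orthogonal signal correction approximates OPLS-DA's predictive/orthogonal
split; for two-class models the predictive interpretation is equivalent,
and the open-math implementation is auditable where proprietary software
is not.

## Pathway over-representation

ORA by the hypergeometric upper tail P(X ≥ k) with BH correction across
pathways, against a built-in six-pathway central-carbon/detox map
(glycolysis; TCA + citrate-malate shuttle; pentose phosphate; lipid
biosynthesis; cholesterol/bile acid; glutathione) whose members follow the
bundled study's annotations, or against any GMT file. This is an open
stand-in for web-service enrichment (MSEA/DAVID), whose versioned
databases cannot be reproduced exactly; absolute pathway counts from such
services are therefore out of scope. The universe defaults to all analytes
surviving screening.

## Isotope tracing

**Measurement.** Labeled fractions are `area(M+k)/Σ_j area(M+j)` per
sample, averaged per group; samples with zero total area are flagged, not
imputed. Natural-abundance correction solves the lower-triangular binomial
system M[i,j] = C(n−j, i−j)·p¹³C^(i−j)·(1−p¹³C)^(n−i), clips negatives and
renormalizes. It is **off by default** to match raw [labeled]/[total]
reporting; p¹³C defaults to 0.0107.

**Network.** 26 metabolites, 0-based carbon indices with carbon 1 = bit 0.
Atom maps follow standard biochemistry: aldolase sends fructose-1,6-bisP
C1–C3 to DHAP (reversed) and C4–C6 to GAP, so glucose C1/C6 both end at
pyruvate C3; PDH releases pyruvate C1 as CO₂; citrate synthase builds
citrate as OAA C1–C4 + acetyl C1–C2; the two TCA CO₂ losses come from the
OAA-derived carboxyls; succinate and fumarate get explicit 50/50
orientation scrambling (two half-flux reactions with reversed maps);
aconitase is treated as prochiral (no scrambling); oxidative PPP releases
G6P C1 and passes C2–C6 to Ru5P; transketolase moves 2-carbon units and
transaldolase 3-carbon units with the standard maps. The shuttle is
citrate export → ATP-citrate lyase cleavage → cytosolic malate →
re-import. Pyruvate carboxylase is included with default flux 0 (its fixed
CO₂ enters unlabeled). Reversible steps are marked but label propagates
along net fluxes only; the symmetry scrambling that reversibility matters
for is modeled explicitly.

**Fluxes.** Glucose uptake is normalized to 1 and branch fractions set the
split at each node: `f_ppp` at G6P (all pentose flux returns through the
non-oxidative branch, 2 X5P + 1 R5P → 2 F6P + 1 GAP), `f_lactate`/`f_pdh`
(+ optional `f_pc`) at pyruvate with the remainder leaving the network,
`f_shuttle` at citrate. Per-metabolite dilution mixes in an unlabeled
influx fraction (anaplerosis, exchange with unmodeled pools).

**Solver.** Positional isotopomer distributions (vectors over ≤ 2⁷
states — the isotopomer representation is desk-scale here and more
auditable than an EMU decomposition) are iterated Gauss–Seidel in network
order: each metabolite becomes the flux-weighted mixture of its producing
reactions' atom-mapped substrate distributions, then diluted. Convergence
is the maximum absolute sweep change < 1e-10 (default), typically a few
dozen sweeps; non-convergence raises with the residual unless a partial
(e.g. single first-turn pass, `max_iter=1, allow_partial=True`) solution
is requested. Steady state, not kinetics: single-time-point enrichment
constrains flux *ratios*, not rates. No inverse (flux-fitting) problem is
attempted — forward simulation and grid comparison only.

**Monte-Carlo cross-check.** An independent stochastic implementation
tracks pools of bitmask molecules through the same network: flux-weighted
reaction choice per molecule, uniform substrate draws, bitwise atom maps,
Bernoulli dilution. After 50 burn-in sweeps, isotopologue counts are
averaged over 25 further sweeps — pool resampling makes a single snapshot
noisier than a binomial draw, and sweep-averaging brings the estimator
within ~3/√n per fraction of the deterministic solver, the agreement bound
used in tests at n = 10⁵ molecules.

## Synthetic data

The peak-table generator plants one of the ten subtypes (or a null) per
analyte: group means walk the subtype's inequalities in steps of the
effect size (groups joined by `=` share a mean) and observations are mean
× exp(N(0, σ)) with σ = √log(1+cv²) — multiplicative log-normal noise,
the natural family for positive right-skewed GC-MS intensities. Defaults:
effect 2.0, cv 0.25, n = 8/group, W/P/T. A 50-replicate calibration at
these conditions (200 analytes, α = 0.05) gave category recovery
0.987 ± 0.01 (min 0.967) and a pooled null false-call rate of 0.024,
against which the test thresholds (≥ 0.90 recovery;
false calls ≤ 1−(1−α)² since a named pattern needs two significant
relations) were pinned.

The isotopologue generator simulates per-group networks and writes areas
as `total_pool × fraction × log-normal noise`. Its default
(`TRACER_BASE_CONFIG`) represents a steady-state tracer delivery with 50%
glucose enrichment, modest dilution at pyruvate/OAA/acetyl-CoA, and the
group contrast `f_shuttle` = 0.1 (W, P) vs 0.6 (T). The enrichment level
matters scientifically: at low (bolus-like, ~30%) enrichment with a
labeled OAA pool, raising the shuttle *spreads* citrate label to M3+ and
the M2 readout inverts; at 50% enrichment the acetyl-driven M2 dominates
and the shuttle elevates citrate M2, the readout the tumor-tissue data
show. The default encodes the second regime.

What the generator does **not** emulate: retention-time structure,
co-eluting peaks, batch effects, heteroscedastic detector noise,
isotopologue-correlated noise, or real biological covariance between
analytes. Passing tests demonstrate correctness of the statistical
machinery under the stated noise model, not performance on raw
instrument data.

## Problem sizes and numerical choices

Test and acceptance runs use 200-analyte tables with n = 8/group,
10-replicate recovery estimates, 400 null datasets for the permutation
type-I check (12 samples × 15 analytes, 39 permutations each), and 10⁵
molecules for Monte-Carlo/solver agreement on randomized network
configurations — sizes chosen as the smallest at which the quantities are
statistically stable. Ties and degenerate inputs: zero-variance analytes
give NaN p-values and count as "not significant"; a zero denominator
leaves a fold change NaN and flagged; constant analytes are excluded from
autoscaled models with a warning; PLS components are truncated at the
design's rank.

## Known limitations

- No raw-spectra processing (deconvolution, RT alignment) and no NGS
  quantification; the pipeline starts at peak/FPKM tables.
- No ¹³C flux *fitting*; the tracer module is forward-only.
- The pattern taxonomy is specific to a three-group ordered design.
- Dataset-dependent counts from the motivating study (total peaks, DEM/DEG
  counts, web-service pathway counts) require the unpublished raw data and
  are not reproduced.
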