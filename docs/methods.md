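# Methods

This note documents the statistical procedures implemented in `gxqtl`,
the assumptions of the synthetic-data generator, and the design choices
made where several reasonable conventions exist. It states no empirical
result beyond what the test-suite and `scripts/acceptance.py` compute.

## Data model and conventions

Genotypes are additive hard calls (0/1/2) with 1-based variant positions
(VCF convention); feature coordinates are 0-based half-open (BED
convention), converted explicitly to 1-based basepairs in every distance
computation. Missing genotype calls are stored as missing and are
mean-imputed per variant **only** inside regression design matrices —
never in stored data — which preserves sample size as in standard QTL
mapping while keeping the raw matrix intact. Minor allele frequency is
always computed on non-missing hard calls. Sex and exposure status enter
models as 0/1 indicators; ancestry enters only through genotype principal
components, mirroring common QTL practice.

## Preprocessing

**RINT.** Feature values are transformed to
`Φ⁻¹((rank − c)/(n − 2c + 1))` with the Blom offset `c = 3/8` (the most
common convention) and average ranks for ties. The transform is undefined
for a constant vector and raises.

**Median-of-ratios.** Gene counts are normalized with the DESeq size
factor estimator: sample *j*'s factor is the median over
everywhere-expressed genes of `k_ij / geomean_i(k)`; normalized values are
`k_ij / s_j`.

**Filters.** A gene is removed iff ≥90% of samples have ≤10 counts *or*
≥90% have TPM ≤1 (all thresholds inclusive; TPM is accepted as input or
computed from gene lengths). Variants enter mapping when pooled MAF is
*strictly* above 0.05; the post hoc "robust" filter additionally requires,
within **each** ancestry stratum, MAF ≥ 0.05 and missingness ≤ 0.10 (both
inclusive). The wording difference (strict vs inclusive) is deliberate and
tested at the boundary. All filters can emit TSV audit tables.

## Mapping and the stratified 2-df test

Cis windows are ±500 kb, boundary-inclusive: for CpGs the distance is
|variant pos − CpG pos|; for genes it is the minimum distance from the
variant to the gene span (0 inside the body). Four OLS models per pair
(baseline, cases-only, controls-only, interaction) use Wald t statistics
with residual-df reference distributions. Stratum models drop covariates
constant within the stratum; a rank-deficient design (e.g. a variant
monomorphic among cases) flags the fit as failed, and its p-values stay
missing — the 2-df statistic is then also missing, with no 1-df fallback.

The stratified 2-df statistic sums squared per-stratum Wald ratios,
`T = z_case² + z_ctrl²`, referred to χ²(2) (`p = exp(−T/2)`). The strata
are disjoint samples, so no covariance term enters. The batch mapper
residualizes the feature values and all cis genotype columns on the
covariates once per feature (Frisch–Waugh–Lovell) and solves the
remaining 1- or 2-column systems in closed form; the test-suite verifies
exact agreement with per-pair OLS and with an independent statsmodels fit.

The interaction-model genotype main-effect p (reported as `p_main`) comes
from the interaction model rather than the baseline model, because main
and interaction p-values are reported side by side from one analysis;
this choice only affects reporting, not the 2-df test.

## Two-stage multiple-testing correction

Stage 1 multiplies each pair's nominal p by the feature's effective test
count `M_eff`: cis variants are ordered by position, partitioned into
consecutive windows of ≤200, and each window contributes the smallest
number of leading eigenvalues of its genotype correlation matrix reaching
99% of the total variance. Stage 2 multiplies by the number of features
tested (features with zero cis variants excluded). The final adjusted p is
`min(p_stage2, p·T_total, 1)` with `T_total` the total pair count, so the
two-stage route is never more stringent than family-wise Bonferroni. The
window size (200) and variance threshold (0.99) are the conventional
defaults of eigenvalue-based effective-test estimators; both are
configurable. Interaction significance across the `N` significant features
uses the Bonferroni threshold `0.05/N`, reported at two significant
figures.

## Enrichment testing

Target variants are LD-pruned greedily in position order (a variant is
kept iff r² < threshold against every kept variant within 500 kb). The
matched background contains exactly 10 pool variants per target with MAF
within ±0.05 and, when further annotation properties are supplied,
matching quintile bins — sampled without replacement across the whole
background, preferring exact property duplicates. Each variant's QTL
evidence is collapsed to its minimum stratified-2-df p, and target vs
background distributions are compared with a two-sided KS test. This
replaces server-side annotation-matched sampling services with a
reproducible offline equivalent that preserves the design (a background
ten times the target set, matched on allele frequency).

## Colocalization

Per-variant log approximate Bayes factors use Wakefield's asymptotic
form: `lABF = ½(log(1−r) + r·z²)` with `r = W/(se² + W)`; the prior
effect variance is `W = 0.15²` for quantitative traits and `0.2²` for
case-control (configurable; GWAS traits default to quantitative).
Pairwise posteriors over H0–H4 use per-variant priors `p1 = p2 = 1e-4`,
`p12 = 1e-5` (the standard defaults of single-causal-variant
colocalization), computed entirely in log space.

The three-trait extension enumerates every sharing configuration — each
trait null or causal at one variant, causal traits grouped by shared
variant — with per-variant configuration priors `p_single = 1e-4`,
`p_pair = 1e-5`, `p_triple = 1e-6`. All configuration sums reduce to
closed-form combinations of `S_t`, `S_tu`, `S_tuv` (sums of exponentiated
lABFs and their products), verified against an O(Q³) brute-force
enumeration to 1e-8. Only the single-cluster three-trait posterior is
implemented (one GWAS trait + one gene + one CpG per test); divisive
clustering over many traits is out of scope. Decision rules: a locus is
called colocalized iff PP.H4 > 0.8 (strict) *and* the feature's two-stage
adjusted baseline p < 0.05; triplets require full-sharing posterior > 0.8.

## Preranked GSEA

Genes are scored by the largest −log₁₀ interaction p over their assigned
CpGs (ties broken by gene id for determinism) and ranked descending. The
enrichment score is the signed maximal deviation of the weighted KS-like
running sum (weight exponent `w = 1`, the weighted default; `w = 0`
recovers the classic KS statistic). Set sizes are restricted to 15–500
after intersection with the ranked universe. Null distributions come from
random same-size gene sets (the preranked tool's permutation scheme, not
phenotype permutation), `p_perm = (1 + #{same-sign |null ES| ≥ |ES|}) /
(n_perm + 1)`, NES divides by the mean |null ES| of matching sign, and
FDR q follows the sign-stratified null-vs-observed NES ratio procedure.
The FDR < 0.10 threshold is a reporting flag, not a filter. One stated
invariant of running-sum scores — insensitivity to appending zero-score
non-members — holds only when the extreme deviation precedes all misses
(the miss step renormalizes with the list length); the test-suite checks
the construction where it holds exactly.

## Synthetic cohorts

The generator emulates the structure of a postmortem brain cohort, not
its biology:

- **Cohort composition** (defaults): 223 donors, case fraction 52/223
  ≈ 0.23 with case status thresholded at a simulated cotinine biomarker
  of 12 ng/mL (smokers' cotinine log-normal around 200, nonsmokers around
  1, so misclassification is rare); two ancestry strata at 104/119.
  Exposure is assigned independently of genotype by default so
  interaction-test calibration is interpretable; a config switch adds
  gene–exposure correlation for robustness checks.
- **Genotypes**: biallelic variants spaced ~10 kb, LD generated by a
  Gaussian copula — within a block of (default) 10 variants, latent
  gametes are exchangeable-correlated normals (r = 0.8) thresholded at
  ancestry-specific MAF quantiles drawn uniformly from [0.05, 0.5] per
  ancestry. This gives tunable, reproducible LD; it does not reproduce
  real recombination maps.
- **Phenotypes**: methylation latent values
  `b0 + β_g·g + β_gx·g·s + covariates + N(0, σ)` mapped through the
  inverse logit (β-values in [0,1] by construction); counts are negative
  binomial (dispersion 0.1) with the same terms in the log mean plus
  log-normal library sizes. Causal features lie within 500 kb of their
  variant; the truth table records every planted (variant, feature, β_g,
  β_gx), sufficient to compute power and type-I error of every downstream
  test. Default effect sizes (β_g = β_gx = 0.5 latent units, 30% of
  features causal, 10% with interaction) are chosen for test power — no
  empirical effect-size distribution is claimed.
- **GWAS summary statistics**: a separate cohort (default 10,000; 4,000
  in the large pipeline run to bound memory) is drawn from the same LD
  model; the trait is driven by the scenario's causal variant (shared
  with the QTL truth table, distinct within the region, or null) and each
  panel variant is regressed on it, so association decays with LD as in
  real summary statistics.

What passing tests on these cohorts do **not** show: robustness to array
probe artifacts, bisulfite conversion error, read-level count noise,
fine-scale LD, population stratification beyond two strata, or latent
confounding — the simulator represents technical covariates as known
columns, whereas real pipelines estimate them.

## Numerical choices and problem sizes

All colocalization sums use log-sum-exp; `log(exp a − exp b)` is clipped
at −∞ when the difference underflows (the corresponding hypothesis then
receives zero mass). OLS uses QR with a rank tolerance of 1e-10 on the
diagonal of R; p-values are floored at the smallest positive float. The
simulated calibration suites use 20,000 replicates for the 2-df null
(strata of 500 and 1,500, large enough for the asymptotic chi-square
reference of the Wald ratios), 4,000 for power, 200 replicates for the
distinct-causal colocalization sweep, and 1,000 draws × 99 permutations
for GSEA calibration; the end-to-end pipeline runs at 2,000 samples ×
5,000 variants × 500 features (about half a minute on one CPU). These
sizes give binomial confidence intervals tight enough for the stated
acceptance bands while keeping the whole suite fast.

## Known limitations

- Hard-call genotypes only (no dosage regression, no bgen/plink binary
  formats, no liftover); mixed models/kinship are not implemented — the
  design follows fixed-effect OLS with genotype PCs.
- The r×c Fisher test enumerates completely and refuses tables beyond a
  configurable size, offering a seeded Monte Carlo mode instead.
- The exposure is binary; continuous exposures would need a different
  stratification or an interaction-only test.
- Latent expression covariates are accepted as inputs (simulated as known
  columns); no latent-factor estimation is performed.
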