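# Methods

## The statistic and its assumptions

`zipburden` tests gene–trait association on collapsed rare-variant
counts. For each gene, every subject contributes one count T_i: the
number of the gene's SNPs at which they carry at least one copy of the
minor allele. Carrier *presence* (0/1 per SNP), not allele dosage, is
the default coding; a dosage coding is available behind
`collapse_gene(..., dosage_coding=True)` for sensitivity analysis.

The counts are modelled as zero-inflated Poisson: with probability p_i
the subject is a structural zero, otherwise T_i ~ Poisson(μ_i).
Both mixture parameters are linked to the same covariates through
canonical links — logit for p_i, log for μ_i — with columns intercept,
trait, age, sex, smoking, and the top-K genotype eigenvectors. The
association test is the Wald z of the trait coefficient β1 in the
log-mean component; we treat the mean component as the natural home of
an abundance effect and leave the zero-component trait coefficient γ1
estimated but untested by default. A joint 2-df likelihood-ratio test
(trait removed from both components) is available via
`ScanConfig(test="lrt")`.

Assumptions worth stating plainly:

- **Conditional ZIP sampling.** Real collapsed counts are sums of
  Bernoulli carrier indicators — binomial-like, hence slightly
  *underdispersed* relative to Poisson. For rare variants (per-SNP
  carrier probability q ≲ 0.1) the variance ratio
  1 − Σq²/Σq is ≈ 0.95–1 and the ZIP/Poisson machinery is calibrated.
  When common variants are collapsed the ratio drops well below 1 and
  the Wald test becomes **conservative** (observed null sd(z) ≈ 0.85,
  type-I ≈ 0.02 at nominal 0.05 in our simulations). This is a property
  of the method, not of the implementation; it is why the evaluation
  studies collapse with the rare ceiling below.
- **Independent subjects** (no kinship correction) and binary-or-linear
  trait effects entering through the linear predictors.
- **Biallelic SNPs** with supplied function labels; multi-allelic sites
  are rejected, not decomposed.

## Collapsing choices

- **Minor allele per analysis subset.** Allele frequencies can differ
  so much between ancestry groups that the minor allele flips identity;
  per-group scans therefore re-orient every SNP and recount within the
  group. Ties at frequency 0.5 break toward the counted (input) allele.
- **MAF ceiling.** Default **none**: the collapsing definition itself
  imposes no threshold, and `collapse_*` will happily sum every minor
  allele. The conventional rare-variant ceiling (`maf_ceiling=0.05`) is
  a first-class option and is the study condition used by the
  calibration/power evaluations, for the dispersion reason above.
- **Missing genotypes** are excluded from MAF denominators and treated
  as non-carriers when counting (a conservative choice that never
  fabricates carriers); per-gene missing-call totals are reported.
- **Empty genes** (no SNP passes the filter) are skipped, not scored 0,
  so the Bonferroni m reflects genes actually tested. Both the
  tested-m threshold and a fixed-m threshold (`ScanConfig.bonferroni_m`)
  are supported.

## Fitting: the fallback ladder

Joint ML by BFGS on the exact log-likelihood with analytic gradient,
warm-started from the Poisson GLM MLE for β and an excess-zero-fraction
logit for the γ intercept; gradient tolerance 1e-8, up to 5 jittered
restarts; covariance = inverse observed information (central-difference
Hessian of the analytic gradient, condition assessed on the
correlation-scaled matrix so covariate scale differences do not
masquerade as singularity).

Collapsed counts routinely sit at the *boundary* of the ZIP family —
with no real zero excess the MLE drives the structural-zero mass to
zero and the zero-component coefficients to ±∞ (quasi-separation), and
the information matrix is singular there. Rather than report such genes
as failures, `fit_zip` walks an explicit ladder, at each rung reporting
the rung's own MLE:

1. **full ZIP** (`fallback="none"`);
2. **intercept-only zero component** (`"intercept_zero"`) when the
   covariate-rich zero component separates;
3. **plain Poisson** (`"poisson"`) when the zero-inflation mass itself
   is at the boundary (including the no-zeros case where the mixture is
   unidentified) — the Wald test of β1 remains valid in this nested
   model;
4. **no test** (`"degenerate"`): all counts zero, or too few carriers
   to support the design. These genes appear as NA rows with a recorded
   skip reason and count as non-significant in power denominators.

The ladder guarantees the reported log-likelihood never falls below the
nested Poisson fit's (ZIP nests Poisson; a "ZIP" optimum below the
Poisson MLE would only mean the optimizer stopped short of the
boundary, so the Poisson MLE is returned instead).

## Population structure

One PCA on the standardized genotype matrix (centre 2f̂, scale
√(2f̂(1−f̂)), monomorphic SNPs dropped, missing calls mean-imputed)
serves both as the source of eigenvector covariates and as coordinates
for grouping. Eigenvectors carry a deterministic sign convention
(largest-magnitude entry positive). Outlier screening removes subjects
beyond 6 SD on the leading PCs with iterative re-decomposition (5
rounds) — on rare-variant panels the deeper PCs are "spiky" (each
dominated by carriers of one very rare allele), so screening is best
confined to the leading ancestry axes (`k=` argument). Grouping is
k-means on the top-2 PCs (fixed seed, 10 restarts, clusters relabelled
by mean PC1), or verbatim user labels. MDS on identity-by-state
distances is deliberately *not* implemented separately: eigenvector
scores track population membership to near-certainty at realistic
divergence, and one embedding serving both roles keeps grouping and
adjustment consistent.

`detect_outliers` takes the genotype matrix as an optional argument
because iterative pruning must re-decompose after each removal; with
only a precomputed decomposition it performs a single pass.

## The synthetic-data generator

`simulate_genotypes` draws fixed genotypes once per seed: per-SNP base
minor-allele frequencies from Beta(0.2, 5) truncated to (0, 0.5] (a
rare-skewed site-frequency spectrum), per-population logit-normal
divergence (sd 1.0 by default — enough to flip minor alleles between
groups, as real multi-ethnic panels do), Hardy–Weinberg draws within
population. Defaults mirror a three-group, 692-subject exome-panel
study (215/321/156 subjects; ~7.6 SNPs per gene; 67% nonsynonymous;
200 phenotype replicates; 30% disease prevalence; age ~ N(50, 10),
sex ~ Bern(0.5), smoking ~ Bern(0.3)). Explicit per-population
frequency matrices (`fixed_pop_freq`) support controlled designs.

Phenotypes are re-drawn per replicate over the fixed genotypes:
quantitative traits are linear in the collapsed causal-gene counts plus
covariate effects plus N(0, 1) noise; disease status thresholds the
same construction (liability with standard-normal noise) at the
within-replicate quantile matching the designed prevalence. All child
streams derive from one master seed by stable hashing of
(component, replicate), so genotypes are identical across replicates
and every component is independently reproducible.

What the generator does **not** emulate: linkage disequilibrium within
genes (SNPs are independent given ancestry), a realistic site-frequency
spectrum from sequence data, pathway-structured effects, or any
particular benchmark data set's undisclosed phenotype model. Passing tests
therefore certify the statistical machinery under the stated sampling
model, not fidelity to any specific real data set.

## Designed power

For a quantitative trait Q = b·T + (covariates) + ε constructed on
collapsed counts T, the Wald z of the trait coefficient is
asymptotically Normal with

    E[z]   = b·ṽ·√N / √((b²ṽ + σ²)·μ̄),     Var[z] = ṽ/μ̄,

where μ̄ is the mean count, ṽ the count variance *residual to the
analysis covariates* (the eigenvectors absorb the between-population
part of T), and σ the noise sd. `effect_for_power` inverts this for the
effect size giving target power; the variance ratio ṽ/μ̄ < 1 carries the
binomial underdispersion correction. The power study picks a causal
gene whose SNPs are rare in every population so the rare ceiling never
truncates the causal construction, sizes b for 80% power, and checks
the empirical replicate power against it.

## Evaluation-study scales

Chosen as the package's reference experiment sizes: coefficient
recovery at N = 2,000 over 500 refits; null calibration over ≥ 2,000
eigenvector-adjusted gene tests at N = 692; power over 200 phenotype
replicates; stratified detection over 30 replicates of a 30-gene panel
with a group-specific causal gene (background divergence sd 1.5 so the
ancestry axes are anchored by many markers and the causal gene's own PC
loading is negligible — with a tiny panel the causal SNPs would
dominate the PCs and the adjustment would absorb the signal being
tested).

## Known limitations

- Conservative below nominal when common variants are collapsed
  (dispersion mismatch above); no overdispersion/zero-inflated-binomial
  variant is provided.
- Observed-information SEs only; no sandwich or permutation option.
- No weighted collapsing (e.g. frequency-weighted burdens), no
  pathway-level collapsing, no mixed models or kinship adjustment.
- The 2-df LRT compares fits from the same fallback ladder; if the full
  and reduced fits land on different rungs the df bookkeeping follows
  the coefficient counts actually fitted.
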