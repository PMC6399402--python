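# Methods

`raregene` implements a gene-centered strategy for detecting association
between a binary phenotype and aggregated rare variation (MAF < 1%) in
case-control cohorts of imputed genotypes. This note records the models,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that a maintainer
would otherwise have to reverse-engineer.

## The analysis model

For each protein-coding gene with at least one polymorphic rare variant
on the independent (LD-pruned) working set, two tests are run against
case/control status `y`:

**Burden test.** The per-individual "genetic variable"
`s_i = Σ_j g_ij` sums the minor-allele dosages of the gene's rare
variants (missing dosages contribute 0). A logistic regression

    logit P(y_i = 1) = α + γ' PC_i + β s_i

is fitted by maximum likelihood; `exp(β)` is the aggregate odds ratio —
above 1 risk, below 1 protective. Interpretation requires the rare
alleles in the gene to act predominantly in one direction.

**SKAT.** The variance-component score statistic

    Q = (y − μ̂)' G W² G' (y − μ̂)

with `G` the gene's dosage submatrix (minor-oriented), `W = diag(w_j)`
per-variant weights and `μ̂` the fitted probabilities of the
covariates-only null model. Under the null, `Q` is distributed as
`Σ_k λ_k χ²_{1,k}` with `λ_k` the nonzero eigenvalues of
`W G' P₀ G W` (`P₀ = V − V X (X'V X)⁻¹ X'V`, `V = diag(μ̂(1−μ̂))`).
SKAT retains power when a gene carries both risk and protective
variants, where the burden sum cancels.

Candidate genes are those significant in **both** tests after both
corrections below — an intersection rule that trades sensitivity for a
lower false-positive rate.

### Stratification correction

Ten principal components of the standardized common-variant genotype
matrix (centered by `2p̂`, scaled by `sqrt(2p̂(1−p̂))`, missing set to 0
after centering) enter both tests as covariates. Residual inflation is
then removed by genomic control: per test family (burden, SKAT — they
inflate differently), λ is the median observed 1-df χ² equivalent
divided by 0.4549, and every statistic is divided by λ before mapping
back to a p-value. λ = 1 leaves p-values untouched; the correction
preserves ordering exactly.

smartpca-style outlier-removal iterations are not replicated; PC signs
are fixed by forcing the largest-magnitude loading positive.

### Multiple-testing correction

The genotype columns of all rare variants of all tested genes are pooled
into one table. For each gene, `N` replicates draw (without replacement
within a replicate) as many columns as the gene has markers and re-run
the identical tests with identical covariates; replicate p-values are
GC-corrected with the same family λ, and the empirical p is
`(r + 1)/(N + 1)` where `r` counts replicates at or below the observed
GC-corrected p. The floor `1/(N+1)` is rendered as `<1.00E-03`-style
strings in reports. Default `N = 1000`. Because the pooled table is
built from the pruned independent set, the loss of LD relations under
random column draws does not bias the replicate null — this is a
precondition, not a convenience: with correlated within-gene markers the
observed statistic's null differs from the random-set null and the
empirical p is no longer uniform.

### Enrichment

Given a gene→disease annotation table (OMIM-style pairs), the number of
pairs hit by the candidate list is compared with the counts of 1,000
random same-size gene sets drawn from the universe of *tested* genes
(not all genome genes — the tested set is the correct reference
population). `Z = (X − mean)/sd`; p is the one-sided upper normal tail
(enrichment direction), with an exact `(r+1)/(R+1)` empirical p also
reported. For one-disease-per-gene tables the replicate counts follow
the hypergeometric law exactly, which the test suite verifies.

## Quality control

Two stages with different purposes:

* **Scaffold stage** (genotyping-array data, before imputation): sample
  call rate ≥ 0.90 → variant call rate ≥ 0.98 → MAF ≥ 1% → HWE →
  differential missingness (p ≥ 1e-5 kept) → relatedness. The HWE
  clause is read as: whole-sample exact p ≥ 1e-4 AND control-only exact
  p ≥ 0.01 (the source wording is ambiguous between per-stratum and
  whole-sample; this reading applies both constraints).
* **Post-imputation stage**: info score ≥ 0.75 and variant call rate
  ≥ 0.99, sample call rate ≥ 0.95, and deliberately **no** MAF filter —
  rare variants are the object of study.

All thresholds are inclusive on the keep side. The HWE test is the
exact conditional test (sum of probabilities of heterozygote
configurations no more probable than the observed one), implemented with
log-gamma arithmetic and validated against a rational-arithmetic
enumeration oracle for every table with n ≤ 20. Differential
missingness uses Fisher's exact test when any expected cell < 5, else a
1-df χ² without continuity correction.

Relatedness uses the pedigree-free robust estimator
`φ̂ = (N_het,het − 2 N_opp_hom)/(N_het(i) + N_het(j))` (duplicates give
0.5, unrelated pairs 0) rather than an admixture-aware method, which
would need external reference allele frequencies; the threshold
semantics are unchanged (pairs with φ̂ ≥ 0.055 lose the lower-call-rate
member, ties broken by sample order). Pairs with fewer than 100 jointly
called genotypes are flagged unreliable and retained. Note that φ̂ has
sampling noise ~1/√m; with fewer than a few thousand markers the 0.055
threshold will flag unrelated pairs.

## Variant classification

MAF and MAC are computed over called genotypes of the combined
case+control sample; the minor allele is the less frequent one, ties
assigned to ALT. Polymorphic rare variants partition into:
singleton (MAC = 1), very rare (MAC > 1, MAF < 0.1%), and strict-sense
rare (0.1% ≤ MAF ≤ 1%). MAF exactly 0.1% goes to strict-rare so the
intervals partition. The aggregate tests weight categories by
minor-allele counts, not variant counts — singletons are ~14.5% of rare
variants in genome-wide imputed data but only ~0.65% of rare minor
alleles, which is why they are retained despite poor imputability.

## LD pruning

r² is the squared Pearson correlation of unphased dosage vectors
(composite LD) over jointly called samples; columns monomorphic on the
joint support get r² = 0 with a log entry. Pruning is sliding-window
greedy (window 50 variants, step 5, both configurable): within a
window, for any kept pair with r² ≥ 0.1 the lower-MAF member is dropped
(tie → later position). Default scope is per gene region — the testing
unit — with a global option. Pruning is idempotent, and the kept set is
verified all-pairs independent by brute force in the tests.

## Statistical calibration choices

These defaults were set by measuring operating characteristics on
synthetic null cohorts (n = 500, 20 rare variants per gene, 20,000 null
simulations), and they matter:

* **Burden p-value: score test by default.** The Wald p from the ML fit
  is conservative for sparse burdens (measured type-I 0.039 at nominal
  0.05); the covariate-adjusted efficient score test is calibrated
  (0.049). The OR and its 95% CI still come from the ML fit
  (`exp(β ± 1.96 SE)`), matching the symmetric-in-log CIs users expect
  in results tables. `p_type="wald"` and `"lrt"` are available.
* **SKAT small-sample variance adjustment (default on).** The
  mixture-of-χ² approximation assumes normal per-variant scores; for
  binary traits `Var(Q)` is overstated (the exact centered-Bernoulli
  fourth moment is `v(1−3v) < 3v²`), making unadjusted p conservative
  (measured 0.031). The null distribution is rescaled to the exact
  variance `2Σλ² + Σ_i A_ii² v_i(1−6v_i)`; measured type-I 0.049.
* **Mixture tail evaluation.** Liu-Tang-Zhang moment matching by
  default, re-evaluated by Imhof characteristic-function integration
  when p < 0.01 (moment matching is a tail approximation: within ~2e-3
  of Imhof in the tail, up to ~0.03 off in the body). A seeded
  residual-permutation p (`method="permutation"`) is available; note
  the analytic p approximates the unconditional null while permutation
  targets the conditional null — they agree to ~0.03 absolute at
  n = 300, not to Monte-Carlo precision.
* **Separation.** Quasi-complete separation (easy with sparse burdens)
  falls back to Firth's penalized likelihood, flagged in the result.
  Constant burden scores and all-zero SKAT eigenvalue sets yield
  untestable flags, excluded from λ estimation.
* **SKAT weights.** Unstated upstream; default Beta(MAF; 1, 25) density
  (the SKAT convention, upweighting rarer variants), with flat weights
  and user arrays as options.
* The permutation correction re-runs the score-test burden p and the
  moment-matched SKAT p per replicate; the Imhof refinement is skipped
  there because the empirical p has resolution 1/(N+1) anyway.

## The synthetic cohort generator

The generator exists so every stage is testable with known ground
truth. It emulates:

* **Population structure**: per-subpopulation allele frequencies drawn
  from the Balding-Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) model around an
  ancestral frequency; confounding induced by unequal subpopulation
  proportions between cases and controls. For European-like cohorts
  F ~ 0.005–0.02 is the realistic range; at continental F (≥ 0.05)
  common-variant PCs genuinely cannot fully correct rare-variant
  stratification, which is a property of the method, not a bug in the
  generator.
* **Site frequency spectrum**: category labels drawn from target
  weights (default 7.4% singleton / 26.4% very rare / 17.2% strict-rare
  / 49.0% common, mirroring the rare-skewed spectrum of dense imputed
  data); ancestral frequencies from an inverse-frequency (1/p) density
  truncated to the category bounds. Singletons are placed as exactly
  one minor-allele copy. Because binomial sampling leaks realizations
  across category boundaries, genotypes are redrawn (up to 50 times)
  until the realized category matches the drawn one
  (`enforce_categories`, default on); disable it for strictly
  unconditional draws. The very-rare category needs MAC ≥ 2 strictly
  below MAF 0.1%, hence > 1,000 samples; smaller cohorts must zero that
  weight (a configuration error says so).
* **LD**: block-diagonal, via latent uniforms copied along consecutive
  variants within a block (probability `ld_copy_prob`, default 0.8,
  blocks of 5); independence across blocks and genes; singletons break
  chains. Sufficient to exercise pruning; no recombination maps.
* **Missingness and info scores**: Bernoulli missing mask (default 0);
  info scores uniform on (0.6, 1.0) so the 0.75 filter has bite.
* **Effects**: per-gene log-odds `β` applied to the minor-allele burden,
  `logit P(case) = α + Σ β_g burden_g`, with `α` solved by Brent's
  method for a requested prevalence; cases/controls then subsampled to
  requested counts. Subsampling a pool dilutes rare MACs (a pool-factor
  of 3 leaves ~1/3 of pool carriers), so demo fixtures use pool factors
  near 1.5.
* **Annotations**: genes annotated with probability `p` (causal genes
  `p × boost`), 1..k diseases each.

Not emulated: realistic demography, recombination, genotyping or
imputation error structure (info scores are decorative, uncorrelated
with dosage accuracy), sex chromosomes, covariates beyond ancestry.
Passing tests therefore demonstrate the statistical machinery under the
model's own assumptions, not robustness to real-data artifacts.

## Problem sizes used by the checks

The bundled suites run on one CPU: calibration uses 2,000 null
gene-simulations at n = 500 with 20 variants/gene; oracle equivalence
uses 100,000-draw permutation oracles at n = 200 with 5 variants, exact
HWE enumeration for all tables n ≤ 20, and brute-force r² on ≤ 200
variants; parameter recovery uses 200 replicates at n = 2,000;
stratification uses three 800-sample two-subpopulation cohorts of 300
genes (λ estimated on ~900 pooled genes — the median-based λ has
SD ≈ 0.13 at 300 genes, so single-cohort λ bounds would be noise-bound);
the empirical-correction null uses 500 genes at N = 200 replicates.
The acceptance script (`scripts/acceptance.py`) re-runs reduced versions
of the same experiments in ~15 s.

## Known limitations

* The burden OR is reported per minor allele of burden; it is not
  comparable across genes with different marker counts.
* λ-based GC assumes a uniform inflation of the χ² scale; it cannot fix
  confounding that varies across the MAF spectrum.
* The empirical correction assumes exchangeability of marker columns
  across genes; strong gene-length or MAF-composition outliers weaken
  it (the draw matches marker *count* but not MAF composition).
* PCA-based correction requires enough common markers for accurate
  ancestry estimates (roughly m × F ≫ 1); desk-scale simulations below
  that regime show residual inflation that disappears with more markers,
  not more PCs.
* The enrichment test's normal-tail p is an approximation for discrete
  counts; use the empirical p for small universes.
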