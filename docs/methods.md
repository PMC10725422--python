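# Methods

## The two-stage TWAS model

`twaskit` implements an individual-level, two-stage transcriptome-wide
association study (TWAS) for small livestock cohorts, where a handful of
animals carry both genotypes and mammary-transcriptome expression and a
larger genotyped herd carries the phenotypes.

**Stage 1 — expression imputation.** For each gene *g*, with cis-genotype
matrix `X` over the SNPs within ±1 Mb of the gene body (minor-allele dosage
coding) and normalized, confounder-residualized expression `e`,

    e = X w + ε,   ε ~ N(0, σ²_ε I)

is fitted on the reference panel to obtain cis-eQTL weights `ŵ`.  Two
estimators are provided:

* **Elastic-Net** minimizes `(1/2n)‖e − Xw‖² + λ[(1−α)/2‖w‖² + α‖w‖₁]`.
  λ is chosen by k-fold cross-validation (MSE criterion) on a log-spaced
  grid; α is either fixed at 0.5 or grid-searched over {0.1, …, 0.9}.
* **Dirichlet-process regression (DPR)** places a nonparametric scale-mixture
  prior on effect sizes: `w_j | z_j = k ~ N(0, σ²_k)` with mixture labels
  drawn from a truncated stick-breaking Dirichlet process
  (`v_k ~ Beta(1, α_DP)`, truncation K) and an inverse-gamma base measure on
  each σ²_k.  Because the mixture adapts the shrinkage profile to the data,
  DPR produces (weakly) nonzero posterior-mean weights for essentially every
  gene, whereas the lasso component of the Elastic-Net zeroes entire genes
  when cross-validation at very small n favours a heavy penalty.  This is
  the mechanism behind the gene-coverage gap between the two estimators at a
  reference size of 8.

**Stage 2 — association.** GReX (genetically regulated expression) is
imputed into the test panel as `GReX = X_test ŵ` and scanned per gene with a
fixed-effect linear model

    y = η C + β · GReX + e,     H₀: β = 0   (identity link)

where `C` holds the stratification and management covariates: the first two
classical-MDS coordinates of genome-wide identity-by-state (IBS) distances,
age at first calving (AFC, months) and birth weight (bwt, kg).  The
companion single-SNP GWAS uses the same covariates with the SNP dosage in
place of GReX.  Inference is a two-sided t-test with n − q degrees of
freedom (the reference distribution is a package choice; the model source
does not state one).  Multiple testing is handled by the Bonferroni
threshold α/m and Benjamini–Hochberg step-up FDR; the genomic-inflation
factor λ_GC (median implied χ²₁ over its null median ≈ 0.4549) is the scan
diagnostic.

## DPR inference

Inference is coordinate-ascent variational Bayes over a mean-field family
with a **full-covariance Gaussian factor** for `w`, categorical factors for
the labels, Beta factors for the stick-breaking weights and inverse-gamma
factors for the component variances; the noise variance σ²_ε is updated by
MAP under the same weak inverse-gamma prior (this keeps σ²_ε bounded away
from zero in the p ≥ n interpolation regime that an 8-sample reference panel
lives in).  Convergence is declared when the relative change of the evidence
lower bound drops below `tol`; label responsibilities are initialized from a
seeded Dirichlet draw, making the fit bit-reproducible given the seed.

Defaults and the reasons behind them:

| parameter | default | why |
| --- | --- | --- |
| truncation K | 4 | enough components to separate null from signal scales at cis-window sizes (tens of SNPs); more adds cost, not accuracy, at this scale |
| tol | 1e-4 | relative-ELBO change; tighter values change weights by < 1e-3 on desk-scale fits |
| max_iter | 1000 | non-convergence is flagged (`converged=False`), never raised |
| α_DP | 1.0 | standard uninformative stick-breaking concentration |
| base measure | InvGamma(1, 1e-8) | sparsity-favouring: an effectively flat base lets mean-field VI stall at a finite-precision fixed point in which pure-noise coordinates keep ≈ 25% of their OLS magnitude; a tiny scale parameter lets null components collapse so noise weights vanish, while data-dominated components are unaffected (signal recovery metrics are unchanged to two decimals) |

Two useful exact identities follow from the full-covariance Gaussian factor:
at K = 1 the posterior-mean weights equal ridge regression at the fitted
variance ratio `σ²_ε · E[1/σ²₁]` (used as a test oracle), and the GReX map
is exactly linear in the weights.

A caution on Bayesian posterior means: they are *not* invariant to
duplicating the data rows (the likelihood sharpens while the prior does
not), so row-duplication checks compare the weight profile (correlation,
norm) rather than demanding bit equality — unlike OLS or the (1/n)-scaled
Elastic-Net objective, which are exactly invariant.

## Training regimes

"With CV" and "without CV" label how the reported training R² is computed,
not how the weights are fitted — weights always come from a fit on all
reference samples (this is how imputation-weight pipelines behave in
practice). `cv5` is the squared Pearson correlation between observed
expression and out-of-fold predictions from seeded 5-fold splits; `nocv` is
the in-sample squared correlation.  In-sample R² is optimistic by
construction; the suite asserts `nocv ≥ cv5` across simulated genes.  A
rotational leave-two-out regime (`loto`) is also exposed for 8-sample
panels, since descriptions of "no cross-validation" at that scale are
ambiguous between fit-on-all and rotational holdout; the package makes
fit-on-all the primary reading and asserts nothing about the other.

A gene is counted **usable** ("predicted") when at least one weight exceeds
1e-8 in absolute value — the accounting needed to compare gene coverage
between estimators.

## Quality control

Two profiles reflect the two analysis arms:

* **Set-1** (TWAS/eQTL training): biallelic SNPs on autosomes + X, per-variant
  call rate strictly > 0.95, Hardy–Weinberg exact-test p ≥ 1e-4, MAF ≥ 0.01.
* **Set-2** (GWAS): Set-1 plus MAF > 0.05 and a greedy sliding-window LD prune
  at r² < 0.8 (window 50 variants, step 5; the pair member with lower MAF is
  dropped, ties drop the later position).  MAF filtering precedes LD pruning.

Per-gene training applies its own exclusions inside the cis window: missing
rate > 0.2, MAF < 0.01, HWE p < 1e-4; surviving missing dosages are
mean-imputed.  The HWE test is the exact conditional test (sum of
heterozygote-configuration probabilities no larger than the observed one,
computed by the stable two-term recurrence from the modal configuration); no
mid-p correction.  The X chromosome is treated as diploid like the autosomes
— the data this models retained X SNPs without a dosage-compensation rule,
and sex-aware coding is out of scope.

Genotypes are coded as minor-allele counts, the minor allele being defined
per variant from the panel's own empirical allele frequency (a tie at 0.5
goes to the alternate allele).  Because reference and test panels may orient
a borderline variant differently, weight sets carry the minor-allele base of
their training panel and imputation flips test dosages (2 − d) where the
orientations disagree.

## Expression preparation

Raw counts are normalized by median-of-ratios size factors (genes with any
zero count are excluded from the geometric-mean reference but kept in the
output) followed by `log2(count/sf + 1)`.  This is a deliberate, documented
substitute for a regularized-log transform: it preserves the property the
imputation model needs — continuous, approximately homoskedastic expression
— without importing a shrinkage estimator whose output depends on dispersion
fitting.  Pipelines that already have rLog output can feed it directly to
the residualization step.  Confounders (production level high/low, sampling
batch) are removed per gene by least-squares residualization on indicator
covariates with an intercept; the operation is idempotent, residuals are
exactly orthogonal to the factor columns, and rank-deficient designs are
handled by least squares on the column space.  Production level enters as
an indicator, not a continuous yield, matching how the labels are defined
(above/below herd-average bands).

## The synthetic cohort

The generator emulates the data structure the pipeline targets, with
defaults mirroring the motivating study design:

* 8 reference / 136 test animals; 20 genes × 20 cis-SNPs on 1–2 synthetic
  chromosomes, gene windows non-overlapping by default (an overlap mode
  exists for stress tests);
* biallelic SNPs with allele frequencies uniform on (0.05, 0.5], genotypes
  as two independent allele draws (exact HWE), optional uniform missingness;
* per-gene expression `E = Xw + ε` with the genetic variance fraction pinned
  to `he2` (default 0.15, inside the 0.04–0.2 band where TWAS is expected to
  out-power GWAS) and `round(pi_causal · snps_per_gene)` causal SNPs;
* phenotypes for test animals only: `y = Σ_g β_g GReX_g + β_AFC·AFC +
  β_bwt·bwt + N(0, σ²)` with AFC ~ N(40 mo, 4) and bwt ~ N(33 kg, 3).

What it does **not** emulate — and what green tests therefore do not show —
is linkage disequilibrium between cis-SNPs (sites are independent),
relatedness/kinship structure, read-level noise, allele-specific expression,
or any trans-regulation.  Power comparisons on this cohort speak to the
many-small-cis-effects regime, not to LD-confounded fine-mapping.

Study-condition constants used by the checks (chosen from the generative
design): heritability-recovery and HWE-proportion properties are evaluated
at n_ref = 2000; parameter recovery at n_ref = 400 with 30 cis-SNPs, he2 =
0.3, all SNPs causal; the TWAS-vs-GWAS direction at he2 = 0.2 with the
causal gene's GReX explaining 5% of trait variance, n_test = 400 and
n_ref = 200 over 20 replicate seeds (200 is a realistic eQTL-reference size
that isolates the aggregation advantage of TWAS from stage-1 estimation
noise; at n_ref = 8 both scans are underpowered and the comparison is
dominated by weight noise); the DPR-vs-Elastic-Net coverage direction at the
study's own n_ref = 8 over 200 genes.  These sizes also keep the default
suite and the acceptance script fast on one CPU.

## Numerical choices and degenerate inputs

* Zero-variance units in a scan (constant SNP dosage, all-zero GReX) are
  flagged with p = 1 and excluded from nothing downstream; zero-variance
  predictions in CV give training R² = 0 by convention.
* Monomorphic sites get HWE p = 1 by convention; all-missing variants have
  undefined MAF and fail any call-rate filter.
* Collinear covariate columns are dropped greedily (never the intercept)
  with a warning; samples missing the trait or any covariate are dropped
  listwise per scan.
* The DPR linear algebra uses a Cholesky inverse with escalating diagonal
  jitter (pinv as last resort) because an 8 × p cis matrix is always
  rank-deficient.
* MDS components fix their sign so each component's largest-magnitude
  loading is positive; eigenvalues ≤ 0 terminate the component list with a
  warning.
* BH adjustment restores input order and caps at 1; NaN p-values are an
  error naming the offending index.
* λ_GC clamps p = 0 to the smallest positive float with a warning.
* Tie-breaks: equal-MAF LD pairs drop the later position; equal extreme
  weights report the earlier position; top-hit ties order by (chrom, pos).

## Reporting conventions

Top-hit tables rank by ascending p and annotate genes whose ±20 kb flanked
interval covers the hit position (1-based, boundary inclusive).  The FDR
column is, by default, the BH adjustment over **all** tests; an opt-in
`fdr_scope="top"` re-adjusts within the selected top-10 only, mirroring a
convention some association reports use — it is statistically unusual
(anti-conservative) and off by default.  TWAS hit windows collect genes
whose midpoint lies within ±1.5 Mb of the hit gene's midpoint on the same
chromosome; these window lists are exported for external pathway enrichment
rather than enriched in-package (enrichment services are database-version
dependent).  Venn/overlap tables report every intersection region of the
named top-gene sets.

## Known limitations

* No kinship or mixed-model correction: stratification is handled by two MDS
  covariates only, as in the fixed-effect design this package reproduces.
* No summary-statistic TWAS, cross-tissue weights, or dominance/epistatic
  terms; only additive cis effects are modeled.
* DPR inference is variational, chosen for determinism and speed at desk
  scale; posterior uncertainty is not propagated into stage 2 (no Bayesian
  credible intervals on β).
* The LD-free simulator cannot exercise clumping/fine-mapping behavior; the
  greedy LD pruner is tested on duplicated/correlated columns instead.
* Training R² at n = 8 is dominated by optimism (in-sample values near 0.8
  are expected and are not evidence of predictive accuracy — the cross-
  validated column is the honest one).
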