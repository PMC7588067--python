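# Methods

## Problem and model

`phenosig` derives a phenotype-specific molecular signature from several
independent control/mutant expression experiments and uses it to score new
experiments for the same phenotype. The central difficulty is that
experiments deposited by different groups differ in location (lab, platform,
normalization), and in latent biological structure (sex, tissue, age), by
amounts that dwarf the phenotype signal. The pipeline addresses both with a
per-gene random-intercept linear mixed model whose fixed effects are the
leading principal components of the combined data:

    y_gs = beta0_g + sum_{k=1..p} beta_gk * PC_k(s) + u_{g,e(s)} + eps_gs
    u_ge ~ N(0, sigma_u_g^2),   eps_gs ~ N(0, sigma_g^2)

The random intercept `u_ge` absorbs per-gene location shifts of each
experiment `e`; the `p` consecutive PC covariates absorb latent sample-level
structure shared across genes. Models with p = 0..7 are fitted (eight
models). Normalized conditional residuals

    r_gs = (y_gs - fixed fit - BLUP_ge) / sigma_hat_g

feed a per-gene univariate logistic regression of class (mutant = 1) on the
residual; genes are ranked by the Wald p-value, ties broken by descending
|beta| then gene ID, and the top N (default 200) form the signature.

Choices made where the procedure is genuinely open:

- *Conditional, not marginal, residuals.* Removing the experiment intercept
  is the purpose of the random effect, so the BLUP is subtracted.
- *Pearson scaling.* Residuals are divided by the estimated residual SD;
  per-gene z-scoring would differ only by a per-gene constant and leaves the
  per-gene logistic ranking unchanged.
- *PCA once.* PCs are computed on the full combined matrix (per-gene mean
  centering, no variance scaling) and reused across all PC counts and all
  cross-validation folds.
- *Wald test*, not LRT, for the scan: a single-covariate scan where the two
  agree asymptotically and the Wald fit is vectorizable; the reference-fit
  test pins the numerics to an independent implementation.

## REML solver

Per-gene mixed-model fitting at genome scale across eight PC counts and all
cross-validation folds requires on the order of 10^5 REML fits, so the
solver is purpose-built rather than delegated to a general mixed-model
routine. With a single variance ratio theta = sigma_u^2/sigma^2 the
covariance is V = sigma^2 (I + theta ZZ') and V^-1 has a closed per-group
form, so the REML criterion profiles to a one-dimensional function of theta
per gene evaluated from group-level sufficient statistics. All genes are
optimized simultaneously: a 41-point grid on log(theta) in [-18, 18]
brackets each gene's optimum, 100 vectorized golden-section iterations
refine it, and the theta = 0 boundary (ordinary least squares) is compared
explicitly and flagged when it wins. Each gene is centered before the
sufficient statistics are formed (restored in the intercept afterwards);
without this the y'y cancellation at typical log2 intensities (~7) limits
theta to about six digits. The test suite checks the solver against the
balanced one-way ANOVA closed form (sigma^2 = MSW, sigma_u^2 =
max(0, (MSB-MSW)/n), BLUP shrinkage sigma_u^2/(sigma_u^2 + sigma^2/n)) to
1e-6 and against an independent general REML fitter by log-likelihood
comparison.

Degenerate cases: a single experiment forces theta = 0 (the random
intercept is unidentifiable) with the OLS flag set; genes with no residual
variance are excluded from ranking, never silently dropped.

## Logistic scan

The per-gene fits run as damped Newton iterations vectorized across genes
(steps capped at 5 per iteration, convergence at 1e-10). Quasi-separation is
detected when the linear predictor escapes |eta| > 30 without convergence;
such genes keep the capped fit's finite statistic and carry a separation
flag. A constant residual yields beta = 0, p = 1 by construction.

## PC-count selection

For each p in 0..p_max the full residual -> scan -> enrichment chain is run.
Each gene set is tested by a Wilcoxon rank-sum comparison of member vs
non-member ranks, one-sided toward the top (the ranking ignores effect
direction, so enrichment is directional in rank only); exact null for small
problems (set <= 8, universe <= 20), tie/continuity-corrected normal
otherwise; BH step-up FDR across the tested collection. The score of p is
the number of user-designated phenotype-related target sets with q < 0.05;
the smallest p attaining the maximal score is selected. This formalizes a
judgment call — the per-p table and trace are returned so the choice can be
overridden, since in real data residual-PCA inspection can also inform it.

## Validation and scoring

LOOCV is at the *experiment* level. Residuals (and the PCA) are computed
once on the full combined dataset before any experiment is held out; this
leaks nuisance structure — not class labels — across folds. It is kept
deliberately because the procedure being validated is defined that way, and
it is flagged here because it is statistically unusual. Per fold the scan
and top-N signature are rebuilt from training samples only, a random forest
(1,000 trees, library defaults otherwise; probabilities are averaged
per-tree leaf class fractions) is trained on training residuals at the
signature genes, and held-out samples receive mutant-class probabilities.
The single reported AUC is the Mann–Whitney concordance of all pooled
held-out samples (not a per-fold average). Two-sided one-sample t-tests
compare held-out control and mutant probabilities with the null value 0.5,
both per fold and pooled. Forest seeds derive deterministically from the
run seed and fold index.

A query experiment is scored by appending it to the reference data as a new
random-effect level, recomputing PCA and residuals on the combined data,
building the signature from reference samples only, and averaging the
forest's mutant-class probabilities per query class; classes absent from
the query are reported absent.

## Overlap permutation analysis

To probe whether unrelated perturbations share a global compensatory
response, many sets of five control/mutant experiments are drawn; each
experiment is ranked by per-gene Welch t-tests (a deliberate plain-variance
stand-in for moderated-t ranking — the analysis needs only a reasonable
ranking), the top-200 lists are intersected pairwise, each overlap gets an
upper-tail hypergeometric p with the analyzed gene set as universe, and the
per-set summary is the median -log10 p. The chance null repeats this with
uniformly drawn 200-gene lists (redrawn per experiment) from a separate
seed stream. Experiment pools can be subsampled to match per-experiment
control/mutant counts.

## Batch handling

Within one experiment, a candidate batch factor is tested by one-way ANOVA
of the leading PC scores (default first 3) on its levels; a PC is flagged
when p < 0.01 and its variance fraction is >= 0.2. The thresholds are
declared operating conventions, configurable, not estimates. Correction is
gene-wise location adjustment (level mean mapped to the gene's grand mean;
idempotent, mean-preserving, and exactly neutral to class contrasts when
batches are class-balanced), with an optional scale mode equalizing
within-level SDs to the pooled SD. A factor that coincides with the class
labels triggers a warning, since correcting on it would erase the signal.

## Synthetic data

The generator emulates the statistical structure the method assumes:

    x_gs = mu_g + a_ge + sum_k lambda_gk f_ks + delta_g 1[mutant] 1[signal] + eps_gs

| parameter | default | meaning (log2 units) |
|---|---|---|
| n_experiments | 5 | independent control/mutant experiments |
| samples per experiment | 8 + 8 | controls + mutants |
| n_genes | 2,000 | shared gene universe |
| baseline mu_g | N(7, 1) | typical log2 intensity scale |
| exp_offset_sd (a_ge) | 0.5 | per-gene-per-experiment location shift |
| latent factors | 2 (1 experiment-level, 1 sample-level) | sex/tissue analogues |
| loading_sd (lambda) | 0.5 | factor loadings |
| n_signal_genes | 100 | planted phenotype genes |
| effect delta_g | ±N(1.0, 0.25) | random sign: both directions occur |
| noise_sd | 1.0 | i.i.d. Gaussian noise |
| gene sets | 50 of size 20–50 | 3 targets at 50% signal fraction, rest decoys |

The five-experiment 8+8 design matches the scale of a small multi-accession
microarray compendium; baseline and noise levels are chosen to resemble
RMA-normalized intensities. The magnitude of real between-experiment
variance is not well characterized, so `exp_offset_sd` is an explicit
modelling choice exposed in the config. Binary factors can be recorded as
metadata columns (batch scenarios); sample-level normal factors accept a
class-correlation parameter to build confounded designs. The shipped
confounded scenario uses correlation 0.45 with loading SD 2.0: strong
enough that the factor swamps the per-gene class signal when no PCs are
included, while regressing out the factor's PC costs only ~20% of the
signal variance (at correlation rho the loss is ~rho^2). Everything is
reproducible bit-for-bit from the seed.

What the generator does *not* emulate: probe-level effects and RMA,
mean-variance trends, count distributions, correlated gene modules beyond
the planted factors, and missing values. Passing tests therefore show the
machinery behaves correctly under the assumed model, not that real
repository data satisfy those assumptions.

### Calibration checks and latent factors

Shared factor scores correlate genes. Each gene's marginal test stays exact,
but across-gene summaries (rejection fractions, KS statistics) acquire extra
variance. Calibration tests therefore either disable the factors or run the
scan at the PC count that absorbs them (p = 2, the generator's true factor
count) — which is also the estimator the pipeline actually uses.

## Problem sizes in the shipped checks

The automated checks run the reference configuration at 2,000 genes; the
t-test type-I calibration uses 200 repetitions at 500 genes with top-50
signatures and 200-tree forests (the calibration of a t-test on held-out
forest probabilities does not depend on those sizes); the overlap analysis
uses 200 experiment sets per arm. `scripts/acceptance.py` recomputes every
reported quantity from scratch with seeds derived from `--seed`.

## Known limitations

- The residual-before-holdout LOOCV leaks nuisance structure across folds
  (see above); AUCs are therefore optimistic relative to a fully nested
  scheme.
- The single-variance-ratio REML solver covers only the random-intercept
  structure used here, not general random effects.
- Null LOOCV AUC for a single 5-experiment run has SD ~0.07 (feature
  selection inside small folds); calibration statements should average
  over replicates.
- No threshold is imposed on the mean mutant probability for calling a
  phenotype; ranking is left quantitative.
- Multi-arm designs must be pre-split into two-class experiments; gene
  universes are intersected, never imputed.
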