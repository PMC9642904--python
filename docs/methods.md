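# Methods

## The model

`prismvote` implements the Prism Vote framework for polygenic trait
prediction in cohorts that mix subjects from multiple populations.  The
central idea is a Bayesian decomposition of each subject's predicted trait
over ancestry strata:

    Pr(Y = 1 | x_i) = Σ_{k=1..K} Pr(Y = 1 | i ∈ k, x_i) · Pr(i ∈ k | x_i)

for a binary trait, and E(Y | x_i) = Σ_k E(Y | i ∈ k, x_i) · Pr(i ∈ k | x_i)
for a continuous one.  The first factor is a *base prediction model* fitted
within stratum k, where the genetic architecture is assumed more
homogeneous than in the pooled cohort; the second is the subject's
*propensity* to stratum k.  Because the propensity spectrum is unique to
each subject, two subjects with identical genotypes at the risk loci can
receive different risk estimates — the individualization the framework is
named for.

### Stratification

Genotypes g_ij (minor-allele counts) are normalized to

    x_ij = (g_ij − ḡ_j) / sqrt(2 p_j (1 − p_j)),   p_j = (1 + Σ_i g_ij) / (2 + 2N),

the shrunk frequency estimate keeping the denominator positive even for
monomorphic variants.  The N×N covariance Ψ = XXᵀ/P is eigendecomposed
(through whichever Gram matrix is smaller, so the result is exact at any
N/P ratio), the top q eigenvalues are normalized to weights
a_r = λ_r / Σ_{r≤q} λ_r, and each subject receives a single weighted
ancestry score w_i = Σ_r a_r v_i^r.  The PCA is fitted jointly on training
and test subjects by default; a project-only mode (fit on training,
project test subjects through the right singular basis) is provided for
settings where test data cannot enter the decomposition, at a small cost
in fidelity.  Eigenvector signs are fixed by making the largest-magnitude
loading positive so scores are reproducible across runs.

Training subjects are cut into K equal-size quantile bins of w (stable
ties on input order; bin sizes differ by at most one).  Stratum k is
summarized by its center c_k (mean of w), its sample variance σ̂_k², and
its prior π_k = N_k/N.  The within-stratum variance is used in the
membership likelihood; the subscript is per stratum, not per subject.

### Propensity

The likelihood of observing a subject at score w given membership in
stratum k treats the squared standardized distance as chi-squared with one
degree of freedom:

    Pr(x_i | i ∈ k) = Pr[χ²₁ > (w_i − c_k)² / σ̂_k²],

and Bayes' theorem with the stratum priors yields the propensity matrix,
whose rows sum to one by construction.  If every likelihood underflows to
zero for some far outlier, the posterior falls back to the priors (with a
warning) instead of producing 0/0.

### Base models

The per-stratum predictors are pluggable.  Built in:

* **ridge** (default for continuous traits) — penalized least squares over
  all variants with the intercept and top-q PC covariates unpenalized.
  This is the GBLUP form of a whole-genome linear mixed model and stands
  in for dense-effect LMM methods (e.g. Dirichlet-process regression);
  sparse-prior methods such as BayesR are intentionally not
  re-implemented.  Absolute accuracies therefore differ from what those
  methods would give; the PV-versus-reference *comparison* is the
  supported scientific readout.
* **linear** — ordinary least squares (minimum-norm when rank deficient).
* **logistic** — L2-penalized logistic regression for binary traits,
  optimized by L-BFGS, covariates unpenalized.
* **external** — an adapter that writes PLINK-format training/test files,
  runs an arbitrary command, and reads back per-subject predictions, so
  BayesR/DPR/LDpred2 binaries can be slotted in unchanged.

The ridge penalty defaults to a profile-REML estimate of
σ_e²/σ_β² computed on the same spectral decomposition used for the solve —
the classical mixed-model estimate of the optimal shrinkage.  Generalized
cross-validation is available as an option, but with many more variants
than subjects its criterion is nearly flat in the penalty and tends to
over-shrink the genotype term relative to the (noisy) PC covariates,
which degrades the within-stratum fits badly; REML does not have this
pathology and is therefore the default.  The covariate block is
residualized out first (Frisch–Waugh–Lovell), so one symmetric
eigendecomposition of the smaller Gram matrix yields both the REML profile
and the coefficients for any penalty.

The reference method — the same base model fitted once on all training
subjects with top-PC covariates — is implemented as an independent code
path, and Prism Vote with K = 1 reproduces it bit for bit (a regression
test enforces exact equality).

### Choosing K and q

`select_k_q` grid-searches (K, q) by internal cross-validation *within the
training data only*: the default grids K ∈ {1,2,3,4}, q ∈ {5,10,20}
bracket the values typically selected on real mixed cohorts (K = 2,
q = 10).  Each cell is scored by mean held-out accuracy (Pearson r or
AUC); ties break toward smaller K, then smaller q, favouring parsimony.
Infeasible cells (under-filled strata) are skipped with a warning.  The
exact selection statistic is not prescribed anywhere authoritative; mean
prediction accuracy over the internal folds is this package's reading.

## The synthetic cohorts

The generator emulates a two-ancestral-population design:

* **Allele frequencies.**  Ancestral MAFs are uniform on (0.05, 0.5) and
  population-specific frequencies follow the Balding–Nichols model at a
  chosen Fst (default 0.15, a typical African–European divergence).  The
  drawn population frequencies can drift above 0.5 and are deliberately
  not folded — folding per population would break the admixture mixture
  model.  A frequency table from real reference data can be supplied
  instead (`load_maf_table`).
* **Genotypes.**  Independent draws x_ij ~ Bin(2, Q_i1 p_j1 + Q_i2 p_j2);
  Q rows are (1,0)/(0,1) for the source populations and uniform on (0,1)
  for admixed subjects.  Loci are in linkage equilibrium by construction.
* **Effects.**  Either the three-tier model — n_causal = 3,000 causal
  variants per population with 75% shared, 10 large effects N(0, 10⁻²),
  300 moderate N(0, 10⁻³), all remaining *causal* variants N(0, 10⁻⁴)
  ("remaining" is read as the remaining causal variants, not all P) — or
  the correlated model, a per-SNP bivariate normal with variances σ_k²/m
  and covariance η σ_k σ_k′ / m, so the cross-population effect
  correlation equals the similarity ratio η.
* **Phenotypes.**  Per-subject effects are the Q-weighted combination
  β_i = Q_i1 β¹ + Q_i2 β², genetic values are computed on normalized
  genotypes (consistent with the N(0,·) effect scale; a raw-count flag
  exists), and the residual variance is calibrated on the *realized*
  sample variance of g so the target h² holds per replicate.  Binary
  traits threshold the liability at the normal quantile matching a
  configurable prevalence.

What the generator does **not** emulate: linkage disequilibrium, real MAF
spectra, genotyping error/missingness patterns, and
genotype-by-environment structure.  Passing tests therefore demonstrate
the statistical behaviour of the method under its own generative
assumptions, not performance on real cohorts.

## Evaluation harness

`run_5gcv` evaluates all method arms on one shared, seeded fold partition
(five folds by default) so comparisons are paired.  Folds are derived from
sorted sample identifiers, making assignments invariant to row order;
binary traits are case-stratified so no test fold is single-class.
Relative improvement is computed fold-wise, 100·(a_f − r_f)/r_f, then
summarized as mean ± SD across folds, matching the usual "mean (SD)"
reporting; folds with non-positive reference accuracy are excluded with a
warning.

## Problem sizes used in the test suite

The automated checks run the full pipeline at reduced scale chosen to
keep the whole suite fast on a single CPU while leaving every scientific
condition (heritability, Fst, η levels, replicate counts, decision
thresholds) intact: the effect-similarity robustness check uses
800 subjects per population, 800 variants and 240 causal (10 replicates
per η); stratum-count selection uses 500 subjects and 500 variants
(20 replicates per scenario); calibration checks use 2,000–2,500 subjects.
The acceptance script uses slightly smaller cohorts again (600 per
population, 3 replicates; 10 selection replicates).  At these sizes the
qualitative results are stable across seeds; accuracies grow with N, so
absolute values are below what large cohorts would give.

## Numerical choices and edge cases

* Missing genotypes are mean-imputed per variant before normalization
  (neutral for centering); how missing data were handled upstream of PCA
  is otherwise unspecified, so the choice is flagged here.
* Hardy–Weinberg filtering uses the 1-df chi-squared test by default with
  an exact-enumeration option; at the default 5×10⁻⁸ threshold the two
  agree for realistic sample sizes.
* Minor-allele designation is by in-sample frequency; exact-0.5 ties break
  lexicographically on the allele string.
* A stratum with fewer than two subjects (variance undefined) raises with
  advice to lower K; zero within-stratum score variance likewise.
* All stochastic steps flow from a single integer seed; given the data,
  fitting and prediction are fully deterministic.

## Known limitations

* Ridge/GBLUP is the only internal LMM; traits with sparse architecture
  will favour sparse-prior base models, available only through the
  external adapter.
* Joint-PCA mode requires the test genotypes at prediction time; the
  project-only mode relaxes this but no incremental/streaming PCA is
  provided.
* No LD-aware simulation or LD pruning; supply a pre-pruned variant list
  when applying the pipeline to real data.
* Binary-trait base models use logistic ridge; no liability-scale mixed
  model is provided.
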