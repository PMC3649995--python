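# Methods

## Model

For one gene and one candidate SNP, expression in tissue s follows the
simple linear model

    y_si = mu_s + beta_s g_i + eps_si,    eps_si ~ N(0, sigma_s^2),

with dosages g coded 0–2.  All inference uses the standardized effect
b_s = beta_s / sigma_s, so results are invariant to the measurement scale
of each tissue's expression.  A *configuration* gamma is a binary vector
over the S tissues; b_s = 0 where gamma_s = 0, and where gamma_s = 1 the
effects follow the two-level prior

    bbar ~ N(0, omega^2),     b_s | bbar ~ N(bbar, phi^2).

omega sets the typical shared effect size and phi the between-tissue
heterogeneity; phi = 0 is the fixed-effects limit, and
phi^2/(phi^2 + omega^2) is the "heterogeneity fraction" (one minus the
prior correlation of effects across tissues).  A fixed grid of
(phi, omega) pairs — effect sizes {0.1, 0.2, 0.4, 0.8, 1.6} crossed with
heterogeneity fractions {0, 1/4, 1/2} (default) or {0, 1/4, 1/2, 3/4, 1}
(lite) — carries mixture weights lambda_l.  The Bayes factor BF(gamma; l)
compares the configuration model against the global null (all b_s = 0);
weighted averages over configurations (eta) and the grid (lambda) give
the BMA test statistic, and a per-gene average over the m_g cis SNPs
(within 1 Mb of the TSS, boundary inclusive) gives the gene-level
statistic under the at-most-one-eQTL assumption.

When tissues are measured on the same individuals, the per-individual
residual vector across tissues is modelled as correlated multivariate
normal; the correlation matrix is estimated from null-model residuals and
shrunk toward the identity (delta = 0.05) to guarantee positive
definiteness, and enters the Bayes factor through the error covariance
V_ij = r_ij se_i se_j.

## Bayes-factor computation

Exact evaluation integrates the nuisance parameters under limiting
diffuse priors, p(mu_s, sigma_s) ∝ 1/sigma_s.  At fixed b, both mu_s and
sigma_s integrate out of the single-tissue likelihood in closed-to-1D
form, leaving

    l_s(b) = -b^2 d/2 + log I(b) - log I(0),
    I(b)   = ∫ u^(n-2) exp(-a u^2/2 + b c u) du,

with a = |y_c|^2, c = y_c·g_c, d = |g_c|^2 (u = 1/sigma).  The production
approximation is a Laplace anchor: Newton iterations on l_s locate its
mode b* and curvature SD s*, and the configuration BF is the multivariate
normal density ratio

    BF = N(b*; 0, V + phi^2 I + omega^2 11') / N(b*; 0, V),

with V = diag(s*^2) (or the correlated form above).  Because the Gaussian
is fitted to the *exact* marginal likelihood rather than to the OLS
sampling distribution, agreement with direct numerical integration (the
`oracle` module: per-tissue 1-D quadrature nested in Gauss–Hermite
integration over the effect prior) is at the 10^-4 relative level in the
bulk and a few percent in the extreme-signal tail — the acceptance suite
asserts the median.

Two cheaper summary paths exist and matter for calibration. Standardizing
by the alternative-model residual SD inflates Bayes factors at strong
signals (t tails treated as normal); standardizing by the null-model SD
truncates them.  Both distort the hierarchical-model likelihood enough to
push the null-fraction estimate to the boundary, which is why the
Laplace-anchored summaries are used wherever Bayes factors feed inference
(bundles, posteriors, reported statistics).  Permutation testing is
immune to this — any deterministic statistic yields valid permutation
p-values — so the permutation path uses a fast quantile-normalized-t
summary (the t statistic mapped through its exact null CDF onto a
standard-normal z), which is exactly calibrated under the null and
vectorizes over hundreds of permutations at once.

All Bayes-factor arithmetic is in natural logs with log-sum-exp
averaging; strong-signal BFs overflow doubles long before their averages
do.  Outputs print log10 values.

## Hierarchical model and EM

Each gene is null with probability pi0 or carries one eQTL at a uniformly
chosen cis SNP with configuration ~ eta and grid point ~ lambda.  The
relative likelihood per gene is pi0 + (1-pi0)(1/m_g) Σ_jγl η_γ λ_l BF.
EM: the E-step computes each gene's null responsibility and the
within-alternative posterior over (SNP, configuration, grid point); the
M-step renormalizes the summed responsibilities.  Initialization is
pi0 = 0.9 with uniform eta and lambda (away from boundaries); convergence
is a relative log-likelihood change below 1e-6 (cap 300 iterations), and
monotonicity of the trace is asserted on every run.  lambda is estimated
jointly with eta by default; `fixed={"lambda"}` freezes it at uniform to
mimic fixed-grid analyses.  Confidence intervals are percentile bootstrap
over genes (resample, refit from the point estimate); the interval method
is a pragmatic choice — model-agnostic, no curvature formulas — and its
widths are not claimed to match any particular analytic interval.

The one-eQTL assumption is relaxed by a second pass: the top SNP per gene
(largest posterior probability of being the eQTL under the round-1 fit)
is regressed out of each tissue's expression, and the residuals enter the
likelihood as independent "artificial" genes — an approximation,
accepted for its simplicity, that slightly double-counts genes whose
residuals still carry signal.

## Significance

Gene-level p-values compare the observed statistic with its distribution
under permutations of individual labels, identical across tissues when
individuals are shared (this preserves intra-individual correlation under
the null).  The add-one estimator p = (1 + #{extreme}) / (n_perm + 1) is
used, ties counting as extreme (conservative and valid for any n_perm;
default 10,000, test suites use 100–200).  Per-gene permutation streams
are seeded by a CRC of (global seed, gene id), making parallel and serial
runs bit-identical.  Storey q-values use the lambda-grid smoother (lambda
∈ {0, 0.05, …, 0.95}, cubic polynomial evaluated at 0.95, clipped to
(0, 1]); below 20 p-values the estimate falls back to pi0 = 1
(Benjamini–Hochberg) with a warning.  The baselines are the
tissue-by-tissue minimum p-value (permuted separately per tissue for
per-tissue calling) and the pooled-variance ANOVA F test with
tissue-specific slopes and intercepts — S and N−2S degrees of freedom,
reducing to the squared-t test at S = 1.

## Synthetic data

The generator emulates the canonical study conditions: genotypes are
i.i.d. Binomial(2, MAF) with MAF 0.3 (Hardy–Weinberg, no LD); effects
are standardized, drawn from the two-level prior with the target
*expected* PVE fixing the scale through PVE = b²v/(b²v + 1),
v = 2·MAF·(1−MAF) (PVE 20% ⇒ scale 0.7715); expression is signal plus
Gaussian noise with per-tissue variances, optionally correlated within an
individual.  Three built-in scenarios:

- **power**: 5 tissues × 100 individuals, 2,000 gene-SNP pairs (one SNP
  per gene), half null, alternatives active in exactly q tissues, effect
  sizes drawn *across* the grid rescaled so the grid-average PVE is 20%
  (a single-point draw at PVE 20% saturates detection at this sample
  size and hides the differences between methods); error variances equal
  or cycling {1, 1.5, 2}.
- **sharing recovery**: 8 active configurations (all-shared, the five
  singletons, tissues 1–2, tissues 3–5) × 200 genes + 200 nulls, tissue 1
  with 60 samples and the rest 100.
- **consistent sharing**: 3 tissues × 75 shared individuals, half the
  genes null, 88% of eQTLs consistent across all three tissues (the
  remainder split among singleton and paired configurations in the
  proportions such data typically show), effects drawn across the default
  grid so per-tissue power is moderate and incomplete.

What the simulator does *not* emulate: linkage disequilibrium among cis
SNPs, multi-SNP architecture beyond the two-eQTL relaxation fixture,
non-normal expression noise, probe/mapping artifacts, population
structure, or confounder-driven covariance beyond a single exchangeable
intra-individual correlation.  Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to everything real data can do; the rank-normal transform and
PC removal in the preprocessing layer are the intended first defenses on
real data.

## Preprocessing defaults

Robust-gene filter: keep genes whose per-tissue mean expression is at
least the median of all expression values in that tissue, intersected
across tissues.  PC removal: per tissue, PCA of the gene × individual
matrix; components are removed while each explains at least 0.0025% of
total variance (the filter runs first, then PCA).  Rank-normal
transform: Phi^-1((rank − 0.5)/n) with average ranks for ties; an
all-equal vector degenerates to zeros with a warning.

## Numerical and design notes

- Full configuration enumeration is capped at S = 20 (2^S − 1 terms);
  beyond that the lite statistic (S + 1 configurations) is the intended
  tool.
- Degenerate perfect fits (zero residual variance) are errors, not
  infinite Bayes factors; monomorphic SNPs are errors at the regression
  layer.
- Missing genotypes/expression are dropped pairwise per tissue; the
  correlated-errors path requires a common-individual design and refuses
  otherwise.
- Posterior configuration probabilities condition on an eQTL being
  present (the null term is excluded from the normalization).
- Experiment sizes in the acceptance script (50 oracle pairs, 1,800 and
  2,000-gene studies, 200 permutations, 5,000 ANOVA replicates) were
  chosen to give stable estimates in minutes on one CPU; all scale up by
  argument.
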