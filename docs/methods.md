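# Methods

## Problem and model

Spatial transcriptomics (ST) assays — Visium spot arrays, GeoMx ROIs,
CosMx-SMI segmented cells — measure gene expression at known planar
positions. A routine analysis step is testing, per gene, whether expression
differs between a tissue domain (niche, cluster, cell type) and the rest of
the sample, or between two domains. Expression at neighbouring positions is
correlated, so treating units as independent (a two-sample t-test) misstates
the variance of the group contrast and, when the compared groups are
themselves spatially coherent — as tissue domains always are — inflates the
type-I error rate.

`stlmm` fits two Gaussian models to each gene's normalized log-expression
`y_s` at unit location `s` in domain `k`:

- **non-spatial**: `y_s = mu_k + eps_s`, `eps_s ~ N(0, sigma^2)`;
- **spatial**: `y_s = mu_k + U_s + eps_s`, with the random field
  `U ~ MVN(0, tau^2 exp(-D / rho))` over the matrix `D` of pairwise
  Euclidean distances, plus the iid nugget `eps`.

The exponential kernel is the smoothness-1/2 member of the Matérn family;
the covariance code accepts the distance matrix and the three variance
components `(tau^2, rho, sigma^2)` so other kernels could be added. The
design is always intercept + binary domain indicator, so the second fixed
effect `beta_1` is the mean log-expression difference of the focal group.

## Estimation

Variance components are estimated by numerically maximizing the restricted
likelihood (REML, default) or the marginal likelihood (ML). The restricted
likelihood follows the error-contrast definition (equal to the density of
`K'y` for an orthonormal contrast basis `K`, i.e. the profiled marginal
likelihood plus the `-1/2 ln|X'V^-1X| + 1/2 ln|X'X|` correction); note nlme
reports values offset by the constant `1/2 ln|X'X|`, which does not affect
estimates.

The search runs in two unconstrained coordinates — logit of the spatial
variance fraction `h = tau^2/(tau^2+sigma^2)` and log range rescaled by the
median pairwise distance — with the total variance and the fixed effects
profiled out analytically (GLS at each step). The range is bounded to
`[1e-3, 10] x` the maximum pairwise distance; outside that window the kernel
is numerically indistinguishable from iid noise or a constant. Three starts
(one central, two jittered from a seeded generator) guard against local
optima; L-BFGS-B runs per start. All likelihood evaluations go through a
Cholesky factorization; if factorization fails, jitter of
`1e-8 x mean(diagonal)` is added and retried up to 3 times, after which the
fit is declared non-converged. Non-convergence is recorded per test, not
raised, so pipelines can report attempted-vs-completed counts.

Model comparison uses `AIC = 2k - 2 ln(L)` with the *marginal* log-likelihood
evaluated at the fitted parameters for both models (`k = 3` non-spatial:
intercept, difference, `sigma^2`; `k = 5` spatial: + `tau^2`, `rho`), so the
two criteria are on the same scale; ties favor the non-spatial model. With
the ML objective the spatial family nests the non-spatial model at
`tau^2 -> 0`, so the maximized spatial log-likelihood is never below the
non-spatial one and on iid data the AIC gap approaches +4. When the fitted
range collapses below the lattice spacing, `tau^2` itself is unidentifiable
(the kernel is numerically the identity); the identifiable measure of fitted
spatial signal is the nearest-neighbour correlation `h exp(-d_min/rho)`.

## Inference

- Non-spatial fits: OLS coefficients; `sigma^2 = RSS/n` (ML, for the
  likelihood and AIC) and `RSS/(n-2)` for the coefficient covariance, so the
  Wald test with a `t(n-2)` reference is *exactly* the pooled two-sample
  t-test.
- Spatial fits: GLS coefficients with plug-in covariance
  `(X'V^-1X)^-1`. For testing, the covariance is inflated by the
  Kenward-Roger first-order correction (propagating the uncertainty of the
  fitted variance components through the inverse observed REML/ML
  information in log-parameter coordinates, second-derivative kernel term
  omitted) and referred to a Student t distribution with Satterthwaite
  effective degrees of freedom, clipped to `[1, n-2]`. A variance component
  on its zero boundary is held fixed and dropped from the free set; with no
  spatial variance at all, no adjustment is applied and the reference is the
  exact `t(n-2)`.

  This adjustment is load-bearing. On null data with two contiguous domains
  on a 10x10 hex grid and spatial fraction 0.8, GLS with the *true*
  covariance rejects at 4.8% (alpha = 5%), but the plug-in Wald test with a
  normal reference rejects at ~10%, entirely because the fitted
  `(tau^2, rho, sigma^2)` are treated as known. With the KR/Satterthwaite
  adjustment the empirical rate returns to ~4-5%. The asymptotic normal
  reference is recovered automatically as n grows (df -> n-2 and the
  information grows).

Multiple-testing correction is Benjamini-Hochberg, by default within each
comparison across genes (matching how per-domain marker tables are read); a
global family is available. The raw (not adjusted) p-values are used when
counting how often the spatial p exceeds the non-spatial p.

## Normalization and stratification

Counts are library-size normalized and natural-log transformed:
`expr = ln(counts / libsize x scale + 1)`, with `scale` defaulting to the
median library size across units. The scale factor and log base are package
choices (common ST practice; they keep values comparable across platforms).
Genes are stratified into high/low expression at the median of the per-gene
mean log-expression, genes exactly at the median going to "low"
(deterministic tie rule).

## Synthetic data

The generator draws expression exactly from the spatial model: per gene,
`baseline + effect(label) + sqrt(tau^2) L z + N(0, sigma^2)` with `L` the
Cholesky factor of the exponential correlation matrix — deliberately sharing
no covariance code with the fitter beyond the kernel formula. Layouts:
hex grid with nearest-neighbour distance = spacing (Visium-like), square
lattice, or uniform random points (imaging-platform-like). Domain labels are
spatially contiguous blocks (k-means partition of the coordinates — the
tissue-niche setting, and the configuration in which ignoring spatial
correlation actually inflates tests) or random assignment. Every quantity is
a pure function of (config, seed); per-gene substreams are spawned from the
master seed so results do not depend on evaluation order. Counts, when
requested, are Poisson draws from the exponentiated log-expression, for
end-to-end I/O tests only.

What the generator does *not* emulate: zero inflation, platform-specific
noise (segmentation error, ROI pooling, optical artifacts), multiple slides,
or mean-variance relationships of real counts. Passing calibration
experiments therefore demonstrate correctness of the statistical machinery
under the stated Gaussian model, not robustness to those real-data features.

## Study sizes used by the calibration experiments

These sizes (also used by `scripts/acceptance.py` and the acceptance tests)
were chosen so each experiment finishes in minutes on one core while leaving
Monte-Carlo error well below the effects being demonstrated:

- likelihood oracles: 100 random instances, n in [6, 12], tolerance 1e-8;
- t-test equivalence: 100 random datasets, tolerance 1e-10;
- iid limit (ML objective): 200 genes at n = 100;
- type-I error: 10x10 hex grid, two contiguous block domains, 500 null
  genes, alpha = 0.05, strong-correlation condition
  `(tau^2, rho, sigma^2) = (0.8, 3, 0.2)` (spatial fraction 0.8, range 3
  spacings) and iid condition `(0, -, 1)`; the nominal band is the central
  99% binomial interval. With 500 genes a perfectly calibrated test still
  lands outside a 99% band about 1% of the time per condition, so seed-level
  fluctuation of borderline rates is expected;
- AIC preference: 100 genes per condition at n = 100;
- recovery: truth `(1, 2 spacings, 0.25)`, 200 replicates at n = 100.
  Recovery is summarized by the relative error of the *median* estimate:
  the REML sampling distribution of `sigma^2` at n = 100 piles ~20-40% of
  its mass exactly at the zero boundary (verified against exhaustive grid
  search and an independent GLS implementation), so per-replicate relative
  errors are dominated by that boundary mass while the median estimate is
  accurate. Both summaries are reported.

## Known limitations

- Gaussian likelihood on log-normalized values; no count model, no
  zero-inflation handling — genes with many zeros in sparse platforms will
  violate the model.
- Only the exponential kernel is built in.
- One sample at a time; no slide-level random effects or cross-sample
  meta-analysis.
- The KR adjustment uses numerically differentiated information and is
  therefore approximate near variance boundaries; p-values there are
  reproducible but carry optimizer-level (~1e-3) noise rather than
  machine-precision determinism.
- Testing domains that were clustered on the same expression matrix is
  circular; results should then be read as cluster phenotyping, not
  discovery.
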