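# Methods

## The estimation problem

A forest inventory records, for a few thousand 1-ha plots with known planar
coordinates, the standing timber volume of a handful of commercially traded
tree genera. Multiplying volumes by averaged export prices (US$/m³) and by a
sawn-wood conversion efficiency gives a *gross* standing value per plot in
US$/ha — the revenue of the timber in place, deliberately ignoring
extraction and transport costs. The task is to interpolate that value
between plots, with a defensible uncertainty map, and to summarise the
resulting surface.

## Valuation

Per plot: `value_g = volume_g × price_g × c` for each genus g, summed to a
total; c is the conversion efficiency (default 0.35, the fraction of raw
standing volume recovered as sawn wood, which puts standing volumes on the
same footing as sawn-wood export prices). Duplicate (plot, genus) records
are summed first, since surveys typically record individual trees. Prices
are unweighted arithmetic means across the years supplied.

Totals are log-transformed, base 10, before any spatial modelling: plot
values are approximately log-normal, and kriging assumes at least
approximate Gaussianity. Because c is a pure multiplicative factor it is a
constant shift on the log scale; the pipeline therefore kriges *unscaled*
log values and applies c at back-transformation, so the choice of c cannot
influence the spatial model.

Plots with zero total value have no logarithm. The default policy excludes
them from the kriging data set (configurable to `offset`, which uses
log₁₀(total + ε)). Exclusion preserves the exact inverse pair
anti-log∘log = identity on the retained plots; an offset would bias the
back-transform everywhere, and nothing in the valuation model motivates a
particular ε.

## Semivariogram

Matheron's binned estimator, γ̂(h) = Σ(zᵢ−zⱼ)²/(2N(h)) over pairs in each
lag bin; default 12 equal-width bins spanning (0, half the maximum pairwise
distance], the common rule of thumb that keeps the estimator away from the
sparsely sampled long lags. Three isotropic families are provided
(spherical — the default, exponential, Gaussian), all parameterised by an
*effective* range: the exponential and Gaussian forms carry a factor 3 (3h/a
and 3h²/a², respectively) so a fitted range means "correlation has decayed
to ~5%" in every family and ranges are comparable across fits.

Fitting is weighted least squares with Cressie's weights N(h)/γ(h)²
(emphasising short lags and well-populated bins), bounds c₀,c ≥ 0, a > 0,
and a deterministic 9-point multistart over lag quantiles and nugget
fractions — the objective is mildly multimodal in the range and a single
start is not reliable. A flat empirical variogram drives c → 0 and pins the
range at its lower bound, with a warning: the field is then treated as pure
nugget.

γ(0) = 0 exactly; the nugget is the limit from the right. Consequently
kriging is an *exact interpolator*: a target coinciding with a datum
reproduces it, with σ = 0 when the nugget is zero. This is a modelling
choice (measurement-error filtering is the alternative); it matches the
usual map-making convention of honouring the data.

## Ordinary kriging

The standard (n+1)-system with a Lagrange multiplier enforcing Σλ = 1; the
kriging variance is σ² = λᵀγ₀ + μ, clipped at 0 against round-off.
Duplicate coordinates are averaged before fitting (the system is singular
otherwise). Neighbourhoods: `all` (dense solve) or k-nearest (default
k = 16, minimum 4, optional search radius), with distance ties broken by
ascending point index so predictions are reproducible to the byte.
Distances are Euclidean in projected km throughout; no geodesy — the
package assumes an equal-area projection upstream.

The `all` path is the reference: the test suite checks it against an
independently assembled dense solve on random small instances, and checks
exactness, Σλ = 1, shift equivariance and rigid-motion invariance.

## Moran's I correlogram

Per distance class (d₁, d₂]: binary symmetric weights wᵢⱼ = 1 iff
d₁ < dᵢⱼ ≤ d₂ (row-standardisation is deliberately not applied — binary
weights are the common correlogram convention and keep the hand-checkable
reference values exact). Significance is two-sided Monte-Carlo permutation
(default R = 999 for the standalone function): each replicate shuffles the
values once and evaluates every class on that shuffle, and
p = (1 + #{|I*| ≥ |I_obs|})/(R + 1), which is a valid p-value at any n. The
null expectation of I is −1/(n−1), and the suite verifies both that and the
test's empirical size (~5% at α = 0.05). No multiple-testing correction
across classes is applied, matching standard correlogram reporting.

## Validation

Leave-one-out cross-validation predicts each plot from all the others under
the fitted variogram (the variogram is not re-fitted per fold; at thousands
of plots the influence of one point on the fit is negligible and re-fitting
would square the cost). Calibration is judged by OLS of **observed on
predicted**: for any (near-)optimal linear predictor cov(ẑ, z) = var(ẑ), so
this slope has expectation 1 under a correctly specified model, while the
reverse regression has expectation r² < 1 — a smoothing predictor is
necessarily less variable than the data, so regressing predictions on
observations *must* flatten. The reverse direction is available behind
`direction="pred_on_obs"` for comparison. The 95% CI is t-based with n − 2
degrees of freedom.

A caveat the test suite quantifies: when the variogram is *estimated* from
the same data, estimation error leaks into the predictions and the
calibration slope acquires a small upward bias (~5% at 300 plots). The
calibration-coverage check therefore runs with the generating variogram;
the fitted-variogram route is exercised separately.

## Surfaces and summaries

Predictions are made at cell centres of a regular km grid (no block
kriging). Back-transformation is the naive anti-log
`value = c × 10^ẑ` — the convention of the analysis this package
implements; predictions of a log-value are medians, not means, of the
implied lognormal, so an optional bias-corrected mode
`× 10^{ln(10)·σ²/2}` is provided but off by default. A boolean forest mask
(same grid) removes non-forest cells before summarising. Summaries are
mean, empirical 2.5/97.5 percentiles, min, max and cell count of the
unmasked cells; the percentile interval describes the heavily skewed
*per-cell value distribution* (for strongly left-concentrated surfaces the
lower bound coincides with the bulk value), not a standard error of the
mean. Rasters are written as ESRI ASCII grids (nodata −9999) with
accompanying per-cell CSVs.

Per-genus surfaces and the total surface come from independent kriging
runs on genus values and totals respectively. Because the anti-log is
nonlinear, summing the 11 anti-logged genus maps does not reproduce the
directly kriged total map; the suite asserts the inequality.

## Synthetic survey generator

The generator is the package's study condition, not a convenience: ~2465
uniformly placed 1-ha plots on a 3500 × 2500 km domain; 11 genera with the
inventory's occupied-plot counts (21–1100 of 2465) as Bernoulli prevalences;
log-normal volumes with log-sd 0.8 and log-mean 1.23 (mean occupied-plot
volume ≈ 4.7 m³, the level implied by recorded per-genus totals such as
101.24 m³ over 21 plots); a spherical spatial structure on the log scale
(nugget 0.1, partial sill 0.9, effective range 200 km) plus a weak
west-to-east drift (2×10⁻⁴ log₁₀ units/km) creating a high-value corner.
Fields are drawn by Cholesky factorisation of the covariance (jitter 10⁻¹⁰
of the sill on the diagonal), and a field restricted to the occupied plots
is simulated directly at those plots. Everything is a pure function of
(config, seed).

Presence is i.i.d. Bernoulli by default; an optional clustered mode
thresholds a second latent field at the prevalence quantile. What the
default does *not* emulate: floristic composition, soils or climate (the
gradient is phenomenological), within-plot tree counts (volumes only), and
spatially clustered presence. A visible consequence — worth knowing when
reading pipeline output — is that the *total* plot value is dominated by
which genera happen to be present, so its variogram is nugget-heavy and
kriging of totals on this fixture is honest but weak. Passing tests
therefore demonstrate correctness of the machinery and calibration of the
uncertainty statements, not that any particular real landscape is
predictable.

## Problem sizes and defaults

Routine runs and the test suite use a coarse prediction grid (~50 columns
across the extent; the cell size is configuration, and `GridSpec` supports
arbitrarily fine grids such as 0.5-km cells). The pipeline's default
permutation count is 199 — a resolution of 0.005 in p, adequate for a
diagnostic; the standalone correlogram default is 999. The calibration
experiment uses 300 plots on a 1200 × 900 km domain, preserving the default
fixture's plot density so the spacing-to-range ratio matches the full-size
conditions. Genera with fewer than 5 valued plots are skipped (with a
warning) rather than kriged from a hopeless variogram.

## Known limitations

- Isotropic models only; no universal/co-kriging, no anisotropy, no block
  kriging.
- Planar Euclidean distances; results depend on the upstream projection
  being near equal-area over the domain.
- The naive anti-log is biased low as an estimator of the lognormal mean;
  the bias-corrected mode depends on σ being well estimated.
- Variogram fitting is WLS on binned estimates — simple and transparent,
  but less efficient than REML at small n.
- The permutation test assumes exchangeability under the null; trends in
  the mean inflate apparent autocorrelation at long lags.
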