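# Methods

## Model

Counts for gene *g* in unit *i* are treated as independent negative
binomial, y_gi ~ NB(μ_gi, ω_g), Var(y) = μ + ωμ², with log-linear mean

    log(μ_gi) = o_i + β_g0 + Σ_{j∈S} x_ij' β_gj.

Categorical variables are reference-coded (first declared level is the
reference; block width = levels − 1), continuous variables enter as given,
and every model contains an intercept and the primary factor (variable 1).
The offset o_i is the natural log of the 0.75 quantile of unit *i*'s counts,
computed with the linear-interpolation ("type 7") quantile convention and
**after** gene filtering; both the quantile order and the filter thresholds
are arguments.  Genes are filtered by mean count (default ≥ 8) and zero
fraction (default ≤ 27/31), the customary low-count exclusion for a
31-unit study.

This working model deliberately ignores sources of structure that the
quasi-likelihood layer is meant to absorb: per-gene dispersion
misspecification, mild dependence across genes, and residual technical
variation.

## Fitting and dispersion estimation

Coefficients are estimated by iteratively reweighted least squares with the
dispersion fixed: working weights μ/(1 + ωμ), step-halving whenever the
deviance would increase, at most 50 iterations, convergence when the
relative deviance change falls below 1e−8.  Linear predictors are clipped
to |η| ≤ 30 to keep intermediate iterates finite; a 1e−10 ridge guards the
normal equations against exact singularity.  Because all genes share one
design matrix, the solver is vectorized across genes (batched weighted
least squares), which is what makes repeated whole-transcriptome refits
during backward selection affordable.  The ω = 0 limit is exact Poisson
regression (verified in the test suite against an independent IRLS
implementation).  The likelihood-ratio statistic for dropping a variable is
the deviance difference between nested fits sharing the same ω; reduced
fits are warm-started from the full fit's coefficients, and any residual
negative difference from numerical noise is clipped to zero.

The NB dispersion is estimated per gene by the moment formula
ω̂ = max{0, Σ[(y−μ̂)² − μ̂] / Σ μ̂²} with μ̂ from a Poisson fit of the same
design.  Two modes are offered:

* **trend** (default): ω̂ is pooled — the median of the moment estimates
  within 10 mean-count bins.  Gene-specific departures from the pooled
  dispersion then remain visible to the quasi-dispersions below.
* **gene**: each gene keeps its own moment estimate.

The default matters for calibration.  With gene-specific ω̂ the residual
deviance of every gene is pulled toward its degrees of freedom — the moment
estimator absorbs exactly the spread that the quasi-dispersion hierarchy is
supposed to model — so the estimated prior degrees of freedom diverge, the
F-reference degenerates to its chi-square limit, and the test's upper tail
is too light: in scenario-1 simulations the realized FDR at a nominal 5%
threshold was roughly doubled, and the all-null rejection fraction at 0.05
was ≈ 0.06.  With the pooled default the hierarchy is identifiable
(d0 ≈ 10–15 in the bundled simulations), the null rejection fraction is
≈ 0.05, and realized FDR tracks the nominal level.

## Quasi-likelihood F-tests

For the full model on S with p columns and df_res = n − p, the raw
quasi-dispersion is φ̂_g = deviance_g / df_res (stored unfloored; a 1e−8
floor is applied only where φ enters an F denominator).  Shrinkage assumes
φ̂_g/φ_g ~ χ²_df/df and a scaled inverse-chi-square prior with d0 degrees
of freedom around a mean-count trend, so that φ̂_g/trend_g is approximately
F(df_res, d0).  The trend is a 4-df natural cubic spline of log φ̂ on mean
log counts (knots at quantiles, linear extrapolation beyond the boundary;
below 10 usable genes the trend is the constant geometric mean).  d0 is
recovered by matching the variance of log(φ̂/trend) to
trigamma(df_res/2) + trigamma(d0/2) (Newton inversion of the trigamma);
when the observed spread does not exceed the sampling noise floor, d0 = ∞
and φ̃ = trend.  Otherwise

    φ̃_g = (d0·trend_g + df_res·φ̂_g) / (d0 + df_res),

a convex combination lying between φ̂_g and trend_g.  The test statistic
F = (LRT/df1)/φ̃_g is referred to F(df1, d0 + df_res) (chi-square limit
when d0 = ∞); the denominator degrees of freedom can never fall below
df_res.  Shrinkage is recomputed at every backward-selection iteration from
that iteration's full model.  Genes whose fit fails carry NaN p-values and
are excluded per-iteration from relevance and rejection counts.

## Multiple testing

m0 (the number of null genes) is estimated by the iterative equal-bin
histogram method: 20 right-closed bins on [0,1] (p = 0 in bin 1), starting
from m0 = m; at each step the leftmost bin whose count is ≤ m0/20
determines the tail whose total is rescaled; iteration stops at a fixed
point (cap 100), and the result is clamped to [0, m].  q-values follow
Storey's construction with the plug-in m0: q_(i) = min_{j≥i} min{1,
m0·p_(j)/j}, ties sharing a value, capped at 1.  Rejection counts use the
inclusive comparison q ≤ α.

## Relevance measures and selection rules

The p.05 measure counts p-values **strictly** below 0.05.  The GKS measure
is √m times the supremum of F̃_m(x) − x over (0,1), where F̃_m is the least
concave majorant of the p-value ECDF — the distribution-function view of
the Grenander decreasing-density estimator.  The majorant is the upper
convex hull of {(0,0)} ∪ {(p_(i), i/m)} ∪ {(1,1)} via a monotone-chain
scan; since a concave piecewise-linear function minus the identity attains
its supremum at a hull vertex and the anchors contribute zero, evaluating
at the knots is exact and the statistic is non-negative.

Tie rules, fixed deterministically: among equally least-relevant
covariates, the one with the largest original index is removed (earlier
declared variables are presumed more important); any minimal tie that
includes the primary factor stops the procedure.  The selected iteration ℓ*
is the smallest maximizer of R_ℓ(α), so ties favor the larger model.
Re-running with the same inputs reproduces the trace exactly.

## The synthetic-data generator

The generator emulates a small two-group RNA-seq study (n = 31 units,
group split 16/15, mimicking divergent selection lines) with gene-specific
log-linear models:

* variables: the two-level primary factor `line`; four independent N(0,1)
  continuous covariates; one three-level categorical covariate (`block`,
  uniform over levels); and, in the confounded designs, a continuous
  covariate `trait` = δ·1(line = L1) + N(0,1) with δ = 2 (group means two
  noise SDs apart), optionally centered within lines;
* per-gene parameters: intercept N(3, 1) on the log scale (typical mean
  count ≈ 20 at unit depth); covariate effects N(0, 0.25²) restricted to
  the gene's relevant set; for DE genes a primary-factor effect N(0, 0.5²)
  resampled to exclude (−0.1, 0.1) so the DE/EE boundary is unambiguous;
  NB dispersion lognormal with median 0.1 and log-SD 0.6 (90% of genes in
  ≈ [0.04, 0.27]);
* offsets: log of Uniform(0.8, 1.25) depth jitter around a common constant;
* π0 controls the exact (rounded) count of EE genes, whose primary-factor
  block is identically zero.

Three regimes: scenario 1 gives every gene the common relevant set
{line, cov1, cov2, block}; scenarios 2–3 partition genes equally across the
nested chain {line, cov1, cov2, block, trait} ⊃ {line, cov1, cov2, block} ⊃
{line, cov1, cov2} ⊃ {line, cov1}, with `trait` confounded (scenario 2) or
centered within lines (scenario 3).  A gene counts as DE only if its
primary-factor block is nonzero under its *own* relevant set; a rejection
at a gene whose expression is driven by the omitted confounded covariate is
therefore a false discovery — the mechanism the scenario-2/3 contrast
isolates.  Covariates are drawn once per study and held fixed across
replicates; all remaining randomness is spawned deterministically from the
base seed, so scenario-2 and scenario-3 runs with the same seed are paired
replicate-for-replicate.

Strategies scored by the driver: backward selection (either relevance
measure), the full model, the primary factor alone, and an oracle fitting
each gene's true relevant set (genes sharing a set are fit and shrunk
together; their p-values are pooled into one q-value family).  Metrics per
replicate: FDP = V/max(R,1); NTP; and the raw trapezoidal partial AUC of
the ROC of 1 − p scores up to FPR = 0.05 (perfect separation 0.05, useless
scoring 0.00125 in expectation).

What the generator does **not** emulate: dependence between genes, library
composition effects, outlier counts and zero inflation, covariate
measurement error, and effect-size distributions estimated from any real
dataset.  Passing benchmarks therefore demonstrate the procedure's internal
error control and power under a faithful NB world, not performance on any
particular real study.

## Problem sizes used in the bundled studies

The packaged benchmarks run at m = 1000 genes (2000 for null-calibration
checks), n = 31, 15–20 replicates per condition, π0 ∈ {0.6, 0.9} for the
error-control study and π0 = 0.6 for the confounding contrast — sizes at
which the Monte-Carlo standard errors are small relative to the effects
being demonstrated while a full study completes in minutes on one core.

## Known limitations

* The quasi-likelihood p-values are approximate at n = 31; the all-null
  rejection fraction at 0.05 sits near 0.05–0.06 rather than exactly 0.05.
* The confounding contrast requires the primary factor to carry enough DE
  signal that the confounded covariate can become the least relevant
  variable.  At π0 = 0.9 under the scaled-down defaults the primary
  factor's relevance (~70/1000) falls below the confounded covariate's
  (~145/1000), the covariate is never dropped, and the false-discovery
  mechanism cannot express itself; the contrast is therefore demonstrated
  at π0 = 0.6, where the generator's absolute false-discovery counts are
  largest.
* The oracle strategy shrinks quasi-dispersions within relevant-set groups
  rather than across all genes, which slightly weakens its shrinkage at
  small group sizes.
* q-value FDR control is marginal, not simultaneous across the selection
  path; the selected model's DE calls inherit the usual caveats of
  post-selection inference, mitigated (as argued in the literature on this
  procedure) by the fact that any single gene has negligible influence on
  the selected covariate set.
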