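# Methods

## Scope and model

`fullsubsets` implements full-subsets model selection over generalized
additive models. The unit of analysis is a *candidate model*: a set of
terms drawn from a vocabulary built out of the declared predictors —
univariate smooths, parametric linear terms, factor main effects,
factor:factor interactions, by-variable smooths (one smooth of a
continuous variable per level of a factor or factor interaction), and
bivariate tensor smooths. Fixed *null terms* can be forced into every
model; the baseline "null model" contains only those (or only an
intercept).

All candidate models are fitted to the identical row set: rows with a
missing value in the response or any declared predictor are removed once,
up front, and the count is logged. Information criteria are not
comparable across differing row sets, so per-model deletion is
deliberately not offered.

## Candidate-set construction

Model enumeration takes all combinations of 1..`max_predictors` terms
plus the null model, then prunes with five checks, logging for each
removed model the lowest-numbered check that caught it:

1. footprint (the set of raw predictor names a model touches, null terms
   excluded) larger than `max_predictors` — possible once interaction
   terms enter, since a factor interaction contributes both factors, a
   by-smooth its continuous variable plus all by-factors, a tensor both
   margins;
2. a by-smooth without its by-factor as a main effect; when the
   by-variable is a factor interaction we require the interaction term
   *and* both marginal mains (standard marginality — a deliberately
   strict reading, documented as a design choice);
3. the same continuous variable inside a by-smooth and as a single
   smooth/linear term;
4. the same continuous variable inside a tensor and as a single term;
5. a footprint pair (including by-factor names) disallowed by the
   inclusion matrix.

Pruning is order-independent and equals, by construction and by
exhaustive test, a brute-force power-set filter. Model identifiers are
canonical term strings sorted and joined with `+`, which fixes table
order and deduplication.

## Collinearity screen

Pairwise association is estimated on a common [0, 1] scale: absolute
Pearson correlation (continuous-continuous), correlation ratio
sqrt(SS_between/SS_total) (continuous-factor), Cramér's V
(factor-factor). All three reduce to |r|-like behaviour in the
all-continuous case for which the default cutoff 0.28 was proposed.
Exclusion is strictly greater than the cutoff; a pair exactly at the
cutoff co-occurs. Cyclic variables are screened as ordinary continuous
variables — no circular correlation estimator is used, a documented
simplification. Users can bypass the derived matrix entirely with their
own 0/1 inclusion CSV (e.g. built from VIF diagnostics elsewhere);
multi-way collinearity measures are out of scope.

## The reference backend

Fitting is behind a backend contract (capability flags + `fit(spec,
data) -> FitRecord`); a backend must return a failed record rather than
raise. The in-package reference backend fits penalized regression
splines:

* **Bases.** Cubic regression margins are degree-3 B-splines with
  interior knots at quantiles of the training data and a second-order
  difference penalty (for k = 3, degree 2). Cyclic margins use periodic
  B-splines on [0, period] built by wrapping an extended knot sequence,
  with a circular difference penalty; the basis is exactly periodic, so
  f(0) = f(period) holds to machine precision. Knot boundaries for
  cyclic smooths are pinned to the declared period (lunar day 29.53,
  month 12, ...), since cyclic continuity is meaningless without one.
  The declared k is applied unchanged to cyclic margins; the wrapped
  basis has k functions before centering.
* **Identifiability.** Every smooth block is centred (sum-to-zero over
  training rows) by projection onto the null space of its column-mean
  vector, keeping intercept and factor mains estimable.
* **By-smooths** replicate the centred marginal basis per level and
  share one smoothing parameter across levels (block-diagonal penalty).
  Sharing keeps the smoothing-selection dimension low; per-level
  smoothing parameters are a known refinement not implemented here.
* **Tensors** are row-wise Kronecker products of the two marginal bases
  with one penalty (and one smoothing parameter) per margin; each margin
  keeps its own basis, so cyclic x non-cyclic surfaces are allowed.
  Marginal k reuses the global k — one knob, matching the single `k`
  argument. No tensor of a by-smooth is ever generated.
* **Estimation.** Gaussian models solve penalized least squares
  directly (with cached Gram matrices); binomial (logit) and poisson
  (log) use penalized IRLS to a 1e-9 relative deviance tolerance, at
  most 100 iterations. Smoothing parameters minimize
  GCV(λ) = n·D/(n − γ·edf)² with γ = 1.4, the standard
  degrees-of-freedom inflation that guards against GCV's tendency to
  undersmooth; optimization is Nelder-Mead on log λ (clipped to ±15)
  from a trace-ratio starting point. Everything is deterministic:
  identical data and configuration give identical records, and parallel
  execution (process-level map over independent fits via joblib) is
  contractually identical to sequential.
* **Degrees of freedom.** edf = tr[(X'WX + Σλ_j S_j)⁻¹ X'WX];
  unpenalized columns (intercept, parametric terms) count 1 each. The k
  fed to AICc/BIC is this edf plus one for the gaussian scale. This is
  the penalty-adjusted notion — nominal basis dimension would grossly
  over-penalize shrunk smooths — so AICc values are not comparable with
  unpenalized-GLM conventions. A cubic-regression smooth cannot shrink
  below ~1 edf (its straight-line component is unpenalized); a centred
  cyclic smooth can shrink to ~0.
* **Likelihood.** Gaussian log-likelihood is evaluated at the MLE scale
  (RSS/n); poisson and binomial use their exact log-mass. Deviance
  explained is 1 − D/D_null with the null deviance from the closed-form
  intercept fit (the response mean, exact for all three canonical-link
  families).
* **Random effects** are reserved in the contract (`random_terms`) but
  rejected by the reference backend with a capability failure; mixed
  GAMs, correlation structures and additional families (Tweedie,
  negative binomial, ...) are out of scope.

Degenerate inputs — constant smooth margins, factors with one observed
level after row filtering, more columns than rows, non-convergence —
become failed records naming the offender; the run continues and the
failures are reported in their own artifact.

## Inference

AICc uses the Hurvich-Tsai correction; a model with n − k − 1 ≤ 0 has
undefined AICc, is flagged, warned about, and excluded from weights.
Akaike weights are computed from deltas for overflow safety, separately
under AICc and BIC (both are reported; importance defaults to AICc and
is switchable). Failed fits carry no likelihood and are excluded from
normalization rather than imputed. The comparison table sorts by AICc
with deterministic tie-breaking (smaller footprint first, then model
id). R² is deviance explained by default, or the squared correlation of
observed and fitted values (`r2_type="cor"`). Importance is the raw
summed weight per predictor (null-term predictors, present everywhere by
construction, are not scored) with a clearly-labelled rescaled variant
(raw/max); the raw sum remains the primary metric given the known
caveats around summed-weight importance.

## Synthetic scenarios

The generator draws correlated continuous predictors through a Gaussian
copula (exact Pearson targets with normal margins), cyclic predictors
uniform on [0, period), factors as categorical draws, and responses from
a fixed shape library (linear, quadratic, full- and half-period cosines,
per-level offsets and per-level curve modulation) plus family noise; one
seeded generator stream makes a scenario byte-identical per seed.

The library's defaults are the study conditions used by the tests and
the acceptance script:

* `habitat` (n = 200): three continuous metrics, two generated at
  correlation 0.6 (above the 0.28 cutoff), plus a two-level zone factor;
  gaussian.
* `predator` (n = 250): three uncorrelated continuous predictors,
  poisson counts declining with predator density.
* `gastropod` (n = 500): lunar day (period 29.53) and month (period 12)
  crossed with species and sex; a strong semilunar species-specific
  cycle (amplitudes −1.5/+0.5, minima at days 0 and ~14.8 for the strong
  species), species-specific annual cycles (amplitudes 1.0/1.5 peaking
  in Feb-Mar and July), and additive species and sex offsets (1.0 each).
  The noise scale 2.23 is set so the declared effects explain ≈28% of
  the response variance; intercept 8 keeps the index in a realistic
  range. Analysis settings: factor-smooth interactions on,
  max_predictors 4 (the true structure touches four predictors).
* `one_active` (n = 300): four mutually uncorrelated standard-normal
  predictors, response a quadratic function of one with noise variance
  half the signal variance (signal-to-noise 2).

What the generator does *not* emulate — and what passing tests therefore
do not establish about field data: spatial/temporal autocorrelation,
zero inflation, overdispersion, unbalanced factor designs, measurement
error in predictors, and non-monotone marginal transformations of the
copula draw.

## Problem sizes and verification

The test suite runs the enumeration-equivalence oracle over 48
predictor-set x interaction-switch configurations, and the stochastic
recovery checks over 20 seeded replicates each of the `one_active` and
`gastropod` scenarios (a few seconds per batch at these n). On these
conditions the active predictor's mean summed-weight importance is 1.0
against ≈0.33-0.44 for inactive predictors (an independent
closed-form OLS oracle puts the expected inactive value near 0.34), and
the true gastropod structure attains the minimum AICc in ≥16 of 20
replicates with a cyclic periodicity gap at machine zero. The backend is
cross-checked against an independent penalized-spline implementation
(statsmodels `GLMGam`) on a single-smooth fit: fitted curves agree to an
RMSE well under the residual standard deviation and deviance explained
to two decimals.

## Known limitations

* Summed Akaike weights are a contested importance metric; the full
  fitted-model registry is exported precisely so users can do
  model-averaged prediction or alternative importance analyses
  downstream.
* GCV (even with γ = 1.4) can differ from REML/ML smoothing in small
  samples; the selection criterion is fixed and documented rather than
  configurable to keep runs reproducible.
* The formula dialect is for interoperability/round-trip only; arbitrary
  external formulas are not parsed.
* Three-way interactions, shrinkage/double-penalty bases, and
  model-averaged standardized coefficients are out of scope.
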