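# Methods

This note records the statistical model, the choices made where the design
was genuinely open, the calibration of the synthetic world, and what the
tests do and do not establish.

## Outcome and exposure construction

The outcome is a four-item health-education score.  Each item is an
integer 0–8 ("do not know" scores 0), the total is their sum on 0–32.
Because zero totals occur, the log transform is `ln(1 + total)`; the raw
total is always retained, and every stage accepts either via a flag.  The
regression stage defaults to the log outcome (the exposure coefficient
then reads as a semi-elasticity); the concentration analysis defaults to
the raw score.

The exposure is the first principal component of five household-
consumption dimensions, each a reverse-coded five-point Likert response
mapped to [0, 1].  PCA is computed on the correlation matrix (columns are
z-scored first), which is the standard choice for mixed-scale asset/
consumption indices and makes the composite invariant to positive affine
rescaling of any input dimension.  Sign convention: the largest-magnitude
loading is positive.  The composite is min–max standardized to [0, 1]
(the composite score, not each item).  Internal consistency is summarized
by Cronbach's α with n−1 variances.

Quantile grouping uses cut-points that are linear-interpolation quantiles
of the *distinct* values, with boundary ties assigned to the lower group;
grouping is infeasible when distinct values are fewer than groups.

## Concentration index, curve, decomposition, inequity

- Fractional ranks are weighted midpoint ranks; a tied block shares the
  block's midpoint, so the weighted mean rank is exactly 0.5.
- `CI = 2 Cov_w(y, R)/μ` with weighted population covariance.  The SE is
  the HC1 slope SE of the convenient regression `2 σ²_R y/μ = a + b R`
  (its WLS slope equals the CI identically, which the tests assert).
- Sign convention is the standard one: CI > 0 ⇔ curve below the diagonal
  ⇔ pro-rich concentration.  (The motivating text's verbal curve reading
  is internally inconsistent; we do not follow it.)
- With midpoint ranks, twice the signed area between the diagonal and the
  piecewise-linear concentration curve reproduces the covariance CI
  almost exactly; the acceptance suite checks agreement on random
  weighted tables at O(1/n).
- The Wagstaff decomposition regresses the CI outcome on the factor set
  by weighted OLS; contribution of factor k is `2 β_k Cov_w(x_k, R)/μ`,
  the residual is `2 Cov_w(ε̂, R)/μ`, and the adding-up identity is a
  hard assertion on every call.  Percent contributions are reported
  relative to the CI.  One-hot fixed-effect blocks are decomposed
  dummy-by-dummy and reported aggregated per block.
- The decomposition covariate set in the pipeline is the exposure plus
  the Lasso-selected controls plus the fixed effects — the residual is
  still computed and reported, never assumed zero.
- `HI = CI − Σ_need η_k C_k` with default need set {gender, education
  years, health status, age²}.  The printed equation in the source text
  subtracts need, non-need and error terms, which would make HI
  identically zero; the text's verbal definition (subtract need only) is
  implemented.
- No Erreygers/Wagstaff bounded-outcome normalization by default (the
  headline numbers being emulated use the plain CI on a 0–32 score); both
  corrections are available: Erreygers `4μCI/(b−a)`, Wagstaff
  `CI(b−a)μ/((b−μ)(μ−a))`.
- Uncertainty for HI and decomposition shares, which have no closed-form
  SE here, comes from a seeded nonparametric row bootstrap (default
  1,000 draws when enabled).  Bootstrap refits exclude the fixed-effect
  dummies: resampling empties small community cells, and the per-draw
  OLS would dominate runtime.  Stars are per-row tests; no
  multiple-testing correction is applied.

## Lasso and post-double selection

Objective `(1/2n)‖y − β₀ − Xβ‖² + λ Σ pf_j |β_j|`, intercept unpenalized,
columns standardized internally (population SD), coefficients returned on
both scales.  The 1/2n scaling makes λ sample-size-free; published λ
values with an unstated scaling are not comparable to ours.  Solver:
cyclic coordinate descent with soft-thresholding on the Gram matrix,
active-set iteration with full-sweep confirmation, warm starts along a
50-point log-spaced grid from λ_max down to 10⁻⁴λ_max; convergence when
the maximum coefficient change falls below 1e-8 (hard failure with the
last change reported otherwise).  Cross-validation uses a seeded random
partition into 10 folds; the per-fold Gram matrices are obtained by
downdating the full-data cross-products.  Selection takes the
out-of-fold-MSE minimizer, ties broken toward the larger (sparser)
penalty; a 1-SE rule is available.  Penalty loadings are uniform.

Post-double selection: Lasso of outcome on controls, Lasso of exposure on
controls, OLS of outcome on exposure ∪ union with HC1 SEs.  City and
community fixed effects are penalized like any column during selection
but always included in OLS stages; communities nest within cities, so the
full-rank parameterization is city dummies (base: first city) plus
within-city community dummies (base: first community per city).  Age
enters as age² by default (the emulated covariate list defines the age
variable that way), with raw age behind a flag.  Inference is reported
for the exposure only; post-selection inference for the controls is out
of scope.

## The synthetic world

The generator is the package's stated world, fixed once:

- **Rank structure.**  A latent consumption factor Z₀ ~ N(0,1); each
  covariate's latent normal correlates with Z₀ at `2 sin(π ρ_s/6)` so the
  *continuous* Spearman correlation hits the target ρ_s exactly.
  Discretized marginals (binaries, Likert items, quantile groups)
  attenuate the observed rank correlation by roughly ×0.9; the ≤0.05
  achievement tolerance is asserted on the continuous/latent scale.
  Default targets: annual/monthly income 0.40, education 0.30, age 0.25,
  health status 0.20, insurance 0.15, married 0.10, rural −0.25,
  gender 0.03.
- **Marginals.**  Gender Bernoulli(0.51), married 0.59, rural 0.44,
  insurance 0.37; education years on {0,6,9,12,16,19} with mean 9.89;
  age truncated-normal (35, 11.3) on [18, 80]; health status ordinal 1–5;
  income groups are exact latent quantile groups (monthly 4, annual 6);
  85 cities, 301 communities with N(0, 0.05) effects each.
- **Consumption battery.**  Five equicorrelated items, loading 0.765 on
  Z₀, discretized to five Likert levels mapped to [0,1] — chosen so that
  Cronbach's α ≈ 0.85 *after* discretization.
- **Outcome.**  Log-scale latent `y* = 2.53 + 0.30·C + Σ β_k x_k + city +
  community + ε`, ε ~ N(0, 0.60); C is the PCA composite computed from
  the generated items by the same routine the pipeline uses, so recovery
  of the 0.30 effect is free of errors-in-variables attenuation.  Score
  `t = clip(round(e^{y*} − 1), 0, 32)`, split into four exchangeable 0–8
  items by a symmetric multivariate hypergeometric draw (items always sum
  to the total).  `discretize=False` keeps t continuous, which the
  exact-identity tests and the recovery experiment use.
- **Calibration** (all targets stated up front, knobs then fixed):
  outcome mean/SD land at 12.33/7.84 against targets 12.17/7.72 — the
  0–32 ceiling (~4.7% of rows at 32) eats part of the upper tail, so the
  SD target is met to ~1.5% rather than exactly; the age² coefficient
  (−2.2e-4, the emulated study's lone negative individual coefficient)
  is the knob that lands the population CI of the score at 0.0320 ≈
  0.032, estimated by `expected_ci` as a single 1.5·10⁶-draw Monte-Carlo
  (exact 0 is returned in the all-null world, where it is a closed form).
- **Weights.**  Uniform by default; `stratified` assigns inverse
  city-sampling-fraction weights.  The original stratum-construction rule
  (30-respondent minimum per stratum) is not reproduced.

What the generator does *not* emulate: snowball/WeChat recruitment,
non-response, item-level missingness, spatial correlation beyond
city/community intercepts, or the printed education-years SD of 7.67
(internally inconsistent with a 0–20 support and the level coding; the
mean is matched instead).  A green test on this world shows the
estimators recover a known linear DGP with realistic marginals — not that
the original study's numbers are correct.

## Numerical choices and known limitations

- **Discretization attenuates.**  With the Table-1-calibrated noise level,
  the 0–32 rounding/ceiling attenuates the recovered exposure coefficient
  by ≈ −0.02 (measured at n=7,715).  The parameter-recovery acceptance
  test therefore runs in the continuous-outcome mode, where the
  estimation model holds exactly and the estimator is conditionally
  unbiased; the attenuation in the discretized world is a property of the
  measurement process, not of the estimator.
- Ties in ranking variables share midpoint ranks; ties in CV error pick
  the sparser model; the PCA sign convention breaks the eigenvector sign
  ambiguity deterministically.
- Degenerate inputs fail loudly with typed errors (configuration / data /
  numerical), which the CLI maps to exit codes 2/3/4.  Within-stratum
  analyses degrade gracefully: strata below the size floor, with constant
  ranking, or with collinear factors are skipped with a logged warning.
- Determinism: one root seed feeds named substreams (generator, CV folds,
  bootstrap); `results.json` is byte-identical across runs with the same
  config and seed (timestamps live only in the manifest).  The serialized
  concentration curve is decimated to ≤513 points; full-precision curves
  are available from the API.
- The CI's convenient-regression SE ignores the sampling variability of
  the estimated PCA weights and of the Lasso selection step; the
  bootstrap covers the ranks and the decomposition OLS but reuses the
  pooled composite.  Dominance tests between curves and longitudinal
  indices are out of scope.
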