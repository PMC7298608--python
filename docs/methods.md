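# Methods

This note records the statistical model the package implements, the design
choices made where several defensible options existed, and what the
synthetic surveys do and do not establish about behaviour on real data.

## The spatial linear mixed model

The stacked observations are modelled as `y = X τ + η + ε`. Rows are
(variable, site) pairs; in the trivariate predictive model the variables
are the target grain's log Se concentration (y₁), the other grain's log
concentration (y₂) and a soil-based fixed-effects prediction of the target
grain available at every site (y₃). The random structure is a linear model
of coregionalization with a single shared Matérn correlation:

* `η` — spatially correlated effects, covariance `S[u,v] · ρ(h)` with
  ρ(h) = 2^(1−κ)/Γ(κ) (h/φ)^κ K_κ(h/φ);
* `ε` — nugget effects, covariance `T[u,v]` shared only between co-located
  rows. Because exactly one crop is observed per site, the teff–wheat
  entry of `T` is a structural zero, enforced exactly in the
  parameterization rather than penalized.

Distance is scaled as h/φ with no √(2κ) factor, so fitted φ values are
comparable across κ only qualitatively. φ is in km on a projected plane;
all distances are Euclidean.

### Estimation

Variances are packed as logs, correlation matrices through hypersphere
(Cholesky-angle) coordinates — every real vector therefore decodes to a
valid positive semi-definite structure, and the structural zero is a
pinned angle. κ is never estimated jointly; it is fixed and, when needed,
profiled over the grid {0.25, 0.5, 1, 1.5, 2, 3}.

Two fitting paths minimise the same objective:

* **single-variable models** use an exact profile likelihood: for each
  candidate φ on a log-spaced grid (18 points up to twice the maximum
  pairwise distance, then a bounded refinement) the Matérn correlation
  matrix is eigendecomposed once; the spatial share w = σ²/(σ²+τ²) is
  profiled on a coarse-then-fine vectorized grid and the total variance
  analytically. This path is exact, deterministic and fast, which matters
  because the selection procedure refits the model at every hypothesis
  test.
* **multivariate models** minimise the packed negative log-likelihood
  with a common variance scale profiled out analytically (the packing is
  scale-redundant; profiling removes a flat direction). The search runs a
  quasi-Newton descent (L-BFGS-B with an analytic gradient, built from
  d logdet = tr(W dV) and d(y'Py) = −(Py)' dV (Py); the per-parameter
  traces collapse to p×p contractions of block sums, so a gradient costs
  about three function evaluations) from several dispersed starts,
  followed by a short Nelder–Mead kick from the best point and a final
  gradient polish. Starts are seeded from the univariate marginal fits
  with cross-correlations 0 and ±0.4 and φ spread over a factor of six.
  Inside the optimizer the Matérn correlation is interpolated from a
  2000-point log-spaced distance table (relative error ≲ 1e−7); the
  public likelihood function evaluates the Bessel form exactly.

Fixed effects follow by GLS at the covariance optimum; standard errors
come from (XᵀV⁻¹X)⁻¹ with no small-sample correction. Fixed-effect testing
always uses ML (likelihood-ratio tests on fixed effects are invalid under
REML); final predictive fits use REML. Negative deviances from optimizer
noise are clamped to zero with a warning.

Numerical guards: ρ(h) returns exactly 1 below h/φ = 1e−10 (Bessel
underflow region); covariance factorizations add an escalating jitter
starting at 1e−10 of the mean diagonal; the PSD tolerance on coregionalization
matrices is −1e−10 on the smallest eigenvalue; invalid parameter vectors
return a large finite sentinel so optimizers continue.

## Sequential selection with α-investing

Predictors are tested one at a time in an order fixed before any response
data are seen. The wealth rule: W(0) = 0.05, payout ω = 0.05; test j runs
at α_j = W(j−1)/(1 + j − k_j) with k_j the index of the latest rejection;
the spend is α_j/(1−α_j), so wealth stays strictly positive for any
finite sequence and the marginal FDR E(V)/(E(R)+1) is controlled at 0.05
when the p-values are valid. A selected predictor is never revisited.
Collinearity is addressed only through the ordering; a design condition
number above 1e8 logs a warning.

The p-values are ML likelihood-ratio tests against χ²₁. Their finite-
sample validity depends on the survey design: with spatially smooth
predictors and responses and *no* short-distance pairs, the χ²₁ reference
is measurably anticonservative (the classic two-autocorrelated-processes
problem), and the simulated marginal FDR can drift above its nominal
level. With the survey's close pairs included — their stated purpose is
to pin down the short-range covariance parameters — the reference is
calibrated at the α-levels the wealth rule actually spends (verified by
simulation down to α = 0.01). The complete-null calibration study
therefore simulates surveys with the design the method assumes: spread
sites plus ~10 % close pairs at 100–1000 m, and predictors with the
synthetic soils' spatial make-up (about 20 % long-range variance, the
rest site-scale). Note that this wealth rule sits close to its own bound:
with perfectly uniform p-values its null marginal FDR is ≈ 0.046
(rejections pay out wealth, so one rejection raises later spending), so
finite-replicate estimates of the 0.05-controlled quantity naturally
straddle 0.05 and are judged with their Monte-Carlo uncertainty.

## Factorial kriging

Covariate surfaces are decomposed against a nugget + two-structure nested
variogram (short before long; exponential structures by default), fitted
by Cressie-weighted least squares (weights N(h)/γ(h)²). Two identifiability
guards: a fitted structure decorrelating below half the first observable
lag is folded into the nugget, and ranges are capped at twice the largest
lag (beyond which they are unobservable). Component kriging solves the
ordinary-kriging system once per covariate with the full model on the left
side and the chosen component's covariance on the right; nugget, structure
and local-mean components add up to the ordinary-kriging estimate exactly
(the module's exactness anchor, tested to 1e−8). The local mean travels
with the long-range component in downstream fixed effects. Components
enter the LMM as candidate fixed effects and survive only if
|estimate/SE| > 2.

Covariates are decomposed on the full grid and extracted at sites from the
containing cell.

## Prediction, validation, risk

The E-BLUP at x₀ is x₀ᵀβ̂ + cᵀV⁻¹(y − Xβ̂) with the full universal-kriging
PEV including the fixed-effect term. The prior variance of a new
target-variable value includes the nugget (maps are interpreted at
observation support). Predictions use a global neighbourhood — one
Cholesky factorization reused across all targets, processed in blocks of
4000 to bound memory. exp(E-BLUP) is the median-unbiased back-transform;
no back-transformed variance is reported (threshold probabilities are
computed on the log scale instead).

Leave-one-out cross-validation deletes, per target-grain site, the grain
row and the soil-predicted row, holding covariance and fixed-effect
parameters fixed (re-estimating 475 times is disproportionate and the
procedure re-predicts, not re-fits). Because no remaining row shares the
deleted site, the full-stack covariance can be assembled once and each
deletion is a submatrix solve. Ordinary-kriging cross-validation uses the
target variable's marginal (nugget + Matérn) model from the same fit, so
the OK/E-BLUP comparison shares provenance. Close pairs are deleted one
at a time like ordinary sites. Calibration is judged by the mean SSPE
(≈ 1) and by whether the median SSPE falls in a Monte-Carlo 95% interval
for the median of n χ²₁ draws.

Risk maps report Φ((ln t − ẑ)/√PEV) with t = RDA/serving (0.183 mg/kg for
55 µg/day over 300 g/day, reported to 3 dp), then bin probabilities into
a calibrated likelihood language (bounds 0.01/0.10/0.33/0.66/0.90/0.99,
config-overridable; bins are [lower, upper), top bin closed).

## The synthetic survey generator

The generator reproduces the features the analysis relies on, on a
region-scale frame (default 300 × 300 km, matching the spatial extent a
survey of ~500 sites at 500-m grid resolution would cover):

* **design** — the frame is stratified into n roughly equal-area cells and
  one 500-m grid node is drawn per cell (a documented approximation to
  balanced-cube sampling that preserves spread and near-uniform
  inclusion); 25 of the 475 primaries, chosen spread through the stratum
  order, receive a close pair placed uniformly in the 100–1000 m annulus.
  Within-plot geometry (the five sub-samples at radii 5.64, 4.89, 2.82
  and 3.99 m) is exposed for completeness but plays no statistical role —
  a site yields one value per quantity.
* **soils** — eleven properties with means, spreads and skewness patterns
  typical of regional trace-element surveys: the extractable Se and S
  fractions, I, oxalate P and PBI are lognormal (so the skewness > 1 log
  rule has true positives), pH and the bulk properties near-symmetric
  (true negatives). A subset loads on a shared long-range latent field.
* **covariates** — nine surfaces, each a mix of the shared latent field,
  an unrelated long-range field, a covariate-specific short-range field
  (exponential, 2 km) and white noise, generated by FFT circulant
  embedding. Climate/terrain covariates carry the latent loading; the
  vegetation-index and reflectance bands are spatially structured but
  unrelated, giving selection genuine false hypotheses.
* **grain** — log grain Se is β₀(crop) + Σ γ_j·(transformed soil_j,
  centred) + δ·latent + η(crop) + ε(crop), with η a correlated bivariate
  Matérn field (κ = 2, φ = 15 km) and independent crop nuggets. True soil
  drivers default to soluble Se, exchangeable Se and pH; the remaining
  soil properties are nulls.

What passing on these surveys shows: the machinery is correct (oracles,
additivity, likelihood identities), the error control holds under the
design the method assumes, and the predictors and PEVs are calibrated
when the model is correctly specified. What it does not show: robustness
to non-Gaussian residuals, preferential sampling, covariate measurement
error, or misspecified correlation shape — none of which the generator
emulates.

## Problem sizes used in the checks

The replication studies run at sizes chosen to keep the full suite
practical on one core while leaving the conclusions statistically
meaningful: the complete-null FDR study uses 200-site surveys (1000
replicates standalone, fewer inside the test suite); SSPE calibration uses
one 400-site survey; trivariate cross-correlation recovery uses 500-site
surveys on a 500-km frame (the frame size matters: with κ = 2 and
φ = 15 km a 300-km frame holds only ~16 effective replicates of the
spatial field, which caps the precision of any cross-correlation estimate
near ±0.2 regardless of site count); the κ-profile recovery uses 400-site
univariate surveys. ML estimation of weakly identified coregionalization
correlations occasionally piles up at the boundary (r = 1), a known
finite-information pathology for never-co-located variable pairs — close
pairs, whose crops are assigned independently, are the main information
source for the grain–grain correlation.

## Known limitations

* Likelihood surfaces over (κ, φ) are nearly flat ridges; fitted φ is
  reliable only to a factor ~2 and κ only via the profile grid.
* The α-investing wealth rule is one published variant; others spend and
  pay out differently, changing power but not validity.
* Factorial kriging assumes the nested-variogram decomposition is
  meaningful for the covariate; a mis-fitted variogram degrades the
  component split but additivity still holds by construction.
* The exact PBI grouping is (Ps + 4.59·P_Olsen)/Pc^0.41, the
  single-addition form; the constant 4.59 converts Olsen P to the sorbed
  scale.
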