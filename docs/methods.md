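# Methods

This note documents the statistical machinery, the synthetic data it is
exercised on, the numerical choices, and the limits of what the test suite
demonstrates.

## Regression engine

The additive models are penalized regressions on B-spline bases (cubic,
equally spaced knots extended beyond the data range) with discrete
difference penalties — the P-spline construction, chosen because its
penalty nullspace is exactly the low-order polynomials, so the
infinite-smoothing limit of a second-order penalty is the linear fit (a
property the suite checks numerically). Defaults: k = 10 basis functions
per 1-D smooth, k = 5 per tensor margin, penalty order 2. Each smooth
block is column-centred against the training data, which removes the
constant exactly and keeps the intercept identifiable. Tensor-product
interactions are row-wise Kronecker products of the marginal bases with
one penalty per margin (`P ⊗ I`, `I ⊗ P`); a tensor may carry a `by`
factor, replicating the smooth per factor level with smoothing parameters
shared across levels.

The station random intercept is a ridge-penalized indicator block: its
penalty weight λ maps to the variance component as σ²_b = φ/λ. This
avoids a full mixed-model solver while delivering shrinkage,
replicate-sharing and a variance estimate; it is a deliberate
approximation, not an EM/REML fit.

Gaussian models are solved by penalized least squares, binomial models by
penalized IRLS with warm starts. Smoothing parameters (one log-λ per
penalty) are chosen by generalized cross-validation,
`n·D/(n − edf)²`, minimized by Nelder–Mead (default budget 150 function
evaluations; 60 inside the pipeline). GCV was chosen because it needs no
scale estimate and behaves uniformly across both families; the criterion
name is recorded on the fit so a restricted-likelihood option could be
swapped in. AIC uses effective degrees of freedom (trace of the influence
matrix): `n·ln(2πσ̂²) + n + 2(edf+1)` for Gaussian, `deviance + 2·edf`
for binomial. Deviance explained is `1 − D/D₀` (Gaussian: `1 − RSS/TSS`).

Degenerate inputs: a constant response yields an intercept-only fit with
zero deviance explained; fewer unique covariate values than k raises a
basis-size error; Cholesky factorizations retry with a progressively
scaled diagonal boost because extreme smoothing parameters can exceed
double-precision conditioning.

Covariate truncation (distance 0.75–4 km, depth 6–18 m) is applied before
fitting and again at prediction; prediction bases clamp covariates to the
training range, so the model never extrapolates a spline.

### Cross-validation

Folds group by station so replicates never straddle the split. Held-out
refits reuse the full-model smoothing parameters (refitting λ per fold
would multiply cost for little change at these sizes). The in-sample
error `Gs` is computed at population level (random intercepts excluded),
the quantity directly comparable to CV predictions at unseen stations;
`D% = 100(Xv − Gs)/Gs` is computed from unrounded values. Binomial folds
that lose all positive rows are reshuffled with a warning.

### Period contrasts

All pairwise period contrasts use the Bayesian posterior covariance
`φ(XᵀWX + S)⁻¹` with Holm adjustment (the multiple-comparison procedure
is a free choice; Holm is uniformly valid and needs no distributional
extras). The ordering summary joins adjacent levels with `<` when their
contrast is significant and `,` otherwise, e.g. `P3 < P1, P2`.

## Zero-inflation handling

The decision rule routes each group by its fraction of exact-zero biomass
values: ≤ 0.10 unconditional, (0.10, 0.50) hurdle, ≥ 0.50 logistic-only.
Boundary conventions: exactly 10 % is still unconditional, exactly 50 %
already logistic-only. The hurdle conditional part uses strictly the
positive rows; the back-transform is `exp(ŷ) − 0.5` clipped at 0 with no
smearing correction (retransformation bias is accepted and documented
rather than corrected, keeping the composition interpretable as
probability × conditional energy). Logistic-only groups are reported as
occupancy surfaces; no energy conversion is invented for them.

## Geostatistics

Working coordinates correct the geometric anisotropy of a narrow shelf:
distance-to-shore km × 10⁴ (decimeters) and northing m × 10⁻³
(kilometers). All variography, kriging and IDW distances live in these
units so the methods are compared on the same footing.

Residuals kriged are response-scale residuals against the
population-level regression prediction (for the Gaussian part this is the
transformed scale; for the logistic part, observed 0/1 minus p̂). Using
population-level rather than conditional fitted values keeps the
station-level spatial structure in the kriged field, which is how it
reaches the map. Exactly coincident replicate coordinates are jittered
(seeded, displacement ≤ 0.5 working units) before kriging.

Empirical variograms are Matheron estimates in 15 equal-width bins to
half the maximum pairwise distance; model fitting is weighted least
squares with Cressie weights `N(h)/γ_model(h)²` under non-negativity
bounds (exponential and spherical families; the spherical reaches its
sill exactly at the range). Kriging is simple with known mean zero by
default — residuals are zero-mean by construction — with ordinary kriging
available by configuration; the neighborhood is global (systems up to a
few hundred points are cheap), with grid predictions chunked for memory.

Regression-kriging composition for hurdle models is ambiguous in prose
("kriging predictions from the logistic and conditional regressions were
multiplied"); the default takes the literal reading — unconditional
regression surface plus the *product of the two kriged-residual surfaces*,
clipped at zero — and the plausible alternative (product of the two full
regression + kriging surfaces) is selectable by configuration. Neither is
asserted to be the original intent. Gaussian surfaces combine trend and
kriged residual on the transformed scale before back-transforming,
because that is the scale the residuals live on.

Grids default to 20-m cells in physical coordinates and are block-averaged
to 1 km² (partial edge blocks use the cells available; empty blocks are
masked). Grids are written as ESRI ASCII (.asc) plus a cell-table CSV.

## IDW comparison

IDW uses power 2 and 12 neighbors by default (the emulated survey's
neighborhood settings are unpublished, so its exact maps are not
reproducible); a target coinciding with a datum returns that datum's
value, and weights are scaled by the nearest distance so large powers
converge to nearest-neighbor without underflow. Model-versus-IDW
comparison uses leave-one-out IDW fits and Spearman rank correlation with
period × zone mean tables.

## Habitat thresholds

Feeding thresholds are 60 and 85 g/m² × 5.2 = 312 and 442 kJ/m².
Exceedance uses ≥ (deterministic on discrete surfaces; boundary cells are
measure-zero on continuous ones) and is reported at both cell and block
scale, since the scale behind published habitat fractions is unstated.

## Synthetic generator

The generator emulates the survey the analysis was designed for: 223
stations × 3 replicates × 3 periods by default, distance-to-shore
0.86–3.56 km, depth a linear function of distance (slope 3.5 m/km,
intercept 3.7 m, noise sd 0.6 m — chosen to reproduce the reported 6.7–16.1
m range; only the collinearity matters, so any monotone map would do),
zone terciles of the northing extent (zone boundaries are otherwise
unpublished). Group configurations reproduce the reported zero fractions
(0.5–67.7 %) by recentring the occupancy logit so the expected absence
fraction hits the target, and carry the reported qualitative structure
(amphipods alongshore-peaked and nearshore, bivalves depth-driven, fishes
northern and midsummer-peaked). Conditional biomass is lognormal on the
ln(X+0.5) scale with a station-level exponential random field in working
coordinates shared by replicates (mirroring the station random effect);
replicate noise is i.i.d. Back-transformed biomass is clipped at zero.

What the generator does not emulate: sediment and oceanographic
covariates, targeted (preferential) sampling of feeding hotspots,
inter-annual change, tide corrections, or shoreline geometry. Passing
tests therefore demonstrate that the machinery recovers structure of this
known generative form — not that the original field conclusions are
reproduced, which is impossible without the undeposited data.

## Problem sizes and experiments

* Smooth recovery: n = 500 Gaussian (RMSE ≤ 0.1 against the sin truth),
  n = 1000 binomial (linear-predictor correlation ≥ 0.9).
* Variogram recovery: 400 stations uniformly scattered over an 80 × 80
  working-unit domain (16 correlation ranges across the domain — the
  variogram is only informative when the domain is much larger than the
  range), 20 seeds, median relative errors of range and partial sill.
* Hurdle benefit: 20 seeds of 100-station surveys with 30 % zeros; the
  hurdle regression-kriging surface is compared with a naive
  unconditional Gaussian fit against the analytic unconditional mean
  `p(s)·(exp(m(s)+s²/2) − 0.5)` on a 250-m probe grid.
* Pipeline: the default configuration runs 100 stations over a 10-km
  alongshore extent with three groups chosen to exercise all three model
  forms (Amphipoda unconditional, Bivalvia hurdle, Actinopterygii
  logistic-only), a 20-m grid, and two candidate structures per model
  part; a full run takes well under a minute on one core and is
  bit-identical under a fixed seed.

## Known limitations

* The random intercept is ridge shrinkage, not REML; its variance
  estimate inherits GCV's occasional undersmoothing.
* GCV can undersmooth small binomial fits; the Nelder–Mead budget is
  deliberately modest, trading a little criterion precision for speed.
* No spatial correlation inside the regression itself — dependence is
  handled downstream by kriging the residuals, by design.
* Kriging variances for the composed hurdle surface report the
  conditional component only; a full variance for the product composition
  is not defined here.
* No co-kriging, no universal kriging with internal drift, no map
  cartography.
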