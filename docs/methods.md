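# Methods

## Maturity classification

An ovary snapshot has five features: the most advanced group of oocytes
(MAGO: unyolked, early yolked, advanced yolked, migratory nucleus,
hydrated), presence of postovulatory follicles (POFs), the extent of
alpha-stage atresia of yolked oocytes (none, <50%, ≥50%, 100%), presence of
beta atresia, and presence of maturity markers (gamma/delta atresia "brown
bodies" or residual hydrated oocytes). Two validity constraints are
enforced: 100% alpha atresia is incompatible with an intact advanced oocyte
group, and partial alpha atresia requires yolked oocytes to exist. The
second constraint is our reading — it makes the classification exhaustive
over the feature grid (104 valid combinations, each matching exactly one
class), which is verified by enumeration.

Rules are evaluated most-advanced-evidence first (C4, C3, C5, C6a, C6b, C7,
C2, C1). The spawning class C4 matches on migratory-nucleus/hydrated MAGO
*or* POFs; "<50% alpha atresia" for the active classes C3/C4 includes zero
atresia. A female is mature iff her ovary shows advanced yolked oocytes,
any atresia of yolked oocytes, maturity markers, or POFs; C3–C4 are
mature/active, C5–C7 mature/inactive, C1–C2 immature. Fish under 70 cm fork
length may be classed immature macroscopically without histology; at or
above 70 cm a development class is required.

## Spline bases

Covariate effects use natural (restricted) cubic splines with df = k − 1,
where the k knots — boundary knots included — sit at equally spaced
quantiles of the training data. Natural splines are the family for which
this df-to-knots counting holds and for which df = 2 is well defined (an
unrestricted cubic B-spline basis needs at least 3 intercept-free columns);
they also extrapolate linearly beyond the boundary knots, which keeps
predictions at the edge of the observed length range stable. df = 1 is a
centered linear term. Knots are frozen at training time and reused for
prediction; rows outside the training span are flagged as extrapolation.

## The mixed model and its estimation

Maturity is Bernoulli with logit link; fixed effects comprise an intercept,
the length (or age) spline, an optional latitude term (spline or three
discrete bands: <23°S, 23–29°S, >29°S), an optional longitude spline, a
season factor (2 levels, Oct–Mar vs Apr–Sep with Apr–Sep as reference; or
calendar quarters with Jan–Mar as reference), and optional
latitude×season / longitude×season interactions. A Gaussian random
intercept is shared by fish from the same fishing set.

The marginal likelihood is maximised with a Laplace approximation: for each
set the conditional mode of the random intercept is found by damped Newton
iterations (vectorised across sets, warm-started between evaluations), and
the outer problem over (β, σ) uses L-BFGS-B with σ bounded below by zero,
so the boundary case degrades exactly to plain logistic regression.
Covariates are standardised internally for conditioning; results are
reported on the original scale. The fixed-effect covariance is the inverse
observed information at the optimum with σ held at its estimate (the usual
mixed-model convention), computed by central finite differences. On a
20-set test problem the fit matches `lme4::glmer` coefficients to four
digits and the log-likelihood to 1e-4.

Complete separation is detected when any standardised coefficient exceeds
12 in magnitude during or after optimisation and raises an error naming the
offending column. An adaptive Gauss–Hermite quadrature evaluator (mode-
centred, curvature-scaled, ≥21 nodes; restricted to ≤30 sets) provides an
independent value of the same marginal likelihood for testing; at σ = 0 it
returns the exact Bernoulli log-likelihood.

Predictions are conditional on a typical set (random intercept 0) by
default, matching common mixed-model ogive reporting; a population-averaged
option integrates the set effect out by Gauss–Hermite quadrature. Note the
two curves cross 0.5 at the same length (the logistic is symmetric), so L50
is insensitive to this choice. Confidence intervals are Wald intervals on
the logit scale mapped to proportions.

## Model selection

AICc uses n = number of fish and k = number of fixed effects + 1 for the
variance component; n ≤ k + 2 is rejected (the correction's denominator
degenerates). Akaike weights are computed after subtracting the minimum
AICc for numerical stability. The default candidate grid crosses predictor
df ∈ {1, 2, 6}, latitude df ∈ {absent, 2}, longitude df ∈ {absent, 1},
season levels ∈ {2, 4} and the admissible interactions (≥24 models);
non-converged candidates are dropped with a logged warning. The
length-vs-age comparison fits the identical structure with each predictor
on the identical aged subset. L50 at a latitude is the first upward
0.5-crossing of the predicted curve within the training length span,
root-found to 0.01 cm; its confidence bounds are the crossings of the
95% prediction bands, and a curve that never crosses yields a missing value
with a reason.

## The weighted ogive

Area/season proportions mature come from the discrete-latitude refit
(length spline 2 df, 3 bands, 2 seasons, latitude×season interaction, set
random intercept) evaluated at 5-cm length-class midpoints (classes are
closed intervals 46–50, 51–55, …; a boundary length belongs to the lower
class). Prediction variance is converted to the proportion scale by the
delta method, `Var(p) = (p(1−p))² Var(logit)`, before weighting — the
reduced variance formula operates on proportions; the logit-scale
alternative would change little but is not what the formula states.

Weights are `W_las = N_as p_las f_las / Σ_a N_as p_las f_las` per length
class and season: relative abundance (e.g. CPUE-derived; only relative
scale matters) × length composition × proportion female. Cells with no
composition data drop their area from that length class with the weights
renormalised and a logged note; classes empty in every area stay undefined.
The combined estimate is the weighted average with
`Var(P̂) = Σ W² Var(p̂)`; the reported intervals therefore exclude weight
uncertainty and are flagged as underestimates. Finer CPUE areas may be
collapsed onto the three bands through a mapping table.

`length_at_quantile` interpolates linearly between the bracketing grid
points of the first upward crossing; "length at 100% maturity" is
operationalised as the smallest class whose estimate reaches 0.99
(configurable), since logistic and spline curves approach 1 only
asymptotically. The pooled ("unweighted") comparison curve is a plain
logistic in length per season with the set random intercept retained.

## The synthetic population

The generator emulates the features of a basin-wide sampling program that
the estimator must survive, with defaults chosen as a realistic study
scale:

| parameter | default | meaning |
|---|---|---|
| n_sets, fish_per_set_mean | 150, 20 | census of ~3 000 fish; the effort thinning below leaves a biological sample of ~1 500 fish in ~75–150 sets |
| latitude_range_degS | (10, 40) | sampled latitudes, degrees south |
| length_by_latitude | (105, 1.0, 6.0) | mean length 105 − 1.0·lat, SD 6 cm: larger fish towards the equator |
| true_ogive | (87, 0.5, 0, 0.2) | L50 = 87 cm at the 25°S reference, +0.5 cm per degree south (adults inhabit the north), no seasonal shift, logit slope 0.2/cm |
| set_re_sd | 0.5 | SD of the set-level logit intercept |
| migration_* | on, 10°, 0.7 | 70% of mature fish shift 10° north (±1.5° dispersion) in Oct–Mar and are caught by spawning-zone sets |
| sample_fraction, effort_bias | 0.5, 10 | sets are sampled with probability ∝ effort; Oct–Mar effort is 10× higher on the spawning ground (<23°S) |
| sex_ratio | (2.4, −0.035) | logit P(female) declines with length: ~0.66 at 50 cm, ~0.32 at 90 cm |

Fish are generated within sets (sharing the set's latitude, month and
random intercept), so the set effect enters the maturity draw exactly as
the model assumes. Migration then reassigns migrating mature fish to a
random spawning-season set near their displaced latitude — dispersing them
across sets the way spawning aggregations mix schools, rather than piling
them into a single nearest set. Effort concentration operates at the set
level because that is where it matters statistically: a mixed model is
insensitive to per-set sample size but follows the spatial distribution of
sets. It is active only when migration is enabled, the rationale being that
the fleet concentrates where aggregations form; this makes
`migration_enabled` the single switch for the whole bias mechanism, with
the migration-off configuration as its clean null.

The returned frame is a census with a `sampled` flag: maturity models use
the sampled rows; abundance truth (the stand-in for CPUE) tabulates all
rows. `true_weighted_ogive` integrates the true maturity process over the
set effect (Gauss–Hermite) and over latitude weighted by where fish of each
length actually live (Bayes weighting of the uniform latitude field by the
Gaussian length density), and is validated against a 10⁶-draw Monte-Carlo.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: oceanographic structure, longitude-dependent
growth, multi-year dynamics, ageing error structure beyond lognormal noise
on an inverted von Bertalanffy curve, histology misclassification, and any
feedback of density on catchability beyond the single effort-bias knob.

## Numerical choices and problem sizes

Inner Newton tolerance 1e-10 (gradient sup-norm); outer L-BFGS-B ftol
1e-12; σ search bounded at [0, 10]; quadrature default 21 nodes. Root
finding for L50 uses Brent's method to 0.01 cm. Band representative
latitudes for discrete-band prediction are any point inside the band (the
design depends only on membership). Test and acceptance runs use ~1 500
fish × 150 sets for the 200-replicate recovery study and a ~40 000-fish
census (~7 500 sampled females) for the bias experiment — sizes at which
the directional and calibration claims are stable across seeds while the
whole suite runs in seconds.

## Known limitations

The weighted-ogive variance ignores uncertainty in abundance, length
composition and sex ratio (propagating it would need variance estimates for
those inputs). Predictions are conditional on a typical set by default.
The Laplace approximation slightly underestimates σ for very small sets
(binary data); the quadrature oracle bounds this error in tests. The
candidate grid is configurable but finite; model-averaged prediction is out
of scope, as are CPUE standardisation and otolith ageing.
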