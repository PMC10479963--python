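# Methods

## The scaling problem

Body weight measures a volume; stature, forearm length and other linear
dimensions measure a length. Under isometric growth the two are tied by a
power law, W = α·L^k, with k = 3 for strict geometric similarity and
empirically closer to 2.5 in large-bodied hominoids (skeletal load-bearing
scales with bone cross-section, not volume). Differentiating the link,

    dL/dt = (1/k) · V^(1/k − 1) · dV/dt,

so an adolescent acceleration of the volume (weight) growth rate is
multiplied by a factor V^(1/k−1) that shrinks as the animal grows. Three
consequences, all implemented analytically in `growthscale.scaling` for
polynomial volume-rate families v(t) = a + b·(t − t₀)^p:

1. For pure power laws V ∝ t^m, the induced linear-length rate is
   decreasing when m < k, constant when m = k, and accelerating only when
   m > k. A pronounced weight spurt can therefore coexist with a falling
   linear length growth rate.
2. Detectability of a linear-length spurt grows with the take-off age/size
   t₀: the same rate change at a larger volume meets a weaker
   V^(1/k−1) deceleration. `detectability_scan` quantifies this; the
   strength of the induced acceleration phase is monotone non-decreasing
   in t₀ once such a phase exists (in the pure-deceleration regime the
   reported "maximum acceleration" is the least-negative value of a
   negative curve and may wobble at the 1e−4 level).
3. Even when both spurts exist and are perfectly synchronous, the
   linear-scale velocity peaks *earlier* than the volume-scale one,
   because d(L^k)/dt = k·L^(k−1)·dL/dt and L^(k−1) is still rising at the
   linear peak. For the calibrated female reference curve below, that
   artifact lag is exactly 1.0 y.

Classification of d²L/dt² sign patterns uses the dimensionless measure
r(t) = d²L/dt² · (window span) / mean(dL/dt) with tolerance 1e−3 —
grid-stable and invariant to unit changes. Rates are closed-form, never
finite differences (a finite-difference oracle lives in the tests). The
initial volume V₀ must be positive (default 1e−3) because V^(1/k−1) is
singular at V = 0; classification tests use windows bounded away from 0.

## Synthetic cohort generator

No individual-level data ship with this package; `growthscale.cohort`
generates longitudinal cohorts with the statistical structure the
analysis assumes, calibrated so the noiseless curves place their
landmarks at the values reported for zoo-housed bonobos:

| landmark | value |
|---|---|
| peak growth velocity (weight and corrected forearm), F / M | 6 y / 8 y |
| female linear-scale (cm/y) peak relative to corrected (cm^2.5/y) | 1 y earlier |
| male muscle (creatinine) velocity peak after the weight peak | +1.5 y |
| urinary testosterone fastest rise, F / M | 4 y / 7 y |
| testosterone decline onset | 30 y |
| DHEA fastest rise / plateau (99 % of range on [0, 25]) | from birth / 15 y |
| female creatinine | no spurt; velocity falling from birth |
| female IGFBP-3 peak | at the female growth peak (6 y) |

**Latent structure.** Each sex's size is a double logistic on the *weight
dimension*, S(t) = A1·σ(r1(t−c1)) + A2·σ(r2(t−c2)) in cm^k units, so the
scale-corrected truth is primary and the linear-length artifact is
emergent: weight = α·S (α set so adults average ≈33 kg (F) / 39 kg (M)
at adult forearm lengths 26 / 27.5 cm) and forearm length = S^(1/k),
k = 2.5. The double logistic was chosen over Preece–Baines for analytic
derivatives and easy calibration; it is a stand-in, the trajectories it
replaces being nonparametric fits. Hormones are modelled on the natural-log
scale: testosterone as a logistic rise (male amplitude larger) with a
C¹ quadratic-hinge senescent decline from 30 y; DHEA as a saturating
exponential shared by both sexes; IGFBP-3 as a Gaussian bump (female
centre at the growth peak, male at the muscle peak); male creatinine as
an offset two-component sigmoid, female creatinine as a saturating
exponential (velocity maximal at birth — no spurt).

**Calibration** (`calibrate_reference`) solves for the free shape
parameters by root-finding on the analytic curves: the female (r2, c2)
jointly hit the corrected peak (S″ = 0) and the linear spurt peak
((1/k − 1)S′² + S·S″ = 0); the male c2 and the male creatinine c2 are
solved by bisection; the DHEA timescale has a closed-form plateau
condition. Every calibration is verified against `true_landmarks`, a
dense-grid (0.01 y) oracle on the noiseless curves, to within 0.05 y;
failure raises with the residual table.

**Heterogeneity and noise.** Per individual: a log-normal size multiplier
(SD 0.08) and a normal timing shift of the adolescent centre c2 (SD
0.5 y); per zoo (12 by default): a log-scale intercept (SD 0.05) applied
to all variables. Multiplicative measurement noise: weight 0.04, length
0.02, urinary markers 0.30 (log-scale SDs); creatinine noise is inflated
×1.5 before age 3 (corrected creatinine is unreliable in infants). About
10 % of weight and forearm records of females past 8 y are flagged
pregnant; pregnant *weights* are inflated ×1.1 (an invented magnitude
that makes the exclusion filter consequential), forearm lengths are not.

**Sampling** mimics a mixed-longitudinal zoo compilation: one observation
career per individual ending at a uniform random age between 2 and 45 y;
weight weighed at irregular exponential intervals (mean 0.5 y, 3 % same-day
repeats); forearm measured at 5 visits; urine collected at 5 visits
(creatinine/DHEA/testosterone at all of them, IGFBP-3 at 3 — the
low-volume marker), matching the published per-individual medians (arm
4–5, markers 4–5, IGFBP-3 1–3). Ages are rounded to 4 decimals before
evaluation so noiseless records are exact curve values. Everything is
driven by one `numpy` Generator: a fixed seed reproduces the cohort
byte-identically. Not simulated: birthdate uncertainty of wild-born
animals, husbandry drift over calendar time, maternal-age effects,
sampling daytime, and specific-gravity correction (the generator emits
already-corrected values).

**Population-level landmarks.** Averaging individuals widens the
cross-scale lag: with the default timing heterogeneity the
population-average female curve has a linear-vs-corrected lag of ~1.24 y
even though every individual's is 1.0 y. Trajectory fits estimate the
population curve, so fitted lags centre near the former.

## Trajectory smoothing

`growthscale.smoothing` is a deliberately simplified stand-in for the
generalized additive mixed models used on real data (random smooths per
individual and zoo, ML/REML selection, AR1 residuals are all out of
scope): a population cubic B-spline smooth with a difference penalty,
plus ridge-penalized per-group intercepts, fitted by penalized least
squares.

* Basis: clamped cubic B-splines on min(20, ⌊n_distinct/2⌋) interior
  knots, quantile-placed by default (uniform available and used by the
  pipeline, below).
* Penalty: order-2 *divided* differences of the coefficients over the
  Greville abscissae. Raw coefficient differences only annihilate
  polynomials on equidistant unclamped knots; the divided-difference form
  keeps the null space equal to the straight lines for any knot vector,
  so λ → ∞ recovers the least-squares line and edf → 2 exactly.
* λ selection: GCV over a 41-point log ladder (1e−4…1e6) with
  golden-section refinement, or a fixed value, or edf-matching
  (`lambda_for_edf`, bisection on the strictly λ-monotone edf).
* Derivatives: analytic, via the differentiated B-spline basis.
  Extrapolation outside the fitted age range is refused.
* Grouped fits: design [B | Z] with indicator block Z, ridge weight τ
  chosen by GCV jointly with λ (13-point τ grid); intercepts centred to
  sum to zero, the mean absorbed into the spline (B-splines sum to one).
* Sex differences: pointwise male − female curves with cluster-bootstrap
  percentile bands (resample individuals, refit at the original λ; 200
  replicates, 95 % level by default; replicate seeds derive from a master
  seed).

**Smoothing policy.** GCV treats within-individual repeats as independent
and between-individual heterogeneity as noise, and mis-selects smoothness
on clustered growth data (both over- and under-smoothing, depending on
the variable) — the same failure that motivated fixing the testosterone
smoothing parameter in mgcv-based analyses of such data. The pipeline
therefore pins trajectory smoothness by effective degrees of freedom per
variable: weight 16 (dense series), forearm and creatinine 12,
testosterone 9 (protects the sudden pubertal rise), DHEA 5 (a saturating
curve), IGFBP-3 by GCV. `fix_lambda_policy` keeps "auto" as the module
default with testosterone fixed; the pipeline supplies the rest through
its config, and an explicit config entry always wins.

## Landmark measurement protocol

`growthscale.landmarks` fixes one way to measure the Fig-4-style landmark
battery so the pipeline report, tests and acceptance script agree:

* Weight and forearm are fitted on the log of the (dimension-transformed)
  response — the generator's size multipliers and measurement noise are
  exactly additive there — with individual intercepts, uniform interior
  knots (equal flexibility across ages; quantile knots concentrate
  flexibility at data-dense young ages and drag bump peaks early), on the
  developmental window 0.5–25 y. Growth velocities are back-transformed
  as exp(f)·f′.
* Spurt peaks come from `detect_spurt` on the velocity grid: the peak is
  the last substantial interior local maximum (candidates ≥ 50 % of the
  grid maximum). On the linear-length scale the *global* argmax sits at
  the infancy boundary — infant linear velocity exceeds the adolescent
  bump, which is precisely the artifact under study — so a plain argmax
  cannot landmark the spurt there; for single-peaked curves the rule
  reduces to argmax. Take-off = last pre-peak local velocity minimum
  (grid start if none); detected requires an interior peak and a relative
  rise ≥ 10 % over take-off; cessation = first post-peak age where
  velocity falls back below the take-off velocity. Take-off and the 10 %
  threshold are operational choices (config-exposed); only peak ages are
  anchored to published values.
* The female cross-scale lag is read off *one* fitted forearm curve:
  corrected peak = interior argmax of exp(kf)·kf′, linear peak = last
  local maximum of exp(f)·f′ within 3 y before it (between the two peaks
  of one spurt the linear velocity has no other critical point, so the
  pairing is exact). Reading both from the same curve differences out fit
  noise; smoothing attenuates the raw lag (≈0.7–0.9 y against the
  population-curve 1.24 y), well within the integer-year rounding used
  for reporting.
* Three landmarks are threshold- or changepoint-like and too fragile for
  spline derivatives at these sample sizes; they use targeted parametric
  estimators instead: the male creatinine velocity peak by multi-start
  nonlinear least squares on a two-component sigmoid (detected only when
  the velocity maximum is attributable to a distinct adolescent
  component); the DHEA plateau by fitting the saturating-exponential
  family and evaluating the 99 %-of-range age in closed form; the
  testosterone decline onset by quadratic-hinge segmented regression on
  ages ≥ 15 pooling sexes through an intercept (a kink at the search-grid
  edge is censored as "not located"). A linear hinge is biased several
  years late on a gradual decline; spline-derivative zero crossings on
  the long noisy plateau are essentially unidentified.
* Single-cohort peak estimates at n = 80/sex wobble by several tenths of
  a year (the corresponding fits of real data carry wide CIs for the same
  reason). The protocol therefore reports medians over 15 replicate
  cohorts, with the three cheap parametric landmarks additionally
  measured on 90 cohorts; cross-variable lags are differences between
  the reported median peak ages, mirroring how such lags are quoted from
  fitted curves. Reported ages are rounded to the year (the muscle lag to
  the half-year), the precision at which the reference values are stated.

## Allometry check

`fit_loglog` regresses log W on log L: OLS with weight as response by
default (weight is the noisier measure), standardized-major-axis slope
(slope_SMA = slope_OLS / |r|, Warton-style CI) for the
errors-in-both-variables case, plus a quadratic log-log curvature term
whose CI diagnoses the adequacy of a single power law. Pairs are matched
within a same-individual 0.25-y age window (weight and length come from
different sampling events). On cohort-matched pairs the shared zoo
intercept acts as correlated error on both axes and attenuates the
estimate by a few hundredths (≈2.40–2.47 for a true 2.5) — a realistic
covariance artifact worth knowing about; under the clean reference
conditions (length exact, 5 % weight noise, n = 500) OLS recovers
k = 2.5 within ±0.05 with bias < 0.01.

## Pipeline

`preprocess` applies, in order: daily averaging of same-individual
same-day weights; exclusion of pregnant-flagged records for every
variable except forearm length; natural-log transform of the urinary
markers with a rename to `log_*` (which makes the step idempotent). A
filter report counts records in/out per rule. `run_full` then fits every
requested sex × variable × dimension, detects spurts, extracts hormone
landmarks (decline onsets via the segmented estimator on ages ≥ 15),
assembles the landmark battery, checks the scaling exponent, and writes
difference curves — all deterministic given the master seed, with
bootstrap seeds derived by counter. Peak ages are written at 0.1-y
resolution; integer/half-year rounding is applied only in the acceptance
summary. The `growthscale` CLI exposes `scenario`, `simulate`, `fit`,
`detect`, `allometry` and `report` subcommands over the same functions.

## What passing tests do and do not show

The generator reproduces the *structure* assumed by the analysis —
isometrically linked weight/length, sex-specific double-sigmoid growth,
hormone trajectories with the published landmark ages, individual/zoo
heterogeneity, multiplicative noise, irregular mixed-longitudinal
sampling. Landmark recovery on these cohorts shows the pipeline measures
such structure correctly at realistic sample sizes; it cannot validate
assumptions the generator does not emulate (assay artifacts, birthdate
errors, calendar-time husbandry trends, autocorrelated within-individual
residuals beyond an intercept, or any real-data coefficient values).
About a third of replicate cohorts yield a spurious female creatinine
"spurt" detection at the battery's smoothness — a known false-positive
rate of the wiggle-sensitive detector on a monotone trajectory, reported
as such by the battery.

## Problem sizes

Default analyses use n = 80 per sex (≈11,700 records per cohort), 15
replicate cohorts for the spline battery, 90 for the parametric
landmarks, 200 bootstrap replicates for bands and CIs, and dense 0.01-y
grids for analytic landmarks; the full acceptance computation runs in
about a minute on one core.
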