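# Methods

`perilesion` implements a structure-function analysis for geographic
atrophy (GA): how mesopic retinal sensitivity, measured by fundus-tracked
microperimetry, varies with the distance of each test locus from the
nearest GA border, and how that relationship evolves over follow-up.

## Geometry and units

Test loci form a T-shaped grid centred on the anatomic fovea: arms of
15 deg (temporal), 12 deg (superior) and 12 deg (inferior) with 1 deg
spacing — 40 loci in the default geometry. Coordinates are degrees of
visual angle in a right-eye convention (temporal = +x, superior = +y);
left-eye data should be mirrored at ingest. Sensitivity is decibels of
attenuation relative to a 127 cd/m^2 maximum stimulus over a 0–20 dB
range (`luminance = 127 * 10^(-dB/10)`), so 0 dB is the brightest
presentable stimulus and a locus with no response there is an absolute
scotoma, recorded as 0 dB. Retinal distance conversions use 290 um/deg;
the studies this package emulates print the pairings 2 deg ~ 580 um and
10 deg ~ 2900 um, which that constant reproduces. It is configurable in
`UnitScale` because the anatomical scale varies between eyes.

## Distance to the GA border

GA is represented as a binary raster (default 768x768 pixels over a
30 deg field, the native format of the fundus autofluorescence images on
which GA is annotated), registered to the grid frame with the fovea at
the raster centre. The distance for a locus is the Euclidean distance
from the locus centre to the centre of the nearest GA pixel, found with a
k-d tree over GA pixel coordinates; with multifocal atrophy this is
automatically the minimum across lesions. A locus whose containing pixel
is GA is *intralesional*: its distance is recorded as 0 and it is
excluded from the regression by default (a pipeline flag, not deletion —
the descriptive analyses concern extralesional function). Because lesions
grow, distances are recomputed against each visit's own mask. An
exhaustive scan over all GA pixels is kept in the test suite as the
oracle for the k-d tree path.

## The segmented mixed model

For extralesional locus i in cluster c = (participant, visit), with GA
distance d (deg) and time t (months since baseline):

    y_ic = beta0 + beta_t * t
           + b1*(k - d) + b2*(k - d)^2    if d <  k
           + b3*(d - k)                   if d >= k
           + u_c + e_ic

    u_c ~ N(0, sigma_u^2),  e_ic ~ N(0, sigma_e^2)

The knot k is a free parameter. Writing the pre-knot segment in powers of
(k - d) makes the mean continuous at the knot by construction and gives
the coefficients their published sign convention: the per-degree rise in
sensitivity at midpoint m below the knot is `-b1 - 2*b2*(k - m)`, and b3
beyond it. The shared intercept u_c induces compound symmetry within a
cluster (covariance sigma_e^2*I + sigma_u^2*J), whose determinant and
inverse have rank-one closed forms, so the exact marginal log-likelihood
is evaluated cluster-by-cluster without materialising any dense
covariance. A participant-visit cluster is the innermost level of the
nesting (loci within axis within orientation within participant-visit);
richer nested intercepts were left out because the reference analysis
does not publish its variance components, and the single-intercept
marginal model is exact and fast. An optional covariate `beta_f *
(foveal distance)` supports the supplementary analysis.

### Fitting

Direct maximum likelihood over (beta0, beta_t, b1, b2, b3[, beta_f], k,
log sigma_u, log sigma_e):

1. coarse profile grid over k in [0.25, 8.0] deg, step 0.25 (for fixed k
   and variances the fixed effects are the closed-form GLS solution; the
   two variance parameters are profiled by L-BFGS-B on the log scale,
   warm-started along the grid);
2. bounded local refinement of k around the best grid point;
3. a joint Nelder-Mead polish of all parameters at once, retained only if
   it improves the likelihood.

Variances are optimised as log(sigma) to stay positive, with bounds
sigma in [1e-6, 1e3] dB. If a candidate knot lies outside the observed
distance range, the corresponding segment columns vanish and the GLS
normal equations become singular; the minimum-norm least-squares solution
is used there. Standard errors come from the inverse observed information
(central-difference Hessian) at the optimum; all 95% intervals are Wald
(+/- 1.96 se, no degrees-of-freedom correction), with variance-component
SEs mapped to the natural scale by the delta method. Contrast CIs (the
per-interval sensitivity changes) use the analytic delta-method gradient,
(-w, -2w(k-m), -2w*b2) with respect to (b1, b2, k) below the knot and w
with respect to b3 above it; an interval that straddles the knot has no
closed form and the API directs the caller to difference the mean
function instead.

One numerical subtlety: the likelihood is only piecewise smooth in k,
with a kink wherever k crosses an observed distance. A naive 1e-4-scale
Hessian step measures the micro-curvature of those kinks and understates
the knot's SE by an order of magnitude, so the knot coordinate uses a
0.05 deg step, wide enough to average over kinks and recover the envelope
curvature. Even so, Wald intervals at an estimated change-point should be
read as approximate.

### Behaviour of the change-point estimator

At realistic noise (sigma_u = 2, sigma_e = 3 dB) the profile likelihood
in k is very flat and asymmetric — much flatter to the right of the
optimum, because a quadratic extended over a wider range can mimic a
kink-plus-line, while a too-small k cannot absorb the curvature. Two
practical consequences, both visible in `analysis/05_recovery_study.py`
and quantified in the test suite: single-cohort knot estimates scatter
widely (replicate SD ~0.6 deg at 26 participants, comparable to the
published interval's half-width), and the ML knot carries a finite-sample
*upward* bias of roughly +0.3 to +0.6 deg that propagates into the
coefficients correlated with it (beta0, b1, and mildly b3). This is a
property of maximum likelihood for weakly identified change-points, not
of the optimiser: in every replicate the fitted likelihood exceeds the
likelihood at the generating parameters, and coarse and fine knot grids
find the same optimum. Recovery checks on the time slope and the
quadratic coefficient are clean.

## Synthetic cohorts

The generator reproduces the data *structure* the analysis assumes, so
the whole pipeline is testable without any patient data.

- **Cohort shape** — 26 participants; visits at months 0, 3, then every
  6 months to month 45. Dropout is monotone: after each attended visit a
  participant leaves with probability 0.15, giving ~4.6–5.2 expected
  visits, matching the emulated trial's mean of 5.2.
- **Lesions** — per participant, 1–3 star-shaped foci: discs perturbed by
  8 radial Fourier harmonics (orders 2–9, amplitudes +/-0.08, normalised
  so the continuous focus area is exactly pi*R^2), centred within 4 deg
  of the fovea. Baseline size is Normal(9, 2) deg in sqrt-area (~2.6 mm,
  a typical GA cohort mean), truncated below at 4 deg; sqrt-area grows
  linearly at 0.09 deg/month (~0.31 mm/year), realised by scaling each
  focus about its own centre. Lesions reaching the field edge are clipped
  with a warning.
- **Sensitivities** — truth follows the segmented model above with
  generative fixed effects beta_t = -0.07, b1 = -1.53, b2 = -0.46,
  b3 = 0.56, k = 2.05 (the published point estimates) and beta0 = 9.0 dB.
  beta0 is not published; 9.0 places the far-field plateau at ~13–14 dB,
  a few dB below the ~18 dB age-normal value, as the reference cohort
  describes. Noise defaults are sigma_u = 2 dB (participant-visit
  intercept) and sigma_e = 3 dB (residual), chosen to produce a realistic
  0–20 dB spread; they are defaults, not published values. Intralesional
  loci are emitted as absolute scotomas.
- **Measurement modes** — `gaussian_rounded` (default): nearest-integer
  dB clipped to [0, 20], scotoma flagged when a negative latent threshold
  clips to 0 — what device exports look like. `staircase_4_2`: a 4-2
  staircase from 10 dB with a deterministic observer (steps of 4 dB to
  the first reversal, 2 dB to the second; the last-seen attenuation is
  returned, accurate to within 2 dB of the latent threshold).
  `gaussian`: the raw continuous latent value, unrounded and uncensored.

The default model fit analyses recorded dB values as-is, ignoring the
floor/ceiling censoring — deliberately, because that matches how such
data are analysed in the reference workflow; a censored-likelihood (Tobit)
variant is out of scope and listed as a limitation. For that reason the
*estimator-validation* studies (replicate bias, single-cohort parameter
recovery) simulate with the `gaussian` mode: they are meant to test the
marginal-ML implementation under its own assumptions, and running them on
censored data would measure the censoring artifact instead. Tests of the
realistic modes (integer range, scotoma flagging, staircase accuracy,
censoring behaviour) are separate.

What the generator does *not* emulate: reticular pseudodrusen, fixation
instability and follow-up registration error, grading variability in the
lesion outlines, spatial correlation between neighbouring loci beyond the
shared cluster intercept, and any treatment effect. Passing recovery
tests therefore show that the pipeline and estimator are correct for
data with the assumed structure — not that the model is adequate for any
particular real dataset.

## LOESS curves

Descriptive curves use plain nearest-neighbour LOESS: at each of 200
evaluation points spanning the observed distance range, the
ceil(span * n) nearest points get tricube weights on distances scaled by
the window radius and a degree-1 weighted polynomial is fitted; span
defaults to 0.5 with no robustness iterations. Curves never extrapolate,
tied x-values collapse to their weighted mean, and strata with fewer than
10 points are skipped with a logged note (mirroring how sparsely attended
late visits are dropped from descriptive figures). Settings are recorded
on every exported curve.

## Problem sizes in the shipped studies

Replicate studies render lesions at 256x256 over the same 30 deg field
(distance quantisation 0.117 deg, immaterial against a 2 deg knot) and
use a 0.5 deg coarse knot grid before refinement; the single-cohort
acceptance fit uses full 768x768 rasters and the 0.25 deg grid. The
recovery acceptance study runs 50 replicates at the full 26-participant
cohort; the foveal-covariate calibration and recovery checks use smaller
direct-from-model datasets (8 participants x 3 visits x 25 loci) with
10–16 replicates, with acceptance thresholds widened accordingly for the
binomial noise of the smaller counts.

## Known limitations

- Censoring at 0/20 dB is simulated but not modelled in the fit (see
  above); estimates from heavily censored cohorts are attenuated.
- Wald intervals for the knot understate uncertainty when the profile is
  flat; profile-likelihood intervals are not implemented.
- The random-effects structure is a single participant-visit intercept;
  axis-level nesting is not fitted (the generator can be extended, the
  fitter treats such correlation as residual).
- Masks are assumed pre-registered to the grid frame; no image
  registration is performed.
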