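# perilesion

Structure-function analysis of mesopic retinal sensitivity around
geographic atrophy (GA) borders.

In late dry age-related macular degeneration, retinal function is lost
not only inside atrophic lesions but across a *perilesional* zone beyond
their borders. This package quantifies that zone from longitudinal
microperimetry: it overlays a fovea-centred T-shaped test grid on binary
GA lesion masks, computes for every locus at every visit the Euclidean
distance to the nearest GA pixel (minimum across lesions when multifocal,
recomputed per visit as lesions grow), draws descriptive LOESS curves of
sensitivity against distance, and fits a segmented nonlinear
mixed-effects model in which mean sensitivity is quadratic in distance
below an estimated change-point (*knot*) and linear above it:

    E[y] = beta0 + beta_t*t + b1*(k-d) + b2*(k-d)^2   (d <  k)
    E[y] = beta0 + beta_t*t + b3*(d-k)                (d >= k)

with a Gaussian random intercept shared by each participant-visit
cluster. The per-degree rise in sensitivity below the knot is
`-b1 - 2*b2*(k-m)` at midpoint m, and `b3` above it. Fitting is exact
marginal maximum likelihood (compound-symmetry clusters evaluated in
closed form), with Wald inference and delta-method contrasts. A
synthetic-cohort generator — growing star-shaped lesions rasterised on a
30 deg / 768x768 field, device-like censored integer-dB measurements or a
simulated 4-2 staircase — makes the whole pipeline testable end to end.
It is aimed at vision scientists and biostatisticians designing or
re-analysing perimetry endpoints for GA trials.

## Worked example

```python
from perilesion import SimulationConfig, annotate_dataset, fit, simulate_cohort

cohort = simulate_cohort(SimulationConfig(rng_seed=7))
annotated = annotate_dataset(cohort.records, cohort.masks, cohort.grid)
result = fit(annotated)
print(result.to_frame().round(4).to_string(index=False))
```

```
parameter  estimate     se  ci95_low  ci95_high
    beta0    8.9933 0.2921    8.4208     9.5659
   beta_t   -0.0678 0.0133   -0.0939    -0.0417
       b1   -2.4391 0.8282   -4.0625    -0.8157
       b2   -0.1234 0.4476   -1.0007     0.7540
       b3    0.5397 0.0250    0.4907     0.5887
     knot    1.7618 0.1642    1.4400     2.0837
  sigma_u    1.8434 0.1307    1.5872     2.0996
  sigma_e    2.9455 0.0380    2.8710     3.0199
```

Read: on this synthetic cohort the transition from steep quadratic to
shallow linear recovery of sensitivity is estimated 1.76 deg outside the
GA border; beyond it sensitivity rises by 0.54 dB per degree of distance,
and at a fixed locus sensitivity declines by 0.068 dB per month over and
above the decline caused by the border moving closer. `result
.interval_change(0.5)` gives the change over 0–1 deg (here 2.75 dB, 95%
CI 1.93–3.58) with a delta-method CI.

The same steps as numbered drivers, each printing what it found and
writing tables under `results/`:

```bash
cd analysis
python 01_simulate_cohort.py      # cohort shape, scotoma fraction
python 02_compute_distances.py    # per-visit distance distributions
python 03_loess_curves.py         # descriptive curves (CSV + plot)
python 04_fit_segmented_model.py  # the fit report shown above
python 05_recovery_study.py       # replicate bias / MC-SE table
```

A `perilesion` CLI exposes the same pipeline for file-based use:
`perilesion simulate | annotate | curves | fit | validate | run`, with
masks as PNG + JSON sidecar and tables as CSV.

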