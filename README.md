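# growthscale

Scale-corrected growth-spurt analysis for longitudinal morphometric and
physiological data, built around the bonobo (*Pan paniscus*) test case of
whether non-human primates have human-like adolescent length growth
spurts.

## The problem

Body weight measures a volume, stature or forearm length a linear
dimension. Under isometric growth they are linked by a power law

    W = α · L^k,        k = 3 (isometry), ≈ 2.5 empirically in large hominoids

so the growth rates obey dL/dt = (1/k)·V^(1/k−1)·dV/dt. The factor
V^(1/k−1) shrinks as the animal grows, which manufactures artifacts
whenever weight and length growth *rates* are compared on their native
scales: a pronounced weight spurt whose aligned length spurt is
undetectable (the length rate merely decelerates more slowly, or
plateaus); spurts that appear in large species but not small ones; and a
spurious lead of the length-velocity peak over the weight-velocity peak
even when the two spurts are perfectly synchronous. The fix is to compare
like with like — length raised to k (cm^2.5) against weight, or weight to
1/k against length — before smoothing and landmarking velocity curves.

The package provides, for anyone analysing growth trajectories:

* `growthscale.scaling` — the analytic engine: induced length curves for
  polynomial volume growth-rate families, classification of the induced
  rate pattern (decreasing iff m < k for V ∝ t^m), take-off-age
  detectability scans, and the cross-scale peak-lag artifact, all in
  closed form;
* `growthscale.cohort` — a seeded synthetic-cohort generator calibrated
  so its noiseless landmarks sit at the published bonobo values (peak
  growth velocity 6 y in females vs 8 y in males, a 1-y female
  linear-scale shift, a +1.5-y male muscle lag, testosterone rising
  fastest at 4 / 7 y and declining after 30 y, a DHEA plateau at 15 y);
* `growthscale.smoothing` — penalized B-spline trajectory fits (GCV,
  fixed-λ or edf-matched), grouped random intercepts, analytic
  velocities, cluster-bootstrap difference bands;
* `growthscale.spurt` / `growthscale.landmarks` — dimension transforms,
  spurt landmark detection (take-off, peak, cessation), cross-variable
  peak alignment, hormone landmarks, and the replicated landmark
  measurement protocol;
* `growthscale.allometry` — log-log estimation of k (OLS and SMA) with a
  curvature diagnostic;
* `growthscale.pipeline` + the `growthscale` CLI — preprocessing
  (daily weight averages, pregnancy exclusion, log-transformed urinary
  markers) and the end-to-end seeded analysis.

## Worked example

```python
>>> import numpy as np
>>> from growthscale import PowerLawScenario, classify_length_rate, peak_lag
>>> from growthscale.cohort import default_reference

# quadratic volume-rate acceleration, cubic link: length rate is constant
>>> s = PowerLawScenario(baseline_rate=0, accel_coeff=3, accel_power=2,
...                      dim_exponent=3, initial_volume=1e-9)
>>> classify_length_rate(s, (1.0, 10.0)).label
'constant'

# the calibrated female latent curve: same growth, two dimensions
>>> ref = default_reference()
>>> t = np.arange(0.0, 25.005, 0.01)
>>> res = peak_lag(lambda x: ref.female.size.value(x) ** (1 / ref.k), t, k=ref.k)
>>> (res.linear_peak_age, res.corrected_peak_age, res.lag)
(5.0, 6.0, 1.0)
```

The length growth rate in cm/year peaks a full year before the same
curve's rate in cm^2.5/year — purely because of the dimension mismatch.

Running the cohort analysis end to end:

```sh
python analysis/01_scaling_engine.py        # Fig-1-style analytic results
python analysis/02_calibrate_and_simulate.py
python analysis/03_fit_and_detect.py        # full pipeline on the seed-1 cohort
python analysis/04_replicate_landmarks.py   # medians over replicate cohorts
```

The replicate summary (master seed 1) prints, among others:

```
                     landmark  measured_median  generator_truth
female_forearm_corrected_peak             5.90              6.0
  male_forearm_corrected_peak             8.24              8.0
           female_weight_peak             5.85              6.0
             male_weight_peak             8.05              8.0
         male_creatinine_peak             9.68              9.5
   testosterone_decline_onset            29.49             30.0
                 dhea_plateau            15.11             15.0
      female_linear_scale_lag             0.71              1.0
              male_muscle_lag             1.63              1.5
```

i.e. the fitted trajectories recover the generator's landmark ages —
females reach peak growth velocity two years before males in both weight
and scale-corrected forearm length, the female spurt is also visible on
the plain cm scale but a year early, and the male muscle (creatinine)
spurt trails the weight spurt by about 1.5 years, in step with the
sex-specific testosterone rises. Single-cohort estimates wobble by a few
tenths of a year; the medians are the stable summary.

A CLI mirrors the library:

```sh
growthscale simulate --n-per-sex 80 --seed 1 --out cohort.csv
growthscale detect --in cohort.csv --variable forearm_cm \
    --dimension length_corrected --sex F --n-boot 200 --seed 1
growthscale report --in cohort.csv --out-dir results/run --seed 1
```

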