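"""Why linear length growth spurts hide: the volume/length scaling engine.

Evaluates the analytic engine over a family of polynomial volume
growth-rate curves: classifies the induced linear-length rate pattern for
pure power laws (V ~ t^m against dimension exponent k), scans how the
take-off age controls detectability, and measures the artifact lag
between the linear- and volume-scale velocity peaks of the calibrated
female reference curve.

Writes results/scaling_classification.csv, results/detectability_scan.csv
and results/scenario_example.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from growthscale.cohort import default_reference
from growthscale.scaling import (
    PowerLawScenario,
    classify_length_rate,
    detectability_scan,
    peak_lag,
    scenario_table,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []
for m in (1.0, 2.0, 2.5, 3.0, 3.5, 4.0):
    for k in (2.0, 2.5, 3.0):
        s = PowerLawScenario(baseline_rate=0, accel_coeff=m, accel_power=m - 1,
                             dim_exponent=k, initial_volume=1e-9)
        pat = classify_length_rate(s, (1.0, 10.0))
        rows.append({"volume_power_m": m, "dim_exponent_k": k, "label": pat.label,
                     "rule": "decreasing" if m < k else ("constant" if m == k else "accelerating")})
cls = pd.DataFrame(rows)
cls.to_csv(OUT / "scaling_classification.csv", index=False)
agree = (cls.label == cls.rule).mean()
print(f"pure-power classification matches the m-vs-k rule in {agree:.0%} of "
      f"{len(cls)} (m, k) combinations")

table, threshold = detectability_scan(
    baseline_rate=1.0, accel_coeff=0.6, accel_power=1.0, dim_exponent=3.0,
    t0_grid=np.linspace(0.0, 12.0, 25), t_max=20.0, initial_volume=0.5,
)
table.to_csv(OUT / "detectability_scan.csv", index=False)
det = table[table.detectable]
print(f"take-off-age scan: once an acceleration phase exists, its strength is "
      f"monotone non-decreasing in t0 ({bool(np.all(np.diff(det.max_d2L_dt2) >= -1e-12))}); "
      f"a detectable linear-length acceleration phase first appears at t0 = {threshold} y "
      f"(at-birth take-off shows only deceleration)")

params = default_reference()
t = np.arange(0.0, 25.0 + 0.005, 0.01)
res = peak_lag(lambda x: params.female.size.value(x) ** (1 / params.k), t, k=params.k)
print(f"calibrated female reference curve (k = {params.k}): linear-scale velocity "
      f"peaks at {res.linear_peak_age:.2f} y, corrected-scale at "
      f"{res.corrected_peak_age:.2f} y -> artifact lag {res.lag:.2f} y "
      f"even though the two curves describe the same growth")

scenario_table(
    PowerLawScenario(baseline_rate=1.0, accel_coeff=0.6, accel_power=1.0,
                     take_off_age=6.0, dim_exponent=2.5, initial_volume=0.5),
    t_max=20.0, step=0.01,
).to_csv(OUT / "scenario_example.csv", index=False)
print("wrote scenario_example.csv (volume spurt at t0=6 with k=2.5)")
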