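# abdoprofile

Quadratic-Bézier modeling of digitized thoracic-abdominal profile curves:
geometric adiposity metrics, interval-based profile classification, seeded
synthetic cohorts, and the accompanying cohort statistics workflow.

A profile is nine named landmark points `P0…P8` in a canonical frame
(`P0` at the anterior axillary fold = origin, `P2` on the positive y axis at
the iliac crest, y growing downward, x pointing anteriorly). The curve is two
linked quadratic Bézier segments — upper `(P0, P5, P3)` and lower
`(P3, P6, P2)` — from which the package derives:

* `t1`, `t4` — curve parameters of the extremum points `P1`/`P4`,
* `K1`, `K2`, `R1`, `R2` — curvatures and osculating radii at `P1`/`P4`,
* `SupArc`, `InfArc`, `TotalArc` — arc lengths (adaptive quadrature),
* `Area1`, `Area2`, `TotalArea` — areas split at the waist plane `y = y1`,
* `Vlow` — half volume of revolution of the axial parabola model,
* `AntPr`, `InfPr` — anterior/inferior projections of `P4`.

Profiles are then classified into raised/fallen (criterion I: `K2` + `InfArc`),
flat/prominent (criterion II: `K1` + `Area2`), projection bands
(criterion III), and the composite A/B steatosis-abdomen types.

## CLI

```bash
# power analysis of the Pearson correlation test
abdoprofile power --n 100 --rho 0.316 --alpha 0.05

# seeded synthetic cohort -> landmarks.csv + patients.csv (+ optional SVGs)
abdoprofile simulate --n 100 --seed 7 --out-dir cohort/ --svg-fixtures 3

# metrics from digitized landmarks (CSV or a two-Q-segment SVG path)
abdoprofile metrics --landmarks cohort/landmarks.csv --out metrics.csv
abdoprofile metrics --svg cohort/S0000.svg --out one.csv

# classification (thresholds overridable via INI config, strict/nearest modes)
abdoprofile classify --metrics metrics.csv --out classified.csv

# cohort statistics report (correlations, partials, regression, t-tests)
abdoprofile analyze --patients cohort/patients.csv --out-dir report/
```

Exit codes: `0` success, `1` domain/validation errors, `2` usage errors.
Logs go to stderr (`-v`/`-vv` for more detail). Output CSVs embed the seed
and command as leading `#` comment lines.

## File formats

* **Landmark table CSV** — header `patient_id,point_label,x,y`; one row per
  point with labels `P0…P8` (`P7` optional). Raw image coordinates are
  accepted; they are rigidly normalized into the canonical frame on read.
* **SVG ingest** — the first `<path>` must consist of a moveto plus exactly
  two quadratic (`Q`/`q`) segments. Anchors/controls map to
  `P0, P5, P3, P6, P2`; `P1`/`P4` are recomputed as the maximal-x on-curve
  points and `P8` is derived. SVG's y-down axis matches the canonical frame.
* **Patient table CSV** — one row per patient:
  `patient_id`, `sex`, `age`, `height`, `weight`, `bmi`, `wc`,
  `rhd`, `lhd`, `shd`, landmark coordinates `p0_x … p8_y`, the fifteen
  metric columns (`t1, t4, k1, k2, r1, r2, sup_arc, inf_arc, total_arc,
  area1, area2, total_area, vlow, ant_pr, inf_pr`) and the six
  classification columns (`criterion1, criterion2, antpr_band, infpr_band,
  type_a, type_b`). Floats are written with `%.17g` (lossless round trip);
  `#` lines are metadata. Comma delimiter, decimal point, UTF-8.

## Library sketch

```python
from abdoprofile import (
    ProfileLandmarks, compute_metrics, classify_profile,
    CohortParams, sample_cohort, run_study_analysis,
)

lm = ProfileLandmarks.from_raw({
    "P0": (0, 0), "P5": (60, 30), "P3": (40, 70),
    "P6": (55, 160), "P2": (0, 220),
})
metrics = compute_metrics(lm)
labels = classify_profile(metrics)

cohort = sample_cohort(CohortParams(n=100, seed=7))
report = run_study_analysis(cohort)
print(report.summary())
```

## Notes on fidelity

The printed closed-form arc-length expressions that this model mirrors
contain typographical defects; they are transcribed verbatim and exposed for
diagnostics (`printed_sup_arc`, `printed_inf_arc`, `closed_form_deviation`),
but all shipped arc lengths come from adaptive quadrature, cross-checked in
the tests against an independent Gauss–Legendre integrator. Curvature is the
standard unsigned plane-curve curvature. `Area2` is computed as
`TotalArea − Area1` so the waist-plane split is exactly additive. The
classification interval bounds are empirical cohort ranges: values in the
gaps are `indeterminate` by default, with an optional `nearest` mode.
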