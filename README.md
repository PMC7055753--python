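# vitalval

Validation analytics for consumer vital-sign monitors (smartwatches,
all-in-one "tricorder" style devices) tested against a hospital-grade
reference under the interleaved protocol used for sphygmomanometer
validation.

## The problem

Consumer devices that claim to measure systolic/diastolic blood pressure
(SBP/DBP), heart rate (HR) and oxygen saturation (SpO2) are sold widely with
little formal validation. The standard way to test one is an interleaved
session per subject:

```
slot:   1    2    3    4    5    6    7
        S    I    S    I    S    I    S        (60 s between readings)
```

with four standard (S) readings bounding three investigational (I) readings.
Because vitals drift during a session, each investigational reading is
compared with the **bounded-average reference**

&nbsp;&nbsp;&nbsp;&nbsp;ref<sub>i</sub> = (S<sub>2i−1</sub> + S<sub>2i+1</sub>) / 2,&nbsp;&nbsp;d<sub>i</sub> = I<sub>i</sub> − ref<sub>i</sub>,

giving up to three comparison pairs per subject per device-vital. Subjects
whose sequential standard readings vary by more than 12 mm Hg (SBP) or
8 mm Hg (DBP) are excluded from all analyses, per the validation guidelines.
Cuffless BP devices additionally take a cuff **calibration value** at setup,
whose influence on later accuracy this package quantifies.

`vitalval` implements the full analysis for anyone running such a study —
and a virtual-study simulator that generates cohorts with the same data
structure, so every stage is testable without clinical data.

## What it computes

* **Pairing & exclusion** — bounded-average references, per-slot retry
  handling (up to three attempts), guideline subject exclusion with the
  consecutive-delta rule (a max−min variant is available).
* **Agreement statistics** — mean absolute difference (MAD) with the sample
  SD of |d|, mean absolute percent difference, RMSE = √(Σd²/n),
  Bland-Altman bias and ±1.96 SD limits of agreement, and a
  normality-gated correlation (Shapiro-Wilk on OLS residuals selects
  Pearson vs Spearman; Spearman p-values are exact by permutation for
  n ≤ 9).
* **Standards grading** — BP guideline criterion (MAD ≤ 5 mm Hg with
  SD ≤ 8 mm Hg), British Hypertension Society grade A–D from the cumulative
  percentages of |d| within 5/10/15 mm Hg, HR criterion (MAD ≤ 5 bpm or
  mean absolute percent difference ≤ 10%), SpO2 criterion (RMSE ≤ 3.0%).
* **Clinical detection rates** — how often the device also flags readings
  the reference flags abnormal (SBP ≥ 140, DBP ≥ 90 mm Hg, HR < 60 bpm,
  SpO2 < 90%).
* **Failure accounting** — per-participant and per-measurement failure
  rates out of the 3-per-subject maximum.
* **Calibration dependence** — correlation of |ref − device| with
  |ref − calibration| (does accuracy degrade away from the calibration
  pressure?), with a signed "figure" variant.

## Worked example

Simulate a 127-subject study with two devices — a calibration-dependent
tricorder-like device (small bias, calibration coupling k = 0.5, ~5% slot
failures) and a watch-like device with a strong proportional bias and ~30%
slot failures — then analyze it:

```sh
vitalval simulate --config examples/study.yaml --seed 1 --out sim/
vitalval validate --records sim/measurements.csv \
                  --calibrations sim/calibrations.csv --out results/
```

`results/report.md` from that exact run begins:

```
Subjects: 127 enrolled, 33 excluded by the variation rules, 94 analyzed.

## tricorder
### SBP
- pairs: 271; MAD 5.20 (SD 3.78) mm Hg; RMSE 6.43 mm Hg
- guideline BP criterion: FAIL
- BHS grade B (within 5/10/15 mm Hg: 56/90/98%)
- hypertension_sbp: detected 48/53 (91%)
- failures: 11/282 measurements (3.9%) in 11/94 participants (11.7%)
...
## watch
### SBP
- pairs: 201; MAD 12.34 (SD 9.35) mm Hg; RMSE 15.46 mm Hg
- guideline BP criterion: FAIL
- BHS grade D (within 5/10/15 mm Hg: 29/48/67%)
...
## Calibration dependence (SBP)
- tricorder [text variant, 271 points]: coefficient 0.22 (spearman)
```

Reading it: ~26% of subjects tripped the 12/8 mm Hg variation rule; the
tricorder-like device misses the BP guideline (MAD > 5 mm Hg) but earns BHS
grade B and detects 91% of hypertensive references, while the watch-like
device is grade D with heavy failure rates; the positive calibration
coefficient shows its SBP error growing with distance from the calibration
value. `results/report.json` carries the same numbers machine-readably
(undefined statistics are explicit nulls with a reason, never 0).

The same pipeline runs on real study exports: any CSV with columns
`subject_id,vital,role,device,slot,attempt,value,failed` (and an optional
`subject_id,device,calibration_value` file) — see `vitalval validate --help`.

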