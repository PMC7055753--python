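# Methods

## Protocol model

One session per subject: seven measurement slots 60 s apart, standard
(reference monitor) readings at slots 1/3/5/7 and investigational readings
at slots 2/4/6, preceded — for calibration-dependent devices — by a cuff
calibration reading (slot 0). The reference value for investigational slot
2i is the mean of the bounding standards, (S₂ᵢ₋₁ + S₂ᵢ₊₁)/2; since standard
readings are integers, references are exact multiples of 0.5 and no floating
rounding is applied to them. A failed investigational attempt may be retried
up to twice in the same slot; only the final attempt's outcome feeds the
analysis, but every attempt stays in the record log, so per device-vital a
slot holds 1–3 records with at most one success. This gives the invariant
used throughout the bookkeeping: pairs + failed slots = 3 × analyzable
subjects.

## Subject exclusion

Following the sphygmomanometer validation guidelines the protocol is based
on, a subject is dropped from every vital's analysis when their standard
readings vary too much: by default, any consecutive delta |Sⱼ₊₁ − Sⱼ| above
12 mm Hg (SBP) or 8 mm Hg (DBP). "Variation" is read as the maximum
consecutive delta — the reading that matches the bounded-pair logic — with a
max − min alternative behind `ExclusionRule(mode="range")`, since the
guideline wording admits both. The decision reads standard records only
(a fuzz test perturbs investigational values and asserts the kept set never
changes). HR and SpO2 have no variation thresholds of their own; they
inherit the BP-based subject exclusion, so all vitals share one analysis
denominator. Subjects lacking a complete standard quadruple for a vital are
"unusable" for it — reported separately from exclusion, never silently
dropped.

## Statistics

All statistics act on the signed difference d = investigational − reference.

* MAD = Σ|dᵢ|/n with the sample SD (n−1 denominator; undefined at n = 1) of
  |d| — the headline BP outcome.
* Mean absolute percent difference = mean of 100·|dᵢ|/refᵢ (requires
  ref > 0) — the HR percent prong.
* RMSE = √(Σdᵢ²/n) — the oximetry outcome. The identity
  RMSE² = mean(d)² + ((n−1)/n)·Var(d) is asserted to 1e−9 in tests, along
  with MAD ≤ RMSE.
* Bland-Altman: bias = mean(d); limits = bias ± 1.96·SD. By default SD is
  that of the signed differences (standard Bland-Altman); a documented
  variant uses the SD of |d| for compatibility with reports phrased that
  way. The bias line is the mean signed difference in both.
* Correlation: Shapiro-Wilk (α = 0.05) on the residuals of the OLS fit of
  investigational on reference gates Pearson (p ≥ α) vs Spearman (p < α).
  Spearman ρ is Pearson on midranks; its p-value is an exact two-sided
  permutation enumeration for n ≤ 9 and the large-sample approximation
  above. When the fit is exact (zero residual variance) normality is
  untestable and Pearson is reported with a null normality p; zero variance
  in either margin yields an undefined coefficient with a reason string.
* Proportional bias: the same gated correlation between the reference value
  and d; negative means low values read high and high values read low.

## Standards

Thresholds are boundary-inclusive and overridable; shipped defaults:

| standard | rule |
|---|---|
| BP guideline | MAD ≤ 5 mm Hg AND SD(|d|) ≤ 8 mm Hg |
| BHS grade | A: ≥60/85/95% of |d| within 5/10/15 mm Hg; B: ≥50/75/90; C: ≥40/65/85; else D (all three must hold; best grade wins) |
| HR | MAD ≤ 5 bpm OR mean abs. percent difference ≤ 10% |
| SpO2 | RMSE ≤ 3.0% |

Detection rates count a pair abnormal when the *reference* satisfies the
clinical cutoff (SBP ≥ 140, DBP ≥ 90 mm Hg, HR < 60 bpm, SpO2 < 90%) and
detected when the *device* satisfies the same cutoff; with no abnormal
references the rate is undefined, not zero, and n_abnormal is always
reported alongside. Failure rates use max = 3 × kept subjects per
device-vital; a participant counts once however many slots failed.

## Calibration dependence

For cuffless BP devices calibrated once at setup, two formulations are
implemented because they probe different things: the default "text" variant
correlates |ref − cal| with |ref − device| (does absolute error grow with
distance from the calibration pressure?); the "figure" variant uses signed
excursions (ref − cal vs device − cal), where a perfectly tracking device
lies on the identity line. All pairs are pooled by default; a
per-subject-mean option collapses each subject to one point.

## The simulator

Per subject, each vital's latent trajectory is a baseline draw
N(mean, SD) — defaults SBP 125 (15), DBP 76 (9), HR 72 (12), SpO2 96 (2),
a resting adult outpatient cohort — followed by a Gaussian random walk
across the seven slots. The standard monitor reads truth plus N(0, σ) noise
(defaults σ = 3 / 2.5 / 2 / 1 for SBP/DBP/HR/SpO2), quantized to display
resolution. Investigational readings are

    reading = base + slope·(true − anchor) + bias + noise,  rounded to integers,

where base is the current true value, or — for calibration-dependent SBP —
cal_reading + k·(true_now − true_at_calibration) with coupling k ∈ [0, 1]:
k = 1 tracks pressure, k = 0 replays the calibration value. The calibration
truth is anchored at the slot-1 time point, matching a cuff reading taken at
the start of the session. Each attempt fails independently with probability
p, so a slot fails with p³ after three attempts. Readings are clamped to the
vital's displayable range before rounding. Per-subject random streams are
keyed by subject index, so trajectories are independent of cohort size and
identical (config, seed) give byte-identical CSVs.

**Free parameters.** The within-session drift SD is not identifiable from
published summaries; the default (3 mm Hg per slot for SBP, 2 for DBP, 1.5
bpm HR, 0.3% SpO2) was chosen once so that with the default monitor noise
roughly 30% of subjects trip the 12/8 mm Hg variation rules — the
qualitative regime of guideline-based studies, not a fitted quantity.

**What the simulator does not model**: circadian/posture effects,
arrhythmia, correlated failures (cold hands affecting a whole session),
reading-level heteroscedasticity, or raw ECG/PPG signals. Passing tests
therefore demonstrate the *analysis* is correct under the stated error
structure, not that any physical device behaves this way.

## Numerical and design choices

* Rounding: readings quantize with floor(x/res + 0.5), avoiding banker's
  rounding, after noise addition (display granularity acts on the final
  value).
* SpO2 baselines are redrawn until inside (0, 100] and trajectories are
  clamped at 100%.
* Exclusion thresholds strict ("greater than 12/8"); standard thresholds
  inclusive ("≤").
* Undefined statistics serialize as nulls with a reason; the report JSON is
  deterministic (sorted keys) given dataset + config.
* Problem sizes in the test-suite oracles — 10,002 pairs for the
  folded-normal recovery, 1,000 subjects for the exclusion and binomial
  checks, 20 seeds × 200 subjects for the calibration direction — were
  chosen so Monte-Carlo error sits well inside the asserted tolerances
  while the whole suite runs at desk scale.

## Known limitations

* The exclusion rule is applied to BP only; studies of devices measuring
  neither BP vital have no exclusion stage (the rules are skipped when no
  standard records exist for the rule's vital).
* Calibration failure (a subject excluded because the device never
  calibrates) is not simulated; calibration readings always succeed.
* The exact-permutation Spearman p is O(n!) and capped at n = 9 by design.
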