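# Methods

## The measurement problem

Hip-worn accelerometers estimate physical-activity intensity well, but a hip
sensor alone cannot tell sitting from standing: both are still. Sedentary
behavior (SB) is defined by *intensity and posture together* — waking
behavior at or below 1.5 metabolic equivalents (MET) while sitting,
reclining or lying — so an intensity-only pipeline mislabels quiet standing
as sedentary. The angle-for-posture-estimation (APE) approach closes the gap
with two physical facts: Earth's gravity vector is constant, and walking
posture is upright. The device orientation captured during recognized
walking serves as the upright reference; the angle between the current
orientation and that reference proxies trunk posture without knowing how the
sensor was mounted.

## Pipeline model

### Epoch features

Raw triaxial acceleration (default 100 Hz, ±16 g range, 0.004 g resolution,
values in g) is cut into half-open 6 s epochs aligned to the recording
start; a trailing remainder is dropped. For samples (x_i, y_i, z_i) with
resultant r_i = √(x_i² + y_i² + z_i²) and epoch means R_ave, X_ave, Y_ave,
Z_ave:

* MAD = (1/N) Σ |r_i − R_ave| — mean amplitude deviation, reported in mg;
* MADxyz = (1/N) (Σ|x_i − X_ave| + Σ|y_i − Y_ave| + Σ|z_i − Z_ave|).

MAD converts to MET piecewise:

| condition | conversion |
|---|---|
| MAD < 91.5 mg | MET = 1.0000 + 0.0223·MAD |
| 91.5 ≤ MAD < 500 mg | MET = 2.1488 + 0.0093·MAD |
| MAD ≥ 500 mg | MET = 0.4027 + 0.0107·MADxyz |

The conversion is implemented exactly as published, including its small
*downward* discontinuity at 91.5 mg (3.0404 from the first piece versus
2.9996 from the second); a pinning test asserts this deliberately. The
sedentary gate that routes epochs into the posture analysis is the
operational rule MAD < 22.5 mg, even though the first piece reaches 1.5 MET
at ≈ 22.42 mg; the printed 22.5 mg rule wins and the discrepancy is noted
here rather than silently resolved.

### Walking recognition and the posture angle

The epoch orientation ê is the epoch-mean acceleration vector normalized to
unit length. An epoch is *normal walking* when MAD ∈ [150, 350] mg, the
step count ∈ [8, 13] per 6 s, and the steadiness ratio MADxyz/MAD < 1.6
(strict). Each walking epoch sets the upright reference û := ê
(most-recent-setting-wins; no backfill before the first setting by default,
so no future information is used — an optional backfill flag serves
whole-file batch analysis). For each worn stationary epoch,

    APE = arccos(ê · û)  ∈ [0°, 180°],

with the inner product clamped to [−1, 1] to absorb rounding. Classification
uses cut-points 11.6° (standing/sitting), 30° (sitting/reclining) and 73.9°
(reclining/lying); stationary time is also histogrammed into 18 bins of 5°
(the last bin open at 85°), each annotated with its descriptive behavior
(standing < 10°, standing–sitting transition 10–15°, desk sitting 15–30°,
sofa sitting 30–55°, sitting–lying transition 55–75°, lying ≥ 75°). All
cut-points and criteria are configurable; the defaults are the published
values.

Step counting is not prescribed by the published method; the detector here
band-passes the resultant to 0.5–3 Hz (2nd-order Butterworth, zero-phase)
and counts maxima with a 0.25 s refractory period and ≥ 100 mg prominence,
which matches the implied cadence of 8–13 steps per 6 s and returns zero on
sub-50 mg noise.

### Trigger emulation and non-wear

The logger's two-stage trigger is re-purposed as a software quiescence
detector: from quiescent, any-axis |a − reference| > 187.5 mg *arms* the
machine; a further any-axis difference > 500 mg within the next 5 s confirms
activity (active from the arming sample onward), otherwise the window stays
quiescent. Reference values update with the coincident sample on every
threshold exceedance. Two details are under-specified by the published
description and fixed here by convention, pinned by a hand-traced oracle
test: (a) reference updates apply during the armed window as well; (b) an
active bout ends when no arm-level exceedance occurs for one confirmation
window — the symmetric counterpart of the arming rule. The per-sample mask
is down-sampled to per-second resolution, and quiescent runs *strictly*
longer than 120 min become non-wear (a run of exactly 120 min is wear).

A consequence worth knowing: a wearer who is perfectly motionless for over
two hours is indistinguishable from an unworn device. The synthetic
generator therefore injects sparse fidget pulses (below), and real
recordings rely on physiological micro-movement.

### Validity and summaries

Days require essentially complete wear (≥ 1436 of 1440 min — the published
rule says "complete 24 h" without a tolerance, so the 4 min slack is a
configurable package choice) and ≥ 10 reference settings; participants
require ≥ 4 valid days, and per-bin daily means are taken over valid days
only. MET time uses nine 1.5-MET bins rolling up to stationary / light /
moderate / vigorous / very-vigorous categories. Sleep-log intervals are
excluded from all behavior summaries (the device moves to the wrist in
bed); hour-by-hour profiles split stationary time at APE 30° (at least 30°
counts as reclining/lying) and average over valid days of the requested
type, with weekends defined as Saturday/Sunday in local time.

### Cohort statistics

Participants are grouped into sex-specific VO2max tertiles and BMI
categories cut at 25 and 30 kg/m² (boundaries inclusive in the mid
category). Age–sex weights equalize the shares of the sex × age-decade
cells (20–29 … 60–70, with 70 included); targets are equal across observed
cells, and an empty canonical cell raises a warning. The partial Spearman
correlation is computed as rank-transform of the two variables, weighted
least-squares residualization on (intercept, sex indicator, centered age,
centered age²), then weighted product-moment correlation of the residuals;
centering the age before squaring curbs collinearity, and weights act as
frequency weights. Group differences use the Kruskal–Wallis omnibus test
(scipy) with a hand-implemented Dunn's pairwise z test (standard tie
correction) and Bonferroni adjustment; group tests run unweighted with the
weights reported alongside, since the published workflow does not state how
weighting entered the tests.

## Synthetic data: what it emulates, and what it does not

The generator scripts ordered activity segments. Stationary segments orient
the 1 g gravity vector at the scripted tilt (about the mediolateral axis)
from the upright reference; walking adds A·sin(2πft) along the
body-vertical axis plus a 0.3·A harmonic at 2f on the anteroposterior axis,
with A started from the closed form MAD = 2A/π and refined by measuring the
realized MAD (converges well inside the ±10 % target tolerance). The
harmonic fraction is 0.3 rather than larger because the steadiness ratio of
this minimal two-sinusoid model is ≈ 1 + fraction/0.5 · 0.5; at 0.5 the
ratio sits at ~1.5, leaving no margin to the 1.6 walking criterion under
any mount rotation, while 0.3 keeps walking recognizable under moderate
mounting misalignment. A fixed mount rotation composes with everything;
white noise (default 5 mg), 0.004 g quantization and ±16 g clipping follow.
Non-wear segments emit exactly constant gravity. Worn stationary segments
receive a 1 s, 0.8 g fidget pulse roughly every 30 min (jittered ±60 s) so
that long still postures are not misread as non-wear.

Ground-truth labels are emitted on the same 6 s grid the pipeline uses,
labeling each epoch by the segment covering its midpoint.

What passing tests on this data do **not** show: real gait is impulsive and
broadband, soft-tissue motion decorrelates the sensor from the trunk, and
real posture is never held at an exact tilt — so the ≥ 95 % label-recovery
results here demonstrate the correctness of the geometry and bookkeeping,
not field accuracy. The synthetic cohort likewise plants clean monotone
effects of BMI and fitness on per-bin minutes (opposite signs below 25° and
at or above 30°, scaled by bin size, with ~12 % noise) to verify sign
recovery, not effect magnitudes.

## Numerical and design choices

* Epochs align to the recording start, not wall-clock minutes; hourly
  summaries use epoch start times.
* mg↔g conversion happens exactly once, at feature computation; raw storage
  is always g.
* Thresholds compare strictly (">" for "exceeded", "<" for the steadiness
  ratio and sedentary gate); intensity and step walking limits are
  inclusive.
* The confirmation window is `round(5 s × fs)` samples after the arming
  sample, inclusive of its last sample.
* Undefined quantities (orientation of a zero-norm mean vector, MAD of a
  1-sample block, APE before the first reference) propagate as NaN /
  'undefined', never as silent zeros.
* Day-long simulations in the test suite run at 20–25 Hz sampling — the
  method is rate-agnostic and this keeps the suite quick; the package
  default stays 100 Hz.

## Known limitations

* Step detection is a package choice (the published criterion states counts,
  not an algorithm); different detectors shift the walking-recognition
  margin.
* The quiescence re-purposing means motionless wear > 120 min is lost as
  non-wear; this is inherent to the rule, not an implementation artifact.
* Large mount rotations (≳ 30–40°) inflate MADxyz relative to MAD for
  near-sinusoidal gait and can defeat walking recognition in synthetic
  data; real broadband gait is less sensitive.
* Weighted partial Spearman treats weights as frequency weights; no
  design-effect correction is applied to its p-value.
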