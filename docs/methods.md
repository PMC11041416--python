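# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, the numerical choices, and the known limitations
of `hragree`. It describes what the code does and why; every number
quoted as an outcome here is computed by the tests or by
`scripts/acceptance.py`, not asserted from memory.

## 1. The measurement problem

Two devices record the same exercise session: a chest-strap reference
producing beat-level R-R intervals (ms), and a wrist device producing one
HR value per minute (bpm). The reference is treated as gold standard.
The scientific questions are (i) how biased the test device is at rest
and during high-intensity exercise, (ii) what functional relationship
links the two devices' session means, and (iii) how reliably the test
device identifies sessions that exceed an intensity threshold defined as
a fraction `p` of the age-predicted maximum HR, `HRmax = 220 − age`.

## 2. Preprocessing

**Reference chain.** R-R intervals are converted to instantaneous HR
(`60000/RR`, attached to each beat's timestamp), linearly interpolated
onto a 1-second grid, low-pass filtered, averaged into 10-second slots
and then into minutes. The filter is a 5th-order Butterworth with 0.1 Hz
cutoff, applied forward-backward (`scipy.signal.filtfilt`) so it has
exactly zero phase: a single-pass filter of this order delays the signal
by tens of seconds, which would systematically misalign the two devices.
The cutoff is normalized against the 0.5 Hz Nyquist frequency of the 1-s
grid. The two-pass application squares the magnitude response; at
0.25 Hz the analytic single-pass gain is `1/√(1+(0.25/0.1)^10) ≈ 0.010`,
so two-pass attenuation is ~10⁴ — the test suite asserts the much weaker
contract (DC gain 1 ± 1e-6, ≥ 20× attenuation at 0.25 Hz, passband
amplitude at 0.01 Hz within 5%) on interior samples, away from the
`filtfilt` edge transients.

A digital cutoff in Hz is only defined on a uniform grid, and the raw
beat series is irregular; 1 s was chosen as the pre-filter grid because
it preserves beat-scale detail at every physiological HR. Grid ticks sit
on the whole-second lattice counted from the manifest's session start
(first tick at or after the first beat, last at or before the last
beat, no extrapolation) so that later minute bins line up across
devices.

**Binning.** All bins are left-closed right-open and labelled by bin
start. A coarse bin is *present* when at least 80% of its constituent
slots are present, and is then the mean of the present slots. The
threshold cannot be 100%: the first beat necessarily falls strictly
after the session start, so second 0 is never on the grid and a strict
rule would void minute 0 of every session, making baseline analysis
impossible. 80% also tolerates occasional dropped test-device minutes
inside 10-minute averages without letting half-empty bins through.

**Validity gate.** Per-minute values outside (20, 250) bpm are set
missing and logged. This is data hygiene against corrupt rows, not a
protocol rule.

**Pairing and exclusion.** Devices are paired on identical absolute
minute indices; only minutes present in both survive. Missing minutes
are excluded pairwise, never imputed. Sessions with fewer than 20 paired
minutes are excluded and logged with a machine-readable reason
(`missing_file`, `reference_stream:…`, `no_overlapping_minutes`,
`too_few_paired_minutes:n`, `no_gap_free_20min_window`); exclusion
accounting is a first-class output because real device studies lose a
substantial fraction of sessions.

## 3. Session features

* **Baseline HRμ**: mean of each device over paired minutes 0–4. If any
  of the first five minutes lacks a pair the baseline is reported absent
  (participants arriving late or starting the device late make a partial
  rest mean uninterpretable); such sessions still contribute to the
  high-intensity analyses.
* **Peak-20 HRμ**: among windows of 20 *consecutive present* paired
  minutes (step 1 min; windows spanning dropout gaps are not 20-minute
  intervals and are skipped), the window with the highest reference-series
  mean is located, and **both** devices are averaged over that shared
  window. Ties go to the earliest start. The window is deliberately
  chosen once, on the gold standard, rather than per device: letting
  each device maximise over windows lets the noisier test channel pick
  its luckiest window, inflating its apparent peak by an amount that at
  cohort scale is several standard errors — a time-window disagreement
  masquerading as an HR disagreement. The per-series sliding-window
  operation `peak20_mean` is exposed and oracle-tested on its own.
* **Intensity ratio**: `HR_N = HRμ / (p · (220 − age))`. A session is
  positive iff `HR_N > 1`, strictly: a ratio of exactly 1 counts as
  negative. With the reference as truth this yields TP/FP/TN/FN per
  session; classification uses the peak-20 means, which define what a
  high-intensity session is.

## 4. Agreement statistics

**Bland-Altman.** Differences are test − reference per session mean;
bias is their mean, and the limits of agreement are bias ± 1.96 SD with
the n−1 SD denominator. Computed for the cohort and per participant,
separately at baseline and high intensity; the overall mean bias is the
average of the two condition biases. Participants with fewer than two
usable sessions in a condition are reported with their n and no
statistics.

**Model families.** The pooled baseline + high-intensity session means
(reference on the abscissa) are fitted with four families:

| family | form | k |
|---|---|---|
| linear | α + βx | 2 |
| logarithmic | α + β ln x | 2 |
| negative exponential | α − β e^(−γx), γ > 0 | 3 |
| sigmoid | a + (b−a)/(1+e^(−(x−c)/d)), d > 0 | 4 |

and ranked by the Gaussian least-squares AIC, `n ln(max(RSS,1e-12)/n) + 2k`.
`k` counts curve parameters only; the error-variance term is a constant
offset within one dataset and cancels in the comparison, the only use
made of AIC here. Ties go to the smaller k. The linear and logarithmic
families are solved in closed form; the nonlinear families use
`scipy.optimize.curve_fit` with deterministic multi-starts (sigmoid:
c ∈ {25, 50, 75}th percentile of x crossed with d ∈ {range/10, range/4},
plus one start derived from the OLS line so a near-linear relationship
is always reachable; negative exponential: three decay-rate scales with
the linear-in-(α, β) profile solved first). Sigmoid parameters are
bounded to physiological bpm ranges (a ∈ [0, 120], b ∈ [80, 260], d > 0)
to prevent degenerate flips. A family whose starts all fail is reported
as a failed fit with infinite AIC and skipped by selection, with a
warning rather than an abort. Predictions outside the fitted reference
range are flagged as extrapolation: a saturating relationship fitted on
60–160 bpm says nothing trustworthy outside it, and the package
deliberately offers no regression-based recalibration of the test
device.

**Diagnostics.** Sensitivity, specificity, PPV and NPV come from the
session confusion counts; any metric with a zero denominator is
undefined (NaN), never coerced, because coercion silently biases the
ROC. The ROC sweeps the threshold fraction p over a grid (default 0.40
to 1.10, step 0.01) with **both devices re-classified at each p** — the
gold-standard labelling shifts with p, exactly as it does between the
fixed 70% and 85% operating points, whose negative-class sizes are
incompatible with any single fixed labelling. Undefined points are
skipped; swept points are sorted by FPR with TPR averaged at duplicate
FPR values, framed by the (0, 0) and (1, 1) anchors, and integrated by
the trapezoid rule.

## 5. The synthetic cohort

The generator emulates the study conditions the analysis assumes; it is
the package's only data source and is first-class, tested code.

* **Cohort**: the default `table1-cohort` preset has 11 participants
  with ages {58, 73, 60, 63, 63, 76, 56, 68, 67, 67, 68} and session
  counts {81, 43, 55, 38, 56, 98, 61, 28, 43, 56, 36} (595 one-hour
  sessions; mean ≈ 54 per participant), with fixed plausible resting HRs
  of 58–70 bpm for older adults.
* **Protocol**: rest 5 min at intensity 0, warm-up 10 min at 0.50, high
  intensity 30 min at 0.85, cool-down 15 min at 0.30, where intensity is
  a fraction of heart-rate reserve: each phase's target is
  `resting + intensity · (220 − age − resting)`.
* **Latent trajectory** (1-s cadence): phase targets approached with a
  first-order exponential, time constant 60 s — realistic cardiac ramping
  with no extra parameters — plus stationary Ornstein-Uhlenbeck noise
  (SD 2 bpm, correlation time 30 s, exact AR(1) discretization).
  White noise would be annihilated by the pipeline's own 0.1 Hz filter,
  making the filter tests vacuous; real beat-to-beat HR is autocorrelated.
* **Reference emission**: beats fire when the integral of hr/60 beats·s⁻¹
  crosses successive integers; each R-R interval gets Gaussian jitter
  (preset SD 5 ms — ECG chest-strap grade; tens of ms would be
  PPG-grade error and would visibly bias `60000/RR` through Jensen's
  inequality at high HR) and is clipped to ≥ 250 ms.
* **Test emission**: each full minute's true mean passes through a
  four-parameter logistic distortion `g`, then Gaussian noise (preset
  SD 3 bpm) is added and the minute is dropped with probability 0.03.
  Presets: `saturating` (a=20, b=160, c=100, d=30 — near-unit slope at
  moderate HR, saturation above ~150 bpm, the study condition);
  `identity-clean` / `identity-noisy` (c=100, d=1000, a=c−2d, b=c+2d:
  unit slope at c and cubic error `(h−c)³/(12d²)` below 0.09 bpm across
  40–200 bpm, used for null tests); `identity-bias6` (the same shape
  shifted +6 bpm, used for bias-recovery studies).
* **Determinism**: per-session seeds are SHA-256 hashes of
  (master seed, participant id, session index), so regeneration is
  byte-identical and independent of iteration order. A ground-truth
  sidecar records each session's latent minute means exactly.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: motion-artifact bursts, ectopic beats
and arrhythmia, device clock drift, the wrist device's actual (unknown,
proprietary) internal averaging — the generator's minute values are true
minute means by choice, since whether real devices report instantaneous
or averaged values is unknown — and any dependence of device error on
movement type or skin contact. Recovery results on synthetic cohorts
demonstrate that the *pipeline* is unbiased and identifies its model,
not that any particular device has a particular bias.

## 6. Problem sizes and numerical choices

The test suite and acceptance script use: the full 595-session cohort
for the end-to-end study and bias recovery; 500 sessions for sigmoid
parameter recovery (midpoint and scale within 15% relative error); 100
replicate 500-session cohorts, generated with a session-mean-level
shortcut that applies the identical distortion/noise model (documented
in `simulate_session_means`), for the AIC model-selection rate; 10,000
Gaussian differences for limits-of-agreement coverage (95% ± 2%); and
200 random gap-containing series for the sliding-window oracle check.
These sizes make the whole suite run in about a minute on one core
while leaving Monte-Carlo margins comfortably away from their bounds.

Numerical details worth knowing: the RSS guard `max(RSS, 1e-12)` keeps
AIC finite on perfect fits; beat emission tolerates 1e-9 cumulative
round-off so a boundary beat is not dropped; sample SDs use ddof=1
throughout; exact window-mean ties break to the earliest start; ratio
exactly 1 classifies negative; undefined metrics propagate as NaN.

## 7. Known limitations

* The first paired minute of the reference channel averages ~59 of 60
  seconds (see §2); the residual effect on minute means is < 0.01 bpm at
  rest but grows during steep ramps.
* Filtering smooths phase-transition kinks; minutes containing a phase
  change can differ from the unfiltered truth by a few tenths of a bpm.
  This is inherent to filtering before averaging, and affects both the
  synthetic truth comparison and real data equally.
* The sigmoid bounds assume adult human bpm ranges; data far outside
  them (e.g. paediatric or animal HR) would need different bounds.
* Per-participant limits of agreement treat sessions as independent;
  within-participant correlation across sessions is not modelled.
* The ROC construction re-labels the gold standard at every threshold
  (a "joint sweep"); with a single fixed labelling the curve and AUC
  would differ. Both constructions are defensible; the joint sweep is
  the one consistent with how the fixed operating points behave.
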