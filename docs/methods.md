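# Methods

This note documents the models and procedures implemented in `edgemonitor`,
the assumptions behind them, the tunable parameters and their defaults, and
what the synthetic cohort does and does not emulate.

## Personalised alert thresholds

Resting SpO2, pulse rate and daily symptom burden vary widely between
people with COPD, so a single population-wide alert threshold either
floods some patients' reviewers with false alerts or misses real
deterioration in others.  The engine therefore learns univariate,
per-patient thresholds from a run-in period of the patient's own
self-monitoring data.

For each parameter, the first `training_size` observations
x₁,…,xₙ (default n = 40, roughly the first six weeks of near-daily use;
a 50-observation preset is also provided) define a Gaussian kernel
density estimate.  Its smoothed CDF is

    F(x) = (1/n) Σᵢ Φ((x − xᵢ)/h)

with Φ the standard normal CDF.  The alert threshold is the quantile
F⁻¹(p): p = 0.95 for symptom score and pulse rate (alert on values
strictly above), p = 0.05 for SpO2 (alert on values strictly below).
F is strictly increasing, so the quantile is unique; it is found by
bisection on the bracket [min xᵢ − 10h, max xᵢ + 10h] to a CDF tolerance
of 1e−9.  By construction, a patient whose physiology is stationary after
the run-in crosses each threshold on about 5% of subsequent days; because
the kernel smoothing slightly widens the fitted distribution relative to
the empirical one, the realised rate sits just below 5% (the acceptance
script measures ≈4.6–5.0% depending on seed).

**Bandwidth.** h follows Silverman's rule of thumb,
h = 0.9·min(sd, IQR/1.34)·n^(−1/5), with a per-parameter floor `h_min`
(0.25 % for SpO2, 1.0 bpm for pulse rate, 0.25 for the symptom score).
The floor keeps the estimate non-degenerate for constant or heavily tied
run-in data — the symptom score is an integer sum (0–27) treated as
continuous, and the floor absorbs its discreteness.  Gaussian kernels are
used so that both the PDF and CDF are smooth.

**Baseline-shift retraining.** Thresholds trained on an old baseline go
stale when a patient's physiology changes persistently (disease
progression, therapy change).  The shift rule compares the median of the
most recent `shift_window` values (default 14) against the training
median, on the training data's robust scale (1.4826·MAD, floored at
`h_min`): a parameter is flagged when |Δmedian| > k·scale with k = 2.
Flagged parameters are refitted on the most recent `training_size`
values; unflagged parameters are returned bit-identical, and every
retraining is appended to the threshold's provenance record.  The rule is
this package's own construction — medians and MAD were chosen over means
and SD so that exacerbation spikes inside the comparison window do not
masquerade as baseline shifts.  At the simulator's default SpO2 profile
(sd 1.4 %), a −5-point step is ≈3.6 robust scales and is detected in
>99% of runs; at the widest cohort sd (2.0 %) the same absolute step is
only 2.5 scales and power drops to ≈90% — an inherent property of any
scale-relative rule.  Both a detect-only and an auto-retrain mode are
exposed, since either could be embedded in a nurse-confirmed workflow.

## Alert workflow

A session raises at most one alert per parameter; crossings are strict
(a value exactly on the threshold does not alert).  Review actions
"patient contacted" (e) and "sign-off" (g) suppress the patient's alert
emission for the 3 days following the action; suppression applies to
emission only — sessions are always stored and analysable.  Vitals from
best-effort-quality recordings still alert by default but carry a
`quality_caveat` flag (configurable to exclude).

Alerts within a 7-day window are clustered greedily left to right: a new
cluster starts at the first alert strictly more than 7 days after the
current cluster's start, so each cluster spans at most 7 days and the
clusters partition the alert stream.  Window anchoring at the cluster
start is the simplest reading of "within a 7-day window"; it counts
episodes rather than raw crossings.

Patients are ranked for review by the number of alerts in the
intersection of the trailing 14-day window and the period since the last
review, i.e. timestamps in (max(now − 14 d, last_review), now]; both the
window length and the use of the intersection are configurable since the
workflow phrase "most recent two weeks since the last review" admits
either reading.  Ties break by most-recent alert, then patient id, so the
ranking is deterministic under permutation of its input.

## Oximetry acquisition protocol

The oximeter streams SpO2/pulse at 3 Hz plus a 75 Hz PPG waveform, with a
per-sample signal-quality flag supplied by the device.  A recording is
high quality when it contains a contiguous artefact-free run of ≥ 30 s.
The state machine records 30 s; on failure extends the same recording by
10 s and re-checks; on failure offers exactly one fresh attempt with the
same logic; and otherwise keeps the best attempt as *best effort* —
retained and flagged, never shown to the patient.  There is never a third
attempt, and never more than one extension per attempt (both are asserted
by instrumented sources in the tests).  Two interpretations are fixed
here as design choices: "sufficiently high quality" after the extension
means the same ≥ 30 s clean-run criterion, and the second attempt mirrors
the first's extension logic (the symmetric reading).

The session-level SpO2/pulse summary is the median over the accepted
clean window (over all samples for best-effort outcomes); the median was
chosen because isolated spikes inside an accepted window should not move
the stored value.  The SQI is consumed as given per-sample flags; the
package does not attempt to reproduce any manufacturer's proprietary
quality index.  `synthesize_ppg` provides deterministic synthetic
recordings (pulse-shaped waveform, configurable artefact segments) for
fixtures and demos only.

## Questionnaires

The daily symptom score is the sum of nine ordinal diary items.  The item
response scale is configuration (default 0–3, a common symptom-diary
Likert range), so the score is bounded by 9·item_max.  The monthly mood
flow always administers the PHQ-2 and GAD-2 screeners; a screener score
at or above its gate (standard screening cutoff 3, configurable) triggers
the corresponding full instrument (PHQ-8, 0–24; GAD-7, 0–21), and a
failed gate never does.  The GP flag fires on a severe full-scale score
(PHQ-8 ≥ 20 or GAD-7 ≥ 15) or an increase of ≥ 10 full-scale points over
the previous administration; all cutoffs are configuration with these
documented defaults, and no clinical-validity claim is attached to them.
"Monthly" is a 28-day interval, exact-boundary inclusive, for determinism
across calendar months.  Content selection maps instrument score bands to
video/content tags through a pure, order-deterministic rule table.

## Usage analytics

Weekly compliance is the number of distinct days with ≥ 1 session in a
7-day block (max 7; duplicate same-day sessions count once).  Patient
weeks are consecutive 7-day blocks anchored at each patient's first
session; cohort summaries group weeks by the calendar month containing
the week start and report mean (sd) across patient-weeks, flagging months
with fewer than `min_participants` active patients (≥ 1 session that
month) as excluded rather than dropping them silently.

The learning curve pools diary completion times by month in the study —
30-day blocks from each patient's enrolment (their first session), since
the per-month grouping does not otherwise define a month length — and
summarises each month as an empirical CDF; proficiency shows as the CDFs
drifting toward the y-axis.  Time-of-day habit uses circular statistics:
the modal hour over 24 hourly bins and the fraction of sessions within
±2 h circular distance of it (midnight wraparound honoured).  Nurse
workload reports per-action totals, per-patient means ± sd, and per-month
rates (mean / months of participation, with no internal rounding so
rate × months reproduces the mean exactly).

## Synthetic cohort

The simulator generates the study conditions the rest of the engine
assumes.  Per patient: SpO2 day values from a normal truncated above at
100% (baseline mean drawn U[88, 96]%, sd U[0.8, 2.0]%; truncation by
rejection so the analytic quantiles are exact), pulse from a normal
(mean U[65, 95] bpm, sd U[3, 8]), nine symptom items i.i.d. from an
ordinal distribution (default P(0..3) = 0.55/0.30/0.10/0.05), daily
adherence Bernoulli(6/7), a habitual clock hour U[6, 23] with 1 h
Gaussian jitter, and ~11% diary-only sessions (no oximetry).  Episodic
exacerbations arrive as a Poisson process (default 2/year, geometric
duration with mean 7 days) during which SpO2 drops 4 points while pulse
rises 10 bpm and the symptom score ~6 points; they are the only
non-stationarity by default, so baseline drifts are injected explicitly
(`inject_baseline_shift`) when a detector is under test.  Diary
completion time is lognormal with a median decaying from 150 s to 60 s
(time constant 25 days, σ = 0.3), so after the third month ~95% of
diaries complete within 100 s.

Every session's vitals pass through the real acquisition protocol on
synthetic flag patterns.  Each attempt is clean with probability 1 − q,
artefacted-but-recoverable (extension succeeds) with probability q·r, and
unrecoverable otherwise; with the defaults q = 0.37, r = 0.30 the
best-effort fraction is (q(1−r))² ≈ 6.7%, the calibration target for
low-quality sessions.  Everything is deterministic under the cohort
master seed via `SeedSequence` spawn keys, so serialised cohorts are
byte-identical across runs and adding patients does not reshuffle
existing ones.

**What the simulator does not emulate.** Physiologically detailed
exacerbation dynamics (onset/recovery ramps, symptom-vitals lag),
autocorrelated day-to-day vitals, seasonal effects, dropout and
device-failure patterns, and waveform-level PPG realism beyond what the
quality protocol consumes.  Passing tests therefore demonstrate the
engine's behaviour under its stated statistical assumptions, not clinical
performance on trial data.

## Problem sizes and numerical choices

The validation suite exercises: the stationary alert-rate property on 100
patients × 200 sessions (the tail-mass calibration of the KDE quantile);
shift detection and post-retrain recovery over 1000 replicates at the
default patient profile; KDE inversion against direct quadrature of the
kernel density on 100 random models (agreement to 1e−6); the protocol
decision table by exhaustive enumeration; and qualitative cohort-scale
patterns on 30 patients × 180 days.  CDF inversion tolerance is 1e−9;
ties in the habit histogram resolve to the earliest hour; degenerate
inputs (constant run-ins, empty windows, partial diaries) are either
handled through documented floors or rejected with named-field errors,
never coerced.
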