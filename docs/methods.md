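# Methods

This note documents the models, estimators, calibrations and numerical
choices behind `slicephys`, in the package's own words. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Data model

A `Trace` is one uniformly sampled channel (default 10 kHz): membrane
voltage in mV under current clamp, membrane current in pA under voltage
clamp. All times are in seconds from trace start; analysis windows are
half-open `[start, end)`. A `ProtocolAnnotation` carries intracellular
pulse times/amplitudes, the extracellular burst-stimulation window (the
reference protocol is 20 pulses at 100 Hz, i.e. a 0.2-s train), the
pharmacological condition and cohort labels. The liquid-junction
potential (−5 mV for the K⁺-based internal solution) is applied once at
load time when the metadata requests it and recorded as applied, so
downstream stages never re-apply it.

## 2. Intrinsic pipeline

**Spike detection.** The action-potential threshold is the membrane
potential at which dV/dt reaches 10 V/s. dV/dt is a 3-point central
difference of the smoothed trace; smoothing is a zero-phase *Gaussian*
kernel with −3 dB at 1 kHz. A Gaussian was chosen over a
forward–backward recursive filter deliberately: the recursive filter's
impulse response undershoots just before a fast upstroke, which delays
the measured dV/dt crossing by more than a sample and biases the
threshold by >1 mV; the Gaussian kernel is positive and preserves
linear-in-time segments of dV/dt exactly. The crossing is interpolated
to sub-sample precision and the threshold voltage is read from the *raw*
trace at the interpolated time (the smoothed trace carries a curvature
offset ≈ a·σ²/2 exactly where dV/dt accelerates). Spikes whose peak —
parabolically refined from the three samples around the maximum — stays
below 0 mV are discarded, matching the recording-quality inclusion rule.

**Waveform features.** Amplitude is threshold→peak; half-width is the
width at threshold + amplitude/2 with linear interpolation of the flank
crossings on the raw trace; the AHP amplitude is threshold minus the most
negative smoothed potential between the peak and min(next threshold,
200 ms). Spikes truncated by the trace edge are flagged undefined, not
fabricated.

**AHP profiles.** Measured on the single-spike sweep (pulse adjusted to
elicit one action potential over 400 ms, membrane held −85…−75 mV):

* **ADP** — a local maximum with prominence ≥ 0.5 mV within 50 ms after
  the fast trough (found on a 300-Hz-smoothed copy, so membrane noise
  cannot mimic a bump);
* **S+** — otherwise, if a two-exponential fit of the 200-ms recovery
  beats the one-exponential fit by ≥ 20% of the residual sum of squares
  and assigns ≥ 10% of the amplitude to a component with τ ≥ 50 ms;
* **S−** — otherwise.

The S+/S− thresholds are conventions (the source phenotypes are
qualitative); all are exposed in `IntrinsicConfig`.

**Firing patterns.** Classified from a pulse family (0.6×, 1×, 2×
rheobase, 400 ms) with a fixed priority cascade; first match wins:

1. **LFR** — ≤ 2 spikes at every suprathreshold level despite ≥ 20 mV
   plateau depolarization (medians, robust to spikes);
2. **LTS / LTS_osc** — a cluster of ≥ 2 spikes with intra-cluster ISI
   < 15 ms starting within 60 ms of pulse onset (and, when later tonic
   spikes exist, intra-cluster ISI < ⅓ of the median later ISI);
   ≥ 2 such clusters in one pulse → the oscillatory-burst subtype;
3. **LAT** — first-spike latency > 100 ms at the just-suprathreshold
   pulse *with* an initial hyperpolarizing sag. The sag statistic is the
   largest negative residual of a monoexponential charging-curve fit to
   the Gaussian-smoothed (σ = 15 ms) pre-first-spike segment — a plain RC
   rise cannot produce a dip, while the smoothing suppresses ≥ 20-Hz
   membrane oscillations ~6-fold so an oscillation trough cannot pass as
   a sag;
4. **OSC** — mean periodogram power in the 5–50 Hz band of the detrended
   pre-first-spike segment ≥ 3× the 60–300 Hz broadband mean;
5. **FIL** — first ISI > 1.5× second ISI;
6. **CON** otherwise.

**Passive properties.** From the −40 pA step at −55…−65 mV:
R_in = ΔV_ss/I with ΔV_ss the plateau change (100-ms means), τ_m from a
monoexponential fit of the onset, C_in = τ_m/R_in. τ/R was chosen for
C_in because the original measurement method is not stated. Sweeps with
spikes during the step abort the estimate.

**Spontaneous firing.** rate = count/segment (segments ≥ 5 s); ISI CV(%)
is defined only for ≥ 3 spikes, otherwise reported absent.

## 3. EPSC / burst-response pipeline

**Noise SD.** 1.4826 × median(|Δx − median Δx|)/√2 over the 2-s
pre-burst window — the MAD of *first differences*, scaled to the Gaussian
SD. Events are slow relative to the sampling interval, so successive
differences are nearly pure noise; the estimate stays within a few
percent of truth even with events at tens per second (a plain sample MAD
is inflated ~12% at realistic rates).

**Deflection removal.** The post-burst segment is replaced by
`original − lowpass(original, 10 Hz)` (zero-phase 4th-order Butterworth)
and spliced to the unmodified pre-burst segment. This removes the slow
stimulus-locked inward deflection (returned to origin by ~300 ms) and
the DC pedestal of the elevated event rate while attenuating the fast
EPSC peaks by well under 10%.

**EPSC detection.** Peak finding runs on a 3-sample boxcar-smoothed copy
(attenuates an EPSC peak by <0.2%, suppresses single-sample noise);
candidate inward peaks must be separated by ≥ 2 ms. The amplitude is the
smoothed peak relative to a local trailing-median baseline taken 1–4 ms
before the peak — close enough to ride the decay tail of a preceding
event, so tail ripples are not re-detected (a 20-ms lookback produced
~5 false detections/s at realistic amplitudes; the 1–4 ms window gives
≤ 0.05/s at ≥ 95% sensitivity for events ≥ 4× noise SD). Detection is
strict: amplitude must *exceed* k·SD (k = 3); an event at exactly 3× is
rejected. The 2-ms separation deviates from a first-draft 5-ms choice:
at the observed ~30 events/s post-burst rates a 5-ms dead time discards
~13% of events; 2 ms matches the kernel's 1.28-ms time-to-peak.

**SMOCs.** Outward peaks above the same amplitude criterion whose decay
to 1/e of the peak takes ≥ 20 ms (spontaneous miniature outward currents
are much slower than synaptic currents; the cutoff is a convention,
config-exposed).

**Burst response.** Events are detected per sweep (pre-burst on the raw
trace, post-burst after deflection removal; the stimulation window itself
is excluded), pooled across sweeps, and binned at 100 ms anchored at
burst offset. F_pre is the pooled rate over the 2 s before onset, F_post
over the 1 s after offset. Neurons with F_pre ≤ 1 event/s are excluded.
The duration of the increased EPSC frequency scans *overlapping* 3-bin
windows in 100-ms steps from offset and reports the start time of the
first window whose mean rate is equal to or smaller than F_pre
(equality terminates; overlapping windows give 0.1-s resolution,
consistent with reported values that are not multiples of 0.3). If no
window qualifies within the recorded span, the span is reported with a
censoring flag.

**Maximum EPSC and drug effects.** The maximum EPSC is the mean over
five sweeps of each sweep's largest pre-burst amplitude (sweeps with no
detection are skipped with a warning). Percent reductions are
100·(control − drug)/control for both the maximum EPSC and the duration.

## 4. Statistics

Normality is gated by Shapiro–Wilk at α = 0.05 per sample (on the
differences for paired designs); a single joint verdict routes the
comparison to a two-sided *t* test or a two-sided Mann–Whitney test.
Effect sizes: pooled-SD Cohen's d (unpaired), d_z (paired), rank-biserial
(Mann–Whitney). Post hoc power uses the noncentral-*t* closed form; for
Mann–Whitney the sample sizes are scaled by the asymptotic relative
efficiency for a normal parent (3/π) — the convention of the usual power
software, flagged as such. At very large noncentrality the noncentral-*t*
CDF underflows and a normal approximation takes over. No multiple-testing
correction is applied by default (none is applied in the reference
workflow); Holm adjustment is available. A paired comparison that fails
the normality gate falls back to the (unpaired-rank) Mann–Whitney test
because the reference workflow names no paired nonparametric test; this
is a documented limitation.

Normalized proportions: each group's total is normalized to 100 and the
share of group g in category c is pct_g(c)/(pct₁(c)+pct₂(c)); shares sum
to 1 per category and are invariant to rescaling either group's counts.

## 5. Synthetic world

**Voltage clamp.** EPSC peak times follow an inhomogeneous Poisson
process: baseline rate before burst offset; from offset, a plateau at the
peak rate followed by a *linear* decline reaching baseline exactly
`true_duration` seconds after offset — so the duration statistic has an
exact recoverable truth. The plateau is chosen as
max(D − 0.6 s, 0.2·D): the decline always spans ~0.6 s, which keeps the
histogram-rule quantization bias equal across paired conditions that
differ only in duration, and for the main cohort presets the full 1-s
F_post window lies inside the plateau. Kernels are biexponential
(τ_rise 0.5 ms, τ_decay 5 ms — conventions; the source reports no
kinetic constants), amplitudes log-normal (median 15 pA, σ_log 0.4,
truncated below 4× noise SD by resampling), noise is white Gaussian
(σ = 2 pA; the acquisition chain's 3-kHz filter leaves the noise broad
relative to 10-kHz sampling), the post-burst deflection is an inward
alpha function (peak 30 pA, <0.5% of peak beyond its 300-ms return
time), and optional SMOCs are slow outward biexponentials
(τ_decay 50 ms = 10× the EPSC decay). The sampler draws three
independent substreams (event times, amplitudes, noise), so paired
control/drug cohorts generated with the same seed and neuron ids share
event times, amplitude ranks and noise fields (common-random-number
coupling; measured per-neuron SD of the paired duration reduction,
≈ 15 points, matches the published ±13.9).

**Rate calibration.** The published post/pre frequency ratio is a
*measured* quantity: at tens of events per second, waveform merging and
the detector's minimum separation thin the detected train by ~5–12%.
Preset calibration therefore inverts an empirically measured detected-
rate-vs-true-rate curve of the *actual* detector on the generative model
(fixed internal seed; a deterministic calibration constant, cross-checked
against an independent point-process dead-time model in the tests) so
that the expected detected ratio equals the published value.

**Duration calibration.** The equal-or-smaller three-bin rule waits past
the true end of the elevated period by ≈ +0.15 s on average at five
pooled sweeps (measured on the generative model across all condition
presets): noise in the pooled F_pre threshold makes early qualification
bounded but late qualification unbounded. Cohort presets whose target is
the *truth parameter itself* (the main INC/PHN durations) are left at
the published means uncorrected. The NAS drug-arm presets, whose target
is the *reduction statistic*, are bias-inverted —
drug truth = (control + 0.15)·(1 − reduction) − 0.15 — so the expected
measured reduction equals the published mean reduction. Both choices were
fixed from model measurements before the acceptance script was first run.

**Current clamp.** Spikes are analytic templates, not conductance
models, so every truth is exact by construction: dV/dt crosses 10 V/s
exactly at the configured threshold (linear in time within ±0.5 ms of
the crossing so detector smoothing cannot bias it), the downstroke
steepness is solved by secant iteration to hit the configured half-width,
the trough sits exactly at threshold − AHP amplitude and is approached
slowly over the last few mV so it survives analyzer smoothing. AHP
recovery is mono-/biexponential per profile with a Gaussian ADP bump
whose amplitude scales with the AHP depth (a fixed bump would be
swallowed by the recovery slope of deep AHPs). Firing patterns are
spike-time layouts plus envelope components on a passive RC response
(onset humps for LTS, a sag carving a real dip for LAT, a 20-Hz
subthreshold oscillation for OSC, a capped plateau for LFR). Cohort
draws cap τ_m at 45 ms (independent R/C draws otherwise combine into
membranes that never charge within the 400-ms pulse, and the residual
charging masquerades as a slow AHP component) and enforce overshooting
spike peaks (>0 mV), mirroring the recording-quality inclusion rule.

**What a green test does and does not establish.** The generator
reproduces the *statistical structure the analysis assumes* — Poisson
event trains, a deterministic rate envelope, stationary Gaussian noise,
stereotyped kernels and spike shapes. Real recordings add vesicular
amplitude correlations, electrode drift and access-resistance changes,
non-stationary noise, stimulus artifacts, and biophysical spike-shape
variability. Green generator–analyzer tests therefore establish internal
consistency and correct implementation of the stated estimators at the
published operating points, not performance on arbitrary real data.

## 6. Numerical choices and degenerate inputs

Zero-phase filtering throughout (no peak-time shifts); sosfiltfilt for
Butterworth stages, Gaussian kernels where recursive edge behavior would
bite (spike smoothing, sag detection). Duration-rule comparisons use a
1e-9 absolute tolerance so exact rational equality ("equal to or
smaller") survives floating point. Degenerate inputs raise typed errors:
mode mismatches (`ModeError`), malformed files (`FormatError`),
protocol/window violations (`ValidationError`), sub-minimum samples
(`InsufficientDataError`), failed estimations (`EstimationError`), and
the burst-analysis inclusion rule (`InclusionError`). Identical samples
in a *t* test return p = 1 and d = 0 rather than NaN.

## 7. Known limitations

* Firing-pattern and S+/S− thresholds are conventions fitted to the
  qualitative phenotype descriptions; borderline real cells will land on
  either side of them.
* The duration statistic inherits heavy right-tail noise from its
  baseline threshold; cohort means of ~7-neuron experiments carry
  several points of sampling error (the published SDs are of the same
  size).
* The paired nonparametric branch uses unpaired Mann–Whitney (see §4).
* Evoked currents during the 20-pulse train itself are not modeled or
  analyzed; stimulus-artifact handling is out of scope.
* Proprietary acquisition formats are not read; use the CSV/JSON or HDF5
  container interfaces.
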