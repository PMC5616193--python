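# slicephys

Trace-level quantification and cohort statistics for whole-cell slice
electrophysiology, built around the analysis chain used to compare the two
brainstem gaze-holding ("neural integrator") nuclei — the interstitial
nucleus of Cajal (INC, vertical gaze) and the prepositus hypoglossi
nucleus (PHN, horizontal gaze). It is aimed at electrophysiologists who
want a tested, scriptable re-implementation of this kind of pipeline, and
at methodologists who want to probe how its estimators behave on data with
known ground truth.

The package has three layers:

* **Intrinsic phenotyping** (`slicephys.intrinsic`): spike detection by
  the derivative criterion (threshold = membrane potential where
  dV/dt reaches 10 V/s), spike amplitude (threshold→peak), half-width at
  half amplitude, afterhyperpolarization (AHP) amplitude
  (threshold − trough), passive properties from a −40 pA step
  (R_in = ΔV_ss/I, C_in = τ_m/R_in), spontaneous rate and ISI CV, and
  rule-based classification of AHP profiles (ADP / S+ / S−) and firing
  patterns (CON, LAT, LTS and its oscillatory-burst subtype, FIL, LFR,
  OSC) from a 400-ms current-pulse family.
* **Burst-evoked EPSC responses** (`slicephys.epsc`): robust baseline
  noise SD, removal of the slow stimulus-locked inward deflection by
  subtracting the 10-Hz low-passed trace, detection of spontaneous EPSCs
  (inward peaks strictly exceeding 3× the baseline noise SD), SMOC
  detection by polarity and slow decay kinetics, and the burst-response
  statistics: F_pre (2 s before burst onset), F_post (1 s after burst
  offset), F_post/F_pre, and the **duration of the increased EPSC
  frequency** — the time from burst offset until the mean of three
  adjacent 100-ms histogram bins first becomes equal to or smaller than
  the baseline frequency. Paired control/drug comparisons yield percent
  reductions in maximum EPSC amplitude and in duration.
* **Cohort statistics** (`slicephys.stats`): Shapiro–Wilk-gated two-sided
  Student's *t* / Mann–Whitney tests with effect sizes and noncentral-*t*
  post hoc power (A.R.E.-corrected for Mann–Whitney), plus the
  normalized-proportion construction for comparing phenotype
  distributions between cohorts of unequal size.

Because the original recordings are not public, `slicephys.synthetic`
generates current- and voltage-clamp traces with full ground truth:
Poisson EPSC trains with a post-burst elevated-rate profile whose return
time to baseline is an exact, recoverable parameter; biexponential EPSC
kernels, slow outward SMOCs, the post-burst baseline deflection, and
Gaussian noise; and analytic spike templates whose threshold, amplitude,
half-width, AHP shape and firing pattern are exact by construction.
Shipped presets (`inc`, `phn`, their NAS-condition variants, `inc_cc`,
`phn_cc`) are calibrated to the published cohort statistics.

## Worked example

Simulate the INC-like burst-response experiment (17 neurons, generator
truths pinned at the cohort means) and run the full measurement chain:

```bash
$ slicephys epsc --preset inc -n 17 --seed 1 --spread 0 --out inc_results.csv
n=17 analyzed; mean duration 1.69 s, mean F_post/F_pre 5.15, mean F_pre 5.75/s
```

The three numbers are the cohort means of the measured duration of the
increased EPSC frequency (generator truth 1.6 s), the post/pre frequency
ratio (calibrated expectation 5.0) and the baseline EPSC frequency
(truth 5.8 events/s); the per-neuron values are in `inc_results.csv`.
The generator–analyzer loop closes on the intrinsic side too:

```bash
$ slicephys intrinsic --preset inc_cc -n 20 --seed 1 --out cc.csv
n=20; firing-pattern agreement with truth 100.0%
```

A two-cohort comparison bundle (results tables, Shapiro-gated tests with
power, normalized phenotype proportions, run log) comes from a JSON
config:

```bash
slicephys all config.json    # see slicephys.pipeline.run_pipeline
```

## Acceptance script

`scripts/acceptance.py` regenerates the calibrated cohorts from scratch
at the published operating points (INC/PHN burst cohorts of 17; paired
7-neuron control/NAS experiments), runs the complete pipeline on them,
and writes the cohort-level summary statistics (mean duration,
F_post/F_pre, baseline frequency, and paired percent duration reductions)
to JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Replicate cohorts derived from `--seed` are averaged so the Monte-Carlo
error is small relative to each statistic's own sampling error; runtime
is about a minute on one CPU.
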