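import numpy as np
import pytest

from slicephys.traceio import (Trace, ProtocolAnnotation, ValidationError,
                               VOLTAGE_CLAMP)
from slicephys.synthetic import (EpscKernel, render_epsc_kernel, RateProfile,
                                 EventDistribution, synth_voltage_clamp,
                                 synth_cohort)
from slicephys.epsc import (baseline_noise_sd, remove_slow_deflection,
                            detect_epscs, detect_smocs, burst_response,
                            duration_from_rates, max_epsc_amplitude,
                            drug_effect, BurstResponse, FrequencyHistogram,
                            InclusionError)

FS = 10_000.0


def event_trace(amplitudes_pa, times_s, duration_s=2.0, noise_sd=0.0, seed=0,
                tau_rise=0.5, tau_decay=5.0, polarity="inward"):
    n = int(duration_s * FS)
    s = (np.zeros(n) if noise_sd == 0
         else np.random.default_rng(seed).normal(0, noise_sd, n))
    for a, t in zip(np.atleast_1d(amplitudes_pa), np.atleast_1d(times_s)):
        w = render_epsc_kernel(EpscKernel(a, tau_rise, tau_decay), FS,
                               polarity=polarity)
        i = int(t * FS)
        s[i:i + w.size] += w[:n - i]
    return Trace(s, FS, VOLTAGE_CLAMP)


class TestBaselineNoise:
    def test_gaussian_sd_within_5pct(self, gauss_trace):
        assert baseline_noise_sd(gauss_trace, (0.0, 3.0)) == pytest.approx(
            2.0, rel=0.05)

    def test_zero_trace(self):
        tr = Trace(np.zeros(10_000), FS, VOLTAGE_CLAMP)
        assert baseline_noise_sd(tr, (0.0, 1.0)) == 0.0

    def test_robust_to_sparse_events(self):
        rng = np.random.default_rng(1)
        tr = event_trace([30.0] * 10, rng.uniform(0.1, 1.9, 10),
                         noise_sd=2.0, seed=1)
        assert baseline_noise_sd(tr, (0.0, 2.0)) == pytest.approx(2.0, rel=0.10)

    def test_window_overlapping_burst_rejected(self, gauss_trace):
        ann = ProtocolAnnotation(burst_onset=1.0, burst_offset=1.2)
        with pytest.raises(ValidationError):
            baseline_noise_sd(gauss_trace, (0.0, 1.5), ann)

    def test_short_window_rejected(self, gauss_trace):
        with pytest.raises(ValidationError):
            baseline_noise_sd(gauss_trace, (0.0, 0.3))


class TestDeflectionRemoval:
    ann = ProtocolAnnotation(burst_onset=1.0, burst_offset=1.2)

    def test_pure_deflection_removed(self):
        ann = ProtocolAnnotation(burst_onset=2.0, burst_offset=2.2)
        profile = RateProfile(baseline_rate=0.0)
        trace, _ = synth_voltage_clamp(profile, EventDistribution(), ann,
                                       0.0, 5.0, seed=2,
                                       deflection_peak_pa=30.0)
        out = remove_slow_deflection(trace, ann)
        late = out.slice(2.5, 5.0).samples
        assert np.abs(late).max() < 0.05 * 30.0

    def test_event_amplitudes_preserved(self):
        times = [1.4, 1.8, 2.3, 3.1]
        tr = event_trace([20.0] * 4, times, duration_s=4.0)
        out = remove_slow_deflection(tr, self.ann)
        det = detect_epscs(out.slice(1.2, 4.0), noise_sd=2.0)
        assert det.n == 4
        np.testing.assert_allclose(det.amplitudes, 20.0, rtol=0.10)

    def test_constant_trace_zeroed_after_burst(self):
        tr = Trace(np.full(40_000, -7.5), FS, VOLTAGE_CLAMP)
        out = remove_slow_deflection(tr, self.ann)
        post = out.slice(1.5, 3.8).samples
        np.testing.assert_allclose(post, 0.0, atol=1e-6)
        # pre-burst segment untouched
        np.testing.assert_allclose(out.slice(0.0, 1.0).samples, -7.5)


class TestDetectEpscs:
    def test_strict_threshold_boundary(self):
        at3 = event_trace(3.0 * 2.0, 0.5)
        above = event_trace(3.1 * 2.0, 0.5)
        assert detect_epscs(at3, 2.0).n == 0
        assert detect_epscs(above, 2.0).n == 1

    def test_k_monotonicity(self):
        tr = event_trace([7.0, 9.0, 30.0], [0.3, 0.9, 1.5], noise_sd=2.0,
                         seed=3)
        e3 = detect_epscs(tr, 2.0, k=3)
        e4 = detect_epscs(tr, 2.0, k=4)
        assert set(np.round(e4.times, 4)) <= set(np.round(e3.times, 4))

    def test_benchmark_sensitivity_and_false_rate(self):
        profile = RateProfile(baseline_rate=5.0)
        events = EventDistribution(amp_min_pa=8.0)  # >= 4 sigma
        tr, truth = synth_voltage_clamp(profile, events, None, 2.0, 60.0,
                                        seed=5)
        det = detect_epscs(tr, baseline_noise_sd(tr, (0.0, 2.0)))
        hits, used = 0, set()
        for t in truth.event_times:
            d = np.abs(det.times - t)
            j = int(np.argmin(d)) if det.n else -1
            if j >= 0 and d[j] < 0.002 and j not in used:
                hits += 1
                used.add(j)
        assert hits / truth.event_times.size >= 0.95
        assert (det.n - hits) / 60.0 <= 0.5

    def test_bad_noise_sd_rejected(self, gauss_trace):
        with pytest.raises(ValueError):
            detect_epscs(gauss_trace, 0.0)


class TestDetectSmocs:
    def test_polarity_and_rate_separation(self):
        rng = np.random.default_rng(6)
        duration = 30.0
        profile = RateProfile(baseline_rate=5.0)
        tr, truth = synth_voltage_clamp(profile, EventDistribution(amp_min_pa=8.0),
                                        None, 2.0, duration, seed=6,
                                        smoc_rate=1.0, smoc_amp_pa=15.0)
        sd = baseline_noise_sd(tr, (0.0, 2.0))
        smocs = detect_smocs(tr, sd)
        n_true = truth.smoc_times.size
        assert abs(smocs.n - n_true) <= 3 * np.sqrt(max(n_true, 1))
        assert smocs.polarity == "outward"

    def test_no_outward_events_empty(self):
        tr = event_trace([20.0, 25.0], [0.4, 1.2], noise_sd=2.0, seed=7)
        assert detect_smocs(tr, 2.0).n == 0

    def test_fast_outward_events_excluded_by_kinetics(self):
        tr = event_trace([20.0] * 3, [0.3, 0.9, 1.5], polarity="outward")
        assert detect_smocs(tr, 2.0).n == 0          # EPSC-like kinetics
        slow = event_trace([20.0] * 3, [0.3, 0.9, 1.5], polarity="outward",
                           tau_rise=5.0, tau_decay=50.0)
        assert detect_smocs(slow, 2.0).n == 3


class TestDurationRule:
    def test_worked_example(self):
        # first qualifying triple: (8+2+2)/3 = 4 <= f_pre -> 0.3 s
        rates = np.array([50, 40, 30, 8, 2, 2, 2, 2, 2, 2], dtype=float)
        d, censored = duration_from_rates(rates, 0.1, 4.0)
        assert d == pytest.approx(0.3)
        assert not censored

    def test_immediate_qualification(self):
        d, censored = duration_from_rates(np.full(20, 4.0), 0.1, 4.0)
        assert d == 0.0 and not censored

    def test_censored_when_never_qualifying(self):
        d, censored = duration_from_rates(np.full(20, 9.0), 0.1, 4.0)
        assert d == pytest.approx(2.0)
        assert censored

    def test_worked_neuron_magnitude(self):
        # a neuron with true duration 1.9 s, three pooled sweeps
        import json
        from slicephys.synthetic.presets import GroupPreset, _synth_vc_neuron, rng_for
        params = dict(baseline_rate_mean=5.8, ratio_mean=5.0,
                      duration_mean=1.9, noise_sd=2.0, amp_median=15.0,
                      amp_sigma_log=0.4, amp_min_noise_sd=4.0, n_sweeps=3,
                      burst_onset=3.0, burst_offset=3.2)
        preset = GroupPreset(name="worked", kind="vclamp_burst", params=params)
        durs = []
        for seed in (1, 2, 3, 4, 5):
            rec = _synth_vc_neuron(preset, "w0", rng_for(seed, "w0"), 0.0)
            durs.append(burst_response(rec.sweeps).duration)
        assert np.mean(durs) == pytest.approx(1.9, abs=0.2)


class TestBurstResponse:
    def test_pooling_additivity(self):
        cohort = synth_cohort("inc", 1, seed=9, spread=0.0)
        sweeps = cohort[0].sweeps
        br1 = burst_response([sweeps[0]])
        br2 = burst_response([sweeps[1]])
        br12 = burst_response(sweeps[:2])
        np.testing.assert_array_equal(
            br12.histogram.counts, br1.histogram.counts + br2.histogram.counts)
        assert br12.f_pre == pytest.approx((br1.f_pre + br2.f_pre) / 2)

    def test_low_baseline_excluded(self):
        params = {"baseline_rate_mean": 0.4, "ratio_mean": 5.0,
                  "duration_mean": 1.0, "n_sweeps": 2,
                  "burst_onset": 3.0, "burst_offset": 3.2}
        from slicephys.synthetic.presets import GroupPreset, _synth_vc_neuron, rng_for
        preset = GroupPreset(name="lo", kind="vclamp_burst", params=params)
        rec = _synth_vc_neuron(preset, "lo0", rng_for(1, "lo0"), 0.0)
        with pytest.raises(InclusionError):
            burst_response(rec.sweeps)

    def test_missing_burst_rejected(self, gauss_trace):
        with pytest.raises(ValidationError):
            burst_response([(gauss_trace, ProtocolAnnotation())])


class TestMaxEpscAndDrugEffect:
    def test_mean_of_sweep_maxima(self):
        # five sweeps engineered so the per-sweep maxima are 28..32 pA
        sweeps = []
        for m in (28.0, 30.0, 29.0, 31.0, 32.0):
            tr = event_trace([m, 10.0], [0.5, 1.2], noise_sd=0.5, seed=int(m))
            sweeps.append((tr, ProtocolAnnotation()))
        got = max_epsc_amplitude(sweeps)
        assert got == pytest.approx(30.0, rel=0.05)

    def test_sweep_count_enforced_and_relaxable(self):
        tr = event_trace([20.0], [0.5], noise_sd=0.5, seed=1)
        sweeps = [(tr, ProtocolAnnotation())] * 3
        with pytest.raises(ValidationError):
            max_epsc_amplitude(sweeps)
        assert max_epsc_amplitude(sweeps, expected_sweeps=None) > 0

    def test_oracle_against_ground_truth(self):
        cohort = synth_cohort("inc_nas_control", 1, seed=10, spread=0.0)
        rec = cohort[0]
        got = max_epsc_amplitude(rec.sweeps)
        oracle = np.mean([
            truth.event_amplitudes[
                (truth.event_times >= 1.0) & (truth.event_times < 3.0)].max()
            for truth in rec.truths])
        assert got == pytest.approx(oracle, rel=0.15)

    def _mk_response(self, duration):
        hist = FrequencyHistogram(0.1, 3.2, np.arange(-2.2, 3.0, 0.1),
                                  np.zeros(51), 3)
        return BurstResponse(5.0, 20.0, 4.0, duration, False, 3, hist)

    def test_printed_arithmetic(self):
        eff = drug_effect(self._mk_response(2.0), self._mk_response(1.4),
                          29.9, 21.2)
        assert eff.amp_reduction == pytest.approx(29.1, abs=0.05)
        assert eff.duration_reduction == pytest.approx(30.0, abs=1e-9)

    def test_no_change_is_zero(self):
        eff = drug_effect(self._mk_response(2.0), self._mk_response(2.0),
                          30.0, 30.0)
        assert eff.amp_reduction == 0.0
        assert eff.duration_reduction == 0.0
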