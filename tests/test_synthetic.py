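import numpy as np
import pytest

from slicephys.traceio import ProtocolAnnotation, ValidationError
from slicephys.synthetic import (EpscKernel, render_epsc_kernel,
                                 biexp_peak_time, RateProfile,
                                 EventDistribution, synth_voltage_clamp,
                                 sample_inhomogeneous_poisson,
                                 CCGroundTruth, synth_current_clamp,
                                 SpikeTemplate, synth_cohort,
                                 ConfigurationError, load_preset,
                                 available_presets)
from slicephys.synthetic.kernels import KernelParameterError
from slicephys.synthetic.presets import (cohort_manifest, rng_for,
                                         expected_detected_rate)
from slicephys.synthetic.vclamp import detected_rate_model


class TestKernel:
    def test_extremum_equals_amplitude(self):
        w = render_epsc_kernel(EpscKernel(20.0), 10_000.0)
        assert w.min() == pytest.approx(-20.0, rel=0.01)

    def test_peak_time_closed_form(self):
        # ln(10) * (0.5*5)/(5-0.5) ms ~= 1.28 ms
        w = render_epsc_kernel(EpscKernel(10.0, 0.5, 5.0), 100_000.0)
        t_peak = np.argmin(w) / 100_000.0 * 1e3
        expect = np.log(10.0) * (0.5 * 5.0) / (5.0 - 0.5)
        assert t_peak == pytest.approx(expect, abs=0.02)
        assert biexp_peak_time(0.5, 5.0) == pytest.approx(expect)

    def test_amplitude_linearity(self):
        w1 = render_epsc_kernel(EpscKernel(10.0), 10_000.0)
        w2 = render_epsc_kernel(EpscKernel(20.0), 10_000.0)
        np.testing.assert_allclose(w2, 2 * w1, rtol=1e-12)

    def test_bad_taus_rejected(self):
        with pytest.raises(KernelParameterError):
            EpscKernel(10.0, tau_rise=5.0, tau_decay=5.0)


class TestVoltageClampSynthesis:
    def test_empty_generative_model_is_zero(self):
        profile = RateProfile(baseline_rate=0.0)
        trace, truth = synth_voltage_clamp(profile, EventDistribution(), None,
                                           0.0, 2.0, seed=1)
        np.testing.assert_array_equal(trace.samples, 0.0)
        assert truth.event_times.size == 0

    def test_same_seed_bit_identical(self):
        profile = RateProfile(baseline_rate=5.0)
        a, ta = synth_voltage_clamp(profile, EventDistribution(), None, 2.0,
                                    5.0, seed=42)
        b, tb = synth_voltage_clamp(profile, EventDistribution(), None, 2.0,
                                    5.0, seed=42)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(ta.event_times, tb.event_times)

    def test_poisson_count_calibration(self):
        # mean ground-truth count matches the integral of the rate profile
        ann = ProtocolAnnotation(burst_onset=3.0, burst_offset=3.2)
        profile = RateProfile(baseline_rate=5.0, post_burst_peak_rate=25.0,
                              true_duration=1.5, plateau=0.9)
        rng = np.random.default_rng(9)
        counts = []
        for _ in range(40):
            _, truth = synth_voltage_clamp(profile, EventDistribution(), ann,
                                           0.0, 7.0, rng)
            counts.append(truth.event_times.size)
        t = np.linspace(0, 7.0, 70_001)
        expected = np.trapezoid(profile.rate(t, 3.2), t)
        sem = np.std(counts) / np.sqrt(len(counts))
        assert np.mean(counts) == pytest.approx(expected, abs=3.5 * sem)

    def test_deflection_bounded_and_returns(self):
        ann = ProtocolAnnotation(burst_onset=3.0, burst_offset=3.2)
        profile = RateProfile(baseline_rate=0.0)
        trace, truth = synth_voltage_clamp(profile, EventDistribution(), ann,
                                           0.0, 6.0, seed=1,
                                           deflection_peak_pa=30.0,
                                           deflection_return_s=0.3)
        assert trace.samples.min() >= -30.0 - 1e-9
        after = trace.slice(3.2 + 0.3, 6.0).samples
        assert np.abs(after).max() < 0.01 * 30.0

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            synth_voltage_clamp(RateProfile(baseline_rate=1.0),
                                EventDistribution(), None, -1.0, 2.0, seed=0)

    def test_duration_must_cover_burst(self):
        ann = ProtocolAnnotation(burst_onset=3.0, burst_offset=3.2)
        profile = RateProfile(baseline_rate=2.0, post_burst_peak_rate=10.0,
                              true_duration=2.0)
        with pytest.raises(ValidationError):
            synth_voltage_clamp(profile, EventDistribution(), ann, 1.0, 4.0,
                                seed=0)

    def test_thinning_sampler_rate(self):
        rng = np.random.default_rng(4)
        times = sample_inhomogeneous_poisson(
            lambda t: np.full_like(t, 8.0), 10.0, 0.0, 200.0, rng)
        assert times.size == pytest.approx(1600, abs=4 * np.sqrt(1600))
        assert np.all(np.diff(times) >= 0)


class TestRateProfile:
    def test_baseline_outside_response(self):
        p = RateProfile(baseline_rate=4.0, post_burst_peak_rate=30.0,
                        true_duration=1.5, plateau=0.9)
        t = np.array([0.0, 2.9, 3.1, 4.8, 10.0])
        r = p.rate(t, 3.2)
        np.testing.assert_allclose(r, [4.0, 4.0, 4.0, 4.0, 4.0])

    def test_plateau_and_linear_decline(self):
        p = RateProfile(baseline_rate=4.0, post_burst_peak_rate=30.0,
                        true_duration=1.5, plateau=0.9)
        assert p.rate(np.array([3.5]), 3.2)[0] == pytest.approx(30.0)
        mid = 3.2 + 0.9 + 0.3  # halfway down the 0.6-s decline
        assert p.rate(np.array([mid]), 3.2)[0] == pytest.approx(17.0)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValidationError):
            RateProfile(baseline_rate=-1.0)


class TestCurrentClampSynthesis:
    def test_template_half_width_exact(self):
        tmpl = SpikeTemplate(-45.0, 69.7, 0.39, 26.4)
        assert tmpl.rendered_half_width == pytest.approx(0.39, abs=2e-3)

    def test_con_isi_cv_by_construction(self):
        rec = synth_current_clamp(CCGroundTruth(firing_pattern="CON"), seed=2)
        from slicephys.intrinsic import detect_spikes
        trace, ann = rec.pulses[1]
        spikes = [s for s in detect_spikes(trace)
                  if ann.pulse_onsets[0] <= s.threshold_time < ann.pulse_offsets[0]]
        isis = np.diff([s.threshold_time for s in spikes])
        assert np.std(isis) / np.mean(isis) < 0.10

    def test_adp_profile_has_local_max_after_trough(self):
        rec = synth_current_clamp(CCGroundTruth(ahp_profile="ADP"), seed=3,
                                  noise_sd_mv=0.0)
        trace, _ = rec.single_spike
        v = trace.samples
        i_pk = int(np.argmax(v))
        i_tr = i_pk + int(np.argmin(v[i_pk:i_pk + 2000]))
        seg = v[i_tr:i_tr + 500]
        interior_max = np.argmax(seg)
        assert 0 < interior_max < seg.size - 1   # a bump, not an endpoint

    def test_fil_first_isi_longer(self):
        rec = synth_current_clamp(CCGroundTruth(firing_pattern="FIL"), seed=4)
        from slicephys.intrinsic import detect_spikes
        trace, ann = rec.pulses[1]
        spikes = [s for s in detect_spikes(trace)
                  if ann.pulse_onsets[0] <= s.threshold_time < ann.pulse_offsets[0]]
        isis = np.diff([s.threshold_time for s in spikes])
        assert isis[0] > isis[1]

    def test_lfr_inconsistent_with_high_spont_rate(self):
        with pytest.raises(ValidationError):
            CCGroundTruth(firing_pattern="LFR", spontaneous_rate=8.0)


class TestCohorts:
    def test_zero_size_rejected(self):
        with pytest.raises(ConfigurationError):
            synth_cohort("inc_cc", 0, seed=1)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            load_preset("no_such_cohort")

    def test_shipped_presets_load(self):
        for name in available_presets():
            p = load_preset(name)
            assert p.kind in ("vclamp_burst", "cclamp")

    def test_manifest_deterministic(self):
        a = cohort_manifest(synth_cohort("inc_cc", 3, seed=5))
        b = cohort_manifest(synth_cohort("inc_cc", 3, seed=5))
        assert a.equals(b)

    def test_vc_cohort_satisfies_inclusion_rule(self):
        cohort = synth_cohort("inc", 5, seed=6, spread=1.0)
        for rec in cohort:
            assert rec.profile.baseline_rate > 1.0

    def test_per_neuron_streams_stable(self):
        r1 = rng_for(3, "inc-007").standard_normal(4)
        r2 = rng_for(3, "inc-007").standard_normal(4)
        r3 = rng_for(3, "inc-008").standard_normal(4)
        np.testing.assert_array_equal(r1, r2)
        assert not np.array_equal(r1, r3)

    def test_detector_rate_table_agrees_with_point_process_model(self):
        # independent dead-time model within 10% of the waveform measurement
        for rate in (5.0, 30.0):
            wf = expected_detected_rate(rate)
            pp = detected_rate_model(rate, 0.002, 0.0012, t_total=1500.0)
            assert wf <= rate + 0.5
            assert wf == pytest.approx(pp, rel=0.10)
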