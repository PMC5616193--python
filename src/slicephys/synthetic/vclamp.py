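"""Voltage-clamp trace synthesis: Poisson EPSC trains, burst responses,
slow baseline deflection, SMOCs and Gaussian noise, with full ground truth.

The generative model mirrors what the analysis pipeline assumes:

* spontaneous EPSCs form a Poisson train at a baseline rate (~1-10
  events/s), rendered as inward biexponential kernels;
* after the extracellular burst the instantaneous rate jumps to a plateau
  and then declines linearly back to baseline, reaching it exactly
  ``true_duration`` seconds after burst offset -- so the duration statistic
  has a well-defined, recoverable truth;
* a slow stimulus-locked inward deflection starts at burst offset and
  returns to the origin by ~300 ms;
* optional SMOCs are slow outward biexponentials;
* baseline noise is white Gaussian (the recorded band after the 3-kHz
  acquisition filter is broad relative to the 10-kHz sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..traceio import Trace, ProtocolAnnotation, ValidationError, VOLTAGE_CLAMP
from .kernels import EpscKernel, render_epsc_kernel, biexp_peak_time

__all__ = [
    "RateProfile", "EventDistribution", "VCGroundTruth",
    "synth_voltage_clamp", "sample_inhomogeneous_poisson",
    "detected_rate_model", "invert_detected_rate",
]


@dataclass(frozen=True)
class RateProfile:
    """Instantaneous EPSC rate around a burst stimulation.

    The rate equals ``baseline_rate`` before burst offset (stimulus-evoked
    currents during the 20-pulse train itself are out of scope), jumps to
    ``post_burst_peak_rate`` at burst offset, stays there for
    ``plateau`` seconds (clipped to ``true_duration``), then declines
    linearly, reaching baseline exactly at offset + ``true_duration``.
    ``decay_shape="exponential"`` substitutes a truncated exponential
    decline with the same endpoint.
    """

    baseline_rate: float
    post_burst_peak_rate: float = 0.0
    true_duration: float = 0.0
    decay_shape: str = "plateau_then_decay"
    plateau: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.post_burst_peak_rate < 0:
            raise ValidationError("rates must be >= 0")
        if self.true_duration < 0:
            raise ValidationError("true_duration must be >= 0")
        if self.decay_shape not in ("plateau_then_decay", "exponential"):
            raise ValidationError(f"unknown decay_shape {self.decay_shape!r}")

    def rate(self, t: np.ndarray, burst_offset: float | None) -> np.ndarray:
        """Instantaneous rate (events/s) at times ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        r = np.full(t.shape, self.baseline_rate)
        if burst_offset is None or self.true_duration == 0:
            return r
        x = t - burst_offset
        D = self.true_duration
        excess = self.post_burst_peak_rate - self.baseline_rate
        if self.decay_shape == "plateau_then_decay":
            p = min(self.plateau, D)
            in_plateau = (x >= 0) & (x < p)
            in_decay = (x >= p) & (x < D)
            r[in_plateau] += excess
            if D > p:
                r[in_decay] += excess * (D - x[in_decay]) / (D - p)
        else:
            tau = D / 3.0
            in_post = (x >= 0) & (x < D)
            scale = (np.exp(-x[in_post] / tau) - np.exp(-D / tau)) / (1 - np.exp(-D / tau))
            r[in_post] += excess * scale
        return r

    @property
    def max_rate(self) -> float:
        return max(self.baseline_rate, self.post_burst_peak_rate)


@dataclass(frozen=True)
class EventDistribution:
    """Amplitude and kinetics law for synthetic EPSCs.

    Amplitudes are log-normal (median ``amp_median_pa``, log-SD
    ``amp_sigma_log``) truncated below at ``amp_min_pa`` by resampling, so
    detectability relative to the noise SD is controlled explicitly.
    """

    amp_median_pa: float = 15.0
    amp_sigma_log: float = 0.4
    amp_min_pa: float = 0.0
    tau_rise_ms: float = 0.5
    tau_decay_ms: float = 5.0

    def sample_amplitudes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        mu = np.log(self.amp_median_pa)
        amps = rng.lognormal(mu, self.amp_sigma_log, size=n)
        for _ in range(100):
            low = amps < self.amp_min_pa
            if not low.any():
                break
            amps[low] = rng.lognormal(mu, self.amp_sigma_log, size=low.sum())
        return np.maximum(amps, self.amp_min_pa)


@dataclass
class VCGroundTruth:
    """Everything the generator placed in a voltage-clamp sweep."""

    event_times: np.ndarray          # EPSC peak times, s, sorted
    event_amplitudes: np.ndarray     # pA magnitudes
    smoc_times: np.ndarray
    deflection_params: tuple[float, float]   # (peak pA, return time s)
    noise_sd: float
    rate_profile: RateProfile
    events: EventDistribution = field(default_factory=EventDistribution)


def sample_inhomogeneous_poisson(rate_fn, r_max: float, t0: float, t1: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Thinning sampler for an inhomogeneous Poisson process.

    Candidates are drawn homogeneously at ``r_max`` and accepted with
    probability ``rate(t)/r_max``; with a shared generator state this gives
    common-random-number coupling across profiles that differ only in the
    acceptance function (used for paired control/drug simulations).
    """
    if r_max <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(r_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n))
    u = rng.uniform(0.0, 1.0, size=n)
    keep = u * r_max < rate_fn(cand)
    return cand[keep]


def _alpha_deflection(t: np.ndarray, start: float, peak_pa: float,
                      return_time: float) -> np.ndarray:
    """Slow inward deflection: alpha function, <0.5% of peak at return_time."""
    tau = return_time / 8.5
    x = t - start
    out = np.zeros_like(t)
    pos = x > 0
    out[pos] = -peak_pa * (x[pos] / tau) * np.exp(1 - x[pos] / tau)
    return out


def _add_events(samples: np.ndarray, fs: float, t0: float,
                peak_times: np.ndarray, amps: np.ndarray,
                kernel_template: np.ndarray, peak_offset_s: float) -> None:
    n = samples.size
    klen = kernel_template.size
    for tp, a in zip(peak_times, amps):
        i0 = int(round((tp - peak_offset_s - t0) * fs))
        j0, j1 = max(i0, 0), min(i0 + klen, n)
        if j1 <= j0:
            continue
        samples[j0:j1] += a * kernel_template[j0 - i0:j1 - i0]


def synth_voltage_clamp(profile: RateProfile,
                        events: EventDistribution,
                        burst: ProtocolAnnotation | None,
                        noise_sd: float,
                        duration: float,
                        seed: int | np.random.Generator,
                        sampling_rate: float = 10_000.0,
                        deflection_peak_pa: float = 30.0,
                        deflection_return_s: float = 0.3,
                        smoc_rate: float = 0.0,
                        smoc_amp_pa: float = 15.0,
                        smoc_tau_rise_ms: float = 5.0,
                        smoc_tau_decay_ms: float = 50.0,
                        ) -> tuple[Trace, VCGroundTruth]:
    """Synthesize one voltage-clamp sweep with ground truth.

    Same seed gives bit-identical output.  When a burst annotation is
    present the trace must cover ``[burst_onset - 2 s, burst_offset +
    true_duration + 2 s]``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    # independent substreams: paired simulations that differ only in the
    # rate profile or amplitude law then share event times, amplitude
    # ranks and the noise field (common-random-number coupling)
    rng_times, rng_amps, rng_noise = rng.spawn(3)

    burst_offset = burst.burst_offset if (burst is not None and burst.has_burst) else None
    if burst_offset is not None:
        need0 = burst.burst_onset - 2.0
        need1 = burst_offset + profile.true_duration + 2.0
        if need0 < 0 or need1 > duration:
            raise ValidationError(
                "trace must cover [burst_onset - 2 s, burst_offset + true_duration + 2 s]")

    n = int(round(duration * sampling_rate))
    samples = np.zeros(n)

    # EPSC train (ground-truth times are peak times)
    peak_times = sample_inhomogeneous_poisson(
        lambda t: profile.rate(t, burst_offset), profile.max_rate, 0.0, duration,
        rng_times)
    amps = events.sample_amplitudes(peak_times.size, rng_amps)
    kernel = render_epsc_kernel(
        EpscKernel(1.0, events.tau_rise_ms, events.tau_decay_ms), sampling_rate,
        polarity="inward")
    tpeak = biexp_peak_time(events.tau_rise_ms, events.tau_decay_ms) / 1e3
    _add_events(samples, sampling_rate, 0.0, peak_times, amps, kernel, tpeak)

    # SMOCs: slow outward events
    if smoc_rate > 0:
        smoc_times = np.sort(rng_times.uniform(
            0.0, duration, rng_times.poisson(smoc_rate * duration)))
        smoc_kernel = render_epsc_kernel(
            EpscKernel(1.0, smoc_tau_rise_ms, smoc_tau_decay_ms), sampling_rate,
            polarity="outward")
        smoc_tpeak = biexp_peak_time(smoc_tau_rise_ms, smoc_tau_decay_ms) / 1e3
        smoc_amps = np.full(smoc_times.size, smoc_amp_pa)
        _add_events(samples, sampling_rate, 0.0, smoc_times, smoc_amps,
                    smoc_kernel, smoc_tpeak)
    else:
        smoc_times = np.empty(0)

    if burst_offset is not None and deflection_peak_pa > 0:
        t = np.arange(n) / sampling_rate
        samples += _alpha_deflection(t, burst_offset, deflection_peak_pa,
                                     deflection_return_s)

    if noise_sd > 0:
        samples += noise_sd * rng_noise.standard_normal(n)

    trace = Trace(samples=samples, sampling_rate=sampling_rate,
                  clamp_mode=VOLTAGE_CLAMP, channel_label="Im")
    truth = VCGroundTruth(event_times=peak_times, event_amplitudes=amps,
                          smoc_times=smoc_times,
                          deflection_params=(deflection_peak_pa, deflection_return_s),
                          noise_sd=noise_sd, rate_profile=profile, events=events)
    return trace, truth


# ---------------------------------------------------------------------------
# Detector dead-time model (used for preset calibration)
#
# The printed post/pre frequency ratio is a *measured* quantity: at ~30
# events/s the detector's minimum peak separation and waveform merging thin
# the detected train.  The preset calibration inverts that thinning so the
# expected detected ratio matches the printed cohort value.  The model is a
# point-process Monte Carlo of the two loss mechanisms: near-coincident
# events merging into one extremum, and greedy keep-highest-within-distance
# peak selection.

def detected_rate_model(rate: float, min_separation: float = 0.002,
                        merge_window: float = 0.0012,
                        t_total: float = 4000.0, seed: int = 987_654_321) -> float:
    """Expected detected event rate for a homogeneous Poisson train."""
    if rate <= 0:
        return 0.0
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(0.0, t_total, rng.poisson(rate * t_total)))
    heights = rng.lognormal(0.0, 0.4, size=times.size)
    if times.size == 0:
        return 0.0
    # merge near-coincident events into one peak (keep the larger)
    keep_t, keep_h = [], []
    ct, ch = times[0], heights[0]
    for t, h in zip(times[1:], heights[1:]):
        if t - ct < merge_window:
            if h > ch:
                ct, ch = t, h
        else:
            keep_t.append(ct)
            keep_h.append(ch)
            ct, ch = t, h
    keep_t.append(ct)
    keep_h.append(ch)
    t_arr = np.asarray(keep_t)
    h_arr = np.asarray(keep_h)
    # greedy keep-highest within min_separation (find_peaks `distance` semantics)
    order = np.argsort(h_arr)[::-1]
    kept = np.zeros(t_arr.size, dtype=bool)
    removed = np.zeros(t_arr.size, dtype=bool)
    for idx in order:
        if removed[idx]:
            continue
        kept[idx] = True
        j = idx - 1
        while j >= 0 and t_arr[idx] - t_arr[j] < min_separation:
            removed[j] = True
            j -= 1
        j = idx + 1
        while j < t_arr.size and t_arr[j] - t_arr[idx] < min_separation:
            removed[j] = True
            j += 1
    return kept.sum() / t_total


def invert_detected_rate(target_detected: float, min_separation: float = 0.002,
                         merge_window: float = 0.0012) -> float:
    """True Poisson rate whose expected detected rate equals the target."""
    if target_detected <= 0:
        return 0.0
    lo, hi = target_detected, target_detected * 3 + 5.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if detected_rate_model(mid, min_separation, merge_window) < target_detected:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
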