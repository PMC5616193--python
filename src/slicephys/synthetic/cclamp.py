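"""Current-clamp trace synthesis: analytic spike templates with exact
ground truth, AHP/ADP shapes, and the six firing phenotypes.

Spikes are analytic waveforms, not conductance-based simulations, so every
ground-truth feature is exact by construction:

* the membrane-potential derivative crosses the 10 V/s detection criterion
  exactly at the configured threshold voltage, with gentle curvature around
  the crossing so zero-phase smoothing in the detector does not bias the
  measured threshold;
* the spike rises to ``threshold + amplitude`` and falls to a trough at
  ``threshold - ahp_amplitude``; the downstroke steepness is solved
  numerically (secant) so the width at half amplitude equals the requested
  half-width;
* the AHP recovery is mono- or biexponential (S- / S+), optionally with a
  Gaussian afterdepolarization bump (ADP profile).

Firing patterns are realized as spike-time layouts plus envelope
components on a passive RC response: an onset low-threshold hump carrying
a spike cluster (LTS, repeated for the oscillatory-burst subtype), an
initial hyperpolarizing sag delaying the first spike (LAT), a longer first
interspike interval (FIL), few spikes despite sustained depolarization
(LFR), and a subthreshold membrane oscillation with locked firing (OSC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..traceio import (Trace, ProtocolAnnotation, ValidationError,
                       CURRENT_CLAMP)

__all__ = ["CCGroundTruth", "CCRecording", "SpikeTemplate",
           "synth_current_clamp", "FIRING_PATTERNS", "AHP_PROFILES"]

FIRING_PATTERNS = ("CON", "LAT", "LTS", "LTS_osc", "FIL", "LFR", "OSC")
AHP_PROFILES = ("ADP", "S+", "S-")


@dataclass
class CCGroundTruth:
    """Generator truth for one current-clamp neuron."""

    firing_pattern: str = "CON"
    ahp_profile: str = "ADP"
    true_threshold: float = -45.0        # mV
    true_spike_amplitude: float = 69.7   # mV, threshold to peak
    true_half_width: float = 0.39        # ms
    true_ahp_amplitude: float = 26.4     # mV, threshold minus trough
    r_in: float = 358.0                  # MOhm
    c_in: float = 54.7                   # pF
    spontaneous_rate: float = 6.1        # spikes/s
    isi_cv: float = 16.3                 # percent

    def __post_init__(self) -> None:
        if self.firing_pattern not in FIRING_PATTERNS:
            raise ValidationError(f"unknown firing pattern {self.firing_pattern!r}")
        if self.ahp_profile not in AHP_PROFILES:
            raise ValidationError(f"unknown AHP profile {self.ahp_profile!r}")
        for name in ("true_spike_amplitude", "true_half_width",
                     "true_ahp_amplitude", "r_in", "c_in"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.spontaneous_rate < 0 or self.isi_cv < 0:
            raise ValidationError("rates must be >= 0")
        if self.firing_pattern == "LFR" and self.spontaneous_rate > 2.0:
            raise ValidationError(
                "LFR (low-firing-rate) truth is inconsistent with a high "
                "spontaneous rate")

    @property
    def tau_m_ms(self) -> float:
        return self.r_in * self.c_in / 1e3  # MOhm * pF -> ms


@dataclass
class CCRecording:
    """The sweep set recorded from one (synthetic) neuron.

    ``passive`` is a -40 pA hyperpolarizing step; ``single_spike`` is a
    400-ms pulse adjusted to elicit exactly one action potential (the
    AHP-profiling context); ``pulses`` is the depolarizing family spanning
    sub- to suprathreshold; ``spontaneous`` is a zero-injection segment.
    """

    neuron_id: str
    passive: tuple[Trace, ProtocolAnnotation]
    single_spike: tuple[Trace, ProtocolAnnotation]
    pulses: list[tuple[Trace, ProtocolAnnotation]]
    spontaneous: tuple[Trace, ProtocolAnnotation] | None = None
    truth: CCGroundTruth | None = None


# ---------------------------------------------------------------------------
# Spike template

_DVDT_AT_THRESHOLD = 10.0  # mV/ms == 10 V/s, the detection criterion
# dV/dt is linear in time (slope _A_LIN) within ~0.5 ms of the crossing, so
# the detector's zero-phase smoothing does not bias the measured threshold;
# the exponential acceleration (e-folding _TAU_G) starts beyond the kernel.
_A_LIN = 20.0     # mV/ms^2
_D_LIN_TOP = 20.0  # mV/ms, end of the linear window after the crossing
_TAU_G = 0.15     # ms


class SpikeTemplate:
    """Analytic spike core from threshold crossing to AHP trough.

    The core is rendered on a fine grid (5 us) and resampled to the trace
    grid at insertion time.  dV/dt rises exponentially through 10 V/s at
    the threshold voltage (e-folding time ``_TAU_G``), decelerates linearly
    to the peak, then a triangular downstroke carries the trace to the
    trough; the downstroke magnitude is solved so the width at
    ``threshold + amplitude/2`` matches the requested half-width.
    """

    def __init__(self, threshold: float, amplitude: float, half_width: float,
                 ahp_amplitude: float, dt_fine_ms: float = 0.005):
        self.threshold = threshold
        self.amplitude = amplitude
        self.ahp_amplitude = ahp_amplitude
        self.dt_fine_ms = dt_fine_ms
        tau_up = min(0.18, 0.35 * half_width)
        t_lin = (_D_LIN_TOP - _DVDT_AT_THRESHOLD) / _A_LIN
        rise_lin = _DVDT_AT_THRESHOLD * t_lin + _A_LIN * t_lin ** 2 / 2
        d_turn = max((amplitude - rise_lin + _D_LIN_TOP * _TAU_G)
                     / (_TAU_G + tau_up / 2), _D_LIN_TOP + 5.0)
        self._tau_up = tau_up
        self._t_lin = t_lin
        self._d_turn = d_turn

        # solve downstroke steepness for the half-width (secant)
        dd = 74.0 * 2 / max(half_width, 0.05)
        w = self._render_width(dd)
        dd2 = dd * w / half_width
        for _ in range(30):
            w2 = self._render_width(dd2)
            if abs(w2 - half_width) < 1e-4 or abs(w2 - w) < 1e-9:
                break
            dd, w, dd2 = dd2, w2, np.clip(
                dd2 - (w2 - half_width) * (dd2 - dd) / (w2 - w), 30.0, 5000.0)
        self._dd = dd2
        self.fine = self._render(dd2)
        self.rendered_half_width = self._width_of(self.fine)

    def _dvdt_profile(self, dd: float) -> np.ndarray:
        dt = self.dt_fine_ms
        t0 = np.arange(0.0, self._t_lin, dt)
        lin = _DVDT_AT_THRESHOLD + _A_LIN * t0
        t_a = _TAU_G * np.log(self._d_turn / _D_LIN_TOP)
        t1 = np.arange(0.0, t_a, dt)
        up = np.concatenate([lin, _D_LIN_TOP * np.exp(t1 / _TAU_G)])
        t2 = np.arange(0.0, self._tau_up, dt)
        dec = self._d_turn * (1 - t2 / self._tau_up)
        # downstroke: fast triangular fall, then a slow final approach to the
        # trough so the trough is smooth on the scale of the analyzers'
        # 1-kHz smoothing kernel (a needle-sharp minimum would bias the
        # measured AHP)
        fall = self.amplitude + self.ahp_amplitude
        d_tail = 8.0
        tail_mv = min(5.0, self.ahp_amplitude / 3)
        tau_tail = 2 * tail_mv / d_tail
        tau_e = 2 * (fall - tail_mv) / (2.5 * dd + 1.5 * d_tail)
        t3 = np.arange(0.0, tau_e, dt)
        down1 = -dd * t3 / tau_e
        t4 = np.arange(0.0, 1.5 * tau_e, dt)
        down2 = -dd + (dd - d_tail) * t4 / (1.5 * tau_e)
        t5 = np.arange(0.0, tau_tail, dt)
        down3 = -d_tail * (1 - t5 / tau_tail)
        return np.concatenate([up, dec, down1, down2, down3])

    def _render(self, dd: float) -> np.ndarray:
        dvdt = self._dvdt_profile(dd)
        v = self.threshold + np.cumsum(dvdt) * self.dt_fine_ms
        # land exactly on the trough (cumulative quadrature error is tiny;
        # rescale the post-peak fall so truth is exact by construction)
        ipk = int(np.argmax(v))
        target_trough = self.threshold - self.ahp_amplitude
        fall = v[ipk] - v[-1]
        want_peak = self.threshold + self.amplitude
        v = v * (want_peak - self.threshold) / (v[ipk] - self.threshold) \
            + self.threshold * (1 - (want_peak - self.threshold) / (v[ipk] - self.threshold))
        fall = v[ipk] - v[-1]
        want_fall = want_peak - target_trough
        v[ipk:] = v[ipk] + (v[ipk:] - v[ipk]) * want_fall / fall
        return v

    def _width_of(self, v: np.ndarray) -> float:
        half = self.threshold + self.amplitude / 2
        above = v >= half
        idx = np.flatnonzero(above)
        i0, i1 = idx[0], idx[-1]
        t0 = (i0 - 1 + (half - v[i0 - 1]) / (v[i0] - v[i0 - 1])) if i0 > 0 else i0
        t1 = i1 + (v[i1] - half) / (v[i1] - v[i1 + 1]) if i1 + 1 < v.size else i1
        return (t1 - t0) * self.dt_fine_ms

    def _render_width(self, dd: float) -> float:
        return self._width_of(self._render(dd))

    def grid_samples(self, sampling_rate: float) -> np.ndarray:
        """Core resampled to the trace grid, first sample at the crossing."""
        step = int(round(1e3 / sampling_rate / self.dt_fine_ms))
        return self.fine[::step].copy()


def _recovery(tau_ms: np.ndarray, profile: str) -> np.ndarray:
    """AHP recovery shape r(tau), r(0)=1, relative to the envelope."""
    if profile == "S-":
        return np.exp(-tau_ms / 20.0)
    return 0.70 * np.exp(-tau_ms / 15.0) + 0.30 * np.exp(-tau_ms / 120.0)


def _adp_bump(tau_ms: np.ndarray, dev0_mv: float) -> np.ndarray:
    # bump must outrun the recovery slope, which scales with the AHP depth
    amp = max(3.0, 0.2 * abs(dev0_mv))
    return amp * np.exp(-((tau_ms - 25.0) ** 2) / (2 * 7.0 ** 2))


def _alpha(t_ms: np.ndarray, onset_ms: float, amp: float, tau_ms: float) -> np.ndarray:
    x = t_ms - onset_ms
    out = np.zeros_like(t_ms)
    pos = x > 0
    out[pos] = amp * (x[pos] / tau_ms) * np.exp(1 - x[pos] / tau_ms)
    return out


# ---------------------------------------------------------------------------
# Sweep assembly

def _insert_spikes(v: np.ndarray, env: np.ndarray, spike_idx: list[int],
                   core: np.ndarray, threshold: float, profile: str,
                   sampling_rate: float, barriers: list[int] | None = None) -> None:
    """Overwrite envelope samples with spikes and their AHP recoveries.

    Each spike gets an approach ramp whose dV/dt stays strictly below the
    10 V/s criterion until the designed crossing, spliced backward into
    whatever the trace currently holds (envelope or the previous AHP).
    ``barriers`` (e.g. pulse onsets) bound how far back a ramp may reach.
    """
    dt_ms = 1e3 / sampling_rate
    n = v.size
    ncore = core.size
    barriers = sorted(barriers or [])
    prev_end = 0
    for idx in spike_idx:
        if idx <= prev_end + 2 or idx + ncore >= n:
            continue
        barrier = max([b for b in barriers if b < idx], default=0)
        start_floor = max(prev_end + 1, barrier)
        if idx <= start_floor + 2:
            continue
        # adaptive approach steepness: bridge the local gap (envelope a few
        # tens of ms before the spike) so the ramp stays short and does not
        # erase slower envelope structure such as a sag
        look = max(start_floor, idx - int(25.0 / dt_ms))
        v_ref = v[look]
        gap = max(threshold - v_ref, 2.0)
        avail_ms = (idx - look) * dt_ms
        c = np.clip((gap - 2.5) / max(avail_ms - 0.5, 0.3), 0.3, 9.0)
        tau_c = (_DVDT_AT_THRESHOLD - c) / _A_LIN
        drop_lin_end = (_DVDT_AT_THRESHOLD ** 2 - c ** 2) / (2 * _A_LIN)
        jmax = idx - start_floor
        for j in range(1, jmax + 1):
            tau = j * dt_ms
            if tau <= tau_c:
                drop = _DVDT_AT_THRESHOLD * tau - _A_LIN * tau ** 2 / 2
            else:
                drop = drop_lin_end + c * (tau - tau_c)
            p = threshold - drop
            if p <= v[idx - j]:
                break
            v[idx - j] = p
        # spike core
        v[idx:idx + ncore] = core
        i_t = idx + ncore - 1
        # AHP recovery rides the envelope; write to the end, later spikes overwrite
        tau = np.arange(n - i_t) * dt_ms
        dev0 = v[i_t] - env[i_t]
        rec = env[i_t:] + dev0 * _recovery(tau, profile)
        if profile == "ADP":
            rec = rec + _adp_bump(tau, dev0)
        v[i_t:] = rec
        prev_end = i_t


def _pattern_layout(pattern: str, level: float, rng: np.random.Generator
                    ) -> tuple[np.ndarray, list[tuple[float, float, float]],
                               bool, bool]:
    """Spike times (ms, relative to pulse onset) and envelope extras.

    ``level`` is the pulse amplitude relative to rheobase (1.0 or 2.0).
    Returns (spike_times, humps [(onset, amp, tau)], sag, oscillation).
    """
    j = lambda s: 1.0 + rng.normal(0.0, s)
    speed = 1.0 if level <= 1.25 else 0.8   # mild rate increase with drive
    if pattern == "CON":
        isi = 38.0 * speed
        t = 22.0 + np.arange(10) * isi * np.array([j(0.01) for _ in range(10)])
        return t[t < 392], [], False, False
    if pattern == "LAT":
        lat = (160.0 if level <= 1.25 else 115.0) * j(0.02)
        isi = 40.0 * speed
        t = lat + np.arange(7) * isi * np.array([j(0.01) for _ in range(7)])
        return t[t < 392], [], True, False
    if pattern == "LTS":
        cluster = 8.0 + np.array([0.0, 8.0, 16.0]) * j(0.02)
        tonic = 170.0 + np.arange(5) * 46.0 * speed * np.array([j(0.01) for _ in range(5)])
        t = np.concatenate([cluster, tonic])
        return t[t < 392], [(3.0, 15.0, 15.0)], False, False
    if pattern == "LTS_osc":
        times, humps = [], []
        for k, start in enumerate((8.0, 128.0, 248.0)):
            s = start * j(0.02) if k else start
            nsp = 3 if level <= 1.25 else 3
            times.extend(s + np.arange(nsp) * 8.5)
            humps.append((s - 5.0, 15.0, 15.0))
        t = np.asarray(times)
        return t[t < 392], humps, False, False
    if pattern == "FIL":
        isi2 = 33.0 * speed
        isis = np.array([65.0 * speed] + [isi2] * 8) * np.array([j(0.01) for _ in range(9)])
        t = 25.0 + np.concatenate([[0.0], np.cumsum(isis)])
        return t[t < 392], [], False, False
    if pattern == "LFR":
        return np.array([30.0 * j(0.02)]), [], False, False
    if pattern == "OSC":
        # one spike per 20-Hz oscillation cycle, locked near the crests
        t = 105.0 + np.arange(6) * 50.0 * np.array([j(0.005) for _ in range(6)])
        return t[t < 392], [], False, True
    raise ValidationError(f"unknown firing pattern {pattern!r}")


def _make_sweep(truth: CCGroundTruth, template: SpikeTemplate,
                duration_s: float, pulse: tuple[float, float, float] | None,
                spike_times_s: np.ndarray, humps, sag: bool, osc: bool,
                v_hold: float, rng: np.random.Generator,
                sampling_rate: float, noise_sd_mv: float,
                env_cap_below_threshold: float = 2.0,
                plateau_cap: float | None = None,
                ) -> tuple[Trace, ProtocolAnnotation]:
    """Render one sweep: passive envelope + extras + inserted spikes."""
    n = int(round(duration_s * sampling_rate))
    t_s = np.arange(n) / sampling_rate
    t_ms = t_s * 1e3
    env = np.full(n, v_hold)
    tau_m = truth.tau_m_ms

    ann = ProtocolAnnotation(neuron_id="", group="")
    if pulse is not None:
        on, off, amp_pa = pulse
        ann.pulse_onsets, ann.pulse_offsets = [on], [off]
        ann.pulse_amplitudes = [amp_pa]
        dv_inf = amp_pa * truth.r_in / 1e3   # pA * MOhm -> mV
        if plateau_cap is not None and dv_inf > plateau_cap:
            dv_inf = plateau_cap
        x = np.clip((t_ms - on * 1e3), 0.0, None)
        rise = dv_inf * (1 - np.exp(-x / tau_m))
        dec = (t_ms > off * 1e3)
        rise[dec] = rise[dec] * np.exp(-(t_ms[dec] - off * 1e3) / tau_m)
        env = env + rise
        rel = t_ms - on * 1e3
        if sag:
            # transient hyperpolarization after onset: fast enough relative
            # to the passive charging to carve a real dip before recovery
            env = env - _alpha(rel, 12.0, 16.0, 18.0)
        for onset, amp, tau in humps:
            env = env + _alpha(rel, onset, amp, tau)
        if osc:
            ramp = np.clip(rel / 50.0, 0.0, 1.0) * (rel > 0) * (t_ms < off * 1e3)
            env = env + 3.0 * ramp * np.sin(2 * np.pi * 20.0 * (rel / 1e3))
    env = np.minimum(env, truth.true_threshold - env_cap_below_threshold)

    v = env.copy()
    spike_idx = sorted(int(round(ts * sampling_rate)) for ts in spike_times_s)
    core = template.grid_samples(sampling_rate)
    barriers = ([int(round(pulse[0] * sampling_rate))] if pulse is not None else [])
    _insert_spikes(v, env, spike_idx, core, truth.true_threshold,
                   truth.ahp_profile, sampling_rate, barriers=barriers)
    if noise_sd_mv > 0:
        v = v + rng.normal(0.0, noise_sd_mv, size=n)
    trace = Trace(samples=v, sampling_rate=sampling_rate,
                  clamp_mode=CURRENT_CLAMP, channel_label="Vm")
    return trace, ann


def synth_current_clamp(truth: CCGroundTruth,
                        seed: int | np.random.Generator,
                        neuron_id: str = "cc000",
                        sampling_rate: float = 10_000.0,
                        noise_sd_mv: float = 0.25,
                        v_hold: float = -80.0,
                        spontaneous_duration_s: float = 10.0,
                        include_spontaneous: bool = True,
                        ) -> CCRecording:
    """Synthesize the full sweep set for one neuron.

    Produces the passive -40 pA step, a single-spike 400-ms pulse for AHP
    profiling, a three-amplitude depolarizing pulse family
    (0.6x / 1x / 2x rheobase, 400 ms each, held at ``v_hold``), and an
    optional spontaneous segment.  Same seed gives bit-identical output.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    template = SpikeTemplate(truth.true_threshold, truth.true_spike_amplitude,
                             truth.true_half_width, truth.true_ahp_amplitude)

    # passive -40 pA step from -60 mV (the standard R_in protocol)
    passive = _make_sweep(truth, template, 1.0, (0.2, 0.6, -40.0),
                          np.empty(0), [], False, False, -60.0, rng,
                          sampling_rate, noise_sd_mv)

    # single-spike sweep: plateau held just below threshold
    cap = truth.true_threshold - 8.0 - v_hold
    i_single = cap / truth.r_in * 1e3  # pA to reach the capped plateau
    single = _make_sweep(truth, template, 1.0, (0.3, 0.7, i_single),
                         np.array([0.3 + 0.150]), [], False, False, v_hold,
                         rng, sampling_rate, noise_sd_mv, plateau_cap=cap)

    # pulse family
    i_rheo = (truth.true_threshold + 4.0 - v_hold) / truth.r_in * 1e3
    i_rheo = max(20.0, round(i_rheo / 20.0) * 20.0)
    plateau_cap = (max(truth.true_threshold - 11.0 - v_hold, 22.0)
                   if truth.firing_pattern == "LFR"
                   else truth.true_threshold - 6.0 - v_hold)
    pulses = []
    for level in (0.6, 1.0, 2.0):
        amp = level * i_rheo
        if level < 1.0:
            times = np.empty(0)
            humps, sag, osc = [], False, False
        else:
            times_ms, humps, sag, osc = _pattern_layout(
                truth.firing_pattern, level, rng)
            times = 0.2 + np.sort(times_ms) / 1e3
        sweep = _make_sweep(truth, template, 0.9, (0.2, 0.6, amp), times,
                            humps, sag, osc, v_hold, rng, sampling_rate,
                            noise_sd_mv,
                            plateau_cap=None if level < 1.0 else plateau_cap)
        pulses.append(sweep)

    spont = None
    if include_spontaneous and truth.spontaneous_rate > 0:
        k = max((100.0 / max(truth.isi_cv, 1.0)) ** 2, 1.05)
        mean_isi = 1.0 / truth.spontaneous_rate
        n_isi = int(truth.spontaneous_rate * spontaneous_duration_s * 3) + 10
        isis = rng.gamma(k, mean_isi / k, size=n_isi)
        times = np.cumsum(isis) + 0.1
        times = times[times < spontaneous_duration_s - 0.05]
        spont = _make_sweep(truth, template, spontaneous_duration_s, None,
                            times, [], False, False, -55.0, rng,
                            sampling_rate, noise_sd_mv)

    for sweep in [passive, single] + pulses + ([spont] if spont else []):
        sweep[1].neuron_id = neuron_id
    return CCRecording(neuron_id=neuron_id, passive=passive,
                       single_spike=single, pulses=pulses,
                       spontaneous=spont, truth=truth)
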