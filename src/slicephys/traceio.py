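"""Trace data model, file I/O and elementary trace transforms.

A :class:`Trace` is one sampled recording channel: membrane voltage (mV) in
current clamp or membrane current (pA) in voltage clamp, with a fixed
sampling rate (10 kHz by default throughout the package).  A
:class:`ProtocolAnnotation` carries the stimulation protocol and recording
metadata (current pulses, extracellular burst stimulation, pharmacological
condition, group label).

The native on-disk format is deliberately plain: one CSV per trace
(``time_s,value`` columns) plus a JSON sidecar for the annotation, so test
fixtures are inspectable and diff-able.  An optional HDF5 container bundles
whole cohorts (one group per sweep).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any

import numpy as np
from scipy import signal

__all__ = [
    "Trace",
    "ProtocolAnnotation",
    "FormatError",
    "ValidationError",
    "ModeError",
    "read_recording",
    "write_recording",
    "read_container",
    "write_container",
    "correct_junction_potential",
    "lowpass",
]

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"


class FormatError(ValueError):
    """A file does not declare the metadata required to interpret it."""


class ValidationError(ValueError):
    """Metadata or data violate a documented invariant."""


class ModeError(ValueError):
    """An operation was applied to a trace of the wrong clamp mode."""


@dataclass
class Trace:
    """One sampled recording channel.

    Parameters
    ----------
    samples:
        Signal values; mV for current clamp, pA for voltage clamp.
    sampling_rate:
        Samples per second (Hz), strictly positive.
    clamp_mode:
        ``"current_clamp"`` or ``"voltage_clamp"``; fixes the units.
    t0:
        Time of the first sample, seconds.
    channel_label:
        Free-text channel name.
    """

    samples: np.ndarray
    sampling_rate: float
    clamp_mode: str
    t0: float = 0.0
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        if self.clamp_mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise ValidationError(f"unknown clamp_mode {self.clamp_mode!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds (absolute, starting at ``t0``)."""
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def index_of(self, t: float) -> int:
        """Index of the first sample at or after time ``t`` (clipped)."""
        i = int(np.ceil((t - self.t0) * self.sampling_rate - 1e-9))
        return min(max(i, 0), self.n_samples)

    def slice(self, start: float, stop: float) -> "Trace":
        """Sub-trace over the half-open interval ``[start, stop)`` seconds."""
        i0, i1 = self.index_of(start), self.index_of(stop)
        return replace(self, samples=self.samples[i0:i1],
                       t0=self.t0 + i0 / self.sampling_rate)

    def with_samples(self, samples: np.ndarray) -> "Trace":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class ProtocolAnnotation:
    """Stimulation protocol and recording metadata for one sweep.

    ``pulse_onsets/offsets/amplitudes`` describe intracellular current
    pulses (seconds / pA); ``burst_*`` describe the extracellular burst
    stimulation (a 100-Hz, 20-pulse train in the reference protocol).
    Times are absolute (same clock as ``Trace.t0``); windows downstream are
    half-open ``[start, end)``.
    """

    pulse_onsets: list[float] = field(default_factory=list)
    pulse_offsets: list[float] = field(default_factory=list)
    pulse_amplitudes: list[float] = field(default_factory=list)
    burst_onset: float | None = None
    burst_offset: float | None = None
    burst_n_pulses: int = 20
    burst_rate: float = 100.0
    condition: str = "control"
    drug_name: str = ""
    group: str = ""
    neuron_id: str = ""
    venus_status: str = "unknown"
    junction_potential_mv: float = 0.0
    junction_corrected: bool = False
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.pulse_onsets)
        if not (len(self.pulse_offsets) == n == len(self.pulse_amplitudes)):
            raise ValidationError("pulse lists must have equal length")
        for a, b in zip(self.pulse_onsets, self.pulse_offsets):
            if b <= a:
                raise ValidationError("pulse offset must exceed onset")
        if self.burst_onset is not None and self.burst_offset is not None:
            if self.burst_offset <= self.burst_onset:
                raise ValidationError("burst_offset must exceed burst_onset")

    @property
    def has_burst(self) -> bool:
        return self.burst_onset is not None and self.burst_offset is not None


# ---------------------------------------------------------------------------
# CSV + JSON sidecar format

_REQUIRED_META = ("sampling_rate", "clamp_mode")


def write_recording(path: str | Path, trace: Trace,
                    annotation: ProtocolAnnotation | None = None) -> None:
    """Write ``trace`` to ``path`` (CSV) with a ``.json`` metadata sidecar."""
    path = Path(path)
    t = trace.times()
    header = "time_s,value"
    np.savetxt(path, np.column_stack([t, trace.samples]), delimiter=",",
               header=header, comments="", fmt="%.9g")
    meta: dict[str, Any] = {
        "sampling_rate": trace.sampling_rate,
        "clamp_mode": trace.clamp_mode,
        "t0": trace.t0,
        "channel_label": trace.channel_label,
    }
    if annotation is not None:
        meta["annotation"] = asdict(annotation)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1, sort_keys=True))


def _annotation_from_dict(d: dict[str, Any]) -> ProtocolAnnotation:
    known = {f for f in ProtocolAnnotation.__dataclass_fields__}
    kwargs = {k: v for k, v in d.items() if k in known}
    ann = ProtocolAnnotation(**kwargs)
    # unknown keys are preserved, not dropped
    for k, v in d.items():
        if k not in known:
            ann.extra[k] = v
    return ann


def read_recording(path: str | Path) -> tuple[Trace, ProtocolAnnotation]:
    """Read a CSV trace and its JSON sidecar back into memory.

    Raises :class:`FormatError` when the sidecar is missing or lacks the
    sampling rate / clamp mode, and :class:`ValidationError` on
    non-monotonic protocol times.
    """
    path = Path(path)
    side = path.with_suffix(path.suffix + ".json")
    if not side.exists():
        raise FormatError(f"missing metadata sidecar {side}")
    meta = json.loads(side.read_text())
    for key in _REQUIRED_META:
        if key not in meta:
            raise FormatError(f"sidecar lacks required key {key!r}")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    trace = Trace(samples=data[:, 1], sampling_rate=float(meta["sampling_rate"]),
                  clamp_mode=str(meta["clamp_mode"]), t0=float(meta.get("t0", 0.0)),
                  channel_label=str(meta.get("channel_label", "")))
    ann_dict = meta.get("annotation", {})
    ann = _annotation_from_dict(ann_dict) if ann_dict else ProtocolAnnotation()
    if ann.junction_potential_mv and not ann.junction_corrected:
        if trace.clamp_mode == CURRENT_CLAMP:
            trace = correct_junction_potential(trace, ann.junction_potential_mv)
            ann.junction_corrected = True
    return trace, ann


# ---------------------------------------------------------------------------
# HDF5 cohort container

def write_container(path: str | Path,
                    recordings: dict[str, list[tuple[Trace, ProtocolAnnotation]]]
                    ) -> None:
    """Bundle sweeps into one HDF5 file, one group per neuron."""
    import h5py

    with h5py.File(path, "w") as f:
        for neuron_id, sweeps in recordings.items():
            g = f.create_group(neuron_id)
            for i, (trace, ann) in enumerate(sweeps):
                sg = g.create_group(f"sweep{i:03d}")
                sg.create_dataset("samples", data=trace.samples)
                sg.attrs["sampling_rate"] = trace.sampling_rate
                sg.attrs["clamp_mode"] = trace.clamp_mode
                sg.attrs["t0"] = trace.t0
                sg.attrs["channel_label"] = trace.channel_label
                sg.attrs["annotation_json"] = json.dumps(asdict(ann))


def read_container(path: str | Path
                   ) -> dict[str, list[tuple[Trace, ProtocolAnnotation]]]:
    import h5py

    out: dict[str, list[tuple[Trace, ProtocolAnnotation]]] = {}
    with h5py.File(path, "r") as f:
        for neuron_id in sorted(f.keys()):
            g = f[neuron_id]
            sweeps = []
            for name in sorted(g.keys()):
                sg = g[name]
                if "sampling_rate" not in sg.attrs or "clamp_mode" not in sg.attrs:
                    raise FormatError(f"{neuron_id}/{name} lacks sampling metadata")
                trace = Trace(samples=sg["samples"][...],
                              sampling_rate=float(sg.attrs["sampling_rate"]),
                              clamp_mode=str(sg.attrs["clamp_mode"]),
                              t0=float(sg.attrs["t0"]),
                              channel_label=str(sg.attrs["channel_label"]))
                ann = _annotation_from_dict(json.loads(sg.attrs["annotation_json"]))
                sweeps.append((trace, ann))
            out[neuron_id] = sweeps
    return out


# ---------------------------------------------------------------------------
# Elementary transforms

def correct_junction_potential(trace: Trace, offset_mv: float) -> Trace:
    """Shift a current-clamp trace by the signed liquid-junction offset.

    The measured junction potential of the K+-based internal solution is
    -5 mV; correction is an additive shift of every sample, so sample
    differences are preserved exactly.
    """
    if trace.clamp_mode != CURRENT_CLAMP:
        raise ModeError("junction-potential correction applies to current clamp")
    return trace.with_samples(trace.samples + offset_mv)


def lowpass(trace: Trace, cutoff_hz: float, order: int = 4) -> Trace:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Phase-neutral filtering is used so event peak times are not shifted;
    DC (constant) traces are fixed points.
    """
    nyq = trace.sampling_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValidationError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trace.sampling_rate,
                        output="sos")
    return trace.with_samples(signal.sosfiltfilt(sos, trace.samples))
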