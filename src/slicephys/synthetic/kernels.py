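"""Synaptic-event waveform kernels.

EPSCs are rendered as a difference of exponentials (biexponential),
normalized so the rendered extremum magnitude equals the requested
amplitude.  Events are inward (negative) on a voltage-clamp trace; SMOCs
reuse the same kernel with outward polarity and much slower decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EpscKernel", "render_epsc_kernel", "biexp_peak_time"]


class KernelParameterError(ValueError):
    pass


@dataclass(frozen=True)
class EpscKernel:
    """Biexponential event kernel.

    ``amplitude`` is stored as a magnitude in pA (> 0); polarity is applied
    at render time.  ``tau_decay > tau_rise > 0`` (ms).
    """

    amplitude: float
    tau_rise: float = 0.5
    tau_decay: float = 5.0

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.tau_decay <= self.tau_rise:
            raise KernelParameterError("require tau_decay > tau_rise > 0")
        if self.amplitude <= 0:
            raise KernelParameterError("amplitude must be > 0")


def biexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time-to-peak of exp(-t/tau_d) - exp(-t/tau_r), closed form (ms)."""
    return np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)


def render_epsc_kernel(kernel: EpscKernel, sampling_rate: float,
                       polarity: str = "inward",
                       support_fraction: float = 1e-3) -> np.ndarray:
    """Render the kernel waveform in pA at the given sampling rate.

    The waveform starts at event onset; its support is truncated where the
    envelope falls below ``support_fraction`` of the amplitude.  For inward
    polarity the extremum equals ``-amplitude`` (within normalization of
    the sampled peak).
    """
    if polarity not in ("inward", "outward"):
        raise KernelParameterError(f"unknown polarity {polarity!r}")
    tr, td = kernel.tau_rise / 1e3, kernel.tau_decay / 1e3  # s
    # decay tail alone bounds the support
    t_end = -td * np.log(support_fraction)
    n = max(int(np.ceil(t_end * sampling_rate)), 2)
    t = np.arange(n) / sampling_rate
    w = np.exp(-t / td) - np.exp(-t / tr)
    w *= kernel.amplitude / w.max()
    return -w if polarity == "inward" else w
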