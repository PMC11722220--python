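"""Visually evoked potential extraction and component measurement.

A VEP is the trial-averaged LFP time-locked to each phase reversal.  Trials
are baseline-normalized by subtracting the mean of their first 10 ms,
averaged, and smoothed with a 10 ms (FWHM) Gaussian.  The component
measurement finds the peak negativity in an early search window and the
subsequent peak positivity; VEP magnitude is peak-negative-to-peak-positive
voltage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .io_core import StimulusSchedule, ValidationError
from .lfp import LfpTrace

logger = logging.getLogger(__name__)

__all__ = [
    "VepWaveform",
    "VepComponents",
    "extract_trials",
    "normalize_and_smooth",
    "measure_components",
    "normalize_to_reference",
    "gaussian_smooth",
]


@dataclass
class VepWaveform:
    voltage_v: np.ndarray       # time axis 0..T ms post-reversal
    fs: float
    n_trials: int
    condition: str = ""
    channel: int | None = None

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.voltage_v.size) / self.fs * 1000.0


@dataclass
class VepComponents:
    negativity_v: float
    negativity_latency_ms: float
    positivity_v: float
    positivity_latency_ms: float

    @property
    def magnitude_v(self) -> float:
        return self.positivity_v - self.negativity_v

    def __post_init__(self) -> None:
        if self.negativity_latency_ms >= self.positivity_latency_ms:
            raise ValidationError("negativity must precede positivity")
        if self.magnitude_v < 0:
            raise ValidationError("magnitude must be non-negative")


def extract_trials(lfp: LfpTrace, schedule: StimulusSchedule, condition: str,
                   channel: int, t_trial_ms: float = 500.0) -> np.ndarray:
    """One row per reversal event, aligned at the event, ``t_trial_ms`` long."""
    events = schedule.events_for(condition)
    if events.size == 0:
        raise ValidationError(f"no reversal events for condition {condition!r}")
    n = int(round(t_trial_ms / 1000.0 * lfp.fs))
    rows, dropped = [], 0
    for ev in events:
        i0 = int(round(ev * lfp.fs))
        if i0 + n > lfp.samples.shape[1]:
            dropped += 1
            continue
        rows.append(lfp.samples[channel, i0:i0 + n])
    if dropped:
        logger.info("extract_trials: dropped %d events too close to recording end", dropped)
    if not rows:
        raise ValidationError("all events fell outside the recording")
    return np.asarray(rows)


def gaussian_smooth(x: np.ndarray, fs: float, fwhm_ms: float = 10.0) -> np.ndarray:
    """Smooth along the last axis with a truncated, renormalized Gaussian.

    The kernel width is given as full width at half maximum; support is
    truncated at +-3 sigma and the kernel renormalized to unit sum so a
    constant input is preserved exactly.
    """
    sigma = fwhm_ms / 1000.0 * fs / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = max(1, int(np.ceil(3.0 * sigma)))
    t = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (t / sigma) ** 2)
    k /= k.sum()
    pad = [(0, 0)] * (x.ndim - 1) + [(half, half)]
    xp = np.pad(x, pad, mode="reflect")
    return scipy.signal.fftconvolve(xp, k.reshape((1,) * (x.ndim - 1) + (-1,)),
                                    mode="valid")


def normalize_and_smooth(trials: np.ndarray, fs: float, condition: str = "",
                         channel: int | None = None,
                         fwhm_ms: float = 10.0) -> VepWaveform:
    """Baseline each trial to its first 10 ms, average, then smooth."""
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.shape[0] < 1 or trials.size == 0:
        raise ValidationError("need at least one trial")
    n10 = int(round(0.010 * fs))
    if trials.shape[1] < n10 or n10 < 1:
        raise ValidationError("trials shorter than the 10 ms baseline window")
    baselined = trials - trials[:, :n10].mean(axis=1, keepdims=True)
    avg = baselined.mean(axis=0)
    smoothed = gaussian_smooth(avg, fs, fwhm_ms)
    return VepWaveform(smoothed, fs, trials.shape[0], condition, channel)


def measure_components(waveform: VepWaveform,
                       neg_window_ms: tuple[float, float] = (25.0, 100.0),
                       pos_window_ms: tuple[float, float] = (60.0, 250.0)
                       ) -> VepComponents:
    """Peak negativity in the early window, later peak positivity, magnitude.

    The positivity search is restricted to latencies after the measured
    negativity; ties break toward the earliest latency.
    """
    t = waveform.time_ms
    v = waveform.voltage_v
    neg_mask = (t >= neg_window_ms[0]) & (t < neg_window_ms[1])
    if not neg_mask.any():
        raise ValidationError("empty negativity window")
    ni = np.flatnonzero(neg_mask)[np.argmin(v[neg_mask])]
    pos_mask = (t >= max(pos_window_ms[0], t[ni])) & (t < pos_window_ms[1]) & (t > t[ni])
    if not pos_mask.any():
        raise ValidationError("empty positivity window after the negativity")
    pi = np.flatnonzero(pos_mask)[np.argmax(v[pos_mask])]
    return VepComponents(float(v[ni]), float(t[ni]), float(v[pi]), float(t[pi]))


def normalize_to_reference(magnitudes: dict, reference: str) -> dict:
    """Divide each level's VEP magnitude by the reference level's magnitude."""
    if reference not in magnitudes:
        raise ValidationError(f"reference level {reference!r} missing")
    ref = magnitudes[reference]
    ref = ref.magnitude_v if isinstance(ref, VepComponents) else float(ref)
    if ref == 0:
        raise ValidationError("reference magnitude is zero")
    out = {}
    for k, m in magnitudes.items():
        m = m.magnitude_v if isinstance(m, VepComponents) else float(m)
        out[k] = m / ref
    return out
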