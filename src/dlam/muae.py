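"""Multiunit activity envelope (MUAe).

The MUAe is a threshold-free proxy for local population spiking: the
wide-band trace is common-median referenced, 60 Hz notched, band-passed
500-5000 Hz, rectified, low-passed below 250 Hz and downsampled to 1 kHz.
Responses are expressed as z-scores against the mean/SD of all interblock
(gray-screen) samples; a z of 1.96 marks a significant visual response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .csd import LaminarAlignment
from .io_core import StimulusSchedule, ValidationError

__all__ = [
    "MuaeTrace",
    "common_median_reference",
    "notch60_iir",
    "compute_muae",
    "zscore_interblock",
    "condition_response",
    "window_means",
    "EARLY_WINDOW_MS",
    "LATE_WINDOW_MS",
    "SIGNIFICANCE_Z",
]

EARLY_WINDOW_MS = (40.0, 80.0)
LATE_WINDOW_MS = (100.0, 200.0)
SIGNIFICANCE_Z = 1.96
MUAE_FS = 1000.0


@dataclass
class MuaeTrace:
    envelope: np.ndarray            # channels x time, volts, >= 0
    fs: float
    z: np.ndarray | None = None     # dimensionless, interblock-referenced
    baseline_mean: np.ndarray | None = None
    baseline_sd: np.ndarray | None = None


def common_median_reference(raw: np.ndarray) -> np.ndarray:
    """Per-channel median removal, then per-timepoint cross-channel median."""
    x = np.atleast_2d(np.asarray(raw, dtype=float))
    if x.shape[0] < 2:
        raise ValidationError("common median reference needs at least 2 channels")
    x = x - np.median(x, axis=1, keepdims=True)
    return x - np.median(x, axis=0, keepdims=True)


def notch60_iir(raw: np.ndarray, fs: float = 25_000.0) -> np.ndarray:
    """Second-order 60 Hz IIR notch with a 10 dB bandwidth of 10 Hz.

    For the standard biquad notch a -10 dB bandwidth of 10 Hz corresponds
    to a -3 dB bandwidth of 30 Hz (Q = 2).
    """
    if fs != 25_000.0:
        raise ValidationError(f"MUA notch expects fs=25000, got {fs}")
    b, a = scipy.signal.iirnotch(60.0, Q=2.0, fs=fs)
    sos = scipy.signal.tf2sos(b, a)
    return scipy.signal.sosfiltfilt(sos, np.atleast_2d(raw), axis=1)


def compute_muae(raw: np.ndarray, fs: float = 25_000.0,
                 band_hz: tuple[float, float] = (500.0, 5000.0),
                 lowpass_hz: float = 250.0, order: int = 3) -> MuaeTrace:
    """Bandpass -> rectify -> lowpass -> downsample to 1 kHz.

    Input should already be common-median referenced and notched.  The
    zero-phase low-pass of the rectified signal can undershoot slightly;
    the output is clipped at zero to keep the envelope non-negative.
    """
    x = np.atleast_2d(np.asarray(raw, dtype=float))
    q = fs / MUAE_FS
    if abs(q - round(q)) > 1e-9:
        raise ValidationError(f"fs {fs} is not an integer multiple of 1 kHz")
    try:
        x = bandpass_spike_band(x, fs, band_hz, order)
        x = np.abs(x)
        x = lowpass_envelope(x, fs, lowpass_hz, order)
    except ValidationError:
        raise
    except Exception as exc:
        raise ValidationError(f"MUAe filter stage failed: {exc}") from exc
    x = np.clip(x[:, :: int(round(q))], 0.0, None)
    return MuaeTrace(x, MUAE_FS)


def bandpass_spike_band(x: np.ndarray, fs: float = 25_000.0,
                        band_hz: tuple[float, float] = (500.0, 5000.0),
                        order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth bandpass isolating spiking-unit activity."""
    sos = scipy.signal.butter(order, band_hz, btype="bandpass", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, np.atleast_2d(x), axis=1)


def lowpass_envelope(x: np.ndarray, fs: float = 25_000.0,
                     cutoff_hz: float = 250.0, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth low-pass smoothing the rectified signal."""
    sos = scipy.signal.butter(order, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, np.atleast_2d(x), axis=1)


def zscore_interblock(muae: MuaeTrace, schedule: StimulusSchedule) -> MuaeTrace:
    """Z-score each channel against all concatenated interblock samples."""
    mask = schedule.interblock_mask(muae.envelope.shape[1], muae.fs)
    if mask.sum() < 2:
        raise ValidationError("need at least 2 interblock samples")
    base = muae.envelope[:, mask]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValidationError("degenerate interblock baseline (zero SD)")
    return MuaeTrace(muae.envelope, muae.fs, z=(muae.envelope - mu) / sd,
                     baseline_mean=mu.ravel(), baseline_sd=sd.ravel())


def _aligned_average(z: np.ndarray, events: np.ndarray, fs: float, n: int) -> np.ndarray:
    rows = []
    for ev in events:
        i0 = int(round(ev * fs))
        if i0 + n <= z.shape[1]:
            rows.append(z[:, i0:i0 + n])
    if not rows:
        raise ValidationError("no complete trials")
    return np.mean(rows, axis=0)


def condition_response(muae: MuaeTrace, schedule: StimulusSchedule,
                       alignment: LaminarAlignment, t_trial_ms: float = 500.0,
                       reference_condition: str = "monocular") -> dict:
    """Trial-aligned average z per layer and condition, and differences
    against the reference (monocular) condition.

    Returns ``{"aligned": {cond: layer -> z(t)}, "delta": {cond: layer ->
    z_cond - z_ref}, "time_ms": ...}``; layers with no channels are absent.
    """
    if muae.z is None:
        raise ValidationError("z-score the MUAe first")
    conditions = schedule.conditions
    if reference_condition not in conditions:
        raise ValidationError(f"missing condition {reference_condition!r}")
    n = int(round(t_trial_ms / 1000.0 * muae.fs))
    layer_channels: dict[str, list[int]] = {}
    for ch, lab in enumerate(alignment.layers):
        if lab != "out" and ch < muae.z.shape[0]:
            layer_channels.setdefault(lab, []).append(ch)

    aligned: dict[str, dict[str, np.ndarray]] = {}
    for cond in conditions:
        ev = schedule.events_for(cond)
        if ev.size == 0:
            raise ValidationError(f"missing condition {cond!r}")
        avg = _aligned_average(muae.z, ev, muae.fs, n)
        aligned[cond] = {lab: avg[chs].mean(axis=0) for lab, chs in layer_channels.items()}
    delta = {
        cond: {lab: aligned[cond][lab] - aligned[reference_condition][lab]
               for lab in aligned[cond]}
        for cond in conditions if cond != reference_condition
    }
    return {"aligned": aligned, "delta": delta,
            "time_ms": np.arange(n) / muae.fs * 1000.0}


def window_means(z_aligned: np.ndarray, fs: float = MUAE_FS,
                 early_ms: tuple[float, float] = EARLY_WINDOW_MS,
                 late_ms: tuple[float, float] = LATE_WINDOW_MS) -> tuple[float, float]:
    """Mean of a trial-aligned trace in the early and late windows."""
    z = np.asarray(z_aligned, dtype=float)
    t = np.arange(z.shape[-1]) / fs * 1000.0
    out = []
    for lo, hi in (early_ms, late_ms):
        m = (t >= lo) & (t < hi)
        if not m.any():
            raise ValidationError(f"empty window {lo}-{hi} ms")
        out.append(float(z[..., m].mean()))
    return out[0], out[1]
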