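"""Raw-trace conditioning into analysis-ready LFP.

The chain is: DC removal -> anti-aliased downsample to 1 kHz -> third-order
1-300 Hz Butterworth bandpass -> local linear detrend (0.5 s windows sliding
by 0.1 s) -> third-order 58-62 Hz Butterworth notch.  All IIR filters are
applied forward-backward (zero phase) so evoked-component latencies survive
filtering.  Each step is recorded in a provenance list and refuses to run
twice on the same trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .io_core import RecordingSession, ValidationError

__all__ = [
    "LfpTrace",
    "remove_dc",
    "downsample_to_1khz",
    "bandpass_1_300",
    "local_detrend",
    "notch_58_62",
    "preprocess_lfp",
    "TARGET_FS",
]

TARGET_FS = 1000.0


@dataclass
class LfpTrace:
    samples: np.ndarray  # channels x time, volts
    fs: float
    provenance: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.samples.shape[1] == 0:
            raise ValidationError("empty trace")

    def _stamped(self, samples: np.ndarray, fs: float, step: str, **params) -> "LfpTrace":
        if any(s == step for s, _ in self.provenance):
            raise ValidationError(f"step {step!r} already applied")
        return LfpTrace(samples, fs, self.provenance + [(step, params)])


def remove_dc(trace: LfpTrace) -> LfpTrace:
    """Subtract each channel's whole-recording mean (DC offset)."""
    out = trace.samples - trace.samples.mean(axis=1, keepdims=True)
    return trace._stamped(out, trace.fs, "remove_dc")


def downsample_to_1khz(trace: LfpTrace) -> LfpTrace:
    """Anti-alias low-pass then decimate to 1 kHz (integer ratios only)."""
    q = trace.fs / TARGET_FS
    if abs(q - round(q)) > 1e-9:
        raise ValidationError(f"fs {trace.fs} is not an integer multiple of 1 kHz")
    q = int(round(q))
    x = trace.samples
    fs = trace.fs
    if q > 1:
        # factor the ratio so no single decimation stage exceeds 13; each
        # stage: zero-phase order-8 Butterworth at 0.4x its target rate
        for stage in _factor_decimation(q):
            target = fs / stage
            sos = scipy.signal.butter(8, 0.4 * target, btype="lowpass", fs=fs,
                                      output="sos")
            x = scipy.signal.sosfiltfilt(sos, x, axis=1)[:, ::stage]
            fs = target
    return trace._stamped(x, TARGET_FS, "downsample_to_1khz", q=q)


def _factor_decimation(q: int) -> list[int]:
    stages, rem = [], q
    for p in (13, 11, 10, 8, 7, 6, 5, 4, 3, 2):
        while rem % p == 0 and rem > 13:
            stages.append(p)
            rem //= p
    stages.append(rem)
    return [s for s in stages if s > 1]


def bandpass_1_300(trace: LfpTrace, order: int = 3,
                   band_hz: tuple[float, float] = (1.0, 300.0)) -> LfpTrace:
    if trace.fs != TARGET_FS:
        raise ValidationError(f"bandpass expects fs={TARGET_FS}, got {trace.fs}")
    sos = scipy.signal.butter(order, band_hz, btype="bandpass", fs=trace.fs, output="sos")
    out = scipy.signal.sosfiltfilt(sos, trace.samples, axis=1)
    return trace._stamped(out, trace.fs, "bandpass_1_300", order=order, band_hz=band_hz)


def local_detrend(trace: LfpTrace, window_s: float = 0.5, step_s: float = 0.1) -> LfpTrace:
    """Subtract a local linear trend fitted on overlapping sliding windows.

    Per-window least-squares lines are combined by overlap-weighted
    (triangular-weight) averaging into a smooth trend estimate; the trace is
    reflect-padded by one window so edges see full overlap.
    """
    if window_s < step_s:
        raise ValidationError("detrend window must be at least the step size")
    n = trace.samples.shape[1]
    win = int(round(window_s * trace.fs))
    step = int(round(step_s * trace.fs))
    if n < win:
        raise ValidationError("trace shorter than the detrend window")
    x = np.pad(trace.samples, ((0, 0), (win, win)), mode="reflect")
    m = x.shape[1]
    trend = np.zeros_like(x)
    weight = np.zeros(m)
    tri = np.bartlett(win + 2)[1:-1] + 1e-12
    t = np.arange(win) - (win - 1) / 2.0
    denom = float((t ** 2).sum())
    for start in range(0, m - win + 1, step):
        seg = x[:, start:start + win]
        a = seg.mean(axis=1, keepdims=True)
        b = (seg * t).sum(axis=1, keepdims=True) / denom
        trend[:, start:start + win] += (a + b * t) * tri
        weight[start:start + win] += tri
    weight[weight == 0] = 1.0
    out = (x - trend / weight)[:, win:win + n]
    return trace._stamped(out, trace.fs, "local_detrend", window_s=window_s, step_s=step_s)


def notch_58_62(trace: LfpTrace, order: int = 3,
                band_hz: tuple[float, float] = (58.0, 62.0)) -> LfpTrace:
    if trace.fs != TARGET_FS:
        raise ValidationError(f"notch expects fs={TARGET_FS}, got {trace.fs}")
    sos = scipy.signal.butter(order, band_hz, btype="bandstop", fs=trace.fs, output="sos")
    out = scipy.signal.sosfiltfilt(sos, trace.samples, axis=1)
    return trace._stamped(out, trace.fs, "notch_58_62", order=order, band_hz=band_hz)


def preprocess_lfp(session: RecordingSession) -> LfpTrace:
    """Full conditioning chain on a raw session, in the canonical order."""
    trace = LfpTrace(session.samples, session.fs)
    for step in (remove_dc, downsample_to_1khz, bandpass_1_300, local_detrend, notch_58_62):
        try:
            trace = step(trace)
        except Exception as exc:
            raise ValidationError(f"LFP stage {step.__name__!r} failed: {exc}") from exc
    return trace
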