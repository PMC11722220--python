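"""Single-unit analysis: waveform classification, PSTHs, window statistics.

Units are split into fast-spiking (FS, putative PV+ interneurons) and
regular-spiking (RS, putative pyramidal) by the trough-to-peak latency of
the mean template: FS below 0.4 ms, RS above; the exact boundary goes to RS
with a logged warning.  PSTHs use 1 ms bins; rate = count / (n_trials *
bin), which reduces to the familiar "multiply by 2" at 500 trials.  Early
and late firing are the mean rates over [40, 80) and [100, 200) ms
post-reversal; per-unit z-scores reference interblock (gray) firing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .csd import LaminarAlignment, layer_of_depth
from .io_core import SortedUnit, StimulusSchedule, ValidationError
from .vep import gaussian_smooth

logger = logging.getLogger(__name__)

__all__ = [
    "Psth",
    "WindowStats",
    "UnitZScore",
    "trough_to_peak_ms",
    "classify_unit",
    "compute_psth",
    "window_rates",
    "zscore_unit",
    "assign_unit_layer",
    "FS_THRESHOLD_MS",
    "EARLY_WINDOW_MS",
    "LATE_WINDOW_MS",
]

FS_THRESHOLD_MS = 0.4
EARLY_WINDOW_MS = (40.0, 80.0)
LATE_WINDOW_MS = (100.0, 200.0)


@dataclass
class Psth:
    rate_hz: np.ndarray   # spikes/s per bin post-reversal
    bin_ms: float
    n_trials: int
    condition: str = ""
    unit_id: str = ""

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.rate_hz.size) * self.bin_ms


@dataclass
class WindowStats:
    early_rate_hz: float
    late_rate_hz: float
    condition: str = ""
    unit_id: str = ""


@dataclass
class UnitZScore:
    z: np.ndarray | None
    fs: float
    baseline_mean_hz: float
    baseline_sd_hz: float
    excluded: bool = False


def trough_to_peak_ms(waveform: np.ndarray, fs: float = 25_000.0) -> float:
    """Latency from the global trough to the later maximum, in ms.

    Ties on the trough value break toward the earliest sample; the peak is
    the global maximum strictly after the trough.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 2:
        raise ValidationError("waveform too short")
    trough = int(np.argmin(w))           # argmin takes the earliest tie
    if trough == w.size - 1:
        raise ValidationError("trough at the last sample: no post-trough peak")
    peak = trough + 1 + int(np.argmax(w[trough + 1:]))
    return (peak - trough) / fs * 1000.0


def classify_unit(latency_ms: float) -> str:
    """FS below 0.4 ms trough-to-peak, RS above (boundary goes to RS)."""
    if latency_ms < 0:
        raise ValidationError("negative trough-to-peak latency")
    if latency_ms < FS_THRESHOLD_MS:
        return "FS"
    if latency_ms == FS_THRESHOLD_MS:
        logger.warning("trough-to-peak exactly %.1f ms: boundary case assigned RS",
                       FS_THRESHOLD_MS)
    return "RS"


def compute_psth(unit: SortedUnit, schedule: StimulusSchedule, condition: str,
                 t_trial_ms: float = 500.0, bin_ms: float = 1.0) -> Psth:
    """Per-bin firing rate: spike counts summed over trials / (n_trials * bin)."""
    events = schedule.events_for(condition)
    if events.size == 0:
        raise ValidationError(f"no trials for condition {condition!r}")
    n_bins = int(round(t_trial_ms / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms / 1000.0
    counts = np.zeros(n_bins)
    for ev in events:
        rel = unit.spike_times_s[
            np.searchsorted(unit.spike_times_s, ev):
            np.searchsorted(unit.spike_times_s, ev + t_trial_ms / 1000.0)
        ] - ev
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (events.size * bin_ms / 1000.0)
    return Psth(rate, bin_ms, int(events.size), condition, unit.unit_id)


def window_rates(psth: Psth,
                 early_ms: tuple[float, float] = EARLY_WINDOW_MS,
                 late_ms: tuple[float, float] = LATE_WINDOW_MS) -> WindowStats:
    """Mean PSTH rate over the half-open early and late windows."""
    t = psth.time_ms
    if t[-1] + psth.bin_ms < late_ms[1]:
        raise ValidationError("PSTH does not cover the late window")
    vals = []
    for lo, hi in (early_ms, late_ms):
        m = (t >= lo) & (t < hi)
        if not m.any():
            raise ValidationError(f"empty window {lo}-{hi} ms")
        vals.append(float(psth.rate_hz[m].mean()))
    return WindowStats(vals[0], vals[1], psth.condition, psth.unit_id)


def zscore_unit(unit: SortedUnit, schedule: StimulusSchedule, duration_s: float | None = None,
                bin_ms: float = 1.0, smooth_fwhm_ms: float = 10.0) -> UnitZScore:
    """Z-score the unit's binned, smoothed rate against interblock firing.

    Units silent during every interblock interval have an undefined
    baseline; they are flagged ``excluded`` (and skipped from z-scored
    aggregates) rather than given an arbitrary score.
    """
    duration_s = duration_s or (schedule.end_s + 1.0)
    fs = 1000.0 / bin_ms
    n = int(round(duration_s * fs))
    counts = np.histogram(unit.spike_times_s, bins=np.arange(n + 1) / fs)[0]
    rate = gaussian_smooth(counts.astype(float) * fs, fs, smooth_fwhm_ms)
    mask = schedule.interblock_mask(n, fs)
    if mask.sum() < 2:
        raise ValidationError("need at least 2 interblock bins")
    mu = float(rate[mask].mean())
    sd = float(rate[mask].std())
    if counts[mask].sum() == 0 or sd == 0:
        logger.warning("unit %s silent in interblock intervals: excluded from z-scores",
                       unit.unit_id)
        return UnitZScore(None, fs, mu, sd, excluded=True)
    return UnitZScore((rate - mu) / sd, fs, mu, sd)


def assign_unit_layer(depth_um: float, alignment: LaminarAlignment | None = None) -> str:
    """Layer label for a unit depth signed relative to the L4 sink."""
    return layer_of_depth(depth_um)
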