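"""Synthetic laminar recordings, spike trains and calcium traces.

The generator emulates the structure of a dichoptic phase-reversal
experiment in mouse binocular V1: four stimulus conditions (monocular,
concordant, phase-offset, orthogonal) presented in interleaved blocks with
gray interblock intervals, a laminar probe spanning the cortical depth with
an L4 current sink and a superficial source, and condition-dependent early
(40-80 ms) and late (100-200 ms) response gains.

The LFP forward model prescribes a current-source-density profile (sink
negative, balanced source a few channels above) and integrates it twice
along depth, so the CSD analysis stage has an exact inverse target.  Spikes
are inhomogeneous Poisson with rate

    rate(t) = base * (1 + g_E(c) * k_E(t) + g_L(c) * k_L(t))

where k_E is supported on 40-80 ms and k_L on 100-200 ms post-reversal.
Calcium fluorescence convolves spike counts with an exponential indicator
kernel and adds a shared neuropil signal plus shot noise.

A single seed fans out to independent child streams (schedule, lfp, spikes,
calcium) so each data modality is reproducible on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import scipy.ndimage
import scipy.signal

from .io_core import (
    Block,
    RecordingSession,
    RoiTraceSet,
    SortedUnit,
    StimulusSchedule,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SessionParams",
    "UnitParams",
    "CalciumParams",
    "GroundTruth",
    "generate_session",
    "generate_schedule",
    "generate_units",
    "generate_calcium",
    "generate_calcium_session",
    "spike_band_trace",
    "early_kernel",
    "late_kernel",
    "lfp_trial_kernel",
    "make_template",
    "CALCIUM_PRESETS",
]

# Condition gains encoding the observed effect pattern: concordant raises the
# early peak, phase offset reduces it, orthogonal adds a late plateau (and a
# modest early increase).
DEFAULT_EARLY_GAIN = {
    "monocular": 1.0,
    "concordant": 1.5,
    "phase_offset": 0.5,
    "orthogonal": 1.25,
}
DEFAULT_LATE_GAIN = {
    "monocular": 0.15,
    "concordant": 0.15,
    "phase_offset": 0.15,
    "orthogonal": 0.9,
}

# Per-condition in-block rate multipliers for the calcium experiments:
# excitatory (Emx1+) populations respond more to orthogonal than monocular,
# SOM+ interneurons respond less (the SOM sessions used three conditions).
CALCIUM_PRESETS = {
    "excitatory": {"monocular": 1.0, "concordant": 1.3, "phase_offset": 0.9, "orthogonal": 1.6},
    "som": {"monocular": 1.0, "concordant": 1.2, "orthogonal": 0.45},
}


@dataclass
class SessionParams:
    """Laminar-session geometry, stimulus structure and effect sizes.

    Defaults follow the acute laminar experiment: a 64-channel probe at
    20 um spacing sampled at 25 kHz, 100 s condition blocks with 30 s
    interblock intervals, 5 blocks per condition, and 1 phase reversal per
    second (500 trials per condition).
    """

    n_channels: int = 64
    spacing_um: float = 20.0
    fs: float = 25_000.0
    conditions: tuple[str, ...] = ("monocular", "concordant", "phase_offset", "orthogonal")
    n_blocks_per_condition: int = 5
    block_s: float = 100.0
    interblock_s: float = 30.0
    reversal_rate_hz: float = 1.0
    sink_channel: int = 32
    source_offset: int = 4          # source this many channels above the sink
    sink_sigma_ch: float = 1.2
    evoked_amplitude_v: float = 150e-6   # sink-channel VEP negativity scale
    early_gain: dict = field(default_factory=lambda: dict(DEFAULT_EARLY_GAIN))
    late_gain: dict = field(default_factory=lambda: dict(DEFAULT_LATE_GAIN))
    pink_noise_v: float = 50e-6     # RMS of 1/f background per channel
    line_noise_v: float = 20e-6     # 60 Hz amplitude, common across channels
    volts_per_count: float = 0.195e-6

    def __post_init__(self) -> None:
        if self.n_channels < 5:
            raise ValidationError("CSD kernel needs at least 5 channels")
        for c in self.conditions:
            if self.early_gain.get(c, 0.0) < 0 or self.late_gain.get(c, 0.0) < 0:
                raise ValidationError("condition gains must be non-negative")
        if not (0 < self.source_offset <= self.sink_channel):
            raise ValidationError("source must sit above the sink, on the probe")
        if self.sink_channel >= self.n_channels - 1:
            raise ValidationError("sink channel must be an interior channel")


@dataclass
class UnitParams:
    n_units: int = 24
    fs_fraction: float = 0.16       # FS/(RS+FS) observed ratio ~52/327
    base_rate_range: tuple[float, float] = (2.0, 10.0)
    depth_range_um: tuple[float, float] = (-460.0, 300.0)
    template_amplitude_mv: float = 0.08
    rs_ttp_range_ms: tuple[float, float] = (0.5, 0.8)
    fs_ttp_range_ms: tuple[float, float] = (0.2, 0.3)
    interblock_rate_factor: float = 1.0  # base-rate multiplier during gray


@dataclass
class CalciumParams:
    frame_rate: float = 14.9
    kernel_amplitude: float = 2.0   # fluorescence units per spike
    tau_s: float = 0.6              # GCaMP6f-like decay
    baseline_f: float = 100.0
    neuropil_alpha: float = 0.7     # mixing of neuropil into the ROI pixels
    neuropil_baseline_f: float = 60.0
    neuropil_pop_fraction: float = 0.3
    shot_noise_f: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValidationError("calcium decay tau must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    seed: int
    sink_channel_index: int
    source_channel_index: int
    evoked_amplitude_v: dict
    early_gain: dict
    late_gain: dict
    pink_noise_v: float = 0.0
    line_noise_v: float = 0.0
    unit_table: list = field(default_factory=list)
    calcium_amplitude: float = 0.0
    calcium_tau_s: float = 0.0
    neuropil_alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.sink_channel_index <= self.source_channel_index:
            raise ValidationError("sink must be deeper than source")
        for g in (*self.early_gain.values(), *self.late_gain.values()):
            if g < 0:
                raise ValidationError("gains must be non-negative")


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ("schedule", "lfp", "spikes", "calcium")
    return {n: np.random.Generator(np.random.PCG64(c)) for n, c in zip(names, ss.spawn(4))}


# ---------------------------------------------------------------------------
# temporal kernels


def early_kernel(t_s: np.ndarray) -> np.ndarray:
    """Unit-peak raised cosine supported on 40-80 ms post-reversal."""
    t = np.asarray(t_s, dtype=float)
    k = np.zeros_like(t)
    m = (t >= 0.040) & (t <= 0.080)
    k[m] = 0.5 * (1 - np.cos(2 * np.pi * (t[m] - 0.040) / 0.040))
    return k


def late_kernel(t_s: np.ndarray) -> np.ndarray:
    """Unit-peak Tukey plateau supported on 100-200 ms post-reversal."""
    t = np.asarray(t_s, dtype=float)
    k = np.zeros_like(t)
    ramp = 0.025
    m = (t >= 0.100) & (t <= 0.200)
    x = t[m]
    k[m] = 1.0
    up = x < 0.100 + ramp
    k[m] = np.where(up, 0.5 * (1 - np.cos(np.pi * (x - 0.100) / ramp)), k[m])
    dn = x > 0.200 - ramp
    k[m] = np.where(dn, 0.5 * (1 - np.cos(np.pi * (0.200 - x) / ramp)), k[m])
    return k


def lfp_trial_kernel(t_s: np.ndarray, g_early: float, g_late: float) -> np.ndarray:
    """Evoked CSD time course: difference of Gaussians peaking ~65 ms (the
    negative lobe yields the later VEP positivity) plus a late plateau."""
    t = np.asarray(t_s, dtype=float)
    dog = (np.exp(-0.5 * ((t - 0.065) / 0.015) ** 2)
           - 0.45 * np.exp(-0.5 * ((t - 0.115) / 0.025) ** 2))
    return g_early * dog + g_late * late_kernel(t)


# ---------------------------------------------------------------------------
# schedule


def generate_schedule(params: SessionParams, rng: np.random.Generator) -> StimulusSchedule:
    """Pseudorandomly interleaved condition blocks with regular reversals."""
    order = np.concatenate([
        rng.permutation(len(params.conditions))
        for _ in range(params.n_blocks_per_condition)
    ])
    blocks, events = [], []
    t = params.interblock_s  # lead-in gray period
    for ci in order:
        cond = params.conditions[ci]
        blocks.append(Block(cond, t, t + params.block_s))
        ev = t + np.arange(0.0, params.block_s - 1e-9, 1.0 / params.reversal_rate_hz)
        events.append(ev)
        t += params.block_s + params.interblock_s
    sched = StimulusSchedule(blocks, events)
    # lead-in gray counts as baseline too
    sched.interblock_intervals = [(0.0, blocks[0].start_s)] + sched.interblock_intervals
    return sched


# ---------------------------------------------------------------------------
# LFP forward model


def _spatial_csd_profile(params: SessionParams) -> np.ndarray:
    """Balanced sink/source dipole along the probe (sink negative)."""
    i = np.arange(params.n_channels, dtype=float)
    s, o, sig = params.sink_channel, params.source_offset, params.sink_sigma_ch
    prof = -np.exp(-0.5 * ((i - s) / sig) ** 2) + np.exp(-0.5 * ((i - (s - o)) / sig) ** 2)
    return prof


def _integrate_csd(profile: np.ndarray, h_um: float) -> np.ndarray:
    """Solve -(phi[i-1] - 2 phi[i] + phi[i+1]) / h^2 = C[i] with grounded ends.

    This discrete double integration is the exact inverse of the central
    second difference the CSD stage applies, so a noise-free session maps
    back onto the prescribed profile.
    """
    n = len(profile)
    ab = np.zeros((3, n - 2))
    ab[0, 1:] = -1.0
    ab[1, :] = 2.0
    ab[2, :-1] = -1.0
    phi = np.zeros(n)
    phi[1:-1] = scipy.linalg.solve_banded((1, 1), ab, profile[1:-1] * h_um ** 2)
    return phi


def _pink_noise(shape: tuple[int, int], fs: float, rms: float,
                rng: np.random.Generator, spatial_sigma_ch: float = 4.0,
                independent_fraction: float = 0.1) -> np.ndarray:
    """1/f-amplitude Gaussian background noise, flattened below 1 Hz.

    Volume conduction makes LFP background coherent across neighboring
    20 um sites, so the dominant component is smoothed along the channel
    axis (Gaussian, ``spatial_sigma_ch`` channels); a small independent
    per-channel component models electrode/thermal noise.
    """
    n = shape[1]
    spec = np.fft.rfft(rng.standard_normal(shape), axis=1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec *= 1.0 / np.sqrt(np.maximum(f, 1.0))
    x = np.fft.irfft(spec, n=n, axis=1)
    x /= np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    if shape[0] > 1 and spatial_sigma_ch > 0:
        coh = scipy.ndimage.gaussian_filter1d(x, spatial_sigma_ch, axis=0, mode="nearest")
        coh /= np.sqrt(np.mean(coh ** 2, axis=1, keepdims=True))
        ind = rng.standard_normal(shape)
        spec_i = np.fft.rfft(ind, axis=1)
        spec_i *= 1.0 / np.sqrt(np.maximum(f, 1.0))
        ind = np.fft.irfft(spec_i, n=n, axis=1)
        ind /= np.sqrt(np.mean(ind ** 2, axis=1, keepdims=True))
        x = np.sqrt(1 - independent_fraction) * coh + np.sqrt(independent_fraction) * ind
    return rms * x


def generate_session(params: SessionParams | None = None, seed: int = 0
                     ) -> tuple[RecordingSession, StimulusSchedule, GroundTruth]:
    """Generate a laminar recording, its stimulus schedule and ground truth."""
    params = params or SessionParams()
    rngs = _child_rngs(seed)
    schedule = generate_schedule(params, rngs["schedule"])

    n_samp = int(round(schedule.end_s * params.fs)) + int(round(params.interblock_s * params.fs))
    lfp = np.zeros((params.n_channels, n_samp))

    profile = _spatial_csd_profile(params)
    phi = _integrate_csd(profile, params.spacing_um)
    # sink-channel deflection = -A exactly (the ground-truth VEP negativity)
    phi = phi / np.abs(phi[params.sink_channel]) * params.evoked_amplitude_v

    t_kernel = np.arange(0.0, 0.35, 1.0 / params.fs)
    evoked_amp = {}
    for cond in params.conditions:
        gE = params.early_gain.get(cond, 0.0)
        gL = params.late_gain.get(cond, 0.0)
        kern = lfp_trial_kernel(t_kernel, gE, gL)
        evoked_amp[cond] = params.evoked_amplitude_v * (kern.max() if kern.size else 0.0)
        trial = np.outer(phi, kern)
        for ev in schedule.events_for(cond):
            i0 = int(round(ev * params.fs))
            i1 = min(i0 + kern.size, n_samp)
            lfp[:, i0:i1] += trial[:, : i1 - i0]

    if params.pink_noise_v > 0:
        lfp += _pink_noise(lfp.shape, params.fs, params.pink_noise_v, rngs["lfp"])
    if params.line_noise_v > 0:
        t = np.arange(n_samp) / params.fs
        lfp += params.line_noise_v * np.sin(
            2 * np.pi * 60.0 * t + rngs["lfp"].uniform(0, 2 * np.pi))

    # quantize onto the acquisition grid so disk round trips are bit exact
    lfp = np.round(lfp / params.volts_per_count) * params.volts_per_count

    depths = np.arange(params.n_channels) * params.spacing_um
    session = RecordingSession(lfp, params.fs, depths, params.volts_per_count,
                               session_id=f"synth-{seed}")
    truth = GroundTruth(
        seed=seed,
        sink_channel_index=params.sink_channel,
        source_channel_index=params.sink_channel - params.source_offset,
        evoked_amplitude_v=evoked_amp,
        early_gain=dict(params.early_gain),
        late_gain=dict(params.late_gain),
        pink_noise_v=params.pink_noise_v,
        line_noise_v=params.line_noise_v,
    )
    return session, schedule, truth


# ---------------------------------------------------------------------------
# spiking


def make_template(trough_to_peak_ms: float, fs: float = 25_000.0,
                  amplitude_mv: float = 0.08, duration_ms: float = 3.0) -> np.ndarray:
    """Biphasic template with an exact on-grid trough-to-peak separation."""
    n = int(round(duration_ms * fs / 1000.0))
    t_ms = np.arange(n) / fs * 1000.0
    t0 = 0.8
    ttp = round(trough_to_peak_ms * fs / 1000.0) / fs * 1000.0
    w = (-np.exp(-0.5 * ((t_ms - t0) / 0.06) ** 2)
         + 0.5 * np.exp(-0.5 * ((t_ms - t0 - ttp) / 0.09) ** 2))
    return amplitude_mv * w


def _sample_inhomogeneous(rate_profile: np.ndarray, dt: float, event_times: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Poisson spike times for one rate profile repeated at each event time."""
    lam = float(rate_profile.sum() * dt)
    if lam <= 0 or event_times.size == 0:
        return np.empty(0)
    counts = rng.poisson(lam, size=event_times.size)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    cdf = np.cumsum(rate_profile) * dt / lam
    grid = (np.arange(rate_profile.size) + 1) * dt
    offsets = np.interp(rng.uniform(size=total), cdf, grid)
    return np.repeat(event_times, counts) + offsets


def generate_units(params: UnitParams | None = None,
                   schedule: StimulusSchedule | None = None,
                   truth: GroundTruth | None = None,
                   seed: int = 0) -> tuple[list[SortedUnit], GroundTruth]:
    """Inhomogeneous-Poisson units with RS/FS templates and known depths.

    Rates follow base * (1 + g_E(c) k_E(t) + g_L(c) k_L(t)) inside blocks
    (per reversal) and the interblock base rate during gray periods.  The
    returned ground truth carries the per-unit table (class, depth, rate).
    """
    params = params or UnitParams()
    if schedule is None or truth is None:
        raise ValidationError("generate_units needs a schedule and ground truth")
    rng = _child_rngs(truth.seed if seed == 0 else seed)["spikes"]

    n_fs = int(round(params.n_units * params.fs_fraction))
    classes = ["FS"] * n_fs + ["RS"] * (params.n_units - n_fs)
    rng.shuffle(classes)

    dt = 1e-3
    # one rate profile per condition per unit scale; period = inter-reversal gap
    periods = {}
    for bi, b in enumerate(schedule.blocks):
        ev = schedule.reversal_events[bi]
        if ev.size >= 2:
            periods[b.condition] = float(np.median(np.diff(ev)))
        else:
            periods.setdefault(b.condition, b.duration_s)

    units: list[SortedUnit] = []
    table = []
    for k in range(params.n_units):
        cls = classes[k]
        base = rng.uniform(*params.base_rate_range)
        depth = rng.uniform(*params.depth_range_um)
        ttp = rng.uniform(*(params.fs_ttp_range_ms if cls == "FS" else params.rs_ttp_range_ms))
        spikes = []
        for cond in schedule.conditions:
            grid = np.arange(0.0, periods.get(cond, 0.5), dt)
            rate = base * (1.0
                           + truth.early_gain.get(cond, 0.0) * early_kernel(grid)
                           + truth.late_gain.get(cond, 0.0) * late_kernel(grid))
            if np.any(rate < 0):
                logger.warning("unit %d: negative rate clipped to 0", k)
                rate = np.clip(rate, 0.0, None)
            spikes.append(_sample_inhomogeneous(rate, dt, schedule.events_for(cond), rng))
        ib_rate = base * params.interblock_rate_factor
        for s, e in schedule.interblock_intervals:
            n = rng.poisson(ib_rate * (e - s))
            spikes.append(s + rng.uniform(0, e - s, size=n))
        times = np.sort(np.concatenate(spikes))
        units.append(SortedUnit(
            unit_id=f"u{k:03d}", spike_times_s=times,
            waveform_mv=make_template(ttp, amplitude_mv=params.template_amplitude_mv),
            depth_um=depth, cls=None,
        ))
        table.append({"unit_id": f"u{k:03d}", "true_cls": cls, "true_ttp_ms": ttp,
                      "depth_um": depth, "base_rate_hz": base})
    truth = replace(truth, unit_table=table)
    return units, truth


def spike_band_trace(units: list[SortedUnit], duration_s: float,
                     n_channels: int = 8, fs: float = 25_000.0,
                     noise_rms_v: float = 8e-6, seed: int = 0,
                     depth_range_um: tuple[float, float] = (-460.0, 300.0)
                     ) -> RecordingSession:
    """Insert scaled unit templates into a noisy wide-band trace.

    Each unit lands on the channel nearest its depth; used to exercise the
    multiunit-envelope chain against known insertion rates.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    n = int(round(duration_s * fs))
    x = rng.standard_normal((n_channels, n)) * noise_rms_v
    ch_depths = np.linspace(depth_range_um[1], depth_range_um[0], n_channels)
    for u in units:
        ch = int(np.argmin(np.abs(ch_depths - u.depth_um)))
        w = u.waveform_mv * 1e-3  # mV -> V
        for t in u.spike_times_s:
            i0 = int(round(t * fs))
            if i0 + w.size > n:
                continue
            x[ch, i0:i0 + w.size] += w
    depths = np.arange(n_channels) * 20.0
    return RecordingSession(x, fs, depths, 0.195e-6, session_id=f"spikeband-{seed}")


# ---------------------------------------------------------------------------
# calcium


def generate_calcium(units: list[SortedUnit], params: CalciumParams | None = None,
                     schedule: StimulusSchedule | None = None, seed: int = 0
                     ) -> tuple[RoiTraceSet, GroundTruth]:
    """Convolve unit spike trains with an indicator kernel; add neuropil.

    F_true = baseline + amp * (spikes (*) exp(-t/tau)); the neuropil trace is
    a shared slow background plus a fraction of the mean population signal;
    the measured ROI trace is F_true + alpha * F_neuropil + shot noise.
    """
    params = params or CalciumParams()
    if schedule is None:
        raise ValidationError("generate_calcium needs the stimulus schedule")
    rng = _child_rngs(seed)["calcium"]
    dt = 1.0 / params.frame_rate
    n_frames = int(np.ceil(schedule.end_s * params.frame_rate)) + 1
    edges = np.arange(n_frames + 1) * dt

    decay = np.exp(-dt / params.tau_s)
    f_true = np.empty((len(units), n_frames))
    for r, u in enumerate(units):
        counts, _ = np.histogram(u.spike_times_s, bins=edges)
        f_true[r] = params.baseline_f + scipy.signal.lfilter(
            [params.kernel_amplitude], [1.0, -decay], counts.astype(float))

    t = np.arange(n_frames) * dt
    background = params.neuropil_baseline_f * (
        1.0 + 0.10 * np.sin(2 * np.pi * 0.03 * t + rng.uniform(0, 2 * np.pi)))
    pop = (f_true - params.baseline_f).mean(axis=0)
    f_np = background + params.neuropil_pop_fraction * pop
    f_roi = (f_true + params.neuropil_alpha * f_np
             + params.shot_noise_f * rng.standard_normal(f_true.shape)
             * np.sqrt(np.maximum(f_true, 0.0) / params.baseline_f))

    traces = RoiTraceSet(f_roi, np.tile(f_np, (len(units), 1)), params.frame_rate,
                         schedule, roi_ids=[u.unit_id for u in units])
    truth = GroundTruth(
        seed=seed, sink_channel_index=1, source_channel_index=0,
        evoked_amplitude_v={}, early_gain={}, late_gain={},
        calcium_amplitude=params.kernel_amplitude, calcium_tau_s=params.tau_s,
        neuropil_alpha=params.neuropil_alpha,
    )
    return traces, truth


def generate_calcium_session(preset: str = "excitatory", n_rois: int = 120,
                             n_blocks_per_condition: int = 24,
                             block_s: float = 10.0, interblock_s: float = 10.0,
                             base_rate_hz: float = 4.0,
                             params: CalciumParams | None = None, seed: int = 0
                             ) -> tuple[RoiTraceSet, StimulusSchedule, dict]:
    """A complete imaging session under a named response preset.

    Presets encode the observed condition orderings: 'excitatory' L2/3
    pyramidal cells respond more to orthogonal than monocular gratings;
    'som' (SOM+ interneurons, three conditions) respond less.  Block
    structure defaults to the imaging protocol: 10 s blocks, 10 s gray.
    """
    if preset not in CALCIUM_PRESETS:
        raise ValidationError(f"unknown calcium preset {preset!r}")
    mult = CALCIUM_PRESETS[preset]
    params = params or CalciumParams()
    rngs = _child_rngs(seed)
    sp = SessionParams(conditions=tuple(mult), n_blocks_per_condition=n_blocks_per_condition,
                       block_s=block_s, interblock_s=interblock_s)
    schedule = generate_schedule(sp, rngs["schedule"])

    rng = rngs["spikes"]
    units = []
    for r in range(n_rois):
        base = rng.gamma(4.0, base_rate_hz / 4.0)
        spikes = []
        for b, ev in zip(schedule.blocks, schedule.reversal_events):
            rate = base * mult[b.condition]
            n = rng.poisson(rate * b.duration_s)
            spikes.append(b.start_s + rng.uniform(0, b.duration_s, size=n))
        for s, e in schedule.interblock_intervals:
            n = rng.poisson(0.3 * base * (e - s))
            spikes.append(s + rng.uniform(0, e - s, size=n))
        units.append(SortedUnit(f"roi{r:04d}", np.sort(np.concatenate(spikes)),
                                make_template(0.6)))
    traces, _ = generate_calcium(units, params, schedule, seed=seed)
    return traces, schedule, {"preset": preset, "multipliers": dict(mult), "seed": seed}
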