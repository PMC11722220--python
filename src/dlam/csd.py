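"""Current-source-density analysis and laminar alignment.

CSD is estimated from trial-averaged laminar LFP as the negative central
second spatial difference of the depth profile, after a 20 ms (FWHM)
Gaussian temporal smoothing and a 5-point Hamming spatial smoothing.
Sinks (inward current) are negative.  The composite spatial stencil
(Hamming * second difference) is 7 channels wide, so the map covers the
interior channels only (3 dropped per probe end); no extrapolation is done.

The L4 reference is the earliest, deepest sink lying below a superficial
source; depths are then signed relative to that channel (positive =
superficial) and layer labels follow the fixed depth table
L2/3 [+60, +300) / L4 [-80, +60) / L5 [-260, -80) / L6 [-460, -260).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import ValidationError
from .vep import gaussian_smooth

__all__ = [
    "CsdMap",
    "LaminarAlignment",
    "NoSinkError",
    "compute_csd",
    "find_l4_sink",
    "assign_layers",
    "layer_of_depth",
    "LAYER_TABLE",
    "HAMMING5",
]

# Standard length-5 Hamming window, normalized to unit sum when applied.
HAMMING5 = np.array([0.08, 0.54, 1.00, 0.54, 0.08])

# (label, deep boundary um, superficial boundary um); half-open, upper
# (more superficial) bound exclusive.
LAYER_TABLE = (
    ("L2/3", 60.0, 300.0),
    ("L4", -80.0, 60.0),
    ("L5", -260.0, -80.0),
    ("L6", -460.0, -260.0),
)


class NoSinkError(ValidationError):
    """No channel crossed the sink threshold (poor signal or wrong window)."""


@dataclass
class CsdMap:
    """CSD over interior channels x time; units proportional to V/um^2."""

    values: np.ndarray
    fs: float
    h_um: float
    channel_offset: int  # interior channel i maps to input channel i + offset

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) / self.fs * 1000.0

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class LaminarAlignment:
    l4_channel_index: int
    depths_um: np.ndarray     # signed, 0 at the L4 sink, positive superficial
    layers: list[str]
    h_um: float

    def depth_of(self, channel: int) -> float:
        return float(self.depths_um[channel])


def compute_csd(avg_lfp: np.ndarray, h_um: float, fs: float = 1000.0,
                temporal_fwhm_ms: float = 20.0) -> CsdMap:
    """Hamming-smoothed second-spatial-difference CSD of a channels x time array.

    Channel spacing must be uniform (``h_um``).  The second difference is
    scaled by 1/h^2 and negated so sinks come out negative.
    """
    phi = np.atleast_2d(np.asarray(avg_lfp, dtype=float))
    if phi.shape[0] < 5:
        raise ValidationError("CSD needs at least 5 channels")
    if h_um <= 0:
        raise ValidationError("channel spacing must be positive")
    if temporal_fwhm_ms > 0:
        phi = gaussian_smooth(phi, fs, temporal_fwhm_ms)
    w = HAMMING5 / HAMMING5.sum()
    # spatial smoothing, valid region only: channels 2..n-3
    sm = sum(w[j] * phi[j: phi.shape[0] - 4 + j] for j in range(5))
    csd = -(sm[:-2] - 2.0 * sm[1:-1] + sm[2:]) / h_um ** 2
    return CsdMap(csd, fs, h_um, channel_offset=3)


def find_l4_sink(csd: CsdMap,
                 baseline_window_ms: tuple[float, float] = (0.0, 20.0),
                 search_window_ms: tuple[float, float] = (20.0, 120.0),
                 k_sd: float = 2.0, rel_floor: float = 0.1,
                 tie_window_ms: float = 20.0) -> int:
    """Locate the L4 sink channel: earliest significant sink below a source.

    Per channel, a baseline mean and SD define a crossing threshold at
    mean - k*SD (sink) and mean + k*SD (source).  A crossing must also
    exceed ``rel_floor`` times the map's peak magnitude in the search
    window, so near-noise-free maps do not flag quantization ripple as
    significant.  Candidates are channels with a sink crossing inside the
    search window that lie deeper than some channel with a source crossing.
    Crossing times closer than ``tie_window_ms`` (the temporal smoothing
    width, below which latencies are not resolvable) count as simultaneous;
    the earliest crossing group wins and within it the deepest (most
    negative) trough, exact ties going to the deeper channel.  Returns the
    channel index in input-channel numbering.
    """
    t = csd.time_ms
    bmask = (t >= baseline_window_ms[0]) & (t < baseline_window_ms[1])
    smask = (t >= search_window_ms[0]) & (t < search_window_ms[1])
    if not bmask.any() or not smask.any():
        raise ValidationError("baseline/search windows outside the time axis")
    base = csd.values[:, bmask]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, keepdims=True)
    seg = csd.values[:, smask]
    floor = rel_floor * np.abs(seg).max()
    sink_cross = seg < (mu - k_sd * sd - floor)
    source_cross = seg > (mu + k_sd * sd + floor)

    source_channels = np.flatnonzero(source_cross.any(axis=1))
    first = np.where(sink_cross.any(axis=1), sink_cross.argmax(axis=1), np.iinfo(np.int64).max)
    candidates = [ch for ch in range(csd.n_channels)
                  if first[ch] != np.iinfo(np.int64).max
                  and np.any(source_channels < ch)]  # needs a source above
    if not candidates:
        raise NoSinkError("no significant sink below a superficial source")
    # Crossings within one temporal-smoothing width of the earliest are not
    # temporally resolvable; among those, the deepest (most negative) trough
    # identifies the dominant sink, spatial depth breaking exact ties.
    tie_samples = int(round(tie_window_ms / 1000.0 * csd.fs))
    earliest = min(first[ch] for ch in candidates)
    pool = [ch for ch in candidates if first[ch] <= earliest + tie_samples]
    troughs = seg.min(axis=1)
    return max(pool, key=lambda ch: (-troughs[ch], ch)) + csd.channel_offset


def layer_of_depth(depth_um: float) -> str:
    """Label a signed depth (0 = L4 sink, positive superficial)."""
    for label, deep, sup in LAYER_TABLE:
        if deep <= depth_um < sup:
            return label
    return "out"


def assign_layers(l4_channel_index: int, n_channels: int, h_um: float) -> LaminarAlignment:
    """Signed depths and layer labels for every channel on the probe.

    Channel indices increase with probe depth, so channel i sits at
    (l4_index - i) * h um relative to the sink (positive = superficial).
    """
    i = np.arange(n_channels)
    depths = (l4_channel_index - i) * h_um
    layers = [layer_of_depth(d) for d in depths]
    return LaminarAlignment(l4_channel_index, depths.astype(float), layers, h_um)
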