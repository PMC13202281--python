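"""Core containers shared across the package.

All time series use seconds and a uniform sampling rate; voltages are in
arbitrary units (a.u.) throughout, since every analysis here is either
normalized (coherence, bicoherence, modulation depth) or scale-free up to an
intercept (spectral slope).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np


class DegenerateSignalError(ValueError):
    """Raised when a requested construction annihilates its own signal
    (e.g. a smoothing kernel so wide the theta fundamental vanishes)."""


@dataclass
class LfpChannel:
    """Uniformly sampled voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage samples, a.u.
    fs : float
        Sampling rate, Hz.
    label : str
        Channel label.
    t0 : float
        Time of the first sample, seconds.
    """

    samples: np.ndarray
    fs: float
    label: str = "lfp"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("LfpChannel needs a 1-D trace of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LfpChannel samples must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def copy_with(self, **kw) -> "LfpChannel":
        return replace(self, **kw)


@dataclass
class SpikeTrain:
    """Spike times for one unit, seconds, strictly increasing."""

    unit_id: str
    times: np.ndarray
    region: str = "CA1"
    cell_type: Literal["pyramidal", "interneuron"] = "pyramidal"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"unit {self.unit_id}: spike times must be "
                             "strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def mean_rate(self, duration: float) -> float:
        return self.n_spikes / duration if duration > 0 else np.nan

    def isis(self) -> np.ndarray:
        """Inter-spike intervals, seconds."""
        return np.diff(self.times)


@dataclass
class SpikeTrainSet:
    """Collection of units recorded over a common interval [t0, t0+duration]."""

    units: list[SpikeTrain]
    duration: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        hi = self.t0 + self.duration
        for u in self.units:
            if u.times.size and (u.times[0] < self.t0 or u.times[-1] > hi):
                raise ValueError(f"unit {u.unit_id}: spikes outside recording")

    def __iter__(self):
        return iter(self.units)

    def __len__(self) -> int:
        return len(self.units)

    def rates(self) -> np.ndarray:
        return np.array([u.mean_rate(self.duration) for u in self.units])


@dataclass
class SpeedTrace:
    """Locomotor speed, cm/s >= 0, sampled at fs_speed."""

    t: np.ndarray
    v: np.ndarray
    fs_speed: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise ValueError("speed trace t and v must have equal length")
        if np.any(self.v < 0):
            raise ValueError("speed must be non-negative")

    def at(self, times: np.ndarray) -> np.ndarray:
        """Speed linearly interpolated at arbitrary times."""
        return np.interp(times, self.t, self.v)


@dataclass
class SimConfig:
    """Parameters of the synthetic LFP/spike generator.

    The defaults are the declared study conditions of the two-region toy
    model: 8 Hz theta with moderate waveform asymmetry, a 65 Hz gamma
    generator emitting one theta-locked burst per cycle (timing jitter SD
    3 ms, log-normal amplitude CV 0.5), on a 1/f^2 background.

    drive is a dimensionless behavioral-drive scalar (0 = quiescence); the
    gamma carrier is gamma_center + gamma_drive_gain * drive.
    """

    duration: float = 100.0
    fs: float = 1000.0
    seed: int = 0
    theta_freq: float = 8.0
    theta_amp: float = 2.0
    asymmetry: float = 0.5
    kernel_sd: float = 0.012
    noise_alpha: float = 2.0
    noise_amp: float = 1.0
    gamma_center: float = 65.0
    gamma_drive_gain: float = 40.0
    gamma_amp: float = 1.0
    burst_phase: float = np.pi
    burst_jitter_sd: float = 0.003
    burst_amp_cv: float = 0.5
    burst_duty: float = 0.5
    drive: float = 0.0
    max_drive: float = 1.5
    carrier_mode: Literal["theta_locked", "oscillator", "burst_locked"] = \
        "theta_locked"

    def __post_init__(self) -> None:
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must lie in [0, 1]")
        for name in ("theta_amp", "noise_amp", "gamma_amp"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs must be an integer sample count")
        if self.drive < 0:
            raise ValueError("drive must be >= 0")
        f_top = self.gamma_center + 3.0 * self.gamma_drive_gain * self.max_drive
        if self.fs <= 2.0 * f_top:
            raise ValueError(
                f"fs={self.fs} too low for gamma carrier headroom (need > {2 * f_top})")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def theta_period(self) -> float:
        return 1.0 / self.theta_freq


@dataclass
class TwoRegionSim:
    """Two simulated channels sharing one theta clock with a fixed offset.

    Gamma generators are statistically independent across channels by
    construction; only the theta organization is shared.
    """

    ch1: LfpChannel
    ch2: LfpChannel
    theta_offset: float
    shared_theta_phase: np.ndarray
    params: SimConfig

    def __post_init__(self) -> None:
        if self.ch1.n != self.ch2.n or self.ch1.fs != self.ch2.fs:
            raise ValueError("channels must share duration and fs")


@dataclass
class PsdResult:
    """Welch power spectral density with estimator metadata."""

    freqs: np.ndarray
    power: np.ndarray
    seg_len: float
    overlap: float
    taper: str
    n_segments: int

    def band_power(self, lo: float, hi: float) -> float:
        """Integrated power over [lo, hi] Hz (trapezoidal)."""
        m = (self.freqs >= lo) & (self.freqs <= hi)
        if not np.any(m):
            raise ValueError(f"band [{lo}, {hi}] Hz outside resolved range")
        return float(np.trapezoid(self.power[m], self.freqs[m]))


@dataclass
class SlopeFit:
    """Log-log power-law fit S(f) ~ f^-alpha; alpha > 0 means decay."""

    alpha: float
    intercept: float
    fit_band: tuple[float, float]
    excluded_bands: list[tuple[float, float]]
    r2: float
    n_bins: int


@dataclass
class CoherenceResult:
    """Welch magnitude-squared coherence with its small-sample bias floor."""

    freqs: np.ndarray
    msc: np.ndarray
    n_segments: int

    @property
    def bias_floor(self) -> float:
        return 1.0 / self.n_segments

    def band_average(self, lo: float, hi: float) -> float:
        m = (self.freqs >= lo) & (self.freqs <= hi)
        if not np.any(m):
            raise ValueError(f"band [{lo}, {hi}] Hz outside resolved range")
        return float(self.msc[m].mean())


@dataclass
class BicoherenceResult:
    """Normalized bispectrum b^2(f1, f2) on a triangular frequency grid."""

    f1: np.ndarray
    f2: np.ndarray
    b2: np.ndarray  # shape (len(f1), len(f2)); NaN where f1+f2 > Nyquist
    n_segments: int
    surrogate_threshold: float | None = None
    n_surrogates: int = 0

    def at(self, f1: float, f2: float) -> float:
        i = int(np.argmin(np.abs(self.f1 - f1)))
        j = int(np.argmin(np.abs(self.f2 - f2)))
        return float(self.b2[i, j])


@dataclass
class BandPowerTimecourse:
    """Windowed band-integrated power for a set of named bands."""

    centers: np.ndarray
    power: dict[str, np.ndarray]
    bands: dict[str, tuple[float, float]]
    window: float


@dataclass
class SpeedBins:
    """Half-open locomotor-speed bins covering [0, inf) cm/s."""

    edges: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "low": (0.0, 7.0),
        "moderate": (7.0, 20.0),
        "high": (20.0, np.inf),
    })

    def __post_init__(self) -> None:
        ivs = sorted(self.edges.values())
        if ivs[0][0] != 0.0 or not np.isinf(ivs[-1][1]):
            raise ValueError("speed bins must cover [0, inf)")
        for (a, b), (c, _) in zip(ivs, ivs[1:]):
            if b != c:
                raise ValueError("speed bins must be contiguous")

    @property
    def labels(self) -> list[str]:
        return sorted(self.edges, key=lambda k: self.edges[k][0])

    def classify(self, v: np.ndarray) -> np.ndarray:
        """Bin label per speed value; half-open [lo, hi) convention."""
        v = np.atleast_1d(np.asarray(v, dtype=float))
        out = np.empty(v.shape, dtype=object)
        for name, (lo, hi) in self.edges.items():
            out[(v >= lo) & (v < hi)] = name
        return out


@dataclass
class PhaseModSpectrum:
    """Spike-phase modulation strength per frequency for one unit/speed bin.

    modulation is the circular concentration (mean resultant length) of the
    binned spike-phase distribution, in [0, 1].
    """

    freqs: np.ndarray
    modulation: np.ndarray
    n_spikes: np.ndarray
    unit_id: str
    speed_bin: str = "all"
    n_phase_bins: int = 24
    min_spikes: int = 50

    @property
    def low_n(self) -> np.ndarray:
        """True where too few spikes fell in this speed bin for a stable value."""
        return self.n_spikes < self.min_spikes


@dataclass
class IsiReturnMap:
    """2-D histogram of successive ISIs on instantaneous-frequency axes (Hz).

    grid holds the bin edges (len = counts.shape + 1); axes are
    1000/ISI_ms so that a preferred firing timescale appears as a blob at
    the corresponding frequency.
    """

    grid: np.ndarray
    counts: np.ndarray
    unit_id: str = ""
    normalized: bool = False
    weight: float = 1.0
    n_pairs: int = 0

    def normalize(self) -> "IsiReturnMap":
        """Peak-normalize (n / max(n)); no-op on an empty map."""
        peak = self.counts.max()
        c = self.counts / peak if peak > 0 else self.counts.copy()
        return IsiReturnMap(grid=self.grid, counts=c, unit_id=self.unit_id,
                            normalized=True, weight=self.weight,
                            n_pairs=self.n_pairs)

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.grid[:-1] * self.grid[1:])  # log-spaced grid


@dataclass
class Autocorrelogram:
    """Spike-pair lag histogram, symmetric about 0, self-pairs excluded."""

    lags: np.ndarray  # bin centers, seconds
    counts: np.ndarray
    bin_width: float
    n_spikes: int
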