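"""Spike-timing analyses: speed-binned spike-phase modulation spectra,
ISI return maps with capped-weight population averaging, autocorrelograms,
and a 20-50 ms attractor score.

These are the tools that test whether a putative rhythm leaves a footprint
in spike timing. If a 20-50 Hz oscillation organized firing, neurons would
show preferred inter-spike intervals, return-map clustering, or phase
locking in that range; theta-paced bursting units instead show a bimodal
structure — intra-burst ISIs of a few ms (>100 Hz) and inter-burst ISIs
near the theta period (~8 Hz) — with the 20-50 ms range as a mere
transition zone.

Phase convention: phase 0 at the filtered waveform's positive peak
(analytic-signal angle of a cosine is 0 at its peak).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import hilbert

from .datatypes import (
    Autocorrelogram,
    IsiReturnMap,
    LfpChannel,
    PhaseModSpectrum,
    SpeedBins,
    SpeedTrace,
    SpikeTrain,
    SpikeTrainSet,
)

__all__ = [
    "segment_by_speed",
    "fourier_bandpass",
    "instantaneous_phase",
    "spike_phases",
    "circular_concentration",
    "phase_mod_spectrum",
    "population_modulation",
    "default_freq_grid",
    "isi_return_map",
    "default_return_map_grid",
    "population_average_maps",
    "autocorrelogram",
    "attractor_score",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# behavioral-state segmentation


def segment_by_speed(spikes: SpikeTrainSet, speed: SpeedTrace,
                     seg_len: float = 1.0,
                     bins: SpeedBins | None = None) -> dict:
    """Label consecutive ``seg_len``-s segments by mean locomotor speed.

    Returns {"segments": list of (t_start, t_end, label),
    "spike_segments": {unit_id: {label: spike-time array}}}. Segments whose
    speed is undefined (outside the speed trace) are dropped with a log
    entry. Bin edges are half-open [lo, hi), so 7.0 cm/s is "moderate" and
    20.0 cm/s is "high" under the defaults.
    """
    if bins is None:
        bins = SpeedBins()
    t0 = spikes.t0
    n_seg = int(np.floor(spikes.duration / seg_len))
    t_lo, t_hi = speed.t[0], speed.t[-1]
    segments = []
    for i in range(n_seg):
        a, b = t0 + i * seg_len, t0 + (i + 1) * seg_len
        if a < t_lo - 1e-9 or b > t_hi + 1e-9:
            log.info("segment [%.1f, %.1f) dropped: speed undefined", a, b)
            continue
        tt = np.linspace(a, b, max(2, int(seg_len * speed.fs_speed)))
        label = bins.classify(float(speed.at(tt).mean()))[0]
        segments.append((a, b, label))
    spike_segments: dict[str, dict[str, np.ndarray]] = {}
    for u in spikes:
        per_bin: dict[str, list] = {lab: [] for lab in bins.labels}
        for a, b, lab in segments:
            i0, i1 = np.searchsorted(u.times, [a, b])
            per_bin[lab].append(u.times[i0:i1])
        spike_segments[u.unit_id] = {
            lab: (np.concatenate(v) if v else np.empty(0))
            for lab, v in per_bin.items()}
    return {"segments": segments, "spike_segments": spike_segments}


# ---------------------------------------------------------------------------
# spike-phase modulation spectrum


def fourier_bandpass(x: LfpChannel, f: float, rel_halfwidth: float = 0.25,
                     ) -> np.ndarray:
    """Frequency-domain bandpass: Gaussian taper centered at f.

    The taper SD is f * rel_halfwidth / 2, i.e. the +/- f/4 half-width of
    the default corresponds to two SDs. Returns the filtered real signal.
    """
    if f >= x.fs / 2:
        raise ValueError(f"{f} Hz is above Nyquist")
    freqs = np.fft.rfftfreq(x.n, 1.0 / x.fs)
    sd = f * rel_halfwidth / 2.0
    taper = np.exp(-0.5 * ((freqs - f) / sd) ** 2)
    return np.fft.irfft(np.fft.rfft(x.samples) * taper, x.n)


def instantaneous_phase(filtered: np.ndarray) -> np.ndarray:
    """Hilbert-transform phase; 0 at the positive peak of the waveform."""
    return np.angle(hilbert(filtered))


def spike_phases(spike_times: np.ndarray, phase: np.ndarray, fs: float,
                 t0: float = 0.0) -> np.ndarray:
    """Phase at each spike time (nearest-sample lookup)."""
    idx = np.round((np.asarray(spike_times) - t0) * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < phase.size)]
    return phase[idx]


def circular_concentration(phases: np.ndarray, n_bins: int = 24,
                           ) -> float:
    """Mean resultant length of the binned phase distribution, in [0, 1].

    Phases are binned into ``n_bins`` equal bins and the resultant is
    computed over bin centers weighted by the per-bin spike rate, so the
    estimate matches a binned spike-phase histogram rather than raw phases.
    """
    if phases.size == 0:
        return float("nan")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    z = np.sum(counts * np.exp(1j * centers))
    return float(np.abs(z) / counts.sum())


def vonmises_concentration_oracle(kappa: float) -> float:
    """Population mean resultant length of a von Mises distribution,
    I1(kappa)/I0(kappa) — the closed-form target for estimator checks."""
    from scipy.special import i0, i1
    return float(i1(kappa) / i0(kappa))


def default_freq_grid(n: int = 40, lo: float = 2.0, hi: float = 120.0,
                      ) -> np.ndarray:
    """Log-spaced frequency grid for the modulation spectrum."""
    return np.geomspace(lo, hi, n)


def phase_mod_spectrum(spikes: SpikeTrainSet, lfp: LfpChannel,
                       freqs: np.ndarray | None = None,
                       speed: SpeedTrace | None = None,
                       bins: SpeedBins | None = None,
                       n_phase_bins: int = 24, min_spikes: int = 50,
                       rel_halfwidth: float = 0.25,
                       ) -> dict[str, dict[str, PhaseModSpectrum]]:
    """Spike-phase modulation strength across frequencies, per unit and
    speed bin.

    For each frequency on a log-spaced grid the LFP is bandpass filtered
    (Gaussian Fourier filter, bandwidth proportional to frequency), the
    instantaneous phase is taken from the analytic signal, each spike is
    assigned a phase, phases are binned into ``n_phase_bins`` equal bins,
    and the circular concentration (mean resultant length) of the binned
    distribution is the modulation strength. Entries with fewer than
    ``min_spikes`` spikes are still computed but flagged via
    :attr:`PhaseModSpectrum.low_n`.

    When ``speed`` is None a single "all" bin is used.

    Returns {unit_id: {speed_bin_label: PhaseModSpectrum}}.
    """
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be strictly increasing")
    if freqs[-1] >= lfp.fs / 2:
        raise ValueError("frequency grid exceeds Nyquist")
    if speed is not None:
        seg = segment_by_speed(spikes, speed, bins=bins or SpeedBins())
        if not seg["segments"]:
            raise ValueError("no segments with defined speed")
        spike_sets = seg["spike_segments"]
        labels = (bins or SpeedBins()).labels
    else:
        spike_sets = {u.unit_id: {"all": u.times} for u in spikes}
        labels = ["all"]

    # phase arrays are the expensive part: compute once per frequency
    out: dict[str, dict[str, PhaseModSpectrum]] = {
        u.unit_id: {} for u in spikes}
    mod = {(uid, lab): np.empty(freqs.size)
           for uid in spike_sets for lab in labels}
    nsp = {(uid, lab): np.zeros(freqs.size, dtype=int)
           for uid in spike_sets for lab in labels}
    for fi, f in enumerate(freqs):
        ph = instantaneous_phase(fourier_bandpass(lfp, f, rel_halfwidth))
        for uid, per_bin in spike_sets.items():
            for lab in labels:
                times = per_bin.get(lab, np.empty(0))
                phases = spike_phases(times, ph, lfp.fs, lfp.t0)
                mod[(uid, lab)][fi] = circular_concentration(
                    phases, n_phase_bins)
                nsp[(uid, lab)][fi] = phases.size
    for uid in spike_sets:
        for lab in labels:
            out[uid][lab] = PhaseModSpectrum(
                freqs=freqs, modulation=mod[(uid, lab)],
                n_spikes=nsp[(uid, lab)], unit_id=uid, speed_bin=lab,
                n_phase_bins=n_phase_bins, min_spikes=min_spikes)
    return out


def population_modulation(spectra: list[PhaseModSpectrum],
                          method: str = "mean_of_units",
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Average modulation across units (per speed bin / region / cell type).

    method="mean_of_units" (default) averages each unit's modulation curve,
    ignoring low-n entries; method="pooled" weights by spike counts. Returns
    (freqs, mean modulation).
    """
    if not spectra:
        raise ValueError("no spectra to average")
    freqs = spectra[0].freqs
    M = np.stack([s.modulation for s in spectra])
    N = np.stack([s.n_spikes for s in spectra])
    low = np.stack([s.low_n for s in spectra])
    if method == "mean_of_units":
        M = np.where(low, np.nan, M)
        with np.errstate(invalid="ignore"):
            return freqs, np.nanmean(M, axis=0)
    elif method == "pooled":
        w = np.where(np.isnan(M), 0, N)
        M0 = np.nan_to_num(M)
        tot = w.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return freqs, np.where(tot > 0, (M0 * w).sum(axis=0) / tot, np.nan)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# ISI return maps


def default_return_map_grid(n_cells: int = 50, lo: float = 1.0,
                            hi: float = 500.0) -> np.ndarray:
    """Log-spaced instantaneous-frequency bin edges (Hz), n_cells bins."""
    return np.geomspace(lo, hi, n_cells + 1)


def isi_return_map(unit: SpikeTrain | np.ndarray,
                   grid: np.ndarray | None = None,
                   normalized: bool = False,
                   duration: float | None = None) -> IsiReturnMap:
    """2-D histogram of successive ISI pairs on instantaneous-frequency axes.

    ISIs (ms) are converted to 1000/ISI (Hz) and the pairs
    (ISI_n, ISI_n+1) are histogrammed on a log-spaced grid. A unit with
    fewer than 2 ISIs yields an empty, flagged map. The per-unit weight used
    later by population averaging is min(rate, 1); the rate needs
    ``duration`` (falls back to the spike-time span).
    """
    times = unit.times if isinstance(unit, SpikeTrain) else np.asarray(unit)
    uid = unit.unit_id if isinstance(unit, SpikeTrain) else ""
    if grid is None:
        grid = default_return_map_grid()
    if times.size < 3:
        log.info("unit %s: fewer than 2 ISIs, empty return map", uid)
        counts = np.zeros((grid.size - 1, grid.size - 1))
        return IsiReturnMap(grid=grid, counts=counts, unit_id=uid,
                            weight=0.0, n_pairs=0)
    isi_ms = np.diff(times) * 1000.0
    inst = 1000.0 / isi_ms
    counts, _, _ = np.histogram2d(inst[:-1], inst[1:], bins=(grid, grid))
    dur = duration if duration is not None else times[-1] - times[0]
    rate = times.size / dur if dur > 0 else 0.0
    m = IsiReturnMap(grid=grid, counts=counts, unit_id=uid,
                     weight=float(min(rate, 1.0)), n_pairs=inst.size - 1)
    return m.normalize() if normalized else m


def population_average_maps(maps: list[IsiReturnMap],
                            rates: np.ndarray | None = None) -> IsiReturnMap:
    """Capped-weight population average of peak-normalized return maps.

    Each map is peak-normalized (n/max(n)) so high-rate cells do not
    dominate, then averaged with weight = min(rate, 1): cells firing below
    1 Hz contribute proportionally to their rate, faster cells equally.
    ``rates`` overrides the weights stored on the maps.
    """
    if not maps:
        raise ValueError("no maps to average")
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid.shape != grid.shape or not np.allclose(m.grid, grid):
            raise ValueError("maps must share a common grid")
    if rates is not None:
        weights = np.minimum(np.asarray(rates, dtype=float), 1.0)
        if weights.size != len(maps):
            raise ValueError("one rate per map required")
    else:
        weights = np.array([m.weight for m in maps])
    normed = np.stack([m.normalize().counts for m in maps])
    wsum = weights.sum()
    if wsum == 0:
        raise ValueError("all weights are zero")
    avg = np.tensordot(weights, normed, axes=1) / wsum
    return IsiReturnMap(grid=grid, counts=avg, unit_id="population",
                        normalized=True, weight=1.0,
                        n_pairs=int(sum(m.n_pairs for m in maps)))


# ---------------------------------------------------------------------------
# autocorrelogram


def autocorrelogram(unit: SpikeTrain | np.ndarray, max_lag: float = 0.5,
                    bin_width: float = 0.005) -> Autocorrelogram:
    """Spike-pair lag histogram over +/- max_lag, zero-lag self-pairs
    excluded; symmetric by construction."""
    times = unit.times if isinstance(unit, SpikeTrain) else np.asarray(unit)
    if times.size < 10:
        raise ValueError("autocorrelogram needs >= 10 spikes")
    n_bins = int(np.ceil(max_lag / bin_width))
    edges = np.arange(0, (n_bins + 1)) * bin_width
    ends = np.searchsorted(times, times + max_lag, side="right")
    diffs = [times[i + 1: j] - times[i]
             for i, j in enumerate(ends) if j > i + 1]
    all_d = np.concatenate(diffs) if diffs else np.empty(0)
    pos = np.histogram(all_d, bins=edges)[0].astype(float)
    counts = np.concatenate([pos[::-1], pos])
    lags = np.concatenate([-edges[1:][::-1] + bin_width / 2,
                           edges[:-1] + bin_width / 2])
    return Autocorrelogram(lags=lags, counts=counts, bin_width=bin_width,
                           n_spikes=times.size)


# ---------------------------------------------------------------------------
# attractor score


def attractor_score(m: IsiReturnMap,
                    band_ms: tuple[float, float] = (20.0, 50.0)) -> dict:
    """Mass and enrichment of the return map in a diagonal ISI block.

    For the default 20-50 ms band the corresponding instantaneous-frequency
    block is 20-50 Hz (1000/50 = 20 ms, 1000/20 = 50 ms). Returns
    ``mass_fraction`` — the fraction of total map mass in the diagonal
    block — and ``enrichment`` — that mass divided by the mass expected
    under independence of successive ISIs (outer product of the marginals).
    A genuinely rhythmic unit in the band scores enrichment >> 1; a
    theta-bursting unit leaves the block nearly empty.
    """
    total = m.counts.sum()
    if total == 0:
        raise ValueError("empty return map")
    lo_hz, hi_hz = 1000.0 / band_ms[1], 1000.0 / band_ms[0]
    centers = m.centers
    sel = (centers >= lo_hz) & (centers <= hi_hz)
    mass = m.counts[np.ix_(sel, sel)].sum() / total
    marg_x = m.counts.sum(axis=1) / total
    marg_y = m.counts.sum(axis=0) / total
    expected = marg_x[sel].sum() * marg_y[sel].sum()
    if expected > 0:
        enrichment = mass / expected
    else:
        # no marginal mass touches the band: enrichment is undefined
        enrichment = float("nan")
    return {"mass_fraction": float(mass), "enrichment": float(enrichment),
            "band_ms": band_ms}
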