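"""Synthetic LFP, spike-train, and speed generators.

The generators emulate the statistical structure of hippocampal recordings
during locomotion: a sawtooth-like theta rhythm whose non-sinusoidal shape
produces phase-locked harmonics, a power-law (1/f^alpha) background, gamma
bursts locked to a preferred theta phase whose carrier frequency scales with
behavioral drive, and bursting theta-modulated spike trains with intra-burst
ISIs of a few milliseconds and inter-burst intervals near the theta period.

Two negative controls are available: an injected independent 40 Hz rhythmic
unit (spike trains) and an independent oscillator added to an LFP mixture.
By construction, no generator places a preferred timescale in the 20-50 ms
range except via these controls.

All functions are deterministic given their seed: substreams for units and
channels are spawned from one master ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .datatypes import (
    DegenerateSignalError,
    LfpChannel,
    SimConfig,
    SpeedTrace,
    SpikeTrain,
    SpikeTrainSet,
    TwoRegionSim,
)

__all__ = [
    "gen_power_law_noise",
    "theta_phase",
    "gen_sawtooth_theta",
    "sawtooth_harmonic_amplitudes",
    "gen_gamma_bursts",
    "gen_cascade_recording",
    "gen_spike_trains",
    "gen_two_region",
    "drive_from_speed",
    "constant_speed",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# power-law background


def gen_power_law_noise(alpha: float, amp: float, duration: float, fs: float,
                        seed=None, label: str = "noise") -> LfpChannel:
    """Gaussian noise whose expected PSD follows f^-alpha.

    Spectral shaping is applied in the Fourier domain: white Gaussian
    coefficients are scaled by f^(-alpha/2) and inverted. The DC component is
    zeroed. The output is rescaled so its standard deviation equals ``amp``.

    Parameters
    ----------
    alpha : float
        Spectral exponent, in [0, 4]. alpha=0 is white noise.
    amp : float
        Target standard deviation, a.u.
    duration, fs : float
        Length (s) and sampling rate (Hz); duration*fs must be >= 1024.
    seed : int, Generator, or None
    """
    if not np.isfinite(amp) or amp < 0:
        raise ValueError("amp must be finite and >= 0")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not 0.0 <= alpha <= 4.0:
        raise ValueError("alpha must lie in [0, 4]")
    n = int(round(duration * fs))
    if n < 1024:
        raise ValueError("need duration*fs >= 1024 samples")
    rng = _rng(seed)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    coef = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(coef * scale, n)
    sd = x.std()
    if sd > 0 and amp > 0:
        x *= amp / sd
    else:
        x = np.zeros(n)
    return LfpChannel(samples=x, fs=fs, label=label)


# ---------------------------------------------------------------------------
# sawtooth theta


def theta_phase(duration: float, fs: float, theta_freq: float,
                t0: float = 0.0, offset: float = 0.0) -> np.ndarray:
    """Unwrapped theta phase 2*pi*f0*(t - offset), radians per sample."""
    t = t0 + np.arange(int(round(duration * fs))) / fs
    return 2.0 * np.pi * theta_freq * (t - offset)


def sawtooth_harmonic_amplitudes(asymmetry: float, n_harmonics: int,
                                 theta_freq: float = 8.0,
                                 kernel_sd: float = 0.0) -> np.ndarray:
    """Harmonic amplitudes h_k (k = 1..n) of the smoothed sawtooth waveform.

    h_k = asymmetry^(k-1) / k, attenuated by the Gaussian smoothing kernel's
    transfer function exp(-(2*pi*k*f0*sd)^2 / 2). At asymmetry=1, kernel_sd=0
    this is the 1/k Fourier series of an ideal sawtooth; at asymmetry=0 only
    the fundamental survives.
    """
    k = np.arange(1, n_harmonics + 1, dtype=float)
    h = asymmetry ** (k - 1) / k
    if kernel_sd > 0:
        h = h * np.exp(-0.5 * (2.0 * np.pi * k * theta_freq * kernel_sd) ** 2)
    return h


def gen_sawtooth_theta(cfg: SimConfig, phase: np.ndarray | None = None,
                       ) -> tuple[LfpChannel, np.ndarray]:
    """Sawtooth-like theta built as a phase-locked harmonic stack.

    The waveform is sum_k h_k * (-1)^(k+1) * sin(k*phi) with h_k from
    :func:`sawtooth_harmonic_amplitudes` — the alternating signs and 1/k
    taper reproduce the ideal sawtooth at asymmetry=1, while intermediate
    asymmetry interpolates smoothly down to a pure sinusoid. Gaussian
    smoothing (kernel_sd) is applied analytically per harmonic, which is
    exactly equivalent to convolution with a Gaussian kernel for a periodic
    signal and avoids edge artifacts.

    Returns the channel and the unwrapped phase trace for downstream
    phase-locking.

    Raises
    ------
    DegenerateSignalError
        If the kernel annihilates the fundamental (power attenuation at f0
        below 1e-6).
    """
    if not 1.0 <= cfg.theta_freq <= 20.0:
        raise ValueError("theta_freq must lie in [1, 20] Hz")
    if cfg.kernel_sd < 0:
        raise ValueError("kernel_sd must be >= 0")
    att = np.exp(-(2.0 * np.pi * cfg.theta_freq * cfg.kernel_sd) ** 2)
    if att < 1e-6:
        raise DegenerateSignalError(
            f"kernel_sd={cfg.kernel_sd}s suppresses the {cfg.theta_freq} Hz "
            f"fundamental to {att:.1e} of its input power")
    if phase is None:
        phase = theta_phase(cfg.duration, cfg.fs, cfg.theta_freq)
    nyq = cfg.fs / 2.0
    n_harm = max(1, int(0.9 * nyq / cfg.theta_freq))
    h = sawtooth_harmonic_amplitudes(cfg.asymmetry, n_harm,
                                     cfg.theta_freq, cfg.kernel_sd)
    k = np.arange(1, n_harm + 1)
    signs = (-1.0) ** (k + 1)
    # (n_harm, n) matrix product kept implicit to bound memory
    x = np.zeros_like(phase)
    for ki, hi, si in zip(k, h, signs):
        if hi < 1e-12:
            continue
        x += hi * si * np.sin(ki * phase)
    x *= cfg.theta_amp
    return LfpChannel(samples=x, fs=cfg.fs, label="theta"), phase


# ---------------------------------------------------------------------------
# theta-locked gamma bursts


def _burst_times(phase: np.ndarray, fs: float, burst_phase: float,
                 ) -> np.ndarray:
    """Ideal (un-jittered) burst centers: times where the unwrapped phase
    crosses burst_phase + 2*pi*k, by linear interpolation."""
    targets = np.arange(np.ceil((phase[0] - burst_phase) / (2 * np.pi)),
                        np.floor((phase[-1] - burst_phase) / (2 * np.pi)) + 1)
    targets = burst_phase + 2.0 * np.pi * targets
    # phase is affine in time here, but interpolate for generality
    idx = np.interp(targets, phase, np.arange(phase.size))
    return idx / fs


def gen_gamma_bursts(phase: np.ndarray, cfg: SimConfig, seed=None,
                     drive: float | np.ndarray | None = None,
                     ) -> LfpChannel:
    """One gamma burst per theta cycle, locked to ``cfg.burst_phase``.

    Each burst has a raised-cosine envelope spanning ``burst_duty`` of the
    theta cycle, Gaussian timing jitter (SD ``burst_jitter_sd``), and
    log-normal amplitude jitter (CV ``burst_amp_cv``, mean 1). The carrier
    frequency is gamma_center + gamma_drive_gain * drive, evaluated at the
    burst time when drive is an array.

    carrier_mode controls the carrier-phase model:

    - ``"theta_locked"`` (default): the carrier phase is reset by the theta
      clock on every cycle (referenced to the ideal, un-jittered burst
      center) plus a fixed random generator phase; timing jitter displaces
      the envelope only. This is the generator used by the two-region toy
      model: the gamma rhythm is locked to the theta drive, as in
      theta-phase-reset gamma, while remaining a local generator.
    - ``"oscillator"``: a continuous-phase local oscillator with a random
      but fixed phase per realization; theta modulates its amplitude only.
    - ``"burst_locked"``: the carrier phase is re-referenced to each
      (jittered) burst center, so timing jitter directly randomizes carrier
      phase — the regime where cross-channel phase consistency at frequency
      f decays as exp(-(2*pi*f*sigma)^2 / 2).
    """
    rng = _rng(seed if seed is not None else cfg.seed)
    if drive is None:
        drive = cfg.drive
    drive_arr = np.asarray(drive, dtype=float)
    if np.any(drive_arr < 0):
        raise ValueError("drive must be >= 0")
    if cfg.burst_jitter_sd < 0:
        raise ValueError("burst_jitter_sd must be >= 0")
    fs = cfg.fs
    n = phase.size
    tbar = _burst_times(phase, fs, cfg.burst_phase)
    nb = tbar.size
    x = np.zeros(n)
    if nb == 0:
        return LfpChannel(samples=x, fs=fs, label="gamma")
    jitter = rng.normal(0.0, cfg.burst_jitter_sd, nb) \
        if cfg.burst_jitter_sd > 0 else np.zeros(nb)
    tb = tbar + jitter
    if cfg.burst_amp_cv > 0:
        s2 = np.log(1.0 + cfg.burst_amp_cv ** 2)
        amps = rng.lognormal(-0.5 * s2, np.sqrt(s2), nb)
    else:
        amps = np.ones(nb)
    amps *= cfg.gamma_amp
    if drive_arr.ndim == 0:
        drive_b = np.full(nb, float(drive_arr))
    else:
        if drive_arr.size != n:
            raise ValueError("per-sample drive must match the phase length")
        idx = np.clip((tbar * fs).astype(int), 0, n - 1)
        drive_b = drive_arr[idx]
    fc = cfg.gamma_center + cfg.gamma_drive_gain * drive_b
    if np.any(fc >= fs / 2):
        raise ValueError("gamma carrier exceeds Nyquist")
    half = 0.5 * cfg.burst_duty * cfg.theta_period
    phi_ch = rng.uniform(0.0, 2.0 * np.pi)
    for tb_i, tbar_i, a_i, fc_i in zip(tb, tbar, amps, fc):
        i0 = max(0, int(np.ceil((tb_i - half) * fs)))
        i1 = min(n, int(np.floor((tb_i + half) * fs)) + 1)
        if i1 <= i0:
            continue
        tt = np.arange(i0, i1) / fs
        env = 0.5 * (1.0 + np.cos(np.pi * (tt - tb_i) / half))
        if cfg.carrier_mode == "burst_locked":
            carrier = np.cos(2.0 * np.pi * fc_i * (tt - tb_i))
        elif cfg.carrier_mode == "oscillator":
            carrier = np.cos(2.0 * np.pi * fc_i * tt + phi_ch)
        else:  # theta_locked
            carrier = np.cos(2.0 * np.pi * fc_i * (tt - tbar_i) + phi_ch)
        x[i0:i1] += a_i * env * carrier
    return LfpChannel(samples=x, fs=fs, label="gamma")


# ---------------------------------------------------------------------------
# behavioral drive and the composite cascade recording


def drive_from_speed(v: np.ndarray, v_scale: float = 30.0,
                     max_drive: float = 1.5) -> np.ndarray:
    """Affine speed-to-drive map: drive = v / v_scale, clipped to [0, max]."""
    return np.clip(np.asarray(v, dtype=float) / v_scale, 0.0, max_drive)


def constant_speed(duration: float, v: float, fs_speed: float = 50.0,
                   ) -> SpeedTrace:
    n = int(round(duration * fs_speed))
    return SpeedTrace(t=np.arange(n) / fs_speed, v=np.full(n, float(v)),
                      fs_speed=fs_speed)


def gen_cascade_recording(cfg: SimConfig,
                          speed_profile: SpeedTrace | Callable[[np.ndarray], np.ndarray],
                          seed=None) -> tuple[LfpChannel, SpeedTrace]:
    """Composite LFP: power-law background + sawtooth theta + theta-locked gamma,
    with every driven component scaled by behavioral drive.

    Drive (mapped from running speed) acts on three fronts, mirroring how the
    hippocampal spectrum reorganizes with locomotion: theta amplitude grows,
    theta waveform asymmetry (hence harmonic content) grows, and gamma bursts
    grow in amplitude while their carrier frequency shifts upward. The 1/f
    background is drive-independent, so stronger drive flattens the fitted
    broadband slope of the composite.

    theta amplitude:  theta_amp * (0.5 + drive)
    asymmetry:        clip(asymmetry + 0.4*drive, 0, 1)
    gamma amplitude:  gamma_amp * drive (per burst, at the burst time)
    gamma carrier:    gamma_center + gamma_drive_gain * drive
    """
    ss = np.random.SeedSequence(cfg.seed if seed is None else seed)
    rng_noise, rng_gamma = [np.random.default_rng(s) for s in ss.spawn(2)]
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    if isinstance(speed_profile, SpeedTrace):
        speed = speed_profile
    else:
        v = np.asarray(speed_profile(t), dtype=float)
        speed = SpeedTrace(t=t.copy(), v=v, fs_speed=cfg.fs)
    if speed.t[-1] + 1.0 / speed.fs_speed < t[-1]:
        raise ValueError("speed profile must cover the full duration")
    v_t = speed.at(t)
    drive_t = drive_from_speed(v_t, max_drive=cfg.max_drive)

    phase = theta_phase(cfg.duration, cfg.fs, cfg.theta_freq)
    # time-varying harmonic stack (amplitude and asymmetry follow drive)
    asym_t = np.clip(cfg.asymmetry + 0.4 * drive_t, 0.0, 1.0)
    amp_t = cfg.theta_amp * (0.5 + drive_t)
    nyq = cfg.fs / 2.0
    n_harm = max(1, min(16, int(0.9 * nyq / cfg.theta_freq)))
    att = np.exp(-0.5 * (2.0 * np.pi * np.arange(1, n_harm + 1)
                         * cfg.theta_freq * cfg.kernel_sd) ** 2)
    theta = np.zeros(n)
    if cfg.theta_amp > 0:
        for k in range(1, n_harm + 1):
            hk = asym_t ** (k - 1) / k * att[k - 1]
            theta += hk * (-1.0) ** (k + 1) * np.sin(k * phase)
        theta *= amp_t

    if cfg.gamma_amp > 0:
        gcfg = cfg
        gamma = gen_gamma_bursts(phase, gcfg, seed=rng_gamma, drive=drive_t)
        # amplitude of each burst should also track drive; cheapest faithful
        # route: modulate the burst train by the (slow) drive envelope
        gamma_x = gamma.samples * drive_t
    else:
        gamma_x = np.zeros(n)

    noise = (gen_power_law_noise(cfg.noise_alpha, cfg.noise_amp, cfg.duration,
                                 cfg.fs, seed=rng_noise).samples
             if cfg.noise_amp > 0 else np.zeros(n))
    lfp = LfpChannel(samples=theta + gamma_x + noise, fs=cfg.fs,
                     label="cascade")
    return lfp, speed


# ---------------------------------------------------------------------------
# bursting spike trains


def gen_spike_trains(cfg: SimConfig, phase: np.ndarray | None = None,
                     n_units: int = 10, regime_params: dict | None = None,
                     seed=None) -> SpikeTrainSet:
    """Theta-modulated bursting units via a burst-renewal process.

    Per unit: a preferred theta phase is drawn uniformly; on each theta cycle
    a burst is emitted with probability ``p_burst`` at the preferred phase
    plus von Mises phase jitter (concentration ``kappa``); each burst holds
    1..``max_spikes_per_burst`` spikes (truncated-geometric count) at
    intra-burst ISIs drawn uniformly from ``isi_range`` (seconds). This
    guarantees the two-regime ISI structure — intra-burst <10 ms, inter-burst
    near the theta period — with no preferred timescale in 20-50 ms.

    ``regime_params`` keys (defaults in brackets): p_burst [per-unit uniform
    in p_burst_range], p_burst_range [(0.3, 0.9)], kappa [4.0],
    max_spikes_per_burst [5], spike_continue_p [0.55], isi_range
    [(0.003, 0.008)], interneuron_fraction [0.2], and the negative-control
    block: n_control [0] units carrying an intermittent independent rhythm
    at control_freq [40.0] Hz — runs of control_run_isis [5] ISIs of
    1/control_freq (jitter SD control_jitter_sd [0.0005] s), separated by
    stretches of irregular non-rhythmic firing (ISIs uniform in
    control_bg_isi_range [(0.055, 0.3)] s, control_bg_count [(6, 16)] per
    stretch). The intermittency is what makes the control detectable as
    rhythmic *clustering*: its 25 ms intervals arrive in runs, far in
    excess of what its ISI marginal predicts.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if cfg.duration <= 0:
        raise ValueError("empty duration")
    p = {
        "p_burst": None,
        "p_burst_range": (0.3, 0.9),
        "kappa": 4.0,
        "max_spikes_per_burst": 5,
        "spike_continue_p": 0.55,
        "isi_range": (0.003, 0.008),
        "n_control": 0,
        "control_freq": 40.0,
        "control_jitter_sd": 0.0005,
        "control_run_isis": 5,
        "control_bg_isi_range": (0.055, 0.3),
        "control_bg_count": (6, 16),
        "interneuron_fraction": 0.2,
    }
    if regime_params:
        unknown = set(regime_params) - set(p)
        if unknown:
            raise ValueError(f"unknown regime_params: {sorted(unknown)}")
        p.update(regime_params)
    if p["kappa"] < 0:
        raise ValueError("kappa must be >= 0")
    if phase is None:
        phase = theta_phase(cfg.duration, cfg.fs, cfg.theta_freq)
    t_hi = cfg.duration
    ss = np.random.SeedSequence(cfg.seed if seed is None else seed)
    streams = ss.spawn(n_units + int(p["n_control"]))
    units: list[SpikeTrain] = []
    n_cycles = int(np.floor(cfg.duration * cfg.theta_freq))
    period = cfg.theta_period
    for i in range(n_units):
        rng = np.random.default_rng(streams[i])
        pref_phase = rng.uniform(0.0, 2.0 * np.pi)
        pb = p["p_burst"] if p["p_burst"] is not None \
            else rng.uniform(*p["p_burst_range"])
        has_burst = rng.random(n_cycles) < pb
        # von Mises jitter around the preferred phase; kappa=inf -> exact
        if np.isinf(p["kappa"]):
            dphi = np.zeros(n_cycles)
        elif p["kappa"] == 0:
            dphi = rng.uniform(-np.pi, np.pi, n_cycles)
        else:
            dphi = rng.vonmises(0.0, p["kappa"], n_cycles)
        burst_t = (np.arange(n_cycles) + (pref_phase + dphi) / (2 * np.pi)) \
            * period
        spikes = []
        for c in np.nonzero(has_burst)[0]:
            t_spk = burst_t[c]
            spikes.append(t_spk)
            # truncated-geometric continuation within the burst
            count = 1
            while count < p["max_spikes_per_burst"] and \
                    rng.random() < p["spike_continue_p"]:
                t_spk = t_spk + rng.uniform(*p["isi_range"])
                spikes.append(t_spk)
                count += 1
        times = np.sort(np.asarray(spikes, dtype=float))
        times = times[(times >= 0.0) & (times <= t_hi)]
        times = _dedupe(times)
        cell = "interneuron" if rng.random() < p["interneuron_fraction"] \
            else "pyramidal"
        units.append(SpikeTrain(unit_id=f"unit{i:03d}", times=times,
                                region="CA1", cell_type=cell))
    for j in range(int(p["n_control"])):
        rng = np.random.default_rng(streams[n_units + j])
        isi_c = 1.0 / p["control_freq"]
        isis: list[float] = []
        t_acc = 0.0
        while t_acc < t_hi:
            n_bg = rng.integers(p["control_bg_count"][0],
                                p["control_bg_count"][1] + 1)
            block = list(rng.uniform(*p["control_bg_isi_range"], n_bg))
            block += list(isi_c + rng.normal(0, p["control_jitter_sd"],
                                             p["control_run_isis"]))
            isis.extend(block)
            t_acc += sum(block)
        times = rng.uniform(0, 0.05) + np.cumsum(isis)
        times = _dedupe(times[(times >= 0) & (times <= t_hi)])
        units.append(SpikeTrain(unit_id=f"control40_{j:03d}", times=times,
                                region="synthetic", cell_type="pyramidal"))
    return SpikeTrainSet(units=units, duration=cfg.duration, t0=0.0)


def _dedupe(times: np.ndarray, min_isi: float = 1e-4) -> np.ndarray:
    """Enforce strictly increasing times (refractory floor of 0.1 ms)."""
    if times.size < 2:
        return times
    keep = np.concatenate([[True], np.diff(times) >= min_isi])
    return times[keep]


# ---------------------------------------------------------------------------
# two-region toy model


def gen_two_region(cfg: SimConfig | None = None, theta_offset: float = 0.025,
                   seed=None, gamma_snr: float = 1.0,
                   theta_modulated: bool = True) -> TwoRegionSim:
    """Two channels with independent gamma generators on a shared theta clock.

    Channel 2's theta (and its gamma bursts' phase reference) is delayed by
    ``theta_offset`` seconds. Gamma carriers, burst timing jitter, amplitude
    jitter, and 1/f background noise are all independent across channels;
    only the theta organization is shared. Background noise is scaled per
    channel so the 30-90 Hz noise power equals the channel's gamma-burst
    power divided by ``gamma_snr`` (the model's declared gamma-band SNR).

    With ``theta_modulated=False`` the burst times are uniform random rather
    than theta-locked (same burst count) — the negative control under which
    cross-channel coherence must fall to the estimator bias floor.
    """
    if cfg is None:
        cfg = SimConfig()
    if not 0.0 <= theta_offset < cfg.theta_period:
        raise ValueError("theta_offset must lie within one theta period")
    ss = np.random.SeedSequence(cfg.seed if seed is None else seed)
    s1, s2 = ss.spawn(2)
    phases = [theta_phase(cfg.duration, cfg.fs, cfg.theta_freq),
              theta_phase(cfg.duration, cfg.fs, cfg.theta_freq,
                          offset=theta_offset)]
    chans = []
    for ph, s in zip(phases, (s1, s2)):
        rng_g, rng_n = [np.random.default_rng(x) for x in s.spawn(2)]
        theta_lfp, _ = gen_sawtooth_theta(cfg, phase=ph)
        if theta_modulated:
            gamma = gen_gamma_bursts(ph, cfg, seed=rng_g)
        else:
            gamma = _uniform_bursts(cfg, rng_g)
        noise = gen_power_law_noise(cfg.noise_alpha, 1.0, cfg.duration,
                                    cfg.fs, seed=rng_n)
        g_pow = _band_var(gamma.samples, cfg.fs, 30.0, 90.0)
        n_pow = _band_var(noise.samples, cfg.fs, 30.0, 90.0)
        scale = np.sqrt(g_pow / (gamma_snr * n_pow)) if n_pow > 0 else 0.0
        x = theta_lfp.samples + gamma.samples + cfg.noise_amp * scale \
            * noise.samples
        chans.append(LfpChannel(samples=x, fs=cfg.fs))
    ch1 = chans[0].copy_with(label="region1")
    ch2 = chans[1].copy_with(label="region2")
    return TwoRegionSim(ch1=ch1, ch2=ch2, theta_offset=theta_offset,
                        shared_theta_phase=phases[0], params=cfg)


def _uniform_bursts(cfg: SimConfig, rng: np.random.Generator) -> LfpChannel:
    """Same burst statistics as gen_gamma_bursts but at uniform random times
    (theta modulation removed): the two-region negative control."""
    n = cfg.n_samples
    nb = int(np.floor(cfg.duration * cfg.theta_freq))
    tb = np.sort(rng.uniform(0.0, cfg.duration, nb))
    s2 = np.log(1.0 + cfg.burst_amp_cv ** 2) if cfg.burst_amp_cv > 0 else 0.0
    amps = rng.lognormal(-0.5 * s2, np.sqrt(s2), nb) if s2 > 0 else np.ones(nb)
    amps *= cfg.gamma_amp
    fc = cfg.gamma_center + cfg.gamma_drive_gain * cfg.drive
    half = 0.5 * cfg.burst_duty * cfg.theta_period
    phi = rng.uniform(0, 2 * np.pi)
    x = np.zeros(n)
    for tb_i, a_i in zip(tb, amps):
        i0 = max(0, int(np.ceil((tb_i - half) * cfg.fs)))
        i1 = min(n, int(np.floor((tb_i + half) * cfg.fs)) + 1)
        if i1 <= i0:
            continue
        tt = np.arange(i0, i1) / cfg.fs
        env = 0.5 * (1.0 + np.cos(np.pi * (tt - tb_i) / half))
        if cfg.carrier_mode == "oscillator":
            carrier = np.cos(2 * np.pi * fc * tt + phi)
        else:
            # burst times are random, so a per-burst phase reference leaves
            # no cross-segment phase consistency at all
            carrier = np.cos(2 * np.pi * fc * (tt - tb_i))
        x[i0:i1] += a_i * env * carrier
    return LfpChannel(samples=x, fs=cfg.fs, label="gamma")


def _band_var(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Variance of x restricted to [lo, hi] Hz (Parseval on the rfft)."""
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    spec = np.abs(np.fft.rfft(x)) ** 2
    m = (freqs >= lo) & (freqs <= hi)
    return 2.0 * spec[m].sum() / x.size ** 2
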