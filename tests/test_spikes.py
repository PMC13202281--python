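"""Spike-timing analyses: phase assignment, modulation estimator calibration,
ISI return maps, population averaging, autocorrelograms, attractor score."""

import numpy as np
import pytest
from scipy.special import i0, i1

from lfpcascade import LfpChannel, SimConfig, SpeedBins, SpeedTrace, synth
from lfpcascade.datatypes import SpikeTrain, SpikeTrainSet
from lfpcascade.spikes import (
    attractor_score,
    autocorrelogram,
    circular_concentration,
    default_return_map_grid,
    fourier_bandpass,
    instantaneous_phase,
    isi_return_map,
    phase_mod_spectrum,
    population_average_maps,
    population_modulation,
    segment_by_speed,
    spike_phases,
)


def _train(times, uid="u0"):
    return SpikeTrain(unit_id=uid, times=np.asarray(times, dtype=float))


def _const_speed(duration, v, fs=50.0):
    n = int(duration * fs)
    return SpeedTrace(t=np.arange(n) / fs, v=np.full(n, float(v)),
                      fs_speed=fs)


class TestSpeedBinning:
    @pytest.mark.parametrize("v,label", [
        (10.0, "moderate"),
        (0.0, "low"),
        (7.0, "moderate"),   # half-open [lo, hi) edges
        (20.0, "high"),
        (6.99, "low"),
    ])
    def test_edge_convention(self, v, label):
        assert SpeedBins().classify(v)[0] == label

    def test_every_segment_in_exactly_one_bin(self):
        rng = np.random.default_rng(1)
        spikes = SpikeTrainSet(
            units=[_train(np.sort(rng.uniform(0, 60, 300)))], duration=60.0)
        t = np.arange(0, 61, 0.02)
        speed = SpeedTrace(t=t, v=25 * (1 + np.sin(t / 5)) / 2, fs_speed=50.0)
        out = segment_by_speed(spikes, speed)
        assert len(out["segments"]) == 60
        labels = [s[2] for s in out["segments"]]
        assert set(labels) <= {"low", "moderate", "high"}
        # spikes are partitioned: per-bin counts add up
        per_bin = out["spike_segments"]["u0"]
        assert sum(v.size for v in per_bin.values()) == 300

    def test_undefined_speed_segments_dropped(self):
        spikes = SpikeTrainSet(units=[_train([1.0, 2.0, 3.0])], duration=60.0)
        speed = _const_speed(30.0, 10.0)  # covers half the recording
        out = segment_by_speed(spikes, speed)
        assert len(out["segments"]) < 60


class TestPhaseAssignment:
    def test_peak_of_sinusoid_is_phase_zero(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        x = LfpChannel(np.cos(2 * np.pi * 8.0 * t), fs)
        filt = fourier_bandpass(x, 8.0)
        ph = instantaneous_phase(filt)
        peaks = np.arange(40) * 0.125  # waveform peaks of cos(2pi*8t)
        sp = spike_phases(peaks, ph, fs)
        # within one sample's phase increment of zero
        assert np.max(np.abs(np.angle(np.exp(1j * sp)))) < 2 * np.pi * 8 / fs \
            + 1e-6


class TestCircularConcentration:
    def test_uniform_null_mean(self, rng):
        """E[R] for n uniform phases approaches sqrt(pi)/2/sqrt(n)."""
        n = 200
        vals = [circular_concentration(rng.uniform(-np.pi, np.pi, n))
                for _ in range(500)]
        expected = np.sqrt(np.pi) / 2 / np.sqrt(n)
        assert np.mean(vals) == pytest.approx(expected, rel=0.1)

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0])
    def test_von_mises_recovery(self, kappa, rng):
        """R converges to I1(k)/I0(k) for von Mises phases, n = 1e4."""
        phases = rng.vonmises(0.0, kappa, 10_000)
        expected = i1(kappa) / i0(kappa)
        assert circular_concentration(phases) == pytest.approx(expected,
                                                               abs=0.02)

    def test_point_mass_gives_unity(self):
        assert circular_concentration(np.zeros(100)) == pytest.approx(
            1.0, abs=1e-2)  # one bin's width of spread at most


class TestPhaseModSpectrum:
    def test_perfectly_locked_spikes_modulation_one(self):
        fs = 1000.0
        t = np.arange(int(60 * fs)) / fs
        lfp = LfpChannel(np.cos(2 * np.pi * 8.0 * t), fs)
        peaks = np.arange(1, 8 * 59) * 0.125
        spikes = SpikeTrainSet(units=[_train(peaks)], duration=60.0)
        out = phase_mod_spectrum(spikes, lfp, freqs=np.array([8.0]))
        assert out["u0"]["all"].modulation[0] > 0.99

    def test_speed_split_reports_per_bin(self, rng):
        fs = 1000.0
        t = np.arange(int(40 * fs)) / fs
        lfp = LfpChannel(np.cos(2 * np.pi * 8.0 * t)
                         + 0.1 * rng.standard_normal(t.size), fs)
        spikes = SpikeTrainSet(
            units=[_train(np.sort(rng.uniform(0, 40, 2000)))], duration=40.0)
        ts = np.arange(0, 41, 0.02)
        speed = SpeedTrace(t=ts, v=np.where(ts < 20, 3.0, 25.0),
                           fs_speed=50.0)
        out = phase_mod_spectrum(spikes, lfp, freqs=np.array([4.0, 8.0]),
                                 speed=speed)
        assert set(out["u0"]) == {"low", "moderate", "high"}
        assert out["u0"]["moderate"].n_spikes.sum() == 0  # never 7-20 cm/s
        assert np.all(out["u0"]["low"].n_spikes > 0)

    def test_above_nyquist_grid_rejected(self):
        lfp = LfpChannel(np.zeros(2000) + np.arange(2000) % 2, 1000.0)
        spikes = SpikeTrainSet(units=[_train([0.5, 1.0, 1.5])], duration=2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            phase_mod_spectrum(spikes, lfp, freqs=np.array([100.0, 600.0]))

    def test_population_average_orders(self):
        s = PhaseSpecFactory.make([0.2, 0.4], [100, 100])
        t = PhaseSpecFactory.make([0.6, 0.8], [300, 10])  # second entry low-n
        freqs, avg = population_modulation([s, t])
        assert avg[0] == pytest.approx(0.4)
        assert avg[1] == pytest.approx(0.4)  # low-n entry ignored
        _, pooled = population_modulation([s, t], method="pooled")
        assert pooled[0] == pytest.approx((0.2 * 100 + 0.6 * 300) / 400)


class PhaseSpecFactory:
    @staticmethod
    def make(mods, ns):
        from lfpcascade.datatypes import PhaseModSpectrum
        return PhaseModSpectrum(
            freqs=np.array([8.0, 16.0]), modulation=np.array(mods),
            n_spikes=np.array(ns), unit_id="x")


class TestIsiReturnMap:
    def test_pure_theta_pacing_occupies_single_cell(self):
        times = np.arange(100) * 0.125
        m = isi_return_map(_train(times))
        assert m.counts.sum() == times.size - 2
        occupied = np.argwhere(m.counts > 0)
        assert len(occupied) == 1
        i, j = occupied[0]
        assert m.centers[i] == pytest.approx(8.0, rel=0.05)
        assert m.centers[j] == pytest.approx(8.0, rel=0.05)

    def test_mass_conservation(self, bursting_trains):
        # grid wide enough that no ISI pair falls outside it
        grid = default_return_map_grid(lo=0.05, hi=500.0)
        for u in list(bursting_trains)[:5]:
            m = isi_return_map(u, grid=grid)
            assert m.counts.sum() == u.n_spikes - 2

    def test_bursting_unit_regimes(self, bursting_trains):
        maps = [isi_return_map(u, duration=120.0) for u in bursting_trains
                if not u.unit_id.startswith("control")]
        pop = population_average_maps(maps)
        c = pop.centers
        total = pop.counts.sum()
        burst = pop.counts[np.ix_(c > 100, c > 100)].sum() / total
        theta = pop.counts[np.ix_((c > 4) & (c < 16),
                                  (c > 4) & (c < 16))].sum() / total
        mid = pop.counts[np.ix_((c >= 20) & (c <= 50),
                                (c >= 20) & (c <= 50))].sum() / total
        assert burst > 0.05 and theta > 0.05
        assert mid < 0.05

    def test_control_unit_dominant_cell_at_40hz(self, bursting_trains):
        ctrl = [u for u in bursting_trains
                if u.unit_id.startswith("control")][0]
        m = isi_return_map(ctrl, duration=120.0)
        i, j = np.unravel_index(np.argmax(m.counts), m.counts.shape)
        assert m.centers[i] == pytest.approx(40.0, rel=0.1)
        assert m.centers[j] == pytest.approx(40.0, rel=0.1)

    def test_too_few_spikes_flagged_empty(self):
        m = isi_return_map(_train([0.1, 0.2]))
        assert m.counts.sum() == 0 and m.n_pairs == 0


class TestPopulationAverage:
    def test_single_map_identity(self):
        m = isi_return_map(_train(np.arange(50) * 0.125)).normalize()
        avg = population_average_maps([m], rates=np.array([2.0]))
        assert np.allclose(avg.counts, m.counts)

    def test_capped_weights(self):
        times = np.arange(50) * 0.125
        m1 = isi_return_map(_train(times, "a"))
        times2 = np.arange(50) * 0.025
        m2 = isi_return_map(_train(times2, "b"))
        avg = population_average_maps([m1, m2], rates=np.array([0.5, 2.0]))
        n1, n2 = m1.normalize().counts, m2.normalize().counts
        expected = (0.5 * n1 + 1.0 * n2) / 1.5
        assert np.allclose(avg.counts, expected)

    def test_identical_maps_any_weights(self):
        m = isi_return_map(_train(np.arange(50) * 0.125))
        avg = population_average_maps([m, m], rates=np.array([0.3, 5.0]))
        assert np.allclose(avg.counts, m.normalize().counts)

    def test_grid_mismatch_rejected(self):
        m1 = isi_return_map(_train(np.arange(50) * 0.125))
        m2 = isi_return_map(_train(np.arange(50) * 0.125),
                            grid=default_return_map_grid(25))
        with pytest.raises(ValueError, match="grid"):
            population_average_maps([m1, m2], rates=np.array([1.0, 1.0]))


class TestAutocorrelogram:
    def test_periodic_train_peaks_at_period_multiples(self):
        times = np.arange(200) * 0.125
        ac = autocorrelogram(_train(times))
        for lag in (0.125, 0.25):
            sel = np.abs(np.abs(ac.lags) - lag) <= ac.bin_width
            assert ac.counts[sel].sum() > 0
        # nothing off-period
        off = np.abs(np.abs(ac.lags) - 0.0625) <= ac.bin_width / 2
        assert ac.counts[off].max() == 0

    def test_symmetry_and_no_self_pairs(self, bursting_trains):
        u = next(iter(bursting_trains))
        ac = autocorrelogram(u)
        half = ac.counts.size // 2
        assert np.array_equal(ac.counts[:half][::-1], ac.counts[half:])

    def test_poisson_flat(self, rng):
        times = np.sort(rng.uniform(0, 200, 2000))
        times = times[np.concatenate(([True], np.diff(times) > 1e-4))]
        ac = autocorrelogram(_train(times))
        rel = ac.counts.std() / ac.counts.mean()
        assert rel < 0.25

    def test_bursting_unit_theta_and_burst_peaks(self, bursting_trains):
        counts = None
        for u in bursting_trains:
            if u.unit_id.startswith("control"):
                continue
            ac = autocorrelogram(u)
            counts = ac.counts if counts is None else counts + ac.counts
        lags = np.abs(ac.lags)
        burst = counts[lags <= 0.010].mean()
        theta = counts[(lags >= 0.105) & (lags <= 0.145)].mean()
        mid = counts[(lags >= 0.025) & (lags <= 0.050)].mean()
        assert burst > 2 * mid
        assert theta > 1.5 * mid

    def test_too_few_spikes_rejected(self):
        with pytest.raises(ValueError, match="10 spikes"):
            autocorrelogram(_train(np.arange(5) * 0.1))


class TestAttractorScore:
    def test_uniform_map_enrichment_one(self):
        grid = default_return_map_grid()
        from lfpcascade.datatypes import IsiReturnMap
        m = IsiReturnMap(grid=grid, counts=np.ones((50, 50)), n_pairs=2500)
        s = attractor_score(m)
        assert s["enrichment"] == pytest.approx(1.0)

    def test_control_enriched_default_not(self, bursting_trains):
        scores = {}
        for u in bursting_trains:
            m = isi_return_map(u, duration=120.0)
            scores[u.unit_id] = attractor_score(m)
        ctrl = [s for k, s in scores.items() if k.startswith("control")]
        dflt = [s for k, s in scores.items() if not k.startswith("control")]
        assert all(s["enrichment"] > 2.0 for s in ctrl)
        assert all(s["mass_fraction"] < 0.05 for s in dflt)

    def test_attractor_auroc_separates_controls(self):
        """Mass-fraction score separates injected 40 Hz units from default
        bursting units with AUROC > 0.95 (50 + 50 units)."""
        cfg = SimConfig(duration=120.0, seed=33)
        trains = synth.gen_spike_trains(
            cfg, n_units=50, regime_params={"n_control": 50}, seed=33)
        pos, neg = [], []
        for u in trains:
            score = attractor_score(isi_return_map(u, duration=120.0))
            (pos if u.unit_id.startswith("control") else neg).append(
                score["mass_fraction"])
        pos, neg = np.asarray(pos), np.asarray(neg)
        auroc = np.mean(pos[:, None] > neg[None, :]) \
            + 0.5 * np.mean(pos[:, None] == neg[None, :])
        assert auroc > 0.95

    def test_empty_map_rejected(self):
        m = isi_return_map(_train([0.1, 0.2]))
        with pytest.raises(ValueError, match="empty"):
            attractor_score(m)
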