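"""ISI statistics, population rates, spectra, voltage statistics, currents
and oscillation-cycle peak analysis."""

import numpy as np
import pytest

import gammanet as gn
from gammanet.types import SpikeRaster


def _raster(times, ids, duration, n=3, pop="single"):
    times = np.asarray(times, dtype=float)
    return SpikeRaster(
        times,
        np.asarray(ids, dtype=np.int64),
        np.full(times.size, pop),
        duration,
        {pop: n},
    )


class TestISIStatistics:
    def test_regular_train_cv_zero(self):
        r = _raster(np.arange(0.1, 9.9, 0.1), np.zeros(98), 10.0, n=1)
        assert gn.isi_statistics(r, "pooled").cv == pytest.approx(0.0, abs=1e-12)

    def test_poisson_train_cv_one(self, rng):
        t = np.cumsum(rng.exponential(0.1, 1000))
        t = t[t < 95.0]
        r = _raster(t, np.zeros(t.size), 100.0, n=1)
        assert gn.isi_statistics(r, "pooled").cv == pytest.approx(1.0, abs=0.1)

    def test_insufficient_spikes_marked_undefined(self):
        r = _raster([0.5], [0], 1.0)
        assert np.isnan(gn.isi_statistics(r, "pooled").cv)
        assert np.isnan(gn.isi_statistics(r, "per_cell").cv)

    def test_unknown_scope_rejected(self):
        r = _raster([0.1, 0.2], [0, 0], 1.0)
        with pytest.raises(ValueError):
            gn.isi_statistics(r, "per_trial")


class TestPopulationRate:
    def test_empty_raster_zero_trace(self):
        rate = gn.population_rate(_raster([], [], 2.0), 66.0, 5e-4)
        assert np.all(rate == 0.0)

    def test_mean_preservation(self, default_run):
        """Unit-DC-gain filtering preserves the overall mean rate."""
        rate = gn.population_rate(default_run.raster, 5.5, 5e-4, population="E")
        overall = default_run.raster.mean_rate("E")
        assert rate[2000:].mean() == pytest.approx(overall, rel=0.1)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            gn.population_rate(_raster([], [], 1.0), 2000.0, 5e-4)

    def test_slow_cutoff_smooths_harder(self, default_run):
        slow = gn.population_rate(default_run.raster, 5.5, 5e-4, population="E")
        fast = gn.population_rate(default_run.raster, 66.0, 5e-4, population="E")
        assert slow[2000:].std() < fast[2000:].std()


class TestPowerSpectrum:
    def test_sinusoid_peak(self, rng):
        dt = 5e-4
        t = np.arange(int(5.0 / dt)) * dt
        x = np.sin(2 * np.pi * 40.0 * t) + 0.05 * rng.standard_normal(t.size)
        spec = gn.power_spectrum(x, dt)
        assert spec.peak_frequency == pytest.approx(40.0, abs=1.0)

    def test_white_noise_is_flat(self, rng):
        # wide bandwidth (many tapers) so the per-bin estimator variance is
        # small enough for a max-vs-median flatness check
        spec = gn.power_spectrum(rng.standard_normal(10_000), 5e-4, time_bandwidth=8.0)
        band = spec.power[spec.frequencies > 5.0]
        assert band.max() < 3.0 * np.median(band)

    def test_parseval_total_power(self, rng):
        x = rng.standard_normal(8192)
        spec = gn.power_spectrum(x, 5e-4)
        df = spec.frequencies[1] - spec.frequencies[0]
        assert spec.power.sum() * df == pytest.approx(x.var(), rel=0.1)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            gn.power_spectrum(np.zeros(100), 5e-4)


class TestSpectrogram:
    def test_stationary_ridge(self):
        dt = 5e-4
        t = np.arange(int(4.0 / dt)) * dt
        x = np.sin(2 * np.pi * 40.0 * t)
        times, freqs, sxx = gn.spectrogram(x, dt)
        ridge = freqs[np.argmax(sxx, axis=0)]
        settled = times > 1.0  # smoothing filter start-up
        assert np.all(np.abs(ridge[settled] - 40.0) < 10.0)

    def test_onset_ridge_appears_after_step(self):
        dt = 5e-4
        t = np.arange(int(6.0 / dt)) * dt
        x = np.where(t > 3.0, np.sin(2 * np.pi * 40.0 * t), 0.0)
        times, freqs, sxx = gn.spectrogram(x, dt)
        gamma = (freqs > 30.0) & (freqs < 50.0)
        power_40 = sxx[gamma].mean(axis=0)
        pre = power_40[(times > 1.0) & (times < 2.8)].mean()
        post = power_40[times > 4.0].mean()
        assert post > 100 * (pre + 1e-30)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            gn.spectrogram(np.zeros(10), 5e-4, window_ms=60.0)

    def test_stimulus_onset_brings_gamma_ridge(self, ei_defaults):
        """Constant-input onset: the population-rate spectrogram shows a
        sustained gamma ridge after onset that is absent before."""
        dt, tau = ei_defaults.dt, ei_defaults.tau
        onset = 2.0
        x = np.where(np.arange(int(5.0 / dt)) * dt >= onset, 50.0, 0.0)
        stim = gn.stimulus_from_target(x, tau, dt)
        res = gn.simulate_ei_network(ei_defaults, stim, seed=0)
        rate = gn.binned_population_rate(res.raster, dt, population="E")
        times, freqs, sxx = gn.spectrogram(rate, dt)
        gamma = (freqs >= 25.0) & (freqs <= 55.0)
        gamma_power = sxx[gamma].mean(axis=0)
        pre = gamma_power[(times > 0.5) & (times < onset - 0.2)].mean()
        post = gamma_power[times > onset + 1.0].mean()
        assert post > 10 * (pre + 1e-30)


class TestVoltagePairStatistics:
    def test_identical_traces_full_correlation(self, rng):
        v = rng.standard_normal(4000)
        corr, _, coh = gn.voltage_pair_statistics(np.stack([v, v], axis=1), 5e-4)
        assert corr == pytest.approx(1.0)
        assert np.all(coh > 0.99)

    def test_independent_traces_uncorrelated(self, rng):
        v = rng.standard_normal((20_000, 4))
        corr, _, coh = gn.voltage_pair_statistics(v, 5e-4)
        assert abs(corr) < 0.05
        assert coh.mean() < 0.3

    def test_constant_trace_rejected(self):
        v = np.zeros((100, 2))
        with pytest.raises(ValueError):
            gn.voltage_pair_statistics(v, 5e-4)

    def test_network_voltage_correlation_decreases_with_noise(
        self, ei_defaults, default_run
    ):
        """Membrane potentials share the prediction-error drive: pairwise
        correlation is positive and shrinks as injected noise grows."""
        v17 = default_run.voltages["E"][1000:, :10]
        corr17, _, _ = gn.voltage_pair_statistics(v17, 5e-4)
        assert corr17 > 0.0
        corrs = {17.0: corr17}
        stim = gn.constant_target(50.0, 3.0, ei_defaults.dt, ei_defaults.tau)
        for sigma in (4.0, 60.0):
            res = gn.simulate_ei_network(
                ei_defaults.replace(sigma=sigma), stim, seed=0, record_voltages=True
            )
            corrs[sigma], _, _ = gn.voltage_pair_statistics(
                res.voltages["E"][1000:, :10], 5e-4
            )
        assert corrs[4.0] > corrs[17.0] > corrs[60.0]

    def test_evoked_correlation_exceeds_spontaneous(self, ei_defaults, default_run):
        """Feed-forward drive raises pairwise membrane-potential correlation
        relative to the undriven (spontaneous) condition."""
        v_evoked = default_run.voltages["E"][1000:7000, :10]
        evoked, _, _ = gn.voltage_pair_statistics(v_evoked, 5e-4)
        stim = gn.constant_target(0.0, 3.0, ei_defaults.dt, ei_defaults.tau)
        res = gn.simulate_ei_network(ei_defaults, stim, seed=0, record_voltages=True)
        spont, _, _ = gn.voltage_pair_statistics(res.voltages["E"][1000:, :10], 5e-4)
        assert evoked > spont


class TestCurrents:
    def test_requires_recorded_inputs(self, ei_defaults):
        stim = gn.constant_target(50.0, 1.5, ei_defaults.dt, ei_defaults.tau)
        res = gn.simulate_ei_network(ei_defaults, stim, seed=0)
        with pytest.raises(ValueError):
            gn.extract_currents(res)

    def test_resistance_rescaling(self, default_run):
        e5, i5 = gn.extract_currents(default_run, membrane_resistance=5.0)
        e10, i10 = gn.extract_currents(default_run, membrane_resistance=10.0)
        np.testing.assert_allclose(e10, e5 / 2.0)
        np.testing.assert_allclose(i10, i5 / 2.0)


class TestPeakDetection:
    def test_single_bump(self):
        t = np.linspace(0, 1, 1000)
        bump = np.exp(-((t - 0.5) ** 2) / 0.01)
        assert gn.detect_peaks(bump).size == 1

    def test_trough_drop_rule(self):
        t = np.linspace(0, 1, 2000)
        two = np.exp(-((t - 0.3) ** 2) / 0.002) + np.exp(-((t - 0.7) ** 2) / 0.002)
        assert gn.detect_peaks(two, drop_fraction=0.8).size == 2
        shallow = 1.0 + 0.05 * np.sin(2 * np.pi * 3 * t)  # ripples, no 80% drop
        assert gn.detect_peaks(shallow, drop_fraction=0.8).size == 1

    def test_pairing_symmetric_under_relabeling(self, default_run):
        """Swapping E and I flips the lag signs of the matched pairs."""
        e_cur, i_cur = gn.extract_currents(default_run)
        start = 1000
        a = gn.detect_and_pair_peaks(e_cur[start:, 0], i_cur[start:, 0], 5e-4)
        b = gn.detect_and_pair_peaks(np.abs(i_cur[start:, 0]), -e_cur[start:, 0], 5e-4)
        assert a.lags_ms.size == b.lags_ms.size
        np.testing.assert_allclose(np.sort(a.lags_ms), np.sort(-b.lags_ms))

    def test_empty_traces_allowed(self):
        ps = gn.detect_and_pair_peaks(np.zeros(100), np.zeros(100), 5e-4)
        assert ps.lags_ms.size == 0
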