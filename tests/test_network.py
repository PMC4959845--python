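"""Synaptic kernel, connectivity builder and the delayed E/I simulator."""

import numpy as np
import pytest

import gammanet as gn
from gammanet.network import DelayedSynapticFilter, _deliver


class TestSynapticKernel:
    def test_zero_before_transmission_delay(self):
        spec = gn.SynapseKernelSpec(1e-3, 3e-3, 1e-3)
        k = gn.synaptic_kernel(spec, 5e-4)
        t = np.arange(k.size) * 5e-4
        assert np.all(k[t <= spec.tau_tr] == 0.0)
        assert np.all(k[t > spec.tau_tr] > 0.0)

    def test_unit_discrete_integral(self):
        spec = gn.SynapseKernelSpec()
        k = gn.synaptic_kernel(spec, 5e-4)
        assert k.sum() * 5e-4 == pytest.approx(1.0, abs=1e-12)

    def test_peak_location(self):
        """Peak at τ_tr + τ_r τ_d/(τ_d - τ_r) · ln(τ_d/τ_r) ≈ 2.65 ms."""
        spec = gn.SynapseKernelSpec(1e-3, 3e-3, 1e-3)
        dt = 1e-5
        k = gn.synaptic_kernel(spec, dt)
        t_peak = np.argmax(k) * dt
        analytic = spec.tau_tr + (
            spec.tau_r * spec.tau_d / (spec.tau_d - spec.tau_r)
        ) * np.log(spec.tau_d / spec.tau_r)
        assert t_peak == pytest.approx(analytic, abs=2 * dt)
        assert analytic == pytest.approx(2.648e-3, abs=1e-5)

    def test_degenerate_time_constants_rejected(self):
        with pytest.raises(ValueError):
            gn.SynapseKernelSpec(tau_r=3e-3, tau_d=3e-3)


class TestEffectiveSynapticDelay:
    def test_exponential_limit(self):
        """τ_r → 0, τ_tr = 0: the kernel tends to a pure exponential whose
        half-mass time is τ_d ln 2."""
        spec = gn.SynapseKernelSpec(tau_r=1e-6, tau_d=3e-3, tau_tr=0.0)
        d = gn.effective_synaptic_delay(spec)
        assert d == pytest.approx(3e-3 * np.log(2), rel=0.01)

    def test_time_rescaling_doubles_delay(self):
        spec = gn.SynapseKernelSpec()
        assert gn.effective_synaptic_delay(spec.scaled(2.0)) == pytest.approx(
            2.0 * gn.effective_synaptic_delay(spec), rel=0.01
        )

    def test_default_value_regression(self):
        """Half-mass time of the default 1/3/1 ms kernel.

        Hand check: the kernel CDF is [τd(1-e^(-s/τd)) - τr(1-e^(-s/τr))]
        /(τd-τr) past the delay; solving CDF = ½ gives s ≈ 3.17 ms, so the
        delay is ≈ 4.17 ms including the 1 ms transmission delay."""
        assert gn.effective_synaptic_delay(gn.SynapseKernelSpec()) == pytest.approx(
            4.173e-3, abs=5e-5
        )


class TestBuildConnectivity:
    def test_homogeneous_outer_products(self):
        conn = gn.build_connectivity(gn.EINetworkConfig())
        assert np.all(conn.w_ie == pytest.approx(1.44))
        assert np.all(conn.w_ei == pytest.approx(1.44))
        assert np.all(conn.w_ii == pytest.approx(1.44))

    def test_no_excitatory_recurrence(self):
        """The architecture has E→I, I→E and I→I pathways only."""
        conn = gn.build_connectivity(gn.EINetworkConfig())
        assert not hasattr(conn, "w_ee")
        assert conn.w_ei.shape == (50, 50) and conn.w_ie.shape == (50, 50)

    def test_heterogeneous_weight_statistics(self):
        cfg = gn.EINetworkConfig(n_e=4000, n_i=4000, connectivity_mode="heterogeneous", seed=3)
        conn = gn.build_connectivity(cfg)
        w = np.concatenate([conn.w_e, conn.w_i])
        assert w.mean() == pytest.approx(1.2, abs=0.02)
        assert w.std() == pytest.approx(0.5, abs=0.02)
        assert np.all(w > 0)

    def test_permuted_preserves_row_sums(self):
        cfg = gn.EINetworkConfig(connectivity_mode="heterogeneous", seed=3)
        het = gn.build_connectivity(cfg)
        per = gn.build_connectivity(cfg.replace(connectivity_mode="permuted"))
        np.testing.assert_allclose(per.w_ei.sum(axis=1), het.w_ei.sum(axis=1))
        np.testing.assert_allclose(per.w_ie.sum(axis=1), het.w_ie.sum(axis=1))
        # I→I untouched, per-connection symmetry broken elsewhere
        np.testing.assert_allclose(per.w_ii, het.w_ii)
        assert not np.allclose(per.w_ie, het.w_ie)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            gn.EINetworkConfig(connectivity_mode="sparse")


class TestDelayedSynapticFilter:
    @pytest.mark.parametrize("tau_tr", [0.0, 5e-4, 1e-3, 2e-3])
    def test_matches_direct_convolution(self, tau_tr):
        """The recursive two-state filter reproduces convolution with the
        sampled kernel (up to the kernel's truncation error)."""
        spec = gn.SynapseKernelSpec(tau_tr=tau_tr)
        dt, n = 5e-4, 400
        imp = np.zeros((n, 3))
        for b, j, m in [(10, 0, 1.44), (11, 1, 2.0), (50, 0, 0.7), (200, 2, 3.0), (201, 2, 1.0)]:
            imp[b, j] += m
        filt = DelayedSynapticFilter(spec, dt, 3)
        drive = np.zeros((n, 3))
        for t in range(n):
            drive[t] = filt.step()
            if imp[t].any():
                filt.enqueue(imp[t])
        kernel = gn.synaptic_kernel(spec, dt)
        ref = np.stack([np.convolve(imp[:, j], kernel)[:n] for j in range(3)], axis=1)
        assert np.abs(drive - ref).max() < 1e-3 * ref.max()

    def test_mass_conservation(self):
        """One spike of mass M delivers integrated drive exactly M."""
        filt = DelayedSynapticFilter(gn.SynapseKernelSpec(), 5e-4, 1)
        total = 0.0
        filt.step()
        filt.enqueue(np.array([2.5]))
        for _ in range(1000):
            total += filt.step()[0] * 5e-4
        assert total == pytest.approx(2.5, rel=1e-6)


class TestSynapticFailures:
    def test_expected_mass_unchanged_by_compensation(self, rng):
        """Bernoulli deletion with 1/(1-p) compensation keeps the mean
        delivered mass per spike equal to the nominal weight."""
        matrix = np.full((200, 1), 1.44)
        spiking = np.array([0])
        for p in (0.0, 0.3, 0.7):
            totals = np.mean(
                [_deliver(matrix, spiking, p, rng).mean() for _ in range(300)]
            )
            assert totals == pytest.approx(1.44, rel=0.05)


class TestSimulateEINetwork:
    def test_zero_input_zero_noise_silent(self):
        cfg = gn.EINetworkConfig(sigma=0.0)
        stim = gn.constant_target(0.0, 1.0, cfg.dt, cfg.tau)
        res = gn.simulate_ei_network(cfg, stim, seed=0)
        assert res.raster.n_spikes == 0
        assert np.all(res.readout_e == 0.0) and np.all(res.readout_i == 0.0)

    def test_mean_excitatory_rate(self, default_run):
        """Unbiased-readout steady state: rate ≈ x/(N_E γ0 τ) ≈ 8.3 Hz."""
        assert default_run.raster.mean_rate("E") == pytest.approx(
            50.0 / (50 * 1.2 * 0.1), rel=0.15
        )

    def test_inhibitory_readout_tracks_excitatory(self, ei_defaults, default_stimulus):
        """x̂I follows x̂E: positively correlated, with their centered
        mismatch well below the level of two uncoupled readouts."""
        start = int(0.5 / ei_defaults.dt)
        for seed in (0, 1):
            res = gn.simulate_ei_network(ei_defaults, default_stimulus, seed=seed)
            xe = res.readout_e[start:]
            xi = res.readout_i[start:]
            assert np.corrcoef(xe, xi)[0, 1] > 0.3
            centered = (xe - xe.mean()) - (xi - xi.mean())
            uncoupled = np.sqrt(xe.var() + xi.var())
            assert np.sqrt((centered**2).mean()) < 0.85 * uncoupled

    def test_dales_law_sign_of_recorded_inputs(self, default_run):
        """All recorded excitatory input is depolarizing, inhibitory input
        hyperpolarizing, for both populations."""
        for pop in ("E", "I"):
            assert np.all(default_run.exc_input[pop] >= 0.0)
            assert np.all(default_run.inh_input[pop] <= 0.0)

    def test_poisson_substitution_keeps_rates(self, ei_defaults, default_stimulus):
        cfg = ei_defaults.replace(poisson_fraction=0.4)
        res = gn.simulate_ei_network(cfg, default_stimulus, seed=2)
        intact = gn.simulate_ei_network(ei_defaults, default_stimulus, seed=2)
        assert res.raster.mean_rate("E") == pytest.approx(
            intact.raster.mean_rate("E"), rel=0.2
        )

    def test_deterministic_given_seed(self, ei_defaults):
        stim = gn.constant_target(50.0, 1.5, ei_defaults.dt, ei_defaults.tau)
        a = gn.simulate_ei_network(ei_defaults, stim, seed=7)
        b = gn.simulate_ei_network(ei_defaults, stim, seed=7)
        np.testing.assert_array_equal(a.raster.times, b.raster.times)
        np.testing.assert_array_equal(a.readout_e, b.readout_e)

    def test_grid_mismatch_rejected(self, ei_defaults):
        stim = gn.constant_target(50.0, 1.0, 1e-3, ei_defaults.tau)
        with pytest.raises(ValueError):
            gn.simulate_ei_network(ei_defaults, stim)


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = gn.EINetworkConfig(
            sigma=8.0,
            failure_prob=0.2,
            kernel=gn.SynapseKernelSpec(2e-3, 6e-3, 1e-3),
            connectivity_mode="heterogeneous",
            seed=11,
        )
        path = tmp_path / "net.yaml"
        cfg.to_yaml(path)
        loaded = gn.EINetworkConfig.from_yaml(path)
        assert loaded == cfg

    def test_invariants(self):
        with pytest.raises(ValueError):
            gn.EINetworkConfig(failure_prob=1.0)
        with pytest.raises(ValueError):
            gn.EINetworkConfig(poisson_fraction=1.5)
        with pytest.raises(ValueError):
            gn.EINetworkConfig(gamma0=0.0)
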