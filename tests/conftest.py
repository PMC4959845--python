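"""Shared fixtures: expensive simulations are session-scoped so several
tests can interrogate one run."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gammanet as gn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ei_defaults() -> gn.EINetworkConfig:
    return gn.EINetworkConfig()


@pytest.fixture(scope="session")
def default_stimulus(ei_defaults) -> gn.Stimulus:
    return gn.constant_target(50.0, 5.5, ei_defaults.dt, ei_defaults.tau)


@pytest.fixture(scope="session")
def default_run(ei_defaults, default_stimulus) -> gn.SimResult:
    """One run of the standard E/I network (x=50, σ=17) with all traces."""
    return gn.simulate_ei_network(
        ei_defaults, default_stimulus, seed=0, record_inputs=True, record_voltages=True
    )


@pytest.fixture(scope="session")
def calibrated17(ei_defaults):
    """Bias-nulled costs at σ=17 plus one measurement run."""
    chunk = gn.constant_target(50.0, 2.5, ei_defaults.dt, ei_defaults.tau)
    calib = gn.calibrate_costs(ei_defaults, chunk, seed=5)
    config = calib.apply(ei_defaults)
    stim = gn.constant_target(50.0, 10.5, config.dt, config.tau)
    result = gn.simulate_ei_network(config, stim, seed=1)
    return calib, config, stim, result


@pytest.fixture(scope="session")
def ideal_toy_run():
    """3-neuron ideal network at constant x=4 with the printed noise σ=0.02."""
    cfg = gn.IdealNetworkConfig(noise_sigma=0.02)
    stim = gn.constant_target(4.0, 30.0, cfg.dt, cfg.tau)
    result = gn.simulate_ideal_network(cfg, stim, seed=1, record_voltages=False)
    return cfg, stim, result


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
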