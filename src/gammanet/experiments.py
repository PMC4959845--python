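"""Scripted experiments: parameter sweeps, the regular-vs-synchronous toy
model, and the two-interval discrimination task.

Each sweep point calibrates the spike costs when asked to (noise-like sweeps
change firing rates, so they need bias-nulling), simulates one or more
seeds, and appends a metrics row: reconstruction error, E/I mismatch, bias,
per-cell CV, mean rates, population-spectrum peak frequency and a
rate-matched Poisson reference error.  Everything is deterministic given the
sweep's seeds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import analysis
from .calibration import calibrate_costs, load_calibration_table, save_calibration_table
from .decoding import (
    decode,
    discrimination_performance,
    ei_mismatch,
    estimation_bias,
    reconstruction_error,
    simulate_poisson_baseline,
)
from .network import EINetworkConfig, build_connectivity, simulate_ei_network
from .stimuli import constant_target
from .types import SimResult, SpikeRaster, Stimulus

__all__ = [
    "SweepSpec",
    "run_sweep",
    "point_metrics",
    "toy_synchrony_experiment",
    "run_discrimination",
]

EXPERIMENTS = (
    "noise_sweep",
    "failure_sweep",
    "poisson_fraction_sweep",
    "amplitude_set",
    "size_sweep",
    "inhibitory_size_sweep",
    "delay_sweep",
    "tau_sweep",
    "heterogeneous_vs_permuted",
)


@dataclass
class SweepSpec:
    """One sweep: which parameter moves, over which grid, for which seeds."""

    experiment: str
    grid: list
    seeds: list[int] = field(default_factory=lambda: [0, 1, 2])
    duration: float = 10.0
    amplitude: float = 50.0
    calibrate: bool = True
    burn_in: float = 0.5
    calibration_chunk_s: float = 2.0
    calibration_max_chunks: int = 50
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if not self.grid:
            raise ValueError("grid must be non-empty")
        if not self.seeds:
            raise ValueError("need at least one seed")


def _config_at(spec: SweepSpec, base: EINetworkConfig, value) -> EINetworkConfig:
    """Materialize the network config for one grid point."""
    exp = spec.experiment
    if exp == "noise_sweep":
        return base.replace(sigma=float(value))
    if exp == "failure_sweep":
        return base.replace(failure_prob=float(value))
    if exp == "poisson_fraction_sweep":
        return base.replace(poisson_fraction=float(value))
    if exp == "amplitude_set":
        return base
    if exp == "size_sweep":
        return base.replace(n_e=int(value), n_i=int(value))
    if exp == "inhibitory_size_sweep":
        return base.replace(n_i=int(value))
    if exp == "delay_sweep":
        return base.replace(kernel=base.kernel.scaled(float(value)))
    if exp == "tau_sweep":
        return base.replace(tau=float(value))
    if exp == "heterogeneous_vs_permuted":
        return base.replace(connectivity_mode=str(value))
    raise AssertionError(exp)


def point_metrics(
    result: SimResult,
    stimulus: Stimulus,
    config: EINetworkConfig,
    burn_in: float = 0.5,
    poisson_seed: int = 12345,
) -> dict[str, float]:
    """Standard metrics row for one simulated grid point."""
    dt = config.dt
    conn = build_connectivity(config)
    start = int(round(burn_in / dt))
    err = reconstruction_error(stimulus.x, result.readout_e, dt, burn_in, "normalized_by_mean")
    mismatch = ei_mismatch(result.readout_e, result.readout_i, dt, burn_in)
    bias = estimation_bias(stimulus.x, result.readout_e, dt, burn_in)
    cv = analysis.isi_statistics(result.raster, "per_cell", population="E").cv
    rate_trace = analysis.binned_population_rate(result.raster, dt, population="E")[start:]
    spectrum = analysis.power_spectrum(rate_trace, dt)
    rates_e = result.raster.per_neuron_rates("E")
    rates_i = result.raster.per_neuron_rates("I")
    poisson = simulate_poisson_baseline(
        rates_e, conn.w_e, config.tau, stimulus.duration, dt, seed=poisson_seed
    )
    poisson_err = reconstruction_error(
        stimulus.x, poisson.readout_e, dt, burn_in, "normalized_by_mean"
    )
    return {
        "error": err,
        "ei_mismatch": mismatch,
        "bias": bias,
        "cv": cv,
        "rate_e": float(rates_e.mean()),
        "rate_i": float(rates_i.mean()),
        "population_rate_e": float(rates_e.mean() * config.n_e),
        "peak_frequency_hz": spectrum.peak_frequency,
        "poisson_error": poisson_err,
    }


def run_sweep(
    spec: SweepSpec,
    base_config: EINetworkConfig,
    cache_path=None,
) -> pd.DataFrame:
    """Run one sweep and return a tidy table (one row per grid point × seed).

    With ``calibrate=True``, each grid point first nulls the estimation
    biases on a constant-target chunk before the measurement runs.  A
    per-point failure is recorded as a row with ``failed=True`` and NaN
    metrics; the sweep continues.
    """
    cache = load_calibration_table(cache_path) if cache_path else {}
    rows = []
    for value in spec.grid:
        config = _config_at(spec, base_config, value)
        amplitude = float(value) if spec.experiment == "amplitude_set" else spec.amplitude
        stim = constant_target(amplitude, spec.duration, config.dt, config.tau)
        try:
            calib_converged = None
            if spec.calibrate:
                key = f"{spec.experiment}:{value}:{amplitude}"
                if key in cache:
                    config = config.replace(
                        beta_e=cache[key]["beta_e"], beta_i=cache[key]["beta_i"]
                    )
                    calib_converged = cache[key]["converged"]
                else:
                    chunk = constant_target(
                        amplitude, spec.calibration_chunk_s + spec.burn_in, config.dt, config.tau
                    )
                    calib = calibrate_costs(
                        config,
                        chunk,
                        max_chunks=spec.calibration_max_chunks,
                        seed=zlib.crc32(f"{spec.experiment}:{value}".encode()) % 2**31,
                        burn_in=spec.burn_in,
                    )
                    config = calib.apply(config)
                    calib_converged = calib.converged
                    if cache_path:
                        save_calibration_table(
                            cache_path,
                            [
                                {
                                    "key": key,
                                    "beta_e": calib.beta_e,
                                    "beta_i": calib.beta_i,
                                    "converged": calib.converged,
                                }
                            ],
                        )
                        cache[key] = {
                            "beta_e": calib.beta_e,
                            "beta_i": calib.beta_i,
                            "converged": calib.converged,
                        }
            for seed in spec.seeds:
                result = simulate_ei_network(config, stim, seed=seed)
                row = {
                    "experiment": spec.experiment,
                    "value": value,
                    "seed": seed,
                    "beta_e": config.beta_e,
                    "beta_i": config.beta_i,
                    "calibration_converged": calib_converged,
                    "failed": False,
                }
                row.update(point_metrics(result, stim, config, spec.burn_in, poisson_seed=seed + 99991))
                rows.append(row)
        except Exception as exc:  # per-point failures must not kill the sweep
            rows.append(
                {
                    "experiment": spec.experiment,
                    "value": value,
                    "seed": None,
                    "failed": True,
                    "error_message": str(exc),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Toy model: regular schedules with k-synchronous spikes vs Poisson firing


def toy_synchrony_experiment(
    n_neurons: int = 10,
    synchrony_k: tuple[int, ...] = (1, 2, 3, 5),
    rate_per_neuron: float = 10.0,
    tau: float = 0.1,
    duration: float = 20.0,
    dt: float = 5e-4,
    weight: float = 1.0,
    seed: int = 0,
    burn_in: float = 0.5,
) -> pd.DataFrame:
    """Coding error of regular spike schedules versus spike synchrony.

    The population emits spikes at a fixed total rate; in the k-synchronous
    schedule, groups of k distinct neurons fire simultaneously at evenly
    spaced times (round-robin through the population).  The encoded value is
    the readout's unbiased steady state x = w · R_total · τ, and the error
    is the mean-normalized RMS reconstruction error.  A final row gives the
    matched-rate independent-Poisson reference.  The default grid stops at
    half the population: at k = n the schedule degenerates to
    population-wide bursts, which is outside the regime being illustrated.
    """
    total_rate = n_neurons * rate_per_neuron
    x_target = weight * total_rate * tau
    n_samples = int(round(duration / dt))
    x = np.full(n_samples, x_target)
    weights = np.full(n_neurons, weight)
    rows = []
    for k in synchrony_k:
        if k < 1 or k > n_neurons:
            raise ValueError(f"synchrony k={k} must lie in [1, n_neurons]")
        interval = k / total_rate
        event_times = np.arange(0.0, duration - 0.5 * dt, interval)
        times, ids = [], []
        for m, t_ev in enumerate(event_times):
            members = (m * k + np.arange(k)) % n_neurons
            times.extend([t_ev] * k)
            ids.extend(members.tolist())
        raster = SpikeRaster(
            np.asarray(times),
            np.asarray(ids, dtype=np.int64),
            np.full(len(times), "single"),
            n_samples * dt,
            {"single": n_neurons},
        )
        xhat = decode(raster, weights, tau, dt)
        err = reconstruction_error(x, xhat, dt, burn_in, "normalized_by_mean")
        rows.append({"model": "regular", "k": k, "error": err})
    poisson = simulate_poisson_baseline(
        np.full(n_neurons, rate_per_neuron), weights, tau, duration, dt, seed=seed
    )
    err = reconstruction_error(x, poisson.readout_e, dt, burn_in, "normalized_by_mean")
    rows.append({"model": "poisson", "k": np.nan, "error": err})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Two-interval discrimination


def run_discrimination(
    base_config: EINetworkConfig,
    centre_amplitude: float = 48.0,
    separation: float = 4.0,
    sigmas: tuple[float, ...] = (8.0, 17.0),
    n_trials: int = 50,
    segment_duration: float = 0.1,
    seed: int = 0,
    calibrate: bool = True,
    burn_in: float = 0.5,
) -> pd.DataFrame:
    """Discriminate two stimulus amplitudes from short readout segments.

    For each noise level the network (optionally bias-nulled at the centre
    amplitude) is driven with each of the two amplitudes; the post-burn-in
    readout is chopped into ``segment_duration`` windows whose time averages
    are per-trial estimates, fed to the signal-detection computation.
    Returns one row per σ with d' and p_correct.
    """
    if n_trials < 20:
        raise ValueError("need at least 20 trials per condition")
    amp_lo = centre_amplitude - separation / 2.0
    amp_hi = centre_amplitude + separation / 2.0
    rows = []
    for sigma in sigmas:
        config = base_config.replace(sigma=float(sigma))
        if calibrate:
            chunk = constant_target(centre_amplitude, 2.5, config.dt, config.tau)
            calib = calibrate_costs(config, chunk, seed=seed + 131, burn_in=burn_in)
            config = calib.apply(config)
        samples = {}
        for label, amp in (("lo", amp_lo), ("hi", amp_hi)):
            duration = burn_in + n_trials * segment_duration
            stim = constant_target(amp, duration, config.dt, config.tau)
            result = simulate_ei_network(config, stim, seed=seed + (17 if label == "hi" else 3))
            start = int(round(burn_in / config.dt))
            seg = int(round(segment_duration / config.dt))
            trace = result.readout_e[start : start + n_trials * seg]
            samples[label] = trace.reshape(n_trials, seg).mean(axis=1)
        d_prime, p_correct = discrimination_performance(samples["lo"], samples["hi"])
        rows.append(
            {
                "sigma": sigma,
                "d_prime": d_prime,
                "p_correct": p_correct,
                "amplitude_low": amp_lo,
                "amplitude_high": amp_hi,
                "n_trials": n_trials,
            }
        )
    return pd.DataFrame(rows)
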