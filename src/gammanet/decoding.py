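"""Leaky readout decoder, reconstruction-error metrics, Poisson baseline and
signal-detection discrimination.

The decoder is the linear readout the network is optimized against: the
reconstruction decays with time constant τ between spikes and jumps by w_i at
each spike of neuron i.  All error metrics exclude an onset burn-in (default
0.5 s) so transients do not contaminate steady-state numbers.
"""

from __future__ import annotations

import numpy as np
from scipy import signal, special

from .types import SimResult, SpikeRaster

__all__ = [
    "decode",
    "reconstruction_error",
    "estimation_bias",
    "ei_mismatch",
    "simulate_poisson_baseline",
    "discrimination_performance",
]

DEFAULT_BURN_IN = 0.5


def decode(
    raster: SpikeRaster,
    weights: np.ndarray,
    tau: float,
    dt: float,
    population: str | None = None,
) -> np.ndarray:
    """Reconstruction x̂(t) from a spike raster (leaky weighted integration).

    x̂ starts at zero, decays by a factor (1 - dt/τ) per bin and gains w_i at
    every spike of neuron i.  ``weights`` must have one entry per neuron of
    the decoded population.
    """
    sub = raster if population is None else raster.select(population)
    n = sum(sub.n_neurons.values())
    weights = np.asarray(weights, dtype=float)
    if weights.size != n:
        raise ValueError(f"expected {n} weights, got {weights.size}")
    n_samples = int(round(sub.duration / dt))
    impulses = np.zeros(n_samples)
    if sub.n_spikes:
        bins = np.rint(sub.times / dt).astype(int)
        bins = np.clip(bins, 0, n_samples - 1)
        np.add.at(impulses, bins, weights[sub.neuron_indices])
    # x̂[n] = (1 - dt/τ) x̂[n-1] + impulses[n]
    return signal.lfilter([1.0], [1.0, -(1.0 - dt / tau)], impulses)


def _post_burn_in(trace: np.ndarray, dt: float, burn_in: float) -> np.ndarray:
    start = int(round(burn_in / dt))
    if start >= trace.size:
        raise ValueError("burn-in longer than trace")
    return trace[start:]


def reconstruction_error(
    x: np.ndarray,
    xhat: np.ndarray,
    dt: float,
    burn_in: float = DEFAULT_BURN_IN,
    mode: str = "normalized_by_mean",
) -> float:
    """RMS reconstruction error, normalized by SD(x) or mean(x).

    ``normalized_by_variance`` (rms / SD of the encoded signal) suits
    time-varying targets; ``normalized_by_mean`` suits constant ones, where
    the SD is zero.
    """
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError("traces must be aligned")
    xs = _post_burn_in(x, dt, burn_in)
    es = _post_burn_in(x - xhat, dt, burn_in)
    rms = float(np.sqrt(np.mean(es**2)))
    if mode == "normalized_by_variance":
        denom = float(xs.std())
    elif mode == "normalized_by_mean":
        denom = float(xs.mean())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if denom == 0.0:
        raise ZeroDivisionError(f"normalization divisor is zero in mode {mode!r}")
    return rms / denom


def estimation_bias(
    x: np.ndarray, xhat: np.ndarray, dt: float, burn_in: float = DEFAULT_BURN_IN
) -> float:
    """Time-averaged signed error ⟨x̂ - x⟩ after the burn-in."""
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError("traces must be aligned")
    return float(np.mean(_post_burn_in(xhat - x, dt, burn_in)))


def ei_mismatch(
    xhat_e: np.ndarray, xhat_i: np.ndarray, dt: float, burn_in: float = DEFAULT_BURN_IN
) -> float:
    """RMS difference between excitatory and inhibitory reconstructions."""
    d = np.asarray(xhat_e, dtype=float) - np.asarray(xhat_i, dtype=float)
    return float(np.sqrt(np.mean(_post_burn_in(d, dt, burn_in) ** 2)))


def simulate_poisson_baseline(
    mean_rates: np.ndarray,
    weights: np.ndarray,
    tau: float,
    duration: float,
    dt: float,
    seed: int = 0,
) -> SimResult:
    """Independent Poisson spike trains at fixed rates, decoded the same way.

    The rate-matched reference model: firing carries no recurrent
    coordination, so reconstruction noise is limited only by spike-count
    statistics.
    """
    mean_rates = np.asarray(mean_rates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(mean_rates < 0):
        raise ValueError("rates must be non-negative")
    if weights.size != mean_rates.size:
        raise ValueError("weights and rates must align")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration / dt))
    counts = rng.poisson(mean_rates * dt, size=(n_samples, mean_rates.size))
    bins, ids = np.nonzero(counts)
    reps = counts[bins, ids]
    bins = np.repeat(bins, reps)
    ids = np.repeat(ids, reps)
    raster = SpikeRaster(
        times=bins * dt,
        neuron_indices=ids,
        population=np.full(bins.size, "single"),
        duration=n_samples * dt,
        n_neurons={"single": mean_rates.size},
    )
    readout = decode(raster, weights, tau, dt)
    return SimResult(
        raster=raster,
        time=np.arange(n_samples) * dt,
        readout_e=readout,
        seed=seed,
        dt=dt,
    )


def discrimination_performance(samples_1, samples_2) -> tuple[float, float]:
    """Signal-detection discriminability of two sets of scalar estimates.

    Returns (d', p_correct) with d' = (μ2 - μ1)/√(½(σ1² + σ2²)) and the
    two-alternative probability p = Φ(d'/√2) = ½ erfc(-d'/2).
    """
    s1 = np.asarray(samples_1, dtype=float)
    s2 = np.asarray(samples_2, dtype=float)
    if s1.size < 2 or s2.size < 2:
        raise ValueError("need at least 2 samples per condition")
    pooled = 0.5 * (s1.var(ddof=1) + s2.var(ddof=1))
    if pooled == 0.0:
        raise ZeroDivisionError("zero pooled variance")
    d_prime = float((s2.mean() - s1.mean()) / np.sqrt(pooled))
    p_correct = float(0.5 * special.erfc(-d_prime / 2.0))
    return d_prime, p_correct
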