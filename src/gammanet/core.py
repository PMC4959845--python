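"""Greedy efficient-coding spike rule and the ideal (instantaneous-synapse) network.

The model encodes a scalar target ``x(t)`` in the spike trains of N leaky
integrate-and-fire neurons.  A leaky readout reconstructs ``x̂`` by adding a
fixed weight ``w_i`` each time neuron i spikes and decaying with the readout
time constant ``tau``.  Each neuron fires greedily: a spike is emitted iff it
instantaneously reduces the loss

    E = (x - x̂)² + α Σ_i r_i + β Σ_i r_i²,

where ``r_i`` is the neuron's leaky own-spike rate trace.  Expanding the
spike/no-spike comparison shows this rule is exactly a threshold condition
V_i > T_i on the "voltage"

    V_i = w_i (x - x̂) - β r_i,        T_i = ½ (w_i² + α + β),

so the derived machine is a recurrent LIF network: each spike of neuron k
knocks every voltage down by w_i w_k (instantaneous inhibition) and resets
the firing cell by a further β.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .types import SimResult, SpikeRaster, Stimulus

__all__ = [
    "spike_threshold",
    "membrane_voltage",
    "coding_loss",
    "spike_decision_from_loss",
    "biophysical_mapping",
    "IdealNetworkConfig",
    "simulate_ideal_network",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Raised when an integration blows up (NaN or runaway voltages)."""


def spike_threshold(w: float, alpha: float, beta: float) -> float:
    """Firing threshold ½(w² + α + β) of the greedy spike rule.

    Parameters
    ----------
    w : readout weight of the neuron (mV^1/2 scale).
    alpha : L1 spike cost (must be ≥ 0).
    beta : L2 spike cost (mV scale, must be ≥ 0).
    """
    if alpha < 0 or beta < 0:
        raise ValueError("spike costs must be non-negative")
    return 0.5 * (w * w + alpha + beta)


def membrane_voltage(w: float, x: float, xhat: float, beta: float, r: float) -> float:
    """Voltage identity V = w(x - x̂) - β r of the derived LIF neuron."""
    return w * (x - xhat) - beta * r


def coding_loss(x: float, xhat: float, rates, alpha: float, beta: float) -> float:
    """Instantaneous loss (x - x̂)² + α Σ r_i + β Σ r_i²."""
    r = np.asarray(rates, dtype=float)
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    return float((x - xhat) ** 2 + alpha * r.sum() + beta * np.sum(r * r))


def spike_decision_from_loss(
    x: float, xhat: float, rates, weights, alpha: float, beta: float, neuron: int
) -> bool:
    """Explicit greedy rule: does a spike of ``neuron`` lower the loss?

    A spike bumps the readout by w_i and the neuron's rate by 1; the decision
    compares the loss after that bump with the loss of staying silent.  Used
    as the brute-force oracle for the V > T threshold rule.
    """
    r = np.asarray(rates, dtype=float)
    w = np.asarray(weights, dtype=float)
    loss_silent = coding_loss(x, xhat, r, alpha, beta)
    r_spike = r.copy()
    r_spike[neuron] += 1.0
    loss_spike = coding_loss(x, xhat + w[neuron], r_spike, alpha, beta)
    return loss_spike < loss_silent


def biophysical_mapping(
    v_thresh: float = -55.0,
    l1: float = 0.0,
    l2: float = 8.5,
    gamma0: float = 1.2,
) -> dict[str, float]:
    """Map the dimensionless model parameters onto membrane-potential landmarks.

    Anchoring the model threshold at a biological spike threshold ``v_thresh``
    (mV) gives

        V_rest  = v_thresh - ½ (L1 + L2 + γ0²)
        V_reset = v_thresh - L2 - γ0²
        V_PSP   = γ0²          (unitary postsynaptic potential)

    With the default parameters (L2 = 8.5 mV, γ0 = 1.2) this puts rest 5 mV
    below threshold and reset 10 mV below, with ~1.4 mV PSPs.
    """
    v_rest = v_thresh - 0.5 * (l1 + l2 + gamma0**2)
    v_reset = v_thresh - l2 - gamma0**2
    return {"v_rest": v_rest, "v_reset": v_reset, "v_psp": gamma0**2}


@dataclass
class IdealNetworkConfig:
    """One-population network with instantaneous recurrent inhibition.

    Defaults are the 3-neuron toy used throughout: unit weights, no L1 cost,
    β = 0.04, τ = 100 ms, σ = 0.02, dt = 0.5 ms.
    """

    n_neurons: int = 3
    weights: np.ndarray | float = 1.0
    l1_cost: float = 0.0
    l2_cost: float = 0.04
    tau: float = 0.1
    noise_sigma: float = 0.02
    dt: float = 5e-4
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be positive")
        if self.dt >= self.tau:
            raise ValueError("dt must be small compared to tau")
        if self.l1_cost < 0 or self.l2_cost < 0:
            raise ValueError("spike costs must be non-negative")
        self.weights = np.broadcast_to(
            np.asarray(self.weights, dtype=float), (self.n_neurons,)
        ).copy()

    @property
    def thresholds(self) -> np.ndarray:
        w = self.weights
        return 0.5 * (w * w + self.l1_cost + self.l2_cost)


def simulate_ideal_network(
    config: IdealNetworkConfig,
    stimulus: Stimulus,
    seed: int = 0,
    record_voltages: bool = True,
    initial_state: str = "zero",
) -> SimResult:
    """Forward-Euler integration of the derived LIF dynamics.

    Per step: voltages leak towards the feed-forward drive w_i c(t) and
    receive independent Gaussian increments σ√(dt/τ)·ξ (white noise entering
    the τ-scaled voltage equation; stationary voltage SD σ/√(2τ)); at most
    one neuron — the
    one with the highest voltage, if supra-threshold — fires per bin (exact
    ties broken by lowest index).  A spike of neuron k subtracts w_i w_k from
    every voltage (self term included) plus an extra β from the firing cell,
    adds w_k to the readout and 1 to r_k.

    With σ = 0 the integrated voltage equals the closed form
    V_i = w_i(x - x̂) - β r_i at every recorded sample (machine precision),
    which the test suite checks.  ``initial_state`` is "zero" (voltages and
    rates start at rest) or "consistent" (voltages start at w_i x(0), the
    value the closed form takes for an empty spiking history — without it the
    zero start decays onto the closed form as e^{-t/τ}).
    """
    if abs(stimulus.dt - config.dt) > 1e-12:
        raise ValueError("stimulus grid step must equal config dt")
    n = config.n_neurons
    w = config.weights
    thresholds = config.thresholds
    tau, dt, beta = config.tau, config.dt, config.l2_cost
    sigma = config.noise_sigma
    n_samples = stimulus.n_samples
    rng = np.random.default_rng(seed)

    if initial_state == "zero":
        V = np.zeros(n)
    elif initial_state == "consistent":
        V = w * stimulus.x[0]
    else:
        raise ValueError(f"unknown initial_state {initial_state!r}")
    r = np.zeros(n)
    xhat = 0.0
    leak = dt / tau
    noise_scale = sigma * np.sqrt(dt / tau)

    spike_bins: list[int] = []
    spike_ids: list[int] = []
    readout = np.zeros(n_samples)
    volt = np.zeros((n_samples, n)) if record_voltages else None
    rate_trace = np.zeros((n_samples, n)) if record_voltages else None
    if record_voltages:
        volt[0] = V

    c = stimulus.c
    for t in range(n_samples - 1):
        if sigma > 0:
            V += leak * (w * c[t] - V) + noise_scale * rng.standard_normal(n)
        else:
            V += leak * (w * c[t] - V)
        xhat -= leak * xhat
        r -= leak * r
        # one spike per bin: highest voltage among supra-threshold cells fires
        above = np.flatnonzero(V > thresholds)
        if above.size:
            i = int(above[np.argmax(V[above])])
            V -= w * w[i]
            V[i] -= beta
            xhat += w[i]
            r[i] += 1.0
            spike_bins.append(t + 1)
            spike_ids.append(i)
        readout[t + 1] = xhat
        if record_voltages:
            volt[t + 1] = V
            rate_trace[t + 1] = r
        if (t & 0x3FF) == 0 and (not np.all(np.isfinite(V)) or np.abs(V).max() > 1e9):
            raise SimulationError(f"voltage blow-up at t={t * dt:.4f} s (max |V|={np.abs(V).max():.3g})")
    if not np.all(np.isfinite(V)):
        raise SimulationError("non-finite voltages at end of run")

    times = stimulus.time[np.asarray(spike_bins, dtype=int)] if spike_bins else np.array([])
    raster = SpikeRaster(
        times=times,
        neuron_indices=np.asarray(spike_ids, dtype=np.int64),
        population=np.full(len(spike_ids), "single"),
        duration=stimulus.duration,
        n_neurons={"single": n},
    )
    voltages = {}
    if record_voltages:
        voltages = {"single": volt, "rates": rate_trace}
    return SimResult(
        raster=raster,
        time=stimulus.time,
        readout_e=readout,
        voltages=voltages,
        config=config,
        seed=seed,
        dt=dt,
    )
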