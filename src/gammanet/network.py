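"""Dale's-law excitatory/inhibitory network with delayed continuous synapses.

The ideal one-population network is split into an excitatory population that
encodes the target ``x`` and an inhibitory population that encodes (and
cancels) the excitatory reconstruction.  All readout weights are positive, so
the architecture has exactly three recurrent pathways — E→I, I→E and I→I —
and no E→E connections.  Cross-neuron spike effects are delivered through a
difference-of-exponentials synaptic current

    h(t) = [exp(-(t-τ_tr)/τ_d) - exp(-(t-τ_tr)/τ_r)] / (τ_d - τ_r),  t > τ_tr

(zero before the transmission delay τ_tr, unit integral), while each
neuron's own post-spike reset −β is applied instantaneously: the reset models
intracellular dynamics, not a synapse.

The simulator realizes the kernel convolution with exact two-state
exponential filters per pathway plus a circular delay buffer, which is
algebraically equivalent to convolving spike trains with the sampled kernel
(a direct-convolution oracle in the test suite checks this).  Optional
Bernoulli synaptic failures delete individual spike→target deliveries, with
recurrent weights divided by the transmission (success) probability so the
expected delivered mass is unchanged.  A fraction of cells can be replaced
by rate-matched Poisson emitters whose spikes still enter the recurrence and
the readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np

from .core import SimulationError
from .types import SimResult, SpikeRaster, Stimulus

__all__ = [
    "SynapseKernelSpec",
    "synaptic_kernel",
    "effective_synaptic_delay",
    "EINetworkConfig",
    "ConnectivityMatrices",
    "build_connectivity",
    "DelayedSynapticFilter",
    "simulate_ei_network",
]


@dataclass(frozen=True)
class SynapseKernelSpec:
    """Rise/decay/transmission-delay time constants of the synaptic current (s)."""

    tau_r: float = 1e-3
    tau_d: float = 3e-3
    tau_tr: float = 1e-3

    def __post_init__(self) -> None:
        if not self.tau_d > self.tau_r > 0:
            raise ValueError("need tau_d > tau_r > 0 (equal values degenerate the normalization)")
        if self.tau_tr < 0:
            raise ValueError("transmission delay must be non-negative")

    def scaled(self, factor: float) -> "SynapseKernelSpec":
        """All three time constants multiplied by ``factor``."""
        return SynapseKernelSpec(self.tau_r * factor, self.tau_d * factor, self.tau_tr * factor)


def synaptic_kernel(spec: SynapseKernelSpec, dt: float) -> np.ndarray:
    """Sampled synaptic waveform, normalized so that ``kernel.sum() * dt == 1``.

    Support is truncated at ``10 τ_d + τ_tr``; samples at ``t <= τ_tr`` are
    exactly zero.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(np.ceil((10 * spec.tau_d + spec.tau_tr) / dt)) + 1
    t = np.arange(n) * dt
    kernel = np.zeros(n)
    late = t > spec.tau_tr
    s = t[late] - spec.tau_tr
    kernel[late] = (np.exp(-s / spec.tau_d) - np.exp(-s / spec.tau_r)) / (spec.tau_d - spec.tau_r)
    mass = kernel.sum() * dt
    if mass <= 0:
        raise ValueError("kernel has no mass on this grid; decrease dt")
    return kernel / mass


def effective_synaptic_delay(spec: SynapseKernelSpec, dt: float = 1e-6) -> float:
    """Time for the cumulative synaptic input of one spike to reach half its maximum.

    Computed by numerical cumulative sum of the finely sampled kernel.  In the
    limit τ_r → 0, τ_tr → 0 this tends to τ_d ln 2 (median of an exponential).
    """
    kernel = synaptic_kernel(spec, dt)
    cdf = np.cumsum(kernel) * dt
    idx = int(np.searchsorted(cdf, 0.5))
    return idx * dt


@dataclass
class EINetworkConfig:
    """Structural and cost parameters of one E/I network variant.

    Defaults are the standard operating point: 50+50 neurons, readout weights
    γ0 = 1.2 (mV^1/2), L2 cost β = 8.5 mV for both populations, τ = 100 ms,
    membrane noise σ = 17, 1/3/1 ms synaptic kernel, dt = 0.5 ms.
    """

    n_e: int = 50
    n_i: int = 50
    gamma0: float = 1.2
    alpha_e: float = 0.0
    beta_e: float = 8.5
    alpha_i: float = 0.0
    beta_i: float = 8.5
    tau: float = 0.1
    sigma: float = 17.0
    dt: float = 5e-4
    kernel: SynapseKernelSpec = field(default_factory=SynapseKernelSpec)
    failure_prob: float = 0.0
    poisson_fraction: float = 0.0
    connectivity_mode: str = "homogeneous"
    weight_sd: float = 0.5
    seed: int = 0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_e < 1 or self.n_i < 1:
            raise ValueError("both populations need at least one neuron")
        if self.gamma0 <= 0:
            raise ValueError("readout weights must be positive")
        if min(self.alpha_e, self.beta_e, self.alpha_i, self.beta_i) < 0:
            raise ValueError("spike costs must be non-negative")
        if self.tau <= 0 or self.dt <= 0 or self.dt >= self.tau:
            raise ValueError("need 0 < dt << tau")
        if not 0.0 <= self.failure_prob < 1.0:
            raise ValueError("failure_prob must lie in [0, 1)")
        if not 0.0 <= self.poisson_fraction <= 1.0:
            raise ValueError("poisson_fraction must lie in [0, 1]")
        if self.connectivity_mode not in ("homogeneous", "heterogeneous", "permuted"):
            raise ValueError(f"unknown connectivity_mode {self.connectivity_mode!r}")

    def replace(self, **kwargs) -> "EINetworkConfig":
        return replace(self, **kwargs)

    # -- YAML round trip (field names mirror the standard parameter table) --

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_e": self.n_e,
            "n_i": self.n_i,
            "gamma0_mV12": self.gamma0,
            "alpha_e": self.alpha_e,
            "beta_mV": self.beta_e,
            "alpha_i": self.alpha_i,
            "beta_i_mV": self.beta_i,
            "tau_s": self.tau,
            "sigma": self.sigma,
            "dt_ms": self.dt * 1e3,
            "tau_r_ms": self.kernel.tau_r * 1e3,
            "tau_d_ms": self.kernel.tau_d * 1e3,
            "tau_tr_ms": self.kernel.tau_tr * 1e3,
            "failure_prob": self.failure_prob,
            "poisson_fraction": self.poisson_fraction,
            "connectivity_mode": self.connectivity_mode,
            "weight_sd": self.weight_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "EINetworkConfig":
        kernel = SynapseKernelSpec(
            tau_r=d.get("tau_r_ms", 1.0) * 1e-3,
            tau_d=d.get("tau_d_ms", 3.0) * 1e-3,
            tau_tr=d.get("tau_tr_ms", 1.0) * 1e-3,
        )
        beta_e = d.get("beta_mV", 8.5)
        return cls(
            n_e=d.get("n_e", 50),
            n_i=d.get("n_i", 50),
            gamma0=d.get("gamma0_mV12", 1.2),
            alpha_e=d.get("alpha_e", 0.0),
            beta_e=beta_e,
            alpha_i=d.get("alpha_i", 0.0),
            beta_i=d.get("beta_i_mV", beta_e),
            tau=d.get("tau_s", 0.1),
            sigma=d.get("sigma", 17.0),
            dt=d.get("dt_ms", 0.5) * 1e-3,
            kernel=kernel,
            failure_prob=d.get("failure_prob", 0.0),
            poisson_fraction=d.get("poisson_fraction", 0.0),
            connectivity_mode=d.get("connectivity_mode", "homogeneous"),
            weight_sd=d.get("weight_sd", 0.5),
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EINetworkConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ConnectivityMatrices:
    """Readout weights and the three recurrent weight matrices.

    In the precisely balanced network every matrix is the outer product of
    the postsynaptic and presynaptic readout weights; ``permute`` breaks that
    per-connection symmetry while preserving each neuron's summed input.
    There is deliberately no E→E matrix.
    """

    w_e: np.ndarray  # readout weights, excitatory population
    w_i: np.ndarray  # readout weights, inhibitory population
    w_ei: np.ndarray  # E→I, shape (n_i, n_e)
    w_ie: np.ndarray  # I→E, shape (n_e, n_i)
    w_ii: np.ndarray  # I→I, shape (n_i, n_i)
    mode: str = "homogeneous"


def build_connectivity(config: EINetworkConfig, rng: np.random.Generator | None = None) -> ConnectivityMatrices:
    """Construct readout weights and recurrent matrices for a config.

    homogeneous
        All readout weights equal γ0; every matrix entry is a product of two
        population weights (γ0² everywhere).
    heterogeneous
        Readout weights drawn from a gamma distribution with mean γ0 and SD
        ``weight_sd``; matrices are exact outer products (precisely balanced).
    permuted
        As heterogeneous, but each neuron's vector of E→I and I→E input
        weights is independently permuted (row sums — the summed input to
        each neuron — are preserved); I→I is left untouched.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.connectivity_mode == "homogeneous":
        w_e = np.full(config.n_e, config.gamma0)
        w_i = np.full(config.n_i, config.gamma0)
    else:
        mean, sd = config.gamma0, config.weight_sd
        shape = (mean / sd) ** 2
        scale = sd * sd / mean
        w_e = rng.gamma(shape, scale, size=config.n_e)
        w_i = rng.gamma(shape, scale, size=config.n_i)
    w_ei = np.outer(w_i, w_e)
    w_ie = np.outer(w_e, w_i)
    w_ii = np.outer(w_i, w_i)
    if config.connectivity_mode == "permuted":
        for row in w_ei:
            rng.shuffle(row)
        for row in w_ie:
            rng.shuffle(row)
    return ConnectivityMatrices(w_e, w_i, w_ei, w_ie, w_ii, mode=config.connectivity_mode)


class DelayedSynapticFilter:
    """Exact recursive realization of the delayed double-exponential synapse.

    Holds one pair of exponential states per postsynaptic neuron plus a
    circular buffer implementing the transmission delay (rounded to the
    grid).  ``step(arrivals)`` advances one time step: ``arrivals`` is the
    vector of synaptic mass injected *now* (it will emerge after the delay),
    and the return value is the current drive in mass/s units — one spike of
    total mass M delivers an integrated drive of exactly M.
    """

    def __init__(self, spec: SynapseKernelSpec, dt: float, n_targets: int):
        self.dt = dt
        self.decay_d = np.exp(-dt / spec.tau_d)
        self.decay_r = np.exp(-dt / spec.tau_r)
        # discrete mass of the unscaled impulse response (geometric sums)
        mass = dt * (1.0 / (1.0 - self.decay_d) - 1.0 / (1.0 - self.decay_r))
        self.scale = 1.0 / mass
        self.delay_bins = int(round(spec.tau_tr / dt))
        self._a = np.zeros(n_targets)
        self._b = np.zeros(n_targets)
        self._buf = np.zeros((max(self.delay_bins, 1), n_targets))
        self._ptr = 0

    def enqueue(self, arrivals: np.ndarray) -> None:
        """Inject synaptic mass for spikes detected in the bin just stepped.

        ``enqueue`` is called after ``step`` within a simulation bin, so mass
        scheduled for ``delay_bins`` later lands ``delay_bins - 1`` reads
        ahead of the advanced pointer; a zero transmission delay feeds the
        filter states directly (its first nonzero output is still one bin
        later, matching the sampled kernel's h(0) = 0).
        """
        if self.delay_bins == 0:
            self._a += arrivals
            self._b += arrivals
        else:
            slot = (self._ptr + self.delay_bins - 1) % self._buf.shape[0]
            self._buf[slot] += arrivals

    def step(self) -> np.ndarray:
        """Advance one bin and return the drive vector (mass/s)."""
        arr = self._buf[self._ptr]
        self._a *= self.decay_d
        self._b *= self.decay_r
        self._a += arr
        self._b += arr
        arr[:] = 0.0
        self._ptr = (self._ptr + 1) % self._buf.shape[0]
        return (self._a - self._b) * self.scale


def _deliver(
    matrix: np.ndarray,
    spiking: np.ndarray,
    failure_prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-target synaptic mass delivered by a set of presynaptic spikes.

    Each (spike, target) delivery independently fails with ``failure_prob``;
    surviving weights are divided by the success probability so the expected
    delivered mass equals the nominal weight.
    """
    cols = matrix[:, spiking]
    if failure_prob > 0.0:
        success = rng.random(cols.shape) >= failure_prob
        cols = cols * success / (1.0 - failure_prob)
    return cols.sum(axis=1)


def simulate_ei_network(
    config: EINetworkConfig,
    stimulus: Stimulus,
    seed: int = 0,
    record_inputs: bool = False,
    record_voltages: bool = False,
    poisson_rates: dict[str, np.ndarray] | None = None,
    connectivity: ConnectivityMatrices | None = None,
) -> SimResult:
    """Forward-Euler integration of the delayed E/I dynamics.

    Excitatory voltages leak towards the feed-forward drive w_i c(t) and are
    hyperpolarized by the convolved I→E drive; inhibitory voltages are driven
    by the convolved E→I drive and hyperpolarized by I→I.  Any number of
    neurons may cross threshold in one bin (synchrony is a real behaviour of
    the delayed network, not an artefact to suppress).  Own-spike resets −β
    are instantaneous.

    ``poisson_rates`` (per-population arrays of target rates) controls the
    rate-matched Poisson substitution; when ``config.poisson_fraction > 0``
    and no rates are given, a reference run of the intact network at the same
    parameters is performed first to measure them.
    """
    if abs(stimulus.dt - config.dt) > 1e-12:
        raise ValueError("stimulus grid step must equal config dt")
    conn = connectivity if connectivity is not None else build_connectivity(config)
    n_e, n_i = config.n_e, config.n_i
    dt, tau = config.dt, config.tau
    leak = dt / tau
    noise_scale = config.sigma * np.sqrt(dt / tau)
    thr_e = 0.5 * (conn.w_e**2 + config.alpha_e + config.beta_e)
    thr_i = 0.5 * (conn.w_i**2 + config.alpha_i + config.beta_i)
    n_samples = stimulus.n_samples
    rng = np.random.default_rng(seed)

    # -- Poisson substitution bookkeeping -----------------------------------
    sub_e = np.zeros(n_e, dtype=bool)
    sub_i = np.zeros(n_i, dtype=bool)
    if config.poisson_fraction > 0.0:
        k_e = int(round(config.poisson_fraction * n_e))
        k_i = int(round(config.poisson_fraction * n_i))
        sub_rng = np.random.default_rng(config.seed + 7919)
        sub_e[sub_rng.choice(n_e, size=k_e, replace=False)] = True
        sub_i[sub_rng.choice(n_i, size=k_i, replace=False)] = True
        if poisson_rates is None and (k_e or k_i):
            ref = simulate_ei_network(
                config.replace(poisson_fraction=0.0),
                stimulus,
                seed=seed + 1_000_003,
                connectivity=conn,
            )
            poisson_rates = {
                "E": ref.raster.per_neuron_rates("E"),
                "I": ref.raster.per_neuron_rates("I"),
            }
    p_spike_e = poisson_rates["E"] * dt if poisson_rates is not None else None
    p_spike_i = poisson_rates["I"] * dt if poisson_rates is not None else None
    thr_e_eff = np.where(sub_e, np.inf, thr_e)
    thr_i_eff = np.where(sub_i, np.inf, thr_i)

    filt_ei = DelayedSynapticFilter(config.kernel, dt, n_i)  # E spikes → I cells
    filt_ie = DelayedSynapticFilter(config.kernel, dt, n_e)  # I spikes → E cells
    filt_ii = DelayedSynapticFilter(config.kernel, dt, n_i)  # I spikes → I cells

    V_e = np.zeros(n_e)
    V_i = np.zeros(n_i)
    xhat_e = 0.0
    xhat_i = 0.0
    readout_e = np.zeros(n_samples)
    readout_i = np.zeros(n_samples)
    if record_inputs:
        exc_in = {"E": np.zeros((n_samples, n_e)), "I": np.zeros((n_samples, n_i))}
        inh_in = {"E": np.zeros((n_samples, n_e)), "I": np.zeros((n_samples, n_i))}
    else:
        exc_in = inh_in = None
    volt_e = np.zeros((n_samples, n_e)) if record_voltages else None
    volt_i = np.zeros((n_samples, n_i)) if record_voltages else None

    ev_bins: list[np.ndarray] = []
    ev_ids: list[np.ndarray] = []
    ev_pop: list[np.ndarray] = []
    c = stimulus.c
    p_fail = config.failure_prob

    for t in range(n_samples - 1):
        drive_ei = filt_ei.step()
        drive_ie = filt_ie.step()
        drive_ii = filt_ii.step()

        ff = conn.w_e * c[t]
        V_e += leak * (ff - V_e) - drive_ie * dt
        V_i += leak * (-V_i) + (drive_ei - drive_ii) * dt
        if config.sigma > 0:
            V_e += noise_scale * rng.standard_normal(n_e)
            V_i += noise_scale * rng.standard_normal(n_i)

        spk_e = V_e > thr_e_eff
        spk_i = V_i > thr_i_eff
        if p_spike_e is not None:
            spk_e |= sub_e & (rng.random(n_e) < p_spike_e)
            spk_i |= sub_i & (rng.random(n_i) < p_spike_i)
        fired_e = np.flatnonzero(spk_e)
        fired_i = np.flatnonzero(spk_i)

        xhat_e -= leak * xhat_e
        xhat_i -= leak * xhat_i
        if fired_e.size:
            V_e[fired_e] -= config.beta_e
            xhat_e += conn.w_e[fired_e].sum()
            filt_ei.enqueue(_deliver(conn.w_ei, fired_e, p_fail, rng))
            ev_bins.append(np.full(fired_e.size, t + 1))
            ev_ids.append(fired_e)
            ev_pop.append(np.full(fired_e.size, "E"))
        if fired_i.size:
            V_i[fired_i] -= config.beta_i
            xhat_i += conn.w_i[fired_i].sum()
            filt_ie.enqueue(_deliver(conn.w_ie, fired_i, p_fail, rng))
            filt_ii.enqueue(_deliver(conn.w_ii, fired_i, p_fail, rng))
            ev_bins.append(np.full(fired_i.size, t + 1))
            ev_ids.append(fired_i)
            ev_pop.append(np.full(fired_i.size, "I"))

        readout_e[t + 1] = xhat_e
        readout_i[t + 1] = xhat_i
        if record_inputs:
            exc_in["E"][t + 1] = ff / tau
            inh_in["E"][t + 1] = -drive_ie
            exc_in["I"][t + 1] = drive_ei
            inh_in["I"][t + 1] = -drive_ii
        if record_voltages:
            volt_e[t + 1] = V_e
            volt_i[t + 1] = V_i
        if (t & 0x3FF) == 0 and (
            not (np.all(np.isfinite(V_e)) and np.all(np.isfinite(V_i)))
            or max(np.abs(V_e).max(), np.abs(V_i).max()) > 1e9
        ):
            raise SimulationError(f"voltage blow-up at t={t * dt:.4f} s")
    if not (np.all(np.isfinite(V_e)) and np.all(np.isfinite(V_i))):
        raise SimulationError("non-finite voltages at end of run")

    if ev_bins:
        bins = np.concatenate(ev_bins)
        order = np.argsort(bins, kind="stable")
        times = stimulus.time[bins[order]]
        ids = np.concatenate(ev_ids)[order]
        pops = np.concatenate(ev_pop)[order]
    else:
        times = np.array([])
        ids = np.array([], dtype=np.int64)
        pops = np.array([], dtype="U6")
    raster = SpikeRaster(times, ids, pops, stimulus.duration, {"E": n_e, "I": n_i})

    voltages = {}
    if record_voltages:
        voltages = {"E": volt_e, "I": volt_i}
    return SimResult(
        raster=raster,
        time=stimulus.time,
        readout_e=readout_e,
        readout_i=readout_i,
        voltages=voltages,
        exc_input=exc_in,
        inh_input=inh_in,
        config=config,
        seed=seed,
        dt=dt,
    )
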