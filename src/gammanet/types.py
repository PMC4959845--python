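"""Shared containers: stimuli, spike rasters, and simulation results.

All simulations run on a uniform time grid with step ``dt``.  Spike events
are stored as parallel arrays (time, neuron index, population label) rather
than per-neuron lists, which keeps rasters cheap to slice and to serialize.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Stimulus", "SpikeRaster", "SimResult"]


@dataclass
class Stimulus:
    """A target trace ``x`` and its command trace ``c`` on a shared grid.

    The target obeys the first-order dynamics ``tau * dx/dt = -x + c``;
    ``c`` is the external command a network receives as feed-forward input,
    ``x`` is what the readout is asked to reconstruct.
    """

    time: np.ndarray
    x: np.ndarray
    c: np.ndarray
    dt: float
    tau: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if not (self.time.shape == self.x.shape == self.c.shape):
            raise ValueError("time, x and c must share one grid")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return self.x.size

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.time, "x": self.x, "c": self.c})


@dataclass
class SpikeRaster:
    """Spike events aligned to the simulation grid.

    ``population`` labels each event 'E', 'I' or 'single' (the one-population
    ideal network).  ``n_neurons`` maps each population label to its size so
    silent neurons are still accounted for in rate statistics.
    """

    times: np.ndarray
    neuron_indices: np.ndarray
    population: np.ndarray
    duration: float
    n_neurons: dict[str, int]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.neuron_indices = np.asarray(self.neuron_indices, dtype=np.int64)
        self.population = np.asarray(self.population, dtype="U6")
        if not (self.times.shape == self.neuron_indices.shape == self.population.shape):
            raise ValueError("event arrays must have equal length")
        if self.times.size and (self.times.min() < 0 or self.times.max() > self.duration):
            raise ValueError("spike times outside [0, duration]")
        for pop in np.unique(self.population):
            if pop not in self.n_neurons:
                raise ValueError(f"population {pop!r} missing from n_neurons")
            n = self.n_neurons[str(pop)]
            idx = self.neuron_indices[self.population == pop]
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"neuron index out of range for population {pop!r}")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def select(self, population: str) -> "SpikeRaster":
        """Sub-raster containing only one population."""
        mask = self.population == population
        return SpikeRaster(
            self.times[mask],
            self.neuron_indices[mask],
            self.population[mask],
            self.duration,
            {population: self.n_neurons[population]},
        )

    def spike_times(self, neuron: int, population: str | None = None) -> np.ndarray:
        mask = self.neuron_indices == neuron
        if population is not None:
            mask &= self.population == population
        return np.sort(self.times[mask])

    def mean_rate(self, population: str | None = None) -> float:
        """Mean firing rate per neuron (spikes/s), counting silent neurons."""
        if population is None:
            n = sum(self.n_neurons.values())
            count = self.n_spikes
        else:
            n = self.n_neurons[population]
            count = int(np.sum(self.population == population))
        if n == 0 or self.duration == 0:
            return 0.0
        return count / (n * self.duration)

    def per_neuron_rates(self, population: str) -> np.ndarray:
        n = self.n_neurons[population]
        mask = self.population == population
        counts = np.bincount(self.neuron_indices[mask], minlength=n)
        return counts / self.duration

    @staticmethod
    def merge(*rasters: "SpikeRaster") -> "SpikeRaster":
        """Concatenate rasters sharing a duration (event-sorted)."""
        duration = rasters[0].duration
        n_neurons: dict[str, int] = {}
        for r in rasters:
            if r.duration != duration:
                raise ValueError("rasters must share duration")
            for k, v in r.n_neurons.items():
                n_neurons[k] = max(n_neurons.get(k, 0), v)
        times = np.concatenate([r.times for r in rasters])
        idx = np.concatenate([r.neuron_indices for r in rasters])
        pop = np.concatenate([r.population for r in rasters])
        order = np.argsort(times, kind="stable")
        return SpikeRaster(times[order], idx[order], pop[order], duration, n_neurons)


@dataclass
class SimResult:
    """Everything a network simulation produced.

    ``readout_e`` is the reconstruction decoded from excitatory (or sole
    population) spikes; ``readout_i`` exists only for the E/I network.
    ``exc_input`` / ``inh_input`` map population label to the per-cell
    depolarizing and hyperpolarizing input traces (voltage-rate units, mV/s),
    recorded when the simulator was asked to.
    """

    raster: SpikeRaster
    time: np.ndarray
    readout_e: np.ndarray
    readout_i: np.ndarray | None = None
    voltages: dict[str, np.ndarray] = field(default_factory=dict)
    exc_input: dict[str, np.ndarray] | None = None
    inh_input: dict[str, np.ndarray] | None = None
    config: Any = None
    seed: int | None = None
    dt: float = 0.0

    @property
    def duration(self) -> float:
        return self.raster.duration
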