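"""Statistics computed from simulations: ISI/CV, population rates, multitaper
spectra, spectrograms, voltage pair statistics, E/I current extraction and
oscillation-cycle peak analysis.

Spectral estimates use the multitaper method built on scipy's DPSS tapers
(time-bandwidth product 4 by default, eigenvalue-weighted periodogram
average).  Peak frequencies are always taken above a floor (default 5 Hz) to
exclude DC and slow drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal

from .types import SimResult, SpikeRaster

__all__ = [
    "ISIStatistics",
    "isi_statistics",
    "population_rate",
    "binned_population_rate",
    "SpectralSummary",
    "power_spectrum",
    "spectrogram",
    "voltage_pair_statistics",
    "extract_currents",
    "detect_peaks",
    "detect_and_pair_peaks",
    "PeakSeries",
]


# --------------------------------------------------------------------------
# Inter-spike intervals


@dataclass
class ISIStatistics:
    """ISI collection with its histogram and coefficient of variation.

    ``cv`` is NaN when the scope holds fewer than two spikes (pooled) or no
    cell has two spikes (per-cell); this is the "undefined marker", not an
    error.
    """

    isis: np.ndarray
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    cv: float
    scope: str


def _cv(isis: np.ndarray) -> float:
    if isis.size < 1 or isis.mean() == 0:
        return float("nan")
    return float(isis.std() / isis.mean())


def isi_statistics(
    raster: SpikeRaster,
    scope: str = "pooled",
    population: str | None = None,
    n_bins: int = 50,
) -> ISIStatistics:
    """Inter-spike-interval statistics, pooled across the population or per cell.

    pooled
        ISIs of the merged spike train of all neurons (the population rhythm).
    per_cell
        ISIs within each neuron's own train; the CV is averaged over cells
        with at least two spikes.
    """
    sub = raster if population is None else raster.select(population)
    if scope == "pooled":
        times = np.sort(sub.times)
        isis = np.diff(times) if times.size >= 2 else np.array([])
        cv = _cv(isis) if isis.size else float("nan")
    elif scope == "per_cell":
        all_isis = []
        cvs = []
        for pop, n in sub.n_neurons.items():
            for i in range(n):
                st = sub.spike_times(i, pop)
                if st.size >= 2:
                    cell_isis = np.diff(st)
                    all_isis.append(cell_isis)
                    cvs.append(_cv(cell_isis))
        isis = np.concatenate(all_isis) if all_isis else np.array([])
        cv = float(np.nanmean(cvs)) if cvs else float("nan")
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if isis.size:
        hist_counts, hist_edges = np.histogram(isis, bins=n_bins)
    else:
        hist_counts, hist_edges = np.array([]), np.array([])
    return ISIStatistics(isis, hist_counts, hist_edges, cv, scope)


# --------------------------------------------------------------------------
# Population rate


def binned_population_rate(
    raster: SpikeRaster, dt: float, population: str | None = None
) -> np.ndarray:
    """Raw per-bin population rate: spikes per bin / (n_neurons · dt), in spikes/s."""
    sub = raster if population is None else raster.select(population)
    n_samples = int(round(sub.duration / dt))
    counts = np.zeros(n_samples)
    if sub.n_spikes:
        bins = np.clip(np.rint(sub.times / dt).astype(int), 0, n_samples - 1)
        np.add.at(counts, bins, 1.0)
    n = sum(sub.n_neurons.values())
    return counts / (max(n, 1) * dt)


def population_rate(
    raster: SpikeRaster,
    cutoff_hz: float,
    dt: float,
    population: str | None = None,
) -> np.ndarray:
    """Smoothed population firing rate (spikes/s per neuron).

    Spike trains are low-pass filtered with a first-order Butterworth filter
    at ``cutoff_hz`` and averaged over neurons; since filtering is linear
    the per-neuron filter commutes with the average.  An empty raster gives a
    zero trace.  The time mean equals the overall mean rate up to filter edge
    effects (the filter has unit DC gain).
    """
    nyquist = 0.5 / dt
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz")
    rate = binned_population_rate(raster, dt, population)
    if not rate.any():
        return rate
    b, a = signal.butter(1, cutoff_hz, btype="low", fs=1.0 / dt)
    return signal.lfilter(b, a, rate)


# --------------------------------------------------------------------------
# Spectral estimation


@dataclass
class SpectralSummary:
    frequencies: np.ndarray
    power: np.ndarray
    peak_frequency: float
    params: dict[str, Any] = field(default_factory=dict)


def power_spectrum(
    trace: np.ndarray,
    dt: float,
    time_bandwidth: float = 4.0,
    min_peak_hz: float = 5.0,
) -> SpectralSummary:
    """Multitaper power spectral density of a (mean-subtracted) trace.

    Uses 2·NW - 1 DPSS tapers with eigenvalue weighting.  The peak frequency
    is the argmax of the PSD above ``min_peak_hz``, excluding DC and slow
    drift.  Total power satisfies a Parseval-style identity with the trace
    variance.
    """
    x = np.asarray(trace, dtype=float)
    if x.size * dt < 1.0:
        raise ValueError("need at least 1 s of samples for a stable spectrum")
    x = x - x.mean()
    n = x.size
    k = max(int(2 * time_bandwidth) - 1, 1)
    tapers, eigvals = signal.windows.dpss(n, time_bandwidth, Kmax=k, return_ratios=True)
    tapers = tapers / np.sqrt(np.sum(tapers**2, axis=1, keepdims=True))  # unit energy
    spectra = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2
    psd = np.average(spectra, axis=0, weights=eigvals) * (2.0 * dt)
    psd[0] /= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, dt)
    above = freqs > min_peak_hz
    peak = float(freqs[above][np.argmax(psd[above])]) if above.any() else float("nan")
    return SpectralSummary(
        freqs,
        psd,
        peak,
        params={"method": "multitaper", "time_bandwidth": time_bandwidth, "n_tapers": k},
    )


def spectrogram(
    trace: np.ndarray,
    dt: float,
    window_ms: float = 60.0,
    smoothing_cutoff_hz: float = 3.0,
    overlap_fraction: float = 0.75,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hamming-window short-time Fourier power, smoothed along time at 3 Hz.

    Returns (times, frequencies, power) with power of shape
    (n_freqs, n_times).  Each frequency row is low-pass filtered with a
    first-order Butterworth filter to stabilize the instantaneous power.
    """
    x = np.asarray(trace, dtype=float)
    nperseg = int(round(window_ms * 1e-3 / dt))
    if nperseg > x.size:
        raise ValueError("window longer than trace")
    noverlap = int(overlap_fraction * nperseg)
    freqs, times, sxx = signal.spectrogram(
        x - x.mean(),
        fs=1.0 / dt,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        mode="psd",
    )
    frame_dt = times[1] - times[0] if times.size > 1 else nperseg * dt
    frame_nyquist = 0.5 / frame_dt
    if 0 < smoothing_cutoff_hz < frame_nyquist:
        b, a = signal.butter(1, smoothing_cutoff_hz, btype="low", fs=1.0 / frame_dt)
        sxx = signal.lfilter(b, a, sxx, axis=1)
    return times, freqs, sxx


def voltage_pair_statistics(
    voltages: np.ndarray,
    dt: float,
    max_pairs: int = 200,
    nperseg: int | None = None,
    seed: int = 0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean zero-lag pairwise correlation and mean coherence spectrum.

    ``voltages`` has shape (n_samples, n_neurons).  Pairs are subsampled to
    ``max_pairs`` for the coherence average when the population is large.
    Returns (mean_correlation, frequencies, mean_coherence).
    """
    v = np.asarray(voltages, dtype=float)
    if v.ndim != 2 or v.shape[1] < 2:
        raise ValueError("need at least 2 voltage traces")
    if np.any(v.std(axis=0) == 0):
        raise ValueError("constant trace: correlation undefined")
    n = v.shape[1]
    corr = np.corrcoef(v.T)
    mean_corr = float(corr[np.triu_indices(n, k=1)].mean())
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    if nperseg is None:
        nperseg = min(v.shape[0], 2048)
    coh_sum = None
    for i, j in pairs:
        freqs, coh = signal.coherence(v[:, i], v[:, j], fs=1.0 / dt, nperseg=nperseg)
        coh_sum = coh if coh_sum is None else coh_sum + coh
    return mean_corr, freqs, coh_sum / len(pairs)


# --------------------------------------------------------------------------
# E/I currents and oscillation-cycle peaks


def extract_currents(
    result: SimResult, membrane_resistance: float = 5.0, population: str = "I"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell excitatory and inhibitory input currents of one population.

    Divides the recorded depolarizing and hyperpolarizing input traces by a
    presumed membrane resistance (5 MΩ by default — the value only rescales
    the axis).  Returns (excitatory, inhibitory) arrays of shape
    (n_samples, n_cells); the inhibitory current is negative.  The default
    population is the inhibitory one: those are the cells whose excitatory
    input (the E→I drive) oscillates with the population rhythm, whereas
    excitatory cells receive a constant feed-forward drive.
    """
    if result.exc_input is None or result.inh_input is None:
        raise ValueError("simulation was run without record_inputs=True")
    if population not in result.exc_input:
        raise ValueError(f"no recorded inputs for population {population!r}")
    return (
        result.exc_input[population] / membrane_resistance,
        result.inh_input[population] / membrane_resistance,
    )


def detect_peaks(trace: np.ndarray, drop_fraction: float = 0.8) -> np.ndarray:
    """Indices of local maxima separated by a sufficient trough.

    A candidate peak is retained only if, between it and the previously
    retained peak, the trace drops below (1 - drop_fraction) of the smaller
    of the two peak amplitudes; otherwise the larger of the two candidates
    survives.  Operates on a non-negative trace (take magnitudes first).
    """
    x = np.asarray(trace, dtype=float)
    cand, _ = signal.find_peaks(x)
    if cand.size == 0:
        return cand
    kept = [cand[0]]
    for idx in cand[1:]:
        prev = kept[-1]
        trough = x[prev : idx + 1].min()
        if trough <= (1.0 - drop_fraction) * min(x[prev], x[idx]):
            kept.append(idx)
        elif x[idx] > x[prev]:
            kept[-1] = idx
    return np.asarray(kept, dtype=int)


@dataclass
class PeakSeries:
    """Paired oscillation-cycle peaks of excitatory and inhibitory currents.

    ``lags_ms`` is (I peak time − E peak time) per pair; positive lags mean
    inhibition follows excitation.  ``cycle_amplitudes`` and
    ``cycle_periods`` pair each E peak's amplitude with the interval to the
    next E peak.
    """

    e_peak_times: np.ndarray
    e_peak_amplitudes: np.ndarray
    i_peak_times: np.ndarray
    i_peak_amplitudes: np.ndarray
    lags_ms: np.ndarray
    paired_amplitudes: np.ndarray  # shape (n_pairs, 2): (E, I) magnitudes
    cycle_amplitudes: np.ndarray
    cycle_periods: np.ndarray


def detect_and_pair_peaks(
    e_current: np.ndarray,
    i_current: np.ndarray,
    dt: float,
    drop_fraction: float = 0.8,
    pair_window_ms: float = 15.0,
) -> PeakSeries:
    """Detect oscillation-cycle peaks in E and I currents and pair them.

    Peaks are local maxima of the current magnitudes passing the trough-drop
    criterion; an E and an I peak are paired when they occur within
    ``pair_window_ms`` of each other.  Candidate pairs are accepted in order
    of increasing time gap with each peak used at most once, which makes the
    pairing symmetric under relabeling E ↔ I (up to the lag sign).
    """
    e_mag = np.abs(np.asarray(e_current, dtype=float))
    i_mag = np.abs(np.asarray(i_current, dtype=float))
    if e_mag.shape != i_mag.shape:
        raise ValueError("traces must be aligned")
    e_idx = detect_peaks(e_mag, drop_fraction)
    i_idx = detect_peaks(i_mag, drop_fraction)
    e_times, i_times = e_idx * dt, i_idx * dt
    window = pair_window_ms * 1e-3

    candidates = [
        (abs(it - et), min(et, it), max(et, it), ei, ii)
        for ei, et in enumerate(e_times)
        for ii, it in enumerate(i_times)
        if abs(it - et) <= window
    ]
    candidates.sort()
    pairs: list[tuple[int, int]] = []
    used_e: set[int] = set()
    used_i: set[int] = set()
    for _, _, _, ei, ii in candidates:
        if ei not in used_e and ii not in used_i:
            pairs.append((ei, ii))
            used_e.add(ei)
            used_i.add(ii)
    pairs.sort()
    lags = np.array([(i_times[ii] - e_times[ei]) * 1e3 for ei, ii in pairs])
    paired_amp = np.array(
        [[e_mag[e_idx[ei]], i_mag[i_idx[ii]]] for ei, ii in pairs]
    ).reshape(-1, 2)
    if e_idx.size >= 2:
        cycle_amp = e_mag[e_idx[:-1]]
        cycle_per = np.diff(e_times)
    else:
        cycle_amp = np.array([])
        cycle_per = np.array([])
    return PeakSeries(
        e_times,
        e_mag[e_idx],
        i_times,
        i_mag[i_idx],
        lags,
        paired_amp,
        cycle_amp,
        cycle_per,
    )
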