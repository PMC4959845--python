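"""Plain-text exports: spike rasters (TSV), traces (CSV), run manifests (JSON)."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import SimResult, SpikeRaster

__all__ = [
    "raster_to_tsv",
    "raster_from_tsv",
    "traces_to_csv",
    "write_manifest",
    "result_summary_frame",
]


def raster_to_tsv(raster: SpikeRaster, path: str | Path) -> None:
    """Write spike events as tab-separated (time_s, neuron_index, population)."""
    df = pd.DataFrame(
        {
            "time_s": raster.times,
            "neuron_index": raster.neuron_indices,
            "population": raster.population,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def raster_from_tsv(path: str | Path, duration: float, n_neurons: dict[str, int]) -> SpikeRaster:
    df = pd.read_csv(path, sep="\t")
    return SpikeRaster(
        df["time_s"].to_numpy(),
        df["neuron_index"].to_numpy(),
        df["population"].to_numpy(dtype="U6"),
        duration,
        n_neurons,
    )


def traces_to_csv(time: np.ndarray, traces: dict[str, np.ndarray], path: str | Path) -> None:
    """Write named traces with a leading time column."""
    df = pd.DataFrame({"time_s": time})
    for name, values in traces.items():
        df[name] = values
    df.to_csv(path, index=False)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(path: str | Path, config, seed: int | None = None, **extra) -> None:
    """Record every run parameter (config + seed + extras) as JSON."""
    payload = {"config": _jsonable(config), "seed": seed}
    payload.update({k: _jsonable(v) for k, v in extra.items()})
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def result_summary_frame(result: SimResult) -> pd.DataFrame:
    """One-row summary of a simulation (rates and spike counts per population)."""
    rows = []
    for pop, n in result.raster.n_neurons.items():
        mask = result.raster.population == pop
        rows.append(
            {
                "population": pop,
                "n_neurons": n,
                "n_spikes": int(mask.sum()),
                "mean_rate_hz": result.raster.mean_rate(pop),
            }
        )
    return pd.DataFrame(rows)
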