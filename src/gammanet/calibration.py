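"""Bias-nulling calibration of the L2 spike costs.

Adding membrane noise (or synaptic failures) changes firing rates and hence
introduces a systematic estimation bias.  The calibration nulls it by
stochastic gradient descent on the two L2 costs: after each simulation chunk
the excitatory cost moves by η·⟨x̂E − x⟩ and the inhibitory cost by
η·⟨x̂I − x̂E⟩ (over-estimation ⇒ firing too much ⇒ raise the cost).  The
spike threshold co-varies automatically with β through T = ½(w² + α + β),
which is what holds firing rates constant across noise levels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .decoding import estimation_bias
from .network import EINetworkConfig, simulate_ei_network
from .types import Stimulus

__all__ = [
    "CalibrationResult",
    "calibrate_costs",
    "save_calibration_table",
    "load_calibration_table",
]


@dataclass
class CalibrationResult:
    """Calibrated costs with the final measured biases and the SGD history."""

    beta_e: float
    beta_i: float
    bias_e: float
    bias_i: float
    n_chunks: int
    converged: bool
    history: list[dict] = field(default_factory=list)

    def apply(self, config: EINetworkConfig) -> EINetworkConfig:
        return config.replace(beta_e=self.beta_e, beta_i=self.beta_i)


def calibrate_costs(
    config: EINetworkConfig,
    stimulus: Stimulus,
    learning_rate: float = 0.5,
    tolerance: float = 0.5,
    max_chunks: int = 50,
    seed: int = 0,
    burn_in: float = 0.5,
) -> CalibrationResult:
    """Null the excitatory and inhibitory estimation biases by SGD on β_E, β_I.

    ``stimulus`` is one constant-target chunk, simulated repeatedly (default
    protocol: 2 s chunks at x = 50).  Chunk i runs with seed ``seed + i``, so
    the procedure is deterministic given (seed, chunk schedule, η).
    Convergence is declared when a chunk measured under the *current* costs
    has both |bias| < tolerance; non-convergence is reported via the flag.
    """
    if stimulus.x.std() > 1e-9:
        raise ValueError("calibration expects a constant-target stimulus")
    if stimulus.duration <= burn_in:
        raise ValueError("stimulus chunk shorter than burn-in")
    beta_e, beta_i = config.beta_e, config.beta_i
    history: list[dict] = []
    converged = False
    bias_e = bias_i = float("nan")
    for chunk in range(max_chunks):
        cfg = config.replace(beta_e=beta_e, beta_i=beta_i)
        result = simulate_ei_network(cfg, stimulus, seed=seed + chunk)
        bias_e = estimation_bias(stimulus.x, result.readout_e, cfg.dt, burn_in)
        bias_i = estimation_bias(result.readout_e, result.readout_i, cfg.dt, burn_in)
        history.append(
            {"chunk": chunk, "beta_e": beta_e, "beta_i": beta_i, "bias_e": bias_e, "bias_i": bias_i}
        )
        if abs(bias_e) < tolerance and abs(bias_i) < tolerance:
            converged = True
            break
        beta_e = max(beta_e + learning_rate * bias_e, 0.0)
        beta_i = max(beta_i + learning_rate * bias_i, 0.0)
    return CalibrationResult(beta_e, beta_i, bias_e, bias_i, len(history), converged, history)


# --------------------------------------------------------------------------
# CSV cache so parameter sweeps are resumable


def save_calibration_table(path: str | Path, rows: list[dict]) -> None:
    """Append calibrated (key, beta_e, beta_i) rows to a CSV cache."""
    path = Path(path)
    fieldnames = ["key", "beta_e", "beta_i", "converged"]
    exists = path.exists()
    with path.open("a", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        if not exists:
            writer.writeheader()
        for row in rows:
            writer.writerow({k: row[k] for k in fieldnames})


def load_calibration_table(path: str | Path) -> dict[str, dict]:
    """Load a calibration cache keyed by the sweep point identifier."""
    path = Path(path)
    if not path.exists():
        return {}
    out: dict[str, dict] = {}
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["key"]] = {
                "beta_e": float(row["beta_e"]),
                "beta_i": float(row["beta_i"]),
                "converged": row["converged"] in ("True", "true", "1"),
            }
    return out
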