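"""Target/command signal generation.

Targets are either constant or low-pass-filtered white noise (first-order
Butterworth, causal), affinely rescaled to an exact sample mean and SD.
The command trace ``c = τ dx/dt + x`` is recovered by forward differences,
which makes forward-Euler integration of ``τ dx/dt = -x + c`` reproduce the
target exactly on the grid.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .types import Stimulus

__all__ = [
    "constant_target",
    "filtered_noise_target",
    "command_from_target",
    "stimulus_from_target",
]

#: Constant target amplitudes used across the standard experiments: the
#: 3-neuron toy runs at x = 4; the E/I network at x = 50 (with 35/65 as the
#: low/high amplitude variants) and the discrimination task centred on 48.
CONSTANT_AMPLITUDES = {
    "toy": 4.0,
    "default": 50.0,
    "low": 35.0,
    "high": 65.0,
    "discrimination_centre": 48.0,
}


def command_from_target(x: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Invert the target dynamics: c = τ dx/dt + x (forward differences).

    The derivative at the last sample is copied from the penultimate one.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    dx = np.empty_like(x)
    dx[:-1] = np.diff(x) / dt
    dx[-1] = dx[-2]
    return tau * dx + x


def stimulus_from_target(x: np.ndarray, tau: float, dt: float, **meta) -> Stimulus:
    """Wrap a target trace into a Stimulus, deriving the command trace."""
    x = np.asarray(x, dtype=float)
    time = np.arange(x.size) * dt
    return Stimulus(time=time, x=x, c=command_from_target(x, tau, dt), dt=dt, tau=tau, meta=meta)


def constant_target(amplitude: float, duration: float, dt: float, tau: float = 0.1) -> Stimulus:
    """Constant target x ≡ amplitude (so c ≡ amplitude as well)."""
    n = int(round(duration / dt))
    if n < 2:
        raise ValueError("duration must cover at least 2 samples")
    x = np.full(n, float(amplitude))
    return stimulus_from_target(x, tau, dt, kind="constant", amplitude=amplitude)


def filtered_noise_target(
    cutoff_hz: float,
    duration: float,
    dt: float,
    mean: float = 3.0,
    sd: float = 1.0,
    filter_order: int = 1,
    tau: float = 0.1,
    seed: int = 0,
) -> Stimulus:
    """Low-pass-filtered white noise with exact sample mean and SD.

    White Gaussian noise on the grid is passed through a causal Butterworth
    low-pass filter of the given order and cutoff, then the realized sample
    is affinely standardized so that ``x.mean() == mean`` and
    ``x.std() == sd`` exactly.  ``sd = 0`` yields a constant trace.
    """
    nyquist = 0.5 / dt
    if cutoff_hz <= 0 or cutoff_hz >= nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    n = int(round(duration / dt))
    if n < 2:
        raise ValueError("duration must cover at least 2 samples")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n)
    b, a = signal.butter(filter_order, cutoff_hz, btype="low", fs=1.0 / dt)
    y = signal.lfilter(b, a, noise)
    y_sd = y.std()
    if sd == 0.0 or y_sd == 0.0:
        x = np.full(n, float(mean))
    else:
        x = mean + sd * (y - y.mean()) / y_sd
    return stimulus_from_target(
        x, tau, dt, kind="filtered_noise", cutoff_hz=cutoff_hz, mean=mean, sd=sd, seed=seed
    )
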