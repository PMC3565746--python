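"""Synthetic count-valued oscillatory signals for validating the period analysis.

These fixtures share the simulator's domain — non-negative integer copy
numbers on a uniform time grid, packaged as :class:`~hes1rdme.simulate.Trajectory`
objects and writable in the same CSV dialect — so the wavelet estimator can
be exercised against known ground truth (period, amplitude, optional linear
period drift, Gaussian noise) without running the stochastic model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import ConfigurationError
from .model import PF, PROTEIN, SPECIES
from .simulate import Trajectory

__all__ = ["SignalSpec", "generate"]


@dataclass(frozen=True)
class SignalSpec:
    """Ground-truth description of a synthetic oscillation.

    ``baseline + amplitude * sin(phase(t)) + N(0, noise_sd)``, rounded to
    non-negative integers.  ``chirp`` (min per min) drifts the instantaneous
    period linearly: ``period(t) = period + chirp * t``; the phase is the
    integral of the instantaneous frequency so the drift is exact.
    """

    period: float = 200.0
    amplitude: float = 100.0
    baseline: float = 300.0
    noise_sd: float = 0.0
    horizon: float = 1200.0
    dt: float = 1.0
    seed: Optional[int] = None
    chirp: float = 0.0

    def __post_init__(self):
        if self.period <= 0 or self.dt <= 0 or self.horizon <= 0:
            raise ConfigurationError("period, dt and horizon must be positive")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ConfigurationError("amplitude and noise_sd must be >= 0")
        if self.baseline < self.amplitude:
            raise ConfigurationError(
                "baseline must be >= amplitude so counts stay non-negative"
            )
        if self.chirp < 0:
            raise ConfigurationError("chirp must be >= 0")


def generate(spec: SignalSpec) -> Trajectory:
    """Generate the synthetic series as a protein-channel trajectory."""
    n = int(round(spec.horizon / spec.dt))
    t = np.arange(n + 1) * spec.dt
    if spec.chirp == 0.0:
        phase = 2 * np.pi * t / spec.period
    else:
        phase = (2 * np.pi / spec.chirp) * np.log1p(spec.chirp * t / spec.period)
    rng = np.random.default_rng(spec.seed)
    y = spec.baseline + spec.amplitude * np.sin(phase)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    counts = np.maximum(np.rint(y), 0).astype(np.int64)
    totals = np.zeros((len(t), len(SPECIES)), dtype=np.int64)
    totals[:, PROTEIN] = counts
    totals[:, PF] = 1
    return Trajectory(
        times=t,
        totals=totals,
        seed=int(spec.seed) if spec.seed is not None else -1,
        params={"synthetic_signal": True, **{k: getattr(spec, k) for k in (
            "period", "amplitude", "baseline", "noise_sd", "horizon", "dt", "chirp")}},
    )
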