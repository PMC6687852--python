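"""Stochastic differential-equation gating for I_Ks, I_Kr, I_to and I_CaL.

The open probability x of a Hodgkin-Huxley gate follows

    dx = (x_inf - x)/tau_x dt + sqrt((x_inf + (1 - 2 x_inf) x)/(tau_x N)) dw

where N is the number of channels of that species and w a Wiener process;
the diffusion term vanishes as N grows, recovering the deterministic gate.
Channel numbers scale with the same conductance factor as the current they
carry, N_j = theta_j * N_j_nominal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import NOMINAL_CHANNEL_COUNTS, STOCH_CURRENTS


@dataclass(frozen=True)
class ChannelCensus:
    """Per-current channel counts of one virtual cell."""

    Ks: int
    Kr: int
    to: int
    CaL: int

    def __post_init__(self):
        for cur in STOCH_CURRENTS:
            if getattr(self, cur) < 1:
                raise ValueError(f"channel count for {cur} must be >= 1")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in STOCH_CURRENTS], dtype=float)


@dataclass
class GateNoiseConfig:
    """Which currents carry gating noise, step size and seeding policy."""

    currents: tuple = STOCH_CURRENTS
    dt: float = 0.02           # ms
    seed: int = 0
    clamp: str = "unit-interval"   # gates clipped to [0, 1] after each step

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        unknown = set(self.currents) - set(STOCH_CURRENTS)
        if unknown:
            raise ValueError(f"no stochastic gating for currents: {sorted(unknown)}")


def em_gate_step(x, x_inf, tau_x, n_channels, dt, z):
    """One Euler-Maruyama update of a gate's open probability.

    Drift is the explicit-Euler relaxation toward ``x_inf``; the diffusion
    coefficient is sqrt((x_inf + (1 - 2 x_inf) x)/(tau_x N)), with the
    radicand clipped at zero (it can turn slightly negative after the [0,1]
    clamp).  The result is clamped back to [0, 1].
    """
    x = np.asarray(x, dtype=float)
    for nm, val in (("x", x), ("x_inf", x_inf), ("tau_x", tau_x),
                    ("N", n_channels), ("dt", dt), ("z", z)):
        if not np.all(np.isfinite(val)):
            raise ValueError(f"non-finite input {nm}")
    if np.any(tau_x <= 0) or np.any(np.asarray(n_channels) < 1):
        raise ValueError("require tau_x > 0 and N >= 1")
    drift = dt * (x_inf - x) / tau_x
    rad = np.maximum(0.0, (x_inf + (1.0 - 2.0 * x_inf) * x) / (tau_x * n_channels))
    x_new = x + drift + np.sqrt(rad) * math.sqrt(dt) * z
    return np.clip(x_new, 0.0, 1.0)


def channel_counts(theta, nominal_counts=None) -> ChannelCensus:
    """Channel census of a cell: N_j = round(theta_j * N_j_nominal), floor 1."""
    nominal = dict(NOMINAL_CHANNEL_COUNTS if nominal_counts is None else nominal_counts)
    # the four stochastic currents are the first four theta components
    th_arr = theta.as_array()[:4] if hasattr(theta, "as_array") \
        else np.asarray(theta, dtype=float)[:4]
    counts = {}
    for k, cur in enumerate(STOCH_CURRENTS):
        n_nom = nominal[cur]
        if n_nom < 1:
            raise ValueError(f"nominal count for {cur} must be >= 1")
        n = int(round(th_arr[k] * n_nom))
        if n < 1:
            warnings.warn(
                f"theta_{cur} so small the channel count floors at 1 "
                "(the current itself is near zero, so its noise is inert)")
            n = 1
        counts[cur] = n
    return ChannelCensus(**counts)
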