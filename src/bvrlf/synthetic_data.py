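"""Synthetic stand-ins mirroring the statistical structure of the study data.

These generators emulate (a) beat series like the human activation-recovery
interval recordings — a linear trend, a 0.1 Hz oscillation and beat-to-beat
noise; (b) cohorts of conductance vectors with known linear measure weights
and logistic event labels, used as ground truth for the relevance and
canonical-correlation machinery; and (c) voltage-trace fixtures with known
event counts.  Everything is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.signal import lfilter
from scipy.stats import qmc


@dataclass(frozen=True)
class SeriesSpec:
    """One synthetic APD/ARI beat series (sampling rate: 1 beat/s)."""

    length: int = 120
    mean_ms: float = 250.0
    slope_ms_per_beat: float = 0.0
    lf_amp_ms: float = 0.0
    lf_freq_hz: float = 0.1
    lf_phase: float = 0.0
    noise_sd_ms: float = 0.0
    ar2_coeffs: tuple | None = None   # optional AR(2) coloring of the noise
    seed: int = 0

    def __post_init__(self):
        if self.length < 1 or self.noise_sd_ms < 0:
            raise ValueError("length >= 1 and noise SD >= 0 required")


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic population: X ~ LHS on [0,2]^8, y linear, z logistic."""

    n_cells: int = 200
    weights: tuple = (0.0, -3.0, 0.0, -2.0, -1.0, 0.0, 0.0, 0.0)
    intercept: float = 0.0
    noise_sd: float = 0.3
    logit_weights: tuple = (0.0, -2.5, 0.0, 1.5, -1.5, 0.0, 0.0, 0.0)
    logit_intercept: float = 0.0
    seed: int = 0


def gen_apd_series(spec: SeriesSpec) -> np.ndarray:
    """APD(l) = mean + slope*l + A*sin(2 pi f l + phi) + noise(l), in ms."""
    rng = np.random.default_rng(spec.seed)
    l = np.arange(spec.length, dtype=float)
    x = (spec.mean_ms + spec.slope_ms_per_beat * l
         + spec.lf_amp_ms * np.sin(2.0 * np.pi * spec.lf_freq_hz * l
                                   + spec.lf_phase))
    if spec.noise_sd_ms > 0:
        eps = rng.normal(0.0, spec.noise_sd_ms, size=spec.length)
        if spec.ar2_coeffs is not None:
            a1, a2 = spec.ar2_coeffs
            eps = lfilter([1.0], [1.0, -a1, -a2], eps)
        x = x + eps
    return x


def gen_relevance_cohort(spec: CohortSpec):
    """(X, y, z, truth): features, linear measure, event labels, ground truth.

    If the logistic labels come out degenerate (all 0 or all 1) the
    intercept is nudged toward balance and the draw repeated.
    """
    rng = np.random.default_rng(spec.seed)
    sampler = qmc.LatinHypercube(d=8, seed=rng.integers(2 ** 31 - 1))
    x = qmc.scale(sampler.random(spec.n_cells), 0.0, 2.0)
    w = np.asarray(spec.weights, dtype=float)
    y = spec.intercept + x @ w
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n_cells)
    v = np.asarray(spec.logit_weights, dtype=float)
    b = spec.logit_intercept
    for attempt in range(20):
        # center the linear predictor so prevalence stays interior
        eta = b + (x - x.mean(axis=0)) @ v
        pz = 1.0 / (1.0 + np.exp(-eta))
        z = (rng.random(spec.n_cells) < pz).astype(int)
        if 0 < z.sum() < spec.n_cells:
            break
        import warnings
        warnings.warn("degenerate event prevalence; adjusting intercept")
        b += 0.5 if z.sum() == 0 else -0.5
    truth = {"weights": w, "logit_weights": v, "intercept": spec.intercept,
             "logit_intercept": b}
    return x, y, z, truth


def _ap_like(t_ms, apd_ms=300.0, v_rest=-85.0, v_peak=35.0):
    """Piecewise AP-shaped pulse: fast upstroke, plateau decay, repolarization."""
    v = np.full_like(t_ms, v_rest, dtype=float)
    up = 2.0
    plateau_end = 0.55 * apd_ms
    for i, t in enumerate(t_ms):
        if t < 0:
            continue
        if t < up:
            v[i] = v_rest + (v_peak - v_rest) * t / up
        elif t < plateau_end:
            v[i] = v_peak - 25.0 * (t - up) / (plateau_end - up)
        elif t < apd_ms:
            frac = (t - plateau_end) / (apd_ms - plateau_end)
            v[i] = (v_peak - 25.0) + (v_rest - (v_peak - 25.0)) * frac
        # else rest
    return v


def gen_event_trace_fixtures(dt_ms: float = 1.0, cl_ms: float = 1000.0) -> dict:
    """Voltage-trace fixtures with known event counts.

    Returns {name: (t_ms, v_mv, stim_times_ms, expected)} where ``expected``
    is a dict of the event counts a detector must report.
    """
    n = int(round(2 * cl_ms / dt_ms))
    t = dt_ms * np.arange(n)
    stims = np.array([0.0, cl_ms])
    out = {}

    def beat_pair():
        return _ap_like(np.mod(t, cl_ms))

    # clean pair of beats
    out["clean"] = (t, beat_pair(), stims,
                    {"eads": 0, "ead_bursts": 0, "spontaneous_beats": 0})

    def add_bump(v, t0, width=30.0, height=8.0):
        """Sine bump on the repolarization ramp of the first beat."""
        mask = (t >= t0) & (t < t0 + width)
        v = v.copy()
        v[mask] += height * np.sin(np.pi * (t[mask] - t0) / width)
        return v

    # one 8 mV secondary depolarization from a -20 mV plateau shelf
    v = beat_pair()
    shelf = (t >= 185.0) & (t < 260.0)
    v[shelf] = -20.0
    ramp = (t >= 260.0) & (t < 320.0)
    v[ramp] = -20.0 + (-85.0 + 20.0) * (t[ramp] - 260.0) / 60.0
    v = add_bump(v, 200.0, width=40.0)
    out["single_ead"] = (t, v, stims,
                         {"eads": 1, "ead_bursts": 0, "spontaneous_beats": 0})

    # a held depolarized shelf carrying three distinct bumps -> EAD burst
    v = beat_pair()
    shelf = (t >= 170.0) & (t < 320.0)
    v[shelf] = -15.0
    ramp = (t >= 320.0) & (t < 380.0)
    v[ramp] = -15.0 + (-85.0 + 15.0) * (t[ramp] - 320.0) / 60.0
    for t0 in (180.0, 230.0, 280.0):
        v = add_bump(v, t0, width=35.0)
    out["ead_burst"] = (t, v, stims,
                        {"eads": 3, "ead_bursts": 1, "spontaneous_beats": 0})

    # unstimulated full upstroke between the paced beats
    v = beat_pair()
    mask = (t >= 600.0) & (t < 900.0)
    v[mask] = _ap_like(t[mask] - 600.0, apd_ms=250.0)
    out["spontaneous"] = (t, v, stims,
                          {"eads": 0, "ead_bursts": 0, "spontaneous_beats": 1})

    # repolarization failure: V hangs at plateau until the next stimulus
    v = beat_pair()
    hang = (t >= 150.0) & (t < cl_ms)
    v[hang] = 0.0
    out["repol_failure"] = (t, v, stims, {"repol_failure_beat": 0})
    return out
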