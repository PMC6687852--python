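"""Beat-to-beat variability of repolarization (BVR) measures.

All measures are evaluated on the last L beats of a condition (L = 120 by
default).  m_SD is the sample standard deviation of APD; m_STV the mean
perpendicular Poincare-plot distance of successive APD pairs averaged over
sliding windows of L_win = 30 beats; m_NSD and m_NSTV are the squared
ratios of those quantities to the mean APD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

L_DEFAULT = 120
L_WIN_DEFAULT = 30


@dataclass(frozen=True)
class VariabilityMeasures:
    m_sd: float        # ms
    m_nsd: float       # dimensionless
    m_stv: float       # ms
    m_nstv: float      # dimensionless
    mean_apd: float    # ms
    t1_mean: float     # ms (nan if APD50 not supplied)
    window: int = L_DEFAULT
    stv_window: int = L_WIN_DEFAULT


def triangulation(apd90, apd50):
    """AP triangulation T1 = APD90 - APD50 (ms)."""
    apd90 = np.asarray(apd90, dtype=float)
    apd50 = np.asarray(apd50, dtype=float)
    if np.any(apd90 < apd50):
        raise ValueError("APD90 must be >= APD50")
    out = apd90 - apd50
    return out if out.ndim else float(out)


def compute_bvr(apd90, apd50=None, window: int = L_DEFAULT,
                stv_window: int = L_WIN_DEFAULT,
                stv_denominator: str = "sqrt2") -> VariabilityMeasures:
    """BVR measures on the last ``window`` beats of an APD series.

    ``stv_denominator`` selects the per-window normalization of the
    short-term variability sum: ``"sqrt2"`` (perpendicular distance to the
    Poincare identity line, (L_win - 1) * sqrt(2)) or ``"2"`` (the literal
    (L_win - 1) * 2).
    """
    apd90 = np.asarray(apd90, dtype=float)
    if apd90.size < window:
        raise ValueError(f"need at least {window} beats, got {apd90.size}")
    bad = np.nonzero(~np.isfinite(apd90[-window:]))[0]
    if bad.size:
        raise ValueError(f"invalid beats in analysis window at {bad.tolist()}")
    x = apd90[-window:]
    mean_apd = float(np.mean(x))
    m_sd = float(np.std(x, ddof=1))
    m_nsd = m_sd ** 2 / mean_apd ** 2

    if stv_denominator == "sqrt2":
        denom = (stv_window - 1) * np.sqrt(2.0)
    elif stv_denominator == "2":
        denom = (stv_window - 1) * 2.0
    else:
        raise ValueError("stv_denominator must be 'sqrt2' or '2'")
    absdiff = np.abs(np.diff(x))
    n_windows = window - stv_window + 1
    # sliding sum of |APD(i+1) - APD(i)| over windows of stv_window beats
    csum = np.concatenate([[0.0], np.cumsum(absdiff)])
    window_sums = csum[stv_window - 1:] - csum[:n_windows]
    m_stv = float(np.mean(window_sums / denom))
    m_nstv = m_stv ** 2 / mean_apd ** 2

    if apd50 is not None:
        apd50 = np.asarray(apd50, dtype=float)
        t1 = float(np.mean(triangulation(apd90[-window:], apd50[-window:])))
    else:
        t1 = float("nan")
    return VariabilityMeasures(m_sd, m_nsd, m_stv, m_nstv, mean_apd, t1,
                               window, stv_window)
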