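"""Autoregressive spectral analysis of APD beat series.

The last L = 120 beats are linearly detrended; an AR model is fitted by
Yule-Walker with the order chosen in [ceil(L/3), floor(L/2)] to minimize
the Gaussian AIC among orders whose residuals pass a Ljung-Box whiteness
test; the power spectral density follows from the AR coefficients at a
1 beat/s sampling rate.  LF power m_PLF integrates the PSD over
[0.04, 0.15] Hz; m_NPLF normalizes it by the power in [0.04, 0.5] Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from statsmodels.regression.linear_model import yule_walker
from statsmodels.stats.diagnostic import acorr_ljungbox

L_DEFAULT = 120
LF_BAND = (0.04, 0.15)   # Hz
TOTAL_BAND = (0.04, 0.5)  # Hz
PSD_GRID_HZ = 0.0005
LJUNGBOX_LAGS = 20
WHITENESS_ALPHA = 0.05


@dataclass
class SpectralMeasures:
    m_plf: float                 # ms^2
    m_nplf: float                # dimensionless in [0, 1]
    ar_order: int
    aic: dict = field(default_factory=dict)          # order -> AIC
    whiteness_p: float = float("nan")
    freqs: np.ndarray | None = None
    psd: np.ndarray | None = None
    whiteness_fallback: bool = False


def ar_psd(rho, sigma2, freqs, fs=1.0):
    """One-sided AR power spectral density at the given frequencies.

    ``rho`` are Yule-Walker coefficients of x_t = sum rho_k x_{t-k} + e_t.
    Normalized so that the integral over [0, fs/2] equals the process
    variance (Parseval).
    """
    rho = np.asarray(rho, dtype=float)
    k = np.arange(1, rho.size + 1)
    z = np.exp(-2j * np.pi * np.outer(freqs / fs, k))
    denom = np.abs(1.0 - z @ rho) ** 2
    return 2.0 * sigma2 / fs / denom


def _detrend(x):
    x = np.asarray(x, dtype=float)
    t = np.arange(x.size, dtype=float)
    slope, intercept = np.polyfit(t, x, 1)
    return x - (slope * t + intercept)


def _fit_order(x, order):
    # biased (1/n) autocovariances; the returned innovation variance makes
    # the AR spectrum integrate exactly to the sample variance (Parseval)
    rho, sigma = yule_walker(x, order=order, method="mle", demean=False)
    sigma2 = float(sigma ** 2)
    resid = lfilter(np.concatenate([[1.0], -rho]), [1.0], x)[order:]
    aic = x.size * np.log(max(sigma2, 1e-300)) + 2.0 * order
    lb = acorr_ljungbox(resid, lags=[LJUNGBOX_LAGS], return_df=True)
    pval = float(lb["lb_pvalue"].iloc[0])
    return rho, sigma2, aic, pval


def select_ar_order(detrended, order_range=None):
    """AR order minimizing AIC among whiteness-passing orders.

    Returns (order, {order: aic}, whiteness p-value at the chosen order,
    fallback flag).  If no order passes the Ljung-Box test the global AIC
    minimum is used and flagged.
    """
    x = np.asarray(detrended, dtype=float)
    n = x.size
    if order_range is None:
        order_range = (int(np.ceil(n / 3)), int(np.floor(n / 2)))
    lo, hi = order_range
    aics = {}
    pvals = {}
    for order in range(lo, hi + 1):
        try:
            _, _, aic, pval = _fit_order(x, order)
        except Exception:
            continue
        aics[order] = aic
        pvals[order] = pval
    if not aics:
        raise ValueError("no AR order could be fitted")
    passing = [o for o in aics if pvals[o] > WHITENESS_ALPHA]
    fallback = not passing
    pool = passing if passing else list(aics)
    best = min(pool, key=lambda o: aics[o])
    return best, aics, pvals[best], fallback


def compute_lf_measures(apd90, window: int = L_DEFAULT, fs: float = 1.0,
                        order_range=None, keep_psd: bool = False) -> SpectralMeasures:
    """LF power measures of the last ``window`` beats of an APD series."""
    x = np.asarray(apd90, dtype=float)
    if x.size < window:
        raise ValueError(f"need at least {window} valid beats, got {x.size}")
    if not np.all(np.isfinite(x[-window:])):
        raise ValueError("invalid beats in analysis window")
    x = _detrend(x[-window:])
    if np.allclose(x, 0.0, atol=1e-12):
        return SpectralMeasures(0.0, 0.0, 0, {}, float("nan"))
    order, aics, pval, fallback = select_ar_order(x, order_range)
    rho, sigma2, _, _ = _fit_order(x, order)
    freqs = np.arange(0.0, 0.5 * fs + PSD_GRID_HZ / 2, PSD_GRID_HZ)
    psd = ar_psd(rho, sigma2, freqs, fs)

    def band_power(f_lo, f_hi):
        m = (freqs >= f_lo) & (freqs <= f_hi)
        return float(np.trapezoid(psd[m], freqs[m]))

    m_plf = band_power(*LF_BAND)
    total = band_power(*TOTAL_BAND)
    m_nplf = m_plf / total if total > 0 else 0.0
    return SpectralMeasures(
        m_plf, m_nplf, order, aics, pval,
        freqs if keep_psd else None, psd if keep_psd else None, fallback)
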