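"""Tests of the autoregressive LF spectral pipeline."""

import numpy as np
import pytest

from bvrlf.lf_spectrum import (
    ar_psd, compute_lf_measures, select_ar_order, _detrend, _fit_order,
)
from bvrlf.synthetic_data import SeriesSpec, gen_apd_series


class TestComputeLfMeasures:
    def test_constant_series_has_zero_lf_power(self):
        m = compute_lf_measures(np.full(120, 250.0))
        assert m.m_plf == 0.0
        assert m.m_nplf == 0.0

    def test_sinusoid_band_power_matches_parseval(self):
        # 5 ms amplitude at 0.1 Hz carries A^2/2 = 12.5 ms^2
        s = gen_apd_series(SeriesSpec(length=120, lf_amp_ms=5.0,
                                      noise_sd_ms=0.5, seed=3))
        m = compute_lf_measures(s, keep_psd=True)
        assert m.m_plf == pytest.approx(12.5, rel=0.20)
        assert 0.08 <= m.freqs[np.argmax(m.psd)] <= 0.12

    def test_total_ar_power_matches_series_variance(self):
        for seed in (1, 5, 9):
            s = gen_apd_series(SeriesSpec(length=120, lf_amp_ms=3.0,
                                          noise_sd_ms=1.0, seed=seed,
                                          ar2_coeffs=(0.4, -0.2)))
            m = compute_lf_measures(s, keep_psd=True)
            total = np.trapezoid(m.psd, m.freqs)
            var = np.var(_detrend(s))
            assert total == pytest.approx(var, rel=0.10)

    def test_white_noise_band_ratio(self):
        # flat spectrum: m_NPLF ~ (0.15-0.04)/(0.5-0.04) = 0.239
        vals = [compute_lf_measures(
            gen_apd_series(SeriesSpec(length=120, noise_sd_ms=1.0,
                                      seed=100 + k))).m_nplf
            for k in range(30)]
        assert np.mean(vals) == pytest.approx(0.239, abs=0.04)

    def test_linear_trend_removed_before_analysis(self):
        s = gen_apd_series(SeriesSpec(length=120, lf_amp_ms=4.0,
                                      noise_sd_ms=0.5, seed=8))
        trended = s + 0.5 * np.arange(120)
        a = compute_lf_measures(s)
        b = compute_lf_measures(trended)
        assert b.m_plf == pytest.approx(a.m_plf, rel=1e-9)

    def test_nplf_bounded_and_plf_bounded_by_total(self):
        s = gen_apd_series(SeriesSpec(length=120, lf_amp_ms=2.0,
                                      noise_sd_ms=1.0, seed=4))
        m = compute_lf_measures(s, keep_psd=True)
        assert 0.0 <= m.m_nplf <= 1.0
        band = (m.freqs >= 0.04) & (m.freqs <= 0.5)
        assert m.m_plf <= np.trapezoid(m.psd[band], m.freqs[band]) + 1e-9

    def test_insufficient_beats_rejected(self):
        with pytest.raises(ValueError):
            compute_lf_measures(np.ones(100))


class TestOrderSelection:
    def test_selected_order_within_prescribed_range(self):
        for seed in range(5):
            s = gen_apd_series(SeriesSpec(length=120, lf_amp_ms=3.0,
                                          noise_sd_ms=1.0, seed=seed))
            order, aics, pval, fallback = select_ar_order(_detrend(s))
            assert 40 <= order <= 60
            assert set(aics) <= set(range(40, 61))

    def test_ar2_coefficients_recovered_at_high_order(self):
        # colored noise from a known AR(2); the first two Yule-Walker
        # coefficients at the selected (high) order stay close to truth
        a1, a2 = 0.5, -0.3
        s = gen_apd_series(SeriesSpec(length=120, noise_sd_ms=1.0,
                                      ar2_coeffs=(a1, a2), seed=21))
        x = _detrend(s)
        order, _, _, _ = select_ar_order(x)
        rho, _, _, _ = _fit_order(x, order)
        assert rho[0] == pytest.approx(a1, abs=0.25)
        assert rho[1] == pytest.approx(a2, abs=0.25)

    def test_selection_is_deterministic(self):
        s = gen_apd_series(SeriesSpec(length=120, lf_amp_ms=3.0,
                                      noise_sd_ms=1.0, seed=2))
        x = _detrend(s)
        assert select_ar_order(x) == select_ar_order(x)


class TestArPsd:
    def test_known_ar1_spectrum(self):
        # AR(1) PSD has a closed form; compare on a coarse grid
        phi, s2 = 0.6, 1.0
        freqs = np.linspace(0.0, 0.5, 11)
        got = ar_psd(np.array([phi]), s2, freqs)
        expected = 2 * s2 / (1 - 2 * phi * np.cos(2 * np.pi * freqs) + phi ** 2)
        assert np.allclose(got, expected)
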