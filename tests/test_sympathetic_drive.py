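"""Tests of forcing waveforms, the phosphorylation surrogate, SACs and disease."""

import numpy as np
import pytest
from scipy.signal import periodogram

from bvrlf.ionic_model import CellState, ConductanceVector, apply_conductance_scaling, ord_rhs
from bvrlf.simulation_engine import run_protocol
from bvrlf.sympathetic_drive import (
    BASELINE, SP, PhosphoState, ProtocolCondition, SACParams,
    disease_modifiers, iso_waveform, phospho_effects, phospho_step,
    sac_current, stretch_waveform,
)


class TestWaveforms:
    @pytest.mark.parametrize("cond,t,expected", [
        (SP, 2.0, 1.0), (SP, 7.0, 0.0), (BASELINE, 2.0, 0.01),
        (BASELINE, 7.0, 0.0), (SP, 12.0, 1.0),
    ])
    def test_iso_square_wave(self, cond, t, expected):
        assert iso_waveform(t, cond) == pytest.approx(expected)

    def test_stretch_range_and_phase(self):
        t = np.linspace(0, 20, 20001)
        for cond, amp in ((SP, 0.10), (BASELINE, 0.01)):
            lam = stretch_waveform(t, cond)
            assert lam.max() == pytest.approx(1.0 + amp, abs=1e-9)
            assert lam.min() == pytest.approx(1.0, abs=1e-9)
            # peak at the midpoint of the ISO-on half-period (t = 2.5 mod 10)
            assert t[np.argmax(lam)] % 10.0 == pytest.approx(2.5, abs=1e-2)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            iso_waveform(-1.0, SP)


class TestPhospho:
    def test_relaxation_to_dose_dependent_target(self):
        st = PhosphoState()
        for _ in range(800):   # 8 s in 10 ms steps
            st = phospho_step(st, 10.0, 10.0)
        # 10 uM >> EC50: f_inf ~ 0.99; CaL substrate (tau 3 s) nearly there
        f_inf = 10.0 / (10.0 + st.ec50_um)
        assert st.fractions[0] > 0.85 * f_inf
        # I_Ks substrate is deliberately slower
        assert st.fractions[1] < st.fractions[0]

    def test_zero_dose_stays_zero(self):
        st = PhosphoState()
        for _ in range(100):
            st = phospho_step(st, 0.0, 1.0)
        assert np.all(st.fractions == 0.0)

    def test_single_step_euler_bound(self):
        st = PhosphoState(fractions=np.full(5, 0.2))
        out = phospho_step(st, 1.0, 5.0)
        f_inf = 1.0 / (1.0 + st.ec50_um)
        bound = 5.0 / (np.minimum(st.tau_phos, st.tau_dephos) * 1000.0) \
            * np.abs(f_inf - st.fractions)
        assert np.all(np.abs(out.fractions - st.fractions) <= bound + 1e-12)

    def test_kinetic_ordering_enforced(self):
        with pytest.raises(ValueError):
            PhosphoState(tau_phos=np.array([30.0, 3.0, 30.0, 3.0, 10.0]))

    def test_effects_identity_midpoint_and_endpoint(self):
        zero = phospho_effects(PhosphoState())
        for mods in zero.values():
            for key, val in mods.items():
                assert val == pytest.approx(0.0 if key.endswith("_mv") else 1.0)
        full = phospho_effects(PhosphoState(fractions=np.ones(5)))
        assert full["PLM"]["nka_knai_mult"] == pytest.approx(0.7)
        half = phospho_effects(PhosphoState(fractions=np.full(5, 0.5)))
        for sub in zero:
            for key in zero[sub]:
                mid = 0.5 * (zero[sub][key] + full[sub][key])
                assert half[sub][key] == pytest.approx(mid)


class TestSac:
    def test_no_stretch_no_current(self):
        ins, ik, tot = sac_current(-20.0, 1.0)
        assert ins == ik == tot == 0.0

    def test_reversal_potential_of_nonspecific_component(self):
        ins, _, _ = sac_current(-10.0, 1.05)
        assert ins == pytest.approx(0.0)

    def test_slack_below_unity(self):
        assert sac_current(-20.0, 0.9) == sac_current(-20.0, 1.0)

    def test_saturation_at_reference_stretch(self):
        a = sac_current(-20.0, 1.10)
        b = sac_current(-20.0, 1.50)
        assert a == b


class TestDisease:
    @pytest.mark.parametrize("level,expected", [
        ("physiological", (1.0, 0.0, 0.0, None)),
        ("mild", (1.5, 0.075, 0.20, None)),
        ("moderate", (2.5, 0.225, 0.60, None)),
        ("severe", (4.0, 0.30, 0.80, 0.01)),
    ])
    def test_modifier_table(self, level, expected):
        d = disease_modifiers(level)
        assert (d.cao_mult, d.kr_block, d.ks_block, d.g_sac_ns) == expected

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            disease_modifiers("terminal")

    def test_block_and_theta_compose_multiplicatively(self):
        # theta_Kr = 0.5 with 30% block equals theta_Kr = 0.35 unblocked
        from bvrlf import _ord_core as core
        st = CellState.resting()
        st.y[0] = -30.0
        st.y[33] = st.y[34] = 0.5
        p1 = apply_conductance_scaling(ConductanceVector(Kr=0.5)).vector
        p1[core.P_KR_BLOCK] = 0.3
        p2 = apply_conductance_scaling(ConductanceVector(Kr=0.35)).vector
        from bvrlf.ionic_model import CellParams
        d1 = ord_rhs(st, 0.0, CellParams(p1))
        d2 = ord_rhs(st, 0.0, CellParams(p2))
        assert np.allclose(d1, d2, rtol=1e-12, atol=1e-15)


@pytest.fixture(scope="module")
def steady():
    from bvrlf.ionic_model import steady_state_pace
    p = apply_conductance_scaling(ConductanceVector())
    return steady_state_pace(p, 1000.0, n_beats=600)


class TestForcedDynamics:
    def test_zero_forcing_keeps_apd_constant(self, steady):
        null = ProtocolCondition("baseline", 0.0, 0.0)
        res = run_protocol(ConductanceVector(), n_beats_per_condition=40,
                           n_realizations=1, seed=0, noise=False,
                           conditions=(null,), init_state=steady["state"],
                           pre_beats=20)
        apd = res.series("baseline", 0).apd90(last=15)
        assert apd.max() - apd.min() < 0.1

    def test_sp_forcing_oscillates_at_one_tenth_hz(self, steady):
        # run long enough for the slow I_Ks phosphorylation to settle, then
        # remove the residual linear trend before reading the periodogram
        res = run_protocol(ConductanceVector(), n_beats_per_condition=120,
                           n_realizations=1, seed=0, noise=False,
                           conditions=(SP,), init_state=steady["state"],
                           pre_beats=10)
        apd = res.series("SP", 0).apd90(last=60)
        t = np.arange(apd.size)
        apd = apd - np.polyval(np.polyfit(t, apd, 1), t)
        freqs, power = periodogram(apd, fs=1.0)
        peak = freqs[np.argmax(power)]
        assert 0.08 <= peak <= 0.12
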