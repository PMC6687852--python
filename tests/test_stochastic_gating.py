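"""Tests of the gating SDE step, channel censuses and noise behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bvrlf.ionic_model import ConductanceVector
from bvrlf.simulation_engine import run_protocol
from bvrlf.sympathetic_drive import BASELINE
from bvrlf.stochastic_gating import (
    ChannelCensus, GateNoiseConfig, channel_counts, em_gate_step,
)


class TestEmGateStep:
    def test_infinite_channel_limit_is_deterministic_euler(self):
        x, x_inf, tau, dt = 0.4, 0.7, 12.0, 0.02
        stepped = em_gate_step(x, x_inf, tau, 1e18, dt, z=3.0)
        euler = x + dt * (x_inf - x) / tau
        assert abs(stepped - euler) < 1e-9

    def test_diffusion_coefficient_at_steady_state(self):
        # at x = x_inf the squared diffusion coefficient reduces to
        # 2 x_inf (1 - x_inf) / (tau N)
        x_inf, tau, n, dt = 0.3, 10.0, 500.0, 1.0
        stepped = em_gate_step(x_inf, x_inf, tau, n, dt, z=1.0)
        increment = stepped - x_inf  # drift is zero here
        expected = np.sqrt(2.0 * x_inf * (1 - x_inf) / (tau * n) * dt)
        assert np.isclose(increment, expected, rtol=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(x=st.floats(0, 1), x_inf=st.floats(0, 1),
           tau=st.floats(0.01, 1e3), n=st.integers(1, 10 ** 9),
           z=st.floats(-6, 6))
    def test_gate_stays_in_unit_interval(self, x, x_inf, tau, n, z):
        out = em_gate_step(x, x_inf, tau, n, 0.02, z)
        assert 0.0 <= out <= 1.0

    @pytest.mark.parametrize("kwargs", [
        {"x": np.nan}, {"tau_x": 0.0}, {"tau_x": -1.0}, {"n_channels": 0},
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        args = {"x": 0.5, "x_inf": 0.5, "tau_x": 1.0, "n_channels": 100,
                "dt": 0.02, "z": 0.0}
        args.update(kwargs)
        with pytest.raises(ValueError):
            em_gate_step(**args)

    def test_stationary_variance_matches_ou_oracle(self):
        # voltage clamp: x_inf, tau fixed.  The linearized SDE is an
        # Ornstein-Uhlenbeck process with stationary variance
        # x_inf (1 - x_inf) / N
        x_inf, tau, n, dt = 0.3, 10.0, 1000.0, 0.02
        rng = np.random.default_rng(12345)
        chains = np.full(2000, x_inf)
        burn = int(5 * tau / dt)
        keep_every = 25
        acc = []
        for step in range(burn + 20000):
            z = rng.standard_normal(chains.size)
            chains = em_gate_step(chains, x_inf, tau, n, dt, z)
            if step >= burn and step % keep_every == 0:
                acc.append(chains.copy())
        var = np.var(np.concatenate(acc))
        expected = x_inf * (1 - x_inf) / n
        assert abs(var - expected) / expected < 0.15


class TestChannelCounts:
    def test_identity_theta(self):
        census = channel_counts(ConductanceVector(),
                                {"Ks": 3000, "Kr": 5000, "to": 8000,
                                 "CaL": 15000})
        assert (census.Ks, census.Kr, census.to, census.CaL) == \
            (3000, 5000, 8000, 15000)

    def test_scaling_and_rounding(self):
        census = channel_counts([0.5, 0.3333, 1.0, 1.0],
                                {"Ks": 4000, "Kr": 3, "to": 10, "CaL": 10})
        assert census.Ks == 2000
        assert census.Kr == 1  # nearest integer floored at 1

    def test_zero_theta_floors_with_warning(self):
        with pytest.warns(UserWarning):
            census = channel_counts([0.0, 1, 1, 1],
                                    {"Ks": 100, "Kr": 100, "to": 100,
                                     "CaL": 100})
        assert census.Ks == 1

    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            ChannelCensus(Ks=0, Kr=1, to=1, CaL=1)


class TestNoiseConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            GateNoiseConfig(dt=0.0)
        with pytest.raises(ValueError):
            GateNoiseConfig(currents=("Na",))


class TestTrajectoryProperties:
    def test_same_seed_bitwise_identical_series(self):
        kwargs = dict(n_beats_per_condition=8, n_realizations=1, seed=5,
                      pre_beats=2, noise=True, conditions=(BASELINE,))
        a = run_protocol(ConductanceVector(), **kwargs)
        b = run_protocol(ConductanceVector(), **kwargs)
        assert np.array_equal(a.beats["apd90_ms"], b.beats["apd90_ms"])
        c = run_protocol(ConductanceVector(), **{**kwargs, "seed": 6})
        assert not np.array_equal(a.beats["apd90_ms"], c.beats["apd90_ms"])

    def test_apd_noise_shrinks_with_channel_count(self):
        # scaling every census x10 / x100 must damp beat-to-beat APD spread
        sds = []
        for mult in (1, 10, 100):
            counts = {k: v * mult for k, v in
                      {"Ks": 750, "Kr": 1250, "to": 2000, "CaL": 3750}.items()}
            res = run_protocol(ConductanceVector(), n_beats_per_condition=50,
                               n_realizations=1, seed=11, pre_beats=50,
                               noise=True, conditions=(BASELINE,),
                               nominal_counts=counts)
            apd = res.series("baseline", 0).apd90(last=40)
            # successive differences suppress any residual slow trend
            sds.append(np.std(np.diff(apd), ddof=1))
        assert sds[0] > sds[1] > sds[2]
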