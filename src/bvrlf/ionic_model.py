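"""Deterministic epicardial human ventricular cell model with conductance scaling.

The electrophysiology is the ORd epicardial formulation.  A virtual cell is
defined by eight dimensionless factors scaling the maximal conductances /
fluxes of I_Ks, I_Kr, I_to, I_CaL, I_K1, I_Na, I_NaCa and I_NaK; all-ones
reproduces the nominal model exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _ord_core as core
from .constants import THETA_ORDER

DT_DEFAULT = 0.02          # ms, fixed integration step
RECORD_EVERY_DEFAULT = 50  # record V every 50 steps -> 1 ms grid
STIM_AMP = -80.0           # uA/uF
STIM_DUR = 0.5             # ms


@dataclass(frozen=True)
class ConductanceVector:
    """Dimensionless multipliers of the nominal maximal conductances."""

    Ks: float = 1.0
    Kr: float = 1.0
    to: float = 1.0
    CaL: float = 1.0
    K1: float = 1.0
    Na: float = 1.0
    NaCa: float = 1.0
    NaK: float = 1.0

    def __post_init__(self):
        for name in THETA_ORDER:
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"theta_{name} must be finite and >= 0, got {val}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in THETA_ORDER], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ConductanceVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (8,):
            raise ValueError("expected 8 scaling factors")
        return cls(**dict(zip(THETA_ORDER, arr)))


@dataclass
class CellParams:
    """Full parameter vector of one virtual cell.

    ``vector`` is the flat array consumed by the integration kernel; the
    remaining fields record how it was built so runs are auditable.
    """

    vector: np.ndarray
    theta: ConductanceVector = field(default_factory=ConductanceVector)
    disease_level: str = "physiological"
    condition_label: str = "none"

    def copy(self) -> "CellParams":
        return CellParams(self.vector.copy(), self.theta,
                          self.disease_level, self.condition_label)

    def to_json(self) -> str:
        return json.dumps({
            "vector": self.vector.tolist(),
            "theta": asdict(self.theta),
            "disease_level": self.disease_level,
            "condition_label": self.condition_label,
        })

    @classmethod
    def from_json(cls, s: str) -> "CellParams":
        d = json.loads(s)
        return cls(np.array(d["vector"], dtype=float),
                   ConductanceVector(**d["theta"]),
                   d["disease_level"], d["condition_label"])


@dataclass
class CellState:
    """Serializable snapshot of the integrator state (bit-exact restart)."""

    y: np.ndarray
    t_ms: float = 0.0

    def copy(self) -> "CellState":
        return CellState(self.y.copy(), self.t_ms)

    def to_json(self) -> str:
        return json.dumps({"y": self.y.tolist(), "t_ms": self.t_ms,
                           "names": list(core.STATE_NAMES)})

    @classmethod
    def from_json(cls, s: str) -> "CellState":
        d = json.loads(s)
        if d.get("names") != list(core.STATE_NAMES):
            raise ValueError("state layout mismatch")
        return cls(np.array(d["y"], dtype=float), float(d["t_ms"]))

    @classmethod
    def resting(cls) -> "CellState":
        return cls(core.initial_state(), 0.0)


def default_param_vector() -> np.ndarray:
    """Kernel parameter vector for the nominal cell, forcing switched off."""
    p = np.zeros(core.NPARAMS)
    p[0:8] = 1.0                 # theta
    p[core.P_CAO_MULT] = 1.0
    p[core.P_GSAC_NS] = 0.006    # nS/pF
    p[core.P_GSAC_K] = 0.003
    p[core.P_E_NS] = -10.0
    p[core.P_LAM_REF] = 1.10
    p[core.P_ISO_ON] = 0.0
    p[core.P_STRETCH_AMP] = 0.0
    p[core.P_FORCE_FREQ] = 0.0
    p[core.P_STIM_AMP] = STIM_AMP
    p[core.P_STIM_DUR] = STIM_DUR
    p[core.P_CL] = 1000.0
    p[core.P_N_KS:core.P_N_CAL + 1] = 1.0e12   # effectively deterministic
    # phosphorylation surrogate kinetics (s); I_Ks deliberately slower
    # than I_CaL so that phasic beta-adrenergic drive produces 0.1 Hz
    # APD oscillations rather than a quasi-static shift
    p[core.P_TAU_PHOS:core.P_TAU_PHOS + 5] = (3.0, 30.0, 30.0, 3.0, 10.0)
    p[core.P_TAU_DEPHOS:core.P_TAU_DEPHOS + 5] = (4.0, 40.0, 40.0, 4.0, 10.0)
    p[core.P_EC50] = 0.1         # uM ISO half-saturation
    p[core.P_HILL] = 1.0
    p[core.P_CAL_PERM_MAX] = 1.8
    p[core.P_CAL_DSHIFT] = 4.0   # mV leftward activation shift at full phosphorylation
    p[core.P_KS_G_MAX] = 3.0
    p[core.P_KS_TAU_FAC] = 0.6
    p[core.P_KNAI_FAC] = 0.7
    p[core.P_RYR_FAC] = 1.4
    p[core.P_TRPN_FAC] = 1.3
    return p


def apply_conductance_scaling(theta: ConductanceVector) -> CellParams:
    """Parameters of the cell whose eight targeted currents are scaled by theta."""
    if not isinstance(theta, ConductanceVector):
        theta = ConductanceVector.from_array(np.asarray(theta))
    p = default_param_vector()
    p[0:8] = theta.as_array()
    return CellParams(p, theta)


def ord_rhs(state: CellState, t_ms: float, params: CellParams,
            stimulus: float = 0.0) -> np.ndarray:
    """Deterministic state derivative (per ms) including external currents."""
    return core.rhs(state.y, t_ms, params.vector, stimulus)


def _beat_biomarkers(v, cl_ms, dt_rec, fractions=(0.9, 0.5)):
    """Biomarkers of the last beat of a recorded trace.

    ``v`` holds one or more beats on a uniform grid of step ``dt_rec`` with
    samples aligned so index 0 is a stimulus instant.
    """
    spb = int(round(cl_ms / dt_rec))
    last = v[-(spb + 1):]
    vrest = last[0]
    vpeak = float(np.max(last))
    ipeak = int(np.argmax(last))
    out = {}
    for frac in fractions:
        thr = vrest + (1.0 - frac) * (vpeak - vrest)
        seg = last[ipeak:]
        below = np.nonzero(seg <= thr)[0]
        if below.size == 0:
            out[frac] = np.nan
            continue
        k = below[0]
        if k == 0:
            out[frac] = ipeak * dt_rec
        else:
            v1, v2 = seg[k - 1], seg[k]
            tcross = (ipeak + k - 1 + (v1 - thr) / (v1 - v2)) * dt_rec
            out[frac] = tcross
    return out.get(0.9, np.nan), out.get(0.5, np.nan), float(vrest), vpeak


def steady_state_pace(params: CellParams, cycle_length_ms: float = 1000.0,
                      n_beats: int = 1000, state: CellState | None = None,
                      dt: float = DT_DEFAULT, min_beats: int = 0,
                      drift_tol_ms: float = 0.1, drift_window: int = 50):
    """Pace deterministically and return last-beat biomarkers.

    Stops early once APD90 drift over ``drift_window`` consecutive beats
    falls below ``drift_tol_ms``.  Returns a dict with apd90, apd50, rmp,
    vpeak (ms / mV), the final :class:`CellState`, a convergence flag and a
    repolarization-failure flag.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    p = params.vector.copy()
    p[core.P_CL] = cycle_length_ms
    st = state.copy() if state is not None else CellState.resting()
    rec = RECORD_EVERY_DEFAULT
    dt_rec = dt * rec
    chunk = drift_window
    done = 0
    converged = False
    apd_prev = None
    v = None
    t0 = st.t_ms
    while done < n_beats:
        nb = min(chunk, n_beats - done)
        v, status = core.run_segment(st.y, p, t0, nb, dt, rec, False, 0)
        t0 += nb * cycle_length_ms
        done += nb
        if status != 0:
            return {"apd90": np.nan, "apd50": np.nan, "rmp": np.nan,
                    "vpeak": np.nan, "state": CellState(st.y, t0),
                    "converged": False, "repol_failure": True,
                    "n_beats_run": done}
        apd90, _, _, _ = _beat_biomarkers(v, cycle_length_ms, dt_rec)
        if (done >= min_beats and apd_prev is not None
                and np.isfinite(apd90) and np.isfinite(apd_prev)):
            if abs(apd90 - apd_prev) < drift_tol_ms and nb == chunk:
                converged = True
                break
        apd_prev = apd90
    apd90, apd50, rmp, vpeak = _beat_biomarkers(v, cycle_length_ms, dt_rec)
    repol_fail = not np.isfinite(apd90)
    return {"apd90": apd90, "apd50": apd50, "rmp": rmp, "vpeak": vpeak,
            "state": CellState(st.y, t0), "converged": converged,
            "repol_failure": repol_fail, "n_beats_run": done}
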