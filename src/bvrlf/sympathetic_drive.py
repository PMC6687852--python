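"""Phasic beta-adrenergic and stretch forcing, phosphorylation surrogate,
stretch-activated channels, and disease-condition modifiers.

Sympathetic drive is modelled as a 0.1 Hz square-wave isoproterenol (ISO)
dose plus a 0.1 Hz raised-cosine stretch-ratio waveform, in phase with each
other (stretch peaks at the midpoint of the ISO-on half-period).  PKA
phosphorylation of I_CaL, I_Ks, phospholemman/NKA, RyR and troponin is a
first-order kinetic surrogate per substrate: fraction f relaxes toward a
saturating function of the ISO dose with substrate-specific time constants,
the I_Ks constants deliberately slower than the I_CaL ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _ord_core as core
from .constants import K_O

#: PKA substrates, in the order used by the kernel state vector
PKA_SUBSTRATES = ("CaL", "Ks", "PLM", "RyR", "TnI")


@dataclass(frozen=True)
class ProtocolCondition:
    """Baseline or sympathetic-provocation (SP) forcing."""

    label: str
    iso_on_um: float
    stretch_amp: float
    freq_hz: float = 0.1

    def __post_init__(self):
        if self.label not in ("baseline", "SP"):
            raise ValueError("label must be 'baseline' or 'SP'")


BASELINE = ProtocolCondition("baseline", iso_on_um=0.01, stretch_amp=0.01)
SP = ProtocolCondition("SP", iso_on_um=1.0, stretch_amp=0.10)


@dataclass
class PhosphoState:
    """Phosphorylation fraction per PKA substrate and its kinetics (s)."""

    fractions: np.ndarray = field(
        default_factory=lambda: np.zeros(len(PKA_SUBSTRATES)))
    tau_phos: np.ndarray = field(
        default_factory=lambda: np.array([3.0, 30.0, 30.0, 3.0, 10.0]))
    tau_dephos: np.ndarray = field(
        default_factory=lambda: np.array([4.0, 40.0, 40.0, 4.0, 10.0]))
    ec50_um: float = 0.1
    hill: float = 1.0

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("phosphorylation fractions must lie in [0, 1]")
        if np.any(self.tau_phos <= 0) or np.any(self.tau_dephos <= 0):
            raise ValueError("time constants must be positive")
        i_cal, i_ks = PKA_SUBSTRATES.index("CaL"), PKA_SUBSTRATES.index("Ks")
        if not (self.tau_phos[i_ks] > self.tau_phos[i_cal]
                and self.tau_dephos[i_ks] > self.tau_dephos[i_cal]):
            raise ValueError("I_Ks kinetics must be slower than I_CaL kinetics")


@dataclass(frozen=True)
class SACParams:
    """Stretch-activated channel parameters (conductances in nS/pF)."""

    g_ns: float = 0.006
    g_k: float = 0.003
    e_ns_mv: float = -10.0
    lam_ref: float = 1.10

    def __post_init__(self):
        if self.g_ns < 0 or self.g_k < 0:
            raise ValueError("SAC conductances must be >= 0")


@dataclass(frozen=True)
class DiseaseCondition:
    """Ca overload + reduced repolarization reserve at a given severity."""

    level: str
    cao_mult: float
    kr_block: float
    ks_block: float
    g_sac_ns: float | None = None   # override for severe disease


_DISEASE_TABLE = {
    "physiological": DiseaseCondition("physiological", 1.0, 0.0, 0.0),
    "mild": DiseaseCondition("mild", 1.5, 0.075, 0.20),
    "moderate": DiseaseCondition("moderate", 2.5, 0.225, 0.60),
    "severe": DiseaseCondition("severe", 4.0, 0.30, 0.80, g_sac_ns=0.01),
}

DISEASE_LEVELS = tuple(_DISEASE_TABLE)


def disease_modifiers(level: str) -> DiseaseCondition:
    try:
        return _DISEASE_TABLE[level]
    except KeyError:
        raise ValueError(
            f"unknown disease level {level!r}; choose from {DISEASE_LEVELS}")


def iso_waveform(t_s, condition: ProtocolCondition):
    """ISO dose (uM) at time t (s): on-dose for the first half-period, else 0."""
    t_s = np.asarray(t_s, dtype=float)
    if np.any(t_s < 0):
        raise ValueError("t must be >= 0")
    period = 1.0 / condition.freq_hz
    dose = np.where(np.mod(t_s, period) < 0.5 * period, condition.iso_on_um, 0.0)
    return dose if dose.ndim else float(dose)


def stretch_waveform(t_s, condition: ProtocolCondition):
    """Stretch ratio lambda(t): raised cosine, min 1, max 1 + amplitude.

    The peak is aligned with the midpoint of the ISO-on half-period so the
    two sympathetic effectors act in phase.
    """
    t_s = np.asarray(t_s, dtype=float)
    if np.any(t_s < 0):
        raise ValueError("t must be >= 0")
    f = condition.freq_hz
    lam = 1.0 + 0.5 * condition.stretch_amp * (
        1.0 - np.cos(2.0 * np.pi * f * t_s + 0.5 * np.pi))
    return lam if lam.ndim else float(lam)


def phospho_step(state: PhosphoState, dose_um: float, dt_ms: float) -> PhosphoState:
    """Advance phosphorylation fractions one explicit-Euler step."""
    if dose_um < 0:
        raise ValueError("dose must be >= 0")
    if dose_um > 0:
        xh = dose_um ** state.hill
        f_inf = xh / (xh + state.ec50_um ** state.hill)
    else:
        f_inf = 0.0
    f = np.asarray(state.fractions, dtype=float)
    tau = np.where(f_inf > f, state.tau_phos, state.tau_dephos) * 1000.0  # s->ms
    f_new = np.clip(f + dt_ms * (f_inf - f) / tau, 0.0, 1.0)
    return replace(state, fractions=f_new)


#: endpoint effects at full phosphorylation (multipliers / shifts);
#: linear interpolation in the fraction f connects them to the identity
PHOSPHO_ENDPOINTS = {
    "CaL": {"permeability_mult": 1.8, "activation_shift_mv": -4.0},
    "Ks": {"conductance_mult": 3.0, "tau_mult": 0.6},
    "PLM": {"nka_knai_mult": 0.7},
    "RyR": {"release_gain_mult": 1.4},
    "TnI": {"ca_affinity_kd_mult": 1.3},
}


def phospho_effects(state: PhosphoState) -> dict:
    """Parameter modifiers at the current phosphorylation fractions.

    Each modifier interpolates linearly between identity (f = 0) and the
    endpoint effect (f = 1).
    """
    f = dict(zip(PKA_SUBSTRATES, np.asarray(state.fractions, dtype=float)))
    out = {}
    for sub, endpoints in PHOSPHO_ENDPOINTS.items():
        mods = {}
        for key, end in endpoints.items():
            identity = 0.0 if key.endswith("_mv") else 1.0
            mods[key] = identity + (end - identity) * f[sub]
        out[sub] = mods
    return out


def sac_current(v_mv, lam, params: SACParams = SACParams(),
                ki_mm: float = 145.0):
    """Stretch-activated currents (uA/uF): nonspecific-cationic, K-selective, total.

    Activation g(lambda) ramps linearly from 0 at lambda = 1 to 1 at the
    reference stretch; the K-selective component carries a sigmoidal outward
    rectification.  lambda < 1 is treated as slack (no current).
    """
    lam = max(float(lam), 1.0)
    g = min(max((lam - 1.0) / (params.lam_ref - 1.0), 0.0), 1.0)
    i_ns = params.g_ns * g * (v_mv - params.e_ns_mv)
    e_k = (8314.0 * 310.0 / 96485.0) * math.log(K_O / ki_mm)
    rect = 1.0 / (1.0 + math.exp(-(v_mv + 10.0) / 30.0))
    i_k = params.g_k * g * rect * (v_mv - e_k)
    return i_ns, i_k, i_ns + i_k


def configure_params(p: np.ndarray, condition: ProtocolCondition,
                     disease: DiseaseCondition,
                     sac: SACParams = SACParams(),
                     phospho: PhosphoState | None = None) -> np.ndarray:
    """Write forcing, SAC and disease settings into a kernel parameter vector."""
    p = p.copy()
    p[core.P_ISO_ON] = condition.iso_on_um
    p[core.P_STRETCH_AMP] = condition.stretch_amp
    p[core.P_FORCE_FREQ] = condition.freq_hz
    p[core.P_CAO_MULT] = disease.cao_mult
    p[core.P_KR_BLOCK] = disease.kr_block
    p[core.P_KS_BLOCK] = disease.ks_block
    p[core.P_GSAC_NS] = disease.g_sac_ns if disease.g_sac_ns is not None else sac.g_ns
    p[core.P_GSAC_K] = sac.g_k
    p[core.P_E_NS] = sac.e_ns_mv
    p[core.P_LAM_REF] = sac.lam_ref
    if phospho is not None:
        p[core.P_TAU_PHOS:core.P_TAU_PHOS + 5] = phospho.tau_phos
        p[core.P_TAU_DEPHOS:core.P_TAU_DEPHOS + 5] = phospho.tau_dephos
        p[core.P_EC50] = phospho.ec50_um
        p[core.P_HILL] = phospho.hill
    return p
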