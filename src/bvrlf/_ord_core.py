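"""Numba core: ORd epicardial dynamics with scaling, forcing and gating noise.

Single code path for deterministic and stochastic runs: gates are advanced
by Rush-Larsen exponential updates, or by the Euler-Maruyama SDE step when
gating noise is enabled for that gate's current; membrane potential,
concentrations and the remaining rate-form states use forward Euler at a
fixed dt (0.02 ms by default).

The parameter vector layout (``P_*`` indices) and state layout
(``STATE_NAMES``) are the package-wide conventions; higher-level modules
build these arrays, this module only consumes them.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .constants import (
    CA_O,
    F_FARADAY as F,
    G_K1,
    G_KB,
    G_KR,
    G_KS,
    G_NA,
    G_NA_L,
    G_NCX,
    G_PCA,
    G_TO,
    K_O,
    NA_O,
    P_CA,
    P_CAB,
    P_NAB,
    P_NAK,
    R_GAS as R,
    T_BODY as T,
)

# ---------------------------------------------------------------------------
# state layout
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1", "Jrelnp", "Jrelp", "CaMKt",
    "fP_CaL", "fP_Ks", "fP_PLM", "fP_RyR", "fP_TnI",
)
NSTATE = len(STATE_NAMES)

# gate-form states (dx/dt = (x_inf - x)/tau)
GATES = np.array(
    [9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23,
     24, 25, 26, 27, 28, 29, 31, 32, 33, 34, 35, 36, 37, 38, 39],
    dtype=np.int64,
)
# channel-census index per gate (-1 = deterministic gate).
# Census order: 0=Ks, 1=Kr, 2=to, 3=CaL.
_stoch = {
    35: 0, 36: 0,                       # xs1, xs2
    33: 1, 34: 1,                       # xrf, xrs
    18: 2, 19: 2, 20: 2, 21: 2, 22: 2, 23: 2,   # a, iF, iS, ap, iFp, iSp
    24: 3, 25: 3, 26: 3, 27: 3, 28: 3, 29: 3, 31: 3, 32: 3,  # CaL HH gates
}
STOCH = np.array([_stoch.get(int(g), -1) for g in GATES], dtype=np.int64)

# ---------------------------------------------------------------------------
# parameter vector layout
# ---------------------------------------------------------------------------

P_TH_KS, P_TH_KR, P_TH_TO, P_TH_CAL, P_TH_K1, P_TH_NA, P_TH_NACA, P_TH_NAK = range(8)
P_CAO_MULT = 8
P_KR_BLOCK = 9
P_KS_BLOCK = 10
P_GSAC_NS = 11
P_GSAC_K = 12
P_E_NS = 13
P_LAM_REF = 14
P_ISO_ON = 15
P_STRETCH_AMP = 16
P_FORCE_FREQ = 17
P_STIM_AMP = 18
P_STIM_DUR = 19
P_CL = 20
P_N_KS = 21
P_N_KR = 22
P_N_TO = 23
P_N_CAL = 24
P_TAU_PHOS = 25      # 25..29: CaL, Ks, PLM, RyR, TnI (seconds)
P_TAU_DEPHOS = 30    # 30..34
P_EC50 = 35
P_HILL = 36
P_CAL_PERM_MAX = 37
P_CAL_DSHIFT = 38
P_KS_G_MAX = 39
P_KS_TAU_FAC = 40
P_KNAI_FAC = 41
P_RYR_FAC = 42
P_TRPN_FAC = 43
NPARAMS = 44

# cell geometry-derived constants
L_CELL = 0.01
RAD_CELL = 0.0011
VCELL = 1000.0 * 3.14 * RAD_CELL * RAD_CELL * L_CELL
AGEO = 2.0 * 3.14 * RAD_CELL * RAD_CELL + 2.0 * 3.14 * RAD_CELL * L_CELL
ACAP = 2.0 * AGEO
VMYO = 0.68 * VCELL
VNSR = 0.0552 * VCELL
VJSR = 0.0048 * VCELL
VSS = 0.02 * VCELL


def initial_state() -> np.ndarray:
    """Published ORd resting initial conditions plus zero phosphorylation."""
    y = np.zeros(NSTATE)
    y[0] = -87.5      # v
    y[1] = 7.0        # nai
    y[2] = 7.0        # nass
    y[3] = 145.0      # ki
    y[4] = 145.0      # kss
    y[5] = 1.0e-4     # cai
    y[6] = 1.0e-4     # cass
    y[7] = 1.2        # cansr
    y[8] = 1.2        # cajsr
    # gates: closed activation, open inactivation
    for name, val in (
        ("m", 0.0), ("hf", 1.0), ("hs", 1.0), ("j", 1.0), ("hsp", 1.0),
        ("jp", 1.0), ("mL", 0.0), ("hL", 1.0), ("hLp", 1.0), ("a", 0.0),
        ("iF", 1.0), ("iS", 1.0), ("ap", 0.0), ("iFp", 1.0), ("iSp", 1.0),
        ("d", 0.0), ("ff", 1.0), ("fs", 1.0), ("fcaf", 1.0), ("fcas", 1.0),
        ("jca", 1.0), ("nca", 0.0), ("ffp", 1.0), ("fcafp", 1.0),
        ("xrf", 0.0), ("xrs", 0.0), ("xs1", 0.0), ("xs2", 0.0), ("xk1", 1.0),
    ):
        y[STATE_NAMES.index(name)] = val
    return y


@njit(cache=True)
def forcing(t_ms, p):
    """ISO dose (uM) and stretch ratio at absolute time t (ms)."""
    freq = p[P_FORCE_FREQ]
    if freq <= 0.0:
        return 0.0, 1.0
    t_s = t_ms * 1.0e-3
    period = 1.0 / freq
    phase = t_s % period
    iso = p[P_ISO_ON] if phase < 0.5 * period else 0.0
    # raised cosine peaking at the midpoint of the ISO-on half-period
    lam = 1.0 + 0.5 * p[P_STRETCH_AMP] * (
        1.0 - math.cos(2.0 * math.pi * freq * t_s + 0.5 * math.pi)
    )
    return iso, lam


@njit(cache=True)
def _eval(y, t_ms, p, ist, xss, tau, dy):
    """Fill gate targets (xss, tau) and rate-form derivatives (dy)."""
    v = y[0]
    nai = y[1]
    nass = y[2]
    ki = y[3]
    kss = y[4]
    cai = y[5]
    cass = y[6]
    cansr = y[7]
    cajsr = y[8]

    nao = NA_O
    cao = CA_O * p[P_CAO_MULT]
    ko = K_O

    frt = F / (R * T)
    vsafe = v if abs(v) > 1.0e-5 else 1.0e-5
    vfrt = vsafe * frt
    vffrt = vsafe * F * frt

    fP_CaL = y[41]
    fP_Ks = y[42]
    fP_PLM = y[43]
    fP_RyR = y[44]
    fP_TnI = y[45]

    # reversal potentials
    ENa = (1.0 / frt) * math.log(nao / nai)
    EK = (1.0 / frt) * math.log(ko / ki)
    EKs = (1.0 / frt) * math.log((ko + 0.01833 * nao) / (ki + 0.01833 * nai))

    # CaMK
    KmCaMK = 0.15
    aCaMK = 0.05
    bCaMK = 0.00068
    CaMKo = 0.05
    KmCaM = 0.0015
    CaMKt = y[40]
    CaMKb = CaMKo * (1.0 - CaMKt) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + CaMKt
    dy[40] = aCaMK * CaMKb * (CaMKb + CaMKt) - bCaMK * CaMKt
    fca_mk = 1.0 / (1.0 + KmCaMK / CaMKa)

    # ---------------- INa ----------------
    mss = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77)
                + 8.552 * math.exp(-(v + 77.42) / 5.955))
    xss[9] = mss
    tau[9] = tm
    hss = 1.0 / (1.0 + math.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285)
                 + 6.149 * math.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * math.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * math.exp((v + 5.730) / 56.66))
    xss[10] = hss
    tau[10] = thf
    xss[11] = hss
    tau[11] = ths
    Ahf = 0.99
    Ahs = 0.01
    h = Ahf * y[10] + Ahs * y[11]
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * math.exp(-(v + 100.6) / 8.281)
                        + 0.3052 * math.exp((v + 0.9941) / 38.45))
    xss[12] = jss
    tau[12] = tj
    hssp = 1.0 / (1.0 + math.exp((v + 89.1) / 6.086))
    xss[13] = hssp
    tau[13] = 3.0 * ths
    hp = Ahf * y[10] + Ahs * y[13]
    xss[14] = jss
    tau[14] = 1.46 * tj
    GNa = G_NA * p[P_TH_NA]
    INa = (GNa * (v - ENa) * y[9] ** 3
           * ((1.0 - fca_mk) * h * y[12] + fca_mk * hp * y[14]))

    # ---------------- INaL ----------------
    mLss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    xss[15] = mLss
    tau[15] = tm
    hLss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    xss[16] = hLss
    tau[16] = 200.0
    hLssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    xss[17] = hLssp
    tau[17] = 600.0
    INaL = (G_NA_L * (v - ENa) * y[15]
            * ((1.0 - fca_mk) * y[16] + fca_mk * y[17]))

    # ---------------- Ito ----------------
    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814)))
    xss[18] = ass
    tau[18] = ta
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    delta_epi = 1.0 - 0.95 / (1.0 + math.exp((v + 70.0) / 5.0))
    tiF = 4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * math.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * math.exp((v + 114.1) / 8.079))
    tiF *= delta_epi
    tiS *= delta_epi
    xss[19] = iss
    tau[19] = tiF
    xss[20] = iss
    tau[20] = tiS
    AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    i_gate = AiF * y[19] + AiS * y[20]
    assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
    xss[21] = assp
    tau[21] = ta
    dti_develop = 1.354 + 1.0e-4 / (math.exp((v - 167.4) / 15.89)
                                    + math.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    xss[22] = iss
    tau[22] = dti_develop * dti_recover * tiF
    xss[23] = iss
    tau[23] = dti_develop * dti_recover * tiS
    ip = AiF * y[22] + AiS * y[23]
    Gto = G_TO * p[P_TH_TO]
    Ito = (Gto * (v - EK)
           * ((1.0 - fca_mk) * y[18] * i_gate + fca_mk * y[21] * ip))

    # ---------------- ICaL / ICaNa / ICaK ----------------
    dshift = p[P_CAL_DSHIFT] * fP_CaL
    dss = 1.0 / (1.0 + math.exp(-(v + 3.940 + dshift) / 4.230))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    xss[24] = dss
    tau[24] = td
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * math.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * math.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * math.exp((v + 5.0) / 6.0))
    xss[25] = fss
    tau[25] = tff
    xss[26] = fss
    tau[26] = tfs
    Aff = 0.6
    Afs = 0.4
    f_gate = Aff * y[25] + Afs * y[26]
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * math.exp(-(v - 4.0) / 7.0)
                         + 0.04 * math.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * math.exp(-v / 3.0)
                           + 0.00012 * math.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    xss[27] = fcass
    tau[27] = tfcaf
    xss[28] = fcass
    tau[28] = tfcas
    fca = Afcaf * y[27] + Afcas * y[28]
    xss[29] = fcass
    tau[29] = 75.0
    xss[31] = fss
    tau[31] = 2.5 * tff
    fp_gate = Aff * y[31] + Afs * y[26]
    xss[32] = fcass
    tau[32] = 2.5 * tfcaf
    fcap = Afcaf * y[32] + Afcas * y[28]
    Kmn = 0.002
    k2n = 1000.0
    km2n = y[29] * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4)
    dy[30] = anca * k2n - y[30] * km2n
    nca = y[30]
    e2v = math.exp(2.0 * vfrt)
    e1v = math.exp(vfrt)
    PhiCaL = 4.0 * vffrt * (cass * e2v - 0.341 * cao) / (e2v - 1.0)
    PhiCaNa = vffrt * (0.75 * nass * e1v - 0.75 * nao) / (e1v - 1.0)
    PhiCaK = vffrt * (0.75 * kss * e1v - 0.75 * ko) / (e1v - 1.0)
    PCa_eff = P_CA * p[P_TH_CAL] * (1.0 + (p[P_CAL_PERM_MAX] - 1.0) * fP_CaL)
    PCap = 1.1 * PCa_eff
    PCaNa = 0.00125 * PCa_eff
    PCaK = 3.574e-4 * PCa_eff
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    d_gate = y[24]
    jca_g = y[29]
    ICaL = ((1.0 - fca_mk) * PCa_eff * PhiCaL * d_gate
            * (f_gate * (1.0 - nca) + jca_g * fca * nca)
            + fca_mk * PCap * PhiCaL * d_gate
            * (fp_gate * (1.0 - nca) + jca_g * fcap * nca))
    ICaNa = ((1.0 - fca_mk) * PCaNa * PhiCaNa * d_gate
             * (f_gate * (1.0 - nca) + jca_g * fca * nca)
             + fca_mk * PCaNap * PhiCaNa * d_gate
             * (fp_gate * (1.0 - nca) + jca_g * fcap * nca))
    ICaK = ((1.0 - fca_mk) * PCaK * PhiCaK * d_gate
            * (f_gate * (1.0 - nca) + jca_g * fca * nca)
            + fca_mk * PCaKp * PhiCaK * d_gate
            * (fp_gate * (1.0 - nca) + jca_g * fcap * nca))

    # ---------------- IKr ----------------
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))
    xss[33] = xrss
    tau[33] = txrf
    xss[34] = xrss
    tau[34] = txrs
    Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    xr = Axrf * y[33] + Axrs * y[34]
    rkr = 1.0 / ((1.0 + math.exp((v + 55.0) / 75.0))
                 * (1.0 + math.exp((v - 10.0) / 30.0)))
    GKr_eff = G_KR * p[P_TH_KR] * (1.0 - p[P_KR_BLOCK])
    IKr = GKr_eff * math.sqrt(ko / 5.4) * xr * rkr * (v - EK)

    # ---------------- IKs ----------------
    xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80)
                          + 0.001292 * math.exp(-(v + 210.0) / 230.0))
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0)
                  + 0.0193 * math.exp(-(v + 66.54) / 31.0))
    ks_tau_scale = 1.0 + (p[P_KS_TAU_FAC] - 1.0) * fP_Ks
    xss[35] = xs1ss
    tau[35] = txs1 * ks_tau_scale
    xss[36] = xs1ss
    tau[36] = txs2 * ks_tau_scale
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs_eff = (G_KS * p[P_TH_KS] * (1.0 - p[P_KS_BLOCK])
               * (1.0 + (p[P_KS_G_MAX] - 1.0) * fP_Ks))
    IKs = GKs_eff * KsCa * y[35] * y[36] * (v - EKs)

    # ---------------- IK1 ----------------
    xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * ko + 144.59)
                                  / (1.5692 * ko + 3.8115)))
    txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36)
                    + math.exp((v + 236.8) / 69.33))
    xss[37] = xk1ss
    tau[37] = txk1
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * ko) / 9.493))
    IK1 = G_K1 * p[P_TH_K1] * math.sqrt(ko) * rk1 * y[37] * (v - EK)

    # ---------------- INaCa ----------------
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    qna = 0.5224
    qca = 0.1670
    hca = math.exp(qca * vfrt)
    hna = math.exp(qna * vfrt)
    Gncx = G_NCX * p[P_TH_NACA]
    KmCaAct = 150.0e-6
    zna = 1.0
    zca = 2.0

    # myoplasmic component
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
    h8 = nao / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + nao / kna1 * (1.0 + nao / kna2)
    h11 = nao * nao / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * cao * kcaon
    k2 = kcaoff
    k3p_ = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p_ + k3pp
    k4p_ = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p_ + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_i = 0.8 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # subspace component
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k4p_ = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p_ + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # ---------------- INaK ----------------
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p = 1899.0
    k3m = 79300.0
    k4p = 639.0
    k4m = 40.0
    Knai0 = 9.073 * (1.0 + (p[P_KNAI_FAC] - 1.0) * fP_PLM)
    Knao0 = 27.78
    delta = -0.1550
    Knai = Knai0 * math.exp(delta * vfrt / 3.0)
    Knao = Knao0 * math.exp((1.0 - delta) * vfrt / 3.0)
    Kki = 0.5
    Kko = 0.3582
    MgADP = 0.05
    MgATP = 9.8
    Kmgatp = 1.698e-7
    H_conc = 1.0e-7
    eP = 4.2
    Khp = 1.698e-7
    Knap = 224.0
    Kxkur = 292.0
    P_ = eP / (1.0 + H_conc / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3) / ((1.0 + nai / Knai) ** 3
                                      + (1.0 + ki / Kki) ** 2 - 1.0)
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (nao / Knao) ** 3) / ((1.0 + nao / Knao) ** 3
                                      + (1.0 + ko / Kko) ** 2 - 1.0)
    a3 = (k3p * (ko / Kko) ** 2) / ((1.0 + nao / Knao) ** 3
                                    + (1.0 + ko / Kko) ** 2 - 1.0)
    b3 = (k3m * P_ * H_conc) / (1.0 + MgATP / Kmgatp)
    a4 = (k4p * MgATP / Kmgatp) / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (ki / Kki) ** 2) / ((1.0 + nai / Knai) ** 3
                                    + (1.0 + ki / Kki) ** 2 - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    zk = 1.0
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    INaK = P_NAK * p[P_TH_NAK] * (zna * JnakNa + zk * JnakK)

    # ---------------- background / minor currents ----------------
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    IKb = G_KB * xkb * (v - EK)
    INab = P_NAB * vffrt * (nai * e1v - nao) / (e1v - 1.0)
    ICab = P_CAB * 4.0 * vffrt * (cai * e2v - 0.341 * cao) / (e2v - 1.0)
    IpCa = G_PCA * cai / (0.0005 + cai)

    # ---------------- stretch-activated channels ----------------
    iso, lam = forcing(t_ms, p)
    g_sac = (lam - 1.0) / (p[P_LAM_REF] - 1.0)
    if g_sac < 0.0:
        g_sac = 0.0
    elif g_sac > 1.0:
        g_sac = 1.0
    Isac_ns = p[P_GSAC_NS] * g_sac * (v - p[P_E_NS])
    rect = 1.0 / (1.0 + math.exp(-(v + 10.0) / 30.0))
    Isac_k = p[P_GSAC_K] * g_sac * rect * (v - EK)

    # ---------------- phosphorylation surrogate ----------------
    hill = p[P_HILL]
    ec50 = p[P_EC50]
    if iso > 0.0:
        xh = iso ** hill
        finf = xh / (xh + ec50 ** hill)
    else:
        finf = 0.0
    for s in range(5):
        fcur = y[41 + s]
        tau_s = p[P_TAU_PHOS + s] if finf > fcur else p[P_TAU_DEPHOS + s]
        dy[41 + s] = (finf - fcur) / (tau_s * 1000.0)  # s -> ms

    # ---------------- SR fluxes ----------------
    bt = 4.75
    a_rel = 0.5 * bt
    ryr_gain = 1.0 + (p[P_RYR_FAC] - 1.0) * fP_RyR
    Jrel_inf = ryr_gain * a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    xss[38] = Jrel_inf
    tau[38] = tau_rel
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = ryr_gain * a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    xss[39] = Jrel_infp
    tau[39] = tau_relp
    Jrel = (1.0 - fca_mk) * y[38] + fca_mk * y[39]

    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    Jleak = 0.0039375 * cansr / 15.0
    Jup = 1.3 * ((1.0 - fca_mk) * Jupnp + fca_mk * Jupp) - Jleak
    Jtr = (cansr - cajsr) / 100.0
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    # ---------------- buffers ----------------
    cmdnmax = 0.05 * 1.3
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005 * (1.0 + (p[P_TRPN_FAC] - 1.0) * fP_TnI)
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8

    # ---------------- balances ----------------
    dy[1] = (-(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab
               + 0.5 * Isac_ns) * ACAP / (F * VMYO)
             + JdiffNa * VSS / VMYO)
    dy[2] = -(ICaNa + 3.0 * INaCa_ss) * ACAP / (F * VSS) - JdiffNa
    dy[3] = (-(Ito + IKr + IKs + IK1 + IKb + ist - 2.0 * INaK
               + Isac_k + 0.5 * Isac_ns) * ACAP / (F * VMYO)
             + JdiffK * VSS / VMYO)
    dy[4] = -ICaK * ACAP / (F * VSS) - JdiffK
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2
                  + trpnmax * kmtrpn / (kmtrpn + cai) ** 2)
    dy[5] = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * ACAP / (2.0 * F * VMYO)
                    - Jup * VNSR / VMYO + Jdiff * VSS / VMYO)
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2
                   + BSLmax * KmBSL / (KmBSL + cass) ** 2)
    dy[6] = Bcass * (-(ICaL - 2.0 * INaCa_ss) * ACAP / (2.0 * F * VSS)
                     + Jrel * VJSR / VSS - Jdiff)
    dy[7] = Jup - Jtr * VJSR / VNSR
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    dy[8] = Bcajsr * (Jtr - Jrel)

    dy[0] = -(INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
              + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab
              + Isac_ns + Isac_k + ist)


@njit(cache=True)
def run_segment(y, p, t0_ms, n_beats, dt, record_every, noise_on, seed):
    """Integrate ``n_beats`` paced beats in place.

    Returns (vrec, status): membrane potential sampled every
    ``record_every`` steps (first sample at t0, last at segment end) and a
    status flag (0 = ok, 1 = numerical blow-up).
    """
    cl = p[P_CL]
    steps_per_beat = int(round(cl / dt))
    stim_steps = int(round(p[P_STIM_DUR] / dt))
    steps = steps_per_beat * n_beats
    nrec = steps // record_every + 1
    vrec = np.empty(nrec)
    if noise_on:
        np.random.seed(seed)
    xss = np.zeros(NSTATE)
    tau = np.ones(NSTATE)
    dy = np.zeros(NSTATE)
    irec = 0
    status = 0
    for k in range(steps):
        t = t0_ms + k * dt
        if k % record_every == 0:
            vrec[irec] = y[0]
            irec += 1
            if not (-300.0 < y[0] < 300.0) or np.isnan(y[0]):
                status = 1
                break
        # stimulus gating by integer step index: exact across restarts
        ist = p[P_STIM_AMP] if (k % steps_per_beat) < stim_steps else 0.0
        _eval(y, t, p, ist, xss, tau, dy)
        for n in range(GATES.size):
            gi = GATES[n]
            ci = STOCH[n]
            if noise_on and ci >= 0:
                x = y[gi]
                ncount = p[P_N_KS + ci]
                drift = dt * (xss[gi] - x) / tau[gi]
                rad = (xss[gi] + (1.0 - 2.0 * xss[gi]) * x) / (tau[gi] * ncount)
                if rad < 0.0:
                    rad = 0.0
                x = x + drift + math.sqrt(rad * dt) * np.random.standard_normal()
                if x < 0.0:
                    x = 0.0
                elif x > 1.0:
                    x = 1.0
                y[gi] = x
            else:
                y[gi] = xss[gi] + (y[gi] - xss[gi]) * math.exp(-dt / tau[gi])
        y[0] += dt * dy[0]
        for ci2 in range(1, 9):
            y[ci2] += dt * dy[ci2]
            if y[ci2] < 1.0e-12:
                y[ci2] = 1.0e-12
        y[30] += dt * dy[30]
        y[40] += dt * dy[40]
        for s in range(41, 46):
            fs_new = y[s] + dt * dy[s]
            if fs_new < 0.0:
                fs_new = 0.0
            elif fs_new > 1.0:
                fs_new = 1.0
            y[s] = fs_new
    if status == 0:
        vrec[nrec - 1] = y[0]
    else:
        for jj in range(irec, nrec):
            vrec[jj] = np.nan
    return vrec, status


def rhs(y, t_ms, p, ist=0.0):
    """Full state derivative dy/dt (1/ms units) at one instant.

    Deterministic right-hand side: gate-form states contribute
    (x_inf - x)/tau; used for fixed-point and component-level checks.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state")
    xss = np.zeros(NSTATE)
    tau = np.ones(NSTATE)
    dy = np.zeros(NSTATE)
    _eval(y, float(t_ms), np.asarray(p, dtype=float), float(ist), xss, tau, dy)
    out = dy.copy()
    for n in range(GATES.size):
        gi = GATES[n]
        out[gi] = (xss[gi] - y[gi]) / tau[gi]
    return out
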