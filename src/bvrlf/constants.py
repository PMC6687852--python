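"""Model constants for the epicardial human ventricular cell model.

All values follow the published O'Hara-Rudy (ORd) dynamic epicardial
formulation.  Conductances are in mS/uF, permeabilities in cm/s,
concentrations in mM, temperature in K.  ``CONSTANTS_VERSION`` tags the
tabulation so serialized runs can assert they were produced against the
same parameter set.
"""

from __future__ import annotations

import json

CONSTANTS_VERSION = "ord-epi-1.0"

# physical constants
R_GAS = 8314.0  # J/(kmol*K)
T_BODY = 310.0  # K
F_FARADAY = 96485.0  # C/mol

# extracellular milieu (mM)
NA_O = 140.0
CA_O = 1.8
K_O = 5.4

# cell geometry (ORd convention)
CELL_LENGTH_CM = 0.01
CELL_RADIUS_CM = 0.0011

# nominal maximal conductances / permeabilities, *including* the
# epicardial scale factors of the published model
G_NA = 75.0
G_NA_L = 0.0075 * 0.6
G_TO = 0.02 * 4.0
P_CA = 0.0001 * 1.2
G_KR = 0.046 * 1.3
G_KS = 0.0034 * 1.4
G_K1 = 0.1908 * 1.2
G_NCX = 0.0008 * 1.1
P_NAK = 30.0 * 0.9
G_KB = 0.003 * 0.6
P_NAB = 3.75e-10
P_CAB = 2.5e-8
G_PCA = 0.0005

#: order of the conductance-scaling factors used throughout the package
THETA_ORDER = ("Ks", "Kr", "to", "CaL", "K1", "Na", "NaCa", "NaK")

#: currents carrying stochastic gating, in channel-census order
STOCH_CURRENTS = ("Ks", "Kr", "to", "CaL")

# Nominal per-current channel counts for the stochastic gating SDE.
# Order-of-magnitude estimates from whole-cell conductance divided by a
# typical single-channel conductance, then scaled once by a single global
# tuning constant so the nominal cell's baseline short-term variability
# falls in the 1-5 ms range.  These are configuration values and may be
# overridden per run.
CHANNEL_COUNT_TUNING = 0.25
NOMINAL_CHANNEL_COUNTS = {
    "Ks": int(3000 * CHANNEL_COUNT_TUNING),
    "Kr": int(5000 * CHANNEL_COUNT_TUNING),
    "to": int(8000 * CHANNEL_COUNT_TUNING),
    "CaL": int(15000 * CHANNEL_COUNT_TUNING),
}


def constants_table() -> dict:
    """Return the full tabulation as a JSON-serializable dict."""
    return {
        "version": CONSTANTS_VERSION,
        "R": R_GAS,
        "T": T_BODY,
        "F": F_FARADAY,
        "nao": NA_O,
        "cao": CA_O,
        "ko": K_O,
        "GNa": G_NA,
        "GNaL": G_NA_L,
        "Gto": G_TO,
        "PCa": P_CA,
        "GKr": G_KR,
        "GKs": G_KS,
        "GK1": G_K1,
        "Gncx": G_NCX,
        "Pnak": P_NAK,
        "GKb": G_KB,
        "PNab": P_NAB,
        "PCab": P_CAB,
        "GpCa": G_PCA,
        "theta_order": list(THETA_ORDER),
        "nominal_channel_counts": dict(NOMINAL_CHANNEL_COUNTS),
    }


def dump_constants(path) -> None:
    with open(path, "w") as fh:
        json.dump(constants_table(), fh, indent=2)
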