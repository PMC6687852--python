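"""Latin Hypercube population of virtual cells and experimental calibration.

Conductance factors are sampled on [0, 2]^8 (±100% around nominal) by
Latin Hypercube Sampling; each candidate is paced to steady state at 1 Hz
and kept only if its AP biomarkers and its APD90 responses to selective
I_Ks / I_Kr / I_K1 block fall within experimentally reported ranges, and it
shows no pro-arrhythmic events at baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .ionic_model import (
    CellParams, ConductanceVector, apply_conductance_scaling,
    steady_state_pace,
)
from .simulation_engine import APTrace, detect_events
from . import _ord_core as core

#: experimentally derived acceptance ranges for 1 Hz steady-state biomarkers
CALIBRATION_BOUNDS = {
    "apd90": (178.1, 442.7),      # ms
    "apd50": (106.6, 349.4),      # ms
    "rmp": (-94.4, -78.5),        # mV
    "vpeak": (7.3, np.inf),       # mV
    "dapd90_iks90": (-54.4, 62.0),    # % change under 90% I_Ks block
    "dapd90_ikr70": (34.25, 91.94),   # % change under 70% I_Kr block
    "dapd90_ik1_50": (-5.26, 14.86),  # % change under 50% I_K1 block
}

#: (theta index, residual conductance factor) per block test
_BLOCK_TESTS = {
    "dapd90_iks90": (0, 0.1),
    "dapd90_ikr70": (1, 0.3),
    "dapd90_ik1_50": (4, 0.5),
}


@dataclass(frozen=True)
class PopulationSpec:
    n_samples: int = 500
    dimension: int = 8
    low: float = 0.0
    high: float = 2.0
    seed: int = 0


@dataclass
class CalibrationReport:
    theta: ConductanceVector
    biomarkers: dict
    criteria: dict            # name -> bool
    baseline_events: bool
    passed: bool
    reason: str = ""
    final_state: object = None


def lhs_sample(spec: PopulationSpec) -> np.ndarray:
    """Latin Hypercube sample: one point per equal-width stratum per column."""
    if spec.n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    sampler = qmc.LatinHypercube(d=spec.dimension, seed=spec.seed)
    unit = sampler.random(spec.n_samples)
    return qmc.scale(unit, spec.low, spec.high)


def evaluate_calibration(theta: ConductanceVector,
                         n_base_beats: int = 1000,
                         n_block_beats: int = 200,
                         check_baseline_events: bool = True,
                         short_circuit: bool = False) -> CalibrationReport:
    """Biomarkers, block responses and pass/fail verdicts for one cell.

    All calibration runs are deterministic (gating noise only enters the
    downstream protocol simulations).  Block responses re-equilibrate for
    ``n_block_beats`` beats starting from the baseline steady state.
    """
    params = apply_conductance_scaling(theta)
    base = steady_state_pace(params, 1000.0, n_beats=n_base_beats)
    bio = {k: base[k] for k in ("apd90", "apd50", "rmp", "vpeak")}
    criteria = {}
    if base["repol_failure"]:
        return CalibrationReport(theta, bio, {}, False, False,
                                 "baseline repolarization failure")
    for name in ("apd90", "apd50", "rmp", "vpeak"):
        lo, hi = CALIBRATION_BOUNDS[name]
        criteria[name] = bool(lo <= bio[name] <= hi)
    if short_circuit and not all(criteria.values()):
        reason = "failed: " + ",".join(k for k, v in criteria.items() if not v)
        return CalibrationReport(theta, bio, criteria, False, False, reason,
                                 base["state"])
    for name, (idx, factor) in _BLOCK_TESTS.items():
        th = theta.as_array()
        th[idx] *= factor
        pblock = apply_conductance_scaling(ConductanceVector.from_array(th))
        blk = steady_state_pace(pblock, 1000.0, n_beats=n_block_beats,
                                state=base["state"], min_beats=n_block_beats)
        if blk["repol_failure"]:
            criteria[name] = False
            bio[name] = np.nan
            continue
        delta = 100.0 * (blk["apd90"] - base["apd90"]) / base["apd90"]
        bio[name] = delta
        lo, hi = CALIBRATION_BOUNDS[name]
        criteria[name] = bool(lo <= delta <= hi)
    baseline_events = False
    if check_baseline_events:
        baseline_events = _baseline_event_check(params, base["state"])
    passed = all(criteria.values()) and not baseline_events
    reason = "" if passed else (
        "baseline pro-arrhythmic events" if baseline_events and
        all(criteria.values())
        else "failed: " + ",".join(k for k, v in criteria.items() if not v))
    return CalibrationReport(theta, bio, criteria, baseline_events, passed,
                             reason, base["state"])


def _baseline_event_check(params: CellParams, state, n_beats: int = 10) -> bool:
    """Deterministic short continuation scanned for pro-arrhythmic events."""
    from .ionic_model import DT_DEFAULT, RECORD_EVERY_DEFAULT
    st = state.copy()
    p = params.vector.copy()
    vrec, status = core.run_segment(st.y, p, st.t_ms, n_beats,
                                    DT_DEFAULT,
                                    RECORD_EVERY_DEFAULT, False, 0)
    if status != 0:
        return True
    dt_rec = DT_DEFAULT * RECORD_EVERY_DEFAULT
    t = st.t_ms + dt_rec * np.arange(len(vrec))
    stims = st.t_ms + 1000.0 * np.arange(n_beats)
    report = detect_events(APTrace(t, vrec, stims))
    return report.pro_arrhythmic


@dataclass
class Population:
    thetas: np.ndarray                      # accepted cells x 8
    reports: list = field(default_factory=list)     # all candidates, in order
    accepted_idx: list = field(default_factory=list)
    spec: PopulationSpec | None = None

    @property
    def n_accepted(self) -> int:
        return len(self.accepted_idx)

    @property
    def accepted_reports(self) -> list:
        return [self.reports[i] for i in self.accepted_idx]

    def audit_frame(self) -> pd.DataFrame:
        rows = []
        for i, rep in enumerate(self.reports):
            row = {"candidate": i, "passed": rep.passed, "reason": rep.reason,
                   "baseline_events": rep.baseline_events}
            row.update({f"theta_{k}": v for k, v in
                        zip(("Ks", "Kr", "to", "CaL", "K1", "Na", "NaCa", "NaK"),
                            rep.theta.as_array())})
            row.update(rep.biomarkers)
            rows.append(row)
        return pd.DataFrame(rows)


def build_population(spec: PopulationSpec, max_accept: int | None = None,
                     n_base_beats: int = 1000, n_block_beats: int = 200,
                     short_circuit: bool = False,
                     progress=None) -> Population:
    """Sample, calibrate and filter a population of virtual cells.

    ``max_accept`` stops early once that many cells pass (used for reduced
    populations); the audit trail keeps every evaluated candidate.
    """
    thetas = lhs_sample(spec)
    reports = []
    accepted = []
    for i, th in enumerate(thetas):
        rep = evaluate_calibration(ConductanceVector.from_array(th),
                                   n_base_beats=n_base_beats,
                                   n_block_beats=n_block_beats,
                                   short_circuit=short_circuit)
        reports.append(rep)
        if rep.passed:
            accepted.append(i)
        if progress is not None:
            progress(i, rep)
        if max_accept is not None and len(accepted) >= max_accept:
            break
    if not accepted:
        raise RuntimeError("no cell passed calibration")
    return Population(thetas[accepted], reports, accepted, spec)
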