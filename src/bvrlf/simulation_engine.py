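"""Paced protocols on a virtual cell, per-beat biomarkers and event detection.

The standard protocol is 640 beats at 1 Hz — 320 under baseline forcing
followed by 320 under sympathetic provocation — with stochastic gating;
variability metrics downstream use the last 120 beats of each segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _ord_core as core
from .ionic_model import (
    CellParams, CellState, ConductanceVector, DT_DEFAULT,
    RECORD_EVERY_DEFAULT, apply_conductance_scaling, steady_state_pace,
)
from .stochastic_gating import channel_counts
from .sympathetic_drive import (
    BASELINE, SP, DiseaseCondition, ProtocolCondition, SACParams,
    configure_params, disease_modifiers,
)

# event-detection thresholds (declared constants)
EAD_VOLTAGE_FLOOR = -40.0   # mV: repolarization-phase window for EADs
EAD_BUMP_MV = 2.0           # mV: minimal secondary depolarization
EAD_BURST_MIN = 3           # EADs within one beat constituting a burst
SPONT_DVDT = 10.0           # mV/ms upstroke criterion for spontaneous beats
SPONT_STIM_GUARD_MS = 10.0  # ignore upstrokes this close to a stimulus
EAD_SCAN_GUARD_MS = 50.0    # skip the spike/notch/dome transient of each beat


@dataclass
class APTrace:
    """Membrane potential on a uniform time grid with known stimulus times."""

    t_ms: np.ndarray
    v_mv: np.ndarray
    stim_times_ms: np.ndarray
    currents: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])

    def to_frame(self) -> pd.DataFrame:
        """Trace as a (time_ms, v_mV) table, e.g. for CSV fixtures/debug."""
        return pd.DataFrame({"time_ms": self.t_ms, "v_mV": self.v_mv})


@dataclass
class BeatSeries:
    """Per-beat APD90/APD50 for one (cell, condition, realization)."""

    table: pd.DataFrame  # beat, apd90_ms, apd50_ms, valid

    cell_id: int = 0
    realization: int = 0
    condition: str = "baseline"

    def apd90(self, last=None, require_valid=True) -> np.ndarray:
        tab = self.table
        if require_valid and not tab["valid"].all():
            bad = tab.index[~tab["valid"]].tolist()
            raise ValueError(f"invalid beats at indices {bad}")
        vals = tab["apd90_ms"].to_numpy()
        return vals[-last:] if last else vals

    def apd50(self, last=None) -> np.ndarray:
        vals = self.table["apd50_ms"].to_numpy()
        return vals[-last:] if last else vals

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "cell_id", self.cell_id)
        out.insert(1, "realization", self.realization)
        out.insert(2, "condition", self.condition)
        return out


@dataclass
class EventReport:
    """Counts of pro-arrhythmic events in one trace."""

    eads: int = 0
    ead_bursts: int = 0
    spontaneous_beats: int = 0
    per_beat: pd.DataFrame | None = None

    @property
    def pro_arrhythmic(self) -> bool:
        return (self.eads + self.ead_bursts + self.spontaneous_beats) > 0


def extract_apd(trace: APTrace, fractions=(0.9, 0.5)) -> BeatSeries:
    """Per-beat APD at the requested repolarization fractions.

    The depolarization reference is the stimulus time; the repolarization
    threshold of each beat is computed from that beat's own diastolic
    minimum (sample at the stimulus) and peak, with linear interpolation
    between grid samples.  Beats whose potential never recrosses the APD90
    threshold before the next stimulus are flagged invalid
    (repolarization failure), not dropped.
    """
    v = np.asarray(trace.v_mv, dtype=float)
    t = np.asarray(trace.t_ms, dtype=float)
    dt = trace.dt
    stims = np.asarray(trace.stim_times_ms, dtype=float)
    rows = []
    for b, t_stim in enumerate(stims):
        i0 = int(round((t_stim - t[0]) / dt))
        i1 = int(round(((stims[b + 1] - t[0]) / dt))) if b + 1 < len(stims) else len(v)
        if i1 - i0 < 3 or i0 < 0 or i1 > len(v):
            continue
        win = v[i0:i1]
        vrest = win[0]
        ipeak = int(np.argmax(win))
        vpeak = win[ipeak]
        vals = {}
        valid = True
        for frac in sorted(fractions, reverse=True):
            thr = vrest + (1.0 - frac) * (vpeak - vrest)
            seg = win[ipeak:]
            below = np.nonzero(seg <= thr)[0]
            if below.size == 0:
                vals[frac] = np.nan
                valid = False
                continue
            k = below[0]
            if k == 0:
                vals[frac] = ipeak * dt
            else:
                v1, v2 = seg[k - 1], seg[k]
                vals[frac] = (ipeak + k - 1 + (v1 - thr) / (v1 - v2)) * dt
        rows.append({"beat": b, "apd90_ms": vals.get(0.9, np.nan),
                     "apd50_ms": vals.get(0.5, np.nan), "valid": valid})
    return BeatSeries(pd.DataFrame(rows))


def detect_events(trace: APTrace) -> EventReport:
    """Count EADs, EAD bursts and spontaneous beats in a trace.

    An EAD is a local minimum during a beat's repolarization phase (after
    the plateau peak, at potentials above ``EAD_VOLTAGE_FLOOR``) followed by
    a depolarization of at least ``EAD_BUMP_MV`` before final
    repolarization.  The plateau peak is located after a
    ``EAD_SCAN_GUARD_MS`` guard so the physiological spike-notch-dome
    transient of epicardial beats is not mistaken for an event.
    A burst is a beat carrying >= ``EAD_BURST_MIN`` EADs.  A spontaneous
    beat is an upstroke through ``EAD_VOLTAGE_FLOOR`` steeper than
    ``SPONT_DVDT`` that is not within ``SPONT_STIM_GUARD_MS`` of a stimulus.
    """
    v = np.asarray(trace.v_mv, dtype=float)
    t = np.asarray(trace.t_ms, dtype=float)
    dt = trace.dt
    stims = np.asarray(trace.stim_times_ms, dtype=float)
    eads_total = 0
    bursts = 0
    rows = []
    for b, t_stim in enumerate(stims):
        i0 = int(round((t_stim - t[0]) / dt))
        i1 = int(round(((stims[b + 1] - t[0]) / dt))) if b + 1 < len(stims) else len(v)
        if i1 - i0 < 3 or i0 < 0 or i1 > len(v):
            continue
        win = v[i0:i1]
        guard = min(int(round(EAD_SCAN_GUARD_MS / dt)), len(win) - 1)
        ipeak = guard + int(np.argmax(win[guard:]))
        n_ead = 0
        cur_min = np.inf
        armed = False
        for x in win[ipeak:]:
            if x < cur_min:
                cur_min = x
                armed = cur_min > EAD_VOLTAGE_FLOOR
            elif armed and x - cur_min >= EAD_BUMP_MV:
                n_ead += 1
                cur_min = x       # require a fresh descent for the next EAD
                armed = False
        eads_total += n_ead
        is_burst = n_ead >= EAD_BURST_MIN
        bursts += int(is_burst)
        rows.append({"beat": b, "eads": n_ead, "burst": is_burst})
    # spontaneous upstrokes
    dvdt = np.diff(v) / dt
    crossings = np.nonzero((v[:-1] < EAD_VOLTAGE_FLOOR)
                           & (v[1:] >= EAD_VOLTAGE_FLOOR))[0]
    spont = 0
    for k in crossings:
        # steep upstroke measured across the crossing neighbourhood
        lo = max(0, k - 1)
        hi = min(len(dvdt), k + max(1, int(round(1.0 / dt))))
        seg = dvdt[lo:hi]
        seg = seg[np.isfinite(seg)]
        if seg.size == 0 or np.max(seg) <= SPONT_DVDT:
            continue
        t_cross = t[k]
        if np.min(np.abs(stims - t_cross)) <= SPONT_STIM_GUARD_MS:
            continue
        spont += 1
    per_beat = pd.DataFrame(rows)
    return EventReport(eads=eads_total, ead_bursts=bursts,
                       spontaneous_beats=spont, per_beat=per_beat)


def _realization_seed(global_seed: int, cell_id: int, realization: int,
                      segment: int = 0) -> int:
    """Independent, reproducible 31-bit seed per (seed, cell, realization, segment)."""
    ss = np.random.SeedSequence([int(global_seed), int(cell_id),
                                 int(realization), int(segment)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31 - 1)) + 1


@dataclass
class ProtocolResult:
    beats: pd.DataFrame
    events: pd.DataFrame
    failed: list = field(default_factory=list)

    def series(self, condition: str, realization: int) -> BeatSeries:
        sub = self.beats[(self.beats.condition == condition)
                         & (self.beats.realization == realization)]
        return BeatSeries(sub[["beat", "apd90_ms", "apd50_ms", "valid"]]
                          .reset_index(drop=True),
                          cell_id=int(sub.cell_id.iloc[0]),
                          realization=realization, condition=condition)


def run_protocol(theta: ConductanceVector,
                 disease: DiseaseCondition | str = "physiological",
                 n_beats_per_condition: int = 320,
                 n_realizations: int = 5,
                 seed: int = 0,
                 cell_id: int = 0,
                 conditions=(BASELINE, SP),
                 init_state: CellState | None = None,
                 pre_beats: int = 100,
                 noise: bool = True,
                 nominal_counts=None,
                 sac: SACParams = SACParams(),
                 dt: float = DT_DEFAULT,
                 keep_traces: bool = False) -> ProtocolResult:
    """Simulate the paced baseline→SP protocol for one cell.

    Each realization runs the conditions consecutively (state carries over),
    preceded by a deterministic equilibration of ``pre_beats`` beats under
    the disease modifiers with forcing off.  Returns all per-beat biomarkers
    and per-(realization, condition) event counts; numerically failed
    realizations are recorded in ``failed`` with a diagnostic.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if isinstance(disease, str):
        disease = disease_modifiers(disease)
    base_params = apply_conductance_scaling(theta)
    census = channel_counts(theta, nominal_counts)
    rec = RECORD_EVERY_DEFAULT
    dt_rec = dt * rec
    cl = 1000.0

    # deterministic equilibration under disease, no forcing
    eq_vec = configure_params(base_params.vector,
                              ProtocolCondition("baseline", 0.0, 0.0),
                              disease, sac)
    eq_vec[core.P_FORCE_FREQ] = 0.0
    eq_params = CellParams(eq_vec, theta, disease.level, "equilibration")
    eq = steady_state_pace(eq_params, cl, n_beats=max(pre_beats, 1),
                           state=init_state, dt=dt, min_beats=pre_beats)
    eq_state = eq["state"]

    beat_frames = []
    event_rows = []
    failed = []
    traces = {}
    for r in range(n_realizations):
        st = eq_state.copy()
        t0 = 0.0
        for ci, cond in enumerate(conditions):
            p = configure_params(base_params.vector, cond, disease, sac)
            p[core.P_CL] = cl
            if noise:
                p[core.P_N_KS:core.P_N_CAL + 1] = census.as_array()
            rng_seed = _realization_seed(seed, cell_id, r, ci)
            vrec, status = core.run_segment(
                st.y, p, t0, n_beats_per_condition, dt, rec,
                noise, rng_seed)
            if status != 0:
                failed.append({"cell_id": cell_id, "realization": r,
                               "condition": cond.label,
                               "reason": "numerical blow-up"})
            stim_times = t0 + cl * np.arange(n_beats_per_condition)
            trace = APTrace(t0 + dt_rec * np.arange(len(vrec)), vrec, stim_times)
            series = extract_apd(trace)
            series.cell_id = cell_id
            series.realization = r
            series.condition = cond.label
            beat_frames.append(series.to_frame())
            report = detect_events(trace)
            event_rows.append({
                "cell_id": cell_id, "realization": r, "condition": cond.label,
                "eads": report.eads, "ead_bursts": report.ead_bursts,
                "spontaneous_beats": report.spontaneous_beats,
                "pro_arrhythmic": report.pro_arrhythmic,
            })
            if keep_traces:
                traces[(r, cond.label)] = trace
            t0 += n_beats_per_condition * cl
    result = ProtocolResult(
        beats=pd.concat(beat_frames, ignore_index=True) if beat_frames
        else pd.DataFrame(),
        events=pd.DataFrame(event_rows), failed=failed)
    if keep_traces:
        result.traces = traces
    return result
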