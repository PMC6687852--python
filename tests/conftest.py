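"""Shared fixtures.

The session-scoped fixtures carry the expensive simulation work: a reduced
calibrated population (Latin Hypercube candidates filtered against the
experimental biomarker ranges) and its mild-disease and severe-disease
protocol runs.  Scales are reduced relative to the full study (candidate
count, beats per condition, realizations) but the protocols themselves are
unchanged.
"""

import numpy as np
import pandas as pd
import pytest

from bvrlf.config import RunConfig
from bvrlf.ionic_model import ConductanceVector
from bvrlf.pipeline import measures_from_beats
from bvrlf.population_builder import (
    PopulationSpec, build_population, evaluate_calibration,
)
from bvrlf.simulation_engine import run_protocol
from bvrlf.sympathetic_drive import SP


@pytest.fixture(scope="session")
def nominal_calibration():
    """Full-scale deterministic calibration of the nominal cell (1 Hz)."""
    return evaluate_calibration(ConductanceVector(), n_base_beats=1000,
                                n_block_beats=200)


@pytest.fixture(scope="session")
def smoke_population():
    """Twelve calibrated cells from a 60-candidate Latin Hypercube draw."""
    spec = PopulationSpec(n_samples=60, seed=7)
    return build_population(spec, max_accept=12, n_base_beats=300,
                            n_block_beats=80, short_circuit=True)


@pytest.fixture(scope="session")
def mild_protocol(smoke_population):
    """Baseline + SP protocol under mild disease for every smoke cell.

    130 beats per condition (last 120 analyzed), one stochastic
    realization per cell; initial states come from the calibration runs.
    """
    pop = smoke_population
    beats, events = [], []
    for cid, (th, rep) in enumerate(zip(pop.thetas, pop.accepted_reports)):
        res = run_protocol(ConductanceVector.from_array(th), disease="mild",
                           n_beats_per_condition=130, n_realizations=1,
                           seed=42, cell_id=cid, init_state=rep.final_state,
                           pre_beats=20)
        beats.append(res.beats)
        events.append(res.events)
    beats = pd.concat(beats, ignore_index=True)
    events = pd.concat(events, ignore_index=True)
    measures = measures_from_beats(beats, RunConfig(window=120))
    return {"population": pop, "beats": beats, "events": events,
            "measures": measures}


@pytest.fixture(scope="session")
def severe_sp_flags(smoke_population):
    """Pro-arrhythmia flag per smoke cell following SP under severe disease."""
    pop = smoke_population
    flags = []
    for cid, (th, rep) in enumerate(zip(pop.thetas, pop.accepted_reports)):
        res = run_protocol(ConductanceVector.from_array(th), disease="severe",
                           n_beats_per_condition=130, n_realizations=1,
                           seed=99, cell_id=cid, init_state=rep.final_state,
                           pre_beats=100, conditions=(SP,))
        flags.append(bool(res.events["pro_arrhythmic"].any())
                     or bool(res.failed))
    return np.array(flags)
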