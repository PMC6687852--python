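"""Stage runners tying population, simulation, metrics, ARD and CCA together.

Each stage reads/writes diffable CSV/JSON artifacts in the configured
output directory and records the config hash and seed alongside, so a rerun
with the same configuration reproduces the tables byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .arrhythmia_cca import fit_cca
from .config import RunConfig
from .constants import THETA_ORDER
from .ionic_model import ConductanceVector
from .lf_spectrum import compute_lf_measures
from .population_builder import PopulationSpec, build_population
from .relevance_ard import RelevanceDataset, fit_ard
from .simulation_engine import run_protocol
from .synthetic_data import CohortSpec, SeriesSpec, gen_apd_series, gen_relevance_cohort
from .variability_metrics import compute_bvr

log = logging.getLogger("bvrlf")

MEASURE_COLUMNS = ("m_sd", "m_nsd", "m_stv", "m_nstv", "m_plf", "m_nplf",
                   "mean_apd", "t1_mean")


def _sidecar(cfg: RunConfig, out: Path, stage: str, extra=None):
    meta = {"stage": stage, "config_hash": cfg.config_hash(),
            "seed": cfg.seed, "config": cfg.to_dict()}
    if extra:
        meta.update(extra)
    (out / f"{stage}_meta.json").write_text(json.dumps(meta, indent=2))


def stage_population(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    spec = PopulationSpec(n_samples=cfg.n_samples, low=cfg.theta_low,
                          high=cfg.theta_high, seed=cfg.seed)
    pop = build_population(spec, max_accept=cfg.max_accept)
    audit = pop.audit_frame()
    audit.to_csv(out / "calibration_audit.csv", index=False)
    acc = pd.DataFrame(pop.thetas, columns=[f"theta_{n}" for n in THETA_ORDER])
    acc.insert(0, "cell_id", range(len(acc)))
    acc.to_csv(out / "population.csv", index=False)
    _sidecar(cfg, out, "population",
             {"n_evaluated": len(pop.reports), "n_accepted": pop.n_accepted,
              "wall_s": round(time.time() - t0, 2)})
    log.info("population: %d/%d accepted in %.1fs", pop.n_accepted,
             len(pop.reports), time.time() - t0)
    return out / "population.csv"


def stage_simulate(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    pop_file = out / "population.csv"
    if not pop_file.exists():
        raise FileNotFoundError(
            f"{pop_file} missing: run the population stage first")
    pop = pd.read_csv(pop_file)
    t0 = time.time()
    beats = []
    events = []
    for _, row in pop.iterrows():
        cid = int(row.cell_id)
        theta = ConductanceVector.from_array(
            row[[f"theta_{n}" for n in THETA_ORDER]].to_numpy())
        res = run_protocol(theta, disease=cfg.disease,
                           n_beats_per_condition=cfg.n_beats_per_condition,
                           n_realizations=cfg.n_realizations, seed=cfg.seed,
                           cell_id=cid, pre_beats=cfg.pre_beats,
                           noise=cfg.noise, nominal_counts=cfg.nominal_counts)
        beats.append(res.beats)
        events.append(res.events)
        log.info("simulated cell %d (%d beats x %d realizations)", cid,
                 2 * cfg.n_beats_per_condition, cfg.n_realizations)
    pd.concat(beats, ignore_index=True).to_csv(out / "beats.csv", index=False)
    pd.concat(events, ignore_index=True).to_csv(out / "events.csv", index=False)
    _sidecar(cfg, out, "simulate", {"wall_s": round(time.time() - t0, 2)})
    return out / "beats.csv"


def measures_from_beats(beats: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Per-(cell, condition) measures, averaged over stochastic realizations."""
    rows = []
    for (cid, cond), group in beats.groupby(["cell_id", "condition"]):
        per_real = []
        for r, sub in group.groupby("realization"):
            sub = sub.sort_values("beat")
            apd90 = sub["apd90_ms"].to_numpy()
            apd50 = sub["apd50_ms"].to_numpy()
            if not sub["valid"].tail(cfg.window).all():
                continue
            bvr = compute_bvr(apd90, apd50, window=cfg.window,
                              stv_window=cfg.stv_window,
                              stv_denominator=cfg.stv_denominator)
            lf = compute_lf_measures(apd90, window=cfg.window)
            per_real.append((bvr.m_sd, bvr.m_nsd, bvr.m_stv, bvr.m_nstv,
                             lf.m_plf, lf.m_nplf, bvr.mean_apd, bvr.t1_mean))
        if not per_real:
            continue
        mean = np.mean(np.array(per_real), axis=0)
        row = {"cell_id": cid, "condition": cond,
               "n_realizations": len(per_real)}
        row.update(dict(zip(MEASURE_COLUMNS, mean)))
        rows.append(row)
    return pd.DataFrame(rows)


def stage_metrics(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    beats_file = out / "beats.csv"
    if not beats_file.exists():
        raise FileNotFoundError(
            f"{beats_file} missing: run the simulate stage first")
    beats = pd.read_csv(beats_file)
    measures = measures_from_beats(beats, cfg)
    measures.to_csv(out / "measures.csv", index=False)
    _sidecar(cfg, out, "metrics")
    return out / "measures.csv"


def stage_ard(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    for req in ("population.csv", "measures.csv"):
        if not (out / req).exists():
            raise FileNotFoundError(f"{out / req} missing: run earlier stages")
    pop = pd.read_csv(out / "population.csv")
    measures = pd.read_csv(out / "measures.csv")
    x = pop[[f"theta_{n}" for n in THETA_ORDER]].to_numpy()
    results = {}
    for cond, sub in measures.groupby("condition"):
        sub = sub.set_index("cell_id").loc[pop.cell_id]
        for meas in ("m_sd", "m_nsd", "m_stv", "m_nstv", "m_plf", "m_nplf"):
            y = sub[meas].to_numpy()
            if np.std(y) == 0:
                continue
            data = RelevanceDataset.from_raw(x, y, THETA_ORDER)
            fit = fit_ard(data, n_folds=min(cfg.n_folds, len(y)),
                          seed=cfg.seed, center=cfg.ard_center)
            results[f"{cond}:{meas}"] = {
                "relevance": dict(zip(THETA_ORDER, fit.relevance.tolist())),
                "signs": dict(zip(THETA_ORDER, fit.signs.tolist())),
                "sigma2_r": fit.sigma2_r,
                "per_fold": fit.per_fold.tolist(),
            }
    path = out / "relevance.json"
    path.write_text(json.dumps(
        {"config_hash": cfg.config_hash(), "seed": cfg.seed,
         "results": results}, indent=2))
    _sidecar(cfg, out, "ard")
    return path


def stage_cca(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    for req in ("population.csv", "events.csv"):
        if not (out / req).exists():
            raise FileNotFoundError(f"{out / req} missing: run earlier stages")
    pop = pd.read_csv(out / "population.csv")
    events = pd.read_csv(out / "events.csv")
    sp = events[events.condition == "SP"]
    z = (sp.groupby("cell_id")["pro_arrhythmic"].any()
         .reindex(pop.cell_id, fill_value=False).astype(int).to_numpy())
    x = pop[[f"theta_{n}" for n in THETA_ORDER]].to_numpy()
    res = fit_cca(x, z)
    path = out / "cca.json"
    path.write_text(json.dumps({
        "config_hash": cfg.config_hash(), "seed": cfg.seed,
        "w_x": dict(zip(THETA_ORDER, res.w_x.tolist())),
        "correlation": res.correlation,
        "signs": dict(zip(THETA_ORDER, res.signs.tolist())),
        "event_fraction": float(z.mean()),
    }, indent=2))
    _sidecar(cfg, out, "cca")
    return path


def stage_synth(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = gen_apd_series(SeriesSpec(length=cfg.window, lf_amp_ms=5.0,
                                       noise_sd_ms=1.0, seed=cfg.seed))
    pd.DataFrame({"beat": np.arange(series.size), "apd90_ms": series}) \
        .to_csv(out / "synthetic_series.csv", index=False)
    x, y, z, truth = gen_relevance_cohort(CohortSpec(seed=cfg.seed))
    cohort = pd.DataFrame(x, columns=[f"theta_{n}" for n in THETA_ORDER])
    cohort.insert(0, "cell_id", range(len(cohort)))
    cohort["measure"] = y
    cohort["event"] = z
    cohort.to_csv(out / "synthetic_cohort.csv", index=False)
    (out / "synthetic_truth.json").write_text(json.dumps(
        {k: np.asarray(v).tolist() for k, v in truth.items()}, indent=2))
    _sidecar(cfg, out, "synth")
    return out / "synthetic_cohort.csv"


STAGES = {
    "population": stage_population,
    "simulate": stage_simulate,
    "metrics": stage_metrics,
    "ard": stage_ard,
    "cca": stage_cca,
    "synth": stage_synth,
}


def run_pipeline(cfg: RunConfig, stage: str = "all"):
    """Run one stage or the full chain in dependency order."""
    if stage == "all":
        order = ("population", "simulate", "metrics", "ard", "cca")
        return [STAGES[s](cfg) for s in order]
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    return STAGES[stage](cfg)
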