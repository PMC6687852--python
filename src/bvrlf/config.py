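"""Run configuration: defaults, JSON/YAML round-trip, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the study conditions."""

    # population
    n_samples: int = 500
    theta_low: float = 0.0
    theta_high: float = 2.0
    max_accept: int | None = None
    # protocol
    disease: str = "physiological"
    n_beats_per_condition: int = 320
    n_realizations: int = 5
    pre_beats: int = 100
    pacing_hz: float = 1.0
    iso_baseline_um: float = 0.01
    iso_sp_um: float = 1.0
    stretch_baseline: float = 0.01
    stretch_sp: float = 0.10
    forcing_freq_hz: float = 0.1
    # metric windows
    window: int = 120
    stv_window: int = 30
    stv_denominator: str = "sqrt2"
    lf_band: tuple = (0.04, 0.15)
    total_band: tuple = (0.04, 0.5)
    # SAC
    g_sac_ns: float = 0.006
    g_sac_ns_severe: float = 0.01
    g_sac_k: float = 0.003
    # stochastic gating
    noise: bool = True
    nominal_counts: dict | None = None
    # ARD / CCA
    n_folds: int = 10
    ard_center: bool = False
    # bookkeeping
    seed: int = 0
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return asdict(self)

    def dump(self, path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data))
        else:
            path.write_text(json.dumps(data, indent=2))

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
            else json.loads(text)
        cfg = cls(**data)
        for tup_field in ("lf_band", "total_band"):
            setattr(cfg, tup_field, tuple(getattr(cfg, tup_field)))
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
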