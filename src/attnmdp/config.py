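"""Run configuration, serialisation and output writing.

Configs are flat YAML/JSON documents with an optional nested ``engine``
block; unknown keys are rejected with the offending key path, and a
write/load round trip reproduces the config bit-exactly.  Experiment
outputs are plain CSV/JSON with a manifest of content hashes, so every
figure-style summary is regenerable from the written files alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import EngineConfig
from .experiments import ExperimentResult

__all__ = ["RunConfig", "load_config", "dump_config", "write_outputs"]

TASKS = ("colour_shape", "yarbus", "face")

_ENGINE_FIELDS = {f.name for f in dataclasses.fields(EngineConfig)}


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for one experiment run."""

    task: str
    n_trials: int = 100
    n_saccades: int = 12
    seed: int = 0
    out: str | None = None
    z: float | None = None
    zeta_fearful: tuple[float, float] = (0.1, 0.9)
    zeta_happy: tuple[float, float] = (0.25, 0.25)
    utilities: tuple[float, float] = (2.0, -4.0)
    engine: EngineConfig = field(default_factory=EngineConfig)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task: unknown task {self.task!r}, expected {TASKS}")
        if self.n_trials < 1:
            raise ValueError("n_trials: must be >= 1")
        if self.n_saccades < 1:
            raise ValueError("n_saccades: must be >= 1")
        if self.z is not None and (self.z < 0 or np.isnan(self.z)):
            raise ValueError(f"z: precision must be >= 0, got {self.z}")
        for name in ("zeta_fearful", "zeta_happy"):
            pair = getattr(self, name)
            if len(pair) != 2 or any(v < 0 for v in pair):
                raise ValueError(f"{name}: must be two values >= 0")
        object.__setattr__(self, "zeta_fearful", tuple(map(float, self.zeta_fearful)))
        object.__setattr__(self, "zeta_happy", tuple(map(float, self.zeta_happy)))
        object.__setattr__(self, "utilities", tuple(map(float, self.utilities)))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["engine"] = dataclasses.asdict(self.engine)
        for k in ("zeta_fearful", "zeta_happy", "utilities"):
            d[k] = list(d[k])
        return d


def _coerce(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    if "task" not in raw:
        raise ValueError("task: missing required key")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for k in raw:
        if k not in known:
            raise ValueError(f"{k}: unknown config key")
    kwargs = dict(raw)
    eng_raw = kwargs.pop("engine", {}) or {}
    if not isinstance(eng_raw, dict):
        raise ValueError("engine: must be a mapping")
    for k in eng_raw:
        if k not in _ENGINE_FIELDS:
            raise ValueError(f"engine.{k}: unknown engine key")
    try:
        engine = EngineConfig(**eng_raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"engine: {exc}") from exc
    def _num(key, value):
        if value is None:
            return None
        if isinstance(value, str) and value.lower() in ("inf", ".inf", "infinity"):
            return float("inf")
        if not isinstance(value, (int, float)):
            raise ValueError(f"{key}: expected a number, got {value!r}")
        return float(value)
    if "z" in kwargs:
        kwargs["z"] = _num("z", kwargs["z"])
    for key in ("zeta_fearful", "zeta_happy", "utilities"):
        if key in kwargs:
            pair = kwargs[key]
            if not isinstance(pair, (list, tuple)):
                raise ValueError(f"{key}: expected a pair of numbers")
            kwargs[key] = tuple(_num(key, v) for v in pair)
    for key in ("n_trials", "n_saccades", "seed"):
        if key in kwargs and not isinstance(kwargs[key], int):
            raise ValueError(f"{key}: expected an integer, got {kwargs[key]!r}")
    return RunConfig(engine=engine, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML (or JSON) run config."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return _coerce(raw)


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=False)
    )


# ---------------------------------------------------------------------------
# outputs
def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _scanpath_frame(result: ExperimentResult) -> pd.DataFrame:
    rows = []
    for label, recs in result.conditions.items():
        for ti, rec in enumerate(recs):
            for t, loc in enumerate(rec.locations):
                row = {
                    "condition": label,
                    "trial": ti,
                    "step": t,
                    "location_label": f"loc{loc + 1}",
                    "action": rec.actions[t] + 1 if t < len(rec.actions) else "",
                    "decision_flag": int(
                        rec.decision_timestep is not None and t == len(rec.locations) - 1
                    ),
                }
                for m, o in rec.observations[t].items():
                    row[f"outcome_{m}"] = o
                rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(result: ExperimentResult, out_dir: str | Path) -> dict:
    """Write scanpath CSV, summary JSON, config snapshot and seed ledger;
    return a manifest of file names and content hashes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    if result.conditions and any(result.conditions.values()):
        csv_path = out / "scanpath.csv"
        _scanpath_frame(result).to_csv(csv_path, index=False)
        files.append(csv_path)
        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(result.summary, indent=2, sort_keys=True))
        files.append(summary_path)
    cfg_path = out / "config.json"
    cfg_path.write_text(json.dumps(result.config, indent=2, sort_keys=True, default=str))
    files.append(cfg_path)
    seed_path = out / "seeds.json"
    seed_path.write_text(json.dumps(result.seeds, indent=2, sort_keys=True))
    files.append(seed_path)
    manifest = {p.name: _sha256(p) for p in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
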