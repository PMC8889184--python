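"""Run configuration, result serialization, and test fixtures."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from fractions import Fraction
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

from .experiments import OptimalityRecord
from .fragmentation import part_composition_pmf
from .growth import GameParams, SizeSchedule
from .solver import solve_growth_rate
from .strategies import (
    Composition,
    enumerate_strategies_upto,
    newborn_compositions,
)

__all__ = ["ConfigError", "RunConfig", "load_config", "write_results", "make_fixtures"]

#: model defaults used whenever a key is absent from config/flags
DEFAULTS: dict[str, Any] = {
    "b": 10.0, "c": 1.0, "k": 3, "w": 0.1, "m": 0.01,
    "gamma": 1.0, "chi": {},
    "seed": None, "tol": 1e-10, "tie_tol": 1e-6,
}

_PARAM_KEYS = ("b", "c", "k", "w", "m")
_SCHEDULE_KEYS = ("gamma", "chi")


class ConfigError(ValueError):
    """Invalid configuration; carries the offending field name."""

    def __init__(self, field: str, message: str):
        super().__init__(f"{field}: {message}")
        self.field = field


@dataclass
class RunConfig:
    """Fully resolved, serializable parameters of one run."""

    params: GameParams
    schedule: SizeSchedule
    seed: int | None
    tol: float
    tie_tol: float

    def to_dict(self) -> dict[str, Any]:
        d = {k: getattr(self.params, k) for k in _PARAM_KEYS}
        d["gamma"] = self.schedule.gamma
        d["chi"] = self.schedule.chi_dict()
        d.update(seed=self.seed, tol=self.tol, tie_tol=self.tie_tol)
        return d


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Build a RunConfig from an optional YAML/JSON file plus overrides.

    Flags (overrides) take precedence over the file; anything unspecified
    falls back to the model defaults (w=0.1, b=10, c=1, m=0.01, gamma=1,
    neutral chi).  Unknown keys and invariant violations raise
    :class:`ConfigError` naming the field.
    """
    data: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, Mapping):
            raise ConfigError("<root>", "config file must contain a mapping")
        data.update(raw)
    for key, value in overrides.items():
        if value is not None:
            data[key] = value

    unknown = set(data) - set(DEFAULTS)
    if unknown:
        raise ConfigError(sorted(unknown)[0], "unknown configuration key")
    merged = {**DEFAULTS, **data}

    try:
        params = GameParams(**{k: merged[k] for k in _PARAM_KEYS})
    except ValueError as exc:
        raise ConfigError("params", str(exc)) from exc
    try:
        schedule = SizeSchedule(gamma=merged["gamma"], chi=dict(merged["chi"] or {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError("chi", str(exc)) from exc
    if merged["tol"] <= 0:
        raise ConfigError("tol", "must be positive")
    if merged["tie_tol"] <= 0:
        raise ConfigError("tie_tol", "must be positive")
    return RunConfig(
        params=params, schedule=schedule, seed=merged["seed"],
        tol=float(merged["tol"]), tie_tol=float(merged["tie_tol"]),
    )


def _records_frame(records: Iterable[OptimalityRecord]) -> pd.DataFrame:
    rows = []
    for i, rec in enumerate(records):
        optimal = {str(s) for s in rec.optimal_set}
        point = {
            k: (json.dumps(v) if isinstance(v, dict) else v)
            for k, v in rec.point.items()
        }
        for strategy, lam in rec.lambda_by_strategy.items():
            rows.append({
                "record": i, **point, "strategy": strategy, "lam": lam,
                "optimal": strategy in optimal, "category": rec.category,
            })
    return pd.DataFrame(rows)


def write_results(
    records: Iterable[OptimalityRecord] | Mapping[Any, OptimalityRecord],
    path: str | Path,
    fmt: str = "both",
    config: RunConfig | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write scan results as a tidy CSV and/or a JSON summary.

    CSV: one row per parameter point x strategy, floats at 12 significant
    digits.  JSON: per-point optimal sets and categories, with the
    resolved config and seed embedded for reproducibility.  ``path`` is
    the stem; suffixes ``.csv`` / ``.json`` are appended.
    """
    if isinstance(records, Mapping):
        records = list(records.values())
    else:
        records = list(records)
    if fmt not in ("csv", "json", "both"):
        raise ValueError(f"unknown format {fmt!r}")
    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt in ("csv", "both"):
        csv_path = stem.with_suffix(".csv")
        _records_frame(records).to_csv(csv_path, index=False, float_format="%.12g")
        written.append(csv_path)
    if fmt in ("json", "both"):
        summary = {
            "config": config.to_dict() if config is not None else None,
            "seed": seed if seed is not None else (config.seed if config else None),
            "records": [
                {
                    "point": rec.point,
                    "optimal_set": [str(s) for s in rec.optimal_set],
                    "category": rec.category,
                    "max_lambda": rec.max_lambda,
                    "tie_tol": rec.tie_tol,
                }
                for rec in records
            ],
        }
        json_path = stem.with_suffix(".json")
        json_path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
        written.append(json_path)
    return written


def make_fixtures(seed: int = 0) -> dict[str, Any]:
    """Small deterministic bundle of reference values for tests and demos.

    Contains all strategies with N <= 4 and their newborn compositions,
    exact fragmentation tables for the mature organisms (2, 1) and
    (3, 1), and the neutral growth-rate table (all entries 1).  The same
    seed always yields a byte-identical JSON rendering
    (``json.dumps(bundle, sort_keys=True)``).
    """
    strategies = enumerate_strategies_upto(4)
    newborns = {
        str(s): [f"{c.n_A},{c.n_B}" for c in newborn_compositions(s)]
        for s in strategies
    }
    frag: dict[str, dict[str, dict[str, str]]] = {}
    for mature in (Composition(2, 1), Composition(3, 1)):
        tables = {}
        for part in range(1, mature.n + 1):
            tables[str(part)] = {
                f"{c.n_A},{c.n_B}": str(p)
                for c, p in sorted(part_composition_pmf(mature, part).items())
            }
        frag[f"{mature.n_A},{mature.n_B}"] = tables
    neutral = {
        str(s): solve_growth_rate(s, GameParams(w=0.0), SizeSchedule()).lam
        for s in strategies
    }
    return {
        "seed": seed,
        "strategies_N_le_4": [str(s) for s in strategies],
        "newborn_compositions": newborns,
        "fragmentation_pmfs": frag,
        "neutral_lambda": neutral,
    }
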