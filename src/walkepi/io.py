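"""Run manifests, result serialization and canned scenario configs.

Every CLI command resolves its parameters into a :class:`RunManifest` that
is written next to the outputs, so any result file is traceable to the
exact configuration and seed that produced it.  Tables go to CSV, fits and
manifests to JSON, snapshot rasters to plain integer text grids.  All
JSON/CSV payloads carry a schema version; readers reject unknown versions.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulator import SimConfig, TwoRegionField, UniformField

__all__ = [
    "SCHEMA_VERSION",
    "RunManifest",
    "write_table",
    "write_json",
    "read_json",
    "write_raster",
    "read_raster",
    "config_to_dict",
    "config_from_dict",
    "generate_fixtures",
    "SCENARIOS",
]

SCHEMA_VERSION = 1


def _version() -> str:
    from . import __version__

    return __version__


@dataclasses.dataclass
class RunManifest:
    """Provenance record of one command invocation."""

    command: str
    params: dict
    seed: int
    outputs: list
    schema_version: int = SCHEMA_VERSION
    code_version: str = dataclasses.field(default_factory=_version)
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        write_json(dataclasses.asdict(self), path)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(payload: dict, path) -> None:
    payload = dict(payload)
    payload.setdefault("schema_version", SCHEMA_VERSION)
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def read_json(path) -> dict:
    payload = json.loads(Path(path).read_text())
    v = payload.get("schema_version")
    if v != SCHEMA_VERSION:
        raise ValueError(f"unknown schema version {v!r} in {path}")
    return payload


def write_table(df: pd.DataFrame, path) -> None:
    """CSV with a one-line schema-version comment header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# walkepi-schema-version: {SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if f"walkepi-schema-version: {SCHEMA_VERSION}" not in header:
            raise ValueError(f"unknown or missing schema version in {path}")
        return pd.read_csv(fh)


def write_raster(grid: np.ndarray, path) -> None:
    """Snapshot raster as a plain integer text grid (one row per line)."""
    np.savetxt(path, np.asarray(grid, int), fmt="%d")


def read_raster(path) -> np.ndarray:
    return np.loadtxt(path, dtype=int, ndmin=2)


# ------------------------------------------------------------- configs


def config_to_dict(cfg: SimConfig) -> dict:
    f = cfg.infection_field
    if isinstance(f, UniformField):
        field = {"kind": "uniform", "p": f.p}
    else:
        field = {
            "kind": "two_region",
            "p1": f.p1,
            "p2": f.p2,
            "boundary_y": f.boundary_y,
            "start_distance": f.start_distance,
        }
    return {
        "tau": cfg.tau,
        "infection_field": field,
        "max_time": cfg.max_time,
        "max_removed": cfg.max_removed,
        "seed": cfg.seed,
    }


def config_from_dict(d: dict) -> SimConfig:
    f = d["infection_field"]
    if f["kind"] == "uniform":
        field = UniformField(p=f["p"])
    elif f["kind"] == "two_region":
        field = TwoRegionField(
            p1=f["p1"],
            p2=f["p2"],
            boundary_y=f.get("boundary_y", 0),
            start_distance=f.get("start_distance", 0),
        )
    else:
        raise ValueError(f"unknown infection field kind {f['kind']!r}")
    return SimConfig(
        tau=d["tau"],
        infection_field=field,
        max_time=d.get("max_time"),
        max_removed=d.get("max_removed", 25_000),
        seed=d.get("seed"),
    )


def load_config(path) -> SimConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


# ------------------------------------------------------------ fixtures

_TABLE1_P = [1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125, 0.015625]
_TABLE1_TAU = [1, 2, 3, 4, 5, 8, 10, 16, 32, 64, 128]
_CRITICAL_TAU50_P = [0.03, 0.035, 0.04, 0.045, 0.05, 0.055, 0.06]


def _table1(full: bool) -> dict:
    return {
        "scenario": "table1",
        "description": "index-case R0 grid on log-log (p, tau) axes",
        "p_values": _TABLE1_P,
        "tau_values": _TABLE1_TAU,
        "n_realizations": 2_500_000 if full else 10_000,
    }


def _two_region_fig5(full: bool) -> dict:
    return {
        "scenario": "two-region-fig5",
        "description": "outbreak crossing a border into a more infectious region",
        "config": config_to_dict(
            SimConfig.two_region(
                p1=0.1, p2=0.3, tau=50, boundary_y=100, start_distance=25,
                max_time=1500 if full else 400,
                max_removed=10**9,
            )
        ),
        "snapshot_window": [[-75, 75], [25, 175]],
    }


def _critical_tau50(full: bool) -> dict:
    return {
        "scenario": "critical-tau50",
        "description": "supercritical cross-section at tau=50 for growth scaling",
        "tau": 50,
        "p_values": _CRITICAL_TAU50_P,
        "n_runs": 500 if full else 20,
        "t_max": 1500 if full else 500,
    }


SCENARIOS = {
    "table1": _table1,
    "two-region-fig5": _two_region_fig5,
    "critical-tau50": _critical_tau50,
}


def generate_fixtures(name: str, out_dir, full: bool = False) -> Path:
    """Write a ready-to-run scenario config; returns the file path.

    Known scenarios: ``table1`` (the R0 grid), ``two-region-fig5`` (the
    border-crossing outbreak) and ``critical-tau50`` (the scaling
    cross-section).  Default replication is desk-scale; ``full=True``
    restores the original experiment sizes.
    """
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(SCENARIOS))}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = SCENARIOS[name](full)
    payload["schema_version"] = SCHEMA_VERSION
    path = out_dir / f"{name}.yaml"
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path
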