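"""CSV/JSON/YAML I/O with schema validation and run provenance.

Every CSV written here starts with a ``# config=<hash> seed=<n>`` comment
line so outputs name the configuration and seed that produced them; all
readers skip ``#`` comments.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .simulate import PULSE_COLUMNS, RECORD_COLUMNS, CovariateTable

PULSE_REQUIRED = PULSE_COLUMNS


class SchemaError(ValueError):
    """A tabular input does not match the documented schema."""


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance_line(seed: int | None, cfg_hash: str | None) -> str:
    return f"# config={cfg_hash or 'none'} seed={'none' if seed is None else seed}\n"


def write_csv(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed, cfg_hash))
        df.to_csv(fh, index=False)
    return path


def _read_csv(path: str | Path, required: list[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file {path} lacks required columns: {missing}")
    return df


def read_records_csv(path: str | Path) -> pd.DataFrame:
    """Read a detector-night table (one row per cell x species)."""
    df = _read_csv(path, RECORD_COLUMNS, "detector-night")
    if df["species"].isna().any():
        raise SchemaError(f"detector-night file {path} has empty species values")
    return df


def write_records_csv(df: pd.DataFrame, path, seed=None, cfg_hash=None) -> Path:
    return write_csv(df[RECORD_COLUMNS + [c for c in df.columns
                                          if c not in RECORD_COLUMNS]],
                     path, seed, cfg_hash)


def read_pulse_csv(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, list(PULSE_REQUIRED), "pulse")


def read_covariates(night_temps_path, site_structure_path) -> CovariateTable:
    nt = _read_csv(night_temps_path, ["transect_id", "night_id", "min_temp_C"],
                   "night-temperature")
    ss = _read_csv(site_structure_path,
                   ["transect_id", "distance_m", "n_large_trees", "canopy_pct"],
                   "site-structure")
    return CovariateTable(night_temps=nt, site_structure=ss)


def read_complex_map(path: str | Path) -> dict[str, str]:
    """Two-column (from_label, to_label) species-complex mapping file."""
    df = _read_csv(path, ["from_label", "to_label"], "complex-map")
    return dict(zip(df["from_label"], df["to_label"]))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"config file {path} must hold a mapping")
    return cfg


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
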