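"""Readers and writers for the package's CSV/TOML/JSON surfaces.

Trajectory CSVs carry columns (track_id, cluster_id, t_h, x_um,
y_um), comma-separated UTF-8 with a mandatory header.  Files exported
from image-analysis software use image coordinates (y increasing
downward); loading with ``image_coords=True`` flips the y axis so
that angles are counterclockwise-positive in the Cartesian
convention assumed by the kinematics module.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import pandas as pd

from . import __version__
from .kinematics import validate_trajectories

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_growth_records",
    "read_confluence_series",
    "load_config",
    "provenance",
    "write_report",
]


def read_trajectories(path, image_coords: bool = False) -> pd.DataFrame:
    """Load and validate a trajectory CSV.

    ``image_coords=True`` negates y on load (image y points down), so
    counterclockwise rotation on screen stays counterclockwise-positive.
    """
    df = pd.read_csv(path)
    df = validate_trajectories(df)
    if image_coords:
        df = df.assign(y_um=-df["y_um"])
    return df


def write_trajectories(df: pd.DataFrame, path) -> None:
    validate_trajectories(df).to_csv(path, index=False)


def read_growth_records(path) -> pd.DataFrame:
    """Load (cluster_id, t_h, n_cells[, area_um2]) growth records."""
    df = pd.read_csv(path)
    required = {"cluster_id", "t_h", "n_cells"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth records missing columns: {sorted(missing)}")
    return df


def read_confluence_series(path) -> pd.DataFrame:
    """Load (sample_id, t_h, a_s) confluence series."""
    df = pd.read_csv(path)
    missing = {"sample_id", "t_h", "a_s"} - set(df.columns)
    if missing:
        raise ValueError(f"confluence series missing columns: {sorted(missing)}")
    return df


_KNOWN_SECTIONS = {"model", "grid", "droplet", "output", "run", "spec"}


def load_config(path) -> dict:
    """Parse a TOML run configuration; unknown top-level keys rejected."""
    raw = Path(path).read_bytes()
    try:
        cfg = tomllib.loads(raw.decode("utf-8"))
    except tomllib.TOMLDecodeError as err:
        raise ValueError(f"malformed TOML in {path}: {err}") from err
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    cfg["_config_hash"] = hashlib.sha256(raw).hexdigest()[:16]
    return cfg


def provenance(seed: int | None = None, config_hash: str | None = None) -> dict:
    return {
        "package": "colonyrot",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash,
    }


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
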