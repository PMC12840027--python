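"""CSV / YAML / manifest I/O shared by every subcommand.

Trajectory CSVs use one row per sampling instant with the fixed header::

    t_min,T_air_C,T_sample_C,M_db,M_wb,MR,DR,area_px,SR_pct,L,a,b,dE

UTF-8, '.' decimal separator, values written at 10 significant digits so a
write/read round trip is lossless to well below 1e-9.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .twin import DryingState, Trajectory

TRAJECTORY_COLUMNS = [
    "t_min", "T_air_C", "T_sample_C", "M_db", "M_wb", "MR", "DR",
    "area_px", "SR_pct", "L", "a", "b", "dE",
]

_STATE_FIELDS = ["t", "T_air", "T_sample", "M_db", "M_wb", "MR", "DR",
                 "area_px", "SR", "L", "a", "b", "dE"]

__all__ = [
    "TRAJECTORY_COLUMNS",
    "TrajectoryFormatError",
    "write_trajectory",
    "read_trajectory",
    "trajectory_to_frame",
    "load_config",
    "save_config",
    "dataclass_from_config",
    "RunManifest",
]


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory CSV violates the declared schema."""


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    data = {col: traj.column(fld) for col, fld in zip(TRAJECTORY_COLUMNS, _STATE_FIELDS)}
    return pd.DataFrame(data, columns=TRAJECTORY_COLUMNS)


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write a trajectory to CSV (plus a sidecar ``<name>.meta.json`` with
    the run metadata, if any)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trajectory_to_frame(traj).to_csv(path, index=False, float_format="%.10g")
    if traj.metadata:
        meta = {k: v for k, v in traj.metadata.items()}
        path.with_suffix(".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n"
        )
    return path


def read_trajectory(path) -> Trajectory:
    """Read and validate a trajectory CSV.

    Raises :class:`TrajectoryFormatError` naming the offending column or
    1-based data row for: missing/extra columns, empty files, NaN entries,
    and non-monotone or unevenly spaced time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise TrajectoryFormatError(f"{path}: empty file")
    df = pd.read_csv(path)
    if df.empty:
        raise TrajectoryFormatError(f"{path}: no data rows")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    extra = [c for c in df.columns if c not in TRAJECTORY_COLUMNS]
    if extra:
        raise TrajectoryFormatError(f"{path}: unexpected column(s) {', '.join(extra)}")
    for col in TRAJECTORY_COLUMNS:
        bad = np.flatnonzero(~np.isfinite(df[col].to_numpy(dtype=float)))
        if bad.size:
            raise TrajectoryFormatError(
                f"{path}: non-finite value in column {col}, row {bad[0] + 1}"
            )
    t = df["t_min"].to_numpy(dtype=float)
    dts = np.diff(t)
    if len(dts):
        if np.any(dts <= 0):
            row = int(np.flatnonzero(dts <= 0)[0]) + 2
            raise TrajectoryFormatError(f"{path}: non-increasing t_min at row {row}")
        if not np.allclose(dts, dts[0], rtol=0, atol=1e-6):
            row = int(np.flatnonzero(~np.isclose(dts, dts[0], rtol=0, atol=1e-6))[0]) + 2
            raise TrajectoryFormatError(f"{path}: uneven sampling interval at row {row}")

    states = [
        DryingState(**{fld: float(df[col].iloc[i])
                       for col, fld in zip(TRAJECTORY_COLUMNS, _STATE_FIELDS)})
        for i in range(len(df))
    ]
    metadata: dict = {"source": str(path)}
    meta_path = path.with_suffix(".meta.json")
    if meta_path.exists():
        metadata.update(json.loads(meta_path.read_text()))
    return Trajectory(states=states, metadata=metadata)


# ------------------------------------------------------------------- config
def load_config(path) -> dict:
    """Load a YAML key/value config file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path


def dataclass_from_config(cls, cfg: dict, **overrides):
    """Build a dataclass from a config mapping, ignoring unknown keys and
    coercing YAML lists to tuples where the field default is a tuple."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in {**cfg, **overrides}.items():
        if key not in fields:
            continue
        default = fields[key].default
        if isinstance(default, tuple) and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


@dataclasses.dataclass
class RunManifest:
    """Record of one CLI run: enough to reproduce every seeded output."""

    command: str
    seed: int | None
    config: dict
    inputs: list[str]
    outputs: list[str]
    package_version: str = "0.1.0"
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True, default=str) + "\n")
        return path

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
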