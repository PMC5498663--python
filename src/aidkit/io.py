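"""Trajectory CSV dialect and flat key = value config files.

The long-format CSV has one row per cell per timepoint with columns
``cell_id, role, time_min, signal, budding, schedule_id``; schedule and
simulation metadata travel in a sidecar flat file (``<csv>.meta``,
``key = value`` lines).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import AuxinSchedule, Segment, SimConfig
from .trajectory import PopulationSample, Trajectory

__all__ = [
    "COLUMNS",
    "write_trajectories",
    "read_trajectories",
    "meta_path",
    "write_flat_config",
    "read_flat_config",
]

COLUMNS = ["cell_id", "role", "time_min", "signal", "budding", "schedule_id"]


def meta_path(csv_path) -> Path:
    return Path(str(csv_path) + ".meta")


def write_flat_config(path, mapping: dict) -> None:
    lines = [f"{k} = {v}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_flat_config(path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def write_trajectories(sample: PopulationSample, path, write_meta: bool = True) -> None:
    """Write a cohort to the long-format trajectory CSV (+ sidecar meta)."""
    frames = []
    for traj in sample:
        budding = np.isin(traj.times, traj.budding_times).astype(int)
        frames.append(pd.DataFrame({
            "cell_id": traj.cell_id,
            "role": traj.role,
            "time_min": traj.times,
            "signal": traj.signal,
            "budding": budding,
            "schedule_id": traj.schedule_id,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
    if write_meta:
        meta: dict = {}
        if sample.schedule is not None:
            meta.update(sample.schedule.to_dict())
        if sample.config is not None:
            meta.update({f"sim_{k}": v for k, v in sample.config.to_dict().items()})
        if meta:
            write_flat_config(meta_path(path), meta)


def read_trajectories(path) -> PopulationSample:
    """Read and validate the trajectory CSV into a cohort.

    Malformed numeric fields are reported with their file line numbers;
    the grid and monotonicity invariants of each cell are enforced by the
    Trajectory constructor.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"cell_id": str, "role": str, "schedule_id": str})
    if df.empty:
        raise ValueError(f"{path}: no trajectory rows")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    for col in ("time_min", "signal", "budding"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
            raise ValueError(f"{path}: malformed {col!r} values at line(s) {lines}")
        df[col] = parsed

    cells = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("time_min")
        roles = g["role"].unique()
        if len(roles) != 1:
            raise ValueError(f"{path}: cell {cell_id!r} has inconsistent roles {list(roles)}")
        times = g["time_min"].to_numpy()
        cells.append(Trajectory(
            cell_id=str(cell_id),
            role=str(roles[0]),
            times=times,
            signal=g["signal"].to_numpy(),
            budding_times=times[g["budding"].to_numpy() != 0],
            schedule_id=str(g["schedule_id"].iloc[0]),
        ))
    return PopulationSample(cells)
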