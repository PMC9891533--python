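"""Delimited-text serialisation of trajectories, datasets and tables.

All artefacts are tab-separated tables with ``#``-prefixed metadata lines
so they round-trip through ``pandas`` and remain human-readable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .growth_models import TimeGrid, Trajectory
from .synthetic_data import Dataset
from .ward_king import WKState

__all__ = [
    "write_table",
    "read_table",
    "write_trajectory",
    "read_trajectory",
    "write_dataset",
    "read_dataset",
    "write_states",
]


def write_table(path, frame: pd.DataFrame, metadata: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key} = {value}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    metadata: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                metadata[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t")
    return frame, metadata


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    cols = {"time_d": traj.times.times, "radius_um": traj.radius}
    if traj.inner_radius is not None:
        cols["inner_radius_um"] = traj.inner_radius
    if traj.necrotic_radius is not None:
        cols["necrotic_radius_um"] = traj.necrotic_radius
    return pd.DataFrame(cols)


def write_trajectory(path, traj: Trajectory, metadata: Optional[dict] = None) -> None:
    write_table(path, trajectory_frame(traj), metadata)


def read_trajectory(path) -> Trajectory:
    frame, _ = read_table(path)
    return Trajectory(
        TimeGrid(frame["time_d"].to_numpy()),
        frame["radius_um"].to_numpy(),
        inner_radius=frame["inner_radius_um"].to_numpy()
        if "inner_radius_um" in frame
        else None,
        necrotic_radius=frame["necrotic_radius_um"].to_numpy()
        if "necrotic_radius_um" in frame
        else None,
    )


def write_dataset(path, data: Dataset, metadata: Optional[dict] = None) -> None:
    meta = dict(metadata or {})
    meta.setdefault("sigma_um", data.sigma)
    frame = pd.DataFrame({"time_d": data.times.times, "radius_obs_um": data.y})
    write_table(path, frame, meta)


def read_dataset(path) -> Dataset:
    frame, meta = read_table(path)
    sigma = float(meta.get("sigma_um", "nan"))
    return Dataset(TimeGrid(frame["time_d"].to_numpy()), frame["radius_obs_um"].to_numpy(), sigma)


def write_states(path, states: list[WKState], metadata: Optional[dict] = None) -> None:
    """Profile snapshots as stacked per-time blocks in one table."""
    frames = []
    for st in states:
        frames.append(
            pd.DataFrame(
                {
                    "t_d": np.full(st.rho.size, st.t),
                    "R_um": np.full(st.rho.size, st.R),
                    "rho": st.rho,
                    "n": st.n,
                    "p": st.p,
                    "c": st.c,
                    "v_um_per_d": st.v,
                }
            )
        )
    write_table(path, pd.concat(frames, ignore_index=True), metadata)
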