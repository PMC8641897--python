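"""Trajectory and configuration file formats.

Trajectories are delimited text (CSV) with columns ``t, id, x, y, z`` and
optionally ``parent_id``; a leading ``#`` comment line documents the units
(positions in um, time in minutes or nuclear-cycle units). Frames are the
groups of rows sharing a time value, sorted by time; ids must be unique
within a frame.

Configurations are YAML files whose keys mirror :class:`SimConfig`
(``spheroid`` as a ``{semi_major, semi_minor}`` mapping, ``force`` as a
mapping of :class:`ForceFieldParams` fields or ``null`` for force-free
runs). Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .forcefields import ForceFieldParams
from .geometry import Spheroid
from .simulator import SimConfig, SimState, Trajectory

HEADER_COMMENT = "# nucarray trajectory: positions in um, time in NC units\n"


class TrajectoryFormatError(ValueError):
    pass


def write_trajectory(traj: Trajectory, path) -> None:
    rows = []
    for t, frame in zip(traj.times, traj.frames):
        rows.append(pd.DataFrame({
            "t": t, "id": frame.ids,
            "x": frame.positions[:, 0], "y": frame.positions[:, 1],
            "z": frame.positions[:, 2], "parent_id": frame.parents,
        }))
    df = pd.concat(rows, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(HEADER_COMMENT)
        df.to_csv(fh, index=False)


def read_trajectory(path, spheroid: Spheroid | None = None) -> Trajectory:
    """Read a trajectory CSV; validates monotone times, unique (t, id) and
    finite numeric fields, reporting the offending line on failure."""
    text = Path(path).read_text()
    if not text.strip():
        raise TrajectoryFormatError("no frames: file is empty")
    df = pd.read_csv(_io.StringIO(text), comment="#")
    required = {"t", "id", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise TrajectoryFormatError(f"missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise TrajectoryFormatError("no frames")
    numeric = df[["t", "x", "y", "z"]].to_numpy(float)
    if not np.all(np.isfinite(numeric)):
        line = int(np.argwhere(~np.isfinite(numeric))[0, 0]) + 2
        raise TrajectoryFormatError(f"non-finite value at data line {line}")
    dup = df.duplicated(subset=["t", "id"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise TrajectoryFormatError(f"duplicate (t, id) at data line {line}")
    if spheroid is None:
        # infer semi-axes from the cloud extent (exact for on-surface data)
        a = float(np.abs(df["x"]).max())
        b = float(np.hypot(df["y"], df["z"]).max())
        if a <= b or b <= 0:
            raise TrajectoryFormatError(
                "cannot infer a prolate spheroid from the cloud; pass "
                "spheroid= explicitly")
        spheroid = Spheroid(a, b)
    traj = Trajectory(spheroid=spheroid)
    has_parent = "parent_id" in df.columns
    times = np.sort(df["t"].unique())
    for t in times:
        sub = df[df["t"] == t]
        state = SimState(
            time=float(t),
            positions=sub[["x", "y", "z"]].to_numpy(float),
            ages=np.zeros(len(sub)),
            ids=sub["id"].to_numpy(int),
            parents=sub["parent_id"].to_numpy(int) if has_parent
            else np.full(len(sub), -1),
            generation=np.zeros(len(sub), dtype=int),
            next_id=int(sub["id"].max()) + 1,
        )
        traj.log(state)
    return traj


# -- config -----------------------------------------------------------------


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["spheroid"] = {"semi_major": config.spheroid.semi_major,
                     "semi_minor": config.spheroid.semi_minor}
    if config.force is not None:
        d["force"] = dataclasses.asdict(config.force)
        d["force"]["kind"] = config.force.kind.value
    d["wave_origins"] = list(config.wave_origins)
    d["wave_start_offsets"] = list(config.wave_start_offsets)
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "spheroid" in d:
        sd = d["spheroid"]
        d["spheroid"] = Spheroid(**{k: sd[k] for k in
                                    ("semi_major", "semi_minor") if k in sd})
    if "force" in d:
        d["force"] = None if d["force"] is None else ForceFieldParams(**d["force"])
    for key in ("wave_origins", "wave_start_offsets"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)


def load_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
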