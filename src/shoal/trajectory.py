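"""Trajectory containers and delimited-text I/O.

All coordinates are kept in body-length units ``L`` (one ``L`` is
``body_length_mm`` millimetres, 30 mm by default for adult zebrafish).
Missing samples — a fish lost by the tracker in some frame — are stored
as NaN and written back out as empty fields.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryDataset",
    "VelocitySeries",
    "read_trajectory",
    "write_trajectory",
    "estimate_velocities",
]

#: speed below which a fish's heading is treated as undefined, in L per second
DEFAULT_SPEED_FLOOR = 1e-6


@dataclass
class TrajectoryDataset:
    """Per-frame, per-fish positions on a common time base.

    Parameters
    ----------
    positions
        Array of shape ``(n_frames, n_fish, ndim)`` with ``ndim`` 2 or 3,
        in body-length units.  NaN marks a missing sample.
    frames
        Strictly increasing integer frame indices, shape ``(n_frames,)``.
    fish_ids
        Integer identifiers, shape ``(n_fish,)``.
    frame_interval
        Seconds elapsed between consecutive *stored* frames.
    body_length_mm
        Physical size of the length unit ``L``.
    """

    positions: np.ndarray
    frames: np.ndarray
    fish_ids: np.ndarray
    frame_interval: float
    body_length_mm: float = 30.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.frames = np.asarray(self.frames, dtype=int)
        self.fish_ids = np.asarray(self.fish_ids, dtype=int)
        if self.positions.ndim != 3 or self.positions.shape[2] not in (2, 3):
            raise ValueError(
                f"positions must have shape (n_frames, n_fish, 2|3), "
                f"got {self.positions.shape}"
            )
        if self.positions.shape[0] != self.frames.size:
            raise ValueError("frames length does not match positions")
        if self.positions.shape[1] != self.fish_ids.size:
            raise ValueError("fish_ids length does not match positions")
        if self.frames.size > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if np.any(np.isinf(self.positions)):
            raise ValueError("positions must be finite or NaN (missing)")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        if not self.body_length_mm > 0:
            raise ValueError("body_length_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_fish(self) -> int:
        return self.positions.shape[1]

    @property
    def ndim(self) -> int:
        return self.positions.shape[2]

    @property
    def is_3d(self) -> bool:
        return self.ndim == 3

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of missing (frame, fish) samples."""
        return np.isnan(self.positions).any(axis=2)


@dataclass
class VelocitySeries:
    """Finite-difference velocities matched to a :class:`TrajectoryDataset`.

    ``velocities`` has the same ``(n_frames, n_fish, ndim)`` shape as the
    trajectory it was derived from, in L per second.  ``valid`` flags the
    samples whose heading is defined: finite, not on a masked sample, and
    faster than the speed floor.  Edge frames computed with one-sided
    differences are flagged in ``one_sided``.
    """

    velocities: np.ndarray
    valid: np.ndarray
    one_sided: np.ndarray = field(default=None)  # type: ignore[assignment]
    scheme: str = "central"

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.one_sided is None:
            self.one_sided = np.zeros(self.velocities.shape[0], dtype=bool)
        if self.valid.shape != self.velocities.shape[:2]:
            raise ValueError("valid mask shape mismatch")

    @property
    def speeds(self) -> np.ndarray:
        return np.linalg.norm(self.velocities, axis=2)


def estimate_velocities(
    traj: TrajectoryDataset, speed_floor: float = DEFAULT_SPEED_FLOOR
) -> VelocitySeries:
    """Estimate per-fish velocities by central differences.

    Interior frames use ``(r[t+1] - r[t-1]) / (2 dt)``; the first and last
    frame fall back to one-sided differences and are flagged.  Velocities
    are exact for uniform linear motion at any frame interval.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames to estimate velocities")
    if traj.frames.size > 1:
        steps = np.diff(traj.frames)
        if np.any(steps != steps[0]):
            raise ValueError("frames must be uniformly spaced for differencing")
    dt = traj.frame_interval
    pos = traj.positions
    vel = np.empty_like(pos)
    vel[1:-1] = (pos[2:] - pos[:-2]) / (2.0 * dt)
    vel[0] = (pos[1] - pos[0]) / dt
    vel[-1] = (pos[-1] - pos[-2]) / dt
    one_sided = np.zeros(traj.n_frames, dtype=bool)
    one_sided[[0, -1]] = True
    speeds = np.linalg.norm(vel, axis=2)
    with np.errstate(invalid="ignore"):
        valid = np.isfinite(speeds) & (speeds > speed_floor)
    return VelocitySeries(vel, valid, one_sided, scheme="central")


def _columns_for(ndim: int) -> list[str]:
    return ["frame", "id", "x", "y"] + (["z"] if ndim == 3 else [])


def read_trajectory(
    path,
    frame_interval: float,
    units: str = "body_length",
    body_length_mm: float = 30.0,
) -> TrajectoryDataset:
    """Read a trajectory CSV into a :class:`TrajectoryDataset`.

    ``frame_interval`` (seconds between stored frames) is an explicit
    required input: the recording rate is a property of the acquisition,
    not of the file format.
    The file must carry a header row naming ``frame,id,x,y[,z]`` columns.
    ``units`` is ``"body_length"`` (coordinates already in L) or ``"mm"``
    (divided by ``body_length_mm`` on ingest).  Any (frame, id) pair absent
    from the file, or with empty coordinate fields, becomes a masked
    (NaN) sample.
    """
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    ndim = 3 if "z" in df.columns else 2
    required = _columns_for(ndim)
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required column(s): {missing_cols}")
    if units not in ("body_length", "mm"):
        raise ValueError(f"unknown units {units!r}; use 'body_length' or 'mm'")

    for col in ("frame", "id"):
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 2  # 1-based incl. header
            raise ValueError(f"unparseable {col} value at file row {row}")
    dup = df.duplicated(subset=["frame", "id"])
    if dup.any():
        bad = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate (frame, id) entry: frame={int(bad['frame'])} "
            f"id={int(bad['id'])}"
        )

    frames = np.sort(df["frame"].unique().astype(int))
    fish_ids = np.sort(df["id"].unique().astype(int))
    n_f, n_i = frames.size, fish_ids.size
    pos = np.full((n_f, n_i, ndim), np.nan)
    fidx = np.searchsorted(frames, df["frame"].to_numpy(dtype=int))
    iidx = np.searchsorted(fish_ids, df["id"].to_numpy(dtype=int))
    coords = df[required[2:]].to_numpy(dtype=float)
    if units == "mm":
        coords = coords / body_length_mm
    pos[fidx, iidx] = coords
    return TrajectoryDataset(
        pos, frames, fish_ids, frame_interval, body_length_mm=body_length_mm
    )


def write_trajectory(traj: TrajectoryDataset, path) -> None:
    """Write a trajectory as ``frame,id,x,y[,z]`` CSV, in body-length units.

    Fully-missing samples are written with empty coordinate fields so the
    mask round-trips through :func:`read_trajectory`.
    """
    cols = _columns_for(traj.ndim)
    n_f, n_i, nd = traj.positions.shape
    frame_col = np.repeat(traj.frames, n_i)
    id_col = np.tile(traj.fish_ids, n_f)
    flat = traj.positions.reshape(n_f * n_i, nd)
    df = pd.DataFrame({"frame": frame_col, "id": id_col})
    for k, name in enumerate(cols[2:]):
        df[name] = flat[:, k]
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.10g", na_rep="")
    if hasattr(path, "write"):
        path.write(buf.getvalue())
    else:
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def write_velocities(vel: VelocitySeries, traj: TrajectoryDataset, path) -> None:
    """Write a velocity sidecar CSV (``frame,id,vx,vy[,vz]``)."""
    n_f, n_i, nd = vel.velocities.shape
    df = pd.DataFrame(
        {
            "frame": np.repeat(traj.frames, n_i),
            "id": np.tile(traj.fish_ids, n_f),
        }
    )
    names = ["vx", "vy"] + (["vz"] if nd == 3 else [])
    flat = vel.velocities.reshape(n_f * n_i, nd)
    for k, name in enumerate(names):
        df[name] = flat[:, k]
    df.to_csv(path, index=False, float_format="%.10g", na_rep="")


def read_velocities(path, traj: TrajectoryDataset,
                    speed_floor: float = DEFAULT_SPEED_FLOOR) -> VelocitySeries:
    """Read a velocity sidecar written by :func:`write_velocities`."""
    df = pd.read_csv(path, comment="#")
    names = ["vx", "vy"] + (["vz"] if traj.is_3d else [])
    vel = np.full((traj.n_frames, traj.n_fish, traj.ndim), np.nan)
    fidx = np.searchsorted(traj.frames, df["frame"].to_numpy(dtype=int))
    iidx = np.searchsorted(traj.fish_ids, df["id"].to_numpy(dtype=int))
    vel[fidx, iidx] = df[names].to_numpy(dtype=float)
    speeds = np.linalg.norm(vel, axis=2)
    with np.errstate(invalid="ignore"):
        valid = np.isfinite(speeds) & (speeds > speed_floor)
    return VelocitySeries(vel, valid, scheme="analytic")
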