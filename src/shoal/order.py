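"""Polarization / rotation order parameters and state classification.

The polarization order parameter is

    O_p = (1/N) | sum_i v_i / |v_i| |

and the rotation order parameter

    O_r = (1/N) | sum_i  v_i/|v_i|  x  (r_i - r_cm)/|r_i - r_cm| |

with r_cm the group centre of mass.  In 2D the cross product is the
scalar z-component; in 3D it is a vector and |.| its Euclidean norm.
Frames are classified per-frame with fixed thresholds: schooling when
O_p is high, milling when O_r is high, swarming when both are low.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .trajectory import TrajectoryDataset, VelocitySeries, estimate_velocities

logger = logging.getLogger(__name__)

__all__ = [
    "StateThresholds",
    "OrderParameterSeries",
    "OccupancyReport",
    "STATES",
    "polarization",
    "rotation",
    "classify",
    "order_parameters",
    "occupancy",
    "op_or_density",
    "subgroup_series",
    "nearest_neighbor_subgroups",
]

STATES = ("schooling", "milling", "swarming", "unclassified")


@dataclass(frozen=True)
class StateThresholds:
    """Classification thresholds on the (O_p, O_r) plane."""

    high: float = 0.65
    low: float = 0.35

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high <= 1:
            raise ValueError("need 0 <= low < high <= 1")


@dataclass
class OrderParameterSeries:
    """Per-frame (O_p, O_r) values and state labels for one group.

    ``op``/``orr`` are NaN on frames where too few fish have a defined
    heading; those frames are labelled ``unclassified``.
    """

    frames: np.ndarray
    op: np.ndarray
    orr: np.ndarray
    state: np.ndarray       # '<U12' labels, one per frame
    group_size: int
    focal_id: int | None = None

    def __post_init__(self) -> None:
        ok = np.isfinite(self.op)
        if np.any((self.op[ok] < 0) | (self.op[ok] > 1 + 1e-12)):
            raise ValueError("O_p out of [0, 1]")
        ok = np.isfinite(self.orr)
        if np.any((self.orr[ok] < 0) | (self.orr[ok] > 1 + 1e-12)):
            raise ValueError("O_r out of [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.size

    def state_mask(self, state: str) -> np.ndarray:
        if state not in STATES:
            raise ValueError(f"unknown state {state!r}")
        return self.state == state


@dataclass
class OccupancyReport:
    """Fraction of frames spent in each dynamical state."""

    fractions: dict[str, float]
    counts: dict[str, int] = field(default_factory=dict)
    group_size: int = 0
    total_frames: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.total_frames and abs(total - 1.0) > 1e-9:
            raise ValueError("state fractions must sum to 1")


def _unit_rows(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalise rows; returns (units, norm>0 mask)."""
    norms = np.linalg.norm(vectors, axis=-1)
    ok = np.isfinite(norms) & (norms > 0)
    units = np.zeros_like(vectors)
    np.divide(vectors, norms[..., None], out=units, where=ok[..., None])
    return units, ok


def polarization(velocities: np.ndarray) -> float:
    """O_p of a single frame given an ``(n, d)`` velocity array."""
    v = np.asarray(velocities, dtype=float)
    units, ok = _unit_rows(v)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no fish with a defined heading")
    return float(np.linalg.norm(units[ok].sum(axis=0)) / n)


def rotation(positions: np.ndarray, velocities: np.ndarray) -> float:
    """O_r of a single frame given ``(n, d)`` positions and velocities.

    Fish coincident with the group centre have no defined radial
    direction and are excluded (and logged).
    """
    r = np.asarray(positions, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if r.shape[0] < 2:
        raise ValueError("rotation needs at least 2 fish")
    vhat, v_ok = _unit_rows(v)
    r_cm = r.mean(axis=0)
    uhat, u_ok = _unit_rows(r - r_cm)
    ok = v_ok & u_ok
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no fish with defined heading and radial direction")
    if n < r.shape[0]:
        logger.debug("rotation: excluded %d degenerate fish", r.shape[0] - n)
    if r.shape[1] == 2:
        cross = vhat[ok, 0] * uhat[ok, 1] - vhat[ok, 1] * uhat[ok, 0]
        return float(abs(cross.sum()) / n)
    cross = np.cross(vhat[ok], uhat[ok])
    return float(np.linalg.norm(cross.sum(axis=0)) / n)


def classify(op: float, orr: float,
             thresholds: StateThresholds = StateThresholds()) -> str:
    """Label a single (O_p, O_r) pair.

    When both order parameters exceed the high threshold — a region the
    frame-wise thresholding leaves ambiguous — the larger of the two
    wins; an exact tie stays unclassified.
    """
    if np.isnan(op) or np.isnan(orr):
        return "unclassified"
    hi, lo = thresholds.high, thresholds.low
    if op > hi and orr > hi:
        if op > orr:
            return "schooling"
        if orr > op:
            return "milling"
        return "unclassified"
    if op > hi:
        return "schooling"
    if orr > hi:
        return "milling"
    if op < lo and orr < lo:
        return "swarming"
    return "unclassified"


def _classify_series(op: np.ndarray, orr: np.ndarray,
                     thresholds: StateThresholds) -> np.ndarray:
    hi, lo = thresholds.high, thresholds.low
    state = np.full(op.shape, "unclassified", dtype="<U12")
    with np.errstate(invalid="ignore"):
        school = op > hi
        mill = orr > hi
        both = school & mill
        state[school & ~both] = "schooling"
        state[mill & ~both] = "milling"
        state[both & (op > orr)] = "schooling"
        state[both & (orr > op)] = "milling"
        state[(op < lo) & (orr < lo)] = "swarming"
    return state


def _series_from_arrays(pos: np.ndarray, vel: np.ndarray, valid: np.ndarray,
                        frames: np.ndarray, thresholds: StateThresholds,
                        group_size: int,
                        focal_id: int | None = None) -> OrderParameterSeries:
    """Vectorised (O_p, O_r) over ``(F, n, d)`` stacks with a valid mask."""
    vhat, v_ok = _unit_rows(vel)
    v_ok &= valid
    n_v = v_ok.sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        psum = np.where(v_ok[..., None], vhat, 0.0).sum(axis=1)
        op = np.where(n_v > 0, np.linalg.norm(psum, axis=1) / n_v, np.nan)

    # O_r: centre of mass over the same fish that enter the sum
    pos_ok = v_ok & np.isfinite(pos).all(axis=2)
    n_p = pos_ok.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cm = (np.where(pos_ok[..., None], pos, 0.0).sum(axis=1)
              / np.maximum(n_p, 1)[:, None])
    rel = pos - cm[:, None, :]
    uhat, u_ok = _unit_rows(rel)
    ok = pos_ok & u_ok
    n_r = ok.sum(axis=1)
    if pos.shape[2] == 2:
        cr = vhat[..., 0] * uhat[..., 1] - vhat[..., 1] * uhat[..., 0]
        csum = np.where(ok, cr, 0.0).sum(axis=1)
        orr_val = np.abs(csum)
    else:
        cr = np.cross(vhat, uhat)
        csum = np.where(ok[..., None], cr, 0.0).sum(axis=1)
        orr_val = np.linalg.norm(csum, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        orr = np.where(n_r >= 2, orr_val / np.maximum(n_r, 1), np.nan)
    op = np.where(n_v >= 1, op, np.nan)
    state = _classify_series(op, orr, thresholds)
    return OrderParameterSeries(frames, op, orr, state, group_size, focal_id)


def order_parameters(
    traj: TrajectoryDataset,
    vel: VelocitySeries | None = None,
    thresholds: StateThresholds = StateThresholds(),
) -> OrderParameterSeries:
    """Per-frame O_p, O_r and state labels for the whole group.

    Fish with undefined headings (missing samples, sub-floor speed) are
    excluded from that frame's sums; a frame with no usable fish is
    labelled ``unclassified`` with NaN order parameters.
    """
    if vel is None:
        vel = estimate_velocities(traj)
    return _series_from_arrays(
        traj.positions, vel.velocities, vel.valid, traj.frames,
        thresholds, traj.n_fish,
    )


def occupancy(series: OrderParameterSeries) -> OccupancyReport:
    """Fraction of frames in each state."""
    total = series.n_frames
    if total == 0:
        raise ValueError("empty order-parameter series")
    counts = {s: int((series.state == s).sum()) for s in STATES}
    fractions = {s: counts[s] / total for s in STATES}
    logger.info("occupancy n=%d frames=%d: %s", series.group_size, total,
                {s: round(f, 4) for s, f in fractions.items()})
    return OccupancyReport(fractions, counts, series.group_size, total)


def op_or_density(
    series: OrderParameterSeries, bin_side: float = 0.025
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D frame-count histogram on the (O_p, O_r) unit square.

    Returns ``(counts, op_edges, or_edges)``; counts sum to the number
    of frames with defined order parameters.
    """
    edges = np.arange(0.0, 1.0 + bin_side / 2, bin_side)
    if edges[-1] < 1.0:  # bin_side does not divide 1: truncate last bin at 1
        edges = np.append(edges, 1.0)
    ok = np.isfinite(series.op) & np.isfinite(series.orr)
    counts, xe, ye = np.histogram2d(
        np.clip(series.op[ok], 0, 1), np.clip(series.orr[ok], 0, 1),
        bins=(edges, edges),
    )
    return counts, xe, ye


def nearest_neighbor_subgroups(
    positions: np.ndarray, n: int, chunk: int = 2048
) -> np.ndarray:
    """Indices ``(F, N, n)`` of each focal fish and its n-1 nearest
    neighbours, per frame.

    Column 0 is the focal fish itself.  Distance ties are broken by fish
    index (stable sort) for determinism.  Missing fish (NaN positions)
    are pushed to the end and never selected while real neighbours
    remain.
    """
    n_frames, n_fish = positions.shape[:2]
    if not 1 <= n <= n_fish:
        raise ValueError(f"subgroup size {n} not in [1, {n_fish}]")
    out = np.empty((n_frames, n_fish, n), dtype=np.intp)
    for lo in range(0, n_frames, chunk):
        hi = min(lo + chunk, n_frames)
        p = positions[lo:hi]
        d = np.linalg.norm(p[:, :, None, :] - p[:, None, :, :], axis=3)
        d = np.where(np.isnan(d), np.inf, d)
        idx = np.arange(p.shape[1])
        d[:, idx, idx] = -1.0  # focal first
        order = np.argsort(d, axis=2, kind="stable")
        out[lo:hi] = order[:, :, :n]
    return out


def subgroup_series(
    traj: TrajectoryDataset,
    n: int,
    vel: VelocitySeries | None = None,
    thresholds: StateThresholds = StateThresholds(),
) -> list[OrderParameterSeries]:
    """Order parameters of every local subgroup of ``n`` nearest
    neighbours, one series per focal fish.

    The subgroup of a focal fish at a frame is itself plus its ``n - 1``
    nearest neighbours by Euclidean distance at that frame; O_r uses the
    subgroup's own centre of mass.
    """
    if n > traj.n_fish:
        raise ValueError(f"subgroup size {n} exceeds group size {traj.n_fish}")
    if n < 2:
        raise ValueError("subgroup size must be >= 2")
    if vel is None:
        vel = estimate_velocities(traj)
    members = nearest_neighbor_subgroups(traj.positions, n)
    f_idx = np.arange(traj.n_frames)[:, None]
    series = []
    for k, fish_id in enumerate(traj.fish_ids):
        sel = members[:, k, :]                      # (F, n)
        pos = traj.positions[f_idx, sel]            # (F, n, d)
        v = vel.velocities[f_idx, sel]
        valid = vel.valid[f_idx, sel]
        series.append(_series_from_arrays(
            pos, v, valid, traj.frames, thresholds, n, focal_id=int(fish_id)
        ))
    return series


def pooled_occupancy(series_list: list[OrderParameterSeries]) -> OccupancyReport:
    """Occupancy pooled over all focal-fish subgroup series."""
    if not series_list:
        raise ValueError("no series given")
    counts = {s: 0 for s in STATES}
    total = 0
    for s in series_list:
        total += s.n_frames
        for name in STATES:
            counts[name] += int((s.state == name).sum())
    fractions = {k: v / total for k, v in counts.items()}
    return OccupancyReport(fractions, counts, series_list[0].group_size, total)
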