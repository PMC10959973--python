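"""Idealised configurations with analytic ground truth.

These generators bypass the simulator entirely: a perfectly polarized
single-file school, a perfect mill rotating about its centre, a fully
random swarm, and independent ideal-gas frames (the exact null for the
Kirkwood superposition).  Each returns the trajectory together with an
analytic velocity sidecar, so order-parameter values are exact rather
than finite-difference approximations.
"""

from __future__ import annotations

import numpy as np

from .trajectory import TrajectoryDataset, VelocitySeries

__all__ = ["perfect_school", "perfect_mill", "random_swarm",
           "ideal_gas_frames"]


def _dataset(pos: np.ndarray, frame_interval: float = 1.0) -> TrajectoryDataset:
    n_frames, n_fish = pos.shape[:2]
    return TrajectoryDataset(
        pos, np.arange(n_frames), np.arange(n_fish), frame_interval
    )


def _analytic(vel: np.ndarray) -> VelocitySeries:
    speeds = np.linalg.norm(vel, axis=2)
    return VelocitySeries(vel, speeds > 1e-12, scheme="analytic")


def perfect_school(
    n: int, spacing: float = 1.0, heading: float = 0.0, n_frames: int = 10
) -> tuple[TrajectoryDataset, VelocitySeries]:
    """A single-file line of ``n`` fish all swimming along ``heading``
    at unit speed; O_p = 1 exactly at every frame.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    e = np.array([np.cos(heading), np.sin(heading)])
    offsets = spacing * np.arange(n)[:, None] * e    # (n, 2)
    t = np.arange(n_frames)[:, None, None]
    pos = offsets[None, :, :] + t * e[None, None, :]
    vel = np.broadcast_to(e, (n_frames, n, 2)).copy()
    return _dataset(pos), _analytic(vel)


def perfect_mill(
    n: int, radius: float = 2.0, angular_speed: float = 0.5,
    n_frames: int = 10,
) -> tuple[TrajectoryDataset, VelocitySeries]:
    """``n`` fish equally spaced on a circle about the group centre with
    tangential (counter-clockwise) velocities; O_r = 1 exactly.

    Fish k starts at polar angle 2*pi*k/n (k = 0 at angle 0).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if radius <= 0:
        raise ValueError("radius must be positive")
    base = 2 * np.pi * np.arange(n) / n
    t = np.arange(n_frames)
    ang = base[None, :] + angular_speed * t[:, None]        # (F, n)
    pos = radius * np.stack([np.cos(ang), np.sin(ang)], axis=2)
    speed = radius * angular_speed
    vel = speed * np.stack([-np.sin(ang), np.cos(ang)], axis=2)
    return _dataset(pos), _analytic(vel)


def random_swarm(
    n: int, region_radius: float = 5.0, n_frames: int = 100, seed: int = 0
) -> tuple[TrajectoryDataset, VelocitySeries]:
    """Positions uniform in a disc, headings uniform on the circle,
    independent across fish and frames; unit speeds.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    pos = _uniform_disc(rng, (n_frames, n), region_radius)
    theta = rng.uniform(-np.pi, np.pi, size=(n_frames, n))
    vel = np.stack([np.cos(theta), np.sin(theta)], axis=2)
    return _dataset(pos), _analytic(vel)


def ideal_gas_frames(
    n: int, region_radius: float = 10.0, n_frames: int = 1000, seed: int = 0
) -> tuple[TrajectoryDataset, VelocitySeries]:
    """Fully independent uniform positions in a disc — the exact null
    for three-body analysis: the observed triplet density and its
    Kirkwood superposition prediction agree up to sampling error
    (and O(1/region_radius) boundary effects near the rim).
    """
    if n < 3:
        raise ValueError("need n >= 3 for triplet analysis")
    rng = np.random.default_rng(seed)
    pos = _uniform_disc(rng, (n_frames, n), region_radius)
    theta = rng.uniform(-np.pi, np.pi, size=(n_frames, n))
    vel = np.stack([np.cos(theta), np.sin(theta)], axis=2)
    return _dataset(pos), _analytic(vel)


def _uniform_disc(rng: np.random.Generator, shape: tuple, radius: float
                  ) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=shape))
    a = rng.uniform(-np.pi, np.pi, size=shape)
    return np.stack([r * np.cos(a), r * np.sin(a)], axis=len(shape))
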