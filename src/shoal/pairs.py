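"""Comoving-frame pair correlations and radial g2.

The comoving map g2(x', y') is the density of neighbour positions in
the reference frame of a focal fish: x' along the focal heading, y'
90 degrees counter-clockwise from it.  Its characteristic features are
a front peak (beta) produced by fish following one another and two side
peaks (alpha left, gamma right) produced by side-by-side swimming or
milling.  For 3D data the frame is built in the horizontal plane from
the horizontal velocity component and vertical separation is
marginalised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .order import OrderParameterSeries
from .trajectory import TrajectoryDataset, VelocitySeries, estimate_velocities

logger = logging.getLogger(__name__)

__all__ = ["ComovingMap", "RadialPairCorrelation", "Peak",
           "comoving_coordinates", "g2_map", "radial_g2", "detect_peaks"]

#: contour levels used in rendered maps
CONTOUR_LEVELS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class ComovingMap:
    """2D histogram of neighbour positions in the focal-fish frame."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray          # raw counts, shape (nx, ny)
    pair_mode: str              # "all" | "nearest"
    state_filter: str | None
    n_samples: int

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if int(self.counts.sum()) != self.n_samples:
            raise ValueError("counts must sum to the number of samples")

    @property
    def intensity(self) -> np.ndarray:
        """Max-normalised map in [0, 1]."""
        m = self.counts.max()
        return self.counts / m if m > 0 else self.counts.astype(float)

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


@dataclass
class RadialPairCorrelation:
    """Shell-normalised, max-normalised radial pair correlation g2(r)."""

    r_centers: np.ndarray
    g2: np.ndarray
    counts: np.ndarray
    state_filter: str | None
    n_samples: int

    def __post_init__(self) -> None:
        if np.any(self.g2 < 0):
            raise ValueError("g2 must be non-negative")

    @property
    def r_max(self) -> float:
        """Location of the principal peak."""
        return float(self.r_centers[int(np.argmax(self.g2))])

    def __call__(self, r: np.ndarray) -> np.ndarray:
        """Linear interpolation of g2 at arbitrary radii (0 outside)."""
        return np.interp(r, self.r_centers, self.g2, left=self.g2[0],
                         right=0.0)


@dataclass
class Peak:
    label: str       # "beta" (front), "alpha" (left), "gamma" (right), "back"
    x: float
    y: float
    height: float    # relative to map maximum


def _headings_2d(vel: VelocitySeries) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal-plane heading angles (F, N) and validity mask."""
    v = vel.velocities[..., :2]
    sp = np.linalg.norm(v, axis=2)
    with np.errstate(invalid="ignore"):
        ok = vel.valid & np.isfinite(sp) & (sp > 1e-12)
    ang = np.arctan2(v[..., 1], v[..., 0])
    return ang, ok


def comoving_coordinates(
    traj: TrajectoryDataset, vel: VelocitySeries, frame: int,
    focal: int, other: int,
) -> tuple[float, float]:
    """Position of ``other`` in the comoving frame of ``focal`` at a
    frame index: x' along the focal heading, y' to its left."""
    f = int(np.searchsorted(traj.frames, frame))
    if f >= traj.n_frames or traj.frames[f] != frame:
        raise ValueError(f"frame {frame} not in dataset")
    ki = int(np.searchsorted(traj.fish_ids, focal))
    kj = int(np.searchsorted(traj.fish_ids, other))
    ang, ok = _headings_2d(vel)
    if not ok[f, ki]:
        raise ValueError(f"focal fish {focal} has undefined heading at "
                         f"frame {frame}")
    d = traj.positions[f, kj, :2] - traj.positions[f, ki, :2]
    c, s = np.cos(ang[f, ki]), np.sin(ang[f, ki])
    return float(c * d[0] + s * d[1]), float(-s * d[0] + c * d[1])


def _state_mask(traj: TrajectoryDataset,
                state_filter: str | None,
                state_series: OrderParameterSeries | None) -> np.ndarray:
    if state_filter is None:
        return np.ones(traj.n_frames, dtype=bool)
    if state_series is None:
        raise ValueError("state_filter given without a state series")
    if state_series.frames.shape != traj.frames.shape or \
            np.any(state_series.frames != traj.frames):
        raise ValueError("state series frames do not match trajectory")
    return state_series.state_mask(state_filter)


def g2_map(
    traj: TrajectoryDataset,
    vel: VelocitySeries | None = None,
    pair_mode: str = "all",
    state_filter: str | None = None,
    state_series: OrderParameterSeries | None = None,
    bin_width: float = 0.2,
    extent: float = 5.0,
    chunk: int = 4096,
) -> ComovingMap:
    """Comoving-frame pair-correlation histogram.

    ``pair_mode="all"`` samples every ordered (focal, other) pair;
    ``"nearest"`` samples only each focal fish's nearest neighbour —
    exactly one sample per focal fish per eligible frame.  An optional
    state filter restricts to frames carrying that label in
    ``state_series``.
    """
    if pair_mode not in ("all", "nearest"):
        raise ValueError("pair_mode must be 'all' or 'nearest'")
    if vel is None:
        vel = estimate_velocities(traj)
    fmask = _state_mask(traj, state_filter, state_series)
    ang, ok = _headings_2d(vel)
    edges = np.arange(-extent, extent + bin_width / 2, bin_width)
    counts = np.zeros((edges.size - 1, edges.size - 1))
    pos = traj.positions[..., :2]
    pos_ok = np.isfinite(traj.positions).all(axis=2)
    n_samples = 0
    for lo in range(0, traj.n_frames, chunk):
        hi = min(lo + chunk, traj.n_frames)
        sub = slice(lo, hi)
        fm = fmask[sub]
        p = pos[sub]                                 # (f, N, 2)
        d = p[:, None, :, :] - p[:, :, None, :]      # d[f, i, j] = r_j - r_i
        focal_ok = ok[sub] & pos_ok[sub]             # (f, N)
        other_ok = pos_ok[sub]
        pair_ok = (focal_ok[:, :, None] & other_ok[:, None, :]
                   & fm[:, None, None])
        idx = np.arange(p.shape[1])
        pair_ok[:, idx, idx] = False
        if pair_mode == "nearest":
            dist = np.linalg.norm(d, axis=3)
            dist = np.where(pair_ok, dist, np.inf)
            nn = np.argsort(dist, axis=2, kind="stable")[:, :, 0]
            sel = np.zeros_like(pair_ok)
            f_i = np.arange(p.shape[0])[:, None]
            sel[f_i, idx[None, :], nn] = True
            pair_ok &= sel & np.isfinite(dist)
        a = ang[sub][:, :, None]
        c, s = np.cos(a), np.sin(a)
        xp = c * d[..., 0] + s * d[..., 1]
        yp = -s * d[..., 0] + c * d[..., 1]
        xs = xp[pair_ok]
        ys = yp[pair_ok]
        h, _, _ = np.histogram2d(xs, ys, bins=(edges, edges))
        counts += h
        n_samples += xs.size
    if n_samples == 0:
        raise ValueError("no eligible pair samples")
    inside = int(counts.sum())
    logger.info("g2_map mode=%s state=%s: %d samples (%d inside extent)",
                pair_mode, state_filter, n_samples, inside)
    return ComovingMap(edges, edges, counts, pair_mode, state_filter, inside)


def disc_set_covariance(r: np.ndarray, radius: float) -> np.ndarray:
    """Fraction of a disc's area overlapping itself displaced by r
    (isotropic set covariance, used for edge correction)."""
    r = np.asarray(r, dtype=float)
    x = np.clip(r / (2.0 * radius), 0.0, 1.0)
    area = 2.0 * radius**2 * np.arccos(x) \
        - 0.5 * r * np.sqrt(np.maximum(4.0 * radius**2 - r**2, 0.0))
    return area / (np.pi * radius**2)


def radial_g2(
    traj: TrajectoryDataset,
    state_filter: str | None = None,
    state_series: OrderParameterSeries | None = None,
    bin_width: float = 0.1,
    r_range: tuple[float, float] = (0.0, 10.0),
    window_radius: float | None = None,
    chunk: int = 8192,
) -> RadialPairCorrelation:
    """Radial pair correlation: pair-distance histogram divided by the
    shell measure (2 pi r dr in 2D, 4 pi r^2 dr in 3D), max-normalised.

    When the positions are confined to a known disc-shaped observation
    window centred on the origin, pass its radius as ``window_radius``
    to apply the isotropic (Ripley) edge correction; without it, g2 of
    even an ideal gas decays with r purely because large separations
    have less room in the window.
    """
    fmask = _state_mask(traj, state_filter, state_series)
    edges = np.arange(r_range[0], r_range[1] + bin_width / 2, bin_width)
    counts = np.zeros(edges.size - 1)
    pos = traj.positions
    pos_ok = np.isfinite(pos).all(axis=2)
    n_samples = 0
    n_fish = traj.n_fish
    iu, ju = np.triu_indices(n_fish, k=1)
    for lo in range(0, traj.n_frames, chunk):
        hi = min(lo + chunk, traj.n_frames)
        p = pos[lo:hi]
        both = pos_ok[lo:hi][:, iu] & pos_ok[lo:hi][:, ju] \
            & fmask[lo:hi][:, None]
        d = np.linalg.norm(p[:, iu] - p[:, ju], axis=2)[both]
        counts += np.histogram(d, bins=edges)[0]
        n_samples += d.size
    if n_samples == 0:
        raise ValueError("no eligible pair samples")
    centers = 0.5 * (edges[:-1] + edges[1:])
    if traj.is_3d:
        shell = 4.0 * np.pi * centers**2 * bin_width
    else:
        shell = 2.0 * np.pi * centers * bin_width
    if window_radius is not None:
        if traj.is_3d:
            raise NotImplementedError("edge correction is 2D-only")
        shell = shell * np.maximum(
            disc_set_covariance(centers, window_radius), 1e-12)
    g = counts / shell
    m = g.max()
    if m > 0:
        g = g / m
    return RadialPairCorrelation(centers, g, counts, state_filter, n_samples)


def detect_peaks(
    cmap: ComovingMap, rel_floor: float = 0.5, y_tol: float = 0.5
) -> list[Peak]:
    """Local maxima of the map above ``rel_floor`` of its maximum,
    labelled by position: ``beta`` the front peak (x' > 0 on-axis),
    ``alpha``/``gamma`` the left/right side peaks, ``back`` behind.
    """
    z = cmap.intensity
    if z.max() <= 0:
        raise ValueError("empty map")
    footprint = np.ones((3, 3), dtype=bool)
    local_max = (ndimage.maximum_filter(z, footprint=footprint,
                                        mode="constant") == z)
    xs, ys = cmap.x_centers, cmap.y_centers
    # merge plateaus: keep one representative per connected component
    lab, n_lab = ndimage.label(local_max & (z >= rel_floor))
    peaks = []
    for k in range(1, n_lab + 1):
        pts = np.argwhere(lab == k)
        i, j = pts[np.argmax(z[pts[:, 0], pts[:, 1]])]
        x, y, h = float(xs[i]), float(ys[j]), float(z[i, j])
        if abs(y) < y_tol:
            label = "beta" if x > 0 else "back"
        else:
            label = "alpha" if y > 0 else "gamma"
        peaks.append(Peak(label, x, y, h))
    peaks.sort(key=lambda p: -p.height)
    return peaks
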