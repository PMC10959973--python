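"""Three-body statistics: bond angles, triplet maps and Kirkwood
superposition.

For a trio of fish the bond angle at a vertex is the angle between the
two bonds meeting there, computed only when both bonds fall in a
separation window (normally centred on the principal peak of g2).  The
triplet map g3(x3~, y3~) histograms the third fish in the frame whose
x-axis lies along a reference pair separated by r12 inside a window
around r_max, with the origin at the pair midpoint.  The Kirkwood
superposition predicts this map from pair correlations alone:

    g3(r12, r23, r31) ~ g2(r12) g2(r23) g2(r31)

which is exact for independent particles; a systematic excess of the
observed map over the prediction signals effective three-body
correlations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .order import OrderParameterSeries
from .pairs import RadialPairCorrelation, _headings_2d, _state_mask
from .trajectory import TrajectoryDataset, VelocitySeries, estimate_velocities

logger = logging.getLogger(__name__)

__all__ = ["OrientationCondition", "BondAngleDistribution", "TripletMap",
           "KirkwoodDiscrepancy", "bond_angles", "g3_map", "kirkwood_map",
           "orientation_filter", "kirkwood_discrepancy"]


@dataclass(frozen=True)
class OrientationCondition:
    """Constraint on the reference pair's relative orientation.

    ``side_by_side``: headings aligned and the separation roughly
    perpendicular to the mean heading.  ``head_to_tail``: headings
    aligned and the separation roughly parallel to it.
    """

    mode: str = "none"               # none | side_by_side | head_to_tail
    heading_tol_deg: float = 30.0    # max angle between the two headings
    separation_tol_deg: float = 30.0  # max angle off perpendicular/parallel

    def __post_init__(self) -> None:
        if self.mode not in ("none", "side_by_side", "head_to_tail"):
            raise ValueError(f"unknown orientation mode {self.mode!r}")
        for v in (self.heading_tol_deg, self.separation_tol_deg):
            if not 0 < v < 90:
                raise ValueError("orientation thresholds must be in (0, 90)")


@dataclass
class BondAngleDistribution:
    """Normalised histogram of three-fish bond angles on [0, 180] deg."""

    angle_centers: np.ndarray   # degrees
    probability: np.ndarray
    counts: np.ndarray
    window: tuple[float, float]
    state_filter: str | None
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples > 0 and abs(self.probability.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def mode_angle(self) -> float:
        """Bin centre of the most probable angle."""
        return float(self.angle_centers[int(np.argmax(self.probability))])


@dataclass
class TripletMap:
    """Observed triplet density and its Kirkwood prediction on a grid."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray              # observed raw counts
    g3: np.ndarray                  # observed, max-normalised
    g3k: np.ndarray | None          # Kirkwood prediction, max-normalised
    r12_window: tuple[float, float]
    orientation: str = "none"
    n_samples: int = 0
    baseline: np.ndarray | None = None   # per-bin geometric acceptance

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.g3k is not None and self.g3k.shape != self.g3.shape:
            raise ValueError("g3 and g3k must share binning")

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


@dataclass
class KirkwoodDiscrepancy:
    """Observed-minus-Kirkwood difference and its sampling envelope."""

    difference: np.ndarray        # g3 - g3k, normalised units
    envelope: np.ndarray          # 1-sigma per-bin sampling error
    interior: np.ndarray          # bool mask of bins entering the summary
    max_abs_interior: float
    central_excess: float         # mean difference over the central region

    @property
    def max_envelope_ratio(self) -> float:
        """max over interior bins of |difference| / envelope."""
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.abs(self.difference) / self.envelope
        ratio = np.where(self.interior & np.isfinite(ratio), ratio, 0.0)
        return float(ratio.max())


def _triplet_frames(traj: TrajectoryDataset, fmask: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Positions (F, 3, 2) of frames with exactly three present fish."""
    if traj.n_fish != 3:
        raise ValueError(
            "triplet statistics need a 3-fish trajectory; extract "
            "subgroups first for larger groups")
    pos = traj.positions[..., :2]
    ok = np.isfinite(traj.positions).all(axis=(1, 2)) & fmask
    return pos[ok], ok


def bond_angles(
    traj: TrajectoryDataset,
    window: tuple[float, float],
    state_filter: str | None = None,
    state_series: OrderParameterSeries | None = None,
    bin_width_deg: float = 10.0,
) -> BondAngleDistribution:
    """Distribution of the bond angle at each vertex of the three-fish
    triangle, counting a vertex only when both incident bonds lie in
    ``window`` (the separation band around the g2 principal peak)."""
    if window[0] >= window[1]:
        raise ValueError("window must satisfy r_lo < r_hi")
    fmask = _state_mask(traj, state_filter, state_series)
    pos, _ = _triplet_frames(traj, fmask)
    edges = np.arange(0.0, 180.0 + bin_width_deg / 2, bin_width_deg)
    counts = np.zeros(edges.size - 1)
    n_samples = 0
    if pos.shape[0]:
        angles = _vertex_angles(pos)                  # (F, 3) degrees
        lens = _bond_lengths(pos)                     # (F, 3): r12, r23, r31
        in_win = (lens >= window[0]) & (lens <= window[1])
        # vertex k has incident bonds (k-1, k): vertex 0 -> bonds r31, r12
        incident = np.stack([in_win[:, 2] & in_win[:, 0],
                             in_win[:, 0] & in_win[:, 1],
                             in_win[:, 1] & in_win[:, 2]], axis=1)
        sel = angles[incident]
        counts = np.histogram(np.clip(sel, 0, 180 - 1e-9), bins=edges)[0]
        n_samples = int(sel.size)
    if n_samples == 0:
        raise ValueError("no bond-angle samples in the given window")
    prob = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    logger.info("bond_angles state=%s window=%s: %d samples, mode %.0f deg",
                state_filter, window, n_samples,
                centers[int(np.argmax(prob))])
    return BondAngleDistribution(centers, prob, counts, tuple(window),
                                 state_filter, n_samples)


def _bond_lengths(pos: np.ndarray) -> np.ndarray:
    """(F, 3) bond lengths r12, r23, r31 for (F, 3, 2) positions."""
    r12 = np.linalg.norm(pos[:, 1] - pos[:, 0], axis=1)
    r23 = np.linalg.norm(pos[:, 2] - pos[:, 1], axis=1)
    r31 = np.linalg.norm(pos[:, 0] - pos[:, 2], axis=1)
    return np.stack([r12, r23, r31], axis=1)


def _vertex_angles(pos: np.ndarray) -> np.ndarray:
    """(F, 3) interior angles in degrees at each vertex of each triangle."""
    out = np.empty((pos.shape[0], 3))
    for k in range(3):
        a = pos[:, (k + 1) % 3] - pos[:, k]
        b = pos[:, (k + 2) % 3] - pos[:, k]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.einsum("ij,ij->i", a, b) / (na * nb)
        out[:, k] = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return out


def orientation_filter(
    vel: VelocitySeries, frame_index: int, fish1: int, fish2: int,
    cond: OrientationCondition,
    separation: np.ndarray | None = None,
    traj: TrajectoryDataset | None = None,
) -> bool:
    """Does the (fish1, fish2) pair satisfy the orientation condition?

    ``separation`` is r2 - r1 (horizontal); it may be given directly or
    found from ``traj``.  For ``head_to_tail``, fish1 is the follower:
    the separation must point from fish1 toward fish2 along the mean
    heading.
    """
    if cond.mode == "none":
        return True
    ang, ok = _headings_2d(vel)
    if not (ok[frame_index, fish1] and ok[frame_index, fish2]):
        return False
    a1, a2 = ang[frame_index, fish1], ang[frame_index, fish2]
    dh = _wrap(a1 - a2)
    if abs(dh) > np.radians(cond.heading_tol_deg):
        return False
    if separation is None:
        if traj is None:
            raise ValueError("need separation or traj")
        separation = (traj.positions[frame_index, fish2, :2]
                      - traj.positions[frame_index, fish1, :2])
    sep_ang = np.arctan2(separation[1], separation[0])
    mean = np.arctan2(np.sin(a1) + np.sin(a2), np.cos(a1) + np.cos(a2))
    off = _wrap(sep_ang - mean)
    tol = np.radians(cond.separation_tol_deg)
    if cond.mode == "side_by_side":
        return bool(abs(abs(off) - np.pi / 2) <= tol)
    return bool(abs(off) <= tol)   # head_to_tail: separation along heading


def _wrap(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


def g3_map(
    traj: TrajectoryDataset,
    r12_window: tuple[float, float],
    vel: VelocitySeries | None = None,
    orientation: OrientationCondition = OrientationCondition(),
    state_filter: str | None = None,
    state_series: OrderParameterSeries | None = None,
    bin_width: float = 0.25,
    extent: float = 4.0,
    window_radius: float | None = None,
) -> TripletMap:
    """Observed triplet map for a 3-fish trajectory.

    For every ordered reference pair (i, j) with |r_ij| inside
    ``r12_window`` (and satisfying the orientation condition, if any),
    the third fish is histogrammed in the frame with origin at the pair
    midpoint and x3~ along r_j - r_i.  With no orientation condition
    all six ordered pairs contribute, which symmetrises the map under
    x3~ -> -x3~; head-to-tail pairs are ordered follower -> leader.

    If the positions live in a known disc-shaped observation window
    centred on the origin, pass its radius as ``window_radius``: each
    bin is then divided by the fraction of reference pairs for which
    that bin lies inside the window (a Monte-Carlo edge correction
    using the sampled pair frames), so an ideal gas yields a flat map.
    """
    if r12_window[0] >= r12_window[1]:
        raise ValueError("r12_window must satisfy r_lo < r_hi")
    fmask = _state_mask(traj, state_filter, state_series)
    if orientation.mode != "none":
        if vel is None:
            vel = estimate_velocities(traj)
        ang, head_ok = _headings_2d(vel)
    pos, frame_sel = _triplet_frames(traj, fmask)
    frame_ids = np.nonzero(frame_sel)[0]
    edges = np.arange(-extent, extent + bin_width / 2, bin_width)
    counts = np.zeros((edges.size - 1, edges.size - 1))
    xc = 0.5 * (edges[:-1] + edges[1:])
    gx, gy = np.meshgrid(xc, xc, indexing="ij")
    baseline = (np.zeros_like(counts) if window_radius is not None else None)
    n_samples = 0
    n_pairs = 0
    for (i, j) in itertools.permutations(range(3), 2):
        k = 3 - i - j
        d = pos[:, j] - pos[:, i]
        r12 = np.linalg.norm(d, axis=1)
        sel = (r12 >= r12_window[0]) & (r12 <= r12_window[1])
        if orientation.mode != "none":
            sel &= _orientation_vec(ang, head_ok, frame_ids, i, j, d,
                                    orientation)
        if not sel.any():
            continue
        dd = d[sel]
        rr = r12[sel]
        mid = 0.5 * (pos[sel, i] + pos[sel, j])
        rel = pos[sel, k] - mid
        ex = dd / rr[:, None]
        x3 = ex[:, 0] * rel[:, 0] + ex[:, 1] * rel[:, 1]
        y3 = -ex[:, 1] * rel[:, 0] + ex[:, 0] * rel[:, 1]
        h, _, _ = np.histogram2d(x3, y3, bins=(edges, edges))
        counts += h
        n_samples += int(h.sum())
        n_pairs += int(sel.sum())
        if baseline is not None:
            # which map bins fall inside the window, per sampled pair frame
            for lo in range(0, dd.shape[0], 512):
                exc = ex[lo:lo + 512]
                mc = mid[lo:lo + 512]
                px = (mc[:, 0, None, None] + exc[:, 0, None, None] * gx
                      - exc[:, 1, None, None] * gy)
                py = (mc[:, 1, None, None] + exc[:, 1, None, None] * gx
                      + exc[:, 0, None, None] * gy)
                baseline += (px * px + py * py
                             < window_radius**2).sum(axis=0)
    if n_samples == 0:
        raise ValueError("no frames with r12 inside the window")
    if baseline is None:
        m = counts.max()
        g3 = counts / m if m > 0 else counts
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            intensity = np.where(baseline > 0.05 * n_pairs,
                                 counts / baseline, np.nan)
        m = np.nanmax(intensity)
        g3 = intensity / m if m > 0 else intensity
    logger.info("g3_map state=%s orient=%s window=%s: %d samples",
                state_filter, orientation.mode, r12_window, n_samples)
    return TripletMap(edges, edges, counts, g3, None, tuple(r12_window),
                      orientation.mode, n_samples, baseline)


def _orientation_vec(ang, head_ok, frame_ids, i, j, d, cond):
    """Vectorised orientation condition over selected triplet frames."""
    a1 = ang[frame_ids, i]
    a2 = ang[frame_ids, j]
    ok = head_ok[frame_ids, i] & head_ok[frame_ids, j]
    dh = np.abs(_wrap(a1 - a2))
    ok &= dh <= np.radians(cond.heading_tol_deg)
    mean = np.arctan2(np.sin(a1) + np.sin(a2), np.cos(a1) + np.cos(a2))
    sep_ang = np.arctan2(d[:, 1], d[:, 0])
    off = _wrap(sep_ang - mean)
    tol = np.radians(cond.separation_tol_deg)
    if cond.mode == "side_by_side":
        ok &= np.abs(np.abs(off) - np.pi / 2) <= tol
    else:
        ok &= np.abs(off) <= tol
    return ok


def kirkwood_map(radial: RadialPairCorrelation, template: TripletMap
                 ) -> TripletMap:
    """Kirkwood superposition prediction on the template's grid.

    With the reference pair fixed at the window centre, the g2(r12)
    factor is a constant absorbed by max-normalisation, leaving
    g3K(x3~, y3~) ~ g2(|r13|) g2(|r23|) with the reference fish at
    (-rc/2, 0) and (+rc/2, 0).  Bins needing g2 beyond its estimated
    support are NaN.
    """
    rc = 0.5 * (template.r12_window[0] + template.r12_window[1])
    xc, yc = np.meshgrid(template.x_centers, template.y_centers,
                         indexing="ij")
    r13 = np.hypot(xc + rc / 2.0, yc)
    r23 = np.hypot(xc - rc / 2.0, yc)
    rmax_support = radial.r_centers[-1]
    g3k = radial(r13) * radial(r23)
    g3k = np.where((r13 > rmax_support) | (r23 > rmax_support), np.nan, g3k)
    m = np.nanmax(g3k)
    if m > 0:
        g3k = g3k / m
    return TripletMap(template.x_edges, template.y_edges, template.counts,
                      template.g3, g3k, template.r12_window,
                      template.orientation, template.n_samples,
                      template.baseline)


def kirkwood_discrepancy(
    tmap: TripletMap, interior_margin: int = 2,
    central_halfwidth: float = 0.5,
) -> KirkwoodDiscrepancy:
    """Per-bin difference g3 - g3K with a binomial sampling envelope.

    The two stored maps are max-normalised for display, but the raw
    maximum of a counted map is biased high by noise-peak selection,
    which would shift every observed bin down relative to the smooth
    Kirkwood side.  The comparison therefore rescales both sides to a
    common unit *interior mean* (an unbiased scale) before
    differencing.  The envelope propagates the per-bin counting error
    and the (small) error of the normalising mean.  The summary is the
    maximum |difference| over interior bins (at least
    ``interior_margin`` bins from every edge, Kirkwood value defined).
    ``central_excess`` reports the mean difference over the central
    region |x|,|y| < central_halfwidth — positive when a third fish
    between the reference pair is more likely than Kirkwood predicts.
    """
    if tmap.g3k is None:
        raise ValueError("map has no Kirkwood side; call kirkwood_map first")
    cmax = tmap.counts.max()
    if cmax <= 0:
        raise ValueError("empty observed map")
    if tmap.baseline is None:
        intensity = tmap.counts.astype(float)
        per_bin_sigma = np.sqrt(tmap.counts + 1.0)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            intensity = np.where(tmap.baseline > 0.0,
                                 tmap.counts / tmap.baseline, np.nan)
        per_bin_sigma = (np.sqrt(tmap.counts + 1.0)
                         / np.maximum(tmap.baseline, 1.0))
    mm = interior_margin
    core = np.zeros(intensity.shape, dtype=bool)
    if intensity.shape[0] > 2 * mm and intensity.shape[1] > 2 * mm:
        core[mm:-mm, mm:-mm] = True
    norm_mask = core & np.isfinite(intensity) & np.isfinite(tmap.g3k)
    if not norm_mask.any():
        raise ValueError("no interior bins with defined Kirkwood value")
    m_obs = float(intensity[norm_mask].mean())
    m_k = float(tmap.g3k[norm_mask].mean())
    if m_obs <= 0 or m_k <= 0:
        raise ValueError("degenerate normalisation")
    obs = intensity / m_obs
    kirk = tmap.g3k / m_k
    diff = obs - kirk
    sigma = per_bin_sigma / m_obs
    # error of the normalising mean: pooled counts of the interior bins
    rel_norm = 1.0 / np.sqrt(max(tmap.counts[norm_mask].sum(), 1.0))
    envelope = sigma + np.abs(np.nan_to_num(obs)) * rel_norm + 1.0 / cmax
    interior = np.zeros(diff.shape, dtype=bool)
    m = interior_margin
    if diff.shape[0] > 2 * m and diff.shape[1] > 2 * m:
        interior[m:-m, m:-m] = True
    interior &= np.isfinite(diff)
    if not interior.any():
        raise ValueError("no interior bins with defined Kirkwood value")
    max_abs = float(np.abs(diff[interior]).max())
    xc, yc = np.meshgrid(tmap.x_centers, tmap.y_centers, indexing="ij")
    central = ((np.abs(xc) < central_halfwidth)
               & (np.abs(yc) < central_halfwidth) & np.isfinite(diff))
    central_excess = float(diff[central].mean()) if central.any() else np.nan
    return KirkwoodDiscrepancy(diff, envelope, interior, max_abs,
                               central_excess)
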