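import numpy as np
import pytest

import shoal
from shoal.pairs import RadialPairCorrelation, radial_g2
from shoal.triplets import (OrientationCondition, _vertex_angles,
                            bond_angles, g3_map, kirkwood_discrepancy,
                            kirkwood_map, orientation_filter)


def traj_from(pos_frames):
    pos = np.asarray(pos_frames, dtype=float)
    return shoal.TrajectoryDataset(pos, np.arange(pos.shape[0]),
                                   np.arange(pos.shape[1]), 1.0)


class TestBondAngles:
    def test_equilateral_all_sixty(self):
        traj, _ = shoal.perfect_mill(3, radius=1.0, n_frames=10)
        side = np.sqrt(3.0)
        ba = bond_angles(traj, (side - 0.1, side + 0.1))
        # 60 deg sits on a bin edge; float rounding may land either side
        assert abs(ba.mode_angle - 60.0) <= 5.0
        mass_bins = np.nonzero(ba.counts)[0]
        assert set(mass_bins) <= {5, 6}

    def test_collinear_zero_and_one_eighty_in_ratio_two_one(self):
        traj, _ = shoal.perfect_school(3, spacing=1.0, n_frames=12)
        ba = bond_angles(traj, (0.9, 1.1))
        # both incident bonds must be in window: only the middle vertex
        # (180 deg) and the two end vertices fail the window on the long
        # 2 L bond, so ends enter only via the two short bonds
        assert ba.counts[-1] > 0   # 180 deg present
        # widen the window to admit the 2 L bonds: ends contribute 0 deg
        ba2 = bond_angles(traj, (0.5, 2.5))
        assert ba2.counts[0] / ba2.counts[-1] == pytest.approx(2.0)

    def test_vertex_angles_sum_to_180(self, rng):
        pos = rng.normal(size=(200, 3, 2))
        ang = _vertex_angles(pos)
        assert np.allclose(ang.sum(axis=1), 180.0, atol=1e-8)

    def test_matches_brute_force_resampling(self):
        """Histogram agrees with a direct per-frame loop oracle."""
        traj, _ = shoal.ideal_gas_frames(3, region_radius=3.0,
                                         n_frames=2000, seed=21)
        window = (1.0, 3.0)
        ba = bond_angles(traj, window, bin_width_deg=20.0)
        # oracle: explicit loop over frames and vertices
        counts = np.zeros(9)
        for f in range(2000):
            p = traj.positions[f]
            for k in range(3):
                a = p[(k + 1) % 3] - p[k]
                b = p[(k + 2) % 3] - p[k]
                na, nb = np.linalg.norm(a), np.linalg.norm(b)
                if window[0] <= na <= window[1] \
                        and window[0] <= nb <= window[1]:
                    ang = np.degrees(np.arccos(np.clip(
                        a @ b / (na * nb), -1, 1)))
                    counts[min(int(ang // 20), 8)] += 1
        assert np.array_equal(ba.counts, counts)

    def test_empty_window_raises(self):
        traj, _ = shoal.perfect_mill(3, radius=1.0, n_frames=5)
        with pytest.raises(ValueError):
            bond_angles(traj, (10.0, 11.0))


class TestG3Map:
    def test_third_fish_at_midpoint_occupies_central_bin(self):
        frames = [[[-1.0, 0.0], [1.0, 0.0], [0.0, 0.0]]] * 10
        tm = g3_map(traj_from(frames), (1.9, 2.1), bin_width=0.5,
                    extent=2.0)
        xc, yc = np.meshgrid(tm.x_centers, tm.y_centers, indexing="ij")
        occ = tm.counts > 0
        assert np.all(np.abs(xc[occ]) < 0.5)
        assert np.all(np.abs(yc[occ]) < 0.5)

    def test_equilateral_mass_at_triangle_height(self):
        side = 2.0
        h = side * np.sqrt(3) / 2
        frames = [[[-1.0, 0.0], [1.0, 0.0], [0.0, h]]] * 5
        tm = g3_map(traj_from(frames), (1.9, 2.1), bin_width=0.25,
                    extent=2.5)
        xc, yc = np.meshgrid(tm.x_centers, tm.y_centers, indexing="ij")
        occ = tm.counts > 0
        # the unconditioned map is symmetrised, so mass appears at +-h
        assert np.all(np.abs(np.abs(yc[occ]) - h) < 0.25)
        assert np.all(np.abs(xc[occ]) < 0.3)

    def test_symmetric_under_pair_relabeling(self):
        """The unconditioned estimator gives the same map when the fish
        labels are permuted."""
        traj, _ = shoal.ideal_gas_frames(3, region_radius=3.0,
                                         n_frames=3000, seed=22)
        tm = g3_map(traj, (1.5, 2.5), bin_width=0.5, extent=3.0)
        perm = traj.positions[:, [2, 0, 1]]
        tm2 = g3_map(traj_from(perm), (1.5, 2.5), bin_width=0.5,
                     extent=3.0)
        assert np.array_equal(tm.counts, tm2.counts)

    def test_point_symmetric_by_construction(self):
        """Summing both pair orderings makes the unconditioned map
        exactly symmetric under 180-degree rotation; the y-mirror
        symmetry alone is only statistical."""
        traj, _ = shoal.ideal_gas_frames(3, region_radius=3.0,
                                         n_frames=3000, seed=23)
        tm = g3_map(traj, (1.5, 2.5), bin_width=0.5, extent=3.0)
        assert np.array_equal(tm.counts, tm.counts[::-1, ::-1])
        asym = np.abs(tm.counts - tm.counts[:, ::-1]).sum() / tm.counts.sum()
        assert asym < 0.5


class TestOrientationFilter:
    def vel_of(self, a1, a2):
        v = np.zeros((1, 2, 2))
        v[0, 0] = [np.cos(a1), np.sin(a1)]
        v[0, 1] = [np.cos(a2), np.sin(a2)]
        return shoal.VelocitySeries(v, np.ones((1, 2), bool),
                                    scheme="analytic")

    def test_parallel_headings_perpendicular_separation(self):
        vel = self.vel_of(0.0, 0.0)
        sep = np.array([0.0, 1.5])
        side = OrientationCondition("side_by_side")
        tail = OrientationCondition("head_to_tail")
        assert orientation_filter(vel, 0, 0, 1, side, separation=sep)
        assert not orientation_filter(vel, 0, 0, 1, tail, separation=sep)

    def test_parallel_headings_inline_separation(self):
        vel = self.vel_of(0.0, 0.05)
        sep = np.array([2.0, 0.0])
        assert orientation_filter(vel, 0, 0, 1,
                                  OrientationCondition("head_to_tail"),
                                  separation=sep)

    def test_antiparallel_fails_both(self):
        vel = self.vel_of(0.0, np.pi)
        for mode in ("side_by_side", "head_to_tail"):
            for sep in ([0.0, 1.0], [1.0, 0.0]):
                assert not orientation_filter(
                    vel, 0, 0, 1, OrientationCondition(mode),
                    separation=np.array(sep))

    def test_none_mode_accepts_everything(self):
        vel = self.vel_of(0.0, np.pi)
        assert orientation_filter(vel, 0, 0, 1, OrientationCondition(),
                                  separation=np.array([1.0, 0.0]))


class TestKirkwood:
    @staticmethod
    def flat_g2(value=1.0, rmax=20.0):
        r = np.arange(0.05, rmax, 0.1)
        return RadialPairCorrelation(r, np.full(r.size, value),
                                     np.full(r.size, 1000.0), None, 10_000)

    def test_flat_g2_gives_flat_prediction(self):
        frames = [[[-1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]] * 5
        tm = g3_map(traj_from(frames), (1.9, 2.1), bin_width=0.5,
                    extent=3.0)
        tm = kirkwood_map(self.flat_g2(), tm)
        assert np.allclose(tm.g3k, 1.0)

    def test_delta_g2_supported_on_circle_intersection(self):
        r = np.arange(0.05, 6.0, 0.1)
        g = np.where(np.abs(r - 2.0) < 0.15, 1.0, 0.0)
        radial = RadialPairCorrelation(r, g, g * 100, None, 1000)
        frames = [[[-1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]] * 5
        tm = g3_map(traj_from(frames), (1.9, 2.1), bin_width=0.25,
                    extent=3.0)
        tm = kirkwood_map(radial, tm)
        xc, yc = np.meshgrid(tm.x_centers, tm.y_centers, indexing="ij")
        high = tm.g3k > 0.5
        r13 = np.hypot(xc + 1.0, yc)
        r23 = np.hypot(xc - 1.0, yc)
        assert high.any()
        assert np.all(np.abs(r13[high] - 2.0) < 0.3)
        assert np.all(np.abs(r23[high] - 2.0) < 0.3)

    def test_identical_sides_give_zero_discrepancy(self):
        traj, _ = shoal.ideal_gas_frames(3, region_radius=4.0,
                                         n_frames=2000, seed=24)
        tm = g3_map(traj, (1.5, 2.5), bin_width=0.5, extent=3.0)
        g3k = np.where(tm.counts > 0, tm.g3, np.nan)  # copy of observed
        tm2 = shoal.TripletMap(tm.x_edges, tm.y_edges, tm.counts, tm.g3,
                               g3k, tm.r12_window, tm.orientation,
                               tm.n_samples)
        d = kirkwood_discrepancy(tm2, interior_margin=1)
        assert d.max_abs_interior == pytest.approx(0.0, abs=1e-12)

    def test_inflated_central_bin_is_flagged(self):
        frames = [[[-1.0, 0.0], [1.0, 0.0], [0.0, 1.5]]] * 50
        frames += [[[-1.0, 0.0], [1.0, 0.0], [0.0, 0.0]]] * 150
        tm = g3_map(traj_from(frames), (1.9, 2.1), bin_width=0.5,
                    extent=2.0)
        tm = kirkwood_map(self.flat_g2(), tm)
        d = kirkwood_discrepancy(tm, interior_margin=1,
                                 central_halfwidth=0.5)
        assert d.central_excess > 0

    def test_ideal_gas_null_within_envelope(self):
        """Observed and Kirkwood sides of an ideal gas agree within the
        binomial sampling envelope (edge-corrected estimators)."""
        traj, _ = shoal.ideal_gas_frames(3, region_radius=8.0,
                                         n_frames=60_000, seed=0)
        radial = radial_g2(traj, bin_width=0.5, r_range=(0.0, 16.0),
                           window_radius=8.0)
        tm = g3_map(traj, (2.0, 2.5), bin_width=1.0, extent=5.0,
                    window_radius=8.0)
        tm = kirkwood_map(radial, tm)
        d = kirkwood_discrepancy(tm, central_halfwidth=1.0)
        assert d.max_envelope_ratio < 3.0

    def test_mismatched_binning_rejected(self):
        tm = g3_map(traj_from([[[-1.0, 0], [1.0, 0], [0, 1.0]]] * 3),
                    (1.9, 2.1), bin_width=0.5, extent=2.0)
        with pytest.raises(ValueError):
            shoal.TripletMap(tm.x_edges, tm.y_edges, tm.counts, tm.g3,
                             np.zeros((2, 2)), tm.r12_window)
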