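import numpy as np
import pytest

from helixpack.core import BundleFrame, Trajectory
from helixpack.radial_geometry import (
    HelixFrameDescriptor,
    density_map,
    frame_descriptor,
    helix_centroid,
    orientation_vector,
    radial_cloud,
    to_reference_frame,
)
from helixpack.synthetic import (
    HELIX_RADIUS,
    PlantedAssembly,
    SyntheticSpec,
    generate_trajectory,
    ideal_helix,
    plan_assemblies,
)

from conftest import assembly_frame


def rotate_z(coords, deg, origin=(0.0, 0.0, 0.0)):
    a = np.radians(deg)
    R = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0],
                  [0, 0, 1.0]])
    origin = np.asarray(origin)
    return (coords - origin) @ R.T + origin


class TestHelixCentroid:
    def test_collinear_mean(self):
        beads = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        np.testing.assert_allclose(helix_centroid(beads, 1), [1, 0, 0])

    def test_halfwidth_insensitive_on_ideal_helix(self):
        # widening the averaging window moves the centroid by a fraction of
        # the helix radius — negligible against the 1.5 nm first orbit
        helix = ideal_helix(21)
        c1 = helix_centroid(helix, 10, halfwidth=1)
        c2 = helix_centroid(helix, 10, halfwidth=2)
        assert np.linalg.norm(c1 - c2) < 0.15
        assert c1[2] == pytest.approx(c2[2], abs=1e-12)

    def test_matches_plain_mean(self, rng):
        beads = rng.normal(size=(5, 3))
        np.testing.assert_allclose(helix_centroid(beads, 2), beads[1:4].mean(axis=0))

    def test_terminus_rejected(self):
        with pytest.raises(ValueError):
            helix_centroid(np.zeros((5, 3)), 0)


class TestOrientationVector:
    def test_points_inward_on_ideal_helix(self):
        # analytic check: the bisector at residue i points from the surface
        # bead back toward the helix axis
        helix = ideal_helix(21)
        for i in (5, 10, 15):
            v, valid = orientation_vector(helix, i)
            assert valid
            radial_out = helix[i][:2] / np.linalg.norm(helix[i][:2])
            angle = np.degrees(np.arccos(np.clip(-radial_out @ v, -1, 1)))
            assert angle < 5.0

    def test_collinear_beads_invalid(self):
        beads = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2.0]])
        _, valid = orientation_vector(beads, 1)
        assert not valid

    def test_equivariance_under_z_rotation(self, rng):
        helix = ideal_helix(15)
        v0, _ = orientation_vector(helix, 7)
        v90, _ = orientation_vector(rotate_z(helix, 90), 7)
        np.testing.assert_allclose(v90, [-v0[1], v0[0]], atol=1e-12)

    def test_terminus_rejected(self):
        with pytest.raises(ValueError):
            orientation_vector(ideal_helix(5), 0)


class TestReferenceFrame:
    def make_ref(self, orientation_deg, centroid=(0, 0, 0)):
        a = np.radians(orientation_deg)
        return HelixFrameDescriptor(0, 0.0, np.asarray(centroid, float),
                                    np.array([np.cos(a), np.sin(a)]), True)

    def test_neighbor_along_orientation_maps_to_plus_x(self):
        ref = self.make_ref(37.0)
        a = np.radians(37.0)
        nbr = np.array([np.cos(a), np.sin(a), 0.3])
        x, y = to_reference_frame(ref, nbr)
        assert (x, y) == pytest.approx((1.0, 0.0), abs=1e-12)

    def test_global_rotation_invariance(self, rng):
        for _ in range(50):
            ang = rng.uniform(0, 360)
            ref_ang = rng.uniform(0, 360)
            nbr = rng.normal(size=3)
            ref = self.make_ref(ref_ang, centroid=rng.normal(size=3))
            xy0 = to_reference_frame(ref, nbr)
            ref_rot = self.make_ref(ref_ang + ang,
                                    centroid=rotate_z(ref.centroid, ang))
            xy1 = to_reference_frame(ref_rot, rotate_z(nbr, ang))
            np.testing.assert_allclose(xy1, xy0, atol=1e-9)

    def test_matches_rotation_matrix_oracle(self, rng):
        for _ in range(1000):
            ref_ang = rng.uniform(0, 360)
            ref = self.make_ref(ref_ang, centroid=rng.normal(size=3))
            nbr = rng.normal(size=3)
            got = to_reference_frame(ref, nbr)
            a = np.radians(ref_ang)
            R = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
            expected = R @ (nbr - ref.centroid)[:2]
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_invalid_reference_rejected(self):
        ref = HelixFrameDescriptor(0, 0.0, np.zeros(3), np.array([1.0, 0]), False)
        with pytest.raises(ValueError):
            to_reference_frame(ref, np.ones(3))


class TestRadialCloud:
    def test_pair_count_accounting(self):
        traj, _ = generate_trajectory(
            SyntheticSpec(n_helices=36, n_residues=15, n_frames=1, seed=4)
        )
        cloud = radial_cloud(traj, center_residue=7, stride_ns=0.0)
        assert len(cloud) + cloud.n_skipped == 36 * 35

    def test_static_dimer_points_identical_across_frames(self):
        assemblies = plan_assemblies(n_c2=1, n_helices=16, box=(20, 20, 10))
        traj, _ = generate_trajectory(
            SyntheticSpec(n_helices=16, n_residues=15, box=(20, 20, 10),
                          assemblies=assemblies, n_frames=5, seed=5)
        )
        cloud = radial_cloud(traj, center_residue=7, stride_ns=0.0)
        mask = (cloud.ref == 0) & (cloud.neighbor == 1)
        assert mask.sum() == 5
        assert np.ptp(cloud.x[mask]) < 1e-9 and np.ptp(cloud.y[mask]) < 1e-9

    def test_c3_points_related_by_120_degrees(self, trimer_frame):
        traj = Trajectory(frames=[trimer_frame])
        cloud = radial_cloud(traj, center_residue=15, stride_ns=0.0)
        # each reference helix sees its two partners at positions that map
        # onto each other under exact +/-120 degree rotations
        pts = {(int(r), int(n)): complex(x, y)
               for r, n, x, y in zip(cloud.ref, cloud.neighbor, cloud.x, cloud.y)}
        # every reference sees its "next" protomer at the same body-frame
        # position, and likewise its "previous" one
        assert abs(pts[(0, 1)] - pts[(1, 2)]) < 1e-9
        assert abs(pts[(1, 2)] - pts[(2, 0)]) < 1e-9
        assert abs(pts[(0, 2)] - pts[(1, 0)]) < 1e-9
        assert abs(pts[(1, 0)] - pts[(2, 1)]) < 1e-9
        # symmetry of the ring: all partner distances equal
        radii = np.hypot(cloud.x, cloud.y)
        assert np.ptp(radii) < 1e-9


class TestDensityMap:
    def make_cloud(self, x, y):
        n = len(x)
        from helixpack.radial_geometry import RadialCloud

        return RadialCloud(0, np.asarray(x, float), np.asarray(y, float),
                           np.zeros(n), np.zeros(n, int), np.ones(n, int),
                           np.full(n, np.nan))

    def test_single_point_peak(self):
        cloud = self.make_cloud([0.7] * 50, [-0.3] * 50)
        dmap = density_map(cloud)
        assert dmap.peak_xy == pytest.approx((0.7, -0.3), abs=0.051)

    def test_two_planted_modes(self, rng):
        c1 = rng.normal([1.0, 0.0], 0.05, size=(500, 2))
        c2 = rng.normal([0.0, 1.0], 0.05, size=(500, 2))
        pts = np.vstack([c1, c2])
        dmap = density_map(self.make_cloud(pts[:, 0], pts[:, 1]), bandwidth=0.08)
        grid = dmap.grid
        x0, x1, y0, y1 = dmap.extent
        xs = np.linspace(x0, x1, grid.shape[1])
        ys = np.linspace(y0, y1, grid.shape[0])
        for cx, cy in [(1.0, 0.0), (0.0, 1.0)]:
            ix, iy = np.argmin(np.abs(xs - cx)), np.argmin(np.abs(ys - cy))
            window = grid[max(iy - 2, 0):iy + 3, max(ix - 2, 0):ix + 3]
            assert window.max() > 0.5 * grid.max()

    def test_integral_matches_point_count(self, rng):
        pts = rng.normal(0, 0.5, size=(800, 2))
        dmap = density_map(self.make_cloud(pts[:, 0], pts[:, 1]))
        assert dmap.total_mass == pytest.approx(800, rel=0.01)

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            density_map(self.make_cloud([], []))


class TestFrameInvariance:
    def test_map_invariant_under_global_rotation_and_translation(self):
        assemblies = plan_assemblies(n_c2=1, n_c3=1, n_helices=16,
                                     box=(20, 20, 10))
        traj, _ = generate_trajectory(
            SyntheticSpec(n_helices=16, n_residues=15, box=(20, 20, 10),
                          assemblies=assemblies, n_frames=2, seed=6)
        )
        moved = Trajectory(frames=[
            BundleFrame(f.time, f.box,
                        rotate_z(f.coords.reshape(-1, 3), 63.0,
                                 origin=(10, 10, 5)).reshape(f.coords.shape)
                        + np.array([1.3, -0.7, 0.2]),
                        periodic=False)
            for f in traj.frames
        ])
        for f in traj.frames:
            f.periodic = False  # compare without wrapping effects
        cloud1 = radial_cloud(moved, 7, stride_ns=0.0)
        cloud0 = radial_cloud(traj, 7, stride_ns=0.0)
        order0 = np.lexsort((cloud0.neighbor, cloud0.ref, cloud0.time))
        order1 = np.lexsort((cloud1.neighbor, cloud1.ref, cloud1.time))
        np.testing.assert_allclose(cloud1.x[order1], cloud0.x[order0], atol=1e-9)
        np.testing.assert_allclose(cloud1.y[order1], cloud0.y[order0], atol=1e-9)
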