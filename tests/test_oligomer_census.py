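import numpy as np
import pytest

from helixpack.core import BundleFrame, Trajectory
from helixpack.oligomer_census import (
    CensusParams,
    association_records,
    association_summary,
    census_frame,
    census_trajectory,
    cluster_spots,
    markov_transitions,
    pair_geometry,
)
from helixpack.radial_geometry import RadialCloud, radial_cloud
from helixpack.synthetic import (
    PlantedAssembly,
    SyntheticSpec,
    generate_trajectory,
    plan_assemblies,
)

from conftest import assembly_frame, descriptors


def make_cloud(x, y, time=None, ref=None, neighbor=None, beta=None):
    n = len(x)
    return RadialCloud(
        0,
        np.asarray(x, float),
        np.asarray(y, float),
        np.zeros(n) if time is None else np.asarray(time, float),
        np.zeros(n, int) if ref is None else np.asarray(ref, int),
        np.ones(n, int) if neighbor is None else np.asarray(neighbor, int),
        np.full(n, np.nan) if beta is None else np.asarray(beta, float),
    )


class TestPairGeometry:
    def test_identical_orientations_give_zero_beta(self, dimer_frame):
        d = descriptors(dimer_frame)
        same = d[0].__class__(1, 0.0, d[1].centroid, d[0].orientation_xy, True)
        assert pair_geometry(d[0], same).beta == pytest.approx(0.0, abs=1e-9)

    def test_ideal_c2_beta_is_180(self, dimer_frame):
        d = descriptors(dimer_frame)
        g = pair_geometry(d[0], d[1], dimer_frame.box)
        assert g.beta == pytest.approx(180.0, abs=1e-9)

    def test_ideal_c3_betas_are_120_and_240(self, trimer_frame):
        d = descriptors(trimer_frame)
        b1 = pair_geometry(d[0], d[1], trimer_frame.box).beta
        b2 = pair_geometry(d[0], d[2], trimer_frame.box).beta
        assert sorted([b1, b2]) == pytest.approx([120.0, 240.0], abs=1e-9)

    def test_beta_independent_of_global_pose(self):
        for phase in (0.0, 33.0, 191.5):
            frame = assembly_frame("C3", center=(8.0, 14.0), phase=phase)
            d = descriptors(frame)
            b = pair_geometry(d[0], d[1], frame.box).beta
            assert b == pytest.approx(120.0, abs=1e-9)

    def test_invalid_descriptor_rejected(self, dimer_frame):
        d = descriptors(dimer_frame)
        broken = d[1].__class__(1, 0.0, d[1].centroid, d[1].orientation_xy, False)
        with pytest.raises(ValueError):
            pair_geometry(d[0], broken)


class TestCensusFrame:
    def test_planted_c2(self, dimer_frame):
        c = census_frame(descriptors(dimer_frame), box=dimer_frame.box)
        assert c.counts == {"C2": 1, "C3_pair": 0, "trimer": 0}

    def test_planted_c3(self, trimer_frame):
        c = census_frame(descriptors(trimer_frame), box=trimer_frame.box)
        assert c.counts == {"C2": 0, "C3_pair": 3, "trimer": 1}
        assert c.trimers == {frozenset((0, 1, 2))}

    def test_dimer_of_trimers(self):
        frame = assembly_frame("C3x2", center=(12.0, 12.0))
        c = census_frame(descriptors(frame), box=frame.box)
        assert len(c.trimers) == 2
        assert len(c.c2_pairs) >= 1

    def test_sparse_grid_is_empty(self):
        traj, _ = generate_trajectory(
            SyntheticSpec(n_helices=36, n_residues=15, n_frames=1, seed=8)
        )
        frame = traj.frames[0]
        c = census_frame(descriptors(frame), box=frame.box)
        assert c.counts == {"C2": 0, "C3_pair": 0, "trimer": 0}

    def test_relabelling_invariance(self, trimer_frame):
        perm = [2, 0, 1]
        permuted = BundleFrame(0.0, trimer_frame.box,
                               trimer_frame.coords[perm])
        c0 = census_frame(descriptors(trimer_frame), box=trimer_frame.box)
        c1 = census_frame(descriptors(permuted), box=trimer_frame.box)
        assert c0.counts == c1.counts

    def test_beta_tolerance_windows_must_not_overlap(self):
        with pytest.raises(ValueError):
            CensusParams(beta_tol=31.0)


class TestAssociationRecords:
    def make_census(self, present):
        from helixpack.oligomer_census import FrameCensus

        return [
            FrameCensus(time=float(k), c2_pairs={frozenset((0, 1))} if on else set(),
                        c3_pairs=set(), trimers=set())
            for k, on in enumerate(present)
        ]

    def test_always_present(self):
        recs = association_records(self.make_census([True] * 7), dt=1.0)
        assert len(recs) == 1
        assert recs[0].accumulated_time == 7.0
        assert recs[0].n_intervals == 1

    def test_gap_tolerance_definition(self):
        pattern = [True] * 5 + [False] + [True] * 4
        strict = association_records(self.make_census(pattern), dt=1.0)[0]
        assert [t1 - t0 for t0, t1 in strict.intervals] == [5.0, 4.0]
        bridged = association_records(self.make_census(pattern), dt=1.0,
                                      gap_tolerance=1)[0]
        assert bridged.intervals == [(0.0, 10.0)]

    def test_planted_schedule_recovered_exactly(self):
        schedule = ((0, 30), (50, 80))
        assemblies = (
            PlantedAssembly("C2", (0, 1), center=(2.0833, 2.0833),
                            schedule=schedule),
        )
        traj, _ = generate_trajectory(
            SyntheticSpec(n_helices=36, n_residues=15, assemblies=assemblies,
                          n_frames=100, dt=1.0, seed=9)
        )
        census = census_trajectory(traj, 7)
        recs = [r for r in association_records(census, dt=1.0)
                if r.category == "C2"]
        assert len(recs) == 1
        assert recs[0].members == frozenset((0, 1))
        assert recs[0].intervals == [(0.0, 30.0), (50.0, 80.0)]
        summary = association_summary(recs, "C2")
        assert summary["accumulated_ns"] == 60.0
        assert summary["longest_ns"] == 30.0
        assert summary["n_distinct_helices"] == 2


class TestClusterSpots:
    def test_two_planted_spots_recovered(self, rng):
        s1 = rng.normal([1.0, 0.0], 0.05, size=(500, 2))
        s2 = rng.normal([-0.5, 0.8], 0.05, size=(500, 2))
        pts = np.vstack([s1, s2])
        cloud = make_cloud(pts[:, 0], pts[:, 1])
        clusters = cluster_spots(cloud)
        assert len(clusters) == 2
        centroids = sorted(c.centroid for c in clusters)
        assert centroids[0] == pytest.approx((-0.5, 0.8), abs=0.05)
        assert centroids[1] == pytest.approx((1.0, 0.0), abs=0.05)

    def test_sparse_uniform_scatter_gives_no_clusters(self, rng):
        pts = rng.uniform(-1.4, 1.4, size=(40, 2))
        clusters = cluster_spots(make_cloud(pts[:, 0], pts[:, 1]),
                                 min_fraction=0.5)
        assert clusters == []

    def test_c2_spot_carries_180_degree_betas(self, rng):
        pts = rng.normal([1.0, 0.0], 0.04, size=(300, 2))
        betas = rng.normal(180.0, 5.0, size=300)
        cloud = make_cloud(pts[:, 0], pts[:, 1], beta=betas)
        clusters = cluster_spots(cloud)
        assert len(clusters) == 1
        assert np.abs(np.mean(clusters[0].betas) - 180.0) < 2.0

    def test_points_outside_first_orbit_ignored(self, rng):
        pts = rng.normal([2.5, 0.0], 0.05, size=(200, 2))
        assert cluster_spots(make_cloud(pts[:, 0], pts[:, 1])) == []


class TestMarkovTransitions:
    def test_static_configuration_gives_identity(self, rng):
        # one pair sitting in the same spot for 10 strides
        n = 10
        x = np.full(n, 1.0) + rng.normal(0, 0.01, n)
        y = rng.normal(0, 0.01, n)
        extra = rng.normal([1.0, 0.0], 0.01, size=(200, 2))
        cloud = make_cloud(
            np.concatenate([x, extra[:, 0]]),
            np.concatenate([y, extra[:, 1]]),
            time=np.concatenate([np.arange(n, dtype=float), np.zeros(200)]),
            ref=np.concatenate([np.zeros(n, int), np.full(200, 5)]),
            neighbor=np.concatenate([np.ones(n, int), np.full(200, 6)]),
        )
        clusters = cluster_spots(cloud)
        tm = markov_transitions(cloud, clusters)
        assert tm.self_transition("spot0") == pytest.approx(1.0)

    def test_two_state_flipper(self):
        # a pair alternating between two spots every stride
        n = 40
        times = np.arange(n, dtype=float)
        x = np.where(times % 2 == 0, 1.0, -1.0) + np.linspace(0, 0.02, n)
        y = np.zeros(n)
        pad = np.concatenate([np.full(50, 1.0), np.full(50, -1.0)])
        cloud = make_cloud(
            np.concatenate([x, pad]),
            np.concatenate([y, np.zeros(100)]),
            time=np.concatenate([times, np.zeros(100)]),
            ref=np.concatenate([np.zeros(n, int), np.full(100, 7)]),
            neighbor=np.concatenate([np.ones(n, int), np.full(100, 8)]),
        )
        clusters = cluster_spots(cloud, eps=0.3)
        assert len(clusters) == 2
        tm = markov_transitions(cloud, clusters)
        for c in clusters:
            assert tm.self_transition(f"spot{c.label}") == pytest.approx(0.0)

    def test_rows_are_stochastic(self):
        assemblies = plan_assemblies(n_c2=2, n_c3=1, n_helices=36)
        traj, _ = generate_trajectory(
            SyntheticSpec(n_helices=36, n_residues=15, assemblies=assemblies,
                          jitter_sigma=0.03, orientation_noise=5.0,
                          n_frames=30, dt=100.0, seed=11)
        )
        cloud = radial_cloud(traj, 7, stride_ns=100.0)
        clusters = cluster_spots(cloud)
        tm = markov_transitions(cloud, clusters)
        sums = tm.probabilities.sum(axis=1)
        assert np.allclose(sums[~tm.empty_rows], 1.0, atol=1e-9)
        total = tm.counts.sum()
        assert total > 0
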