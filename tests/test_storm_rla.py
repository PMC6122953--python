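"""Relative-localization analysis: registration, clustering, voxel measures,
signed distances and perinexal classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from perinexus.storm_rla import (
    ChannelRegistrar,
    Cluster,
    ClusterDetector,
    LocalizationTable,
    RelativeLocalizationClassifier,
    classify_relative_localization,
    detect_clusters,
    hull_volume,
    overlap_fraction,
    register_channels,
    signed_closest_distance,
    voxelize,
)
from conftest import grid_sphere, make_cluster


def _rotz(deg):
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1.0]])


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


class TestRegistration:
    def test_pure_translation_recovered_exactly(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 10_000, (8, 3))
        shift = np.array([50.0, -30.0, 10.0])
        moved, tf = register_channels(a, a + shift, a + shift)
        np.testing.assert_allclose(tf.translation_nm, -shift, atol=1e-9)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(moved, a, atol=1e-9)
        assert tf.residual_rms_nm < 1e-9

    def test_identity_misregistration_gives_identity(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 5000, (5, 3))
        _, tf = register_channels(a, a, a)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(tf.translation_nm, 0.0, atol=1e-9)

    def test_known_rotation_recovered_to_microdegrees(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 10_000, (10, 3))
        rot = _rotz(5.0)
        b = a @ rot.T
        reg = ChannelRegistrar().fit(a, b)
        # the fitted rotation must invert the applied one
        angle = np.degrees(np.arccos(np.clip((np.trace(reg.rotation_ @ rot) - 1) / 2, -1, 1)))
        assert angle < 1e-6

    def test_fewer_than_three_pairs_raises(self):
        a = np.array([[0.0, 0, 0], [1000, 0, 0]])
        with pytest.raises(ValueError, match="usable fiducial pairs"):
            ChannelRegistrar().fit(a, a)

    def test_collinear_fiducials_raise(self):
        a = np.array([[0.0, 0, 0], [1000, 0, 0], [2000, 0, 0], [3000, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            ChannelRegistrar().fit(a, a + 5.0)

    def test_scene_misregistration_recovered(self, storm_scene):
        cfg, (tables, fids, truth) = storm_scene
        reg = ChannelRegistrar().fit(fids["A"], fids["B"])
        # forward transform was rot(theta) then +t; the fit must undo it
        rot_fwd = _rotz(cfg.misreg_rotation_z_deg)
        resid = reg.rotation_ @ rot_fwd - np.eye(3)
        assert np.abs(resid).max() < 1e-3  # limited by 2 nm bead noise
        assert reg.residual_rms_nm_ < 3 * cfg.fiducial_sigma_nm * np.sqrt(2)


# ---------------------------------------------------------------------------
# cluster detection
# ---------------------------------------------------------------------------


class TestClusterDetection:
    def test_two_planted_clusters_fully_recovered(self):
        rng = np.random.default_rng(3)
        c1 = rng.normal(0, 20, (200, 3))
        c2 = rng.normal(0, 20, (150, 3)) + [1000.0, 0, 0]
        pts = np.vstack([c1, c2])
        cs = detect_clusters(pts)
        assert len(cs) == 2
        # memberships match the planted split, allowing a few stray
        # tail points to be labelled noise
        assert (cs.labels == -1).sum() <= 3
        first = cs.labels[:200][cs.labels[:200] >= 0]
        second = cs.labels[200:][cs.labels[200:] >= 0]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert set(first) != set(second)

    def test_sparse_uniform_background_yields_no_clusters(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 10_000, (300, 3))  # ~0.3 points per µm³
        assert len(detect_clusters(pts)) == 0

    def test_all_points_identical_form_one_cluster(self):
        pts = np.zeros((50, 3))
        cs = detect_clusters(pts)
        assert len(cs) == 1 and cs[0].n_points == 50

    def test_empty_table_gives_empty_set(self):
        table = LocalizationTable(points=pd.DataFrame(columns=["x_nm", "y_nm", "z_nm"]))
        assert len(detect_clusters(table)) == 0

    def test_small_components_discarded_as_background(self):
        rng = np.random.default_rng(5)
        big = rng.normal(0, 15, (100, 3))
        small = rng.normal(0, 5, (7, 3)) + [5000.0, 0, 0]
        cs = detect_clusters(np.vstack([big, small]), min_cluster_size=10)
        assert len(cs) == 1 and cs[0].n_points == 100

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            detect_clusters(np.zeros((5, 3)), radius_nm=0.0)
        with pytest.raises(ValueError):
            detect_clusters(np.zeros((5, 3)), min_points=0)


# ---------------------------------------------------------------------------
# voxelization and volume
# ---------------------------------------------------------------------------


class TestVoxelize:
    def test_single_point_zero_dilation_is_one_voxel(self):
        cl = make_cluster(np.array([[5.0, 5.0, 5.0]]), voxel_nm=20.0)
        assert cl.occupancy.n_occupied == 1
        assert cl.volume_nm3 == pytest.approx(20.0**3)

    def test_dense_sphere_volume_within_ten_percent(self):
        rng = np.random.default_rng(0)
        n = 20_000
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = v * (rng.uniform(size=n) ** (1 / 3))[:, None] * 100.0
        cl = make_cluster(pts, voxel_nm=10.0)
        analytic = 4 / 3 * np.pi * 100.0**3
        assert cl.volume_nm3 == pytest.approx(analytic, rel=0.10)

    def test_halving_voxel_changes_volume_by_at_most_a_surface_shell(self):
        pts = grid_sphere((0, 0, 0), 100.0, spacing=4.0)
        v20 = make_cluster(pts, voxel_nm=20.0).volume_nm3
        v10 = make_cluster(pts, voxel_nm=10.0).volume_nm3
        shell = 4 * np.pi * 100.0**2 * 20.0  # sphere area x coarse voxel
        assert abs(v20 - v10) <= shell

    def test_hull_volume_close_to_voxel_volume_for_convex_cluster(self):
        cl = make_cluster(grid_sphere((0, 0, 0), 100.0), voxel_nm=10.0)
        assert hull_volume(cl) == pytest.approx(cl.volume_nm3, rel=0.15)

    def test_invalid_voxel_size_raises(self):
        with pytest.raises(ValueError):
            make_cluster(np.zeros((3, 3)), voxel_nm=0.0)


# ---------------------------------------------------------------------------
# overlap fraction and signed distance
# ---------------------------------------------------------------------------


class TestPairwiseMeasures:
    def test_identical_clusters_fully_overlap(self):
        pts = grid_sphere((0, 0, 0), 60.0)
        a, b = make_cluster(pts), make_cluster(pts, cid=1)
        assert overlap_fraction(b, a) == 1.0

    def test_disjoint_clusters_do_not_overlap(self):
        a = make_cluster(grid_sphere((0, 0, 0), 60.0))
        b = make_cluster(grid_sphere((500, 0, 0), 60.0), cid=1)
        assert overlap_fraction(b, a) == 0.0

    def test_sphere_lens_overlap_matches_analytic_within_shell_error(self):
        r, d = 100.0, 150.0
        a = make_cluster(grid_sphere((0, 0, 0), r))
        b = make_cluster(grid_sphere((d, 0, 0), r), cid=1)
        lens = np.pi * (4 * r + d) * (2 * r - d) ** 2 / 12
        sphere = 4 / 3 * np.pi * r**3
        # voxelization error bound: half a voxel over the lens surface
        # (two spherical caps of height r - d/2)
        cap_area = 2 * 2 * np.pi * r * (r - d / 2)
        shell = cap_area * 10.0 / 2
        assert abs(overlap_fraction(b, a) - lens / sphere) <= shell / sphere

    def test_zero_volume_partner_raises(self):
        a = make_cluster(grid_sphere((0, 0, 0), 50.0))
        b = Cluster(id=1, point_indices=np.array([]), points_nm=np.zeros((1, 3)))
        voxelize(b, voxel_nm=10.0, dilation_nm=0.0)
        b.occupancy.dense[:] = False
        with pytest.raises(ValueError, match="zero-volume"):
            overlap_fraction(b, a)

    @pytest.mark.parametrize(
        "centre_dist,expected", [(250.0, 50.0), (150.0, -50.0)], ids=["disjoint", "overlap"]
    )
    def test_equal_spheres_signed_distance_is_d_minus_2r(self, centre_dist, expected):
        a = make_cluster(grid_sphere((0, 0, 0), 100.0))
        b = make_cluster(grid_sphere((centre_dist, 0, 0), 100.0), cid=1)
        assert signed_closest_distance(b, a) == pytest.approx(expected, abs=10.0)

    def test_coincident_clusters_depth_is_the_inradius(self):
        pts = grid_sphere((0, 0, 0), 100.0)
        a, b = make_cluster(pts), make_cluster(pts, cid=1)
        assert signed_closest_distance(b, a) == pytest.approx(-100.0, abs=10.0)

    def test_disjoint_distance_matches_brute_force(self):
        """Oracle equivalence: voxel-pipeline distance equals the minimum
        pairwise point distance minus twice the dilation, within a voxel."""
        rng = np.random.default_rng(6)
        checked = 0
        for _ in range(100):
            n1, n2 = rng.integers(20, 500, 2)
            c2_dir = rng.normal(size=3)
            c2_dir /= np.linalg.norm(c2_dir)
            c1 = rng.uniform(0, 500, 3)
            c2 = c1 + c2_dir * rng.uniform(200, 800)
            p1 = c1 + rng.normal(0, 40, (n1, 3))
            p2 = c2 + rng.normal(0, 40, (n2, 3))
            dil = rng.uniform(0, 15)
            a = make_cluster(p1, dilation_nm=dil)
            b = make_cluster(p2, cid=1, dilation_nm=dil)
            d = signed_closest_distance(b, a)
            if d > 0:
                brute = max(cdist(p1, p2).min() - 2 * dil, 0.0)
                assert abs(d - brute) <= 10.0
                checked += 1
        assert checked > 50


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _pair_scene(gap_nm):
    """One reference sphere at the origin and one partner at a planted gap."""
    a = make_cluster(grid_sphere((0, 0, 0), 100.0), voxel_nm=20.0)
    b = make_cluster(grid_sphere((100.0 + gap_nm + 50.0, 0, 0), 50.0), cid=0, voxel_nm=20.0)
    from perinexus.storm_rla import ClusterSet

    return ClusterSet(clusters=[b]), ClusterSet(clusters=[a])


class TestClassification:
    @pytest.mark.parametrize(
        "gap,expected",
        [(100.0, "adjacent"), (400.0, "distant"), (-80.0, "overlapping")],
        ids=["gap100", "gap400", "gap-80"],
    )
    def test_planted_gap_classifies_correctly(self, gap, expected):
        partners, refs = _pair_scene(gap)
        summary = classify_relative_localization(partners, refs, voxel_nm=20.0, dilation_nm=0.0)
        assert summary.table["class"].iloc[0] == expected
        assert summary.fractions[expected] == 1.0

    def test_empty_reference_set_flags_all_distant_infinite(self):
        from perinexus.storm_rla import ClusterSet

        partners, _ = _pair_scene(100.0)
        summary = classify_relative_localization(partners, ClusterSet(), voxel_nm=20.0)
        assert (summary.table["class"] == "distant").all()
        assert np.isinf(summary.table["signed_distance_nm"]).all()

    def test_overlap_consistency_invariant(self, storm_scene):
        """class == overlapping <=> signed distance < 0 <=> overlap fraction > 0."""
        _, (tables, fids, _) = storm_scene
        moved, _ = register_channels(fids["A"], fids["B"], tables["B"])
        summary = classify_relative_localization(
            detect_clusters(moved), detect_clusters(tables["A"])
        )
        t = summary.table
        overlapping = t["class"] == "overlapping"
        assert (overlapping == (t["signed_distance_nm"] < 0)).all()
        assert (overlapping == (t["overlap_fraction"] > 0)).all()
        assert abs(sum(summary.fractions.values()) - 1.0) < 1e-9

    def test_threshold_monotonicity(self, storm_scene):
        """Raising the adjacency threshold never decreases adjacent+overlapping."""
        _, (tables, fids, _) = storm_scene
        moved, _ = register_channels(fids["A"], fids["B"], tables["B"])
        partners, refs = detect_clusters(moved), detect_clusters(tables["A"])
        prev = -1.0
        for thr in (100.0, 200.0, 400.0, 800.0):
            s = classify_relative_localization(partners, refs, adjacency_nm=thr)
            frac = s.fractions["adjacent"] + s.fractions["overlapping"]
            assert frac >= prev - 1e-12
            prev = frac

    def test_registration_invariance(self):
        """A rigid motion applied to both channels leaves the summary unchanged."""
        from perinexus.synth import StormSceneConfig, gen_storm_scene

        cfg = StormSceneConfig(n_pairs=6, background_per_um3=0.0)
        tables, _, _ = gen_storm_scene(cfg, seed=13)
        rot, shift = _rotz(25.0), np.array([500.0, -200.0, 100.0])

        def classify(pts_a, pts_b):
            return classify_relative_localization(
                detect_clusters(pts_b), detect_clusters(pts_a)
            )

        s0 = classify(tables["A"].coords, tables["B"].coords)
        s1 = classify(tables["A"].coords @ rot.T + shift, tables["B"].coords @ rot.T + shift)
        assert s0.fractions == s1.fractions
        d0 = np.sort(s0.table["signed_distance_nm"].to_numpy())
        d1 = np.sort(s1.table["signed_distance_nm"].to_numpy())
        np.testing.assert_allclose(d0, d1, atol=20.0)  # one voxel

    def test_scene_recovery_against_truth(self, storm_scene):
        """Planted classes recovered with >= 95% agreement and fractions
        within 3 percentage points on the default synthetic scene."""
        _, (tables, fids, truth) = storm_scene
        moved, _ = register_channels(fids["A"], fids["B"], tables["B"])
        partners = detect_clusters(moved)
        refs = detect_clusters(tables["A"])
        summary = RelativeLocalizationClassifier().fit(partners, refs).summary_

        truth_partners = [c for c in truth.records["clusters"] if c["channel"] == "B"]
        tree = cKDTree([c["centroid_nm"] for c in truth_partners])
        labels = [c["class_label"] for c in truth_partners]
        agree = 0
        for _, row in summary.table.iterrows():
            _, idx = tree.query(partners[int(row.cluster_id)].centroid_nm)
            agree += labels[idx] == row["class"]
        assert agree / len(summary.table) >= 0.95
        for cls, frac in truth.records["class_fractions"].items():
            assert abs(summary.fractions[cls] - frac) <= 0.03
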