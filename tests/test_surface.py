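"""Surface pipeline: resampling, sampling, PSM, ICP, generalized alignment."""

import numpy as np
import pytest
import trimesh
from scipy.spatial import cKDTree

import osteomorph as om
from osteomorph.synthetic import _random_pose
from conftest import brute_hausdorff


class TestCleanAndResample:
    def test_icosphere_decimation_quality(self):
        ico = trimesh.creation.icosphere(subdivisions=4)  # 5120 faces, r=1
        dec = om.clean_and_resample(ico, 2000)
        assert 1800 <= len(dec.faces) <= 2200
        a, _ = trimesh.sample.sample_surface(ico, 600, seed=0)
        b, _ = trimesh.sample.sample_surface(dec, 600, seed=0)
        d = max(brute_hausdorff(a, dec).max(), brute_hausdorff(b, ico).max())
        assert d < 0.01  # < 1% of the radius

    def test_hole_filled_watertight(self):
        ico = trimesh.creation.icosphere(subdivisions=2)
        holey = trimesh.Trimesh(vertices=ico.vertices.copy(),
                                faces=ico.faces[1:], process=False)
        assert not holey.is_watertight
        out = om.clean_and_resample(holey, len(holey.faces))
        assert out.is_watertight

    def test_upsample_small_mesh(self):
        small = trimesh.creation.icosphere(subdivisions=1)  # 80 faces
        up = om.clean_and_resample(small, 500)
        assert 450 <= len(up.faces) <= 550

    def test_noop_within_band(self):
        ico = trimesh.creation.icosphere(subdivisions=3)   # 1280 faces
        out = om.clean_and_resample(ico, 1300)
        assert len(out.faces) == 1280                      # already in band


class TestSamplePoints:
    def test_area_weighted_uniformity(self):
        square = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
            faces=[[0, 1, 2], [0, 2, 3]], process=False)
        s = om.sample_points(square, 10000, seed=0)
        counts = np.bincount(s.face_index, minlength=2)
        assert abs(counts[0] - 5000) <= 3 * np.sqrt(2500)  # binomial bound

    def test_seed_reproducible(self, reference_mesh):
        a = om.sample_points(reference_mesh, 500, seed=9)
        b = om.sample_points(reference_mesh, 500, seed=9)
        np.testing.assert_array_equal(a.points, b.points)

    def test_points_on_source_faces(self, reference_mesh):
        s = om.sample_points(reference_mesh, 300, seed=1)
        d = trimesh.triangles.points_to_barycentric(
            np.asarray(reference_mesh.triangles)[s.face_index], s.points)
        assert np.abs(d.sum(axis=1) - 1).max() < 1e-9
        assert d.min() > -1e-9

    def test_m_bounds(self, reference_mesh):
        with pytest.raises(ValueError):
            om.sample_points(reference_mesh, 50)
        with pytest.raises(ValueError):
            om.sample_points(reference_mesh, 20_000_001)


class TestPSM:
    def test_metric_axioms(self, reference_mesh):
        s = om.sample_points(reference_mesh, 400, seed=0)
        t = om.sample_points(reference_mesh, 350, seed=1)
        assert om.psm(s, s) == 0.0
        assert om.psm(s, t) == om.psm(t, s)
        assert om.psm(s, t) > 0

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((200, 3))
        B = rng.standard_normal((200, 3))
        dAB = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
        expected = np.sqrt((dAB.min(axis=1) ** 2).sum() / (2 * 200)
                           + (dAB.min(axis=0) ** 2).sum() / (2 * 200))
        assert om.psm(A, B) == expected

    def test_offset_squares_limit(self):
        """Two dense unit squares offset by delta: PSM ~ c * delta."""
        n = 60
        g = np.linspace(0, 1, n)
        xx, yy = np.meshgrid(g, g)
        A = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
        for delta in (0.3, 0.1, 0.03):
            B = A + [delta, 0, 0]
            v = om.psm(A, B)
            assert 0 < v <= delta

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            om.psm(np.zeros((0, 3)), np.ones((5, 3)))


class TestInitializePose:
    def test_large_rotation_recovered(self, reference_mesh):
        s = om.sample_points(reference_mesh, 600, seed=0)
        a = np.deg2rad(170)
        R = np.array([[np.cos(a), -np.sin(a), 0],
                      [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
        moved = om.PointSample(s.points @ R.T + [3, -1, 2], s.face_index)
        tf, branch, mirror = om.initialize_pose(moved, s)
        err = np.degrees(np.arccos(np.clip((np.trace(tf.rotation @ R) - 1) / 2,
                                           -1, 1)))
        assert err < 5.0

    def test_identity_for_identical_clouds(self, reference_mesh):
        s = om.sample_points(reference_mesh, 600, seed=0)
        tf, branch, mirror = om.initialize_pose(s, s)
        assert np.abs(tf.rotation - np.eye(3)).max() < 1e-6
        assert np.abs(tf.translation).max() < 1e-6
        assert not mirror

    def test_mirrored_cloud_flagged_not_reflected(self, reference_mesh):
        s = om.sample_points(reference_mesh, 600, seed=0)
        mirrored = om.PointSample(s.points * [1, 1, -1], s.face_index)
        tf, branch, mirror = om.initialize_pose(mirrored, s)
        assert np.linalg.det(tf.rotation) > 0
        assert mirror

    def test_rank_deficient_rejected(self):
        flat = np.zeros((200, 3))
        flat[:, 0] = np.arange(200)
        with pytest.raises(ValueError):
            om.initialize_pose(om.PointSample(flat, np.zeros(200)),
                               om.PointSample(flat, np.zeros(200)))


class TestICP:
    def test_random_pose_recovery(self, reference_mesh):
        s = om.sample_points(reference_mesh, 800, seed=2)
        diag = np.linalg.norm(s.points.max(0) - s.points.min(0))
        rng = np.random.default_rng(5)
        for _ in range(5):
            p = _random_pose(rng)
            posed = om.PointSample(p.apply(s.points), s.face_index)
            res = om.icp_align(posed, s, allow_scale=True)
            ang = np.degrees(np.arccos(np.clip(
                (np.trace(res.transform.rotation @ p.rotation) - 1) / 2, -1, 1)))
            assert ang < 0.5
            assert abs(res.transform.scale * p.scale - 1) < 1e-3
            assert res.psm < 1e-6 * diag

    def test_self_alignment_identity(self, reference_mesh):
        s = om.sample_points(reference_mesh, 500, seed=0)
        res = om.icp_align(s, s, allow_scale=False)
        assert res.psm < 1e-12
        assert np.abs(res.transform.rotation - np.eye(3)).max() < 1e-6

    def test_psm_history_nonincreasing(self, reference_mesh):
        rng = np.random.default_rng(1)
        s = om.sample_points(reference_mesh, 600, seed=3)
        p = _random_pose(rng)
        noisy = om.PointSample(p.apply(s.points)
                               + rng.normal(0, 0.01, s.points.shape),
                               s.face_index)
        res = om.icp_align(noisy, s, allow_scale=True)
        assert np.all(np.diff(res.psm_history) <= 0)


class TestRigidTransform:
    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            om.RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            om.RigidTransform(np.eye(3) * 2.0, np.zeros(3))


class TestGeneralizedAlignment:
    def _posed_copies(self, mesh, n, m_points, seed):
        rng = np.random.default_rng(seed)
        samples = {}
        for i in range(n):
            p = _random_pose(rng)
            mm = mesh.copy()
            mm.vertices = p.apply(np.asarray(mm.vertices))
            samples[f"s{i}"] = om.sample_points(mm, m_points, seed=11,
                                                specimen_id=f"s{i}")
        return samples

    def test_identical_cohort_zero_ordination(self, reference_mesh):
        samples = self._posed_copies(reference_mesh, 5, 1000, seed=7)
        res = om.generalized_alignment(samples, "s0", allow_scale=True)
        assert res.mean_psm_history[-1] < 1e-6
        assert np.all(res.ordination.eigenvalues < 1e-10)

    def test_mean_psm_nonincreasing(self):
        rng = np.random.default_rng(3)
        spec = om.ShapeEffectSpec(coefficient_noise_sd=0.03, vertex_jitter_sd=0.005)
        samples = {}
        for i in range(6):
            mesh, _ = om.make_mesh(spec, 1500, rng)
            samples[f"s{i}"] = om.sample_points(mesh, 800, seed=i, specimen_id=f"s{i}")
        res = om.generalized_alignment(samples, "s0", allow_scale=True,
                                       rel_tol=1e-4)
        assert np.all(np.diff(res.mean_psm_history) <= 0)

    def test_homologized_matches_brute_force(self, reference_mesh):
        """Small instance: homologized rows equal all-pairs NN selection."""
        samples = self._posed_copies(reference_mesh, 5, 200, seed=2)
        res = om.generalized_alignment(samples, "s0", allow_scale=True,
                                       max_outer=1)
        P = res.prototype_points
        for k, sid in enumerate(res.specimen_ids):
            moved = res.alignments[sid].transform.apply(samples[sid].points)
            D = np.linalg.norm(P[:, None, :] - moved[None, :, :], axis=2)
            brute = moved[D.argmin(axis=1)]
            np.testing.assert_array_equal(
                res.homologized[k].reshape(-1, 3), brute)

    def test_pose_invariance_of_scores(self):
        rng = np.random.default_rng(9)
        spec = om.ShapeEffectSpec(coefficient_noise_sd=0.03)
        meshes = {f"s{i}": om.make_mesh(spec, 1500, rng)[0] for i in range(5)}
        samples = {sid: om.sample_points(m, 800, seed=4, specimen_id=sid)
                   for sid, m in meshes.items()}
        res1 = om.generalized_alignment(samples, "s0", allow_scale=True)
        pose_rng = np.random.default_rng(1)
        moved = {}
        for sid, m in meshes.items():
            p = _random_pose(pose_rng)
            p.scale = 1.0  # rigid only: identical sampling in new pose
            mm = m.copy()
            mm.vertices = p.apply(np.asarray(mm.vertices))
            moved[sid] = om.sample_points(mm, 800, seed=4, specimen_id=sid)
        res2 = om.generalized_alignment(moved, "s0", allow_scale=True)
        diag = np.abs(res1.ordination.scores).max()
        assert np.abs(np.abs(res1.ordination.scores)
                      - np.abs(res2.ordination.scores)).max() < 1e-4 * diag

    def test_scale_handling(self):
        rng = np.random.default_rng(13)
        spec = om.ShapeEffectSpec(coefficient_noise_sd=0.03)
        meshes = {f"s{i}": om.make_mesh(spec, 1500, rng)[0] for i in range(5)}
        big = meshes["s3"].copy()
        big.vertices = np.asarray(big.vertices) * 2.0
        meshes_big = dict(meshes, s3=big)

        def scores_of(ms, allow_scale):
            samples = {sid: om.sample_points(m, 800, seed=6, specimen_id=sid)
                       for sid, m in ms.items()}
            return om.generalized_alignment(samples, "s0",
                                            allow_scale=allow_scale)

        r_ref = scores_of(meshes, True)
        r_big = scores_of(meshes_big, True)
        assert r_big.centroid_sizes["s3"] == pytest.approx(
            2 * r_ref.centroid_sizes["s3"], rel=1e-6)
        spread = np.abs(r_ref.ordination.scores).max()
        assert np.abs(np.abs(r_big.ordination.scores)
                      - np.abs(r_ref.ordination.scores)).max() < 1e-3 * spread
        # without scale removal the doubled specimen separates on PC1
        r_ns = scores_of(meshes_big, False)
        idx = r_ns.specimen_ids.index("s3")
        pc1 = r_ns.ordination.scores[:, 0]
        others = np.delete(pc1, idx)
        assert np.abs(pc1[idx] - others.mean()) > 5 * (others.std() + 1e-12)

    def test_eigenvalue_contracts(self):
        rng = np.random.default_rng(21)
        spec = om.ShapeEffectSpec(coefficient_noise_sd=0.04)
        samples = {}
        for i in range(6):
            mesh, _ = om.make_mesh(spec, 1500, rng)
            samples[f"s{i}"] = om.sample_points(mesh, 600, seed=i, specimen_id=f"s{i}")
        res = om.generalized_alignment(samples, "s0")
        eig = res.ordination.eigenvalues
        assert res.ordination.proportions.sum() == pytest.approx(1.0, abs=1e-12)
        assert (eig > eig[0] * 1e-12).sum() <= 5  # n - 1

    def test_unknown_prototype(self, reference_mesh):
        s = om.sample_points(reference_mesh, 300, seed=0)
        with pytest.raises(KeyError):
            om.generalized_alignment({"a": s}, "nope")


class TestDeviationExport:
    def test_zero_field_for_identical_cohort(self, reference_mesh, tmp_path):
        rng = np.random.default_rng(7)
        samples = {}
        for i in range(4):
            p = _random_pose(rng)
            mm = reference_mesh.copy()
            mm.vertices = p.apply(np.asarray(mm.vertices))
            samples[f"s{i}"] = om.sample_points(mm, 500, seed=11, specimen_id=f"s{i}")
        res = om.generalized_alignment(samples, "s0")
        assert len(res.deviation) == 500
        assert np.all(res.deviation >= 0)
        assert res.deviation.max() < 1e-8
        from osteomorph.surface import deviation_heat_export
        # zero-variance ordination: the deviation field is exported, the
        # (nonexistent) PC loading fields are skipped
        paths = deviation_heat_export(res, tmp_path / "heat.ply",
                                      include_pc_loadings=2)
        assert len(paths) == 1 and paths[0].exists()
        header = (tmp_path / "heat.ply").read_text().splitlines()[:8]
        assert any("quality" in line for line in header)

    def test_pc_loading_fields_written(self, tmp_path):
        rng = np.random.default_rng(3)
        spec = om.ShapeEffectSpec(coefficient_noise_sd=0.04)
        samples = {}
        for i in range(4):
            mesh, _ = om.make_mesh(spec, 1500, rng)
            samples[f"s{i}"] = om.sample_points(mesh, 400, seed=i, specimen_id=f"s{i}")
        res = om.generalized_alignment(samples, "s0")
        from osteomorph.surface import deviation_heat_export
        paths = deviation_heat_export(res, tmp_path / "heat.ply",
                                      include_pc_loadings=2)
        assert len(paths) == 3 and all(p.exists() for p in paths)
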