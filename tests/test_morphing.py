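import numpy as np
import pytest
import trimesh

import footmech.phantom as ph
from footmech.geometry import TriangleIndex, hrmsd, make_mesh
from footmech.morphing import (
    LandmarkSet,
    MorphResult,
    ProjectionSchedule,
    RBFParams,
    SimilarityTransform,
    align_and_scale,
    morph,
    normal_projection,
    normal_projection_step,
    projection_weight,
    rbf_kernel,
    rbf_morph_step,
    select_landmarks,
    smooth_windowed_sinc,
    solve_rbf_weights,
    transfer_attachments,
)


@pytest.fixture(scope="module")
def blob():
    """Irregular star-shaped test mesh (non-spherical principal axes)."""
    return ph.generate_bone((14, 9, 7), noise_amplitude=0.8, seed=21, subdivisions=4).mesh


class TestAlignAndScale:
    def test_recovers_pure_scaling(self, blob):
        target = blob.copy()
        target.apply_scale(1.3)
        target.apply_translation(-0.3 * np.asarray(blob.vertices).mean(axis=0))
        aligned, sim = align_and_scale(blob, target)
        assert sim.scale == pytest.approx(1.3, abs=1e-6)
        assert hrmsd(aligned, target) < 1e-6

    def test_identity_pair(self, blob):
        aligned, sim = align_and_scale(blob, blob)
        assert sim.scale == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(sim.rotation, np.eye(3), atol=1e-6)

    def test_alignment_improves_hrmsd(self, bone_pair):
        aligned, _ = align_and_scale(bone_pair["source"], bone_pair["target"])
        assert hrmsd(aligned, bone_pair["target"]) < hrmsd(
            bone_pair["source"], bone_pair["target"])

    def test_near_spherical_source_warns(self, sphere):
        target = sphere.copy()
        target.apply_scale(1.2)
        with pytest.warns(UserWarning, match="near-spherical"):
            align_and_scale(sphere, target)


class TestProjectionWeight:
    @pytest.mark.parametrize("t,expected", [
        (0, 0.025),          # first step at the documented slope
        (39, 1.0),           # 0.025 * 40, exactly at the cap
        (1000, 1.0),         # deep in the capped regime
    ])
    def test_schedule_values(self, t, expected):
        assert projection_weight(t, ProjectionSchedule()) == pytest.approx(expected)

    def test_weight_stays_in_range(self):
        sched = ProjectionSchedule(a=0.07, w1=0.8)
        for t in range(100):
            assert 0 < projection_weight(t, sched) <= 0.8


class TestProjectionStep:
    def test_fixed_point_on_target_surface(self, sphere):
        index = TriangleIndex(sphere)
        out = normal_projection_step(sphere, index, w=1.0)
        assert hrmsd(out, sphere) < 1e-9

    @pytest.mark.parametrize("w,expected_r", [(1.0, 12.0), (0.5, 11.0)])
    def test_concentric_spheres_step(self, w, expected_r):
        src = trimesh.creation.icosphere(3, radius=10.0)
        target = trimesh.creation.icosphere(4, radius=12.0)
        out = normal_projection_step(src, TriangleIndex(target), w=w)
        radii = np.linalg.norm(np.asarray(out.vertices), axis=1)
        np.testing.assert_allclose(radii, expected_r, atol=0.15)


class TestSmoothing:
    def test_volume_preserved_within_one_percent(self, sphere):
        out = smooth_windowed_sinc(sphere, 0.1, 20)
        assert abs(out.volume - sphere.volume) / sphere.volume < 0.01

    def test_zero_iterations_is_identity(self, sphere):
        out = smooth_windowed_sinc(sphere, 0.1, 0)
        np.testing.assert_array_equal(np.asarray(out.vertices),
                                      np.asarray(sphere.vertices))

    def test_spike_damped_by_half(self, sphere):
        v = np.asarray(sphere.vertices).copy()
        v[0] *= 1.5  # 5 mm spike on a 10 mm sphere
        spiked = make_mesh(v, np.asarray(sphere.faces))
        out = smooth_windowed_sinc(spiked, 0.1, 20)
        assert np.linalg.norm(np.asarray(out.vertices)[0]) - 10.0 < 2.5

    def test_topology_unchanged(self, blob):
        out = smooth_windowed_sinc(blob, 0.1, 20)
        assert len(out.vertices) == len(blob.vertices)
        np.testing.assert_array_equal(np.asarray(out.faces), np.asarray(blob.faces))


class TestNormalProjection:
    def test_identical_meshes_terminate_immediately(self, blob):
        out, trace, converged = normal_projection(blob, blob)
        assert converged and len(trace) == 1

    def test_trace_finite_and_decreasing_overall(self, bone_pair):
        aligned, _ = align_and_scale(bone_pair["source"], bone_pair["target"])
        out, trace, converged = normal_projection(aligned, bone_pair["target"])
        assert np.all(np.isfinite(trace))
        assert trace[-1] <= trace[0]
        assert converged


class TestRBFKernel:
    def test_value_at_zero_is_one(self):
        assert rbf_kernel(0.0, c=0.5) == pytest.approx(1.0)

    @pytest.mark.parametrize("d,c,expected", [
        (1.0, 0.5, 0.96026),     # beta capped at k1=0.1: 1.5 ** -0.1
        (0.005, 0.01, 1.6079),   # beta = 10 * 0.005: (7.5e-5) ** -0.05
    ])
    def test_hand_evaluations(self, d, c, expected):
        assert rbf_kernel(d, c) == pytest.approx(expected, abs=1e-4)

    def test_positive_and_finite(self, rng):
        d = rng.uniform(0, 100, 1000)
        k = rbf_kernel(d, c=2.0)
        assert np.all(k > 0) and np.all(np.isfinite(k))

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel(1.0, c=0.0)

    def test_power_reading_selectable(self):
        k_prod = rbf_kernel(2.0, c=0.5, params=RBFParams())
        k_pow = rbf_kernel(2.0, c=0.5, params=RBFParams(power_c=True))
        assert k_prod != pytest.approx(k_pow)


class TestLandmarks:
    def test_identical_meshes_give_zero_displacements(self, blob):
        lm, c = select_landmarks(blob, blob, fraction=1.0)
        assert lm.magnitudes.max() < 1e-9
        assert c > 0

    def test_concentric_spheres_unit_displacements(self):
        src = trimesh.creation.icosphere(4, radius=10.0)
        tgt = trimesh.creation.icosphere(4, radius=11.0)
        lm, _ = select_landmarks(src, tgt, fraction=1.0)
        np.testing.assert_allclose(lm.magnitudes, 1.0, atol=0.05)

    def test_fraction_keeps_top_magnitudes(self, bone_pair):
        aligned, _ = align_and_scale(bone_pair["source"], bone_pair["target"])
        small, _ = select_landmarks(aligned, bone_pair["target"], fraction=0.1)
        full, _ = select_landmarks(aligned, bone_pair["target"], fraction=1.0)
        assert len(small) < len(full)
        assert small.magnitudes.min() >= np.percentile(full.magnitudes, 50)


class TestRBFSolveAndStep:
    def test_zero_displacement_gives_zero_weights(self, rng):
        p = rng.normal(scale=10, size=(10, 3))
        lm = LandmarkSet(p, p)
        w = solve_rbf_weights(lm, c=2.0)
        np.testing.assert_allclose(w, 0.0, atol=1e-12)

    def test_interpolation_residual(self, rng):
        src = rng.normal(scale=10, size=(10, 3))
        tgt = src + rng.normal(scale=1.0, size=(10, 3))
        lm = LandmarkSet(src, tgt)
        w = solve_rbf_weights(lm, c=2.0)
        d = np.linalg.norm(src[:, None] - src[None, :], axis=2)
        k = rbf_kernel(d, 2.0)
        assert np.abs(k @ w - lm.displacements).max() < 1e-6

    def test_landmarks_land_on_targets_pre_smoothing(self, blob, rng):
        verts = np.asarray(blob.vertices)
        sel = rng.choice(len(verts), 40, replace=False)
        src_pts = verts[sel]
        tgt_pts = src_pts + rng.normal(scale=0.8, size=src_pts.shape)
        lm = LandmarkSet(src_pts, tgt_pts)
        out = rbf_morph_step(blob, lm, c=2.0)
        moved = np.asarray(out.vertices)[sel]
        assert np.abs(moved - tgt_pts).max() < 1e-4

    def test_dense_translation_field_reproduced(self, sphere):
        # landmarks at every vertex: the interpolant reproduces the
        # constant field at each vertex exactly
        verts = np.asarray(sphere.vertices)
        lm = LandmarkSet(verts, verts + np.array([1.0, 0, 0]))
        out = rbf_morph_step(sphere, lm, c=2.0)
        disp = np.asarray(out.vertices) - verts
        np.testing.assert_allclose(disp, np.broadcast_to([1.0, 0, 0], disp.shape),
                                   atol=0.05)


class TestMorph:
    def test_source_equals_target_is_noop(self, blob):
        res = morph(blob, blob)
        assert res.hrmsd_trace["aligned"] < 1e-6
        assert all(v < 1e-3 for v in res.hrmsd_trace.values())

    def test_phantom_pair_protocol(self, bone_pair):
        res = morph(bone_pair["source"], bone_pair["target"])
        t = res.hrmsd_trace
        assert t["aligned"] >= t["projected"] >= t["rbf_5"]
        assert t["rbf_5"] < 0.01  # interpolation-level final accuracy
        # the morph removes at least 95% of the aligned-stage mismatch
        assert t["rbf_5"] <= 0.05 * t["aligned"]
        assert len(res.displacements) == len(np.asarray(bone_pair["source"].vertices))
        assert np.all(np.isfinite(np.asarray(res.morphed.vertices)))
        assert len(res.morphed.faces) == len(bone_pair["source"].faces)


class TestAttachmentTransfer:
    def _affine_morph_result(self, mesh, a_matrix):
        """MorphResult whose displacement field is exactly the affine map."""
        verts = np.asarray(mesh.vertices)
        morphed = make_mesh(verts @ a_matrix.T, np.asarray(mesh.faces))
        sim = SimilarityTransform(np.eye(3), 1.0, np.zeros(3), np.zeros(3))
        return MorphResult(morphed, mesh, verts @ a_matrix.T - verts,
                           {"aligned": 0.0}, sim)

    def test_affine_sphere_to_ellipsoid(self, rng):
        sphere = trimesh.creation.icosphere(4, radius=10.0)
        a_matrix = np.diag([1.3, 1.1, 0.85])
        res = self._affine_morph_result(sphere, a_matrix)
        q = rng.normal(size=(10, 3))
        q = 10.0 * q / np.linalg.norm(q, axis=1, keepdims=True)
        out = transfer_attachments(res, q)
        truth = q @ a_matrix.T
        rel = np.linalg.norm(out - truth, axis=1) / np.linalg.norm(truth, axis=1)
        assert rel.max() < 0.02

    def test_attachment_at_vertex_moves_with_vertex(self, blob):
        verts = np.asarray(blob.vertices)
        a_matrix = np.diag([1.1, 1.05, 0.95])
        res = self._affine_morph_result(blob, a_matrix)
        out = transfer_attachments(res, verts[7][None, :])
        np.testing.assert_allclose(out[0], verts[7] @ a_matrix.T, atol=1e-6)

    def test_zero_displacement_morph_leaves_attachment(self, blob):
        res = MorphResult(blob, blob, np.zeros_like(np.asarray(blob.vertices)),
                          {"aligned": 0.0},
                          SimilarityTransform(np.eye(3), 1.0, np.zeros(3), np.zeros(3)))
        q = np.asarray(blob.vertices)[3][None, :]
        out = transfer_attachments(res, q)
        np.testing.assert_allclose(out, q, atol=1e-9)

    def test_far_attachment_rejected_with_name(self, blob):
        res = MorphResult(blob, blob, np.zeros_like(np.asarray(blob.vertices)),
                          {"aligned": 0.0},
                          SimilarityTransform(np.eye(3), 1.0, np.zeros(3), np.zeros(3)))
        far = np.array([[500.0, 0, 0]])
        with pytest.raises(ValueError, match="deltoid"):
            transfer_attachments(res, far, names=["deltoid"])

    def test_phantom_pair_known_map(self, bone_pair):
        res = morph(bone_pair["source"], bone_pair["target"])
        out = transfer_attachments(res, bone_pair["attachment_source"][None, :])
        err = np.linalg.norm(out[0] - bone_pair["attachment_truth"])
        scale = np.linalg.norm(bone_pair["attachment_truth"]
                               - bone_pair["target"].center_mass)
        assert err / scale < 0.02
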