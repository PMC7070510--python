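import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smileasym import (
    AlignmentResult,
    FiducialSet,
    LandmarkSet,
    apply_transform,
    batch_align,
    solve_rigid_transform,
    weighted_centroids,
)
from smileasym.align import (
    DegenerateFiducialsError,
    _batch_solve_arrays,
    alignment_results_to_tsv,
)

from conftest import (
    brute_force_min_objective,
    random_similarity,
    weighted_objective,
)


def _as_set(points, frame_id=0, **kw):
    pts = np.zeros((68, 3))
    pts[: len(points)] = points
    return LandmarkSet(frame_id, pts, **kw)


class TestWeightedCentroids:
    def test_two_point_uniform_mean(self):
        fid = FiducialSet((0, 1))
        src = _as_set([(0, 0, 0), (2, 0, 0)])
        p, q = weighted_centroids(src, src, fid)
        assert np.allclose(p, (1, 0, 0)) and np.allclose(q, (1, 0, 0))

    def test_weighted_mean(self):
        # weights (1, 3) on (0,0,0) and (4,0,0): (1*0 + 3*4)/4 = 3
        fid = FiducialSet((0, 1), (1.0, 3.0))
        src = _as_set([(0, 0, 0), (4, 0, 0)])
        p, _ = weighted_centroids(src, src, fid)
        assert np.allclose(p, (3, 0, 0))

    def test_all_zero_points(self, fiducials, template):
        zero = template.with_points(np.zeros((68, 3)))
        p, q = weighted_centroids(zero, zero, fiducials)
        assert np.allclose(p, 0) and np.allclose(q, 0)


class TestSolveRigidTransform:
    def test_identity_when_target_equals_source(self, template, fiducials):
        ar = solve_rigid_transform(template, template, fiducials)
        assert np.allclose(ar.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(ar.translation, 0, atol=1e-9)
        assert ar.scale == pytest.approx(1.0, abs=1e-9)
        assert ar.mean_residual < 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_known_similarity(self, template, fiducials, seed):
        rng = np.random.default_rng(seed)
        R, t, s = random_similarity(rng)
        target = template.with_points(s * (template.points @ R.T) + t)
        ar = solve_rigid_transform(template, target, fiducials)
        assert np.abs(ar.rotation - R).max() < 1e-6
        assert np.abs(ar.translation - t).max() < 1e-6
        assert ar.scale == pytest.approx(s, abs=1e-6)
        assert ar.mean_residual < 1e-9

    def test_rotation_proper_even_for_mirrored_target(self, template, fiducials):
        mirrored = template.with_points(template.points * [-1, 1, 1])
        ar = solve_rigid_transform(template, mirrored, fiducials)
        assert np.linalg.det(ar.rotation) == pytest.approx(1.0, abs=1e-9)
        idx = fiducials.index_array
        w = fiducials.weight_array
        obj = weighted_objective(
            template.points[idx], mirrored.points[idx], w,
            ar.rotation, ar.translation, ar.scale,
        )
        best = brute_force_min_objective(
            template.points[idx], mirrored.points[idx], w, seed=7
        )
        assert obj <= best + 1e-9 * max(1.0, best)

    def test_beats_brute_force_on_random_configurations(self, rng):
        fid = FiducialSet(tuple(range(6)))
        w = fid.weight_array
        for _ in range(10):
            P = rng.normal(0, 20, (6, 3))
            Q = rng.normal(0, 20, (6, 3))
            src, tgt = _as_set(P), _as_set(Q)
            ar = solve_rigid_transform(src, tgt, fid)
            obj = weighted_objective(P, Q, w, ar.rotation, ar.translation, ar.scale)
            best = brute_force_min_objective(P, Q, w, n_rotations=5000, seed=1)
            assert obj <= best + 1e-9 * max(1.0, best)

    def test_collinear_fiducials_raise(self):
        fid = FiducialSet((0, 1, 2, 3))
        pts = [(float(i), 0, 0) for i in range(4)]
        with pytest.raises(DegenerateFiducialsError):
            solve_rigid_transform(_as_set(pts), _as_set(pts), fid)

    def test_fewer_than_three_fiducials_raise(self, template):
        with pytest.raises(ValueError, match="3 fiducial"):
            solve_rigid_transform(template, template, FiducialSet((0, 1)))

    def test_common_rotation_invariance(self, template, fiducials, rng):
        noisy = template.with_points(
            template.points + rng.normal(0, 1.0, (68, 3))
        )
        base = solve_rigid_transform(template, noisy, fiducials)
        R, _, _ = random_similarity(rng)
        src2 = template.with_points(template.points @ R.T)
        tgt2 = noisy.with_points(noisy.points @ R.T)
        rotated = solve_rigid_transform(src2, tgt2, fiducials)
        assert rotated.mean_residual == pytest.approx(base.mean_residual, abs=1e-9)

    def test_with_scale_false_forces_unit_scale(self, template, fiducials):
        target = template.with_points(1.2 * template.points)
        ar = solve_rigid_transform(template, target, fiducials, with_scale=False)
        assert ar.scale == 1.0


class TestApplyTransform:
    def test_identity_leaves_points_unchanged(self, template):
        out = apply_transform(template, AlignmentResult.identity())
        assert np.array_equal(out.points, template.points)

    def test_pure_translation(self, template):
        ar = AlignmentResult(np.eye(3), np.array([5.0, 0, 0]), 1.0, np.zeros(0), 0.0)
        out = apply_transform(template, ar)
        assert np.allclose(out.points[:, 0], template.points[:, 0] + 5)
        assert np.allclose(out.points[:, 1:], template.points[:, 1:])

    def test_pure_scale(self):
        ls = _as_set([(1.0, 1.0, 1.0)])
        ar = AlignmentResult(np.eye(3), np.zeros(3), 2.0, np.zeros(0), 0.0)
        assert np.allclose(apply_transform(ls, ar).points[0], (2, 2, 2))


class TestBatchAlign:
    def test_copies_of_reference_give_identity(self, template, fiducials):
        frames = [
            LandmarkSet(i, template.points.copy(), 0.99, True) for i in range(10)
        ]
        out = batch_align(frames, template, fiducials)
        assert len(out) == 10
        for _, ar in out:
            assert ar.mean_residual < 1e-9

    def test_known_poses_recovered(self, template, fiducials, rng):
        frames, truth = [], []
        for i in range(10):
            R, t, s = random_similarity(rng)
            frames.append(
                LandmarkSet(i, s * (template.points @ R.T) + t, 0.99, True)
            )
            truth.append((R, t, s))
        out = batch_align(frames, template, fiducials)
        assert max(ar.mean_residual for _, ar in out) < 1e-9
        for (aligned, ar), (R, t, s) in zip(out, truth):
            # recovered transform inverts the applied pose
            assert np.abs(ar.rotation - R.T).max() < 1e-6
            assert np.abs(aligned.points - template.points).max() < 1e-6

    def test_failed_frames_skipped(self, template, fiducials):
        frames = [
            LandmarkSet(i, template.points.copy(), 0.99, True) for i in range(9)
        ]
        frames.append(LandmarkSet(9, template.points.copy(), 0.99, False))
        frames.append(LandmarkSet(10, template.points.copy(), 0.10, True))
        out = batch_align(frames, template, fiducials)
        assert [f.frame_id for f, _ in out] == list(range(9))

    def test_empty_sequence_raises(self, template, fiducials):
        with pytest.raises(ValueError, match="empty"):
            batch_align([], template, fiducials)

    def test_vectorised_path_matches_scalar_solver(self, template, fiducials, rng):
        frames = []
        for i in range(6):
            R, t, s = random_similarity(rng)
            noisy = s * (template.points @ R.T) + t + rng.normal(0, 0.5, (68, 3))
            frames.append(LandmarkSet(i, noisy, 0.99, True))
        stack = np.stack([f.points for f in frames])
        _, Rb, tb, sb, resb = _batch_solve_arrays(stack, template.points, fiducials)
        for i, f in enumerate(frames):
            ar = solve_rigid_transform(f, template, fiducials)
            assert np.abs(ar.rotation - Rb[i]).max() < 1e-9
            assert np.abs(ar.translation - tb[i]).max() < 1e-9
            assert ar.scale == pytest.approx(sb[i], abs=1e-12)
            assert ar.mean_residual == pytest.approx(resb[i], abs=1e-9)

    def test_residual_grows_with_noise(self, template, fiducials):
        rng = np.random.default_rng(99)
        means = []
        for sigma in (0.1, 0.5, 1.0):
            frames = [
                LandmarkSet(
                    i, template.points + rng.normal(0, sigma, (68, 3)), 0.99, True
                )
                for i in range(200)
            ]
            out = batch_align(frames, template, fiducials)
            means.append(np.mean([ar.mean_residual for _, ar in out]))
        assert means[0] < means[1] < means[2]


@given(
    angles=st.tuples(*[st.floats(-180, 180) for _ in range(3)]),
    scale=st.floats(0.5, 2.0),
    tx=st.floats(-100, 100),
)
@settings(max_examples=30, deadline=None)
def test_any_similarity_transform_recovered(angles, scale, tx):
    """Whatever proper similarity transform is applied, the solver
    recovers it exactly in the noise-free case."""
    from scipy.spatial.transform import Rotation

    from smileasym import template_face

    template = template_face()
    fid = FiducialSet()
    R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
    t = np.array([tx, -tx / 2, 3.0])
    target = template.with_points(scale * (template.points @ R.T) + t)
    ar = solve_rigid_transform(template, target, fid)
    assert np.abs(ar.rotation - R).max() < 1e-6
    assert ar.scale == pytest.approx(scale, abs=1e-6)
    assert ar.mean_residual < 1e-7


def test_alignment_results_tsv(tmp_path, template, fiducials):
    ar = solve_rigid_transform(template, template, fiducials)
    path = tmp_path / "transforms.tsv"
    alignment_results_to_tsv([ar], path)
    lines = path.read_text().splitlines()
    assert lines[0].split("\t")[:2] == ["frame_id", "r00"]
    assert len(lines) == 2 and len(lines[1].split("\t")) == 15
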