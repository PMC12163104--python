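import numpy as np
import pytest

from hipshape.alignment import gpa_align, pose_correct_femurs
from hipshape.geometry import SimilarityTransform, apply_transform, centroid_size
from hipshape.synthetic import generate_cohort

from conftest import small_cohort_config
from test_geometry import random_rotation


def jittered_copies(base, n, rng, scales=None):
    out = []
    for i in range(n):
        s = scales[i] if scales is not None else 1.0
        T = SimilarityTransform(
            rotation=random_rotation(rng), translation=rng.normal(0, 20, 3), scale=s
        )
        out.append(apply_transform(T, base))
    return out


class TestGpaAlign:
    def test_two_identical_shapes_in_different_poses(self, rng):
        base = rng.normal(size=(40, 3)) * 10
        shapes = jittered_copies(base, 2, rng)
        aligned, _, mean, _ = gpa_align(shapes, allow_scale=False)
        assert np.linalg.norm(aligned[0] - aligned[1]) < 1e-6
        assert np.linalg.norm(mean - aligned[0]) < 1e-6

    def test_pure_similarity_cohort_collapses(self, rng):
        base = rng.normal(size=(60, 3)) * 15
        scales = rng.uniform(0.7, 1.4, 10)
        shapes = jittered_copies(base, 10, rng, scales=scales)
        aligned, _, _, _ = gpa_align(shapes, allow_scale=True)
        for i in range(10):
            for j in range(i + 1, 10):
                rms = np.sqrt(np.mean(np.sum((aligned[i] - aligned[j]) ** 2, axis=1)))
                assert rms < 1e-6

    def test_objective_monotone_nonincreasing(self, small_cohort):
        shapes = [
            np.concatenate([s.shapes["pelvis_L"].points, s.shapes["pelvis_R"].points])
            for s in small_cohort.subjects
        ]
        # instrument: track the objective across iterations manually
        from hipshape.geometry import optimal_superposition

        target = np.mean([centroid_size(s) for s in shapes])
        cur = [target / centroid_size(s) * (s - s.mean(0)) for s in shapes]
        mean = cur[0].copy()
        objs = []
        for _ in range(8):
            for i in range(len(cur)):
                cur[i] = apply_transform(optimal_superposition(cur[i], mean), cur[i])
            mean = np.mean(cur, axis=0)
            objs.append(sum(np.sum((c - mean) ** 2) for c in cur))
        assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))

    def test_local_optimality_against_random_rerotations(self):
        rng = np.random.default_rng(3)
        cohort = generate_cohort(small_cohort_config(seed=3))
        shapes = [
            np.concatenate([s.shapes["pelvis_L"].points, s.shapes["pelvis_R"].points])
            for s in cohort.subjects
        ]
        aligned, _, mean, _ = gpa_align(shapes, allow_scale=True)
        base_obj = sum(np.sum((a - mean) ** 2) for a in aligned)
        for _ in range(100):
            i = rng.integers(len(aligned))
            perturbed = [a.copy() for a in aligned]
            c = perturbed[i].mean(axis=0)
            perturbed[i] = (perturbed[i] - c) @ random_rotation(rng).T + c
            new_mean = np.mean(perturbed, axis=0)
            new_obj = sum(np.sum((a - new_mean) ** 2) for a in perturbed)
            assert new_obj >= base_obj - 1e-6

    def test_ordering_invariance_up_to_similarity(self, small_cohort):
        from hipshape.geometry import optimal_superposition

        shapes = [
            np.concatenate([s.shapes["pelvis_L"].points, s.shapes["pelvis_R"].points])
            for s in small_cohort.subjects
        ]
        _, _, mean_a, _ = gpa_align(shapes, allow_scale=True)
        order = np.random.default_rng(1).permutation(len(shapes))
        _, _, mean_b, _ = gpa_align([shapes[i] for i in order], allow_scale=True)
        T = optimal_superposition(mean_b, mean_a, allow_scale=True)
        assert np.abs(apply_transform(T, mean_b) - mean_a).max() < 1e-6

    def test_scale_removal_equalizes_centroid_sizes(self, small_cohort):
        shapes = [
            np.concatenate([s.shapes["pelvis_L"].points, s.shapes["pelvis_R"].points])
            for s in small_cohort.subjects
        ]
        target = np.mean([centroid_size(s) for s in shapes])
        aligned, _, _, _ = gpa_align(shapes, allow_scale=True)
        for a in aligned:
            assert centroid_size(a) == pytest.approx(target, rel=1e-6)

    def test_transforms_map_input_to_aligned(self, small_cohort):
        shapes = [
            np.concatenate([s.shapes["pelvis_L"].points, s.shapes["pelvis_R"].points])
            for s in small_cohort.subjects
        ]
        aligned, transforms, _, _ = gpa_align(shapes, allow_scale=True)
        for s, T, a in zip(shapes, transforms, aligned):
            assert np.abs(apply_transform(T, s) - a).max() < 1e-8

    def test_fewer_than_two_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            gpa_align([rng.normal(size=(10, 3))])


def synthetic_femurs(rng, n=8, rot_deg=0.0):
    """Identical femur-like clouds, optionally rotated about their head centres."""
    base = np.concatenate(
        [
            8.0 * _unit(rng, 120),                                # head at origin
            np.column_stack([np.linspace(5, 60, 80), np.zeros(80), -np.linspace(5, 90, 80)]),
        ]
    )
    head_idx = np.arange(120)
    femurs, centers = [], []
    for i in range(n):
        c = rng.normal(0, 30, 3)
        ang = np.deg2rad(rot_deg) * rng.uniform(-1, 1, 3) if rot_deg else np.zeros(3)
        R = _euler(ang)
        femurs.append(base @ R.T + c)
        centers.append(c)
    return femurs, centers, head_idx


def _unit(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _euler(ang):
    cx, sx = np.cos(ang[0]), np.sin(ang[0])
    cy, sy = np.cos(ang[1]), np.sin(ang[1])
    cz, sz = np.cos(ang[2]), np.sin(ang[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


class TestPoseCorrection:
    def test_fixed_point_when_already_at_mean_pose(self, rng):
        femurs, centers, _ = synthetic_femurs(rng, rot_deg=0.0)
        corrected, transforms, _, disps = pose_correct_femurs(femurs, centers)
        assert len(disps) == 1  # converges immediately
        for f, c in zip(corrected, femurs):
            assert np.abs(f - c).max() < 1e-9
        for T in transforms:
            assert np.allclose(T.rotation, np.eye(3), atol=1e-9)

    def test_single_outlier_rotated_back_to_mean(self, rng):
        femurs, centers, _ = synthetic_femurs(rng, n=10, rot_deg=0.0)
        R20 = _euler(np.deg2rad([0, 20.0, 0]))
        femurs[3] = (femurs[3] - centers[3]) @ R20.T + centers[3]
        corrected, transforms, mean, _ = pose_correct_femurs(femurs, centers)
        # after correction the outlier shares the common (mean) orientation:
        # the relative rotation to any other corrected femur is < 0.1 degrees
        from hipshape.geometry import optimal_superposition

        rel = optimal_superposition(corrected[3], corrected[0]).rotation
        angle = np.rad2deg(np.arccos(np.clip((np.trace(rel) - 1) / 2, -1, 1)))
        assert angle < 0.1
        # and the head centre moved by less than 1e-6 mm
        moved = apply_transform(transforms[3], np.asarray(centers[3]))
        assert np.linalg.norm(moved - centers[3]) < 1e-6

    def test_head_center_preservation_and_scale_one(self, rng):
        femurs, centers, _ = synthetic_femurs(rng, n=12, rot_deg=15.0)
        corrected, transforms, _, _ = pose_correct_femurs(femurs, centers)
        for T, c in zip(transforms, centers):
            assert T.scale == 1.0
            assert np.linalg.norm(apply_transform(T, np.asarray(c)) - c) < 1e-6

    def test_shaft_axis_dispersion_decreases(self):
        rng = np.random.default_rng(4)
        femurs, centers, _ = synthetic_femurs(rng, n=15, rot_deg=15.0)
        shaft = slice(120, 200)

        def axis_var(fems):
            axes = []
            for f in fems:
                seg = f[shaft]
                d = seg[-1] - seg[0]
                axes.append(d / np.linalg.norm(d))
            return float(np.trace(np.cov(np.asarray(axes).T)))

        corrected, _, _, _ = pose_correct_femurs(femurs, centers)
        assert axis_var(corrected) < axis_var(femurs)


class TestAlignCohort:
    def test_full_alignment_invariants(self, default_result):
        aligned = default_result.aligned
        # head-centre preservation after pose correction
        for side in "LR":
            d = np.linalg.norm(
                aligned.head_centers_after[side] - aligned.head_centers_before[side], axis=1
            )
            assert d.max() < 1e-6
            for T in aligned.femur_transforms[side]:
                assert T.scale == 1.0
        # aligned pelvis sizes are equalized
        sizes = [
            centroid_size(np.concatenate([sub["pelvis_L"], sub["pelvis_R"]]))
            for sub in aligned.aligned
        ]
        assert np.ptp(sizes) / np.mean(sizes) < 1e-6

    def test_femur_orientation_dispersion_reduced(self, default_result):
        aligned = default_result.aligned
        cohort = default_result.cohort

        def axis_var(get_points):
            axes = []
            for i, subj in enumerate(cohort.subjects):
                idx = subj.shapes["femur_R"].landmark_index_map["shaft"]
                seg = get_points(i)[np.atleast_1d(idx)]
                d = seg[-1] - seg[0]
                axes.append(d / np.linalg.norm(d))
            return float(np.trace(np.cov(np.asarray(axes).T)))

        before = axis_var(lambda i: cohort.subjects[i].shapes["femur_R"].points)
        after = axis_var(lambda i: aligned.aligned[i]["femur_R"])
        assert after < before
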