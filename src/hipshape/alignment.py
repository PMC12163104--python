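"""Cohort alignment: generalized Procrustes analysis of the combined pelvic
bones with size removal, then femur pose correction to a mean pose that
preserves each femoral head centre, iterated to convergence.

GPA here follows the geometric-morphometrics convention: when scaling is
allowed, every shape is first normalised to the mean input centroid size
(keeping millimetre units meaningful), then rotations/translations are
iterated against the evolving mean. Each half-step of the iteration is an
exact coordinate-descent step on the sum of squared distances to the mean,
so the objective is monotone non-increasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import SIDES, Cohort
from .geometry import (
    SimilarityTransform,
    apply_transform,
    centroid_size,
    fit_sphere,
    optimal_superposition,
)

__all__ = ["AlignedCohort", "gpa_align", "pose_correct", "align_cohort"]

GPA_TOL = 1e-7          # relative mean-shape change
POSE_TOL = 1e-5         # mm, max per-point displacement between iterations
MAX_ITER = 100


@dataclass
class AlignedCohort:
    """Aligned shapes plus the transforms and diagnostics that produced them.

    ``pelvis_transforms`` map each subject's original combined pelvis to the
    aligned frame (similarity); ``femur_transforms`` are the additional rigid
    (scale exactly 1) pose corrections applied per side after the pelvis
    transform. Head centres are recorded before and after pose correction;
    their preservation is the defining invariant of the procedure.
    """

    cohort: Cohort
    aligned: list                       # per subject: dict bone_id -> (N,3) points
    pelvis_transforms: list             # SimilarityTransform per subject
    femur_transforms: dict = field(default_factory=dict)   # side -> list of rigid transforms
    head_centers_before: dict = field(default_factory=dict)  # side -> (n,3)
    head_centers_after: dict = field(default_factory=dict)   # side -> (n,3)
    gpa_iterations: list = field(default_factory=list)       # relative mean change per iter
    pose_iterations: dict = field(default_factory=dict)      # side -> max displacement per iter
    mean_pelvis: np.ndarray = None
    mean_femur: dict = field(default_factory=dict)           # side -> (N,3)

    def stacked(self, bone_ids) -> np.ndarray:
        """(n_subjects, 3N) flattened aligned coordinates for the given bones."""
        rows = [
            np.concatenate([sub[b].ravel() for b in bone_ids]) for sub in self.aligned
        ]
        return np.stack(rows, axis=0)


def gpa_align(shapes, allow_scale: bool = True, tol: float = GPA_TOL, max_iter: int = MAX_ITER):
    """Generalized Procrustes alignment of corresponded point sets.

    Returns ``(aligned, transforms, mean, changes)`` where ``transforms[i]``
    maps ``shapes[i]`` onto ``aligned[i]`` and ``changes`` is the per-iteration
    relative mean-shape change. With ``allow_scale`` every aligned shape has
    exactly the mean input centroid size (size differences removed).
    """
    shapes = [np.asarray(s, dtype=float) for s in shapes]
    if len(shapes) < 2:
        raise ValueError(f"GPA needs at least 2 shapes, got {len(shapes)}")
    if len({s.shape for s in shapes}) != 1:
        raise ValueError("all shapes must have identical point counts")

    target_size = float(np.mean([centroid_size(s) for s in shapes]))
    aligned, transforms = [], []
    for s in shapes:
        c = s.mean(axis=0)
        scale = target_size / centroid_size(s) if allow_scale else 1.0
        aligned.append(scale * (s - c))
        transforms.append(SimilarityTransform(translation=-scale * c, scale=scale))

    mean = aligned[0].copy()   # bootstrap from the first subject, then iterate
    changes = []
    for _ in range(max_iter):
        for i in range(len(aligned)):
            T = optimal_superposition(aligned[i], mean, allow_scale=False)
            aligned[i] = apply_transform(T, aligned[i])
            transforms[i] = T.compose(transforms[i])
        new_mean = np.mean(aligned, axis=0)
        change = float(np.linalg.norm(new_mean - mean) / np.linalg.norm(mean))
        changes.append(change)
        mean = new_mean
        if change < tol:
            break
    else:
        warnings.warn(f"GPA did not converge in {max_iter} iterations (last change {change:.3g})")
    return aligned, transforms, mean, changes


def pose_correct_femurs(femurs, head_centers, tol: float = POSE_TOL, max_iter: int = MAX_ITER):
    """Align femurs to a mean pose (rotation+translation only), then translate
    each back so its head centre returns to ``head_centers[i]``; repeat until
    the maximum per-point displacement between iterations falls below ``tol``.

    Returns ``(corrected, transforms, mean, displacements)``; every returned
    transform has scale exactly 1 and maps the input femur to its corrected
    pose, and every corrected femur's head centre equals the input centre.
    """
    femurs = [np.asarray(f, dtype=float).copy() for f in femurs]
    centers = [np.asarray(c, dtype=float).reshape(3) for c in head_centers]
    if len(femurs) != len(centers):
        raise ValueError("need one head centre per femur")
    transforms = [SimilarityTransform() for _ in femurs]
    mean = np.mean(femurs, axis=0)
    displacements = []
    for _ in range(max_iter):
        prev = np.stack(femurs, axis=0)
        for i in range(len(femurs)):
            T = optimal_superposition(femurs[i], mean, allow_scale=False)
            moved_center = apply_transform(T, centers[i])
            correction = centers[i] - moved_center
            T = SimilarityTransform(rotation=T.rotation, translation=T.translation + correction)
            femurs[i] = apply_transform(T, femurs[i])
            transforms[i] = T.compose(transforms[i])
        mean = np.mean(femurs, axis=0)
        disp = float(np.abs(np.linalg.norm(np.stack(femurs, axis=0) - prev, axis=-1)).max())
        displacements.append(disp)
        if disp < tol:
            break
    else:
        warnings.warn(f"pose correction did not converge in {max_iter} iterations")
    return femurs, transforms, mean, displacements


def pose_correct(aligned: AlignedCohort, tol: float = POSE_TOL, max_iter: int = MAX_ITER) -> AlignedCohort:
    """Apply femur pose correction (per side, separately) to a GPA-aligned cohort."""
    for side in SIDES:
        bone = f"femur_{side}"
        femurs = [sub[bone] for sub in aligned.aligned]
        centers = []
        for i, sub in enumerate(aligned.aligned):
            idx = aligned.cohort.subjects[i].shapes[bone].landmark_index_map["head"]
            try:
                centers.append(fit_sphere(sub[bone][idx]).center)
            except Exception as err:
                subj = aligned.cohort.subjects[i].subject_id
                raise RuntimeError(f"sphere fit failed for subject {subj}, side {side}: {err}") from err
        corrected, transforms, mean, disps = pose_correct_femurs(femurs, centers, tol=tol, max_iter=max_iter)
        for i, pts in enumerate(corrected):
            aligned.aligned[i][bone] = pts
        aligned.femur_transforms[side] = transforms
        aligned.head_centers_before[side] = np.stack(centers, axis=0)
        aligned.head_centers_after[side] = np.stack(
            [fit_sphere(corrected[i][np.atleast_1d(aligned.cohort.subjects[i].shapes[bone].landmark_index_map["head"])]).center
             for i in range(len(corrected))],
            axis=0,
        )
        aligned.pose_iterations[side] = disps
        aligned.mean_femur[side] = mean
    return aligned


def align_cohort(
    cohort: Cohort,
    allow_scale: bool = True,
    gpa_tol: float = GPA_TOL,
    pose_tol: float = POSE_TOL,
    max_iter: int = MAX_ITER,
) -> AlignedCohort:
    """Full alignment: GPA of the combined left+right pelvis, the same
    similarity applied to the femurs, then head-preserving femur pose
    correction per side."""
    pelvis_pairs = [
        np.concatenate([s.shapes["pelvis_L"].points, s.shapes["pelvis_R"].points], axis=0)
        for s in cohort.subjects
    ]
    aligned_pelvis, transforms, mean_pelvis, changes = gpa_align(
        pelvis_pairs, allow_scale=allow_scale, tol=gpa_tol, max_iter=max_iter
    )
    n_left = cohort.subjects[0].shapes["pelvis_L"].n_points
    aligned = []
    for i, subj in enumerate(cohort.subjects):
        T = transforms[i]
        aligned.append(
            {
                "pelvis_L": aligned_pelvis[i][:n_left],
                "pelvis_R": aligned_pelvis[i][n_left:],
                "femur_L": apply_transform(T, subj.shapes["femur_L"].points),
                "femur_R": apply_transform(T, subj.shapes["femur_R"].points),
            }
        )
    out = AlignedCohort(
        cohort=cohort,
        aligned=aligned,
        pelvis_transforms=transforms,
        gpa_iterations=changes,
        mean_pelvis=mean_pelvis,
    )
    return pose_correct(out, tol=pose_tol, max_iter=max_iter)
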