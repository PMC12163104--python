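"""Shared domain containers: corresponded shapes, angle sets, subjects, cohorts.

A :class:`CorrespondedShape` is an ordered 3D point set for one bone in which
index ``i`` marks the same anatomical location in every subject; point counts
and landmark indices are therefore identical across a cohort for a given bone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BONE_IDS", "SIDES", "ANGLE_NAMES", "CorrespondedShape", "AngleSet", "Subject", "Cohort"]

BONE_IDS = ("pelvis_L", "pelvis_R", "femur_L", "femur_R")
SIDES = ("L", "R")
ANGLE_NAMES = ("ce", "ai", "acav", "aasa", "pasa", "hasa")


@dataclass
class CorrespondedShape:
    """Ordered point set (mm) for one bone with named landmark indices.

    ``landmark_index_map`` maps landmark names to a single point index or, for
    region landmarks such as the acetabular rim circle or the femoral head
    patch, to an integer index array.
    """

    bone_id: str
    points: np.ndarray
    landmark_index_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bone_id not in BONE_IDS:
            raise ValueError(f"unknown bone_id {self.bone_id!r}; expected one of {BONE_IDS}")
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")
        if not np.isfinite(self.points).all():
            raise ValueError("points contain non-finite coordinates")
        n = len(self.points)
        for name, idx in self.landmark_index_map.items():
            arr = np.atleast_1d(np.asarray(idx))
            if arr.min(initial=0) < 0 or (n and arr.max(initial=-1) >= n):
                raise ValueError(f"landmark {name!r} has indices outside [0, {n})")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def landmark(self, name: str) -> np.ndarray:
        """Coordinates of a single-point landmark."""
        idx = self.landmark_index_map[name]
        if np.ndim(idx) != 0:
            raise ValueError(f"landmark {name!r} is a region, not a single point")
        return self.points[int(idx)]

    def region(self, name: str) -> np.ndarray:
        """Coordinates of a multi-point (region) landmark."""
        return self.points[np.atleast_1d(np.asarray(self.landmark_index_map[name], dtype=int))]

    def with_points(self, points: np.ndarray) -> "CorrespondedShape":
        return CorrespondedShape(self.bone_id, points, self.landmark_index_map)


@dataclass(frozen=True)
class AngleSet:
    """The six diagnostic hip angles in degrees.

    HASA is not free: it is defined as AASA + PASA and the identity is
    enforced at construction, so ``hasa`` is always exactly their sum.
    """

    ce: float
    ai: float
    acav: float
    aasa: float
    pasa: float

    def __post_init__(self) -> None:
        for name in ("ce", "ai", "acav", "aasa", "pasa"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"angle {name} is not finite: {v}")
            object.__setattr__(self, name, v)

    @property
    def hasa(self) -> float:
        return self.aasa + self.pasa

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in ANGLE_NAMES}


@dataclass
class Subject:
    """One subject: four bone shapes, sex, ground-truth angles and labels."""

    subject_id: str
    sex: str  # "F" or "M"
    shapes: dict  # bone_id -> CorrespondedShape
    true_angles: dict  # side -> AngleSet
    dysplasia: dict  # side -> bool (ground truth: true CE < 25 deg)
    params: object = None  # SubjectParams when generated synthetically

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")

    def shape(self, bone_id: str) -> CorrespondedShape:
        return self.shapes[bone_id]


@dataclass
class Cohort:
    """An ordered collection of subjects with a shared point correspondence."""

    subjects: list
    config: object = None  # GeneratorConfig when generated synthetically

    def __post_init__(self) -> None:
        for bone in BONE_IDS:
            counts = {s.shapes[bone].n_points for s in self.subjects if bone in s.shapes}
            if len(counts) > 1:
                raise ValueError(f"inconsistent point counts across subjects for {bone}: {counts}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_female(self) -> int:
        return sum(1 for s in self.subjects if s.sex == "F")

    def stacked_points(self, bone_ids) -> np.ndarray:
        """(n_subjects, N_total, 3) array concatenating ``bone_ids`` per subject."""
        rows = [
            np.concatenate([s.shapes[b].points for b in bone_ids], axis=0)
            for s in self.subjects
        ]
        return np.stack(rows, axis=0)
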