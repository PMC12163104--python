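"""Low-level 3D primitives: sphere fitting, rigid/similarity superposition.

All coordinates are millimetres in a right-handed anatomical frame:
x subject-left -> subject-right, y posterior -> anterior, z inferior -> superior.
The coronal plane is x-z, the axial plane is x-y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "Sphere",
    "SimilarityTransform",
    "fit_sphere",
    "optimal_superposition",
    "apply_transform",
    "centroid_size",
]


class DegenerateGeometryError(ValueError):
    """Raised for inputs that do not determine the requested primitive."""


@dataclass(frozen=True)
class Sphere:
    """A sphere in mm: ``center`` (3-vector) and ``radius`` (> 0)."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        if not np.isfinite(self.center).all():
            raise DegenerateGeometryError("sphere center must be finite")
        if not (self.radius > 0):
            raise DegenerateGeometryError(f"sphere radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class SimilarityTransform:
    """p -> scale * R @ p + t with R proper orthonormal and scale > 0."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    _ORTHO_TOL = 1e-9

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not (self.scale > 0):
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return SimilarityTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation + self.translation,
            scale=self.scale * other.scale,
        )

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        sinv = 1.0 / self.scale
        return SimilarityTransform(
            rotation=Rinv, translation=-sinv * Rinv @ self.translation, scale=sinv
        )


def _as_points(points, min_points: int) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (N, 3) point array, got shape {pts.shape}")
    if pts.shape[0] < min_points:
        raise DegenerateGeometryError(
            f"need at least {min_points} points, got {pts.shape[0]}"
        )
    if not np.isfinite(pts).all():
        raise ValueError("points contain non-finite coordinates")
    return pts


def fit_sphere(points) -> Sphere:
    """Algebraic least-squares sphere through ``points``.

    Solves ``||p||^2 = 2 c.p + (r^2 - ||c||^2)`` as a linear system for the
    center ``c`` and radius ``r``; exact for noise-free spherical samples.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 4 points or a coplanar/degenerate configuration.
    """
    pts = _as_points(points, 4)
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError("points are coplanar or otherwise degenerate for a sphere fit")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("sphere fit produced a non-positive radius")
    return Sphere(center=center, radius=float(np.sqrt(r2)))


def optimal_superposition(source, target, allow_scale: bool = False) -> SimilarityTransform:
    """Least-squares similarity (Kabsch/Procrustes) mapping ``source`` onto ``target``.

    Points correspond by index. Reflections are forbidden: the rotation
    determinant is forced to +1 by sign-correcting the smallest singular
    vector, so anatomy is never mirrored. With ``allow_scale`` off the scale
    is exactly 1.
    """
    src = _as_points(source, 3)
    tgt = _as_points(target, 3)
    if src.shape != tgt.shape:
        raise ValueError(f"point counts differ: {src.shape[0]} vs {tgt.shape[0]}")
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    sc = src - mu_s
    tc = tgt - mu_t
    var_s = float(np.einsum("ij,ij->", sc, sc))
    if var_s < 1e-24:
        raise DegenerateGeometryError("all source points coincide")
    H = sc.T @ tc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if allow_scale:
        scale = float((S @ np.diag(D)) / var_s)
        if scale <= 0:
            raise DegenerateGeometryError("degenerate configuration: non-positive optimal scale")
    else:
        scale = 1.0
    t = mu_t - scale * R @ mu_s
    return SimilarityTransform(rotation=R, translation=t, scale=scale)


def apply_transform(transform: SimilarityTransform, points) -> np.ndarray:
    """Apply ``p -> scale * R p + t`` per point, preserving order."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = transform.scale * pts @ transform.rotation.T + transform.translation
    return out[0] if single else out


def centroid_size(points) -> float:
    """Root-sum-of-squares distance of the points from their centroid (mm)."""
    pts = _as_points(points, 1)
    c = pts - pts.mean(axis=0)
    return float(np.sqrt(np.einsum("ij,ij->", c, c)))
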