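"""Point-distribution model: mean shape, PCA modes, projection, perturbation.

The covariance eigendecomposition uses the dual (small-matrix) trick via an
SVD of the centred data matrix, so cohorts with 3N >> n are cheap. The
sample-covariance ``1/(n-1)`` convention is used throughout; eigenvector
sign is fixed by making each mode's largest-magnitude component positive,
so stored models and tests are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PDM",
    "DisplacementMap",
    "build_pdm",
    "project",
    "reconstruct",
    "modes_for_variance",
    "perturb_mode",
    "displacement_map",
    "training_scores",
]

EIGENVALUE_FLOOR = 1e-10  # relative to the leading eigenvalue


@dataclass
class PDM:
    """Mean shape (3N-vector, mm), orthonormal modes (3N x K), eigenvalues."""

    mean_shape: np.ndarray
    modes: np.ndarray
    eigenvalues: np.ndarray
    n_training: int
    composition: list = field(default_factory=list)  # [(bone_id, n_points), ...]

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, dtype=float).ravel()
        self.modes = np.asarray(self.modes, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).ravel()
        if self.modes.shape != (self.mean_shape.size, self.eigenvalues.size):
            raise ValueError("modes must be (3N, K) matching mean shape and eigenvalues")
        if np.any(self.eigenvalues < 0) or np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be non-negative and non-increasing")

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    def bone_slice(self, bone_id: str) -> slice:
        """Flat-coordinate slice of one bone inside the composed shape vector."""
        offset = 0
        for bid, n in self.composition:
            if bid == bone_id:
                return slice(3 * offset, 3 * (offset + n))
            offset += n
        raise KeyError(bone_id)


@dataclass
class DisplacementMap:
    """Per-point displacement magnitudes normalized to [0, 1].

    For non-identical shape pairs the maximum is exactly 1; for identical
    shapes all values are 0 and ``degenerate`` is set.
    """

    values: np.ndarray
    max_displacement_mm: float
    degenerate: bool = False


def _as_matrix(shapes) -> np.ndarray:
    X = np.asarray(shapes, dtype=float)
    if X.ndim == 3:  # (n, N, 3) point stacks
        X = X.reshape(X.shape[0], -1)
    if X.ndim != 2:
        raise ValueError(f"expected (n_subjects, 3N) data, got shape {X.shape}")
    return X


def build_pdm(shapes, composition=None) -> PDM:
    """PCA point-distribution model from aligned shape vectors.

    ``shapes`` is (n, 3N) (or an (n, N, 3) stack). Modes with eigenvalue
    below ``1e-10`` of the leading one are dropped as numerical rank noise.
    """
    X = _as_matrix(shapes)
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 training shapes, got {n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    keep = eigenvalues > EIGENVALUE_FLOOR * (eigenvalues[0] if eigenvalues.size else 0.0)
    keep &= np.arange(eigenvalues.size) < n - 1
    modes = Vt[keep].T
    eigenvalues = eigenvalues[keep]
    # sign convention: largest-magnitude component of each mode is positive
    flip = modes[np.abs(modes).argmax(axis=0), np.arange(modes.shape[1])] < 0
    modes[:, flip] *= -1.0
    return PDM(
        mean_shape=mean,
        modes=modes,
        eigenvalues=eigenvalues,
        n_training=n,
        composition=list(composition or []),
    )


def project(pdm: PDM, shape) -> np.ndarray:
    """Mode scores ``b = modes^T (x - mean)`` of one shape (or a stack)."""
    x = np.asarray(shape, dtype=float)
    stack = x.ndim == 2 or (x.ndim == 3)
    x = _as_matrix(x) if stack else x.ravel()
    if x.shape[-1] != pdm.mean_shape.size:
        raise ValueError(
            f"dimension mismatch: shape has {x.shape[-1]} coords, model has {pdm.mean_shape.size}"
        )
    return (x - pdm.mean_shape) @ pdm.modes


def training_scores(pdm: PDM, shapes) -> np.ndarray:
    """(n, K) scores of a set of shapes (row per subject)."""
    return project(pdm, _as_matrix(shapes))


def reconstruct(pdm: PDM, scores, n_modes: int | None = None) -> np.ndarray:
    """Shape ``mean + sum_k b_k mode_k`` using the first ``n_modes`` modes."""
    b = np.asarray(scores, dtype=float).ravel()
    if n_modes is None:
        n_modes = b.size
    if n_modes > pdm.n_modes:
        raise ValueError(f"n_modes {n_modes} exceeds available modes {pdm.n_modes}")
    b = b[:n_modes]
    return pdm.mean_shape + pdm.modes[:, :n_modes] @ b


def modes_for_variance(pdm: PDM, fraction: float) -> int:
    """Smallest K' whose leading eigenvalues reach ``fraction`` of total variance."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    cum = np.cumsum(pdm.eigenvalues)
    return int(np.searchsorted(cum / cum[-1], fraction - 1e-12) + 1)


def perturb_mode(pdm: PDM, k: int, c: float) -> np.ndarray:
    """Mean shape displaced ``c`` standard deviations along mode ``k`` (0-based)."""
    if not 0 <= k < pdm.n_modes:
        raise ValueError(f"mode index {k} out of range [0, {pdm.n_modes})")
    return pdm.mean_shape + c * np.sqrt(pdm.eigenvalues[k]) * pdm.modes[:, k]


def displacement_map(shape_a, shape_b) -> DisplacementMap:
    """Per-point displacement between two shapes, normalized by its maximum."""
    a = np.asarray(shape_a, dtype=float).reshape(-1, 3)
    b = np.asarray(shape_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError(f"shape dimensions differ: {a.shape} vs {b.shape}")
    mags = np.linalg.norm(b - a, axis=1)
    peak = float(mags.max())
    if peak == 0.0:
        return DisplacementMap(values=mags, max_displacement_mm=0.0, degenerate=True)
    return DisplacementMap(values=mags / peak, max_displacement_mm=peak)
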