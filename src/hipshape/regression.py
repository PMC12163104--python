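"""Regression of sex, dysplasia and angle values on PCA mode scores.

A fitted model is a *discriminating direction* in mode space: its
coefficient vector, mapped through the modes back to 3D, is the shape-change
path associated with the outcome, and points along the regression line
through the mean shape correspond to chosen probabilities (logistic) or
angle values (linear). Logistic fits carry a small ridge penalty because
~28 predictors on ~75 subjects can separate perfectly; the intercept is
never penalized. Leave-one-out evaluation refits only the regression — the
mode basis stays fixed from the full model unless explicitly rebuilt by the
caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .ssm import PDM, reconstruct

__all__ = [
    "DiscriminatingDirection",
    "LooResult",
    "fit_logistic_direction",
    "fit_linear_direction",
    "shape_along_direction",
    "loo_evaluate",
    "loo_evaluate_rebuilt_basis",
]

DEFAULT_RIDGE = 1e-4


@dataclass
class DiscriminatingDirection:
    """Regression coefficients over mode scores, mappable back to 3D shape."""

    kind: str                 # "logistic" or "linear"
    target_name: str
    beta: np.ndarray          # K-vector, zero-padded beyond n_modes_used
    intercept: float
    n_modes_used: int
    variance_fraction: float = float("nan")

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if self.kind not in ("logistic", "linear"):
            raise ValueError(f"kind must be 'logistic' or 'linear', got {self.kind!r}")
        if self.n_modes_used > self.beta.size:
            raise ValueError("n_modes_used exceeds the coefficient length")

    def predict(self, scores) -> np.ndarray:
        """Linear predictor (linear) or probability (logistic) for score rows."""
        eta = np.atleast_2d(np.asarray(scores, dtype=float)) @ self.beta + self.intercept
        return 1.0 / (1.0 + np.exp(-eta)) if self.kind == "logistic" else eta


@dataclass
class LooResult:
    """Held-out predictions: probabilities + AUC, or residuals + 95% interval."""

    kind: str
    predictions: np.ndarray
    targets: np.ndarray
    auc: float = float("nan")
    residuals: np.ndarray = None
    interval: tuple = None          # central 95% empirical residual interval
    skipped_folds: list = None

    @property
    def interval_width(self) -> float:
        return float(self.interval[1] - self.interval[0])


def _check_scores(scores, n_modes):
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2:
        raise ValueError(f"scores must be (n_subjects, K), got shape {S.shape}")
    if n_modes is None:
        n_modes = S.shape[1]
    if not 1 <= n_modes <= S.shape[1]:
        raise ValueError(f"n_modes {n_modes} outside [1, {S.shape[1]}]")
    return S, int(n_modes)


def fit_logistic_direction(
    scores, labels, n_modes: int | None = None, ridge: float = DEFAULT_RIDGE,
    target_name: str = "label",
) -> DiscriminatingDirection:
    """Ridge-penalized maximum-likelihood logistic fit on the leading modes."""
    S, n_modes = _check_scores(scores, n_modes)
    y = np.asarray(labels).astype(int).ravel()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class; cannot fit a direction")
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=10000, tol=1e-10)
    clf.fit(S[:, :n_modes], y)
    if int(np.max(clf.n_iter_)) >= 10000:
        raise RuntimeError(f"logistic fit did not converge ({int(np.max(clf.n_iter_))} iterations)")
    beta = np.zeros(S.shape[1])
    beta[:n_modes] = clf.coef_[0]
    return DiscriminatingDirection(
        kind="logistic", target_name=target_name, beta=beta,
        intercept=float(clf.intercept_[0]), n_modes_used=n_modes,
    )


def fit_linear_direction(
    scores, values, n_modes: int | None = None, target_name: str = "angle"
) -> DiscriminatingDirection:
    """Ordinary least squares of a value (e.g. an angle) on the leading modes."""
    S, n_modes = _check_scores(scores, n_modes)
    y = np.asarray(values, dtype=float).ravel()
    if y.size < n_modes + 2:
        raise ValueError(f"need at least n_modes+2={n_modes + 2} subjects, got {y.size}")
    X = np.column_stack([np.ones(y.size), S[:, :n_modes]])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < n_modes + 1:
        raise ValueError("rank-deficient design: mode scores are collinear")
    beta = np.zeros(S.shape[1])
    beta[:n_modes] = coef[1:]
    return DiscriminatingDirection(
        kind="linear", target_name=target_name, beta=beta,
        intercept=float(coef[0]), n_modes_used=n_modes,
    )


def shape_along_direction(pdm: PDM, direction: DiscriminatingDirection, target: float) -> np.ndarray:
    """Shape on the regression line through the mean associated with ``target``.

    The line runs through the score-space origin (the mean shape) along the
    coefficient vector; ``target`` is a probability in (0, 1) for logistic
    directions or any finite value for linear ones.
    """
    norm = float(np.linalg.norm(direction.beta))
    if norm == 0.0:
        raise ValueError("direction has zero coefficients; the path is undefined")
    if direction.kind == "logistic":
        if not 0.0 < target < 1.0:
            raise ValueError(f"logistic target must be in (0, 1), got {target}")
        eta = float(np.log(target / (1.0 - target)))
    else:
        eta = float(target)
        if not np.isfinite(eta):
            raise ValueError("linear target must be finite")
    t = (eta - direction.intercept) / norm
    return reconstruct(pdm, t * direction.beta / norm)


def loo_evaluate(
    scores, targets, kind: str, n_modes: int | None = None, ridge: float = DEFAULT_RIDGE,
) -> LooResult:
    """Leave-one-out evaluation: refit the regression per fold (the mode basis
    is fixed), predict the held-out subject; AUC via the rank statistic with
    ties counted half (logistic) or residuals with their central 95%
    empirical interval (linear)."""
    S, n_modes = _check_scores(scores, n_modes)
    n = S.shape[0]
    if n < 3:
        raise ValueError(f"leave-one-out needs at least 3 subjects, got {n}")
    if kind not in ("logistic", "linear"):
        raise ValueError(f"kind must be 'logistic' or 'linear', got {kind!r}")
    y = np.asarray(targets)
    y = y.astype(int if kind == "logistic" else float).ravel()

    preds = np.full(n, np.nan)
    skipped = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            if kind == "logistic":
                d = fit_logistic_direction(S[mask], y[mask], n_modes=n_modes, ridge=ridge)
            else:
                d = fit_linear_direction(S[mask], y[mask], n_modes=n_modes)
        except ValueError:
            skipped.append(i)
            continue
        preds[i] = d.predict(S[i : i + 1])[0]

    ok = ~np.isnan(preds)
    if skipped:
        warnings.warn(f"{len(skipped)} leave-one-out folds skipped (single-class training labels)")
    if kind == "logistic":
        auc = float(roc_auc_score(y[ok], preds[ok]))
        return LooResult(kind=kind, predictions=preds, targets=y, auc=auc, skipped_folds=skipped)
    residuals = y[ok] - preds[ok]
    lo, hi = np.quantile(residuals, [0.025, 0.975])
    return LooResult(
        kind=kind, predictions=preds, targets=y, residuals=residuals,
        interval=(float(lo), float(hi)), skipped_folds=skipped,
    )


def loo_evaluate_rebuilt_basis(
    shapes,
    targets,
    kind: str,
    variance_fraction: float = 0.95,
    ridge: float = DEFAULT_RIDGE,
) -> LooResult:
    """Stricter leave-one-out: the PCA basis itself is rebuilt per fold.

    ``shapes`` is the (n, 3N) aligned-shape matrix. Slower than
    :func:`loo_evaluate` (one PCA per fold) but the held-out subject never
    influences the mode basis.
    """
    from .ssm import build_pdm, modes_for_variance, project

    X = np.asarray(shapes, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError(f"basis-rebuilding leave-one-out needs at least 4 subjects, got {n}")
    y = np.asarray(targets)
    y = y.astype(int if kind == "logistic" else float).ravel()

    preds = np.full(n, np.nan)
    skipped = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        pdm = build_pdm(X[mask])
        n_modes = modes_for_variance(pdm, variance_fraction)
        S_train = project(pdm, X[mask])
        try:
            if kind == "logistic":
                d = fit_logistic_direction(S_train, y[mask], n_modes=n_modes, ridge=ridge)
            else:
                d = fit_linear_direction(S_train, y[mask], n_modes=n_modes)
        except ValueError:
            skipped.append(i)
            continue
        preds[i] = d.predict(project(pdm, X[i])[None, :])[0]

    ok = ~np.isnan(preds)
    if skipped:
        warnings.warn(f"{len(skipped)} basis-rebuilding folds skipped (degenerate training set)")
    if kind == "logistic":
        return LooResult(
            kind=kind, predictions=preds, targets=y,
            auc=float(roc_auc_score(y[ok], preds[ok])), skipped_folds=skipped,
        )
    residuals = y[ok] - preds[ok]
    lo, hi = np.quantile(residuals, [0.025, 0.975])
    return LooResult(
        kind=kind, predictions=preds, targets=y, residuals=residuals,
        interval=(float(lo), float(hi)), skipped_folds=skipped,
    )
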