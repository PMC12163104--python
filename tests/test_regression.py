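import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipshape.regression import (
    fit_linear_direction,
    fit_logistic_direction,
    loo_evaluate,
    shape_along_direction,
)
from hipshape.ssm import build_pdm, project


def pairwise_auc(labels, scores):
    """Brute-force concordant-pair count / (n_pos * n_neg), ties half."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestLogisticDirection:
    def test_separated_clusters_training_auc_one(self, rng):
        b = np.concatenate([rng.normal(-4, 1, 20), rng.normal(4, 1, 20)])[:, None]
        y = np.repeat([0, 1], 20)
        d = fit_logistic_direction(np.column_stack([b, rng.normal(size=(40, 2))]), y, n_modes=1)
        assert d.beta[0] > 0
        assert np.all(d.beta[1:] == 0)
        probs = d.predict(np.column_stack([b, np.zeros((40, 2))]))
        assert pairwise_auc(y, probs) == 1.0

    def test_permuted_labels_give_chance_auc(self):
        # permutation null: mean LOO AUC over 20 shuffles stays near 0.5
        rng = np.random.default_rng(7)
        S = rng.normal(size=(40, 4))
        y = np.repeat([0, 1], 20)
        aucs = []
        for _ in range(20):
            yp = rng.permutation(y)
            aucs.append(loo_evaluate(S, yp, "logistic", n_modes=4).auc)
        assert 0.3 < np.mean(aucs) < 0.7

    def test_symmetric_gaussian_classes_boundary_through_midpoint(self):
        # two equal-covariance 2-mode clusters: p=0.5 at the midpoint of means
        rng = np.random.default_rng(4)
        mu = np.array([2.0, 1.0])
        S = np.vstack([rng.normal(-mu, 1.0, (200, 2)), rng.normal(mu, 1.0, (200, 2))])
        y = np.repeat([0, 1], 200)
        d = fit_logistic_direction(S, y, ridge=1e-2)
        midpoint_prob = d.predict(np.zeros((1, 2)))[0]
        assert midpoint_prob == pytest.approx(0.5, abs=0.05)
        # decision boundary is orthogonal to beta by construction of the model
        w = d.beta / np.linalg.norm(d.beta)
        assert w @ mu / np.linalg.norm(mu) == pytest.approx(1.0, abs=0.05)

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError):
            fit_logistic_direction(rng.normal(size=(10, 2)), np.zeros(10))


class TestLinearDirection:
    def test_constant_values(self, rng):
        d = fit_linear_direction(rng.normal(size=(12, 3)), np.full(12, 7.5))
        assert np.abs(d.beta).max() < 1e-9
        assert d.intercept == pytest.approx(7.5, abs=1e-9)

    def test_exact_linear_relation(self, rng):
        S = rng.normal(size=(15, 4))
        y = 2.0 * S[:, 0] + 5.0
        d = fit_linear_direction(S, y, n_modes=2)
        assert d.beta[0] == pytest.approx(2.0, abs=1e-9)
        assert d.beta[1] == pytest.approx(0.0, abs=1e-9)
        assert d.intercept == pytest.approx(5.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        S = rng.normal(size=(30, 5))
        y = S @ [1.5, -2.0, 0.3, 0.0, 0.7] + 20.4 + rng.normal(0, 0.5, 30)
        d = fit_linear_direction(S, y)
        X = np.column_stack([np.ones(30), S])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        assert d.intercept == pytest.approx(coef[0], abs=1e-8)
        assert np.allclose(d.beta, coef[1:], atol=1e-8)

    def test_rank_deficiency_raises(self, rng):
        S = np.repeat(rng.normal(size=(10, 1)), 3, axis=1)  # collinear modes
        with pytest.raises(ValueError):
            fit_linear_direction(S, rng.normal(size=10), n_modes=3)


class TestShapeAlongDirection:
    @pytest.fixture(scope="class")
    def pdm(self):
        rng = np.random.default_rng(6)
        return build_pdm(rng.normal(size=(15, 30)))

    def test_half_probability_with_zero_intercept_is_mean(self, pdm):
        from hipshape.regression import DiscriminatingDirection

        d = DiscriminatingDirection("logistic", "sex", np.ones(pdm.n_modes), 0.0, pdm.n_modes)
        assert np.allclose(shape_along_direction(pdm, d, 0.5), pdm.mean_shape, atol=1e-10)

    def test_linear_target_at_intercept_is_mean(self, pdm):
        from hipshape.regression import DiscriminatingDirection

        d = DiscriminatingDirection("linear", "ce", np.ones(pdm.n_modes), 20.4, pdm.n_modes)
        assert np.allclose(shape_along_direction(pdm, d, 20.4), pdm.mean_shape, atol=1e-10)

    def test_logit_antisymmetry(self, pdm):
        from hipshape.regression import DiscriminatingDirection

        rng = np.random.default_rng(1)
        d = DiscriminatingDirection("logistic", "sex", rng.normal(size=pdm.n_modes), 0.0, pdm.n_modes)
        lo = shape_along_direction(pdm, d, 0.1)
        hi = shape_along_direction(pdm, d, 0.9)
        assert np.allclose(lo + hi, 2 * pdm.mean_shape, atol=1e-8)

    def test_prediction_consistency(self, pdm):
        # projecting the returned shape and applying the model recovers the target
        rng = np.random.default_rng(2)
        from hipshape.regression import DiscriminatingDirection

        d = DiscriminatingDirection("logistic", "sex", rng.normal(size=pdm.n_modes), -0.7, pdm.n_modes)
        for target in (0.1, 0.5, 0.9):
            x = shape_along_direction(pdm, d, target)
            assert d.predict(project(pdm, x)[None, :])[0] == pytest.approx(target, abs=1e-6)
        dl = DiscriminatingDirection("linear", "ce", rng.normal(size=pdm.n_modes), 13.5, pdm.n_modes)
        for target in (5.0, 13.5, 40.0):
            x = shape_along_direction(pdm, dl, target)
            assert dl.predict(project(pdm, x)[None, :])[0] == pytest.approx(target, abs=1e-6)

    def test_zero_direction_raises(self, pdm):
        from hipshape.regression import DiscriminatingDirection

        d = DiscriminatingDirection("linear", "ce", np.zeros(pdm.n_modes), 0.0, pdm.n_modes)
        with pytest.raises(ValueError):
            shape_along_direction(pdm, d, 1.0)


class TestLooEvaluate:
    def test_perfectly_separable_auc_one(self, rng):
        S = np.concatenate([rng.normal(-6, 0.5, 15), rng.normal(6, 0.5, 15)])[:, None]
        y = np.repeat([0, 1], 15)
        assert loo_evaluate(S, y, "logistic").auc == 1.0

    def test_anti_predictive_scores(self, rng):
        # held-out probabilities scored against flipped labels invert the AUC
        from sklearn.metrics import roc_auc_score

        S = np.concatenate([rng.normal(-6, 0.5, 15), rng.normal(6, 0.5, 15)])[:, None]
        y = np.repeat([0, 1], 15)
        res = loo_evaluate(S, y, "logistic")
        assert roc_auc_score(1 - y, res.predictions) <= 0.5
        assert roc_auc_score(1 - y, res.predictions) == pytest.approx(1 - res.auc, abs=1e-12)

    def test_auc_equals_pairwise_count_oracle(self):
        rng = np.random.default_rng(9)
        S = rng.normal(size=(10, 2))
        y = (rng.uniform(size=10) < 0.5).astype(int)
        while len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
            y = (rng.uniform(size=10) < 0.5).astype(int)
        res = loo_evaluate(S, y, "logistic")
        assert res.auc == pytest.approx(pairwise_auc(y, res.predictions), abs=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_auc_invariant_to_monotone_transform(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        y = np.concatenate([np.zeros(8), np.ones(8)]).astype(int)
        p = rng.uniform(size=16)
        a1 = roc_auc_score(y, p)
        a2 = roc_auc_score(y, np.exp(3 * p) / (1 + np.exp(3 * p)))
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_linear_residual_interval(self):
        rng = np.random.default_rng(3)
        S = rng.normal(size=(60, 3))
        y = S @ [2.0, -1.0, 0.5] + 10 + rng.normal(0, 1.0, 60)
        res = loo_evaluate(S, y, "linear")
        assert res.interval[0] < 0 < res.interval[1]
        assert res.interval_width < 6.0  # ~2 * 1.96 * sigma with LOO inflation
        lo, hi = np.quantile(res.residuals, [0.025, 0.975])
        assert res.interval == (pytest.approx(lo), pytest.approx(hi))

    def test_minimum_cohort_size(self, rng):
        with pytest.raises(ValueError):
            loo_evaluate(rng.normal(size=(2, 2)), [0, 1], "logistic")

    def test_rebuilt_basis_variant_agrees_on_strong_signal(self):
        # refitting the PCA basis per fold still recovers a strong linear
        # relation carried by a high-variance shape direction
        from hipshape.regression import loo_evaluate_rebuilt_basis

        rng = np.random.default_rng(13)
        direction = rng.normal(size=30)
        direction /= np.linalg.norm(direction)
        t = rng.normal(0, 5, 40)
        X = np.outer(t, direction) * 10 + rng.normal(0, 0.5, (40, 30))
        y = 3.0 * t + 7.0
        from hipshape.ssm import training_scores

        from hipshape.ssm import modes_for_variance

        pdm = build_pdm(X)
        res = loo_evaluate_rebuilt_basis(X, y, "linear", variance_fraction=0.95)
        fixed = loo_evaluate(
            training_scores(pdm, X), y, "linear", n_modes=modes_for_variance(pdm, 0.95)
        )
        assert res.interval_width < 0.25 * np.ptp(y)
        assert res.interval_width == pytest.approx(fixed.interval_width, rel=0.5)
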