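"""Hierarchical structural component model: GLM oracle equivalence,
identification constraints, descent of the penalized objective, ridge
limits, permutation inference and penalty selection."""

import numpy as np
import pytest
import statsmodels.api as sm

from nutrigen.hiscom import HiscomModel, fit_hiscom, select_lambda1


def binary_matrix(rng, n, p, prob=0.4):
    return rng.binomial(1, prob, size=(n, p)).astype(float)


def logistic_draw(rng, eta):
    return (rng.uniform(size=len(eta)) < 1 / (1 + np.exp(-eta))).astype(int)


@pytest.fixture(scope="module")
def toy_fit():
    rng = np.random.default_rng(7)
    n = 1200
    g = binary_matrix(rng, n, 6)
    w_true = np.array([0.2, 0.6, 1.0, 0.4, 1.0, 1.0])
    y = logistic_draw(rng, -1.0 + 0.8 * (g @ w_true))
    groups = ["a", "a", "a", "b", "b", "c"]
    return g, y, groups, HiscomModel(y, g, groups=groups).fit(lambda1=0.5)


class TestGlmOracle:
    def test_single_item_group_matches_logistic_regression(self):
        """With one item in one group the model collapses to univariate
        logistic regression: beta*w equals the GLM slope to 1e-6 and the
        standardized-metric weight is +/-1."""
        rng = np.random.default_rng(3)
        n = 900
        g = binary_matrix(rng, n, 1)
        y = logistic_draw(rng, -0.4 + 1.1 * g[:, 0])
        res = HiscomModel(y, g, groups=["veg"]).fit(lambda1=0.0)
        glm = sm.GLM(y, sm.add_constant(g),
                     family=sm.families.Binomial()).fit()
        assert res.beta[0] * res.w[0] == pytest.approx(glm.params[1], abs=1e-6)
        assert res.beta0 == pytest.approx(glm.params[0], abs=1e-6)
        assert abs(res.w_std[0]) == pytest.approx(1.0, abs=1e-10)


class TestIdentification:
    def test_components_have_unit_variance(self, toy_fit):
        g, _, groups, res = toy_fit
        for k, ci in enumerate(res.model.group_cols):
            assert (g[:, ci] @ res.w[ci]).std() == pytest.approx(1.0, abs=1e-8)

    def test_within_group_weight_sums_nonnegative(self, toy_fit):
        _, _, _, res = toy_fit
        for ci in res.model.group_cols:
            assert res.w[ci].sum() >= 0

    def test_sign_flip_leaves_score_and_deviance_unchanged(self, toy_fit):
        g, y, _, res = toy_fit
        score = res.score(g)
        w2, b2 = res.w.copy(), res.beta.copy()
        ci = res.model.group_cols[0]
        w2[ci] = -w2[ci]
        b2[0] = -b2[0]
        flipped = np.zeros(len(g))
        for k, cj in enumerate(res.model.group_cols):
            flipped += (g[:, cj] @ w2[cj]) * b2[k]
        np.testing.assert_allclose(flipped, score, atol=1e-12)


class TestObjective:
    def test_penalized_objective_monotone_nonincreasing(self, toy_fit):
        _, _, _, res = toy_fit
        assert np.all(np.diff(res.objective_trace) <= 1e-8)
        assert res.converged

    def test_large_ridge_pulls_weights_toward_equal_magnitude(self):
        """Ridge limit on a two-item toy with positively correlated items:
        under the unit-component-variance constraint the penalty favours the
        leading eigenvector of the within-group Gram matrix, i.e. equal
        weight magnitudes, even though the planted effects are unequal."""
        rng = np.random.default_rng(11)
        n = 2000
        latent = rng.uniform(size=n)
        g = np.column_stack([
            rng.uniform(size=n) < 0.3 + 0.4 * latent,
            rng.uniform(size=n) < 0.2 + 0.5 * latent,
        ]).astype(float)
        y = logistic_draw(rng, -0.5 + 1.5 * g[:, 0] + 0.1 * g[:, 1])
        gaps = []
        for lam in (0.0, 100.0, 1e4):
            res = HiscomModel(y, g, groups=["a", "a"]).fit(lambda1=lam)
            gaps.append(abs(abs(res.w_std[0]) - abs(res.w_std[1])))
        assert gaps[2] < gaps[1] < gaps[0]
        assert gaps[2] < 0.05


class TestScore:
    def test_zero_indicators_score_zero(self, toy_fit):
        g, _, _, res = toy_fit
        np.testing.assert_allclose(res.score(np.zeros((5, g.shape[1]))), 0.0)

    def test_doubling_a_group_coefficient_doubles_its_contribution(self, toy_fit):
        g, _, _, res = toy_fit
        ci = res.model.group_cols[1]
        contrib = (g[:, ci] @ res.w[ci]) * res.beta[1]
        res2 = res.__class__(**{**res.__dict__})
        res2.beta = res.beta.copy()
        res2.beta[1] *= 2
        np.testing.assert_allclose(res2.score(g) - res.score(g), contrib,
                                   atol=1e-10)

    def test_matches_brute_force_double_loop(self, toy_fit):
        g, _, groups, res = toy_fit
        expected = np.zeros(len(g))
        for i in range(len(g)):
            for k, lab in enumerate(res.model.group_labels):
                inner = sum(g[i, j] * res.w[j]
                            for j in range(g.shape[1]) if groups[j] == lab)
                expected[i] += inner * res.beta[k]
        np.testing.assert_allclose(res.score(g), expected, atol=1e-10)


class TestErrors:
    def test_constant_phenotype_rejected(self, rng):
        g = binary_matrix(rng, 50, 2)
        with pytest.raises(ValueError, match="constant"):
            HiscomModel(np.ones(50), g, groups=["a", "a"])

    def test_non_binary_indicators_rejected(self, rng):
        g = rng.normal(size=(50, 2))
        y = rng.binomial(1, 0.5, 50)
        with pytest.raises(ValueError, match="binary"):
            HiscomModel(y, g, groups=["a", "a"])

    def test_constant_column_without_penalty_is_singular(self, rng):
        g = binary_matrix(rng, 80, 2)
        g[:, 1] = 0.0
        y = rng.binomial(1, 0.5, 80)
        with pytest.raises(np.linalg.LinAlgError):
            HiscomModel(y, g, groups=["a", "a"]).fit(lambda1=0.0)


class TestPermutation:
    def test_strong_effect_reaches_minimum_p(self):
        rng = np.random.default_rng(19)
        n = 600
        g = binary_matrix(rng, n, 4)
        y = logistic_draw(rng, -1.0 + 2.5 * (g[:, 0] + g[:, 1]))
        res = HiscomModel(y, g, groups=["a", "a", "b", "b"]).fit(lambda1=1.0)
        res.permutation_test(B=199, seed=0)
        assert res.perm_p_beta[0] == pytest.approx(1 / 200)

    def test_same_seed_identical_pvalues(self, rng):
        g = binary_matrix(rng, 150, 4)
        y = rng.binomial(1, 0.4, 150)
        r1 = fit_hiscom(g, y, lambda1=1.0, groups=["a", "a", "b", "b"])
        r1.permutation_test(B=29, seed=5)
        r2 = fit_hiscom(g, y, lambda1=1.0, groups=["a", "a", "b", "b"])
        r2.permutation_test(B=29, seed=5)
        np.testing.assert_array_equal(r1.perm_p_beta, r2.perm_p_beta)
        np.testing.assert_array_equal(r1.perm_p_w, r2.perm_p_w)

    def test_invalid_b_rejected(self, toy_fit):
        _, _, _, res = toy_fit
        with pytest.raises(ValueError):
            res.permutation_test(B=0)


class TestLambdaSelection:
    def test_single_grid_value_returned(self, rng):
        g = binary_matrix(rng, 200, 4)
        y = rng.binomial(1, 0.4, 200)
        assert select_lambda1(g, y, [3.0], groups=["a", "a", "b", "b"]) == 3.0

    def test_strong_signal_selects_below_grid_maximum(self):
        rng = np.random.default_rng(23)
        n = 1000
        g = binary_matrix(rng, n, 4)
        y = logistic_draw(rng, -1.0 + 2.0 * g[:, 0] + 1.5 * g[:, 2])
        grid = [0.1, 1.0, 1e6]
        lam = select_lambda1(g, y, grid, groups=["a", "a", "b", "b"], seed=1)
        assert lam < max(grid)

    def test_deterministic_under_seed(self, rng):
        g = binary_matrix(rng, 300, 4)
        y = rng.binomial(1, 0.35, 300)
        args = (g, y, [0.1, 1.0, 10.0])
        kw = dict(groups=["a", "a", "b", "b"], seed=9)
        assert select_lambda1(*args, **kw) == select_lambda1(*args, **kw)

    def test_empty_grid_rejected(self, rng):
        g = binary_matrix(rng, 100, 2)
        y = rng.binomial(1, 0.5, 100)
        with pytest.raises(ValueError):
            select_lambda1(g, y, [], groups=["a", "a"])
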