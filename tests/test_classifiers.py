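import numpy as np
import pytest
from scipy.stats import norm

from pinhub.classifiers import (
    CostMatrix,
    class_posteriors,
    decide_map,
    fit_gaussian_bayes,
    fit_knn,
    fit_mdm_bayes,
    fit_predict_knn,
    min_risk_decide,
)


def two_gaussian_data(rng, n=2000):
    X = np.concatenate([rng.normal(0, 1, n), rng.normal(10, 1, n)])[:, None]
    y = np.array([1] * n + [2] * n)
    return X, y


class TestCostMatrix:
    def test_default_matches_packaged_file(self):
        np.testing.assert_array_equal(
            CostMatrix.default().values, CostMatrix.from_tsv().values
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            CostMatrix(np.eye(4))  # nonzero diagonal
        with pytest.raises(ValueError):
            CostMatrix(-np.ones((4, 4)) + np.eye(4))


class TestGaussianBayes:
    def test_decision_boundary_equal_variance(self, rng):
        """Two 1-D classes N(0,1) / N(10,1), equal priors: boundary at 5."""
        X, y = two_gaussian_data(rng)
        model = fit_gaussian_bayes(X, y)
        grid = np.linspace(0, 10, 2001)[:, None]
        pred = decide_map(class_posteriors(model, grid))
        boundary = grid[np.argmax(pred == 2), 0]
        assert boundary == pytest.approx(5.0, abs=0.2)

    def test_posteriors_sum_to_one(self, rng):
        X, y = two_gaussian_data(rng, n=100)
        model = fit_gaussian_bayes(X, y)
        post = class_posteriors(model, rng.normal(5, 3, size=(50, 1)))
        np.testing.assert_allclose(post.sum(axis=1), 1.0)

    def test_single_sample_per_class_survives_with_ridge(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([1, 2])
        with pytest.warns(UserWarning):
            model = fit_gaussian_bayes(X, y)
        np.testing.assert_allclose(model.priors, [0.5, 0.5])

    def test_extreme_point_no_nan(self, rng):
        X, y = two_gaussian_data(rng, n=100)
        model = fit_gaussian_bayes(X, y)
        post = class_posteriors(model, np.array([1e6]))
        assert not np.any(np.isnan(post))
        assert decide_map(post) in (1, 2)

    def test_grid_oracle_agreement(self, rng):
        """MAP decisions match a brute-force prior x density comparison."""
        X = np.concatenate([rng.normal(0, 1, 300), rng.normal(3, 2, 900)])[:, None]
        y = np.array([1] * 300 + [2] * 900)
        model = fit_gaussian_bayes(X, y)
        grid = np.linspace(-5, 10, 1000)
        pred = decide_map(class_posteriors(model, grid[:, None]))
        c = 0  # classes are (1, 2) in model order
        j1 = model.priors[0] * norm.pdf(grid, model.means[0, 0],
                                        np.sqrt(model.covariances[0, 0, 0]))
        j2 = model.priors[1] * norm.pdf(grid, model.means[1, 0],
                                        np.sqrt(model.covariances[1, 0, 0]))
        oracle = np.where(j1 >= j2, 1, 2)
        assert (pred == oracle).mean() >= 0.999


class TestDecisionRules:
    def test_map_examples(self):
        assert decide_map(np.array([0.7, 0.1, 0.1, 0.1])) == 1
        assert decide_map(np.array([0.25, 0.25, 0.25, 0.25])) == 1  # tie-break
        assert decide_map(np.array([0.1, 0.2, 0.3, 0.4])) == 4

    def test_zero_one_loss_equals_map(self, rng):
        post = rng.dirichlet(np.ones(4), size=10_000)
        zero_one = CostMatrix.zero_one()
        np.testing.assert_array_equal(
            min_risk_decide(post, zero_one), decide_map(post)
        )

    def test_hub_cost_matrix_examples(self):
        L = CostMatrix.default()
        post = np.array([0.6, 0.2, 0.1, 0.1])
        risks = post @ L.values
        np.testing.assert_allclose(risks, [0.20, 0.24, 0.18, 0.18])
        assert min_risk_decide(post, L) == 3  # tie with class 4 -> lower index
        uniform = np.full(4, 0.25)
        np.testing.assert_allclose(uniform @ L.values, [0.475, 0.475, 0.15, 0.15])
        assert min_risk_decide(uniform, L) == 3

    def test_hub_cost_never_loses_hubs_to_nonhubs(self, rng):
        """Relative to MAP, the hub-favouring costs can only move decisions
        toward classes 3-4, never away from them."""
        post = rng.dirichlet(np.ones(4), size=10_000)
        map_pred = decide_map(post)
        risk_pred = min_risk_decide(post, CostMatrix.default())
        assert int(np.isin(risk_pred, (3, 4)).sum()) >= int(np.isin(map_pred, (3, 4)).sum())
        # stronger, pointwise: a MAP hub decision stays a hub decision
        hubs = np.isin(map_pred, (3, 4))
        assert np.all(np.isin(risk_pred[hubs], (3, 4)))


class TestMixtureBayes:
    def test_single_component_equals_gaussian(self, rng):
        X = np.vstack([rng.normal(0, 1, (150, 2)), rng.normal(3, 1.5, (250, 2))])
        y = np.array([1] * 150 + [2] * 250)
        gauss = fit_gaussian_bayes(X, y)
        mdm = fit_mdm_bayes(X, y, max_components=1, seed=0)
        grid = rng.normal(1.5, 2, size=(500, 2))
        np.testing.assert_array_equal(
            decide_map(class_posteriors(mdm, grid)),
            decide_map(class_posteriors(gauss, grid)),
        )

    def test_bimodal_component_recovery(self, rng):
        """A class drawn from N(0,1) + N(10,1) recovers both component means."""
        X = np.concatenate([
            rng.normal(0, 1, 500), rng.normal(10, 1, 500),  # class 1: bimodal
            rng.normal(5, 1, 300),                          # class 2
        ])[:, None]
        y = np.array([1] * 1000 + [2] * 300)
        model = fit_mdm_bayes(X, y, max_components=3, seed=1)
        c1 = int(np.flatnonzero(model.classes == 1)[0])
        assert model.n_components[c1] >= 2
        means = np.sort(model.mixtures[c1].means_.ravel())
        assert abs(means[0] - 0) < 0.5
        assert abs(means[-1] - 10) < 0.5

    def test_em_loglik_trace_nondecreasing(self, rng):
        X = np.concatenate([rng.normal(0, 1, 200), rng.normal(4, 1, 200)])[:, None]
        y = np.array([1] * 200 + [2] * 200)
        model = fit_mdm_bayes(X, y, max_components=2, seed=3)
        for trace in model.loglik_traces:
            assert len(trace) >= 1
            diffs = np.diff(trace)
            assert np.all(diffs >= -1e-6 * np.abs(trace[:-1]))

    def test_posteriors_sum_to_one(self, rng):
        X = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(3, 1, (100, 2))])
        y = np.array([1] * 100 + [2] * 100)
        model = fit_mdm_bayes(X, y, max_components=2, seed=0)
        post = class_posteriors(model, rng.normal(1, 2, size=(50, 2)))
        np.testing.assert_allclose(post.sum(axis=1), 1.0)


class TestKnn:
    def test_own_point_k1(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.integers(1, 5, 20)
        pred = fit_predict_knn(X, y, X, k=1)
        np.testing.assert_array_equal(pred, y)

    def test_majority_and_tie_rules(self):
        X = np.array([[0.0], [1.0], [2.0]])
        # k=3 neighbours labeled 2,2,4 -> majority 2
        assert fit_predict_knn(X, np.array([2, 2, 4]), np.array([[1.0]]), k=3)[0] == 2
        # k=2 neighbours labeled 3,4 -> vote tie -> lower class index
        assert fit_predict_knn(X[:2], np.array([3, 4]), np.array([[0.5]]), k=2)[0] == 3

    def test_distance_tie_prefers_lower_row_index(self):
        X = np.array([[1.0], [-1.0]])  # both at distance 1 from query 0
        y = np.array([4, 2])
        assert fit_predict_knn(X, y, np.array([[0.0]]), k=1)[0] == 4

    def test_vote_fraction_posteriors(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0]])
        y = np.array([1, 1, 3, 4])
        model = fit_knn(X, y, k=3)
        post = class_posteriors(model, np.array([0.05]))
        np.testing.assert_allclose(post, [2 / 3, 0, 1 / 3, 0])

    def test_k_validation(self):
        with pytest.raises(ValueError):
            fit_knn(np.zeros((3, 1)), np.array([1, 2, 3]), k=4)
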