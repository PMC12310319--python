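"""EBIC, nodewise penalised paths, and the Ising network estimator."""

import warnings

import numpy as np
import pytest
from scipy.special import logit

from symptomnet.data import BinarySymptomMatrix
from symptomnet.ising import (
    IsingModel,
    ebic,
    fit_ising,
    global_strength,
    nodewise_lasso_path,
)
from symptomnet.simulate import sample_ising_gibbs, sample_two_wave


class TestEbic:
    def test_zero_active_is_minus_two_loglik(self):
        assert ebic(-57.3, 0, 500, 9, 0.5) == pytest.approx(114.6)

    def test_plug_in_arithmetic(self):
        # -2(-100) + 2 ln 1000 + 2*0.5*2*ln 9
        expected = 200 + 2 * np.log(1000) + 2 * np.log(9)
        assert ebic(-100, 2, 1000, 9, 0.5) == pytest.approx(expected)
        assert ebic(-100, 2, 1000, 9, 0.5) == pytest.approx(218.21, abs=0.005)

    def test_gamma_zero_reduces_to_bic(self):
        ll, k, n = -80.0, 3, 400
        assert ebic(ll, k, n, 9, 0.0) == pytest.approx(-2 * ll + k * np.log(n))


def _sim_logistic(n, beta, b0=0.0, seed=0, density=0.5):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, len(beta))) < density).astype(float)
    eta = b0 + X @ np.asarray(beta)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


class TestNodewisePath:
    def test_null_model_at_lambda_max(self):
        X, y = _sim_logistic(1000, [0.8, 0, 0], seed=1)
        fit = nodewise_lasso_path(y, X)
        assert np.all(fit.coefs[0] == 0)
        assert fit.intercepts[0] == pytest.approx(logit(y.mean()), abs=1e-6)
        assert np.all(np.diff(fit.lambdas) < 0)

    def test_strong_predictor_recovered_at_small_lambda(self):
        X, y = _sim_logistic(5000, [2.0, 0, 0, 0], b0=-0.5, seed=2)
        fit = nodewise_lasso_path(y, X)
        assert fit.coefs[-1, 0] == pytest.approx(2.0, abs=0.25)
        # and agrees with the unpenalised sklearn fit at tiny penalty
        from sklearn.linear_model import LogisticRegression

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = LogisticRegression(C=1e6, tol=1e-10, max_iter=2000).fit(X, y)
        # residual shrinkage at lambda_max/100 keeps a small gap to the MLE
        assert fit.coefs[-1, 0] == pytest.approx(ref.coef_[0, 0], abs=0.05)

    def test_kkt_conditions_along_path(self):
        X, y = _sim_logistic(2000, [1.5, -0.8, 0, 0, 0], seed=3, density=0.4)
        fit = nodewise_lasso_path(y, X)
        n = len(y)
        for idx in range(0, 100, 7):
            beta, b0 = fit.coefs[idx], fit.intercepts[idx]
            mu = 1 / (1 + np.exp(-(b0 + X @ beta)))
            score = X.T @ (mu - y) / n
            lam = fit.lambdas[idx]
            for j, bj in enumerate(beta):
                if bj == 0:
                    assert abs(score[j]) <= lam + 1e-4
                else:
                    assert abs(score[j]) == pytest.approx(lam, abs=1e-4)
            assert abs((mu - y).sum() / n) < 1e-6  # intercept stationarity

    def test_coefficients_continuous_in_lambda(self):
        X, y = _sim_logistic(2000, [1.0, -1.0, 0.5, 0], seed=4)
        fit = nodewise_lasso_path(y, X, n_lambda=100)
        steps = np.abs(np.diff(fit.coefs, axis=0)).max(axis=1)
        assert steps.max() < 0.15

    def test_constant_outcome_rejected(self):
        X = np.zeros((50, 3))
        with pytest.raises(ValueError, match="constant"):
            nodewise_lasso_path(np.ones(50), X)

    def test_standardize_returns_original_scale(self):
        X, y = _sim_logistic(3000, [1.2, 0, -0.7], seed=5, density=0.3)
        raw = nodewise_lasso_path(y, X, standardize=False)
        std = nodewise_lasso_path(y, X, standardize=True)
        # at the unpenalised end both must approach the same MLE
        np.testing.assert_allclose(raw.coefs[-1], std.coefs[-1], atol=0.05)


class TestFitIsing:
    def test_network_symmetric_zero_diagonal(self, preset, two_wave_medium):
        net = fit_ising(two_wave_medium[0])
        np.testing.assert_array_equal(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)

    def test_row_order_invariance(self, two_wave_medium, rng):
        m = two_wave_medium[0]
        shuffled = BinarySymptomMatrix(
            m.values[rng.permutation(m.n)], m.item_labels, m.wave_tag
        )
        np.testing.assert_allclose(
            fit_ising(m).weights, fit_ising(shuffled).weights, atol=1e-9
        )

    def test_duplicated_rows_same_active_set(self, two_wave_medium):
        m = two_wave_medium[0]
        doubled = BinarySymptomMatrix(
            np.vstack([m.values, m.values]), m.item_labels, m.wave_tag
        )
        w1 = fit_ising(m).weights
        w2 = fit_ising(doubled).weights
        # likelihood scales by 2 while log n grows slowly, so the doubled
        # data can only admit extra edges, never lose one
        assert set(map(tuple, np.argwhere(w1 != 0))) <= set(
            map(tuple, np.argwhere(w2 != 0))
        )
        # doubling n halves the selected relative penalty, so shared edges
        # agree up to the difference in shrinkage, not exactly
        shared = (w1 != 0) & (w2 != 0)
        np.testing.assert_allclose(w1[shared], w2[shared], atol=0.2)

    def test_and_rule_sparser_than_or_rule(self, two_wave_medium):
        m = two_wave_medium[0]
        net_and = fit_ising(m, rule="and")
        net_or = fit_ising(m, rule="or")
        and_edges = set(map(tuple, np.argwhere(net_and.weights != 0)))
        or_edges = set(map(tuple, np.argwhere(net_or.weights != 0)))
        assert and_edges <= or_edges

    def test_independent_columns_few_false_edges(self):
        rng = np.random.default_rng(17)
        vals = (rng.random((5000, 10)) < 0.4).astype(int)
        m = BinarySymptomMatrix(vals, tuple(f"V{i}" for i in range(10)))
        net = fit_ising(m)
        assert np.count_nonzero(net.weights[np.triu_indices(10, 1)]) <= 2

    def test_recovery_improves_with_n(self, preset):
        # active-set recovery is monotone over n in {500, 2000, 8000}
        iu = np.triu_indices(10, 1)
        true_nz = preset.wave1.weights[iu] != 0
        sens = []
        for n, seed in [(500, 31), (2000, 31), (8000, 31)]:
            w1, _ = sample_two_wave(preset, n, seed=seed, burn_in=300)
            est = fit_ising(w1).weights[iu] != 0
            sens.append((true_nz & est).sum() / true_nz.sum())
        assert sens[0] <= sens[1] <= sens[2]
        assert sens[2] >= 0.9

    def test_constant_column_isolated_with_warning(self):
        rng = np.random.default_rng(5)
        vals = (rng.random((300, 4)) < 0.5).astype(int)
        vals[:, 2] = 1
        m = BinarySymptomMatrix(vals, ("a", "b", "c", "d"))
        with pytest.warns(RuntimeWarning, match="constant"):
            net = fit_ising(m)
        assert np.all(net.weights[2] == 0)

    def test_n_not_greater_than_p_rejected(self):
        with pytest.raises(ValueError, match="n > p"):
            IsingModel(np.zeros((5, 10), dtype=int))

    def test_results_summary_and_edge_frame(self, two_wave_medium):
        res = IsingModel(two_wave_medium[0]).fit()
        ef = res.edge_frame()
        assert len(ef) == 45
        assert "nonzero edges" in res.summary()
        assert res.global_strength == pytest.approx(
            np.abs(res.network.edge_vector()).sum()
        )


class TestGlobalStrength:
    def _net(self, edges):
        from symptomnet.data import IsingNetwork

        W = np.zeros((4, 4))
        for i, j, w in edges:
            W[i, j] = W[j, i] = w
        return IsingNetwork(W, np.zeros(4), ("a", "b", "c", "d"))

    def test_zero_network(self):
        assert global_strength(self._net([])) == 0.0

    def test_single_edge(self):
        assert global_strength(self._net([(0, 1, 1.48)])) == pytest.approx(1.48)

    def test_hand_sum_with_mixed_signs(self):
        net = self._net([(0, 1, 0.5), (1, 2, -0.25), (2, 3, 1.0)])
        assert global_strength(net) == pytest.approx(1.75)
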