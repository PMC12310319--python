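"""Exact Ising pmf, Gibbs sampler, two-wave generator, calibrated preset."""

import numpy as np
import pytest
from scipy.special import expit

from symptomnet.simulate import (
    DRIVER_NODE,
    IsingParameters,
    TwoWaveParameters,
    ising_marginals_exact,
    ising_pmf_exact,
    cohort_preset,
    sample_ising_gibbs,
    sample_two_wave,
)


def _ising(p, edges=(), tau=None):
    W = np.zeros((p, p))
    for i, j, w in edges:
        W[i, j] = W[j, i] = w
    return IsingParameters(W, np.zeros(p) if tau is None else np.asarray(tau, float))


class TestExactPmf:
    def test_independence_gives_uniform(self):
        states, probs = ising_pmf_exact(_ising(2))
        np.testing.assert_allclose(probs, 0.25)

    def test_single_edge_log3(self):
        # tau = 0, W12 = ln 3: Z = 1+1+1+3, so P(1,1) = 3/6
        states, probs = ising_pmf_exact(_ising(2, [(0, 1, np.log(3))]))
        p11 = probs[np.all(states == 1, axis=1)][0]
        assert p11 == pytest.approx(0.5)

    def test_probabilities_sum_to_one(self, rng):
        W = rng.normal(size=(5, 5))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        _, probs = ising_pmf_exact(IsingParameters(W, rng.normal(size=5)))
        assert probs.sum() == pytest.approx(1.0)

    def test_enumeration_bound(self):
        with pytest.raises(ValueError, match="p <= 14"):
            ising_pmf_exact(_ising(15))


class TestGibbs:
    def test_null_model_means_half(self):
        m = sample_ising_gibbs(_ising(4), 10_000, burn_in=50, seed=0)
        se = 3 * np.sqrt(0.25 / 10_000)
        assert np.all(np.abs(m.values.mean(0) - 0.5) < se)

    def test_same_seed_identical(self):
        a = sample_ising_gibbs(_ising(3, [(0, 1, 0.8)]), 500, seed=5)
        b = sample_ising_gibbs(_ising(3, [(0, 1, 0.8)]), 500, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_marginals_match_enumeration(self):
        # 1-way margins of the sampler agree with the exact pmf
        params = _ising(4, [(0, 1, 1.0), (2, 3, -0.7)], tau=[0.3, -0.2, 0.1, 0.0])
        exact = ising_marginals_exact(params)
        m = sample_ising_gibbs(params, 20_000, burn_in=200, seed=1)
        assert np.max(np.abs(m.values.mean(0) - exact)) < 0.015

    def test_pairwise_margins_match_enumeration(self):
        params = _ising(3, [(0, 1, 1.2), (1, 2, 0.6)])
        states, probs = ising_pmf_exact(params)
        exact11 = probs @ (states[:, 0] * states[:, 1])
        m = sample_ising_gibbs(params, 20_000, burn_in=200, seed=2)
        emp = (m.values[:, 0] * m.values[:, 1]).mean()
        assert abs(emp - exact11) < 0.015

    def test_single_chain_mode_reproducible(self):
        params = _ising(3, [(0, 1, 0.5)])
        a = sample_ising_gibbs(params, 200, burn_in=100, thin=2, seed=3,
                               independent_chains=False)
        b = sample_ising_gibbs(params, 200, burn_in=100, thin=2, seed=3,
                               independent_chains=False)
        np.testing.assert_array_equal(a.values, b.values)


class TestTwoWave:
    def test_null_crosslag_independent_waves(self):
        params = TwoWaveParameters(_ising(4), np.zeros((4, 4)), np.zeros(4))
        w1, w2 = sample_two_wave(params, 10_000, seed=0, burn_in=50)
        assert np.all(np.abs(w2.values.mean(0) - 0.5) < 0.02)
        for j in range(4):
            r = np.corrcoef(w1.values[:, j], w2.values[:, j])[0, 1]
            assert abs(r) < 0.05

    def test_autoregressive_conditionals_closed_form(self):
        # B = 2I, alpha = -1: P(X2=1 | X1=1) = expit(1), | X1=0) = expit(-1)
        params = TwoWaveParameters(_ising(3), 2.0 * np.eye(3), -np.ones(3))
        w1, w2 = sample_two_wave(params, 20_000, seed=4, burn_in=50)
        for j in range(3):
            on = w2.values[w1.values[:, j] == 1, j].mean()
            off = w2.values[w1.values[:, j] == 0, j].mean()
            assert on == pytest.approx(expit(1.0), abs=0.02)
            assert off == pytest.approx(expit(-1.0), abs=0.02)

    def test_same_seed_identical_panel(self, preset):
        a1, a2 = sample_two_wave(preset, 300, seed=9, burn_in=100)
        b1, b2 = sample_two_wave(preset, 300, seed=9, burn_in=100)
        np.testing.assert_array_equal(a1.values, b1.values)
        np.testing.assert_array_equal(a2.values, b2.values)

    def test_wave2_conditionally_independent_given_wave1(self, preset):
        # residuals of Wave-2 items after their true linear predictors
        # are uncorrelated across items
        w1, w2 = sample_two_wave(preset, 20_000, seed=12, burn_in=200)
        eta = preset.intercepts + w1.values @ preset.crosslag
        resid = w2.values - expit(eta)
        corr = np.corrcoef(resid.T)
        off = corr[~np.eye(10, dtype=bool)]
        assert np.max(np.abs(off)) < 0.03


class TestPreset:
    def test_reproducible(self):
        a, b = cohort_preset(0), cohort_preset(0)
        np.testing.assert_array_equal(a.wave1.weights, b.wave1.weights)
        np.testing.assert_array_equal(a.intercepts, b.intercepts)

    def test_structure(self, preset):
        iu = np.triu_indices(10, 1)
        nz = preset.wave1.weights[iu]
        nz = nz[nz != 0]
        assert len(nz) == 12
        assert np.all((np.abs(nz) >= 0.5) & (np.abs(nz) <= 1.5))
        diag = np.diag(preset.crosslag)
        assert np.all((diag >= 0.5) & (diag <= 1.2))
        cross = preset.crosslag[~np.eye(10, dtype=bool)]
        assert np.count_nonzero(cross) == 5

    def test_exact_marginals_in_empirical_band(self, preset):
        m1 = ising_marginals_exact(preset.wave1)
        assert np.all((m1 >= 0.20) & (m1 <= 0.67))

    def test_sampled_endorsement_rates_in_band(self, preset):
        w1, w2 = sample_two_wave(preset, 20_000, seed=21, burn_in=200)
        for m in (w1, w2):
            rates = m.values.mean(0)
            assert np.all((rates >= 0.15) & (rates <= 0.72))

    def test_driver_has_largest_true_out_ei(self, preset):
        B = preset.crosslag.copy()
        np.fill_diagonal(B, 0.0)
        out_ei = B.sum(axis=1)
        assert int(np.argmax(out_ei)) == DRIVER_NODE
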