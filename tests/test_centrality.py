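"""Centrality indices for undirected and directed networks."""

import numpy as np
import pytest

from symptomnet.centrality import (
    closeness_betweenness,
    expected_influence,
    out_in_ei,
    standardize_values,
    strength,
)
from symptomnet.data import CrossLaggedNetwork, IsingNetwork


def _inet(p, edges, labels=None):
    W = np.zeros((p, p))
    for i, j, w in edges:
        W[i, j] = W[j, i] = w
    return IsingNetwork(
        W, np.zeros(p), labels or tuple(f"V{i}" for i in range(p))
    )


def _dnet(p, entries):
    B = np.zeros((p, p))
    for i, j, w in entries:
        B[i, j] = w
    return CrossLaggedNetwork(B, np.zeros(p), tuple(f"V{i}" for i in range(p)))


class TestStrength:
    def test_star_center_dominates(self):
        net = _inet(4, [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)])
        tab = strength(net)
        assert tab.raw[0] == pytest.approx(3.0)
        assert np.all(tab.raw[1:] == 1.0)
        assert tab.z.idxmax() == 0

    def test_hand_sum_with_negative_edge(self):
        net = _inet(3, [(0, 1, 0.5), (0, 2, -0.25)])
        assert strength(net).raw[0] == pytest.approx(0.75)

    def test_empty_network_flagged_degenerate(self):
        tab = strength(_inet(3, []))
        assert np.all(tab.raw == 0) and np.all(tab.z == 0)
        assert tab.attrs["degenerate"]

    def test_permutation_equivariance(self, rng):
        p = 6
        W = rng.normal(size=(p, p))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        labels = tuple(f"V{i}" for i in range(p))
        net = IsingNetwork(W, np.zeros(p), labels)
        perm = rng.permutation(p)
        net_p = IsingNetwork(
            W[np.ix_(perm, perm)], np.zeros(p), tuple(labels[i] for i in perm)
        )
        s = strength(net).set_index("node").raw
        sp = strength(net_p).set_index("node").raw
        for lbl in labels:
            assert s[lbl] == pytest.approx(sp[lbl])


class TestExpectedInfluence:
    def test_all_positive_equals_strength(self):
        net = _inet(3, [(0, 1, 0.4), (1, 2, 0.9)])
        np.testing.assert_allclose(
            expected_influence(net).raw, strength(net).raw
        )

    def test_mixed_signs_hand_sum(self):
        net = _inet(3, [(0, 1, 0.5), (0, 2, -0.25)])
        assert expected_influence(net).raw[0] == pytest.approx(0.25)

    def test_sign_flip_negates(self, rng):
        W = rng.normal(size=(5, 5))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        labels = tuple(f"V{i}" for i in range(5))
        pos = IsingNetwork(W, np.zeros(5), labels)
        neg = IsingNetwork(-W, np.zeros(5), labels)
        np.testing.assert_allclose(
            expected_influence(pos).raw, -expected_influence(neg).raw
        )


class TestOutInEI:
    def test_single_directed_edge(self):
        # one prospective effect of 0.26 from node 0 onto node 1
        tab = out_in_ei(_dnet(3, [(0, 1, 0.26)]))
        out = tab[tab.metric == "out_ei"].reset_index(drop=True)
        inn = tab[tab.metric == "in_ei"].reset_index(drop=True)
        assert out.raw[0] == pytest.approx(0.26)
        assert inn.raw[1] == pytest.approx(0.26)
        assert out.raw[1] == 0 and inn.raw[0] == 0

    def test_diagonal_only_gives_zero(self):
        tab = out_in_ei(_dnet(4, [(i, i, 2.0) for i in range(4)]))
        assert np.all(tab.raw == 0)

    def test_include_loops_flag(self):
        tab = out_in_ei(_dnet(2, [(0, 0, 1.5), (0, 1, 0.5)]), include_loops=True)
        out = tab[tab.metric == "out_ei"].reset_index(drop=True)
        assert out.raw[0] == pytest.approx(2.0)

    def test_matches_brute_force_sums(self, rng):
        B = rng.normal(size=(8, 8))
        net = CrossLaggedNetwork(B, np.zeros(8), tuple(f"V{i}" for i in range(8)))
        tab = out_in_ei(net)
        out = tab[tab.metric == "out_ei"].raw.to_numpy()
        inn = tab[tab.metric == "in_ei"].raw.to_numpy()
        for i in range(8):
            assert out[i] == pytest.approx(
                sum(B[i, j] for j in range(8) if j != i), abs=1e-12
            )
            assert inn[i] == pytest.approx(
                sum(B[j, i] for j in range(8) if j != i), abs=1e-12
            )


class TestStandardize:
    def test_z_scores_have_zero_mean_unit_population_sd(self, rng):
        z, degenerate = standardize_values(rng.normal(size=20))
        assert not degenerate
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)

    def test_constant_input_flagged(self):
        z, degenerate = standardize_values(np.full(5, 3.0))
        assert degenerate and np.all(z == 0)


class TestClosenessBetweenness:
    def test_path_graph_middle_has_max_betweenness(self):
        net = _inet(3, [(0, 1, 1.0), (1, 2, 1.0)])
        tab = closeness_betweenness(net)
        betw = tab[tab.metric == "betweenness"].reset_index(drop=True)
        assert betw.raw.idxmax() == 1
        assert tab.attrs["exploratory"]

    def test_fully_disconnected_harmonic_zero(self):
        tab = closeness_betweenness(_inet(4, []))
        clo = tab[tab.metric == "closeness"]
        assert np.all(clo.raw == 0)
        assert tab.attrs["harmonic_closeness"]

    def test_four_node_toy_against_exhaustive_paths(self):
        # distances are 1/|w|; verify closeness on a connected 4-cycle
        edges = [(0, 1, 1.0), (1, 2, 0.5), (2, 3, 1.0), (3, 0, 0.25)]
        net = _inet(4, edges)
        import itertools

        d = np.full((4, 4), np.inf)
        np.fill_diagonal(d, 0)
        adj = {}
        for i, j, w in edges:
            adj[(i, j)] = adj[(j, i)] = 1.0 / abs(w)
        for perm in itertools.permutations(range(4), 2):
            # brute force all simple paths between the pair
            i, j = perm
            best = np.inf
            for k in range(2, 5):
                for mid in itertools.permutations(
                    [x for x in range(4) if x not in (i, j)], k - 2
                ):
                    path = (i, *mid, j)
                    try:
                        cost = sum(
                            adj[(path[t], path[t + 1])] for t in range(len(path) - 1)
                        )
                    except KeyError:
                        continue
                    best = min(best, cost)
            d[i, j] = best
        expected = 1.0 / d.sum(axis=1)
        tab = closeness_betweenness(net)
        clo = tab[tab.metric == "closeness"].raw.to_numpy()
        np.testing.assert_allclose(clo, expected, atol=1e-12)
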