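"""Voxel-network thresholding and fROI aggregation/normalization."""

import numpy as np
import pytest

from froinet import (
    CohortSpec,
    aggregate_froi,
    analyze_subject,
    correlation_matrix,
    normalize_weights,
    simulate_cohort,
    threshold_network,
)
from froinet.cohort import CORE_FROIS
from froinet.errors import InvalidThresholdError, UndefinedCorrelationError


class TestCorrelationMatrix:
    def test_identical_rows(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=20)
        c = correlation_matrix(np.vstack([row, row]))
        assert c[0, 1] == pytest.approx(1.0)

    def test_negated_row(self):
        rng = np.random.default_rng(1)
        row = rng.normal(size=20)
        c = correlation_matrix(np.vstack([row, -row]))
        assert c[0, 1] == pytest.approx(-1.0)

    def test_matches_double_loop_moment_oracle(self):
        """Entrywise agreement with the direct temporal-moment formula."""
        rng = np.random.default_rng(2)
        bold = rng.normal(size=(6, 20))
        c = correlation_matrix(bold)
        for i in range(6):
            for j in range(6):
                xi, xj = bold[i], bold[j]
                num = (xi * xj).mean() - xi.mean() * xj.mean()
                den = np.sqrt(
                    ((xi**2).mean() - xi.mean() ** 2) * ((xj**2).mean() - xj.mean() ** 2)
                )
                assert abs(c[i, j] - num / den) < 1e-12
        assert np.allclose(c, c.T)
        assert np.all(np.diag(c) == 1.0)

    def test_constant_row_rejected(self):
        bold = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(UndefinedCorrelationError):
            correlation_matrix(bold)


class TestThresholdNetwork:
    def _corr_and_labels(self, n=8, seed=3):
        rng = np.random.default_rng(seed)
        bold = rng.normal(size=(n, 30))
        return correlation_matrix(bold), ["A"] * (n // 2) + ["B"] * (n - n // 2)

    def test_invalid_theta_rejected(self):
        corr, labels = self._corr_and_labels()
        for theta in (0.0, 1.0, 1.0001, -0.2):
            with pytest.raises(InvalidThresholdError):
                threshold_network(corr, labels, theta)

    def test_boundary_threshold_keeps_all_positive_pairs(self):
        corr, labels = self._corr_and_labels()
        off = corr[np.triu_indices_from(corr, k=1)]
        pos = off[off > 0]
        theta = pos.min() * 0.999
        vnet = threshold_network(corr, labels, theta)
        assert vnet.n_edges == pos.size

    def test_raising_theta_never_adds_edges(self):
        corr, labels = self._corr_and_labels(n=12)
        prev = None
        for theta in (0.1, 0.3, 0.5, 0.7, 0.9):
            edges = set(map(frozenset, threshold_network(corr, labels, theta).graph.edges()))
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_high_threshold_on_noise_is_near_edgeless(self):
        rng = np.random.default_rng(4)
        bold = rng.normal(size=(40, 60))
        vnet = threshold_network(correlation_matrix(bold), ["A"] * 40, 0.99)
        assert vnet.n_edges == 0
        assert vnet.n_nodes == 40  # isolated voxels retained

    def test_tie_at_theta_included(self):
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.7
        corr[0, 2] = corr[2, 0] = 0.69
        vnet = threshold_network(corr, ["A", "B", "C"], 0.7)
        assert set(map(frozenset, vnet.graph.edges())) == {frozenset((0, 1))}


class TestAggregateFroi:
    def test_eq2_arithmetic(self):
        """fROI A (3 voxels), B (2 voxels), 4 cross edges -> W = 4/5."""
        corr = np.eye(5)
        labels = ["A", "A", "A", "B", "B"]
        cross = [(0, 3), (0, 4), (1, 3), (2, 4)]
        for i, j in cross:
            corr[i, j] = corr[j, i] = 0.9
        corr[0, 1] = corr[1, 0] = 0.95  # within-fROI edge: sizes only
        fnet = aggregate_froi(threshold_network(corr, labels, 0.8))
        assert fnet.graph.edges[("A", "B")]["W"] == pytest.approx(4 / 5)
        assert fnet.graph.nodes["A"]["size"] == 3
        assert fnet.graph.nodes["B"]["size"] == 2

    def test_no_cross_edges_means_absent_edge(self):
        corr = np.eye(4)
        corr[0, 1] = corr[1, 0] = 0.9  # within A only
        fnet = aggregate_froi(threshold_network(corr, ["A", "A", "B", "B"], 0.8))
        assert fnet.n_edges == 0
        assert set(fnet.graph.nodes()) == {"A", "B"}

    def test_matches_exhaustive_pair_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(6, 15))
            bold = rng.normal(size=(n, 25))
            labels = [rng.choice(["A", "B", "C"]) for _ in range(n)]
            corr = correlation_matrix(bold)
            theta = 0.2
            vnet = threshold_network(corr, labels, theta)
            fnet = aggregate_froi(vnet)
            # oracle: enumerate all voxel pairs directly from the corr matrix
            from collections import Counter

            counts, sizes = Counter(), Counter(labels)
            for i in range(n):
                for j in range(i + 1, n):
                    if corr[i, j] >= theta and labels[i] != labels[j]:
                        counts[tuple(sorted((labels[i], labels[j])))] += 1
            expected = {pair: c / (sizes[pair[0]] + sizes[pair[1]]) for pair, c in counts.items()}
            got = {tuple(sorted((u, v))): d["W"] for u, v, d in fnet.graph.edges(data=True)}
            assert got.keys() == expected.keys()
            for pair in expected:
                assert got[pair] == pytest.approx(expected[pair], abs=1e-12)


class TestNormalizeWeights:
    def _fnet(self, weights):
        import networkx as nx

        from froinet.networks import FROINetwork

        g = nx.Graph()
        for idx, w in enumerate(weights):
            g.add_edge(f"F{idx}", f"G{idx}", W=w)
        return FROINetwork(graph=g)

    def test_single_edge_self_normalizes(self):
        fnet = normalize_weights(self._fnet([0.3]))
        assert list(fnet.edge_weights().values()) == [1.0]

    def test_arithmetic(self):
        fnet = normalize_weights(self._fnet([0.8, 0.4]))
        assert sorted(fnet.edge_weights().values()) == [0.5, 1.0]

    def test_scale_equivariance(self):
        a = normalize_weights(self._fnet([0.8, 0.4, 0.1]))
        b = normalize_weights(self._fnet([8.0, 4.0, 1.0]))
        assert a.edge_weights() == b.edge_weights()

    def test_edgeless_network_warns(self):
        import networkx as nx

        from froinet.networks import FROINetwork

        g = nx.Graph()
        g.add_node("A", size=3)
        with pytest.warns(UserWarning, match="no edges"):
            fnet = normalize_weights(FROINetwork(graph=g))
        assert not fnet.normalized


def test_planted_core_pairs_rank_top(design, kernel, regressor):
    """Across default synthetic subjects, the top-10 fROI links by W_norm are
    the planted core pairs in >= 90% of subjects."""
    from itertools import combinations

    core_pairs = {tuple(sorted(p)) for p in combinations(CORE_FROIS, 2)}
    cohort = simulate_cohort(CohortSpec(seed=77), design, kernel)
    good = 0
    for subject in cohort:
        res = analyze_subject(subject, regressor, theta=0.7)
        weights = res.fnet.edge_weights()
        top = set(sorted(weights, key=weights.get, reverse=True)[: len(core_pairs)])
        good += top == core_pairs
    assert good >= 18
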