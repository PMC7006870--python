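"""k-core decomposition, shell normalization, occupancy, and its null."""

import networkx as nx
import numpy as np
import pytest

from froinet import core_decompose, normalized_shells, null_occupancy, occupancy_by_froi
from froinet.errors import UndefinedNormalizationError
from froinet.kcore import KShellAssignment

from conftest import random_simple_graph


def check_core_definition(g, core_number):
    """Definitional oracle: for every k, the nodes with core >= k induce a
    subgraph of min degree >= k, and re-adding any excluded node gives it
    degree < k within the augmented node set."""
    if not core_number:
        return
    kmax = max(core_number.values())
    for k in range(1, kmax + 1):
        inside = {v for v, c in core_number.items() if c >= k}
        sub = g.subgraph(inside)
        assert all(d >= k for _, d in sub.degree()), f"min-degree violated at k={k}"
        for v in set(g.nodes()) - inside:
            deg_into = sum(1 for u in g.neighbors(v) if u in inside)
            assert deg_into < k, f"maximality violated at k={k} by node {v}"


class TestCoreDecompose:
    def test_clique(self):
        a = core_decompose(nx.complete_graph(4))
        assert set(a.core_number.values()) == {3}
        assert a.kcore_max == 3

    def test_path(self):
        a = core_decompose(nx.path_graph(5))
        assert set(a.core_number.values()) == {1}

    def test_empty_graph(self):
        assert core_decompose(nx.Graph()).core_number == {}

    def test_definitional_oracle_on_random_graphs(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            g = random_simple_graph(rng, 12)
            check_core_definition(g, core_decompose(g).core_number)

    def test_nestedness_and_edge_monotonicity(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            g = random_simple_graph(rng, 10)
            cn = core_decompose(g).core_number
            # nestedness: (k+1)-core subset of k-core is implied by per-node
            # core numbers; check via node sets
            kmax = max(cn.values(), default=0)
            for k in range(kmax):
                assert {v for v, c in cn.items() if c >= k + 1} <= {
                    v for v, c in cn.items() if c >= k
                }
            # adding one edge never decreases any core number
            non_edges = list(nx.non_edges(g))
            if non_edges:
                u, v = non_edges[int(rng.integers(len(non_edges)))]
                g2 = g.copy()
                g2.add_edge(u, v)
                cn2 = core_decompose(g2).core_number
                assert all(cn2[w] >= cn[w] for w in g.nodes())


class TestNormalizedShells:
    def test_arithmetic(self):
        a = KShellAssignment(core_number={"x": 2, "y": 4})
        shells = normalized_shells(a)
        assert shells == {"x": 0.5, "y": 1.0}

    def test_clique_all_ones(self):
        shells = normalized_shells(core_decompose(nx.complete_graph(5)))
        assert set(shells.values()) == {1.0}

    def test_cross_subject_top_shell_comparability(self):
        s1 = normalized_shells(core_decompose(nx.complete_graph(4)))
        s2 = normalized_shells(core_decompose(nx.complete_graph(9)))
        assert max(s1.values()) == max(s2.values()) == 1.0

    def test_edgeless_graph_raises(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2])
        with pytest.raises(UndefinedNormalizationError):
            normalized_shells(core_decompose(g))


class TestOccupancy:
    def _pair(self, g, labels):
        return core_decompose(g), labels

    def test_single_subject_all_in_max_shell(self):
        g = nx.complete_graph(6)
        labels = {v: "A" for v in g}
        occ = occupancy_by_froi([self._pair(g, labels)])
        assert occ.counts["A"][-1] == 6
        assert occ.counts["A"][:-1].sum() == 0
        assert occ.max_shell_fraction["A"] == 1.0

    def test_counts_conserve_voxels_per_froi(self):
        rng = np.random.default_rng(12)
        pairs = []
        expected = {"A": 0, "B": 0}
        for _ in range(4):
            g = random_simple_graph(rng, 12)
            if core_decompose(g).kcore_max < 1:
                continue
            labels = {v: ("A" if rng.random() < 0.5 else "B") for v in g}
            pairs.append(self._pair(g, labels))
            for froi in labels.values():
                expected[froi] += 1
        occ = occupancy_by_froi(pairs, froi_filter=["A", "B"])
        for froi in "AB":
            assert occ.counts[froi].sum() == expected[froi] == occ.totals[froi]

    def test_unknown_froi_in_filter_rejected(self):
        g = nx.complete_graph(3)
        with pytest.raises(ValueError, match="unknown"):
            occupancy_by_froi([self._pair(g, {v: "A" for v in g})], froi_filter=["Z"])

    def test_isolated_nodes_fall_in_lowest_bin(self):
        g = nx.complete_graph(4)
        g.add_node(99)
        labels = {v: "A" for v in g}
        occ = occupancy_by_froi([self._pair(g, labels)])
        assert occ.counts["A"][0] == 1 and occ.counts["A"][-1] == 4


class TestNullOccupancy:
    def test_single_froi_null_equals_observed(self):
        g = nx.gnp_random_graph(20, 0.3, seed=1)
        pairs = [(core_decompose(g), {v: "A" for v in g})]
        null = null_occupancy(pairs, n_perm=50, seed=0)
        assert null.null_sd["A"] == pytest.approx(0.0, abs=1e-12)
        assert null.null_mean["A"] == pytest.approx(null.observed["A"])
        assert null.p_value["A"] == 1.0

    def test_null_mean_matches_hypergeometric_expectation(self):
        """Under label shuffling, E[max-shell count for f] =
        size_f * (top nodes / total nodes)."""
        g = nx.gnp_random_graph(60, 0.15, seed=2)
        assignment = core_decompose(g)
        rng = np.random.default_rng(13)
        labels = {v: ("A" if rng.random() < 0.3 else "B") for v in g}
        pairs = [(assignment, labels)]
        n_perm = 1000
        # pool several independent permutation runs for a tight SE
        runs = [null_occupancy(pairs, n_perm=n_perm, seed=s) for s in range(5)]
        n_top = len(assignment.max_shell_nodes())
        n_total = g.number_of_nodes()
        expected = n_top / n_total  # expected fraction of A's voxels in top shell
        pooled_mean = np.mean([r.null_mean["A"] for r in runs])
        se = np.mean([r.null_sd["A"] for r in runs]) / np.sqrt(5 * n_perm)
        assert abs(pooled_mean - expected) <= 3 * se

    def test_planted_enriched_froi_detected(self):
        # clique fROI "core" + pendant periphery: core is top-shell enriched
        g = nx.complete_graph(10)
        for i in range(10, 25):
            g.add_edge(i, i % 10)
        labels = {v: ("core" if v < 10 else "periph") for v in g}
        null = null_occupancy([(core_decompose(g), labels)], n_perm=199, seed=4)
        assert null.observed["core"] == 1.0
        assert null.p_value["core"] < 0.05
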