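"""Small-world graph metrics against closed forms and independent oracles."""

import numpy as np
import pytest

import networkx as nx
from oracles_util import (betweenness_oracle, clustering_oracle, cpl_oracle,
                          fw_distances, ge_oracle, random_weighted_graph,
                          transitivity_oracle)

from eegfc import (GraphContext, betweenness, char_path_length,
                   clustering_coef, global_efficiency, graph_metrics,
                   shortest_paths, transitivity)


def complete(n):
    return np.ones((n, n)) - np.eye(n)


def cycle(n):
    w = np.zeros((n, n))
    for i in range(n):
        w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
    return w


def star(n):
    w = np.zeros((n, n))
    w[0, 1:] = w[1:, 0] = 1.0
    return w


class TestClosedForms:
    def test_complete_graph_limits(self):
        gm = graph_metrics(complete(6), mode="binary")
        assert gm.cpl == pytest.approx(1.0)
        assert gm.ge == pytest.approx(1.0)
        assert gm.transitivity == pytest.approx(1.0)
        np.testing.assert_allclose(gm.cc, 1.0)
        np.testing.assert_allclose(gm.bc, 0.0, atol=1e-12)

    def test_five_cycle(self):
        g = GraphContext(cycle(5))
        sp = shortest_paths(g)
        np.testing.assert_allclose(np.sort(sp.dist[0, 1:]), [1, 1, 2, 2])
        assert char_path_length(g) == pytest.approx(1.5)

    def test_star_center_betweenness_is_one(self):
        bc = betweenness(GraphContext(star(5)))
        assert bc[0] == pytest.approx(1.0)
        np.testing.assert_allclose(bc[1:], 0.0)

    def test_star_transitivity_zero(self):
        assert transitivity(GraphContext(star(5)), "binary") == 0.0

    def test_triangle_clustering(self):
        gm = graph_metrics(complete(3), mode="binary")
        np.testing.assert_allclose(gm.cc, 1.0)
        assert gm.transitivity == pytest.approx(1.0)
        gm_w = graph_metrics(complete(3), mode="weighted")
        np.testing.assert_allclose(gm_w.cc, 1.0)

    def test_path_graph_no_triangles(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        np.testing.assert_allclose(clustering_coef(GraphContext(w), "binary"),
                                   0.0)


class TestDisconnection:
    def test_disconnected_pair_infinite_distance(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[2, 3] = w[3, 2] = 1.0
        g = GraphContext(w)
        sp = shortest_paths(g)
        assert np.isinf(sp.dist[0, 2])
        assert sp.sigma[0, 2] == 0.0
        assert np.isinf(char_path_length(g))
        # 4 ordered connected pairs of 12: GE = 1/3
        assert global_efficiency(g) == pytest.approx(1.0 / 3.0)
        assert not graph_metrics(w).connected

    def test_connected_flag_set(self):
        gm = graph_metrics(complete(4))
        assert gm.connected


@pytest.fixture(scope="module")
def graphs():
    rng = np.random.default_rng(1630)
    return [random_weighted_graph(rng, int(rng.integers(4, 9)))
            for _ in range(200)]


class TestOracleEquivalence:
    """200 random weighted graphs, N in [4, 8], against brute force."""

    def test_distances_match_floyd_warshall(self, graphs):
        for w in graphs:
            sp = shortest_paths(GraphContext(w))
            np.testing.assert_allclose(sp.dist, fw_distances(w), atol=1e-9)

    def test_betweenness_matches_path_enumeration(self, graphs):
        for w in graphs:
            np.testing.assert_allclose(betweenness(GraphContext(w)),
                                       betweenness_oracle(w), atol=1e-9)

    def test_cpl_and_ge_match_oracles(self, graphs):
        for w in graphs:
            g = GraphContext(w)
            assert char_path_length(g) == pytest.approx(cpl_oracle(w),
                                                        abs=1e-9)
            assert global_efficiency(g) == pytest.approx(ge_oracle(w),
                                                         abs=1e-9)

    @pytest.mark.parametrize("mode", ["binary", "weighted"])
    def test_clustering_and_transitivity_match(self, graphs, mode):
        for w in graphs[:80]:
            g = GraphContext(w)
            np.testing.assert_allclose(clustering_coef(g, mode),
                                       clustering_oracle(w, mode), atol=1e-9)
            assert transitivity(g, mode) == pytest.approx(
                transitivity_oracle(w, mode), abs=1e-9)


class TestNetworkxCrossCheck:
    """The standard library implementation as a second independent route."""

    def test_weighted_betweenness(self, rng):
        for _ in range(20):
            w = random_weighted_graph(rng, 7)
            g = nx.from_numpy_array(w)
            for u, v, d in g.edges(data=True):
                d["length"] = 1.0 / d["weight"]
            ref = nx.betweenness_centrality(g, weight="length",
                                            normalized=True)
            ours = betweenness(GraphContext(w))
            np.testing.assert_allclose(ours, [ref[i] for i in range(7)],
                                       atol=1e-9)

    def test_onnela_weighted_clustering(self, rng):
        for _ in range(20):
            w = random_weighted_graph(rng, 7)
            g = nx.from_numpy_array(w)
            ref = nx.clustering(g, weight="weight")
            ours = clustering_coef(GraphContext(w), "weighted")
            np.testing.assert_allclose(ours, [ref[i] for i in range(7)],
                                       atol=1e-9)

    def test_binary_transitivity(self, rng):
        for _ in range(20):
            w = random_weighted_graph(rng, 7)
            assert transitivity(GraphContext(w), "binary") == pytest.approx(
                nx.transitivity(nx.from_numpy_array(w > 0)), abs=1e-12)


class TestInvariances:
    def test_permutation_equivariance(self, rng):
        w = random_weighted_graph(rng, 7)
        perm = rng.permutation(7)
        wp = w[np.ix_(perm, perm)]
        gm, gmp = graph_metrics(w), graph_metrics(wp)
        np.testing.assert_allclose(gmp.bc, gm.bc[perm], atol=1e-10)
        np.testing.assert_allclose(gmp.cc, gm.cc[perm], atol=1e-10)
        assert gmp.cpl == pytest.approx(gm.cpl)
        assert gmp.ge == pytest.approx(gm.ge)
        assert gmp.transitivity == pytest.approx(gm.transitivity)

    @pytest.mark.parametrize("c", [0.1, 3.0])
    def test_weight_scaling(self, rng, c):
        w = random_weighted_graph(rng, 6)
        gm, gmc = graph_metrics(w), graph_metrics(c * w)
        # reciprocal lengths: CPL scales by 1/c, GE by c
        assert gmc.cpl == pytest.approx(gm.cpl / c)
        assert gmc.ge == pytest.approx(gm.ge * c)
        # max-normalized triangle terms are scale free
        np.testing.assert_allclose(gmc.cc, gm.cc, atol=1e-10)
        assert gmc.transitivity == pytest.approx(gm.transitivity)
        np.testing.assert_allclose(gmc.bc, gm.bc, atol=1e-10)

    def test_negative_weights_rejected(self):
        w = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError):
            GraphContext(w)

    def test_betweenness_needs_three_nodes(self):
        with pytest.raises(ValueError):
            betweenness(GraphContext(np.zeros((2, 2))))
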