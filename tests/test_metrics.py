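import numpy as np
import pytest

from nirsnet import toy_graph
from nirsnet import metrics as M

import oracles


def er(n, p, seed):
    return toy_graph("erdos_renyi", n, p=p, seed=seed)


class TestClosedForms:
    def test_complete_graph_limits(self):
        g = toy_graph("complete", 6)
        assert M.clustering_coefficient(g)[0] == pytest.approx(1.0)
        assert M.characteristic_path_length(g).lp == pytest.approx(1.0)
        assert M.global_efficiency(g) == pytest.approx(1.0)
        assert M.local_efficiency(g)[0] == pytest.approx(1.0)
        assert np.allclose(M.nodal_betweenness(g), 0.0)

    def test_path_graph_has_no_triangles(self):
        assert M.clustering_coefficient(toy_graph("path", 6))[0] == 0.0

    def test_ring_six_hand_computed_lengths(self):
        g = toy_graph("ring", 6)
        # per-node distances 1,1,2,2,3
        assert M.characteristic_path_length(g).lp == pytest.approx(1.8)
        assert M.global_efficiency(g) == pytest.approx(
            (1 + 1 + 0.5 + 0.5 + 1 / 3) / 5
        )

    def test_star_graph_centralities(self):
        g = toy_graph("star", 6)
        b = M.nodal_betweenness(g)
        assert b[0] == pytest.approx(1.0)
        assert np.allclose(b[1:], 0.0)
        assert M.local_efficiency(g)[0] == 0.0

    def test_two_cliques_modularity_half(self):
        g = toy_graph("two_cliques", 8)
        part = M.modularity_partition(g)
        assert part.Q == pytest.approx(0.5)
        assert part.n_modules == 2

    def test_single_module_partition_q_zero(self):
        g = er(8, 0.5, 1)
        assert M.partition_modularity(g, np.ones(8)) == pytest.approx(0.0)

    def test_two_isolated_nodes_zero_efficiency(self):
        a = np.zeros((2, 2))
        assert M.global_efficiency(a) == 0.0


@pytest.mark.parametrize("seed", range(10))
def test_metrics_match_bruteforce_on_random_graphs(seed):
    """Cp, Lp, Eglob, Eloc, k_i, E_i, b_i against enumeration oracles."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 13))
    g = er(n, float(rng.uniform(0.25, 0.6)), seed + 100)
    a = g.adjacency.astype(float)

    cp, c_nodes = M.clustering_coefficient(g)
    assert np.allclose(c_nodes, oracles.clustering_per_node(a), atol=1e-9)

    lp = M.characteristic_path_length(g).lp
    ref = oracles.characteristic_path_length(a)
    assert lp == pytest.approx(ref, abs=1e-9) or (np.isnan(lp) and np.isnan(ref))

    assert M.global_efficiency(g) == pytest.approx(oracles.global_efficiency(a), abs=1e-9)
    assert np.allclose(M.nodal_efficiency(g), oracles.nodal_efficiency(a), atol=1e-9)
    assert M.local_efficiency(g)[0] == pytest.approx(oracles.local_efficiency(a), abs=1e-9)
    assert np.array_equal(M.nodal_degree(g), a.sum(axis=1).astype(int))
    assert np.allclose(M.nodal_betweenness(g), oracles.betweenness(a), atol=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_partition_q_evaluation_matches_longhand(seed):
    g = er(10, 0.4, seed)
    labels = np.random.default_rng(seed).integers(1, 4, size=10)
    assert M.partition_modularity(g, labels) == pytest.approx(
        oracles.modularity_of_labels(g.adjacency.astype(float), labels), abs=1e-12
    )


@pytest.mark.parametrize("seed", range(4))
def test_greedy_q_reaches_exhaustive_optimum_on_small_graphs(seed):
    g = er(8, 0.35, seed + 40)
    if g.K == 0:
        pytest.skip("edgeless draw")
    best_q, _ = oracles.best_modularity_exhaustive(g.adjacency.astype(float))
    part = M.modularity_partition(g, method="multistart", seed=seed, n_restarts=10)
    assert part.Q == pytest.approx(best_q, abs=1e-9)


class TestHierarchy:
    def test_exact_power_law_recovered(self):
        k = np.array([2, 4, 8, 16], dtype=float)
        c = k**-0.5
        fit = M.fit_hierarchy(k, c)
        assert fit.beta == pytest.approx(0.5, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_regular_graph_flagged_undefined(self):
        fit = M.hierarchy_coefficient(toy_graph("ring", 8))
        assert not fit.defined

    def test_er_graph_matches_regression_oracle(self):
        g = er(30, 0.3, 3)
        a = g.adjacency.astype(float)
        k = a.sum(axis=1)
        c = oracles.clustering_per_node(a)
        use = (k >= 2) & (c > 0)
        ks = np.unique(k[use])
        cs = np.array([c[use][k[use] == kv].mean() for kv in ks])
        slope, r2 = oracles.loglog_slope(ks, cs)
        fit = M.hierarchy_coefficient(g)
        assert fit.beta == pytest.approx(-slope, abs=1e-9)
        assert fit.r2 == pytest.approx(r2, abs=1e-9)


class TestPlantedPartitionRecovery:
    def test_louvain_recovers_strong_planting(self):
        from sklearn.metrics import adjusted_rand_score

        g = toy_graph(
            "planted_partition", 0, n_modules=4, module_size=8, p_in=0.9,
            p_out=0.05, seed=2,
        )
        truth = np.repeat(np.arange(4), 8)
        part = M.modularity_partition(g, method="multistart", seed=1, n_restarts=10)
        assert adjusted_rand_score(truth, part.labels) == 1.0

    def test_reported_q_matches_recomputation(self):
        g = er(20, 0.25, 9)
        part = M.modularity_partition(g)
        assert part.Q == pytest.approx(
            M.partition_modularity(g, part.labels), abs=1e-12
        )

    def test_edgeless_graph_flagged(self):
        part = M.modularity_partition(np.zeros((5, 5)))
        assert not part.defined


class TestComputeAll:
    def test_agrees_with_individual_calls(self):
        g = er(15, 0.3, 5)
        gm, nm = M.compute_all(g)
        assert gm.Cp == pytest.approx(M.clustering_coefficient(g)[0])
        assert gm.Lp == pytest.approx(M.characteristic_path_length(g).lp)
        assert gm.Eglob == pytest.approx(M.global_efficiency(g))
        assert gm.Eloc == pytest.approx(M.local_efficiency(g)[0])
        assert np.allclose(nm.betweenness, M.nodal_betweenness(g))

    def test_handshake_between_degree_and_edges(self):
        g = er(20, 0.4, 6)
        _, nm = M.compute_all(g)
        assert nm.degree.sum() == 2 * g.K

    def test_disconnection_fraction_reported(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1
        gm = M.compute_global(a, include=("Lp", "Eglob"))
        # finite pair: only (0,1); 10 of 12 ordered pairs disconnected
        assert gm.frac_disconnected_pairs == pytest.approx(10 / 12)
        assert "disconnected" in gm.flags
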