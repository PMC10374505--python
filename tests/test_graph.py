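"""Weighted graph measures against closed forms and brute-force oracles."""

import numpy as np
import pytest

from neurocoh.graph import (DegenerateGraphError, GraphMeasures,
                            GraphMetricConfig, _maslov_sneppen, assortativity,
                            clustering_and_transitivity, compute_all,
                            degree_and_strength, modularity_louvain,
                            modularity_value, path_measures,
                            shortest_path_matrix, small_worldness,
                            weights_to_lengths)

import oracles


def complete_graph(n):
    W = np.ones((n, n))
    np.fill_diagonal(W, 0)
    return W


def star_graph(n):
    W = np.zeros((n, n))
    W[0, 1:] = W[1:, 0] = 1.0
    return W


def chain_half():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 0.5
    return W


class TestClosedForms:
    def test_complete_unit_graph(self):
        K = complete_graph(19)
        pm = path_measures(shortest_path_matrix(weights_to_lengths(K)))
        assert pm["characteristic_path_length"] == 1.0
        assert pm["global_efficiency"] == 1.0
        assert pm["radius"] == pm["diameter"] == pm["eccentricity"] == 1.0
        ct = clustering_and_transitivity(K)
        assert ct["clustering_coefficient"] == pytest.approx(1.0)
        assert ct["transitivity"] == pytest.approx(1.0)
        assert ct["local_efficiency"] == pytest.approx(1.0)
        ds = degree_and_strength(K, tau=0.0)
        assert ds["average_degree"] == 18.0
        assert ds["strength"] == 18.0
        q, part = modularity_louvain(K, seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert len(np.unique(part)) == 1
        assert small_worldness(K, seed=0) == pytest.approx(1.0)
        with pytest.raises(DegenerateGraphError):
            assortativity(K)

    def test_star_graph(self):
        S = star_graph(7)
        ct = clustering_and_transitivity(S)
        assert ct["clustering_coefficient"] == 0.0
        assert ct["transitivity"] == 0.0
        assert assortativity(S) == pytest.approx(-1.0)

    def test_half_weight_chain(self):
        D = shortest_path_matrix(weights_to_lengths(chain_half()))
        assert D[0, 1] == D[1, 2] == 2.0
        assert D[0, 2] == 4.0
        pm = path_measures(D)
        assert pm["characteristic_path_length"] == pytest.approx(8 / 3)
        assert pm["global_efficiency"] == pytest.approx(5 / 12)
        assert pm["radius"] == 2.0 and pm["diameter"] == 4.0

    def test_three_node_path_degrees(self):
        P = np.zeros((3, 3))
        P[0, 1] = P[1, 0] = P[1, 2] = P[2, 1] = 1.0
        ds = degree_and_strength(P, tau=0.0)
        assert ds["average_degree"] == pytest.approx(4 / 3)

    def test_two_cliques_modularity(self):
        W = np.zeros((8, 8))
        W[:4, :4] = 1.0
        W[4:, 4:] = 1.0
        np.fill_diagonal(W, 0)
        q, part = modularity_louvain(W, seed=1)
        assert q == pytest.approx(0.5)
        assert len(np.unique(part)) == 2
        assert np.all(part[:4] == part[0]) and np.all(part[4:] == part[4])


class TestWeightsToLengths:
    def test_basic_mapping(self):
        W = np.array([[0, 0.5, 0], [0.5, 0, 0], [0, 0, 0]], dtype=float)
        L = weights_to_lengths(W)
        assert L[0, 1] == 2.0
        assert np.isinf(L[0, 2])
        assert np.all(np.diag(L) == 0)

    def test_monotone(self, rng):
        W = oracles.random_weighted_graph(6, 0.8, rng)
        L = weights_to_lengths(W)
        iu = np.triu_indices(6, 1)
        w, l = W[iu], L[iu]
        present = w > 0
        order = np.argsort(w[present])
        assert np.all(np.diff(l[present][order]) <= 1e-12)

    def test_negative_weight_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = -0.1
        with pytest.raises(ValueError, match="non-negative"):
            weights_to_lengths(W)


@pytest.mark.parametrize("seed", range(12))
def test_oracle_equivalence_small_graphs(seed):
    """Deterministic measures equal exhaustive-enumeration oracles."""
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(4, 8))
    W = oracles.random_weighted_graph(n, rng.uniform(0.4, 0.9), rng)
    tau = 0.3

    D = shortest_path_matrix(weights_to_lengths(W))
    D_oracle = oracles.shortest_paths_bruteforce(oracles.lengths_bruteforce(W))
    assert np.allclose(D, D_oracle, atol=1e-9)

    pm = path_measures(D)
    pm_oracle = oracles.path_measures_bruteforce(D_oracle)
    for key, val in pm_oracle.items():
        assert pm[key] == pytest.approx(val, abs=1e-9), key

    ds = degree_and_strength(W, tau)
    ds_oracle = oracles.degree_strength_bruteforce(W, tau)
    for key, val in ds_oracle.items():
        assert ds[key] == pytest.approx(val, abs=1e-9), key

    ct = clustering_and_transitivity(W)
    ct_oracle = oracles.clustering_bruteforce(W)
    for key, val in ct_oracle.items():
        assert ct[key] == pytest.approx(val, abs=1e-9), key

    try:
        r = assortativity(W, tau)
    except DegenerateGraphError:
        pass
    else:
        assert r == pytest.approx(oracles.assortativity_bruteforce(W, tau),
                                  abs=1e-9)


@pytest.mark.parametrize("seed", range(8))
def test_louvain_reaches_exhaustive_optimum(seed):
    rng = np.random.default_rng(300 + seed)
    n = int(rng.integers(4, 9))
    W = oracles.random_weighted_graph(n, rng.uniform(0.3, 0.9), rng)
    q, part = modularity_louvain(W, n_restarts=10, seed=seed)
    q_best, _ = oracles.modularity_bruteforce(W)
    assert q <= q_best + 1e-9
    assert q >= q_best - 1e-9
    # self-consistency: returned Q equals Q of returned partition
    assert q == pytest.approx(modularity_value(W, part), abs=1e-12)
    assert q == pytest.approx(
        oracles.modularity_of_partition_bruteforce(W, part), abs=1e-9)


class TestInvariants:
    def test_permutation_invariance(self, rng):
        W = oracles.random_weighted_graph(7, 0.7, rng)
        perm = rng.permutation(7)
        Wp = W[np.ix_(perm, perm)]
        a = compute_all(W, GraphMetricConfig(tau=0.3))
        b = compute_all(Wp, GraphMetricConfig(tau=0.3))
        for name in ("average_degree", "strength", "radius", "diameter",
                     "eccentricity", "characteristic_path_length",
                     "global_efficiency", "local_efficiency",
                     "clustering_coefficient", "transitivity", "modularity"):
            assert getattr(a, name) == pytest.approx(getattr(b, name),
                                                     abs=1e-9), name

    def test_weight_scaling(self, rng):
        W = oracles.random_weighted_graph(7, 0.7, rng)
        c = 0.37
        ds = degree_and_strength(W, tau=0.0)
        ds_scaled = degree_and_strength(c * W, tau=0.0)
        assert ds_scaled["average_degree"] == ds["average_degree"]
        assert ds_scaled["strength"] == pytest.approx(c * ds["strength"])
        e = path_measures(shortest_path_matrix(weights_to_lengths(W)))
        e_scaled = path_measures(shortest_path_matrix(weights_to_lengths(c * W)))
        assert e_scaled["global_efficiency"] == pytest.approx(
            c * e["global_efficiency"])

    def test_adding_edge_never_decreases_efficiency(self, rng):
        for _ in range(10):
            W = oracles.random_weighted_graph(6, 0.5, rng)
            absent = np.argwhere(np.triu(W == 0, k=1))
            if len(absent) == 0:
                continue
            i, j = absent[rng.integers(len(absent))]
            W2 = W.copy()
            W2[i, j] = W2[j, i] = rng.uniform(0.1, 1.0)
            e1 = path_measures(shortest_path_matrix(weights_to_lengths(W)))
            e2 = path_measures(shortest_path_matrix(weights_to_lengths(W2)))
            assert e2["global_efficiency"] >= e1["global_efficiency"] - 1e-12

    def test_radius_le_mean_ecc_le_diameter(self, rng):
        W = oracles.random_weighted_graph(7, 0.8, rng, connected=True)
        pm = path_measures(shortest_path_matrix(weights_to_lengths(W)))
        assert pm["radius"] <= pm["eccentricity"] + 1e-12
        assert pm["eccentricity"] <= pm["diameter"] + 1e-12


class TestSmallWorldness:
    def test_deterministic_given_seed(self, rng):
        W = oracles.random_weighted_graph(12, 0.5, rng)
        a = small_worldness(W, seed=4)
        b = small_worldness(W, seed=4)
        assert a == b

    def test_random_graph_sigma_near_one(self):
        # an Erdos-Renyi weighted graph is its own null model
        sigmas = []
        for rep in range(20):
            g = np.random.default_rng(500 + rep)
            W = oracles.random_weighted_graph(16, 0.4, g)
            sigmas.append(small_worldness(W, n_random=10, seed=rep))
        assert abs(np.mean(sigmas) - 1.0) < 0.1

    def test_surrogates_preserve_degree_sequence(self, rng):
        W = oracles.random_weighted_graph(12, 0.4, rng)
        adj = W > 0
        before = adj.sum(axis=1)
        for s in range(5):
            A = _maslov_sneppen(adj, 200, np.random.default_rng(s))
            assert np.array_equal(A.sum(axis=1), before)
            assert np.array_equal(A, A.T)
            assert not A.diagonal().any()

    def test_weight_multiset_preserved(self, rng):
        W = oracles.random_weighted_graph(10, 0.5, rng)
        _, details = small_worldness(W, n_random=3, seed=0, return_details=True)
        orig = np.sort(W[np.triu_indices(10, 1)])
        for Wr in details["surrogates"]:
            assert np.allclose(np.sort(Wr[np.triu_indices(10, 1)]), orig)


class TestComputeAll:
    def test_measures_round_trip(self, rng):
        W = oracles.random_weighted_graph(7, 0.8, rng)
        m = compute_all(W, GraphMetricConfig(tau=0.3), band="delta",
                        subject_id="s1", group_label="g")
        again = GraphMeasures.from_dict(m.to_dict())
        assert again == m

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateGraphError):
            modularity_louvain(np.zeros((5, 5)))

    def test_degenerate_assortativity_becomes_nan(self):
        m = compute_all(complete_graph(6))
        assert np.isnan(m.assortativity)
        with pytest.raises(DegenerateGraphError):
            compute_all(complete_graph(6),
                        GraphMetricConfig(on_degenerate="raise"))
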