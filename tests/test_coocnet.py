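import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import floyd_warshall

from rhizonet import (
    CoocNetwork,
    OtuTable,
    RhizonetError,
    TaxonomyMap,
    bh_adjust,
    build_network,
    hub_scores,
    network_metrics,
    node_composition,
    pearson_matrix,
    permutation_pvalues,
)


def _table(mat, otus=None):
    # shift to non-negative "abundances"; Pearson is shift-invariant
    mat = np.asarray(mat, dtype=float)
    if mat.size and mat.min() < 0:
        mat = mat - mat.min()
    otus = otus or [f"o{i:02d}" for i in range(mat.shape[0])]
    cols = [f"s{j}" for j in range(mat.shape[1])]
    return OtuTable(pd.DataFrame(mat, index=otus, columns=cols))


def _net_from_graph(g, alpha=0.01):
    return CoocNetwork(graph=g, alpha=alpha)


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3], [1, 3, 2], 0.5),
        ],
    )
    def test_hand_values(self, x, y, expected):
        r = pearson_matrix(_table([x, y]))
        assert r[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_row_flagged(self):
        r = pearson_matrix(_table([[1, 1, 1], [1, 2, 3]]))
        assert np.isnan(r[0, 1]) and np.isnan(r[0, 0])
        assert r[1, 1] == 1.0

    def test_too_few_samples(self):
        with pytest.raises(RhizonetError, match="3 samples"):
            pearson_matrix(_table([[1, 2], [3, 4]]))


class TestPermutationPvalues:
    def test_deterministic_given_seed(self, rng):
        t = _table(rng.normal(size=(10, 12)) ** 2)
        a = permutation_pvalues(t, 50, seed=9)
        b = permutation_pvalues(t, 50, seed=9)
        np.testing.assert_array_equal(a.p_raw, b.p_raw)

    def test_constant_row_excluded(self, rng):
        t = _table(np.vstack([np.full(10, 3.0), rng.normal(size=(3, 10))]))
        res = permutation_pvalues(t, 20, seed=0)
        assert np.isnan(res.p_raw[0, 1:]).all()
        assert not np.isnan(res.p_raw[1, 2])

    def test_duplicate_rows_give_zero_p(self, rng):
        x = rng.normal(size=10)
        t = _table(np.vstack([x, x, rng.normal(size=10)]))
        res = permutation_pvalues(t, 100, seed=1)
        assert res.r[0, 1] == pytest.approx(1.0)
        assert res.p_raw[0, 1] == 0.0

    def test_pseudocount_variant_floor(self, rng):
        x = rng.normal(size=10)
        t = _table(np.vstack([x, x + rng.normal(0, 1e-3, 10)]))
        res = permutation_pvalues(t, 100, seed=1, pseudocount=True)
        assert res.p_raw[0, 1] == pytest.approx(1 / 101)

    def test_affine_row_rescaling_invariance(self, rng):
        X = rng.normal(size=(6, 15))
        t1 = _table(X)
        scales = rng.uniform(0.5, 3.0, size=(6, 1))
        offsets = rng.uniform(-2, 2, size=(6, 1))
        t2 = _table(X * scales + offsets)
        a = permutation_pvalues(t1, 40, seed=3)
        b = permutation_pvalues(t2, 40, seed=3)
        np.testing.assert_allclose(a.p_raw, b.p_raw, equal_nan=True)

    def test_adjusted_never_below_raw_and_symmetric(self, rng):
        t = _table(rng.normal(size=(12, 10)))
        res = permutation_pvalues(t, 60, seed=4)
        mask = res.testable_pairs()
        assert (res.p_adj[mask] >= res.p_raw[mask] - 1e-12).all()
        np.testing.assert_allclose(res.p_adj, res.p_adj.T, equal_nan=True)

    def test_invalid_b(self, rng):
        with pytest.raises(ValueError):
            permutation_pvalues(_table(rng.normal(size=(3, 5))), 0)


class TestBhAdjust:
    def _oracle(self, p):
        # literal step-up: sort, adj_(i) = min_{j>=i} p_(j) m / j, cap at 1
        p = np.asarray(p, float)
        m = p.size
        order = np.argsort(p, kind="stable")
        adj_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj_sorted, 1.0)
        return out

    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_step_up_flat(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-12
        )

    def test_hand_step_up_staggered(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.011, 0.02, 0.04]),
            [0.02, 0.022, 1 / 37.5, 0.04],
            atol=1e-6,
        )

    def test_matches_step_up_oracle_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), self._oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestBuildNetwork:
    def test_nothing_significant_gives_empty_network(self, rng):
        t = _table(rng.normal(size=(8, 20)))
        res = permutation_pvalues(t, 30, seed=2, pseudocount=True)
        net = build_network(res, alpha=1 / 31 / 2)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_single_pair_network(self, rng):
        x = rng.normal(size=20)
        # only the first pair is testable: constant rows are excluded
        t = _table(np.vstack([x, x + rng.normal(0, 0.01, 20),
                              np.full((4, 20), 7.0)]))
        res = permutation_pvalues(t, 100, seed=6)
        net = build_network(res, alpha=0.01)
        assert net.n_nodes == 2 and net.n_edges == 1
        assert network_metrics(net).density == 1.0

    def test_edge_set_monotone_in_alpha_and_rmin(self, rng):
        t = _table(rng.normal(size=(15, 12)))
        res = permutation_pvalues(t, 50, seed=8)
        loose = build_network(res, alpha=0.5).edge_set()
        tight = build_network(res, alpha=0.05).edge_set()
        assert tight <= loose
        strong = build_network(res, alpha=0.5, r_min=0.6).edge_set()
        assert strong <= loose

    def test_isolates_optional(self, rng):
        x = rng.normal(size=20)
        t = _table(np.vstack([x, x, rng.normal(size=(3, 20))]))
        res = permutation_pvalues(t, 100, seed=3)
        with_iso = build_network(res, alpha=0.01, include_isolates=True)
        assert with_iso.n_nodes == 5

    def test_bad_alpha(self, rng):
        t = _table(rng.normal(size=(4, 10)))
        res = permutation_pvalues(t, 10, seed=0)
        with pytest.raises(ValueError):
            build_network(res, alpha=0.0)


class TestHubScores:
    def _power_iteration(self, A, iters=5000):
        v = np.ones(A.shape[0])
        for _ in range(iters):
            nv = A @ v
            norm = np.linalg.norm(nv)
            if norm == 0:
                return v / np.abs(v).max()
            v = nv / norm
        return v / v.max()

    def test_complete_graph_all_ones(self):
        net = _net_from_graph(nx.complete_graph(5))
        scores, top = hub_scores(net)
        assert all(s == pytest.approx(1.0) for s in scores.values())
        assert top == sorted(net.graph.nodes, key=str)

    def test_star_hand_eigenvector(self):
        g = nx.star_graph(3)  # center 0, leaves 1-3
        scores, top = hub_scores(_net_from_graph(g))
        assert scores[0] == pytest.approx(1.0)
        for leaf in (1, 2, 3):
            assert scores[leaf] == pytest.approx(1 / np.sqrt(3), abs=1e-9)
        assert top[0] == 0

    def test_matches_power_iteration_oracle(self, rng):
        for i in range(10):
            g = nx.gnp_random_graph(40, 0.15, seed=100 + i)
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_nodes() == 0:
                continue
            net = _net_from_graph(g)
            scores, _ = hub_scores(net)
            nodes = sorted(g.nodes, key=str)
            A = nx.to_numpy_array(g, nodelist=nodes)
            expected = self._power_iteration(A)
            got = np.array([scores[n] for n in nodes])
            np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_empty_network_rejected(self):
        with pytest.raises(RhizonetError):
            hub_scores(_net_from_graph(nx.Graph()))


def _metric_oracle(g):
    """Floyd-Warshall + exhaustive triple enumeration."""
    nodes = list(g.nodes)
    n = len(nodes)
    A = nx.to_numpy_array(g, nodelist=nodes)
    dist = floyd_warshall(A, unweighted=True, directed=False)
    finite = dist[np.isfinite(dist) & (dist > 0)]
    diameter = finite.max() if finite.size else np.nan
    apl = finite.mean() if finite.size else np.nan  # ordered pairs == unordered mean
    triangles = triples = 0
    for i, j, k in itertools.combinations(range(n), 3):
        e = A[i, j] + A[j, k] + A[i, k]
        if e == 3:
            triangles += 1
        if e >= 2:
            triples += sum(
                1
                for a, b, c in ((i, j, k), (j, i, k), (k, i, j))
                if A[b, a] and A[a, c]
            )
    transitivity = 3 * triangles / triples if triples else 0.0
    density = 2 * g.number_of_edges() / (n * (n - 1)) if n > 1 else np.nan
    return density, transitivity, diameter, apl


class TestNetworkMetrics:
    def test_complete_k4(self):
        m = network_metrics(_net_from_graph(nx.complete_graph(4)))
        assert (m.density, m.transitivity, m.diameter, m.average_path_length) == (
            1.0, 1.0, 1.0, 1.0
        )

    def test_path_p4(self):
        m = network_metrics(_net_from_graph(nx.path_graph(4)))
        assert m.density == pytest.approx(0.5)
        assert m.transitivity == 0.0
        assert m.diameter == 3.0
        assert m.average_path_length == pytest.approx(10 / 6)

    def test_disconnected_uses_reachable_pairs(self):
        g = nx.Graph([("a", "b"), ("c", "d"), ("d", "e")])
        m = network_metrics(_net_from_graph(g))
        assert m.n_components == 2
        assert m.diameter == 2.0
        assert m.average_path_length == pytest.approx((1 + 1 + 1 + 2) / 4)

    def test_matches_floyd_warshall_oracle_on_random_graphs(self):
        for i in range(15):
            g = nx.gnp_random_graph(30, 0.08, seed=i)
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_nodes() < 2:
                continue
            m = network_metrics(_net_from_graph(g))
            density, transitivity, diameter, apl = _metric_oracle(g)
            assert m.density == pytest.approx(density, abs=1e-12)
            assert m.transitivity == pytest.approx(transitivity, abs=1e-12)
            assert m.diameter == pytest.approx(diameter)
            assert m.average_path_length == pytest.approx(apl, abs=1e-12)

    def test_single_node_flagged_missing(self):
        g = nx.Graph()
        g.add_node("x")
        m = network_metrics(_net_from_graph(g))
        assert np.isnan(m.density) and np.isnan(m.average_path_length)


class TestNodeComposition:
    def test_single_phylum(self):
        g = nx.path_graph(3)
        tax = TaxonomyMap({i: ("Bacteria", "Proteobacteria") for i in g.nodes})
        comp = node_composition(_net_from_graph(g), tax)
        assert comp.to_dict() == {"Proteobacteria": 1.0}

    def test_two_phyla_fractions(self):
        g = nx.path_graph(3)
        tax = TaxonomyMap({0: ("B", "Proteo"), 1: ("B", "Proteo"), 2: ("B", "Acido")})
        comp = node_composition(_net_from_graph(g), tax)
        assert comp["Proteo"] == pytest.approx(2 / 3)
        assert comp["Acido"] == pytest.approx(1 / 3)

    def test_matches_brute_tally_with_missing_taxonomy(self, rng):
        g = nx.gnp_random_graph(20, 0.3, seed=3)
        phyla = ["A", "B", "C"]
        tax = TaxonomyMap({
            n: ("d", phyla[n % 3]) for n in list(g.nodes)[:15]  # 5 unclassified
        })
        comp = node_composition(_net_from_graph(g), tax)
        tally = {}
        for n in g.nodes:
            lab = tax.get_rank(n, "phylum")
            tally[lab] = tally.get(lab, 0) + 1
        for lab, cnt in tally.items():
            assert comp[lab] == pytest.approx(cnt / g.number_of_nodes())
        assert comp.sum() == pytest.approx(1.0)
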