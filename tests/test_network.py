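"""Correlation network construction and Newman modularity clustering.

Independent oracles: hand-sorted edge lists, exhaustive enumeration of
bisections/partitions on small graphs, and networkx's modularity function.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aeropower import (
    FeatureNetwork,
    ModularityClustering,
    build_network,
    cluster,
    correlation_matrix,
    modularity,
    modularity_from_labels,
    spectral_bisect,
)
from aeropower.errors import ConstantColumnError, DataValidationError


def graph(n, edges, weights=None):
    A = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else weights[k]
        A[i, j] = A[j, i] = w
    return FeatureNetwork([f"n{i}" for i in range(n)], A)


TRIANGLES = graph(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


class TestCorrelation:
    def test_shape_diagonal_symmetry(self, cohort20):
        corr = correlation_matrix(cohort20.features)
        assert corr.shape == (51, 51)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_monotone_transform_gives_rho_one(self, rng):
        x = rng.normal(size=30)
        frame = pd.DataFrame({"a": x, "b": np.exp(x), "c": rng.normal(size=30)})
        corr = correlation_matrix(frame)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_constant_column_named(self, rng):
        frame = pd.DataFrame({"a": rng.normal(size=10), "flat": np.ones(10)})
        with pytest.raises(ConstantColumnError) as err:
            correlation_matrix(frame)
        assert "flat" in err.value.columns

    def test_too_few_subjects(self, rng):
        frame = pd.DataFrame(rng.normal(size=(3, 4)))
        with pytest.raises(DataValidationError):
            correlation_matrix(frame)


class TestBuildNetwork:
    def test_six_features_keep_top_five_pairs(self, rng):
        # 6 features -> 15 pairs; top 30% -> ceil(4.5) = 5 edges
        X = pd.DataFrame(rng.normal(size=(40, 6)),
                         columns=[f"f{i}" for i in range(6)])
        corr = correlation_matrix(X)
        net = build_network(corr, top_fraction=0.30)
        assert net.n_edges == 5
        # they must be exactly the 5 largest |rho| (hand sort)
        C = corr.to_numpy()
        iu, ju = np.triu_indices(6, 1)
        top5 = sorted(np.abs(C[iu, ju]))[-5:]
        kept = sorted(w for _, _, w in net.edges())
        assert np.allclose(kept, top5)

    def test_full_fraction_gives_complete_graph(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 6)))
        X.columns = [f"f{i}" for i in range(6)]
        net = build_network(correlation_matrix(X), top_fraction=1.0)
        assert net.n_edges == 15

    def test_all_nodes_retained_even_if_isolated(self, cohort20):
        corr = correlation_matrix(cohort20.features)
        net = build_network(corr, top_fraction=0.05)
        assert net.n_nodes == 51

    def test_binary_mode(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 5)),
                         columns=[f"f{i}" for i in range(5)])
        net = build_network(correlation_matrix(X), top_fraction=0.5, weighted=False)
        weights = {w for _, _, w in net.edges()}
        assert weights == {1.0}


class TestModularity:
    def test_no_division_gives_zero(self):
        assert modularity(TRIANGLES, np.ones(6)) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_split_is_half(self):
        S = np.array([1, 1, 1, -1, -1, -1])
        assert modularity(TRIANGLES, S) == pytest.approx(0.5)

    def test_half_is_the_exhaustive_maximum(self):
        best = max(
            modularity(TRIANGLES, np.array((1,) + bits, dtype=float))
            for bits in itertools.product([1, -1], repeat=5)
        )
        assert best == pytest.approx(0.5)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 6 - 1))
    def test_sign_flip_invariance(self, bits):
        S = np.array([1 if bits >> k & 1 else -1 for k in range(6)], dtype=float)
        assert modularity(TRIANGLES, S) == pytest.approx(modularity(TRIANGLES, -S))

    def test_matches_networkx_on_labels(self, rng):
        import networkx as nx

        for rep in range(5):
            g = nx.gnp_random_graph(9, 0.5, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            A = nx.to_numpy_array(g)
            net = FeatureNetwork([f"n{i}" for i in range(9)], A)
            labels = rng.integers(0, 3, size=9)
            groups = [set(np.nonzero(labels == v)[0]) for v in range(3)]
            groups = [grp for grp in groups if grp]
            expected = nx.community.modularity(g, groups)
            assert modularity_from_labels(net, labels) == pytest.approx(expected)


class TestBisection:
    def test_complete_graph_indivisible(self):
        K4 = graph(4, list(itertools.combinations(range(4), 2)))
        S, dq = spectral_bisect(K4)
        assert dq == 0.0
        assert np.all(S == 1.0)

    def test_triangles_separate_components(self):
        S, dq = spectral_bisect(TRIANGLES)
        assert dq == pytest.approx(0.5)
        assert len({tuple(S[:3]), tuple(S[3:])}) == 2
        assert len(set(S[:3])) == 1 and len(set(S[3:])) == 1

    def test_matches_exhaustive_best_bisection(self):
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            n = int(rng.integers(4, 11))
            A = (rng.random((n, n)) < 0.4).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            if A.sum() == 0:
                A[0, 1] = A[1, 0] = 1.0
            net = FeatureNetwork([f"n{i}" for i in range(n)], A)
            best = max(
                modularity(net, np.array((1,) + bits, dtype=float))
                for bits in itertools.product([1, -1], repeat=n - 1)
            )
            _, dq = spectral_bisect(net)
            if best > 1e-12:
                assert dq >= 0.95 * best - 1e-12
            else:
                assert dq <= 1e-12


class TestCluster:
    def test_single_clique_one_group(self):
        K5 = graph(5, list(itertools.combinations(range(5), 2)))
        part = cluster(K5)
        assert part.n_groups == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_three_bridged_cliques_recover_three_groups(self):
        edges = []
        for blk in range(3):
            edges += list(itertools.combinations(range(4 * blk, 4 * blk + 4), 2))
        edges += [(3, 4), (7, 8), (11, 0)]
        net = graph(12, edges)
        part = cluster(net)
        assert part.n_groups == 3
        labels = part.labels
        for blk in range(3):
            assert len(set(labels[4 * blk: 4 * blk + 4])) == 1
        # oracle: exhaustive max modularity over partitions into <= 4 groups
        best = -np.inf
        for assign in itertools.product(range(3), repeat=11):
            lab = np.array((0,) + assign)
            best = max(best, modularity_from_labels(net, lab))
        assert part.q == pytest.approx(best, abs=1e-9)

    def test_q_equals_sum_of_accepted_dq(self, cohort20):
        corr = correlation_matrix(cohort20.features)
        net = build_network(corr, 0.30)
        part = cluster(net)
        accumulated = sum(t["dQ"] for t in part.tree if t["split"])
        assert part.q == pytest.approx(accumulated, abs=1e-9)
        assert 0.0 <= part.q <= 1.0

    def test_latent_factor_blocks_recovered_exactly(self):
        rng = np.random.default_rng(77)
        F = rng.standard_normal((200, 3))
        cols = {}
        truth = []
        for j in range(3):
            for k in range(5):
                cols[f"g{j}_{k}"] = 0.9 * F[:, j] + 0.1 * rng.standard_normal(200)
                truth.append(j)
        part = ModularityClustering(top_fraction=0.30).fit(pd.DataFrame(cols))
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, part.labels_) == 1.0

    def test_node_permutation_permutes_labels(self, rng):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
        net = graph(6, edges)
        part = cluster(net)
        perm = rng.permutation(6)
        A2 = net.adjacency[np.ix_(perm, perm)]
        net2 = FeatureNetwork([net.names[i] for i in perm], A2)
        part2 = cluster(net2)
        for a in range(6):
            for b in range(6):
                same1 = part.labels[perm[a]] == part.labels[perm[b]]
                same2 = part2.labels[a] == part2.labels[b]
                assert same1 == same2
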