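"""Spatial-level statistics: exact oracles, sign structure, determinism."""

import numpy as np
import pytest
import scipy.sparse as sp

import ssbench as sb
from ssbench.datamodel import NeighborGraph, ValidationError

from .conftest import random_labeled_graph
from .oracles import centralities_naive, moran_naive, transition_matrix_naive


def _chain_graph(n=4):
    A = np.zeros((n, n))
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 1
    return NeighborGraph(adjacency=sp.csr_matrix(A), method="chain")


def _labeled_ds(labels, coords=None, counts=None, props=None):
    n = len(labels)
    if coords is None:
        coords = np.column_stack([np.arange(n), np.zeros(n)])
    if counts is None:
        counts = np.ones((2, n))
    return sb.SpatialDataset(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        spot_ids=[f"s{i}" for i in range(n)],
        coords=coords,
        domains=np.asarray(labels),
        proportions=props,
    )


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        A = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (1, 3), (2, 3)]:  # rook adjacency
            A[i, j] = A[j, i] = 1
        graph = NeighborGraph(adjacency=sp.csr_matrix(A))
        values = np.array([1.0, -1.0, -1.0, 1.0])
        assert sb.morans_i(values, graph) == pytest.approx(-1.0, abs=1e-12)

    def test_smooth_gradient_strongly_positive(self):
        xs, ys = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
        coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        graph = sb.build_neighbor_graph(coords, k=4)
        assert sb.morans_i(coords[:, 0], graph) > 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        _, graph, _ = random_labeled_graph(rng)
        x = rng.normal(size=graph.n_spots)
        assert sb.morans_i(x, graph) == pytest.approx(
            moran_naive(x, graph.adjacency.toarray()), abs=1e-12
        )

    def test_constant_vector_returns_zero(self):
        graph = _chain_graph()
        with pytest.warns(UserWarning):
            assert sb.morans_i(np.ones(4), graph) == 0.0


class TestTransitionMatrix:
    def test_single_domain(self):
        ds = _labeled_ds(["A", "A", "A", "A"])
        tm, labels = sb.transition_matrix(ds, _chain_graph())
        np.testing.assert_array_equal(tm, [[1.0]])

    def test_chain_hand_enumeration(self):
        # ordered neighbor pairs: A-A 2, A-B 1, B-A 1, B-B 2
        ds = _labeled_ds(["A", "A", "B", "B"])
        tm, labels = sb.transition_matrix(ds, _chain_graph())
        np.testing.assert_allclose(tm[0], [2 / 3, 1 / 3])
        np.testing.assert_allclose(tm[1], [1 / 3, 2 / 3])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        _, graph, labels = random_labeled_graph(rng, k_domains=3)
        ds = _labeled_ds(labels, coords=np.zeros((len(labels), 2)))
        tm, _ = sb.transition_matrix(ds, graph)
        expected, _ = transition_matrix_naive(labels, graph.adjacency.toarray())
        np.testing.assert_allclose(tm, expected, atol=1e-12)
        np.testing.assert_allclose(tm.sum(axis=1), 1.0, atol=1e-9)


class TestNeighborhoodEnrichment:
    def test_segregated_bands_have_positive_diagonal(self, band_ds, band_graph):
        ds, _ = band_ds
        nem, _ = sb.neighborhood_enrichment(ds, band_graph, n_perm=200, seed=0)
        assert (np.diag(nem) > 0).all()
        off = nem[~np.eye(nem.shape[0], dtype=bool)]
        assert (off < 0).all()

    def test_random_labels_give_moderate_z(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 10, size=(60, 2))
        graph = sb.build_neighbor_graph(coords, k=4)
        ds = _labeled_ds(rng.integers(0, 3, size=60), coords=coords)
        nem, _ = sb.neighborhood_enrichment(ds, graph, n_perm=1000, seed=1)
        assert np.abs(nem).max() < 4

    def test_seeded_determinism(self, small_ds, small_graph):
        ds, _ = small_ds
        a, _ = sb.neighborhood_enrichment(ds, small_graph, n_perm=100, seed=9)
        b, _ = sb.neighborhood_enrichment(ds, small_graph, n_perm=100, seed=9)
        np.testing.assert_array_equal(a, b)


class TestCentralityScores:
    def test_chain_group_degree(self):
        ds = _labeled_ds(["A", "A", "B", "B"])
        csm, labels = sb.centrality_scores(ds, _chain_graph())
        assert csm[labels.index("A"), 0] == pytest.approx(0.5)

    def test_triangle_free_graph_has_zero_clustering(self):
        ds = _labeled_ds(["A", "A", "B", "B"])
        csm, _ = sb.centrality_scores(ds, _chain_graph())
        np.testing.assert_array_equal(csm[:, 1], [0.0, 0.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        _, graph, labels = random_labeled_graph(rng, k_domains=3)
        ds = _labeled_ds(labels, coords=np.zeros((len(labels), 2)))
        csm, _ = sb.centrality_scores(ds, graph)
        expected, _ = centralities_naive(labels, graph.adjacency.toarray())
        np.testing.assert_allclose(csm, expected, atol=1e-12)

    def test_all_singleton_domains_rejected(self):
        ds = _labeled_ds(["A", "B", "C", "D"])
        with pytest.raises(ValidationError):
            sb.centrality_scores(ds, _chain_graph())


class TestNnCorrelation:
    def test_duplicated_nearest_neighbors_correlate_perfectly(self):
        rng = np.random.default_rng(4)
        base = rng.integers(1, 30, size=(10, 6)).astype(float)
        # each spot duplicated at distance 0.01; nearest neighbor = twin
        counts = np.repeat(base, 2, axis=1)
        coords = np.repeat(rng.uniform(0, 10, size=(6, 2)), 2, axis=0)
        coords[1::2] += 0.01
        ds = sb.SpatialDataset(
            counts=counts,
            gene_ids=[f"g{i}" for i in range(10)],
            spot_ids=[f"s{i}" for i in range(12)],
            coords=coords,
        )
        out = sb.nn_correlation(ds)
        np.testing.assert_allclose(out.values, 1.0, atol=1e-12)

    def test_iid_noise_has_near_zero_mean_correlation(self):
        rng = np.random.default_rng(5)
        n = 1024
        counts = rng.poisson(5, size=(50, n))
        ds = sb.SpatialDataset(
            counts=counts,
            gene_ids=[f"g{i}" for i in range(50)],
            spot_ids=[f"s{i}" for i in range(n)],
            coords=rng.uniform(0, 32, size=(n, 2)),
        )
        out = sb.nn_correlation(ds)
        assert abs(out.values.mean()) < 0.1

    def test_matches_direct_correlation_oracle(self, small_ds):
        from .oracles import pearson_naive

        ds, _ = small_ds
        out = sb.nn_correlation(ds)
        expr = sb.dataset_log2cpm(ds)
        d = np.sqrt(
            ((ds.coords[:, None] - ds.coords[None]) ** 2).sum(-1)
        )
        np.fill_diagonal(d, np.inf)
        nn = d.argmin(axis=1)
        kept = [g for g in range(ds.n_genes) if expr[g].std() > 0]
        expected = [pearson_naive(expr[g], expr[g][nn]) for g in kept]
        np.testing.assert_allclose(out.values, expected, atol=1e-9)


class TestCelltypeInteraction:
    def test_single_type_is_unity(self):
        ds = _labeled_ds(
            ["A"] * 4, props=np.ones((4, 1))
        )
        out = sb.celltype_interaction(ds, _chain_graph())
        np.testing.assert_allclose(out.values, [1.0])

    def test_segregated_types_interact_less_across(self):
        labels = ["A"] * 8 + ["B"] * 8
        props = np.zeros((16, 2))
        props[:8, 0] = 1.0
        props[8:, 1] = 1.0
        coords = np.column_stack([np.arange(16), np.zeros(16)])
        ds = _labeled_ds(labels, coords=coords, props=props)
        graph = sb.build_neighbor_graph(coords, k=2)
        out = sb.celltype_interaction(ds, graph)
        same = [out.values[0], out.values[2]]  # (A,A), (B,B)
        cross = out.values[1]  # (A,B)
        assert cross < min(same)

    def test_matches_bruteforce_pair_sum(self, small_ds, small_graph):
        ds, _ = small_ds
        out = sb.celltype_interaction(ds, small_graph)
        P = ds.proportions.to_numpy()
        W = small_graph.adjacency.toarray()
        T = P.shape[1]
        expected = []
        for a in range(T):
            for b in range(a, T):
                s = sum(
                    W[i, j] * P[i, a] * P[j, b]
                    for i in range(ds.n_spots)
                    for j in range(ds.n_spots)
                )
                expected.append(s / W.sum())
        np.testing.assert_allclose(out.values, expected, atol=1e-12)


class TestLStatistic:
    def test_output_shape(self, small_ds):
        ds, _ = small_ds
        radii = [1.0, 2.0, 3.0]
        out = sb.l_statistic(ds, radii)
        n_types = ds.proportions.shape[1]
        assert len(out) == (n_types * (n_types + 1) // 2) * 3

    def test_csr_tracks_identity(self):
        rng = np.random.default_rng(0)
        n = 1000
        coords = rng.uniform(0, 1, size=(n, 2))
        ds = sb.SpatialDataset(
            counts=np.ones((3, n)),
            gene_ids=["a", "b", "c"],
            spot_ids=[f"s{i}" for i in range(n)],
            coords=coords,
            proportions=np.full((n, 2), 0.5),
        )
        radii = np.array([0.05, 0.08, 0.10])
        L = sb.l_statistic(ds, radii).values.reshape(3, 3)
        np.testing.assert_allclose(L, np.tile(radii, (3, 1)), rtol=0.15)

    def test_colocated_type_exceeds_csr(self):
        rng = np.random.default_rng(1)
        n = 400
        coords = rng.uniform(0, 1, size=(n, 2))
        props = np.full((n, 2), 0.5)
        clustered = (coords[:, 0] < 0.3) & (coords[:, 1] < 0.3)
        props[clustered] = [0.95, 0.05]
        props[~clustered] = [0.05, 0.95]
        ds = sb.SpatialDataset(
            counts=np.ones((2, n)),
            gene_ids=["a", "b"],
            spot_ids=[f"s{i}" for i in range(n)],
            coords=coords,
            proportions=props,
        )
        r = 0.1
        L = sb.l_statistic(ds, [r]).values  # pairs (0,0), (0,1), (1,1)
        assert L[0] > 1.2 * r  # co-located type above the CSR line


def test_domain_relabeling_permutes_matrices(small_ds, small_graph):
    ds, _ = small_ds
    tm, labels = sb.transition_matrix(ds, small_graph)
    swapped = sb.SpatialDataset(
        counts=ds.counts,
        gene_ids=ds.gene_ids,
        spot_ids=ds.spot_ids,
        coords=ds.coords,
        domains=np.where(ds.domains == 0, "z", "a"),
    )
    tm2, labels2 = sb.transition_matrix(swapped, small_graph)
    assert labels2 == ["a", "z"]  # old domain 1 first
    np.testing.assert_allclose(tm2, tm[::-1, ::-1])
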