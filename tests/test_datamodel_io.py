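"""Container validation, file round-trips, preprocessing and graph building."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import ssbench as sb
from ssbench.datamodel import DimensionMismatchError, ValidationError

from .oracles import moran_naive


def _toy_dataset(n_genes=3, n_spots=4, seed=0):
    rng = np.random.default_rng(seed)
    return sb.SpatialDataset(
        counts=rng.integers(0, 20, size=(n_genes, n_spots)),
        gene_ids=[f"g{i}" for i in range(n_genes)],
        spot_ids=[f"s{i}" for i in range(n_spots)],
        coords=rng.uniform(size=(n_spots, 2)),
    )


class TestSpatialDataset:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValidationError):
            sb.SpatialDataset(
                counts=np.array([[1, -1]]),
                gene_ids=["g"],
                spot_ids=["a", "b"],
                coords=np.zeros((2, 2)),
            )

    def test_rejects_mismatched_coords(self):
        with pytest.raises(DimensionMismatchError):
            sb.SpatialDataset(
                counts=np.ones((2, 3)),
                gene_ids=["a", "b"],
                spot_ids=["s1", "s2", "s3"],
                coords=np.zeros((2, 2)),
            )

    def test_rejects_unnormalized_proportions(self):
        with pytest.raises(ValidationError):
            sb.SpatialDataset(
                counts=np.ones((1, 2)),
                gene_ids=["g"],
                spot_ids=["a", "b"],
                coords=np.zeros((2, 2)),
                proportions=np.array([[0.5, 0.6], [0.5, 0.5]]),
            )

    def test_duplicate_spot_ids_rejected(self):
        with pytest.raises(ValidationError):
            sb.SpatialDataset(
                counts=np.ones((1, 2)),
                gene_ids=["g"],
                spot_ids=["a", "a"],
                coords=np.zeros((2, 2)),
            )


class TestRoundTrip:
    def test_read_back_identity(self, tmp_path):
        ds = _toy_dataset()
        ds.domains = np.array(["A", "A", "B", "B"])
        sb.write_spatial_dataset(ds, tmp_path / "d")
        back = sb.read_dataset_dir(tmp_path / "d")
        np.testing.assert_array_equal(back.counts, ds.counts)
        assert back.gene_ids == ds.gene_ids
        assert back.spot_ids == ds.spot_ids
        np.testing.assert_allclose(back.coords, ds.coords)
        assert list(back.domains) == list(ds.domains)

    def test_write_read_write_is_byte_stable(self, tmp_path):
        ds = _toy_dataset(n_genes=5, n_spots=7, seed=3)
        sb.write_spatial_dataset(ds, tmp_path / "a")
        back = sb.read_dataset_dir(tmp_path / "a")
        sb.write_spatial_dataset(back, tmp_path / "b")
        for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv", "coords.csv"):
            assert (tmp_path / "a" / fname).read_bytes() == (
                tmp_path / "b" / fname
            ).read_bytes()

    def test_missing_coordinate_row_raises(self, tmp_path):
        ds = _toy_dataset()
        sb.write_spatial_dataset(ds, tmp_path / "d")
        coords = pd.read_csv(tmp_path / "d" / "coords.csv").iloc[:-1]
        coords.to_csv(tmp_path / "d" / "coords.csv", index=False)
        with pytest.raises(DimensionMismatchError):
            sb.read_dataset_dir(tmp_path / "d")


class TestQcFilter:
    def _ref(self, counts, genes):
        return sb.SingleCellReference(
            counts=counts,
            gene_ids=genes,
            cell_ids=[f"c{i}" for i in range(counts.shape[1])],
            cell_types=np.array(["t"] * counts.shape[1]),
        )

    def test_feature_count_boundaries(self):
        n_genes = 2600
        genes = [f"g{i}" for i in range(n_genes)]
        counts = np.zeros((n_genes, 3))
        counts[:2501, 0] = 1  # 2501 detected features -> removed
        counts[:2500, 1] = 1  # 2500 -> retained
        counts[:1000, 2] = 1  # interior -> retained
        out, tally = sb.qc_filter_cells(self._ref(counts, genes))
        assert out.cell_ids == ["c1", "c2"]
        assert tally["high_features"] == 1

    def test_mito_fraction_boundary(self):
        genes = ["MT-1"] + [f"g{i}" for i in range(300)]
        counts = np.zeros((301, 2))
        counts[1:251, :] = 1  # 250 features each
        counts[0, 0] = 20  # 20/270 > 5% -> removed
        counts[0, 1] = 13  # 13/263 < 5% -> retained
        out, tally = sb.qc_filter_cells(self._ref(counts, genes))
        assert out.cell_ids == ["c1"]
        assert tally["high_mito"] == 1

    def test_matches_bruteforce_predicates(self):
        rng = np.random.default_rng(5)
        n_genes = 3000
        genes = ["MT-a", "MT-b"] + [f"g{i}" for i in range(n_genes - 2)]
        counts = np.zeros((n_genes, 100))
        for c in range(100):
            k = int(rng.integers(50, 2800))
            rows = rng.choice(n_genes, size=k, replace=False)
            counts[rows, c] = rng.integers(1, 5, size=k)
        ref = self._ref(counts, genes)
        out, _ = sb.qc_filter_cells(ref)
        expected = []
        for c in range(100):
            feats = int((counts[:, c] > 0).sum())
            mito = counts[:2, c].sum() / counts[:, c].sum()
            if 200 <= feats <= 2500 and mito <= 0.05:
                expected.append(f"c{c}")
        assert out.cell_ids == expected

    def test_empty_result_raises(self):
        counts = np.ones((10, 2))  # 10 features < 200
        with pytest.raises(ValidationError):
            sb.qc_filter_cells(self._ref(counts, [f"g{i}" for i in range(10)]))


class TestLog2Cpm:
    def test_single_gene_closed_form(self):
        out = sb.log2cpm(np.full((1, 4), 7.0))
        np.testing.assert_allclose(out, np.log2(1e6 + 1))

    def test_depth_scaling_invariance(self):
        counts = np.random.default_rng(0).integers(1, 30, size=(10, 5)).astype(float)
        scaled = counts.copy()
        scaled[:, 2] *= 2
        np.testing.assert_allclose(
            sb.log2cpm(counts)[:, 2], sb.log2cpm(scaled)[:, 2]
        )

    def test_elementwise_hand_evaluation(self):
        counts = np.array([[1.0, 0.0, 2.0], [3.0, 5.0, 0.0], [0.0, 1.0, 4.0]])
        out = sb.log2cpm(counts)
        libs = counts.sum(axis=0)
        for g in range(3):
            for k in range(3):
                assert out[g, k] == pytest.approx(
                    np.log2(1e6 * counts[g, k] / libs[k] + 1), abs=1e-12
                )

    def test_zero_library_spot_named(self):
        counts = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValidationError, match="s1"):
            sb.log2cpm(counts, spot_ids=["s0", "s1"])


class TestSelectGenes:
    def test_small_dataset_unchanged(self, small_ds, small_graph):
        ds, _ = small_ds
        assert sb.select_genes(ds, small_graph, max_genes=1000) is ds

    def test_caps_gene_count(self):
        cfg = sb.SyntheticConfig(n_spots_side=8, n_genes=120, n_domains=2, seed=2)
        ds, _ = sb.generate_dataset(cfg, with_proportions=False)
        graph = sb.build_neighbor_graph(ds.coords)
        out = sb.select_genes(ds, graph, max_genes=50)
        assert out.n_genes == 50

    def test_matches_moran_ranking_oracle(self):
        cfg = sb.SyntheticConfig(n_spots_side=6, n_genes=30, n_domains=2, seed=3)
        ds, _ = sb.generate_dataset(cfg, with_proportions=False)
        graph = sb.build_neighbor_graph(ds.coords)
        out = sb.select_genes(ds, graph, max_genes=10)
        W = graph.adjacency.toarray()
        expr = sb.dataset_log2cpm(ds)
        scores = [moran_naive(expr[g], W) for g in range(ds.n_genes)]
        order = sorted(
            range(ds.n_genes), key=lambda i: (-scores[i], ds.gene_ids[i])
        )
        expected = sorted(order[:10])
        assert out.gene_ids == [ds.gene_ids[i] for i in expected]

    def test_idempotent(self):
        cfg = sb.SyntheticConfig(n_spots_side=6, n_genes=40, n_domains=2, seed=4)
        ds, _ = sb.generate_dataset(cfg, with_proportions=False)
        graph = sb.build_neighbor_graph(ds.coords)
        once = sb.select_genes(ds, graph, max_genes=15)
        twice = sb.select_genes(once, graph, max_genes=15)
        assert twice.gene_ids == once.gene_ids
        np.testing.assert_array_equal(twice.counts, once.counts)


class TestNeighborGraph:
    def test_unit_square_k1(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        graph = sb.build_neighbor_graph(coords, k=1)
        # each spot picks one unit-distance neighbor, ties to the lower
        # index: 0->1, 1->0, 2->0, 3->1; union symmetrization gives the
        # ordered edges {0-1, 0-2, 1-3}, hence W = 6
        assert graph.total_weight == 6.0
        A = graph.adjacency.toarray()
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert all(d[i, j] == 1.0 for i, j in zip(*np.nonzero(A)))

    def test_chain_k1(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        graph = sb.build_neighbor_graph(coords, k=1)
        A = graph.adjacency.toarray()
        expected = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            expected[i, j] = expected[j, i] = 1
        np.testing.assert_array_equal(A, expected)

    def test_matches_bruteforce_knn(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(size=(25, 2))
        k = 4
        graph = sb.build_neighbor_graph(coords, k=k)
        expected = np.zeros((25, 25))
        for i in range(25):
            d = np.sqrt(((coords - coords[i]) ** 2).sum(1))
            d[i] = np.inf
            for j in np.argsort(d)[:k]:
                expected[i, j] = expected[j, i] = 1
        np.testing.assert_array_equal(graph.adjacency.toarray(), expected)

    def test_k_too_large_raises(self):
        with pytest.raises(ValidationError):
            sb.build_neighbor_graph(np.zeros((3, 2)) + np.arange(3)[:, None], k=3)

    def test_delaunay_duplicate_coords_raise(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValidationError):
            sb.build_neighbor_graph(coords, method="delaunay")

    @given(
        coords=arrays(
            float,
            st.tuples(st.integers(5, 15), st.just(2)),
            elements=st.floats(0, 100, allow_nan=False),
        )
    )
    def test_symmetry_and_zero_diagonal(self, coords):
        coords = coords + 1e-6 * np.arange(coords.shape[0])[:, None]
        graph = sb.build_neighbor_graph(coords, k=2)
        A = graph.adjacency.toarray()
        np.testing.assert_array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)
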