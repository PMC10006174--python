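"""Landmark hierarchy contracts: kNN oracles, influence stochasticity,
weight conservation, embedding determinism and drill-down recovery."""

import numpy as np
import pytest
import scipy.sparse as sp

import pixplore as px
from pixplore.hierarchy import (
    csr_row_argmax,
    drill_down_indices,
    load_hierarchy,
    save_hierarchy,
)
from pixplore.preprocess import PixelTable


def _table_from_values(values):
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[1] == 1 and values.ndim == 2 and values.shape[0] > 1:
        pass
    n = values.shape[0]
    coords = np.column_stack([np.arange(n), np.zeros(n, int)])
    markers = [f"m{i}" for i in range(values.shape[1])]
    return PixelTable(values=values, coords=coords, marker_names=markers)


class TestKnnGraph:
    def test_collinear_points_nearest_neighbor(self):
        table = _table_from_values([[0.0], [1.0], [10.0]])
        graph = px.build_knn_graph(table, k=1)
        assert graph.neighbors[:, 0].tolist() == [1, 0, 1]

    def test_k_equals_n_minus_one_is_complete_digraph(self):
        table = _table_from_values([[0.0], [1.0], [3.0], [7.0]])
        graph = px.build_knn_graph(table, k=3)
        for i in range(4):
            assert sorted(graph.neighbors[i]) == sorted(set(range(4)) - {i})

    def test_duplicate_rows_yield_zero_distance_but_no_self_edge(self):
        table = _table_from_values([[2.0], [2.0], [5.0]])
        graph = px.build_knn_graph(table, k=2)
        assert np.all(graph.neighbors != np.arange(3)[:, None])
        assert graph.dists[0, 0] == 0.0

    def test_oversized_k_clamped_with_warning(self, caplog):
        table = _table_from_values([[0.0], [1.0], [2.0]])
        with caplog.at_level("WARNING", logger="pixplore"):
            graph = px.build_knn_graph(table, k=10)
        assert graph.k == 2
        assert any("clamp" in r.message for r in caplog.records)

    def test_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(40, 3))
        table = _table_from_values(values)
        graph = px.build_knn_graph(table, k=5)
        d = np.linalg.norm(values[:, None] - values[None], axis=2)
        np.fill_diagonal(d, np.inf)
        for i in range(40):
            expected = np.sort(d[i])[:5]
            assert np.allclose(np.sort(graph.dists[i]), expected)


class TestBuildHierarchy:
    def test_single_scale_is_identity(self, two_blob_table):
        table, _ = two_blob_table
        graph = px.build_knn_graph(table, k=5)
        h = px.build_hierarchy(graph, n_scales=1, seed=0)
        assert h.n_scales == 1
        assert (h.scales[0].influence != sp.identity(table.n_pixels)).nnz == 0

    def test_landmarks_cover_both_blobs_with_little_cross_influence(
        self, two_blob_hierarchy
    ):
        h, labels = two_blob_hierarchy
        lm_labels = labels[h.scales[1].landmark_indices]
        assert {0, 1} <= set(lm_labels.tolist())
        C = h.cumulative_influence(1).toarray()
        for blob in (0, 1):
            mass = C[labels == blob][:, lm_labels != blob].sum()
            total = C[labels == blob].sum()
            assert mass / total < 0.05

    def test_influence_rows_stochastic_and_weights_conserved(
        self, two_blob_hierarchy
    ):
        h, _ = two_blob_hierarchy
        n = h.table.n_pixels
        for s in range(h.n_scales):
            rowsums = np.asarray(h.scales[s].influence.sum(axis=1)).ravel()
            assert np.all(np.abs(rowsums - 1) <= 1e-6)
            assert h.scales[s].landmark_weight.sum() == pytest.approx(n, abs=1e-3)
            assert np.all(h.scales[s].landmark_weight > 0)

    def test_landmark_counts_strictly_decrease_and_nest(self, two_blob_hierarchy):
        h, _ = two_blob_hierarchy
        counts = [h.n_points(s) for s in range(h.n_scales)]
        assert counts == sorted(counts, reverse=True)
        assert len(set(counts)) == len(counts)
        for s in range(1, h.n_scales):
            idx = h.scales[s].landmark_indices
            assert idx.min() >= 0 and idx.max() < h.n_points(s - 1)

    def test_composed_influence_is_row_stochastic(self, two_blob_hierarchy):
        h, _ = two_blob_hierarchy
        top = h.n_scales - 1
        rowsums = np.asarray(h.cumulative_influence(top).sum(axis=1)).ravel()
        assert np.all(np.abs(rowsums - 1) <= 1e-6)

    def test_identical_seed_reproduces_hierarchy(self, two_blob_table):
        table, _ = two_blob_table
        graph = px.build_knn_graph(table, k=10)
        h1 = px.build_hierarchy(graph, n_scales=2, seed=5)
        h2 = px.build_hierarchy(graph, n_scales=2, seed=5)
        assert np.array_equal(
            h1.scales[1].landmark_indices, h2.scales[1].landmark_indices
        )
        assert (h1.scales[1].influence != h2.scales[1].influence).nnz == 0

    def test_truncates_when_landmarks_too_few(self, caplog):
        rng = np.random.default_rng(1)
        table = _table_from_values(rng.normal(size=(30, 2)))
        graph = px.build_knn_graph(table, k=5)
        with caplog.at_level("WARNING", logger="pixplore"):
            h = px.build_hierarchy(graph, n_scales=6, seed=0)
        assert h.n_scales < 6


class TestEmbedScale:
    def test_fixed_seed_bitwise_deterministic(self, two_blob_hierarchy):
        h, _ = two_blob_hierarchy
        params = px.EmbedParams(n_iter=120, early_iter=60)
        e1 = px.embed_scale(h, 1, params=params, seed=7)
        e2 = px.embed_scale(h, 1, params=params, seed=7)
        assert np.array_equal(e1.points, e2.points)

    def test_single_point_scale_returns_origin(self):
        table = _table_from_values([[1.0]])
        graph = px.build_knn_graph(table, k=1)
        h = px.build_hierarchy(graph, n_scales=1, seed=0)
        emb = px.embed_scale(h, 0, seed=0)
        assert emb.points.shape == (1, 2)

    def test_separated_classes_form_silhouette_clusters(self, two_blob_hierarchy):
        from sklearn.metrics import silhouette_score

        h, labels = two_blob_hierarchy
        emb = px.embed_scale(h, 1, seed=7)
        lm_labels = labels[h.scales[1].landmark_indices]
        assert silhouette_score(emb.points, lm_labels) > 0.5

    def test_unknown_scale_rejected(self, two_blob_hierarchy):
        h, _ = two_blob_hierarchy
        with pytest.raises(IndexError, match="scale"):
            px.embed_scale(h, 5, seed=0)


class TestDrillDown:
    def test_select_all_returns_every_pixel(self, two_blob_hierarchy):
        h, _ = two_blob_hierarchy
        table = px.drill_down(h, 1, range(h.n_points(1)))
        assert table.n_pixels == h.table.n_pixels

    def test_single_blob_selection_is_pure(self, two_blob_hierarchy):
        h, labels = two_blob_hierarchy
        lm_labels = labels[h.scales[1].landmark_indices]
        sel = np.flatnonzero(lm_labels == 0)
        idx = drill_down_indices(h, 1, sel)
        assert idx.size > 0
        assert (labels[idx] == 0).mean() >= 0.95

    def test_identity_hierarchy_single_landmark_selects_that_pixel(self):
        table = _table_from_values([[0.0], [4.0], [9.0]])
        graph = px.build_knn_graph(table, k=1)
        h = px.build_hierarchy(graph, n_scales=1, seed=0)
        sub = px.drill_down(h, 0, [1])
        assert sub.n_pixels == 1
        assert np.array_equal(sub.values, table.values[[1]])

    def test_empty_selection_rejected(self, two_blob_hierarchy):
        h, _ = two_blob_hierarchy
        with pytest.raises(ValueError, match="empty"):
            px.drill_down(h, 1, [])

    def test_partition_of_landmarks_partitions_pixels(self, two_blob_hierarchy):
        h, _ = two_blob_hierarchy
        n_land = h.n_points(1)
        part_a = list(range(n_land // 2))
        part_b = list(range(n_land // 2, n_land))
        ia = set(drill_down_indices(h, 1, part_a).tolist())
        ib = set(drill_down_indices(h, 1, part_b).tolist())
        assert ia.isdisjoint(ib)
        assert ia | ib == set(range(h.table.n_pixels))


class TestSerialization:
    def test_roundtrip(self, two_blob_hierarchy, tmp_path):
        h, _ = two_blob_hierarchy
        save_hierarchy(tmp_path / "h.npz", h, config_hash="abc")
        back, chash = load_hierarchy(tmp_path / "h.npz")
        assert chash == "abc"
        assert back.n_scales == h.n_scales
        assert np.array_equal(back.table.values, h.table.values)
        for s in range(h.n_scales):
            assert (back.scales[s].influence != h.scales[s].influence).nnz == 0
            assert np.array_equal(
                back.scales[s].landmark_weight, h.scales[s].landmark_weight
            )


def test_csr_row_argmax_breaks_ties_toward_lowest_column():
    A = sp.csr_matrix(np.array([[0.2, 0.5, 0.5], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]))
    assert csr_row_argmax(A).tolist() == [1, -1, 0]
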