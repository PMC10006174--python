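"""Gating contracts: mean-shift modes, label expansion, signature naming."""

import numpy as np
import pytest
import scipy.sparse as sp

import pixplore as px
from pixplore.gating import DEFAULT_SIGNATURES
from pixplore.hierarchy import EmbedParams, Embedding, csr_row_argmax


def _embedding(points, weights=None):
    points = np.asarray(points, float)
    return Embedding(
        points=points,
        scale=0,
        seed=0,
        params=EmbedParams(),
        weights=weights if weights is not None else np.ones(len(points)),
    )


class TestClusterEmbedding:
    def test_two_separated_blobs_give_two_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.normal([0, 0], 1.0, size=(40, 2))
        b = rng.normal([100, 100], 1.0, size=(40, 2))
        labels = px.cluster_embedding(_embedding(np.vstack([a, b])))
        assert labels.n_clusters == 2
        assert len(set(labels.labels[:40])) == 1
        assert len(set(labels.labels[40:])) == 1
        assert labels.labels[0] != labels.labels[40]

    def test_single_point_single_cluster(self):
        labels = px.cluster_embedding(_embedding([[3.0, 4.0]]))
        assert labels.n_clusters == 1

    def test_bandwidth_above_diameter_merges_everything(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(30, 2))
        labels = px.cluster_embedding(_embedding(pts), bandwidth=100.0)
        assert labels.n_clusters == 1

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            px.cluster_embedding(_embedding([[0, 0], [1, 1]]), bandwidth=0.0)

    def test_partition_invariant_to_point_order(self):
        rng = np.random.default_rng(2)
        pts = np.vstack(
            [rng.normal([0, 0], 1, (25, 2)), rng.normal([50, 0], 1, (25, 2))]
        )
        perm = rng.permutation(len(pts))
        l1 = px.cluster_embedding(_embedding(pts)).labels
        l2 = px.cluster_embedding(_embedding(pts[perm])).labels
        # same partition: co-membership must agree under the permutation
        co1 = l1[:, None] == l1[None, :]
        co2 = l2[:, None] == l2[None, :]
        inv = np.argsort(perm)
        assert np.array_equal(co1, co2[inv][:, inv])

    def test_heavy_weight_attracts_mode(self):
        # one heavy landmark and a light satellite merge onto the heavy side
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        labels = px.cluster_embedding(
            _embedding(pts, weights=np.array([100.0, 1.0])), bandwidth=1.5
        )
        assert labels.n_clusters == 1


class TestExpandToPixels:
    def test_identity_hierarchy_is_passthrough(self, two_blob_table):
        table, labels = two_blob_table
        graph = px.build_knn_graph(table, k=5)
        h = px.build_hierarchy(graph, n_scales=1, seed=0)
        cl = px.ClusterLabels(labels=labels, n_clusters=2)
        labeling = px.expand_to_pixels(h, 0, cl)
        back = labeling.label_map[table.coords[:, 0], table.coords[:, 1]]
        assert np.array_equal(back, labels + 1)

    def test_every_pixel_gets_one_label_or_background(self, two_blob_hierarchy):
        h, labels = two_blob_hierarchy
        lm_labels = labels[h.scales[1].landmark_indices]
        cl = px.ClusterLabels(labels=lm_labels, n_clusters=2)
        labeling = px.expand_to_pixels(h, 1, cl)
        values = labeling.label_map[h.table.coords[:, 0], h.table.coords[:, 1]]
        assert set(np.unique(values)) <= {0, 1, 2}

    def test_expansion_recovers_blob_membership(self, two_band):
        spec, stack, gt = two_band
        table = px.flatten(stack)
        graph = px.build_knn_graph(table, k=10)
        h = px.build_hierarchy(graph, n_scales=2, seed=3)
        truth = gt.label_map[table.coords[:, 0], table.coords[:, 1]] - 1
        lm_labels = truth[h.scales[1].landmark_indices]
        cl = px.ClusterLabels(labels=lm_labels, n_clusters=2)
        labeling = px.expand_to_pixels(h, 1, cl, shape=spec.shape)
        agree = (labeling.label_map == gt.label_map).mean()
        assert agree >= 0.95

    def test_matches_direct_argmax_of_composed_influence(self, two_blob_hierarchy):
        # oracle: explicit dense matrix product of the per-scale influences
        h, labels = two_blob_hierarchy
        dense = np.asarray(h.scales[0].influence.todense())
        for s in range(1, h.n_scales):
            dense = dense @ np.asarray(h.scales[s].influence.todense())
        oracle = np.where(dense.sum(axis=1) > 0, dense.argmax(axis=1), -1)
        assert np.array_equal(h.pixel_assignments(h.n_scales - 1), oracle)

    def test_label_count_mismatch_rejected(self, two_blob_hierarchy):
        h, _ = two_blob_hierarchy
        cl = px.ClusterLabels(labels=np.zeros(3, int), n_clusters=1)
        with pytest.raises(ValueError, match="landmarks"):
            px.expand_to_pixels(h, 1, cl)


class TestAssignCellTypes:
    @pytest.fixture
    def typed_scene(self, quadrant_image):
        from conftest import QUADRANT_SIGNATURES

        spec, stack, gt = quadrant_image
        table = px.flatten(stack)
        labeling = px.PixelClusterLabeling(
            label_map=gt.label_map,
            class_names={i + 1: f"cluster {i}" for i in range(4)},
        )
        return table, labeling, QUADRANT_SIGNATURES

    def test_marker_positive_clusters_named_from_signatures(self, typed_scene):
        table, labeling, signatures = typed_scene
        named = px.assign_cell_types(labeling, table, signatures)
        assert set(named.class_names.values()) == {
            "T cell",
            "B cell",
            "macrophage",
            "epithelium",
        }

    def test_unmatched_cluster_kept_as_unassigned(self, typed_scene):
        table, labeling, _ = typed_scene
        sigs = px.SignatureTable(
            [px.Signature("T cell", positive=("CD3", "CD7"))]
        )
        named = px.assign_cell_types(labeling, table, sigs)
        assert "unassigned" in named.class_names.values()
        assert "T cell" in named.class_names.values()
        # unassigned pixels are retained, not dropped
        assert (named.label_map > 0).sum() == (labeling.label_map > 0).sum()

    def test_first_matching_signature_wins_with_warning(self, typed_scene, caplog):
        table, labeling, _ = typed_scene
        sigs = px.SignatureTable(
            [
                px.Signature("lymphoid", positive=("CD7",)),
                px.Signature("T cell", positive=("CD3", "CD7")),
            ]
        )
        with caplog.at_level("WARNING", logger="pixplore"):
            named = px.assign_cell_types(labeling, table, sigs)
        assert "lymphoid" in named.class_names.values()
        assert "T cell" not in named.class_names.values()
        assert any("first match" in r.message for r in caplog.records)

    def test_unknown_signature_marker_rejected(self, typed_scene):
        table, labeling, _ = typed_scene
        sigs = px.SignatureTable([px.Signature("x", positive=("CD999",))])
        with pytest.raises(ValueError, match="CD999"):
            px.assign_cell_types(labeling, table, sigs)


class TestMarkerGate:
    def test_modes_partition_consistently(self, quadrant_image):
        _, stack, _ = quadrant_image
        table = px.flatten(stack)
        pos = px.marker_gate(table, "CD3", "positive")
        dim = px.marker_gate(table, "CD3", "dim")
        either = px.marker_gate(table, "CD3", "positive_or_dim")
        assert not np.any(pos & dim)
        assert np.array_equal(either, pos | dim)

    def test_positive_gate_enriches_true_class(self, quadrant_image):
        _, stack, gt = quadrant_image
        table = px.flatten(stack)
        pos = px.marker_gate(table, "E-cadherin", "positive")
        truth = gt.class_mask("epithelium")[
            table.coords[:, 0], table.coords[:, 1]
        ]
        assert truth[pos].mean() > 0.9


def test_signature_csv_roundtrip(tmp_path):
    path = tmp_path / "sigs.csv"
    path.write_text(
        "cell_type,positive,negative\nT cell,CD3 CD7,\nILC,CD7,CD3\n"
    )
    sigs = px.SignatureTable.from_csv(path)
    assert [s.cell_type for s in sigs] == ["T cell", "ILC"]
    assert sigs.signatures[1].negative == ("CD3",)
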