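"""Shared fixtures: small synthetic scenes with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

import pixplore as px

TWO_BLOB_SIGNATURES = {
    "A": {"x": 10.0, "y": 0.0},
    "B": {"x": 0.0, "y": 10.0},
}


@pytest.fixture(scope="session")
def two_blob_table():
    """200-row pixel table: two well-separated classes, lognormal noise."""
    table, labels = px.generate_pixel_clusters(
        100, TWO_BLOB_SIGNATURES, noise_model="lognormal", sigma=0.1, seed=3
    )
    return table, labels


@pytest.fixture(scope="session")
def two_blob_hierarchy(two_blob_table):
    table, labels = two_blob_table
    graph = px.build_knn_graph(table, k=10)
    hierarchy = px.build_hierarchy(graph, n_scales=2, seed=5)
    return hierarchy, labels


def quadrant_spec(seed: int, side: int = 60, sigma: float = 0.3) -> px.SyntheticSpec:
    """Four marker-distinct classes tiling the image in quadrants."""
    half = side // 2
    classes = {
        "T cell": {"CD3": 20.0, "CD7": 18.0},
        "B cell": {"CD20": 22.0, "HLA-DR": 15.0},
        "macrophage": {"CD163": 20.0, "HLA-DR": 16.0},
        "epithelium": {"E-cadherin": 25.0},
    }
    regions = [
        px.Region(f"q{i}", px.Rect(half * (i // 2), half * (i % 2), half, half),
                  "background")
        for i in range(4)
    ]
    rule = {f"q{i}": {name: 1.0} for i, name in enumerate(classes)}
    return px.SyntheticSpec(
        image_height=side,
        image_width=side,
        regions=regions,
        classes=classes,
        class_map_rule=rule,
        noise_model="lognormal",
        lognormal_sigma=sigma,
        seed=seed,
    )


QUADRANT_SIGNATURES = px.SignatureTable(
    [
        px.Signature("T cell", positive=("CD3", "CD7")),
        px.Signature("B cell", positive=("CD20", "HLA-DR"), negative=("CD163",)),
        px.Signature("macrophage", positive=("CD163", "HLA-DR")),
        px.Signature("epithelium", positive=("E-cadherin",)),
    ]
)


@pytest.fixture(scope="session")
def quadrant_image():
    spec = quadrant_spec(seed=11)
    stack, gt = px.generate_multiplex_image(spec)
    return spec, stack, gt


def two_band_image(seed: int = 0, side: int = 40):
    """Two exclusive rectangle classes splitting the image top/bottom."""
    classes = {"A": {"x": 15.0}, "B": {"y": 15.0}}
    spec = px.SyntheticSpec(
        image_height=side,
        image_width=side,
        regions=[
            px.Region("top", px.Rect(0, 0, side // 2, side), "background"),
            px.Region("bottom", px.Rect(side // 2, 0, side // 2, side), "background"),
        ],
        classes=classes,
        class_map_rule={"top": {"A": 1.0}, "bottom": {"B": 1.0}},
        noise_model="lognormal",
        lognormal_sigma=0.15,
        seed=seed,
    )
    return (spec, *px.generate_multiplex_image(spec))


@pytest.fixture(scope="session")
def two_band():
    return two_band_image()


def planted_lf_image(seed: int = 0):
    """The 7-vs-5 follicle/control quantification scene."""
    spec = px.synthetic.lf_quantification_spec(seed=seed)
    return (spec, *px.generate_multiplex_image(spec))


@pytest.fixture(scope="session")
def lf_scene():
    return planted_lf_image()
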