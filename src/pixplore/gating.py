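"""From embeddings to pixel class labels.

Landmark embeddings are clustered with weighted Gaussian mean-shift (the
density modes stand in for the interactive gates a user would draw on the
map), cluster labels are expanded to every pixel through the landmark
areas of influence, and clusters are named against a table of marker
signatures — e.g. T cell: CD3⁺CD7⁺; ILC: CD3⁻CD7⁺; B cell: CD20⁺HLA-DR⁺;
Lin⁻HLA-DR⁺ myeloid: CD3⁻CD7⁻CD20⁻CD163⁻HLA-DR⁺; macrophage: CD163⁺HLA-DR⁺.

A cluster is positive for a marker when its member-median transformed
intensity reaches the per-marker positivity threshold, a quantile over all
analyzed pixels (default the 60th percentile; "dim" spans the 30th–60th,
which operationalizes gates like CD45⁺/dim).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .hierarchy import Embedding, HsneHierarchy
from .preprocess import PixelTable

logger = logging.getLogger("pixplore")

DEFAULT_POSITIVITY_QUANTILE = 0.60
DIM_QUANTILE = 0.30
MAX_RENDERED_CLASSES = 9


@dataclass
class ClusterLabels:
    """Per-point cluster assignment: integer >= 0, or -1 for unassigned."""

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = set(np.unique(self.labels)) - {-1}
        if not present <= set(range(self.n_clusters)):
            raise ValueError(
                f"labels {sorted(present)} inconsistent with n_clusters={self.n_clusters}"
            )
        for c in range(self.n_clusters):
            if not np.any(self.labels == c):
                raise ValueError(f"cluster {c} is empty")


@dataclass(frozen=True)
class Signature:
    cell_type: str
    positive: tuple[str, ...]
    negative: tuple[str, ...] = ()


@dataclass
class SignatureTable:
    """Ordered cell-type definitions; first matching signature wins."""

    signatures: list[Signature]

    def __post_init__(self) -> None:
        if not self.signatures:
            raise ValueError("signature table must not be empty")
        names = [s.cell_type for s in self.signatures]
        if len(set(names)) != len(names):
            raise ValueError(f"cell-type names must be unique, got {names}")

    def __iter__(self):
        return iter(self.signatures)

    def __len__(self) -> int:
        return len(self.signatures)

    def markers(self) -> list[str]:
        out: list[str] = []
        for s in self.signatures:
            for m in (*s.positive, *s.negative):
                if m not in out:
                    out.append(m)
        return out

    @classmethod
    def from_csv(cls, path: str | Path) -> "SignatureTable":
        """Read rows of cell_type, positive (space-separated), negative."""
        sigs = []
        with open(path, newline="") as fh:
            sample = fh.read(4096)
            fh.seek(0)
            delim = "\t" if "\t" in sample.splitlines()[0] else ","
            for row in csv.DictReader(fh, delimiter=delim):
                sigs.append(
                    Signature(
                        cell_type=row["cell_type"],
                        positive=tuple((row.get("positive") or "").split()),
                        negative=tuple((row.get("negative") or "").split()),
                    )
                )
        return cls(sigs)


# Default signatures matching the immune phenotypes resolvable with the
# CD45/CD3/CD7/CD20/HLA-DR/CD163 (+E-cadherin) marker set.
DEFAULT_SIGNATURES = SignatureTable(
    [
        Signature("T cell", positive=("CD3", "CD7")),
        Signature("ILC", positive=("CD7",), negative=("CD3",)),
        Signature("B cell", positive=("CD20", "HLA-DR")),
        Signature("macrophage", positive=("CD163", "HLA-DR")),
        Signature(
            "myeloid",
            positive=("HLA-DR",),
            negative=("CD3", "CD7", "CD20", "CD163"),
        ),
        Signature("epithelium", positive=("E-cadherin",)),
    ]
)


@dataclass
class PixelClusterLabeling:
    """H×W class raster (0 = background) with a label → name map."""

    label_map: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map, dtype=np.int32)
        if self.label_map.ndim != 2:
            raise ValueError("label_map must be H×W")
        present = [int(v) for v in np.unique(self.label_map) if v != 0]
        missing = [v for v in present if v not in self.class_names]
        if missing:
            raise ValueError(f"labels {missing} have no class name")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def rendered_class_names(self) -> dict[int, str]:
        """Classes that will be drawn (named, excluding 'unassigned')."""
        return {k: v for k, v in self.class_names.items() if v != "unassigned"}


# ---------------------------------------------------------------------------
# Weighted Gaussian mean-shift on the 2-D embedding
# ---------------------------------------------------------------------------

def _mean_shift_modes(
    X: np.ndarray,
    weights: np.ndarray,
    bandwidth: float,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> np.ndarray:
    """Gradient-ascent mode per point under the weighted Gaussian KDE."""
    Y = X.copy()
    h2 = bandwidth * bandwidth
    for _ in range(max_iter):
        d2 = np.sum((Y[:, None, :] - X[None, :, :]) ** 2, axis=2)
        K = np.exp(-0.5 * d2 / h2) * weights[None, :]
        denom = K.sum(axis=1, keepdims=True)
        Y_new = (K @ X) / np.maximum(denom, 1e-300)
        shift = np.max(np.abs(Y_new - Y))
        Y = Y_new
        if shift < tol * bandwidth:
            break
    return Y


def cluster_embedding(
    embedding: Embedding,
    weights: np.ndarray | None = None,
    bandwidth: float | None = None,
) -> ClusterLabels:
    """Cluster an embedding by weighted Gaussian mean-shift.

    Every point ascends the kernel density to its mode; modes closer than
    half the bandwidth are merged into one cluster. Bandwidth defaults to
    5% of the embedding's bounding-box diagonal. Cluster ids are assigned
    in lexicographic mode order, so the partition is invariant to point
    order.
    """
    X = np.asarray(embedding.points, dtype=np.float64)
    n = X.shape[0]
    if n == 0:
        raise ValueError("embedding has no points")
    if weights is None:
        weights = (
            embedding.weights
            if embedding.weights is not None
            else np.ones(n)
        )
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape[0] != n:
        raise ValueError("weights length must match point count")
    if bandwidth is None:
        span = X.max(axis=0) - X.min(axis=0)
        diag = float(np.hypot(*span))
        bandwidth = 0.05 * diag if diag > 0 else 1.0
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    if n == 1:
        return ClusterLabels(labels=np.zeros(1, dtype=np.int64), n_clusters=1)

    modes = _mean_shift_modes(X, weights, bandwidth)

    # merge modes within bandwidth/2 (single-linkage over the mode set)
    order = np.lexsort((modes[:, 1], modes[:, 0]))
    labels = np.full(n, -1, dtype=np.int64)
    centers: list[np.ndarray] = []
    for i in order:
        m = modes[i]
        assigned = False
        for c, ctr in enumerate(centers):
            if np.hypot(*(m - ctr)) <= bandwidth / 2:
                labels[i] = c
                assigned = True
                break
        if not assigned:
            centers.append(m)
            labels[i] = len(centers) - 1
    return ClusterLabels(labels=labels, n_clusters=len(centers))


# ---------------------------------------------------------------------------
# Landmark → pixel label expansion
# ---------------------------------------------------------------------------

def expand_to_pixels(
    hierarchy: HsneHierarchy,
    scale: int,
    landmark_labels: ClusterLabels,
    shape: tuple[int, int] | None = None,
) -> PixelClusterLabeling:
    """Expand landmark cluster labels to every pixel via argmax influence.

    Each pixel takes the label of the landmark holding its strongest
    cumulative influence; pixels with no influence mass (or whose landmark
    is unassigned) become background 0. Cluster c maps to raster label
    c + 1.
    """
    if not 0 <= scale < hierarchy.n_scales:
        raise ValueError(
            f"scale {scale} not in hierarchy (0..{hierarchy.n_scales - 1})"
        )
    n_land = hierarchy.n_points(scale)
    if landmark_labels.labels.shape[0] != n_land:
        raise ValueError(
            f"labels cover {landmark_labels.labels.shape[0]} landmarks but "
            f"scale {scale} has {n_land}"
        )
    assign = hierarchy.pixel_assignments(scale)
    coords = hierarchy.table.coords
    if shape is None:
        shape = (int(coords[:, 0].max()) + 1, int(coords[:, 1].max()) + 1)
    label_map = np.zeros(shape, dtype=np.int32)
    ok = assign >= 0
    pix_labels = np.where(ok, landmark_labels.labels[np.maximum(assign, 0)], -1)
    keep = pix_labels >= 0
    label_map[coords[keep, 0], coords[keep, 1]] = pix_labels[keep] + 1
    names = {c + 1: f"cluster {c}" for c in range(landmark_labels.n_clusters)}
    return PixelClusterLabeling(label_map=label_map, class_names=names)


# ---------------------------------------------------------------------------
# Marker-threshold gates (positive / dim)
# ---------------------------------------------------------------------------

def marker_gate(
    table: PixelTable,
    marker: str,
    mode: str = "positive_or_dim",
    dim_quantile: float = DIM_QUANTILE,
    positive_quantile: float = DEFAULT_POSITIVITY_QUANTILE,
) -> np.ndarray:
    """Boolean row mask selecting pixels by marker intensity quantiles.

    Modes: "positive" (above the positive quantile), "dim" (between the
    dim and positive quantiles) and "positive_or_dim" (above the dim
    quantile) — the latter reproduces gates like CD45⁺/dim used to isolate
    immune pixels before fine clustering. The alternative route, selecting
    landmarks on the embedding, is :func:`cluster_embedding` plus
    drill-down.
    """
    v = table.column(marker)
    lo = np.quantile(v, dim_quantile)
    hi = np.quantile(v, positive_quantile)
    if mode == "positive":
        return v > hi
    if mode == "dim":
        return (v > lo) & (v <= hi)
    if mode == "positive_or_dim":
        return v > lo
    raise ValueError(f"unknown gate mode {mode!r}")


# ---------------------------------------------------------------------------
# Cell-type naming from marker signatures
# ---------------------------------------------------------------------------

def assign_cell_types(
    labeling: PixelClusterLabeling,
    table: PixelTable,
    signatures: SignatureTable,
    positivity_quantile: float = DEFAULT_POSITIVITY_QUANTILE,
) -> PixelClusterLabeling:
    """Name clusters by ordered first-match against marker signatures.

    Positivity thresholds are per-marker quantiles of the transformed
    intensities over all pixels in ``table``; a cluster is positive for a
    marker when its member-median strictly exceeds the threshold (so a
    marker absent everywhere — threshold and medians both zero — never
    reads as positive). Clusters matching the same cell type are merged
    into one output class; clusters matching nothing are kept as
    "unassigned".
    """
    if len(signatures) == 0:
        raise ValueError("signature table must not be empty")
    unknown = [m for m in signatures.markers() if m not in table.marker_names]
    if unknown:
        raise ValueError(f"signature marker(s) {unknown} not in pixel table")
    if not 0.0 < positivity_quantile < 1.0:
        raise ValueError("positivity quantile must lie in (0, 1)")

    thresholds = {
        m: float(np.quantile(table.column(m), positivity_quantile))
        for m in signatures.markers()
    }

    coords = table.coords
    pixel_labels = labeling.label_map[coords[:, 0], coords[:, 1]]
    old_labels = [int(v) for v in np.unique(labeling.label_map) if v != 0]

    name_to_new: dict[str, int] = {}
    remap: dict[int, int] = {}
    new_names: dict[int, str] = {}
    next_id = 1
    for old in old_labels:
        members = pixel_labels == old
        if not members.any():
            raise ValueError(
                f"cluster label {old} has no member pixels in the table"
            )
        med = {
            m: float(np.median(table.column(m)[members]))
            for m in signatures.markers()
        }
        matches = [
            s
            for s in signatures
            if all(med[m] > thresholds[m] for m in s.positive)
            and all(med[m] <= thresholds[m] for m in s.negative)
        ]
        if matches:
            name = matches[0].cell_type
            if len(matches) > 1:
                logger.warning(
                    "cluster %d satisfies %s; first match %r wins",
                    old,
                    [s.cell_type for s in matches],
                    name,
                )
        else:
            name = "unassigned"
        if name in name_to_new:
            remap[old] = name_to_new[name]
        else:
            name_to_new[name] = next_id
            new_names[next_id] = name
            remap[old] = next_id
            next_id += 1

    lut = np.zeros(max(old_labels, default=0) + 1, dtype=np.int32)
    for old, new in remap.items():
        lut[old] = new
    return PixelClusterLabeling(
        label_map=lut[labeling.label_map], class_names=new_names
    )
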