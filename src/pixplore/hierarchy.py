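"""HSNE-style multi-scale landmark hierarchy over tissue pixels.

Millions of pixels cannot be embedded directly, so the hierarchy follows
the hierarchical stochastic neighbor embedding recipe: build a k-nearest-
neighbor graph on the pixels-by-markers table, select *landmarks* at each
coarser scale as nodes whose random-walk visit count exceeds a multiple of
the expected count, and describe each landmark's *area of influence* by
the frequency with which finer-scale points' random walks are absorbed at
it. Influence matrices are row-stochastic, landmark weights accumulate the
number of pixels each landmark represents, and any scale can be embedded
in 2-D with a weighted exact-gradient t-SNE. Drill-down maps a landmark
selection back to the scale-0 pixels it dominates, yielding a fresh pixel
table for a finer analysis — the overview → tissue → immune-pixel workflow
used for segmentation-free IMC phenotyping.

All stochastic steps (walks, embedding initialisation) are driven by
explicit seeds; identical inputs and seeds reproduce results bit for bit.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from numba import njit

from .preprocess import PixelTable

logger = logging.getLogger("pixplore")

DEFAULT_K = 30
BRUTE_FORCE_MAX_N = 8192
APPROX_KNN_MIN_N = 50_000
EMBED_MAX_POINTS = 12_000


# ---------------------------------------------------------------------------
# Random-walk kernels (seeded splitmix64; single-threaded, deterministic)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _mix64(s):
    z = s
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def _walk_visits(indptr, indices, cumprob, n_walks, walk_len, seed):
    """Total visit counts from n_walks random walks of walk_len per node."""
    n = indptr.size - 1
    visits = np.zeros(n, dtype=np.int64)
    state = np.uint64(seed)
    golden = np.uint64(0x9E3779B97F4A7C15)
    for i in range(n):
        for _ in range(n_walks):
            cur = i
            for _ in range(walk_len):
                lo = indptr[cur]
                hi = indptr[cur + 1]
                if hi == lo:
                    break
                state = state + golden
                r = (_mix64(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)
                a = lo
                b = hi - 1
                while a < b:
                    mid = (a + b) // 2
                    if cumprob[mid] < r:
                        a = mid + 1
                    else:
                        b = mid
                cur = indices[a]
                visits[cur] += 1
    return visits


@njit(cache=True)
def _walk_absorb(indptr, indices, cumprob, landmark_col, n_walks, max_len, seed):
    """Absorbing-walk outcomes: landmark column reached per walk, -1 if none.

    A walk starting at a landmark is absorbed immediately at itself, so
    landmark influence rows are identity rows.
    """
    n = indptr.size - 1
    out = np.full((n, n_walks), -1, dtype=np.int32)
    state = np.uint64(seed)
    golden = np.uint64(0x9E3779B97F4A7C15)
    for i in range(n):
        if landmark_col[i] >= 0:
            out[i, :] = landmark_col[i]
            continue
        for w in range(n_walks):
            cur = i
            for _ in range(max_len):
                lo = indptr[cur]
                hi = indptr[cur + 1]
                if hi == lo:
                    break
                state = state + golden
                r = (_mix64(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)
                a = lo
                b = hi - 1
                while a < b:
                    mid = (a + b) // 2
                    if cumprob[mid] < r:
                        a = mid + 1
                    else:
                        b = mid
                cur = indices[a]
                if landmark_col[cur] >= 0:
                    out[i, w] = landmark_col[cur]
                    break
    return out


@njit(cache=True)
def _topk_rows(indptr, indices, data, k):
    """Keep the k largest entries per CSR row (ties: lower column index)."""
    n = indptr.size - 1
    new_indptr = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        new_indptr[i + 1] = new_indptr[i] + min(indptr[i + 1] - indptr[i], k)
    new_indices = np.empty(new_indptr[-1], dtype=np.int64)
    new_data = np.empty(new_indptr[-1], dtype=np.float64)
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        width = hi - lo
        keep = min(width, k)
        # argsort descending by value, ascending by column on ties
        order = np.argsort(-data[lo:hi], kind="mergesort")
        sel = np.sort(order[:keep])  # preserve column order within the row
        for j in range(keep):
            new_indices[new_indptr[i] + j] = indices[lo + sel[j]]
            new_data[new_indptr[i] + j] = data[lo + sel[j]]
    return new_indptr, new_indices, new_data


def _prune_csr(A: sp.csr_matrix, k: int) -> sp.csr_matrix:
    """Top-k sparsification of each row (deterministic tie-break)."""
    A = sp.csr_matrix(A)
    A.sum_duplicates()
    A.sort_indices()
    if A.nnz == 0 or k <= 0:
        return A
    indptr, indices, data = _topk_rows(
        A.indptr.astype(np.int64), A.indices.astype(np.int64), A.data.astype(np.float64), k
    )
    return sp.csr_matrix((data, indices, indptr), shape=A.shape)


@njit(cache=True)
def _row_cumprob(indptr, data):
    """Per-row normalized cumulative probabilities (last entry of a row = 1)."""
    out = np.empty_like(data)
    n = indptr.size - 1
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        total = 0.0
        for j in range(lo, hi):
            total += data[j]
        acc = 0.0
        if total <= 0.0:
            width = hi - lo
            for j in range(lo, hi):
                acc += 1.0 / width
                out[j] = acc
        else:
            for j in range(lo, hi):
                acc += data[j] / total
                out[j] = acc
        if hi > lo:
            out[hi - 1] = 1.0
    return out


# ---------------------------------------------------------------------------
# kNN similarity graph
# ---------------------------------------------------------------------------

@dataclass
class SimilarityGraph:
    """Directed kNN graph on PixelTable rows (Euclidean on transformed values).

    ``neighbors``/``dists``/``weights`` are n×k arrays; weights decay as
    exp(-d²/σ_i²) with σ_i the mean neighbor distance of node i.
    """

    table: PixelTable
    neighbors: np.ndarray
    dists: np.ndarray
    weights: np.ndarray
    k: int

    @property
    def n_nodes(self) -> int:
        return self.neighbors.shape[0]

    def transition_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(indptr, indices, cumprob) of the row-stochastic walk matrix."""
        n, k = self.neighbors.shape
        indptr = (np.arange(n + 1) * k).astype(np.int64)
        indices = self.neighbors.ravel().astype(np.int64)
        cumprob = _row_cumprob(indptr, self.weights.ravel().astype(np.float64))
        return indptr, indices, cumprob


def _brute_force_knn(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact kNN with stable tie-break by row index (smallest index wins)."""
    n = X.shape[0]
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    dists = np.sqrt(np.take_along_axis(d2, order, axis=1))
    return order.astype(np.int64), dists


def _remove_self(neigh: np.ndarray, dist: np.ndarray, k: int):
    """Drop the query point from a (k+1)-neighbor result, keep k columns."""
    n = neigh.shape[0]
    out_n = np.empty((n, k), dtype=np.int64)
    out_d = np.empty((n, k), dtype=np.float64)
    rows = np.arange(n)
    is_self = neigh == rows[:, None]
    for i in range(n):
        sel = np.flatnonzero(is_self[i])
        drop = sel[0] if sel.size else neigh.shape[1] - 1
        keep = np.concatenate([np.arange(drop), np.arange(drop + 1, neigh.shape[1])])
        out_n[i] = neigh[i, keep][:k]
        out_d[i] = dist[i, keep][:k]
    return out_n, out_d


def build_knn_graph(
    table: PixelTable, k: int = DEFAULT_K, seed: int = 0
) -> SimilarityGraph:
    """k-nearest-neighbor similarity graph over the pixel table.

    Exact (brute force, stable tie-break by row index) up to 8192 rows;
    sklearn ball-tree/brute at intermediate sizes; approximate NN-descent
    beyond 50k rows, which is what makes the 2.5×10⁵-pixel ROI scale
    tractable on one CPU.
    """
    if table.n_pixels == 0:
        raise ValueError("pixel table is empty")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = table.n_pixels
    if k >= n:
        logger.warning("k=%d >= n_nodes=%d; clamping to %d", k, n, n - 1)
        k = max(n - 1, 1)
    X = np.ascontiguousarray(table.values, dtype=np.float64)

    if n == 1:
        # degenerate single-pixel table: self-loop so walks stay put
        return SimilarityGraph(
            table=table,
            neighbors=np.zeros((1, 1), np.int64),
            dists=np.zeros((1, 1)),
            weights=np.ones((1, 1)),
            k=1,
        )
    if n <= BRUTE_FORCE_MAX_N:
        neighbors, dists = _brute_force_knn(X, k)
    else:
        neighbors = dists = None
        if n >= APPROX_KNN_MIN_N:
            try:
                from pynndescent import NNDescent

                index = NNDescent(
                    X.astype(np.float32),
                    n_neighbors=k + 1,
                    metric="euclidean",
                    random_state=seed % (2**31),
                    n_jobs=1,
                )
                neigh, dist = index.neighbor_graph
                neighbors, dists = _remove_self(
                    neigh.astype(np.int64), dist.astype(np.float64), k
                )
            except ImportError:  # pragma: no cover - env-dependent
                logger.warning("pynndescent unavailable; exact kNN at n=%d", n)
        if neighbors is None:
            from sklearn.neighbors import NearestNeighbors

            nn = NearestNeighbors(n_neighbors=k + 1, n_jobs=1).fit(X)
            dist, neigh = nn.kneighbors(X)
            neighbors, dists = _remove_self(
                neigh.astype(np.int64), dist.astype(np.float64), k
            )

    sigma = dists.mean(axis=1)
    sigma[sigma <= 0] = 1.0  # duplicate-only neighborhoods: uniform weights
    weights = np.exp(-((dists / sigma[:, None]) ** 2))
    return SimilarityGraph(
        table=table, neighbors=neighbors, dists=dists, weights=weights, k=k
    )


# ---------------------------------------------------------------------------
# Hierarchy construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WalkParams:
    """Monte-Carlo settings for landmark selection and areas of influence.

    ``landmark_threshold`` multiplies the expected visit count
    (n_walks × walk_length per node under a uniform stationary law).
    """

    n_walks: int = 100
    walk_length: int = 50
    landmark_threshold: float = 1.5
    influence_walks: int = 100
    max_walk_length: int = 500
    min_landmarks: int = 10
    # sparsification: keep only the strongest Monte-Carlo absorption targets
    # per point (singleton hits are sampling noise) and the strongest
    # neighbors in the derived next-scale transition — bounds memory at the
    # quarter-million-pixel ROI scale
    influence_top: int = 10
    transition_top: int = 30


@dataclass
class Scale:
    """One hierarchy level.

    ``landmark_indices`` index into the previous scale's point set;
    ``influence`` is the row-stochastic (previous-scale points ×
    this-scale landmarks) area-of-influence map; ``landmark_weight`` is
    the number of scale-0 pixels each landmark represents; ``transition``
    is the row-stochastic walk matrix among this scale's points.
    """

    landmark_indices: np.ndarray
    influence: sp.csr_matrix
    landmark_weight: np.ndarray
    transition: sp.csr_matrix
    # scale 0 only: raw kNN arrays in neighbor-list order, for perplexity
    # calibration of the embedding similarities
    knn_neighbors: np.ndarray | None = None
    knn_dists: np.ndarray | None = None

    @property
    def n_points(self) -> int:
        return self.landmark_indices.size


@dataclass
class HsneHierarchy:
    """Nested landmark scales over one pixel table (scale 0 = all pixels)."""

    table: PixelTable
    scales: list[Scale]
    seed: int = 0

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def n_points(self, scale: int) -> int:
        return self.scales[scale].n_points

    def scale_rows(self, scale: int) -> np.ndarray:
        """Scale-0 table row index of every point at the given scale."""
        rows = self.scales[0].landmark_indices
        for s in range(1, scale + 1):
            rows = rows[self.scales[s].landmark_indices]
        return rows

    def cumulative_influence(self, scale: int) -> sp.csr_matrix:
        """Row-stochastic pixels × scale-s landmarks map (composition)."""
        if not 0 <= scale < self.n_scales:
            raise IndexError(f"scale {scale} not in hierarchy (0..{self.n_scales - 1})")
        out = self.scales[0].influence
        for s in range(1, scale + 1):
            out = out @ self.scales[s].influence
        return sp.csr_matrix(out)

    def pixel_assignments(self, scale: int) -> np.ndarray:
        """Hard pixel → landmark argmax of composed influence (-1 = none).

        Ties break toward the lowest landmark index.
        """
        return csr_row_argmax(self.cumulative_influence(scale))


def csr_row_argmax(A: sp.csr_matrix) -> np.ndarray:
    """Per-row argmax column of a CSR matrix; -1 for rows without mass.

    Ties resolve to the lowest column index (rows scanned in sorted order).
    """
    A = sp.csr_matrix(A)
    A.sum_duplicates()
    A.sort_indices()
    out = np.full(A.shape[0], -1, dtype=np.int64)
    indptr, indices, data = A.indptr, A.indices, A.data
    for i in range(A.shape[0]):
        lo, hi = indptr[i], indptr[i + 1]
        if hi == lo:
            continue
        row = data[lo:hi]
        best = row.argmax()  # first (lowest column) max under sorted indices
        if row[best] > 0:
            out[i] = indices[lo + best]
    return out


def _derive_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % 2**31)


def _csr_walk_arrays(T: sp.csr_matrix):
    T = sp.csr_matrix(T, copy=True)
    T.sort_indices()
    indptr = T.indptr.astype(np.int64)
    indices = T.indices.astype(np.int64)
    cumprob = _row_cumprob(indptr, T.data.astype(np.float64))
    return indptr, indices, cumprob


def _bfs_nearest_landmark(
    indptr: np.ndarray, indices: np.ndarray, start: int, landmark_col: np.ndarray
) -> int:
    """Deterministic fallback for walks that never reached a landmark."""
    seen = {start}
    queue = deque([start])
    while queue:
        cur = queue.popleft()
        for nxt in indices[indptr[cur] : indptr[cur + 1]]:
            nxt = int(nxt)
            if landmark_col[nxt] >= 0:
                return int(landmark_col[nxt])
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return 0  # isolated component without landmarks: attach to landmark 0


def build_hierarchy(
    graph: SimilarityGraph,
    n_scales: int = 3,
    walk_params: WalkParams | None = None,
    seed: int = 0,
) -> HsneHierarchy:
    """Build the landmark hierarchy by Monte-Carlo random walks.

    ``n_scales`` counts the data scale: 1 yields only the identity scale.
    Landmarks at scale s are the scale s-1 points whose visit count
    exceeds ``landmark_threshold`` × the expected count; areas of
    influence are absorption frequencies of seeded walks. The hierarchy is
    truncated (with a warning) when a further scale would drop below
    ``min_landmarks`` landmarks.
    """
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    wp = walk_params or WalkParams()
    n = graph.n_nodes

    scale0 = Scale(
        landmark_indices=np.arange(n, dtype=np.int64),
        influence=sp.identity(n, format="csr"),
        landmark_weight=np.ones(n, dtype=np.float64),
        transition=sp.csr_matrix(
            (
                (graph.weights / graph.weights.sum(axis=1, keepdims=True)).ravel(),
                graph.neighbors.ravel(),
                np.arange(n + 1) * graph.neighbors.shape[1],
            ),
            shape=(n, n),
        ),
        knn_neighbors=graph.neighbors,
        knn_dists=graph.dists,
    )
    scales = [scale0]

    indptr, indices, cumprob = graph.transition_csr()
    weight_cur = scale0.landmark_weight

    for s in range(1, n_scales):
        n_cur = scales[-1].n_points
        visits = _walk_visits(
            indptr,
            indices,
            cumprob,
            wp.n_walks,
            wp.walk_length,
            _derive_seed(seed, 2 * s),
        )
        expected = wp.n_walks * wp.walk_length
        landmarks = np.flatnonzero(visits > wp.landmark_threshold * expected)
        if landmarks.size < wp.min_landmarks or landmarks.size >= n_cur:
            logger.warning(
                "scale %d would have %d landmarks; truncating hierarchy at %d scale(s)",
                s,
                landmarks.size,
                len(scales),
            )
            break

        landmark_col = np.full(n_cur, -1, dtype=np.int32)
        landmark_col[landmarks] = np.arange(landmarks.size, dtype=np.int32)
        absorbed = _walk_absorb(
            indptr,
            indices,
            cumprob,
            landmark_col,
            wp.influence_walks,
            wp.max_walk_length,
            _derive_seed(seed, 2 * s + 1),
        )

        rows = np.repeat(np.arange(n_cur, dtype=np.int64), wp.influence_walks)
        cols = absorbed.ravel().astype(np.int64)
        ok = cols >= 0
        influence = sp.coo_matrix(
            (np.ones(ok.sum()), (rows[ok], cols[ok])),
            shape=(n_cur, landmarks.size),
        ).tocsr()

        empty = np.flatnonzero(np.diff(influence.indptr) == 0)
        if empty.size:
            logger.info(
                "scale %d: %d point(s) unabsorbed after %d steps; BFS fallback",
                s,
                empty.size,
                wp.max_walk_length,
            )
            fb_cols = [
                _bfs_nearest_landmark(indptr, indices, int(i), landmark_col)
                for i in empty
            ]
            influence = (
                influence
                + sp.coo_matrix(
                    (np.ones(empty.size), (empty, fb_cols)),
                    shape=influence.shape,
                ).tocsr()
            )
        # keep dominant absorption targets, then row-normalize to stochastic
        influence = _prune_csr(influence, wp.influence_top)
        rowsum = np.asarray(influence.sum(axis=1)).ravel()
        influence = sp.diags(1.0 / rowsum) @ influence
        influence = sp.csr_matrix(influence)

        weight_new = influence.T @ weight_cur
        # next-scale similarities: area-of-influence overlap weighted by the
        # mass of the finer points each pair of landmarks shares
        overlap = sp.csr_matrix(
            influence.T @ sp.diags(weight_cur) @ influence
        )
        overlap.setdiag(0.0)
        overlap.eliminate_zeros()
        overlap = _prune_csr(overlap, wp.transition_top)
        rowsum = np.asarray(overlap.sum(axis=1)).ravel()
        rowsum[rowsum <= 0] = 1.0
        transition = sp.csr_matrix(sp.diags(1.0 / rowsum) @ overlap)

        scales.append(
            Scale(
                landmark_indices=landmarks.astype(np.int64),
                influence=influence,
                landmark_weight=np.asarray(weight_new, dtype=np.float64),
                transition=transition,
            )
        )
        weight_cur = scales[-1].landmark_weight
        indptr, indices, cumprob = _csr_walk_arrays(transition)

    return HsneHierarchy(table=graph.table, scales=scales, seed=seed)


# ---------------------------------------------------------------------------
# Weighted exact t-SNE on one scale
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbedParams:
    perplexity: float = 30.0
    n_iter: int = 1000
    early_exaggeration: float = 12.0
    early_iter: int = 250
    learning_rate: float | None = None  # default max(n/12, 2)


@dataclass
class Embedding:
    """2-D layout of one hierarchy scale (or a drilled subset)."""

    points: np.ndarray
    scale: int
    seed: int
    params: EmbedParams
    weights: np.ndarray | None = None


def _perplexity_conditionals(
    neighbors_dists: np.ndarray, perplexity: float
) -> np.ndarray:
    """Binary-search Gaussian bandwidths so each row's entropy = log(perp)."""
    n, k = neighbors_dists.shape
    perplexity = min(perplexity, max(k - 1, 1))
    target = np.log(perplexity)
    P = np.zeros((n, k))
    d2 = neighbors_dists**2
    for i in range(n):
        lo, hi = 1e-20, 1e20
        beta = 1.0
        row = d2[i] - d2[i].min()
        for _ in range(64):
            p = np.exp(-row * beta)
            s = p.sum()
            if s <= 0:
                p = np.ones_like(p)
                s = p.sum()
            p /= s
            h = -(p * np.log(np.maximum(p, 1e-300))).sum()
            if abs(h - target) < 1e-5:
                break
            if h > target:
                lo = beta
                beta = beta * 2 if hi >= 1e20 else (beta + hi) / 2
            else:
                hi = beta
                beta = beta / 2 if lo <= 1e-20 else (beta + lo) / 2
        P[i] = p
    return P


def _knn_dense_chunked(X: np.ndarray, k: int, chunk: int = 2048):
    """Exact kNN (stable ties) computed chunk-wise to bound memory."""
    n = X.shape[0]
    sq = np.sum(X * X, axis=1)
    neigh = np.empty((n, k), dtype=np.int64)
    dists = np.empty((n, k), dtype=np.float64)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d2 = sq[lo:hi, None] + sq[None, :] - 2.0 * (X[lo:hi] @ X.T)
        np.maximum(d2, 0.0, out=d2)
        d2[np.arange(hi - lo), np.arange(lo, hi)] = np.inf
        order = np.argsort(d2, axis=1, kind="stable")[:, :k]
        neigh[lo:hi] = order
        dists[lo:hi] = np.sqrt(np.take_along_axis(d2, order, axis=1))
    return neigh, dists


def _joint_p(hierarchy: HsneHierarchy, scale: int, perplexity: float) -> np.ndarray:
    """Perplexity-calibrated Gaussian similarities at one scale.

    Similarities are computed in marker-feature space over the scale's
    points (the stored kNN distances at scale 0, a fresh exact kNN over
    the landmark features at coarser scales); landmark weights scale the
    conditionals so heavy landmarks structure the layout.
    """
    sc = hierarchy.scales[scale]
    n = sc.n_points
    w = sc.landmark_weight
    if scale == 0 and sc.knn_dists is not None and sc.knn_neighbors is not None:
        neighbors, dists = sc.knn_neighbors, sc.knn_dists
    else:
        X = hierarchy.table.values[hierarchy.scale_rows(scale)]
        k = int(min(n - 1, max(3 * perplexity, 10)))
        neighbors, dists = _knn_dense_chunked(np.ascontiguousarray(X), k)
    cond = _perplexity_conditionals(dists, perplexity)
    rows = np.repeat(np.arange(n), cond.shape[1])
    P_cond = sp.csr_matrix(
        (cond.ravel(), (rows, neighbors.ravel())), shape=(n, n)
    )
    Pw = sp.diags(w) @ P_cond
    P = np.asarray((Pw + Pw.T).todense(), dtype=np.float64)
    np.fill_diagonal(P, 0.0)
    total = P.sum()
    if total <= 0:
        P[:] = 1.0 / max(n * (n - 1), 1)
        np.fill_diagonal(P, 0.0)
    else:
        P /= total
    return P


def _spectral_init(P: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic informative initialisation: top eigenvectors of P."""
    from scipy.sparse.linalg import eigsh

    n = P.shape[0]
    rng = np.random.default_rng(seed)
    if n <= 4:
        return rng.normal(scale=1e-4, size=(n, 2))
    v0 = rng.normal(size=n)
    _, vecs = eigsh((P + P.T) / 2, k=3, which="LA", v0=v0)
    Y = np.ascontiguousarray(vecs[:, :2][:, ::-1], dtype=np.float64)
    scale = np.abs(Y).max()
    return Y * (1e-4 / scale) if scale > 0 else rng.normal(scale=1e-4, size=(n, 2))


def _tsne_optimize(
    P: np.ndarray, params: EmbedParams, seed: int
) -> np.ndarray:
    n = P.shape[0]
    Y = _spectral_init(P, seed)
    dY = np.zeros_like(Y)
    gains = np.ones_like(Y)
    eta = params.learning_rate or max(n / 12.0, 2.0)
    Pe = P * params.early_exaggeration
    for it in range(params.n_iter):
        Pcur = Pe if it < params.early_iter else P
        momentum = 0.5 if it < params.early_iter else 0.8
        d2 = np.sum((Y[:, None, :] - Y[None, :, :]) ** 2, axis=2)
        num = 1.0 / (1.0 + d2)
        np.fill_diagonal(num, 0.0)
        Q = num / max(num.sum(), 1e-300)
        PQn = (Pcur - Q) * num
        grad = 4.0 * (np.diag(PQn.sum(axis=1)) - PQn) @ Y
        inc = np.sign(grad) != np.sign(dY)
        gains = np.where(inc, gains + 0.2, gains * 0.8)
        np.maximum(gains, 0.01, out=gains)
        dY = momentum * dY - eta * gains * grad
        Y = Y + dY
        Y = Y - Y.mean(axis=0)
    return Y


def embed_scale(
    hierarchy: HsneHierarchy,
    scale: int,
    params: EmbedParams | None = None,
    seed: int = 0,
) -> Embedding:
    """2-D weighted t-SNE layout of one hierarchy scale.

    Similarities are perplexity-calibrated Gaussian conditionals on
    marker-feature distances among the scale's points, multiplied by the
    landmark weights; the exact gradient is descended from a seeded
    spectral initialisation. Deterministic for a fixed (hierarchy, params,
    seed).
    """
    if not 0 <= scale < hierarchy.n_scales:
        raise IndexError(f"scale {scale} not in hierarchy (0..{hierarchy.n_scales - 1})")
    params = params or EmbedParams()
    sc = hierarchy.scales[scale]
    n = sc.n_points
    if n < 2:
        logger.warning("embedding a scale with %d point(s); returning origin", n)
        return Embedding(
            points=np.zeros((n, 2)),
            scale=scale,
            seed=seed,
            params=params,
            weights=sc.landmark_weight.copy(),
        )
    if n > EMBED_MAX_POINTS:
        raise ValueError(
            f"scale {scale} has {n} points; embed a coarser scale or drill down "
            f"(exact-gradient layout is limited to {EMBED_MAX_POINTS} points)"
        )
    P = _joint_p(hierarchy, scale, params.perplexity)
    Y = _tsne_optimize(P, params, seed)
    return Embedding(
        points=Y,
        scale=scale,
        seed=seed,
        params=params,
        weights=sc.landmark_weight.copy(),
    )


# ---------------------------------------------------------------------------
# Drill-down
# ---------------------------------------------------------------------------

def drill_down(
    hierarchy: HsneHierarchy, scale: int, selected_landmarks: Sequence[int]
) -> PixelTable:
    """Pixels whose strongest cumulative influence flows into a selection.

    Returns a fresh PixelTable (subset of the hierarchy's scale-0 table)
    ready for a new analysis round.
    """
    rows = drill_down_indices(hierarchy, scale, selected_landmarks)
    return hierarchy.table.subset(rows)


def drill_down_indices(
    hierarchy: HsneHierarchy, scale: int, selected_landmarks: Sequence[int]
) -> np.ndarray:
    """Scale-0 row indices selected by a landmark drill-down."""
    selected = np.unique(np.asarray(list(selected_landmarks), dtype=np.int64))
    if selected.size == 0:
        raise ValueError("landmark selection must not be empty")
    n_land = hierarchy.n_points(scale)
    if selected.min() < 0 or selected.max() >= n_land:
        raise IndexError(
            f"selection out of range for scale {scale} with {n_land} landmarks"
        )
    assign = hierarchy.pixel_assignments(scale)
    mask = np.isin(assign, selected)
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Serialization (documented .npz container)
# ---------------------------------------------------------------------------

FORMAT_VERSION = "pixplore-hierarchy-1"


def save_hierarchy(path, hierarchy: HsneHierarchy, config_hash: str = "") -> None:
    """Persist a hierarchy to a versioned .npz container."""
    payload: dict[str, np.ndarray] = {
        "format": np.array(FORMAT_VERSION),
        "config_hash": np.array(config_hash),
        "seed": np.array(hierarchy.seed),
        "n_scales": np.array(hierarchy.n_scales),
        "table_values": hierarchy.table.values,
        "table_coords": hierarchy.table.coords,
        "table_markers": np.array(hierarchy.table.marker_names),
    }
    for s, sc in enumerate(hierarchy.scales):
        pre = f"s{s}_"
        payload[pre + "landmarks"] = sc.landmark_indices
        payload[pre + "weight"] = sc.landmark_weight
        for name, M in (("inf", sc.influence), ("trans", sc.transition)):
            M = sp.csr_matrix(M)
            payload[pre + name + "_data"] = M.data
            payload[pre + name + "_indices"] = M.indices
            payload[pre + name + "_indptr"] = M.indptr
            payload[pre + name + "_shape"] = np.array(M.shape)
        if sc.knn_dists is not None and sc.knn_neighbors is not None:
            payload[pre + "knn_dists"] = sc.knn_dists
            payload[pre + "knn_neighbors"] = sc.knn_neighbors
    np.savez_compressed(path, **payload)


def load_hierarchy(path) -> tuple[HsneHierarchy, str]:
    """Load a hierarchy; returns (hierarchy, config_hash)."""
    with np.load(path, allow_pickle=False) as z:
        if str(z["format"]) != FORMAT_VERSION:
            raise ValueError(f"unsupported hierarchy container: {z['format']}")
        table = PixelTable(
            values=z["table_values"],
            coords=z["table_coords"],
            marker_names=[str(m) for m in z["table_markers"]],
        )
        scales = []
        for s in range(int(z["n_scales"])):
            pre = f"s{s}_"
            mats = {}
            for name in ("inf", "trans"):
                mats[name] = sp.csr_matrix(
                    (
                        z[pre + name + "_data"],
                        z[pre + name + "_indices"],
                        z[pre + name + "_indptr"],
                    ),
                    shape=tuple(z[pre + name + "_shape"]),
                )
            has_knn = pre + "knn_dists" in z.files
            scales.append(
                Scale(
                    landmark_indices=z[pre + "landmarks"],
                    influence=mats["inf"],
                    landmark_weight=z[pre + "weight"],
                    transition=mats["trans"],
                    knn_neighbors=z[pre + "knn_neighbors"] if has_knn else None,
                    knn_dists=z[pre + "knn_dists"] if has_knn else None,
                )
            )
        return (
            HsneHierarchy(table=table, scales=scales, seed=int(z["seed"])),
            str(z["config_hash"]),
        )
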