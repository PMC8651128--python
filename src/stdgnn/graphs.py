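"""Patch feature sets and discriminant graph construction.

Backbone feature maps are partitioned into a grid of 3-D blocks and
average-pooled, giving one feature vector per patch; the N = T x P patch
vectors of a sequence (or the pooled embeddings of a batch) become graph
nodes.  Two complementary binary adjacencies are built over labeled nodes:

* W_w links each node to its nearest neighbours *within* its class
  (samples to be pulled together);
* W_b links each node to its nearest neighbours in *other* classes
  (samples to be pushed apart).

Both use the symmetric-OR k-nearest-neighbour rule with Euclidean
distances in feature space (the embedding is treated as locally
Euclidean); an edge is within- or between-class, never both.  Hypersphere
neighbourhoods are operationalized as k-NN counts, ties broken by lower
node index for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class PatchFeatureSet:
    """N pooled patch vectors with (time, patch, class) tags."""

    features: np.ndarray            # (N, d)
    time_index: np.ndarray          # (N,) in [0, T)
    patch_index: np.ndarray         # (N,) in [0, P)
    class_label: Optional[np.ndarray] = None  # (N,) of {V,E,NV} or None
    source_id: str = ""

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.time_index = np.asarray(self.time_index, dtype=int)
        self.patch_index = np.asarray(self.patch_index, dtype=int)
        n = self.features.shape[0]
        if self.time_index.shape != (n,) or self.patch_index.shape != (n,):
            raise ValueError("one (time, patch) tag per feature row required")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        if self.class_label is not None:
            self.class_label = np.asarray(self.class_label)
            if self.class_label.shape != (n,):
                raise ValueError("one class label per row required")

    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]


@dataclass
class DiscriminantGraph:
    """Within/between-class adjacencies with normalized forms + Laplacian."""

    W_w: np.ndarray
    W_b: np.ndarray
    W_w_hat: np.ndarray = field(init=False)
    W_b_hat: np.ndarray = field(init=False)
    L: np.ndarray = field(init=False)
    feats: Optional[PatchFeatureSet] = None

    def __post_init__(self):
        if np.any(self.W_w * self.W_b != 0):
            raise ValueError("within- and between-class edge sets overlap")
        self.W_w_hat = normalize_adjacency(self.W_w)
        self.W_b_hat = normalize_adjacency(self.W_b)
        self.L = laplacian(self.W_w)


def extract_patch_features(feature_map: np.ndarray, P_grid) -> np.ndarray:
    """Average-pool a (h, w, n, c) feature map over a P_grid block partition.

    Returns a (P, c) matrix with P = prod(P_grid), block-major order
    (x fastest-varying last).  Trailing remainder voxels (when the grid does
    not divide the map) are folded into the last block along each axis.
    """
    fm = np.asarray(feature_map, dtype=float)
    if fm.ndim != 4:
        raise ValueError("feature map must be (h, w, n, c)")
    P_grid = tuple(int(p) for p in P_grid)
    if any(p < 1 for p in P_grid):
        raise ValueError("grid counts must be positive")
    if any(p > s for p, s in zip(P_grid, fm.shape[:3])):
        raise ValueError(f"grid {P_grid} larger than map {fm.shape[:3]}")
    edges = [np.linspace(0, s, p + 1).astype(int)
             for s, p in zip(fm.shape[:3], P_grid)]
    out = np.empty((np.prod(P_grid), fm.shape[3]))
    idx = 0
    for i in range(P_grid[0]):
        for j in range(P_grid[1]):
            for k in range(P_grid[2]):
                block = fm[edges[0][i]:edges[0][i + 1],
                           edges[1][j]:edges[1][j + 1],
                           edges[2][k]:edges[2][k + 1]]
                out[idx] = block.mean(axis=(0, 1, 2))
                idx += 1
    return out


def patch_features_from_maps(maps, P_grid, labels=None, source_id=""):
    """Stack per-volume patch features into one PatchFeatureSet (N = T*P)."""
    rows, t_idx, p_idx = [], [], []
    for t, fm in enumerate(maps):
        feats = extract_patch_features(fm, P_grid)
        rows.append(feats)
        t_idx.extend([t] * feats.shape[0])
        p_idx.extend(range(feats.shape[0]))
    features = np.vstack(rows)
    lab = None
    if labels is not None:
        lab = np.repeat(np.asarray(labels), features.shape[0] // len(labels)) \
            if np.ndim(labels) else np.full(features.shape[0], labels)
    return PatchFeatureSet(features, np.asarray(t_idx), np.asarray(p_idx),
                           class_label=lab, source_id=source_id)


def _knn_select(dist_row, candidates, k):
    """Indices of the k nearest candidates; ties broken by lower index."""
    if candidates.size == 0:
        return candidates
    order = np.lexsort((candidates, dist_row[candidates]))
    return candidates[order[:k]]


def _pairwise_dist(X):
    sq = np.sum(X ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    return np.sqrt(np.maximum(d2, 0.0))


def build_within_graph(feats: PatchFeatureSet, k_w: int = 5) -> np.ndarray:
    """Binary within-class adjacency: W_w[i, j] = 1 iff i and j share a
    class and either is among the other's k_w nearest same-class
    neighbours (symmetric OR)."""
    if k_w < 1:
        raise ValueError("k_w must be >= 1")
    if feats.class_label is None:
        raise ValueError("within-class graph requires labels")
    X, labels = feats.features, feats.class_label
    n = feats.n_nodes
    D = _pairwise_dist(X)
    W = np.zeros((n, n))
    for cls in np.unique(labels):
        members = np.nonzero(labels == cls)[0]
        if members.size < 2:
            warnings.warn(f"class {cls!r} has <2 samples; nodes isolated")
            continue
        for i in members:
            cand = members[members != i]
            for j in _knn_select(D[i], cand, k_w):
                W[i, j] = W[j, i] = 1.0
    return W


def build_between_graph(feats: PatchFeatureSet, k_b: int = 3) -> np.ndarray:
    """Binary between-class adjacency: W_b[i, j] = 1 iff i and j belong to
    different classes and either is among the other's k_b nearest
    other-class neighbours (symmetric OR)."""
    if k_b < 1:
        raise ValueError("k_b must be >= 1")
    if feats.class_label is None:
        raise ValueError("between-class graph requires labels")
    X, labels = feats.features, feats.class_label
    n = feats.n_nodes
    if np.unique(labels).size < 2:
        warnings.warn("single class present; between-class graph is empty")
        return np.zeros((n, n))
    D = _pairwise_dist(X)
    W = np.zeros((n, n))
    for i in range(n):
        cand = np.nonzero(labels != labels[i])[0]
        for j in _knn_select(D[i], cand, k_b):
            W[i, j] = W[j, i] = 1.0
    return W


def build_discriminant_graph(feats: PatchFeatureSet, k_w: int = 5,
                             k_b: int = 3) -> DiscriminantGraph:
    return DiscriminantGraph(build_within_graph(feats, k_w),
                             build_between_graph(feats, k_b), feats=feats)


def build_sequence_graph(feats: PatchFeatureSet, k_w: int = 5):
    """Graphs for a single (single-class or unlabeled) sequence.

    All nodes of one sequence share the sequence's viability class, so the
    within-class graph is a plain k-NN graph over its patches and the
    between-class graph is empty; this makes branch forward passes
    label-free at test time.
    """
    dummy = PatchFeatureSet(feats.features, feats.time_index,
                            feats.patch_index,
                            class_label=np.zeros(feats.n_nodes, dtype=int),
                            source_id=feats.source_id)
    W_w = build_within_graph(dummy, k_w)
    W_b = np.zeros_like(W_w)
    return normalize_adjacency(W_w), normalize_adjacency(W_b)


def normalize_adjacency(W: np.ndarray) -> np.ndarray:
    """Degree-symmetric normalization with self-loops:
    W_hat = D^(-1/2) (W + I) D^(-1/2), D = degree of (W + I).

    The self-loop keeps isolated nodes well-defined and bounds the spectral
    radius by 1.
    """
    W = np.asarray(W, dtype=float)
    if W.shape[0] != W.shape[1] or not np.allclose(W, W.T):
        raise ValueError("adjacency must be square symmetric")
    if np.any(W < 0):
        raise ValueError("adjacency must be nonnegative")
    A = W + np.eye(W.shape[0])
    dinv_sqrt = 1.0 / np.sqrt(A.sum(axis=1))
    return A * dinv_sqrt[:, None] * dinv_sqrt[None, :]


def laplacian(W: np.ndarray) -> np.ndarray:
    """Combinatorial graph Laplacian L = Diag - W with
    Diag(i, i) = sum_{j != i} W_ij; rows sum to zero and L is PSD."""
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T):
        raise ValueError("adjacency must be symmetric")
    off = W - np.diag(np.diag(W))
    return np.diag(off.sum(axis=1)) - off


def graph_to_triplets(W: np.ndarray):
    """Sparse (i, j, w) triplet list of the upper triangle, for inspection."""
    iu, ju = np.nonzero(np.triu(W, k=1))
    return [(int(i), int(j), float(W[i, j])) for i, j in zip(iu, ju)]
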