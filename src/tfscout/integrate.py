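"""PCA on highly variable genes and mutual-nearest-neighbor batch correction.

Batches are merged sequentially (largest first by default). For every merge,
mutual k-nearest-neighbor pairs between the accumulated reference and the
incoming batch define per-pair correction vectors; each incoming cell is
shifted by a Gaussian-kernel-weighted average of the vectors of nearby
pairs. Cells already in the reference never move.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from tfscout.qc_norm import NormalizedMatrix


@dataclass
class Embedding:
    """Cells x components coordinates with batch labels."""

    coordinates: np.ndarray
    barcode_ids: np.ndarray
    batch_of_cell: np.ndarray
    corrected: bool = False
    explained_variance_ratio: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class MnnParams:
    k_mnn: int = 20
    smoothing_bandwidth: float | None = None  # None -> median pair-vector length
    merge_order: tuple[str, ...] | str = "size-descending"
    cosine: bool = True  # cosine-normalize before neighbor search

    def __post_init__(self) -> None:
        if self.k_mnn < 1:
            raise ValueError("k_mnn must be >= 1")


def run_pca(
    norm: NormalizedMatrix, hvgs: set[str], n_components: int = 50
) -> Embedding:
    """Exact PCA of the gene-centered HVG submatrix (cells as observations).

    Components are ordered by decreasing explained variance;
    ``min(n_components, rank)`` components are returned (with a warning when
    fewer than requested are available).
    """
    if not hvgs:
        raise ValueError("hvgs must be non-empty")
    if norm.n_cells < 2:
        raise ValueError("PCA needs at least 2 cells")
    idx = norm.gene_index(hvgs)
    if len(idx) == 0:
        raise ValueError("none of the HVG symbols are present in the matrix")
    X = norm.dense()[idx, :].T  # cells x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    rank = int(np.sum(S > S[0] * max(X.shape) * np.finfo(float).eps)) if S.size else 0
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; returning {k}"
        )
    var = S**2
    total_var = var.sum()
    ratio = var[:k] / total_var if total_var > 0 else np.zeros(k)
    return Embedding(
        coordinates=U[:, :k] * S[:k],
        barcode_ids=norm.barcode_ids.copy(),
        batch_of_cell=norm.batch_of_barcode.copy(),
        corrected=False,
        explained_variance_ratio=ratio,
    )


def cosine_normalize(coords: np.ndarray) -> np.ndarray:
    """L2-normalize rows; zero rows are left as zeros."""
    norms = np.linalg.norm(coords, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return coords / norms


def _knn_sets(dist: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest columns per row (stable tie-break by index)."""
    order = np.argsort(dist, axis=1, kind="stable")
    return order[:, :k]


def find_mutual_pairs(
    ref: np.ndarray, new: np.ndarray, k: int
) -> list[tuple[int, int]]:
    """Mutual k-nearest-neighbor pairs (ref index, new index)."""
    dist = cdist(new, ref)
    nn_of_new = _knn_sets(dist, min(k, ref.shape[0]))  # new -> ref
    nn_of_ref = _knn_sets(dist.T, min(k, new.shape[0]))  # ref -> new
    ref_neighbors = [set(row) for row in nn_of_ref]
    pairs = []
    for j in range(new.shape[0]):
        for i in nn_of_new[j]:
            if j in ref_neighbors[i]:
                pairs.append((int(i), int(j)))
    return pairs


def mnn_correct(emb: Embedding, params: MnnParams | None = None) -> Embedding:
    """Sequentially merge batches, shifting each incoming batch onto the reference."""
    params = params or MnnParams()
    batches = np.asarray(emb.batch_of_cell)
    labels, counts = np.unique(batches, return_counts=True)
    if params.merge_order == "size-descending":
        order = [labels[i] for i in np.argsort(-counts, kind="stable")]
    else:
        order = list(params.merge_order)
        if set(order) != set(labels):
            raise ValueError("merge_order must list every batch label exactly once")
    coords = np.array(emb.coordinates, dtype=float)
    if params.cosine:
        coords = cosine_normalize(coords)
    if len(order) == 1:
        return replace(emb, corrected=True)

    ref_mask = batches == order[0]
    for label in order[1:]:
        new_mask = batches == label
        ref = coords[ref_mask]
        new = coords[new_mask]
        k = params.k_mnn
        smallest = min(ref.shape[0], new.shape[0])
        if smallest < k:
            warnings.warn(
                f"batch {label!r}: only {smallest} cells available; lowering k to {smallest}"
            )
            k = smallest
        pairs = find_mutual_pairs(ref, new, k)
        if pairs:
            ref_idx = np.array([p[0] for p in pairs])
            new_idx = np.array([p[1] for p in pairs])
            vectors = ref[ref_idx] - new[new_idx]
            if params.smoothing_bandwidth is not None:
                bandwidth = params.smoothing_bandwidth
            else:
                lengths = np.linalg.norm(vectors, axis=1)
                bandwidth = float(np.median(lengths))
                if bandwidth <= 0:
                    bandwidth = 1.0
            d = cdist(new, new[new_idx])  # distance of each new cell to pair anchors
            w = np.exp(-0.5 * (d / bandwidth) ** 2)
            wsum = w.sum(axis=1, keepdims=True)
            # cells far from every pair fall back to the mean pair vector
            mean_vec = vectors.mean(axis=0)
            shift = np.where(wsum > 1e-12, (w @ vectors) / np.maximum(wsum, 1e-12), mean_vec)
            coords[new_mask] = new + shift
        else:
            warnings.warn(f"batch {label!r}: no mutual pairs found; left unshifted")
        ref_mask = ref_mask | new_mask

    return Embedding(
        coordinates=coords,
        barcode_ids=emb.barcode_ids.copy(),
        batch_of_cell=emb.batch_of_cell.copy(),
        corrected=True,
        explained_variance_ratio=emb.explained_variance_ratio,
    )
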