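"""Shared-nearest-neighbor graph, Louvain communities, cell-cycle scoring."""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from tfscout.integrate import Embedding
from tfscout.qc_norm import NormalizedMatrix


@dataclass(frozen=True)
class ClusterParams:
    k_neighbors: int = 20
    prune_jaccard: float = 1.0 / 15.0
    resolution: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if not 0 <= self.prune_jaccard < 1:
            raise ValueError("prune_jaccard must be in [0, 1)")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-cell integer labels, contiguous from 0
    barcode_ids: np.ndarray
    params: ClusterParams
    modularity: float = float("nan")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def cells_in(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


@dataclass
class CellCycleScore:
    s_score: np.ndarray
    g2m_score: np.ndarray
    phase: np.ndarray  # "S" | "G2M" | "G1"
    barcode_ids: np.ndarray = field(default_factory=lambda: np.array([]))


def _knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """k-nearest-neighbor indices (self included), stable tie-break by index."""
    dist = cdist(coords, coords)
    order = np.argsort(dist, axis=1, kind="stable")
    return order[:, :k]


def build_snn_graph(emb: Embedding, params: ClusterParams | None = None) -> ig.Graph:
    """Weighted SNN graph: edge weight = Jaccard overlap of kNN sets.

    Each cell's neighborhood includes itself (so every set has exactly
    ``k_neighbors`` members). Edges with weight <= the prune threshold are
    removed.
    """
    params = params or ClusterParams()
    n = emb.n_cells
    k = params.k_neighbors
    if k >= n:
        raise ValueError(f"k_neighbors={k} must be < n_cells={n}")
    nn = _knn_indices(np.asarray(emb.coordinates, float), k)
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix(
        (np.ones(n * k), (rows, nn.ravel())), shape=(n, n)
    )
    inter = (adj @ adj.T).tocoo()  # |N(i) & N(j)| for every sharing pair
    mask = inter.row < inter.col
    i_idx, j_idx, shared = inter.row[mask], inter.col[mask], inter.data[mask]
    jaccard = shared / (2 * k - shared)  # |union| = 2k - |intersection|
    keep = jaccard > params.prune_jaccard
    edges = list(zip(i_idx[keep].tolist(), j_idx[keep].tolist()))
    graph = ig.Graph(n=n, edges=edges)
    graph.es["weight"] = jaccard[keep].tolist()
    graph.vs["name"] = list(map(str, emb.barcode_ids))
    return graph


def louvain_cluster(
    graph: ig.Graph, params: ClusterParams | None = None
) -> ClusterAssignment:
    """Louvain communities maximizing resolution-scaled modularity.

    The seed fixes the node sweep order; labels are relabeled to be
    contiguous, ordered by decreasing cluster size.
    """
    params = params or ClusterParams()
    if graph.vcount() == 0:
        raise ValueError("graph is empty")
    barcodes = np.array(
        graph.vs["name"] if "name" in graph.vs.attributes() else range(graph.vcount()),
        dtype=object,
    )
    if graph.ecount() == 0:
        warnings.warn("graph has no edges; every cell becomes its own cluster")
        labels = np.arange(graph.vcount())
        return ClusterAssignment(labels, barcodes, params, modularity=0.0)
    state = random.getstate()
    try:
        random.seed(params.seed)  # python-igraph draws from the stdlib RNG
        clustering = graph.community_multilevel(
            weights="weight", resolution=params.resolution
        )
    finally:
        random.setstate(state)
    membership = np.asarray(clustering.membership)
    # relabel by decreasing size, ties by original label
    unique, counts = np.unique(membership, return_counts=True)
    order = unique[np.lexsort((unique, -counts))]
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array([remap[int(m)] for m in membership])
    modularity = graph.modularity(membership, weights="weight")
    return ClusterAssignment(labels, barcodes, params, modularity=float(modularity))


def score_cell_cycle(
    norm: NormalizedMatrix,
    s_genes: set[str],
    g2m_genes: set[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> CellCycleScore:
    """Module-score phase assignment.

    Per phase gene set: score = mean expression of the set genes minus the
    mean expression of ``n_ctrl`` control genes drawn (per set gene) from
    the same mean-expression bin. Phase is S or G2M if the larger score is
    positive, else G1; an exact positive tie resolves to G2M.
    """
    s_genes = {g.upper() for g in s_genes}
    g2m_genes = {g.upper() for g in g2m_genes}
    present = set(norm.gene_symbols)
    missing = (s_genes | g2m_genes) - present
    if missing:
        if not ((s_genes | g2m_genes) & present):
            raise ValueError("no cell-cycle gene symbols found in the matrix")
        warnings.warn(f"{len(missing)} cell-cycle symbols absent, dropped")
    dense = norm.dense()
    gene_means = dense.mean(axis=1)

    # bin all genes by mean expression
    n_bins = min(n_bins, len(gene_means))
    quantiles = np.quantile(gene_means, np.linspace(0, 1, n_bins + 1))
    bin_of_gene = np.clip(
        np.searchsorted(quantiles, gene_means, side="right") - 1, 0, n_bins - 1
    )
    genes_in_bin = {b: np.flatnonzero(bin_of_gene == b) for b in range(n_bins)}
    rng = np.random.default_rng(seed)

    def module_score(gene_set: set[str]) -> np.ndarray:
        idx = norm.gene_index(gene_set)
        if len(idx) == 0:
            return np.zeros(norm.n_cells)
        ctrl_idx: list[int] = []
        for g in idx:
            pool = genes_in_bin[int(bin_of_gene[g])]
            take = min(n_ctrl, len(pool))
            ctrl_idx.extend(rng.choice(pool, size=take, replace=False).tolist())
        set_mean = dense[idx, :].mean(axis=0)
        ctrl_mean = dense[np.array(ctrl_idx), :].mean(axis=0)
        return set_mean - ctrl_mean

    s_score = module_score(s_genes & present)
    g2m_score = module_score(g2m_genes & present)
    phase = np.where(
        np.maximum(s_score, g2m_score) <= 0,
        "G1",
        np.where(g2m_score >= s_score, "G2M", "S"),
    )
    return CellCycleScore(
        s_score=s_score,
        g2m_score=g2m_score,
        phase=phase.astype(object),
        barcode_ids=norm.barcode_ids.copy(),
    )
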