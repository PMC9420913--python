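"""Centroid-consensus projection of query cells onto an annotated reference.

Reference features are selected by ranking genes on the residual of a
dropout-rate-versus-mean fit; cluster centroids are per-gene medians.
Each query cell is compared to every centroid with cosine, Pearson and
Spearman similarity; each measure votes for its argmax centroid and a cell
is assigned only when enough measures agree and the top similarity clears
the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tfscout.cluster import ClusterAssignment
from tfscout.qc_norm import NormalizedMatrix

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ProjectionParams:
    n_features: int = 500
    similarity_threshold: float = 0.7
    consensus_min_agree: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.consensus_min_agree <= 3:
            raise ValueError("consensus_min_agree must be in [1, 3]")
        if not 0 <= self.similarity_threshold <= 1:
            raise ValueError("similarity_threshold must be in [0, 1]")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")


@dataclass
class ProjectionResult:
    assignments: pd.DataFrame
    """Per query cell: ``assigned`` (reference cluster label or "unassigned")
    plus ``cosine``, ``pearson``, ``spearman`` similarities to the winning
    centroid (to each measure's own best centroid when unassigned)."""


def select_projection_features(ref: NormalizedMatrix, n_features: int) -> list[str]:
    """Rank genes by the residual of a linear dropout-vs-mean fit.

    Genes expressed in every cell or in none carry no dropout signal and
    are excluded.
    """
    dense = ref.dense()
    dropout = (dense == 0).mean(axis=1) * 100.0
    mean_expr = dense.mean(axis=1)
    informative = (dropout > 0) & (dropout < 100) & (mean_expr > 0)
    if informative.sum() == 0:
        raise ValueError("no informative genes for feature selection")
    x = np.log2(mean_expr[informative])
    y = np.log2(dropout[informative])
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    idx = np.flatnonzero(informative)
    order = idx[np.argsort(-residuals, kind="stable")]
    return [str(g) for g in ref.gene_symbols[order[:n_features]]]


def compute_cluster_centroids(
    ref: NormalizedMatrix,
    labels: ClusterAssignment,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene median expression of each cluster, restricted to ``features``.

    Returns a genes x clusters frame indexed by feature symbol.
    """
    if len(labels.labels) != ref.n_cells:
        raise ValueError("labels do not match the matrix")
    dense = ref.dense()
    if features is not None:
        idx = ref.gene_index(features)
        if len(idx) == 0:
            raise ValueError("no selected features present in the reference")
    else:
        idx = np.arange(ref.n_genes)
    clusters = np.unique(labels.labels)
    cols = {}
    for c in clusters:
        members = labels.labels == c
        if members.sum() == 0:
            raise ValueError(f"cluster {c} is empty")
        cols[c] = np.median(dense[np.ix_(idx, np.flatnonzero(members))], axis=1)
    return pd.DataFrame(cols, index=pd.Index(ref.gene_symbols[idx], name="gene"))


def _column_similarities(query_vec: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """(3, n_centroids) matrix of cosine, Pearson, Spearman similarities."""
    n_cent = centroids.shape[1]
    out = np.full((3, n_cent), np.nan)
    qn = np.linalg.norm(query_vec)
    q_rank = stats.rankdata(query_vec)
    for j in range(n_cent):
        c = centroids[:, j]
        cn = np.linalg.norm(c)
        out[0, j] = query_vec @ c / (qn * cn) if qn > 0 and cn > 0 else 0.0
        out[1, j] = _safe_corr(query_vec, c)
        out[2, j] = _safe_corr(q_rank, stats.rankdata(c))
    return out


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def project_to_reference(
    query: NormalizedMatrix,
    centroids: pd.DataFrame,
    params: ProjectionParams | None = None,
    ortholog_map: dict[str, str] | None = None,
) -> ProjectionResult:
    """Assign each query cell to a reference centroid by similarity consensus.

    ``ortholog_map`` translates query symbols to reference symbols
    (uppercased exact matching); the default is the identity map. Errors
    when fewer than 10 features are shared.
    """
    params = params or ProjectionParams()
    mapped = {}
    for i, sym in enumerate(query.gene_symbols):
        target = (ortholog_map or {}).get(sym, sym).upper()
        mapped.setdefault(target, i)
    shared = [g for g in centroids.index if g in mapped]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared features; projection meaningless")
    cent = centroids.loc[shared].to_numpy(dtype=float)
    cluster_labels = list(centroids.columns)
    qdense = query.dense()[[mapped[g] for g in shared], :]

    records = []
    for c in range(query.n_cells):
        sims = _column_similarities(qdense[:, c], cent)
        votes = sims.argmax(axis=1)
        vote_labels, vote_counts = np.unique(votes, return_counts=True)
        winner_pos = vote_labels[np.argmax(vote_counts)]
        n_agree = int(vote_counts.max())
        top_sim = float(np.nanmax(sims[:, winner_pos]))
        if n_agree >= params.consensus_min_agree and top_sim >= params.similarity_threshold:
            assigned = cluster_labels[winner_pos]
            row_sims = sims[:, winner_pos]
        else:
            assigned = UNASSIGNED
            row_sims = sims[np.arange(3), votes]
        records.append(
            {
                "barcode": query.barcode_ids[c],
                "assigned": assigned,
                "cosine": float(row_sims[0]),
                "pearson": float(row_sims[1]),
                "spearman": float(row_sims[2]),
            }
        )
    return ProjectionResult(assignments=pd.DataFrame(records).set_index("barcode"))
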