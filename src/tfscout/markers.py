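"""Marker and transcription-factor candidate discovery.

Three stages: detection-based F1 marker ranking (a gene is "detected" in a
cell when it has at least one UMI), two-sided Wilcoxon rank-sum
differential expression with a minimum detection-fraction filter, and
selection of checklist-matching TF candidates ranked by log fold change of
average expression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tfscout.cluster import ClusterAssignment
from tfscout.qc_norm import CountMatrix, NormalizedMatrix


@dataclass(frozen=True)
class MarkerScore:
    gene: str
    cluster: int
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def f1_marker_scores(
    counts: CountMatrix, clusters: ClusterAssignment, cluster: int
) -> list[MarkerScore]:
    """Rank every gene as a detection marker of one cluster.

    TP = in-cluster cells detecting the gene, FN = in-cluster cells not
    detecting it, FP = out-of-cluster cells detecting it, TN = the rest.
    Genes are sorted by F1 descending, ties broken by precision then symbol.
    """
    in_cluster = clusters.labels == cluster
    n_in = int(in_cluster.sum())
    if n_in == 0:
        raise ValueError(f"cluster {cluster} is empty or absent")
    if counts.n_barcodes != len(clusters.labels):
        raise ValueError("cluster assignment does not match the matrix")
    detected = counts.counts > 0
    tp = np.asarray(detected[:, in_cluster].sum(axis=1)).ravel().astype(int)
    det_total = np.asarray(detected.sum(axis=1)).ravel().astype(int)
    fp = det_total - tp
    fn = n_in - tp
    tn = (counts.n_barcodes - n_in) - fp
    scores = [
        MarkerScore(gene=g, cluster=cluster, tp=int(a), fp=int(b), fn=int(c), tn=int(d))
        for g, a, b, c, d in zip(counts.gene_symbols, tp, fp, fn, tn)
    ]
    scores.sort(key=lambda s: (-s.f1, -s.precision, s.gene))
    return scores


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum differential expression
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 8


def _rank_sum_statistic(pooled_ranks: np.ndarray, idx_a: Sequence[int]) -> float:
    return float(pooled_ranks[list(idx_a)].sum())


def exact_rank_sum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments.

    Counts the assignments whose rank-sum deviates from its mean by at
    least the observed deviation. Handles ties through midranks.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n_a, n = len(a), len(a) + len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n_a].sum()
    mean_w = n_a * (n + 1) / 2.0
    dev = abs(w_obs - mean_w)
    count = 0
    total = 0
    for combo in combinations(range(n), n_a):
        total += 1
        if abs(ranks[list(combo)].sum() - mean_w) >= dev - 1e-12:
            count += 1
    return count / total


def asymptotic_rank_sum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Normal approximation with tie correction and continuity correction."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = ranks[:n_a].sum()
    mean_w = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_w = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var_w <= 0:
        return 1.0
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    z = max(z, 0.0)
    return float(2 * stats.norm.sf(z))


def rank_sum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p: exact enumeration for small groups, else normal."""
    if len(a) <= _EXACT_MAX_N and len(b) <= _EXACT_MAX_N:
        return exact_rank_sum_pvalue(a, b)
    return asymptotic_rank_sum_pvalue(a, b)


def wilcoxon_de(
    norm: NormalizedMatrix,
    clusters: ClusterAssignment,
    cluster: int,
    min_pct: float = 0.25,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential expression of one cluster versus all remaining cells.

    Genes detected (value > 0) in less than ``min_pct`` of cells in both
    groups are skipped. Returns a table with columns ``gene``, ``p_value``,
    ``avg_logfc`` (natural-log fold change of de-logged average expression
    with a pseudocount), ``pct_in``, ``pct_out`` and Bonferroni-adjusted
    ``adjusted_p``, sorted by ``avg_logfc`` descending.
    """
    in_mask = clusters.labels == cluster
    out_mask = ~in_mask
    if in_mask.sum() == 0 or out_mask.sum() == 0:
        raise ValueError("both groups must be non-empty")
    dense = norm.dense()
    x_in = dense[:, in_mask]
    x_out = dense[:, out_mask]
    pct_in = (x_in > 0).mean(axis=1)
    pct_out = (x_out > 0).mean(axis=1)
    tested = np.flatnonzero(np.maximum(pct_in, pct_out) >= min_pct)

    rows = []
    for g in tested:
        a, b = x_in[g], x_out[g]
        mean_in = np.expm1(a).mean()
        mean_out = np.expm1(b).mean()
        logfc = math.log((mean_in + pseudocount) / (mean_out + pseudocount))
        if np.ptp(dense[g]) == 0:  # constant across every cell
            p = 1.0
            logfc = 0.0
        else:
            p = rank_sum_pvalue(a, b)
        rows.append((norm.gene_symbols[g], p, logfc, pct_in[g], pct_out[g]))
    table = pd.DataFrame(
        rows, columns=["gene", "p_value", "avg_logfc", "pct_in", "pct_out"]
    )
    n_tests = len(table)
    table["adjusted_p"] = np.minimum(table["p_value"] * n_tests, 1.0)
    return table.sort_values(
        ["avg_logfc", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


@dataclass
class TfCandidateList:
    cluster: int
    table: pd.DataFrame  # DE records of the selected TFs, logFC descending
    checklist_name: str = "tf_checklist"

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()


def select_candidate_tfs(
    de: pd.DataFrame,
    tf_checklist: Iterable[str],
    top_n: int = 20,
    cluster: int = -1,
    checklist_name: str = "tf_checklist",
) -> TfCandidateList:
    """Keep DE genes whose symbols exactly match the checklist, top ``top_n`` by logFC.

    Matching is exact string equality after uppercasing; ties in logFC break
    by gene symbol.
    """
    checklist = {str(s).upper() for s in tf_checklist}
    if not checklist:
        raise ValueError("tf_checklist must be non-empty")
    hits = de[de["gene"].str.upper().isin(checklist)].copy()
    hits = hits.sort_values(
        ["avg_logfc", "gene"], ascending=[False, True], kind="stable"
    )
    if len(hits) == 0:
        warnings.warn("no DE genes matched the TF checklist")
    elif len(hits) < top_n:
        warnings.warn(f"only {len(hits)} eligible TFs (requested {top_n})")
    return TfCandidateList(
        cluster=cluster,
        table=hits.head(top_n).reset_index(drop=True),
        checklist_name=checklist_name,
    )
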