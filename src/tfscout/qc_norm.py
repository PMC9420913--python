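"""Pre-clustering stages: droplet QC, ambient flagging, normalization, HVGs.

All thresholds use strict inequalities: a barcode is an empty droplet when
its total UMI count is strictly below ``empty_umi_threshold``; a gene is
ambient when its share of counts in empty droplets is strictly above
``ambient_fraction_threshold``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess


class QcError(ValueError):
    """Raised when a QC operation cannot proceed (e.g. all cells removed)."""


@dataclass(frozen=True)
class QcParams:
    """Thresholds for the pre-clustering stages.

    Attributes
    ----------
    empty_umi_threshold
        Barcodes with total UMIs strictly below this are empty droplets.
    ambient_fraction_threshold
        Genes with strictly more than this fraction of their counts in
        empty droplets are flagged ambient.
    normalization_scale_factor
        Per-cell counts are scaled to this total before ``log1p``.
    n_hvgs
        Number of highly variable genes to select.
    """

    empty_umi_threshold: int = 50
    ambient_fraction_threshold: float = 0.30
    normalization_scale_factor: float = 10_000.0
    n_hvgs: int = 2000

    def __post_init__(self) -> None:
        if self.empty_umi_threshold < 1:
            raise ValueError("empty_umi_threshold must be >= 1")
        if not 0.0 < self.ambient_fraction_threshold < 1.0:
            raise ValueError("ambient_fraction_threshold must be in (0, 1)")
        if self.normalization_scale_factor <= 0:
            raise ValueError("normalization_scale_factor must be positive")
        if self.n_hvgs < 1:
            raise ValueError("n_hvgs must be >= 1")


@dataclass
class CountMatrix:
    """Sparse genes x barcodes UMI count matrix with per-barcode labels."""

    counts: sp.csr_matrix
    gene_symbols: np.ndarray
    barcode_ids: np.ndarray
    batch_of_barcode: np.ndarray
    stage_of_barcode: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_symbols = np.asarray(
            [str(s).upper() for s in self.gene_symbols], dtype=object
        )
        self.barcode_ids = np.asarray(self.barcode_ids, dtype=object)
        self.batch_of_barcode = np.asarray(self.batch_of_barcode, dtype=object)
        n_genes, n_barcodes = self.counts.shape
        if len(self.gene_symbols) != n_genes:
            raise ValueError("gene_symbols length mismatch")
        if len(self.barcode_ids) != n_barcodes:
            raise ValueError("barcode_ids length mismatch")
        if len(self.batch_of_barcode) != n_barcodes:
            raise ValueError("batch_of_barcode length mismatch")
        if self.stage_of_barcode is not None:
            self.stage_of_barcode = np.asarray(self.stage_of_barcode, dtype=object)
            if len(self.stage_of_barcode) != n_barcodes:
                raise ValueError("stage_of_barcode length mismatch")
        if len(set(self.gene_symbols)) != n_genes:
            raise ValueError("gene symbols must be unique after uppercasing")
        if len(set(self.barcode_ids)) != n_barcodes:
            raise ValueError("barcode ids must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[1]

    def barcode_totals(self) -> np.ndarray:
        """Total UMIs per barcode (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def gene_index(self, symbols: Iterable[str]) -> np.ndarray:
        """Row indices of the given symbols (uppercased); absent symbols skipped."""
        lookup = {s: i for i, s in enumerate(self.gene_symbols)}
        return np.array(
            [lookup[s.upper()] for s in symbols if s.upper() in lookup], dtype=int
        )

    def subset_barcodes(self, keep: np.ndarray) -> "CountMatrix":
        """New matrix restricted to the barcodes selected by ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            counts=self.counts[:, keep].tocsr(),
            gene_symbols=self.gene_symbols.copy(),
            barcode_ids=self.barcode_ids[keep],
            batch_of_barcode=self.batch_of_barcode[keep],
            stage_of_barcode=(
                None if self.stage_of_barcode is None else self.stage_of_barcode[keep]
            ),
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, genes x cells. Zero counts stay exactly zero."""

    values: sp.csr_matrix
    gene_symbols: np.ndarray
    barcode_ids: np.ndarray
    batch_of_barcode: np.ndarray
    provenance: QcParams = field(default_factory=QcParams)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def gene_index(self, symbols: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.gene_symbols)}
        return np.array(
            [lookup[s.upper()] for s in symbols if s.upper() in lookup], dtype=int
        )


def detect_empty_droplets(counts: CountMatrix, params: QcParams | None = None) -> set[str]:
    """Barcodes whose total UMI count is strictly below the threshold."""
    params = params or QcParams()
    totals = counts.barcode_totals()
    mask = totals < params.empty_umi_threshold
    return set(counts.barcode_ids[mask])


def flag_ambient_genes(
    counts: CountMatrix, empties: set[str], params: QcParams | None = None
) -> set[str]:
    """Genes whose empty-droplet count share strictly exceeds the threshold.

    Genes with zero total count are never flagged. The result is invariant
    to barcode and gene order.
    """
    params = params or QcParams()
    unknown = empties - set(counts.barcode_ids)
    if unknown:
        raise ValueError(f"empties contains unknown barcodes: {sorted(unknown)[:5]}")
    empty_mask = np.array([b in empties for b in counts.barcode_ids])
    gene_totals = np.asarray(counts.counts.sum(axis=1)).ravel()
    empty_counts = np.asarray(counts.counts[:, empty_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(gene_totals > 0, empty_counts / np.maximum(gene_totals, 1), 0.0)
    flagged = (gene_totals > 0) & (frac > params.ambient_fraction_threshold)
    return set(counts.gene_symbols[flagged])


def exclude_cells_by_markers(
    counts: CountMatrix,
    marker_sets: Mapping[str, Iterable[str]],
    min_detected: int = 1,
) -> CountMatrix:
    """Remove barcodes detecting >= ``min_detected`` genes of any one marker set.

    Detection means count >= 1. Symbols absent from the matrix are ignored
    with a warning. Returns a new matrix; the input is untouched.
    """
    if min_detected < 1:
        raise ValueError("min_detected must be >= 1")
    drop = np.zeros(counts.n_barcodes, dtype=bool)
    detected = counts.counts > 0
    for name, symbols in marker_sets.items():
        symbols = [s.upper() for s in symbols]
        idx = counts.gene_index(symbols)
        missing = set(symbols) - set(counts.gene_symbols[idx])
        if missing:
            warnings.warn(
                f"marker set {name!r}: symbols absent from matrix, ignored: "
                f"{sorted(missing)}"
            )
        if len(idx) == 0:
            continue
        n_hit = np.asarray(detected[idx, :].sum(axis=0)).ravel()
        drop |= n_hit >= min_detected
    if drop.all():
        raise QcError("marker-based exclusion removed every cell")
    return counts.subset_barcodes(~drop)


def exclude_clusters_by_markers(
    counts: CountMatrix,
    cluster_labels: np.ndarray,
    marker_sets: Mapping[str, Iterable[str]],
    min_detected: int = 1,
    min_positive_fraction: float = 0.5,
) -> CountMatrix:
    """Whole-cluster variant of marker gating.

    Removes every cell of any cluster in which more than
    ``min_positive_fraction`` of cells detect >= ``min_detected`` genes of
    one marker set. Per-cell gating (:func:`exclude_cells_by_markers`) is
    the default mode of the pipeline.
    """
    cluster_labels = np.asarray(cluster_labels)
    if len(cluster_labels) != counts.n_barcodes:
        raise ValueError("cluster_labels length mismatch")
    detected = counts.counts > 0
    positive = np.zeros(counts.n_barcodes, dtype=bool)
    for name, symbols in marker_sets.items():
        idx = counts.gene_index([s.upper() for s in symbols])
        if len(idx) == 0:
            warnings.warn(f"marker set {name!r}: no symbols present, skipped")
            continue
        n_hit = np.asarray(detected[idx, :].sum(axis=0)).ravel()
        positive |= n_hit >= min_detected
    drop = np.zeros(counts.n_barcodes, dtype=bool)
    for label in np.unique(cluster_labels):
        members = cluster_labels == label
        if positive[members].mean() > min_positive_fraction:
            drop |= members
    if drop.all():
        raise QcError("cluster-level exclusion removed every cell")
    return counts.subset_barcodes(~drop)


def log_normalize(counts: CountMatrix, params: QcParams | None = None) -> NormalizedMatrix:
    """``ln(1 + scale_factor * count / cell_total)`` per entry.

    Errors on any zero-total cell, naming the first offending barcode.
    """
    params = params or QcParams()
    totals = counts.barcode_totals().astype(float)
    if (totals == 0).any():
        bad = counts.barcode_ids[np.flatnonzero(totals == 0)[0]]
        raise QcError(f"cell with zero total counts: {bad!r}")
    mat = counts.counts.tocsc(copy=True).astype(float)
    # scale columns so each cell sums to scale_factor, then log1p on the
    # stored (non-zero) entries only: zeros map to exactly zero
    scale = params.normalization_scale_factor / totals
    mat = mat @ sp.diags(scale)
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(
        values=mat.tocsr(),
        gene_symbols=counts.gene_symbols.copy(),
        barcode_ids=counts.barcode_ids.copy(),
        batch_of_barcode=counts.batch_of_barcode.copy(),
        provenance=params,
    )


def scaled_cell_sums(counts: CountMatrix, params: QcParams | None = None) -> np.ndarray:
    """Per-cell sums of the pre-log scaled values (each equals the scale factor).

    Exposed for the conservation check in the test suite.
    """
    params = params or QcParams()
    totals = counts.barcode_totals().astype(float)
    if (totals == 0).any():
        raise QcError("zero-total cell")
    scaled = counts.counts.multiply(params.normalization_scale_factor / totals)
    return np.asarray(scaled.sum(axis=0)).ravel()


def _fit_variance_trend(means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Smooth mean -> variance trend evaluated at each gene's mean.

    Local (lowess) regression when enough genes support it; a monotone
    interpolant through binned medians for tiny fixtures.
    """
    n = len(means)
    order = np.argsort(means, kind="stable")
    if n >= 30:
        fitted_sorted = lowess(
            variances[order], means[order], frac=0.3, it=3, return_sorted=False
        )
        fitted = np.empty(n)
        fitted[order] = fitted_sorted
        return fitted
    # tiny fixture fallback: piecewise-linear through a running median
    from scipy.interpolate import interp1d

    ms, vs = means[order], variances[order]
    uniq, inv = np.unique(ms, return_inverse=True)
    med = np.array([np.median(vs[inv == i]) for i in range(len(uniq))])
    if len(uniq) == 1:
        return np.full(n, med[0])
    f = interp1d(uniq, med, bounds_error=False, fill_value=(med[0], med[-1]))
    return f(means)


def decompose_variance(
    norm: NormalizedMatrix,
    ambient: set[str] | Sequence[str] = (),
    params: QcParams | None = None,
) -> pd.DataFrame:
    """Split per-gene variance into a fitted technical trend and a residual.

    Returns a table indexed by gene symbol with columns ``mean``, ``total``,
    ``technical``, ``biological`` and ``selected``. ``biological`` is exactly
    ``total - technical``; the top ``n_hvgs`` genes by biological variance,
    ambient genes excluded, are marked selected.
    """
    params = params or QcParams()
    if norm.n_cells < 2:
        raise QcError("variance decomposition needs >= 2 cells")
    ambient = {s.upper() for s in ambient}
    dense = norm.dense()
    means = dense.mean(axis=1)
    totals = dense.var(axis=1, ddof=1)
    technical = _fit_variance_trend(means, totals)
    biological = totals - technical

    table = pd.DataFrame(
        {
            "mean": means,
            "total": totals,
            "technical": technical,
            "biological": biological,
        },
        index=pd.Index(norm.gene_symbols, name="gene"),
    )
    eligible = ~table.index.isin(ambient) & (table["total"] > 0)
    n_eligible = int(eligible.sum())
    n_select = params.n_hvgs
    if n_eligible < n_select:
        warnings.warn(
            f"only {n_eligible} non-ambient variable genes available; "
            f"selecting all (requested {n_select})"
        )
        n_select = n_eligible
    ranked = table.loc[eligible].sort_values(
        ["biological"], ascending=False, kind="stable"
    )
    chosen = set(ranked.index[:n_select])
    table["selected"] = [g in chosen for g in table.index]
    return table
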