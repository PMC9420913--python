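"""Synthetic single-cell counts and qPCR tables with planted ground truth.

Counts are negative-binomial (mean/dispersion parameterization) with
cluster-specific marker boosts, per-(gene, batch) log-normal multiplicative
batch factors, optional cell-cycle programs, and ambient-profile empty
droplets whose totals stay strictly below 50 UMIs. A single seed is split
into independent sub-streams so extending one feature never perturbs the
draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from tfscout.qc_norm import CountMatrix

_N_CELLCYCLE_GENES = 20
_EMPTY_MAX_TOTAL = 50  # empty-droplet totals are strictly below this
_CELLCYCLE_CELL_FRACTION = 0.10


class SimConfigError(ValueError):
    """Raised for contradictory simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 1000
    n_cells_per_cluster: tuple[int, ...] | int = 200
    n_clusters: int = 3
    n_batches: int = 2
    batch_effect_sd: float = 0.1
    marker_genes_per_cluster: int = 20
    marker_fold_change: float = 4.0
    tf_fraction_of_markers: float = 0.5
    nb_dispersion: float = 0.1
    mean_library_size: float = 2000.0
    n_empty_droplets: int = 0
    ambient_gene_fraction: float = 0.02
    cellcycle_program_strength: float = 1.0
    seed: int = 0

    def cells_per_cluster(self) -> tuple[int, ...]:
        if isinstance(self.n_cells_per_cluster, int):
            return (self.n_cells_per_cluster,) * self.n_clusters
        return tuple(self.n_cells_per_cluster)

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_clusters < 1 or self.n_batches < 1:
            raise SimConfigError("n_genes, n_clusters, n_batches must be >= 1")
        if self.n_empty_droplets < 0:
            raise SimConfigError("n_empty_droplets must be >= 0")
        sizes = self.cells_per_cluster()
        if len(sizes) != self.n_clusters:
            raise SimConfigError("n_cells_per_cluster length must equal n_clusters")
        if any(s < 1 for s in sizes):
            raise SimConfigError("cluster sizes must be >= 1")
        if self.marker_fold_change <= 1:
            raise SimConfigError("marker_fold_change must be > 1")
        if not 0 <= self.tf_fraction_of_markers <= 1:
            raise SimConfigError("tf_fraction_of_markers must be in [0, 1]")
        if not 0 <= self.ambient_gene_fraction <= 1:
            raise SimConfigError("ambient_gene_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0 or self.mean_library_size <= 0:
            raise SimConfigError("nb_dispersion and mean_library_size must be > 0")
        if self.batch_effect_sd < 0:
            raise SimConfigError("batch_effect_sd must be >= 0")
        if self.cellcycle_program_strength < 1:
            raise SimConfigError("cellcycle_program_strength must be >= 1")
        n_markers = self.marker_genes_per_cluster * self.n_clusters
        n_ambient = int(round(self.ambient_gene_fraction * self.n_genes))
        n_reserved = n_markers + n_ambient + 2 * _N_CELLCYCLE_GENES
        if n_reserved > self.n_genes:
            raise SimConfigError(
                f"config reserves {n_reserved} special genes "
                f"(markers {n_markers}, ambient {n_ambient}, cell-cycle "
                f"{2 * _N_CELLCYCLE_GENES}) but only n_genes={self.n_genes} exist"
            )


@dataclass
class GroundTruth:
    true_cluster_of_cell: dict[str, int]
    true_markers_of_cluster: dict[int, set[str]]
    true_tfs_of_cluster: dict[int, set[str]]
    ambient_genes: set[str]
    batch_of_cell: dict[str, str]
    s_program_cells: set[str]
    g2m_program_cells: set[str]
    s_genes: set[str] = field(default_factory=set)
    g2m_genes: set[str] = field(default_factory=set)

    def all_true_tfs(self) -> set[str]:
        out: set[str] = set()
        for tfs in self.true_tfs_of_cluster.values():
            out |= tfs
        return out


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion * mu^2."""
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Generate a genes x (cells + empty droplets) count matrix with truth."""
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_base = np.random.default_rng(streams[0])
    rng_batch = np.random.default_rng(streams[1])
    rng_counts = np.random.default_rng(streams[2])
    rng_cc = np.random.default_rng(streams[3])
    rng_empty = np.random.default_rng(streams[4])

    G = config.n_genes
    sizes = config.cells_per_cluster()
    n_cells = sum(sizes)
    n_ambient = int(round(config.ambient_gene_fraction * G))

    width = max(4, len(str(G)))
    genes = np.array([f"GENE{i:0{width}d}" for i in range(G)], dtype=object)

    # reserved gene blocks: cluster markers, then S / G2M programs, then ambient
    pos = 0
    markers_of_cluster: dict[int, set[str]] = {}
    tfs_of_cluster: dict[int, set[str]] = {}
    marker_rows: dict[int, np.ndarray] = {}
    for k in range(config.n_clusters):
        rows = np.arange(pos, pos + config.marker_genes_per_cluster)
        pos += config.marker_genes_per_cluster
        marker_rows[k] = rows
        markers_of_cluster[k] = set(genes[rows])
        n_tf = int(round(config.tf_fraction_of_markers * len(rows)))
        tfs_of_cluster[k] = set(genes[rows[:n_tf]])
    s_rows = np.arange(pos, pos + _N_CELLCYCLE_GENES)
    pos += _N_CELLCYCLE_GENES
    g2m_rows = np.arange(pos, pos + _N_CELLCYCLE_GENES)
    pos += _N_CELLCYCLE_GENES
    ambient_rows = np.arange(pos, pos + n_ambient)
    pos += n_ambient

    # baseline relative abundances (log-normal), normalized to a library profile
    base = rng_base.lognormal(mean=0.0, sigma=1.0, size=G)
    base /= base.sum()
    mu_gene = config.mean_library_size * base  # expected counts per gene per cell

    batch_labels = np.array([f"batch{b}" for b in range(config.n_batches)], dtype=object)
    log_factors = rng_batch.normal(0.0, config.batch_effect_sd, size=(G, config.n_batches))
    batch_factor = np.exp(log_factors)

    cluster_of_cell = np.concatenate(
        [np.full(s, k, dtype=int) for k, s in enumerate(sizes)]
    )
    batch_idx = np.arange(n_cells) % config.n_batches

    # cell-cycle program membership (disjoint S / G2M subsets per cluster)
    s_cells_mask = np.zeros(n_cells, dtype=bool)
    g2m_cells_mask = np.zeros(n_cells, dtype=bool)
    if config.cellcycle_program_strength > 1:
        n_cc = max(1, int(round(_CELLCYCLE_CELL_FRACTION * n_cells)))
        chosen = rng_cc.choice(n_cells, size=min(2 * n_cc, n_cells), replace=False)
        s_cells_mask[chosen[:n_cc]] = True
        g2m_cells_mask[chosen[n_cc : 2 * n_cc]] = True

    mu = np.tile(mu_gene[:, None], (1, n_cells))
    for k in range(config.n_clusters):
        cols = cluster_of_cell == k
        mu[np.ix_(marker_rows[k], cols)] *= config.marker_fold_change
    mu *= batch_factor[:, batch_idx]
    if config.cellcycle_program_strength > 1:
        mu[np.ix_(s_rows, np.flatnonzero(s_cells_mask))] *= config.cellcycle_program_strength
        mu[np.ix_(g2m_rows, np.flatnonzero(g2m_cells_mask))] *= config.cellcycle_program_strength

    cells = _nb_sample(rng_counts, mu, config.nb_dispersion).astype(np.int64)

    # guarantee real cells stay out of the empty-droplet domain (< 50 UMIs)
    totals = cells.sum(axis=0)
    for c in np.flatnonzero(totals < _EMPTY_MAX_TOTAL):
        top_gene = int(np.argmax(mu[:, c]))
        cells[top_gene, c] += _EMPTY_MAX_TOTAL - int(totals[c])

    # empty droplets: multinomial draws from the ambient gene pool
    n_empty = config.n_empty_droplets
    empty_cols = np.zeros((G, n_empty), dtype=np.int64)
    if n_empty > 0:
        if n_ambient == 0:
            raise SimConfigError("n_empty_droplets > 0 requires ambient genes")
        ambient_weights = base[ambient_rows]
        ambient_weights = ambient_weights / ambient_weights.sum()
        empty_totals = rng_empty.integers(10, _EMPTY_MAX_TOTAL, size=n_empty)
        for j, tot in enumerate(empty_totals):
            empty_cols[ambient_rows, j] = rng_empty.multinomial(tot, ambient_weights)

    counts = np.concatenate([cells, empty_cols], axis=1)
    cell_ids = np.array([f"CELL{i:06d}" for i in range(n_cells)], dtype=object)
    empty_ids = np.array([f"EMPTY{i:06d}" for i in range(n_empty)], dtype=object)
    barcodes = np.concatenate([cell_ids, empty_ids])
    batch_of_barcode = np.concatenate(
        [
            batch_labels[batch_idx],
            batch_labels[np.arange(n_empty) % config.n_batches],
        ]
    )

    matrix = CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_symbols=genes,
        barcode_ids=barcodes,
        batch_of_barcode=batch_of_barcode,
    )
    truth = GroundTruth(
        true_cluster_of_cell={cid: int(k) for cid, k in zip(cell_ids, cluster_of_cell)},
        true_markers_of_cluster=markers_of_cluster,
        true_tfs_of_cluster=tfs_of_cluster,
        ambient_genes=set(genes[ambient_rows]),
        batch_of_cell={bid: str(b) for bid, b in zip(barcodes, batch_of_barcode)},
        s_program_cells=set(cell_ids[s_cells_mask]),
        g2m_program_cells=set(cell_ids[g2m_cells_mask]),
        s_genes=set(genes[s_rows]),
        g2m_genes=set(genes[g2m_rows]),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

LV2_GENE = "LV2"
ACTIN_GENE = "ACTB"
_ACTIN_BASE_CT = 20.0
_TARGET_BASE_CT_OFFSET = 2.0
_REF_RELATIVE_COPY = 1.0


@dataclass(frozen=True)
class QpcrSimConfig:
    true_fold_changes: Mapping[str, float] = field(default_factory=dict)
    housekeeping_ct: float = 18.0
    amplification_efficiency: float = 2.0
    ct_noise_sd: float = 0.0
    replicates: int = 3
    titration_volumes: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 15.0)
    true_titer: float = 2.0e5
    n_cells_transduced: int = 100_000
    moi: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1.0 < self.amplification_efficiency <= 2.0:
            raise SimConfigError("amplification_efficiency must be in (1, 2]")
        if self.ct_noise_sd < 0:
            raise SimConfigError("ct_noise_sd must be >= 0")
        if self.replicates < 1:
            raise SimConfigError("replicates must be >= 1")
        vols = tuple(self.titration_volumes)
        if len(vols) != len(set(vols)) or any(v <= 0 for v in vols):
            raise SimConfigError("titration volumes must be positive and distinct")
        if any(f <= 0 for f in self.true_fold_changes.values()):
            raise SimConfigError("fold changes must be positive")
        if self.true_titer <= 0 or self.moi <= 0 or self.n_cells_transduced < 1:
            raise SimConfigError("true_titer, moi, n_cells_transduced must be positive")


@dataclass
class TitrationTable:
    """Per-volume LV2 / beta-actin Ct replicates plus the reference context."""

    frame: pd.DataFrame  # columns: volume, gene, replicate, ct
    lv2_gene: str
    actin_gene: str
    ref_relative_copy: float
    n_cells: int
    moi: float


def simulate_qpcr(config: QpcrSimConfig) -> tuple[pd.DataFrame, TitrationTable]:
    """Generate a ddCt-design Ct table and a titration table.

    Ct values follow ``Ct = Ct_ref - log_E(relative quantity) + noise``.
    The titration encodes ``true_titer`` through the volume-per-dose
    relation: at the reference virus's relative copy number the fitted
    curve returns ``VPD = n_cells * moi / true_titer``.
    """
    streams = np.random.SeedSequence(config.seed).spawn(2)
    rng_ct = np.random.default_rng(streams[0])
    rng_tit = np.random.default_rng(streams[1])
    log_e = np.log(config.amplification_efficiency)

    def noise(rng, size):
        if config.ct_noise_sd == 0:
            return np.zeros(size)
        return rng.normal(0.0, config.ct_noise_sd, size)

    rows = []
    target_base_ct = config.housekeeping_ct + _TARGET_BASE_CT_OFFSET
    for sample, fold_map in (
        ("REFERENCE", {g: 1.0 for g in config.true_fold_changes}),
        ("TREATED", dict(config.true_fold_changes)),
    ):
        for gene, fold in sorted(fold_map.items()):
            cts = target_base_ct - np.log(fold) / log_e + noise(rng_ct, config.replicates)
            for r, ct in enumerate(cts, start=1):
                rows.append((sample, gene.upper(), r, float(ct)))
        hk = config.housekeeping_ct + noise(rng_ct, config.replicates)
        for r, ct in enumerate(hk, start=1):
            rows.append((sample, ACTIN_GENE, r, float(ct)))
    ct_table = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])

    vpd_true = config.n_cells_transduced * config.moi / config.true_titer
    slope = vpd_true / _REF_RELATIVE_COPY  # volume = slope * relative copy
    tit_rows = []
    for volume in config.titration_volumes:
        rel_copy = volume / slope
        lv2_ct = _ACTIN_BASE_CT - np.log(rel_copy) / log_e
        for r in range(1, config.replicates + 1):
            tit_rows.append(
                (float(volume), LV2_GENE, r, float(lv2_ct + noise(rng_tit, 1)[0]))
            )
            tit_rows.append(
                (float(volume), ACTIN_GENE, r, float(_ACTIN_BASE_CT + noise(rng_tit, 1)[0]))
            )
    titration = TitrationTable(
        frame=pd.DataFrame(tit_rows, columns=["volume", "gene", "replicate", "ct"]),
        lv2_gene=LV2_GENE,
        actin_gene=ACTIN_GENE,
        ref_relative_copy=_REF_RELATIVE_COPY,
        n_cells=config.n_cells_transduced,
        moi=config.moi,
    )
    return ct_table, titration
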