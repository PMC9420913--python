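import numpy as np
import pytest
import scipy.sparse as sp

from tfscout.cluster import ClusterAssignment, ClusterParams
from tfscout.qc_norm import CountMatrix, log_normalize
from tfscout.simdata import SimConfig, simulate_counts


def make_count_matrix(counts, genes=None, barcodes=None, batches=None):
    counts = np.asarray(counts)
    n_genes, n_barcodes = counts.shape
    if genes is None:
        genes = [f"G{i}" for i in range(n_genes)]
    if barcodes is None:
        barcodes = [f"BC{i}" for i in range(n_barcodes)]
    if batches is None:
        batches = ["batch0"] * n_barcodes
    return CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_symbols=np.array(genes, dtype=object),
        barcode_ids=np.array(barcodes, dtype=object),
        batch_of_barcode=np.array(batches, dtype=object),
    )


def make_assignment(labels, barcodes=None):
    labels = np.asarray(labels, dtype=int)
    if barcodes is None:
        barcodes = np.array([f"BC{i}" for i in range(len(labels))], dtype=object)
    return ClusterAssignment(
        labels=labels, barcode_ids=np.asarray(barcodes, dtype=object),
        params=ClusterParams(),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared across tests (read-only)."""
    config = SimConfig(
        n_genes=400,
        n_cells_per_cluster=80,
        n_clusters=3,
        n_batches=2,
        n_empty_droplets=40,
        marker_fold_change=5.0,
        cellcycle_program_strength=4.0,
        seed=11,
    )
    return simulate_counts(config)


@pytest.fixture(scope="session")
def small_norm(small_sim):
    matrix, truth = small_sim
    cells = matrix.subset_barcodes(
        np.array([b.startswith("CELL") for b in matrix.barcode_ids])
    )
    return log_normalize(cells), truth
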