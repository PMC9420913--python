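"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as a 10x-style triplet: ``matrix.mtx`` (Matrix Market
coordinate, integer, genes x barcodes), ``features.tsv`` and
``barcodes.tsv``. Per-barcode batch/stage labels live in a separate TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from tfscout.qc_norm import CountMatrix


def write_counts(matrix: CountMatrix, directory: str | Path) -> Path:
    """Write a CountMatrix as matrix.mtx + features.tsv + barcodes.tsv + labels.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = matrix.counts.tocoo()
    scipy.io.mmwrite(directory / "matrix.mtx", coo, field="integer")
    pd.DataFrame(
        {"id": matrix.gene_symbols, "name": matrix.gene_symbols, "type": "Gene Expression"}
    ).to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(matrix.barcode_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
    labels = pd.DataFrame(
        {"barcode": matrix.barcode_ids, "batch": matrix.batch_of_barcode}
    )
    if matrix.stage_of_barcode is not None:
        labels["stage"] = matrix.stage_of_barcode
    labels.to_csv(directory / "labels.tsv", sep="\t", index=False)
    return directory


def read_counts(directory: str | Path, labels_file: str | Path | None = None) -> CountMatrix:
    """Read a 10x-style triplet directory back into a CountMatrix.

    Batch labels come from ``labels.tsv`` in the directory (or an explicit
    ``labels_file``); if absent every barcode lands in batch ``"batch0"``.
    """
    directory = Path(directory)
    counts = sp.csr_matrix(scipy.io.mmread(directory / "matrix.mtx"))
    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)
    symbols = features.iloc[:, 1 if features.shape[1] > 1 else 0].astype(str).to_numpy()
    ids = barcodes.iloc[:, 0].astype(str).to_numpy()

    labels_path = Path(labels_file) if labels_file else directory / "labels.tsv"
    batch = np.array(["batch0"] * len(ids), dtype=object)
    stage = None
    if labels_path.exists():
        labels = pd.read_csv(labels_path, sep="\t").set_index("barcode")
        labels = labels.reindex(ids)
        batch = labels["batch"].fillna("batch0").to_numpy(dtype=object)
        if "stage" in labels.columns:
            stage = labels["stage"].to_numpy(dtype=object)
    return CountMatrix(
        counts=counts,
        gene_symbols=symbols,
        barcode_ids=ids,
        batch_of_barcode=batch,
        stage_of_barcode=stage,
    )


def read_gene_list(path: str | Path) -> list[str]:
    """One uppercased symbol per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.upper())
    return out


def write_gene_list(symbols, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(str(s).upper() for s in symbols) + "\n")
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default, sort_keys=True))
    return path


def bundled_cell_cycle_genes() -> tuple[list[str], list[str]]:
    """The shipped human S-phase and G2/M gene lists (symbol substitution
    for non-human data is the caller's responsibility)."""
    data = Path(__file__).parent / "data"
    return (
        read_gene_list(data / "s_genes.txt"),
        read_gene_list(data / "g2m_genes.txt"),
    )


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Ct table CSV with columns sample, gene, replicate, ct."""
    table = pd.read_csv(path)
    required = {"sample", "gene", "replicate", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    table["gene"] = table["gene"].astype(str).str.upper()
    return table
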