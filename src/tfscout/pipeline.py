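"""End-to-end composition of the analysis stages.

qc -> hvg -> pca -> mnn -> snn/louvain -> cell-cycle -> f1 markers -> DE ->
TF selection, with per-stage TSV outputs and a JSON run manifest. A single
pipeline seed fans out deterministically to per-stage seeds.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tfscout import io as tio
from tfscout.cluster import ClusterParams, build_snn_graph, louvain_cluster, score_cell_cycle
from tfscout.integrate import MnnParams, mnn_correct, run_pca
from tfscout.markers import f1_marker_scores, select_candidate_tfs, wilcoxon_de
from tfscout.qc_norm import (
    CountMatrix,
    QcParams,
    detect_empty_droplets,
    decompose_variance,
    exclude_cells_by_markers,
    flag_ambient_genes,
    log_normalize,
)
from tfscout.report import composition_table

logger = logging.getLogger("tfscout.pipeline")

_STAGE_SEED_STEP = 10_007  # prime stride: stage seeds stay distinct per stage index


@dataclass
class PipelineConfig:
    qc: QcParams = field(default_factory=QcParams)
    mnn: MnnParams = field(default_factory=MnnParams)
    clustering: ClusterParams = field(default_factory=ClusterParams)
    n_pcs: int = 50
    min_pct: float = 0.25
    top_n_tfs: int = 20
    pseudocount: float = 1.0
    exclusion_marker_sets: dict[str, list[str]] = field(default_factory=dict)
    exclusion_min_detected: int = 1
    s_genes: list[str] = field(default_factory=list)
    g2m_genes: list[str] = field(default_factory=list)
    tf_checklist: list[str] = field(default_factory=list)
    seed: int = 0
    output_dir: Path | str = "tfscout_out"

    def stage_seed(self, stage_index: int) -> int:
        return (self.seed + _STAGE_SEED_STEP * (stage_index + 1)) % (2**31 - 1)


@dataclass
class PipelineResult:
    clusters: "pd.DataFrame"
    tf_candidates: dict[int, pd.DataFrame]
    manifest: dict


def run_pipeline(counts: CountMatrix, config: PipelineConfig) -> PipelineResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "params": {
            "qc": vars(config.qc),
            "n_pcs": config.n_pcs,
            "clustering": {
                "k_neighbors": config.clustering.k_neighbors,
                "resolution": config.clustering.resolution,
                "prune_jaccard": config.clustering.prune_jaccard,
            },
            "min_pct": config.min_pct,
            "top_n_tfs": config.top_n_tfs,
        },
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)

        def done(**info):
            dt = time.perf_counter() - t0
            logger.info("stage %s: done in %.2fs", name, dt)
            manifest["stages"][name] = info

        return done

    # --- QC --------------------------------------------------------------
    done = stage("qc")
    empties = detect_empty_droplets(counts, config.qc)
    ambient = flag_ambient_genes(counts, empties, config.qc)
    keep = np.array([b not in empties for b in counts.barcode_ids])
    cells = counts.subset_barcodes(keep)
    if config.exclusion_marker_sets:
        cells = exclude_cells_by_markers(
            cells, config.exclusion_marker_sets, config.exclusion_min_detected
        )
    done(n_empty=len(empties), n_ambient=len(ambient), n_cells=cells.n_barcodes)

    # --- normalize + HVGs ------------------------------------------------
    done = stage("hvg")
    norm = log_normalize(cells, config.qc)
    hvg_table = decompose_variance(norm, ambient, config.qc)
    hvgs = set(hvg_table.index[hvg_table["selected"]])
    hvg_table.to_csv(out / "hvg_table.tsv", sep="\t")
    done(n_hvgs=len(hvgs))

    # --- PCA + MNN -------------------------------------------------------
    done = stage("integrate")
    emb = run_pca(norm, hvgs, config.n_pcs)
    n_batches = len(set(emb.batch_of_cell))
    if n_batches > 1:
        emb = mnn_correct(emb, config.mnn)
    coords = pd.DataFrame(
        emb.coordinates,
        index=pd.Index(emb.barcode_ids, name="barcode"),
        columns=[f"PC{i+1}" for i in range(emb.n_components)],
    )
    coords.to_csv(out / "embedding.tsv", sep="\t")
    done(n_components=emb.n_components, corrected=bool(emb.corrected))

    # --- clustering ------------------------------------------------------
    done = stage("cluster")
    cparams = ClusterParams(
        k_neighbors=config.clustering.k_neighbors,
        prune_jaccard=config.clustering.prune_jaccard,
        resolution=config.clustering.resolution,
        seed=config.stage_seed(3),
    )
    graph = build_snn_graph(emb, cparams)
    assignment = louvain_cluster(graph, cparams)
    cluster_frame = pd.DataFrame(
        {"barcode": assignment.barcode_ids, "cluster": assignment.labels}
    )
    cluster_frame.to_csv(out / "clusters.tsv", sep="\t", index=False)
    composition = composition_table(assignment.labels)
    done(n_clusters=assignment.n_clusters, modularity=assignment.modularity,
         composition=composition)

    # --- cell cycle ------------------------------------------------------
    if config.s_genes and config.g2m_genes:
        done = stage("cell_cycle")
        cc = score_cell_cycle(
            norm, set(config.s_genes), set(config.g2m_genes), seed=config.stage_seed(4)
        )
        pd.DataFrame(
            {
                "barcode": cc.barcode_ids,
                "s_score": cc.s_score,
                "g2m_score": cc.g2m_score,
                "phase": cc.phase,
            }
        ).to_csv(out / "cell_cycle.tsv", sep="\t", index=False)
        phases, phase_counts = np.unique(cc.phase, return_counts=True)
        done(**{str(p): int(c) for p, c in zip(phases, phase_counts)})

    # --- markers + DE + TFs ----------------------------------------------
    done = stage("markers")
    tf_candidates: dict[int, pd.DataFrame] = {}
    for c in range(assignment.n_clusters):
        scores = f1_marker_scores(cells, assignment, c)
        marker_frame = pd.DataFrame(
            [
                {
                    "gene": s.gene,
                    "tp": s.tp,
                    "fp": s.fp,
                    "fn": s.fn,
                    "tn": s.tn,
                    "precision": s.precision,
                    "recall": s.recall,
                    "f1": s.f1,
                }
                for s in scores[:50]
            ]
        )
        marker_frame.to_csv(out / f"markers_cluster{c}.tsv", sep="\t", index=False)
        de = wilcoxon_de(norm, assignment, c, config.min_pct, config.pseudocount)
        de.to_csv(out / f"de_cluster{c}.tsv", sep="\t", index=False)
        if config.tf_checklist:
            tfs = select_candidate_tfs(
                de, config.tf_checklist, config.top_n_tfs, cluster=c
            )
            tfs.table.to_csv(out / f"tfs_cluster{c}.tsv", sep="\t", index=False)
            tf_candidates[c] = tfs.table
    done(n_clusters_scored=assignment.n_clusters)

    tio.write_json(manifest, out / "manifest.json")
    return PipelineResult(
        clusters=cluster_frame, tf_candidates=tf_candidates, manifest=manifest
    )
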