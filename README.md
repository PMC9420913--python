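# tfscout

Cluster-specific transcription-factor discovery from single-cell UMI count
matrices, plus the accompanying qPCR quantification math (2^-ddCt expression
analysis and Xo-method lentiviral titering).

The pipeline goes from a raw genes x barcodes count matrix to ranked
TF candidates per cluster:

1. **QC** — empty-droplet detection (total UMIs < 50), ambient-gene flagging
   (> 30% of a gene's counts in empty droplets), optional marker-based cell
   exclusion (e.g. hemoglobin+ red blood cells).
2. **Normalization & HVGs** — log-normalization (`ln(1 + 1e4 * c/total)`),
   variance decomposition into a fitted mean-variance trend (technical) and
   a residual (biological); top genes by biological variance are the HVGs,
   ambient genes excluded.
3. **Integration** — PCA on the HVG submatrix (50 components by default),
   mutual-nearest-neighbor batch correction of the PCA coordinates.
4. **Clustering** — shared-nearest-neighbor graph (Jaccard weights, pruned at
   1/15) and Louvain community detection with a resolution parameter;
   cell-cycle phase scoring (S / G2M / G1) with binned control genes.
5. **Markers & TFs** — detection-based F1 marker ranking per cluster
   (precision/recall over >= 1 UMI detection), two-sided Wilcoxon rank-sum
   differential expression with a min.pct filter (0.25), and selection of the
   top-20 checklist-matching TFs by log fold change of average expression.
6. **Projection** — centroid-consensus projection of query cells onto an
   annotated reference (cosine + Pearson + Spearman voting, 2-of-3 consensus,
   similarity threshold 0.7).

A synthetic-data module (`tfscout.simdata`) generates negative-binomial count
matrices with planted clusters, marker/TF genes, batch effects, cell-cycle
programs and ambient-contaminated empty droplets — plus log-linear qPCR Ct
tables — so the entire pipeline is exercisable offline with known ground
truth.

## CLI

```bash
# generate a demo dataset with ground truth
tfscout simulate --out demo --n-genes 1000 --cells-per-cluster 200 --seed 1

# QC report (empty droplets, ambient genes, HVG table)
tfscout qc --counts demo --out demo_qc --n-hvgs 500

# full clustering (QC -> normalize -> PCA -> MNN -> SNN -> Louvain)
tfscout cluster --counts demo --out demo_clusters --resolution 1.6 --seed 1

# markers + DE + TF candidates for one cluster
tfscout markers --counts demo --clusters demo_clusters/clusters.tsv \
    --cluster-id 0 --tf-checklist demo/tf_checklist.txt --out demo_markers

# project query cells onto an annotated reference
tfscout project --query demo --reference demo --ref-clusters demo_clusters/clusters.tsv \
    --out projection.tsv

# wet-lab math
tfscout titer --table titration.csv --ref-copy 1.0 --cells 100000 --moi 10
tfscout ddct --table ct.csv --reference-sample REFERENCE --housekeeping ACTB

# whole pipeline from a YAML config
tfscout run --config pipeline.yaml
```

A minimal `pipeline.yaml`:

```yaml
counts: demo            # 10x-style triplet directory (matrix.mtx, features.tsv, barcodes.tsv)
qc: {n_hvgs: 500}
clustering: {resolution: 1.6, k_neighbors: 20}
n_pcs: 50
tf_checklist: demo/tf_checklist.txt
seed: 1
output_dir: out
```

## Data formats

Counts travel as a 10x-style text triplet (`matrix.mtx` Matrix Market
coordinate + `features.tsv` + `barcodes.tsv`, with per-barcode batch/stage
labels in `labels.tsv`). Gene lists are one-symbol-per-line text; Ct tables
are CSV with columns `sample, gene, replicate, ct` (titrations use `volume`
in place of `sample`). Human S-phase and G2/M gene lists ship with the
package (`tfscout.io.bundled_cell_cycle_genes()`); symbols are matched
case-insensitively throughout.
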