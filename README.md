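# sctip

Tipping-point (critical transition) analysis for single-cell UMI time
courses.

A cell population moving between two attractor states shows a
characteristic correlation signature at the transition: cells decohere
(mean cell–cell Pearson correlation drops) while genes start to
co-fluctuate (mean absolute gene–gene correlation rises).  The transition
index — the ratio of the two pair means — peaks at the tipping point.
`sctip` implements that analysis as a tested pipeline:

- **`matrix_io`** — count matrices (MatrixMarket + id lists, or dense TSV)
  and cell/gene annotation TSVs, with a strict genes × cells data model.
- **`simulate`** — negative-binomial synthetic UMI time courses with two
  antagonistic gene programs driven by a latent state whose distribution
  broadens at a configurable transition time; also a two-condition
  ligand/receptor fixture and a discrete-cluster fixture.  Every
  downstream statistic has a parameter-recovery test against this
  generator.
- **`preprocess`** — cell filters (≥ 500 detected genes; log10 total UMIs
  within mean ± 2 sd), gene filters (detected in ≥ 10 cells; mitochondrial
  exclusion), TPM-like natural-log normalization (size factor 10,000), and
  a housekeeping-gene RLE batch diagnostic.
- **`transition`** — cell–cell / gene–gene Pearson matrices, the
  transition index per time point, and trend summaries.
- **`markers`** — Wilcoxon rank-sum marker detection with detection-
  fraction (`min.pct` 0.2) and log-fold-change (0.2; 0.58 for block
  comparisons) filters and BH q-values; stage-specific TF selection.
- **`tfpairs`** — per-cell products of opposing stage-specific TF
  expression (bifurcation vs co-expression).
- **`similarity`** — Jaccard matching of cluster signature-gene sets.
- **`lr`** — ligand–receptor interaction scoring with a cluster-label
  permutation null, top-20 ranking by mean expression, and ± 0.4
  between-condition delta classification.
- **`pipeline` / `cli`** — orchestration with a flat YAML config,
  per-stage logging, manifests with output digests, and full determinism
  under a fixed seed.

## CLI

```sh
sctip simulate --seed 1 --out data/
sctip preprocess --matrix data/ --gene-annotation data/genes_annotation.tsv \
    --out filtered/ --min-genes 500 --min-cells 10 --umi-sd 2
sctip transition-index --matrix data/ --annotation data/cells.tsv --out series.csv
sctip markers --matrix data/ --annotation data/cells.tsv --groupby cluster --out markers.csv
sctip tf-pairs --matrix data/ --annotation data/cells.tsv \
    --early-tfs early.txt --late-tfs late.txt --out tf_scores.csv
sctip match-clusters --markers-a a.csv --markers-b b.csv --out jaccard.csv
sctip lr-delta --matrix data/ --annotation data/cells.tsv --pairs pairs.tsv \
    --n-perm 1000 --seed 7 --threshold 0.4 --top 20 --out lr.csv
sctip run-all --seed 1 --out run/          # simulate + every stage
```

`run-all` accepts `--config config.yaml` (flat key: value mapping; CLI
flags override the file).  Threshold defaults match the values listed
above; for simulated runs the 500-gene cell filter is capped at half the
synthetic panel size (recorded in the manifest), since the panel is far
smaller than a transcriptome.

## Conventions

Matrices are genes × cells everywhere in memory.  Normalized expression is
`ln(1 + count / cell_total × 10,000)`, so `sum(exp(x) − 1)` is the size
factor for every cell.  Log fold changes are natural-log values on the
mean de-logged expression scale.  The transition-index denominator uses
absolute cell–cell coefficients by default; `--signed-cell-corr`
reproduces the signed variant.
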