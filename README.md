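# pipet

Nearest-template prediction of bulk-derived phenotypes for single cells,
together with a splat-style simulation study for validating the method
end to end on synthetic data.

Given a bulk RNA-seq cohort with a categorical phenotype (k >= 2 classes),
the package

1. selects per-class marker genes from the bulk counts (one-vs-rest
   differential expression at configurable FDR and log2 fold-change
   thresholds), or ingests externally computed marker lists;
2. builds per-class template weight vectors over the marker genes
   (mirrored +1/-1 weights for two classes, one-hot weights for more);
3. scores every single cell against every template (cosine similarity by
   default; Pearson, Spearman, Euclidean, Manhattan and Chebyshev are
   available);
4. attaches permutation-based empirical p-values (templates re-applied to
   randomly resampled gene sets) with Benjamini–Hochberg adjustment; and
5. labels each cell with its nearest significant template, or
   "Unassigned" when the significance gate fails.

A synthetic-data module (`pipet.simdata`) emulates group-structured
scRNA-seq counts (gamma gene means, per-group log-normal DE factors with
condition effects shared across group subsets, simulated individuals with
variable signature penetrance, log-normal library sizes, gamma-Poisson
counts, calibrated logistic dropout), aggregates pseudobulk samples, and
evaluates label agreement with Cohen's kappa.

## Command-line interface

```bash
# select markers from bulk counts + phenotype labels
pipet markers --bulk bulk.tsv --phenotype pheno.tsv --fdr 0.05 --lfc 1 --out markers.tsv

# label cells (MTX triplet directory or dense TSV; markers TSV or GMT)
pipet predict --sc mtx_dir/ --templates markers.tsv \
    --metric cosine --nperm 1000 --alpha 0.05 --gate p --seed 1 --out outdir/

# ... or derive templates on the fly from bulk data
pipet predict --sc cells.tsv --bulk bulk.tsv --phenotype pheno.tsv --out outdir/

# synthetic data: counts (MTX), labels, pseudobulk
pipet simulate --k 3 --dropout 0.5 --seed 1 --out simdir/

# Cohen's kappa between truth and predictions
pipet evaluate --truth truth.tsv --pred outdir/predictions.tsv

# the full consistency grid (class counts x dropout levels)
pipet run-sim-study --ks 2,3,4 --dropouts 0,0.35,0.5,0.65 --seeds 3 --out study/
```

`predict` writes `predictions.tsv` (cell id, label, best class, statistic,
p-value, FDR, flags) and `manifest.json` (seed, metric, thresholds, gene
and cell counts). Reruns with identical arguments produce byte-identical
outputs.

## Layout

| module | contents |
| --- | --- |
| `pipet.templates` | bulk dataset type, marker selection, template construction |
| `pipet.similarity` | cell matrix type, gene filtering, log-normalization, scoring |
| `pipet.inference` | permutation null, empirical p-values, BH, label assignment |
| `pipet.simdata` | synthetic counts, pseudobulk, Cohen's kappa, study driver |
| `pipet.io` / `pipet.cli` | readers/writers for MTX/TSV/GMT/JSON and the CLI |
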