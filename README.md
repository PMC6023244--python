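# agemark

Detection and characterisation of **age-dynamic histone-mark domains** from
binned ChIP-seq coverage, built around the design of aging studies in
*Caenorhabditis elegans* somatic tissue: H3K4me3 and H3 ChIP-seq at larval
(L3) and adult (day 2, day 12) timepoints with three biological replicates,
plus matched RNA-seq at the adult timepoints.

The package is for computational biologists who want a self-contained,
testable reimplementation of this analysis style — including a synthetic-data
generator with per-gene ground truth, so every stage can be validated without
downloading any sequencing data.

## What it computes

1. **Tracks** — 25-bp binned coverage (bedGraph I/O), RPKM control
   subtraction, 2-kb-window log2 CPM ratios, replicate Pearson-correlation QC
   (threshold 0.8) and PCA.
2. **Peaks** — a dual-mode (narrow/broad) enrichment caller against a local
   Poisson background λ_local = max(λ_genome, λ_1kb, λ_10kb) scaled to the
   mark depth, with BH q < 0.01 (narrow) or p < 0.05 cores linked through
   p < 0.1 (broad); 1-bp union merging; ≥2-of-3 replicate consistency gating.
3. **Differential binding** — raw peak counts with full-library-size offsets
   in a negative-binomial log-linear model: common dispersion by Cox–Reid
   adjusted profile likelihood, tagwise shrinkage (prior df 10), per-peak
   likelihood-ratio tests; then the domain filters — FDR < 0.05, |fold
   change| ≥ 30 %, and mark/H3 ratio > 1 in all replicates of at least one
   timepoint — classify peaks as increased / decreased / stable.
4. **Gene assignment** — overlap (≥1 bp) or nearest upstream-of-gene
   assignment with the beyond-TES removal rule.
5. **Profiles** — strand-oriented metagene matrices (50 + 100 + 50 bins over
   2-kb flanks and the length-scaled gene body), k-means into 25 clusters
   (labels a–y by descending centroid signal), per-cluster Fisher exact
   enrichment for any binary gene flag.
6. **GSEA** — preranked weighted-KS enrichment score with ≥1-bp-overlap set
   membership and permutation significance.
7. **Integration** — TMM-scaled NB-GLM RNA differential expression, Spearman
   correlation of per-gene mark and RNA log fold changes, three-set Venn
   partitions with direction-resolved concordance, the peak-length /
   expression-change trend, and parameter-recovery scoring against the
   simulator's ground truth.

## Worked example

```python
from agemark import SimConfig, run_pipeline

result = run_pipeline(SimConfig(seed=1), outdir="report")
print(len(result.peaks))                                  # 500
print((result.diff.table["class"] != "stable").mean())    # 0.27
print(result.correlation.rho)                             # 0.670
print(result.gsea.es, result.gsea.p)                      # 0.532 0.002
print(result.recovery.recall, result.recovery.precision)  # 1.0 1.0
```

On the default simulated design (one 5-Mb chromosome, 500 genes, 30 %
dynamic marking at |log2FC| = 1, mark–RNA coupling 0.8), the run above calls
500 enrichment domains of which 27 % are classified age-dynamic; the Spearman
correlation between per-gene mark changes and RNA changes is 0.67 (the
generator's own measurement-level Monte-Carlo oracle gives 0.70); the
preranked GSEA of age-dynamic peaks along the adult-vs-larval ranking yields
an enrichment score of 0.53 at the permutation floor p ≈ 0.002 — i.e. the
dynamic domains are strongly biased toward adult-deposited marking; and every
truth-dynamic gene is recovered with the correct direction.

The same pipeline is scriptable from the shell:

```bash
agemark simulate --seed 7 --outdir sim/      # bedGraphs + GFF3 + truth TSV
agemark run --seed 7 --outdir report/        # full analysis, deterministic
agemark gsea --ranked ranked.tsv --set set.txt --nperm 1000 --seed 7
```

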