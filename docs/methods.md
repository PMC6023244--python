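# Methods

## The analysis model

The pipeline detects genomic domains whose histone-mark level changes with
adult age and relates them to when the marking was deposited (larval vs
adult), its geometry (TSS-peaked vs gene-body-spanning) and matched RNA
expression changes. All stages operate on fixed 25-bp binned coverage;
coordinates are 0-based half-open throughout.

**Control normalization.** Signal tracks are RPKM(mark) − RPKM(control) per
bin. The control is any occupancy track (histone H3 by default): H3 is flat
over chromatin in the generator, and in practice nucleosome occupancy
normalization removes accessibility artifacts. Replicate QC uses 2-kb
windows, log2(CPM_mark + 0.5) − log2(CPM_control + 0.5); windows are
non-overlapping tiles (a sliding variant adds nothing for correlation QC).
Replicates must correlate at r ≥ 0.8 *within their replicate group*;
cross-timepoint correlations are genuinely lower when marking is
adult-deposited, so they do not gate replicates.

**Peak calling.** Mark counts are smoothed by a 200-bp moving sum (a fixed
fragment-extension stand-in; no fragment-shift model is built). The
background for each bin is the depth-scaled maximum of the genome-wide,
1-kb-local and 10-kb-local control rates, and each smoothed count gets a
Poisson upper-tail p-value. Narrow mode keeps BH q < 0.01 bins; broad mode
keeps p < 0.05 cores extended through p < 0.1 linking bins. Significant bins
merge across gaps ≤ 25 bp; domains shorter than 200 bp (the smoothing scale)
are dropped. Summits are the leftmost maximal-signal bin. Narrow and broad
sets from both adult timepoints are union-merged at ≥ 1-bp overlap.
Replicate consistency requires a per-replicate Poisson enrichment test
(mark vs depth-scaled control within the domain, BH across domains) at
q < 0.05 in ≥ 2 of 3 replicates; the test is pluggable because no single
convention exists for this gate.

**Differential binding.** Raw (unscaled) counts per domain enter a
negative-binomial log-linear model with full library sizes as offsets. A
common dispersion maximises the Cox–Reid adjusted profile likelihood summed
over domains on a 40-point log grid (1e-4…5, plus a near-zero floor);
per-domain dispersions maximise their own APL plus `prior_df / residual_df`
(default 10/4) times the mean APL curve — weighted-likelihood shrinkage
toward the common value. Group means are fitted by Newton iterations (the
Poisson closed form seeds them), and the group effect is tested by a
likelihood-ratio chi-square with 1 df. Reported log2 fold changes use a
half-read pseudo-rate to stay finite at zero counts. A domain is classified
**increased** when FDR < 0.05, fold ≥ 1.3, and the depth-normalized mark/H3
ratio exceeds 1 in *all* replicates of at least one timepoint ("at either
time point" is read as: the ratio condition holds across every replicate of
one of the two timepoints); **decreased** symmetrically; otherwise stable.
The same machinery with relabelled classes produces the larval-vs-adult
(L3 vs D2) deposition-timing contrast.

**Gene assignment.** A peak overlapping one or more gene spans by ≥ 1 bp is
assigned to all of them. A wholly intergenic peak goes to the nearest gene
for which the peak lies 5' of the TSS in the gene's reading orientation;
candidates with the peak entirely 3' of a gene's TES are removed, and
equidistant genes on both flanks are all kept (flagged by the shared
distance). Biotype filtering (protein-coding only) is applied downstream,
not during assignment.

**Metagene clustering.** Each gene is a 200-bin vector: 50 fixed 40-bp bins
per 2-kb flank and 100 length-scaled gene-body bins, strand-oriented. Bin
values are exact step-function integrals of the normalized track, so
rebinning conserves the per-gene mean. The D2 and D12 matrices are
concatenated column-wise and partitioned by Euclidean k-means (k = 25,
k-means++ with 10 restarts, best inertia kept, fixed seed). Cluster letters
a–y are assigned by descending centroid mean, making labels reproducible.
Per-cluster enrichment for any binary gene flag is a two-sided Fisher exact
test with BH correction over clusters; a cluster *group* (e.g. all gene-body
clusters vs the rest) is a single 2×2 Fisher test.

**Preranked GSEA.** Items are ranked by log2 level ratios (adult D2 over
larval L3 by default), ties broken by id so the score is deterministic.
Set membership is either explicit or by ≥ 1-bp overlap with a peak set. The
enrichment score is the signed maximum of the running sum in which member
hits add |score|^w (normalised over members; w = 1 by default, the classic
weighted statistic) and misses subtract 1/(N − N_members); the sum starts
and ends at zero by construction. Significance comes from random equal-size
member sets (the only meaningful null for preranked input), with an add-one
rule so p ≥ 1/(1 + n_perm); NES divides ES by the mean |null ES| of the same
sign.

**RNA integration.** RNA counts are TMM-scaled (trimmed mean of M values,
trims 0.3 / 0.05, delta-method weights, reference by upper-quartile rule)
and tested with the same NB-GLM. Per-gene mark change is the depth-weighted
mean log2FC over that gene's dynamic domains (one value per gene; a per-peak
variant is available). The mark–RNA coupling statistic is Spearman's rho
with average ranks, exact permutation p for n ≤ 8 and the t-approximation
otherwise. Venn partitions, direction-resolved concordance counts, and the
peak-length trend (fraction of expression-changed genes per geometric length
bin, 0.2–10 kb; Spearman trend with a permutation p) complete the picture.

## The synthetic experiment

The generator emulates the study design: 3 ChIP replicates × {L3, D2, D12}
× {mark, H3 control} and 2 RNA replicates × {D2, D12}, over a toy genome
(default one 5-Mb chromosome, 500 non-overlapping genes of 0.5–6 kb with
≥ 1-kb intergenic gaps, both strands, 95 % protein-coding).

Per gene, the truth table draws:

| field | values | default law |
|---|---|---|
| pattern | tss / gene_body | 0.6 / 0.4 |
| onset | larval / adult | 0.9/0.1 given tss; 0.3/0.7 given gene_body |
| level | low / mid / high (2/4/8 × background) | larval: .25/.35/.40; adult: .60/.40/0 |
| trend | up / down / stable | stratum weights 3 : 1.5 : 1.5 : 1 (gene-body+adult highest), rescaled so the marginal dynamic fraction is exactly 30 % |
| effect | ±1 log2 (D12 vs D2) | fixed magnitude |
| rna_trend | matches trend with probability `coupling` (0.8), else stable | ±1 log2 |

Making level conditional on onset (adult-acquired marking is low-to-mid
level; high-level marking is larval and stable) mirrors the biology being
emulated *and* keeps the library-composition shift between timepoints small
— with full-library-size offsets, a large adult-onset signal mass would
otherwise bias every stable gene's apparent L3-vs-adult fold change.

Counts are negative-binomial per 25-bp bin around a smooth mean: background
1, plus per gene either a Gaussian TSS kernel (sd 300 bp) or a flat
TSS-to-TES plateau, scaled by level, onset (adult-onset enrichment at L3 is
attenuated to 0.1× its D2 value) and trend (applied at D12); the surface is
smoothed with a 200-bp moving average standing in for fragment extension and
normalised so the expected library total equals `chip_depth` (default 2 M
reads ≈ 8 reads per background bin). ChIP dispersion is 0.1 per bin. RNA
counts are NB per gene around lognormal baselines scaled to `rna_depth`
(1 M), with dispersion 0.02 (biological CV ≈ 0.14, the convention for
isogenic model-organism populations; gene-level RNA counts are tighter than
25-bp ChIP bins). A single seed fans out to per-library substreams keyed by
CRC32 of "(antibody, timepoint, replicate)", so any library is reproducible
regardless of call order.

**The coupling-rho oracle.** `expected_coupling_rho` is a 10⁵-draw
Monte-Carlo of the *measured* correlation: it pushes the truth-level coupling
through the generator's own count law (NB noise at the configured depths,
replicate sums, within-peak background dilution) and returns the Spearman
rho of the estimated changes (~0.70 at defaults). The truth-label rho with
midranked ties would be ~0.90; comparing the pipeline's estimate against
that would conflate coupling recovery with estimation noise.

**What the generator does not model** — and hence what passing tests do not
show about real data: read-level artifacts (PCR duplicates, mappability, GC
bias), fragment-length variation, tissue mixtures, isoform structure,
inter-gene correlation, and composition shifts larger than the configured
adult-onset mass. Real peak shapes are also more heterogeneous than a
two-archetype kernel/plateau mixture.

## Numerical choices

- Dispersion grid: `geomspace(1e-4, 5, 40)` plus 1e-6; estimates are
  grid-valued, which is ample for a statistic used through shrinkage.
- Newton mean fits: 8 iterations from the Poisson closed form; means floored
  at 1e-12; LR statistics floored at 0.
- Pseudocounts: 0.5 CPM in window log-ratios; half a read in reported
  logFCs; +0.5 on summed counts in the rho oracle's ratio estimates.
- Tie-breaks: summits at the leftmost maximal bin; ranked lists by id;
  cluster letters by descending centroid mean.
- Fisher tests are two-sided throughout; all multiple-testing correction is
  Benjamini–Hochberg.
- Degenerate inputs are explicit: empty tracks call zero peaks (not an
  error); constant QC columns fail QC rather than producing NaN; single-bin
  or saturated length trends are reported as not applicable; permutation p
  is never zero (add-one rule).

## Problem sizes

The default design (5 Mb / 500 genes / 2 M-read libraries) is the package's
reference configuration: large enough that the 30 % dynamic fraction, the
deposition-timing contrast and the coupling correlation are all comfortably
estimable, small enough that the full pipeline runs in seconds. The test
suite's calibration studies use 2,000 null peaks (type-I error) and a 5-Mb
null genome with 20 spiked domains (peak-caller calibration).

## Known limitations

- The NB likelihood-ratio test is mildly liberal at very small counts
  (a chi-square approximation property shared by the standard GLM tools);
  calibration is verified at peak-scale counts.
- `bFullLibrarySize`-style offsets are composition-naive by design; a
  strongly asymmetric gain of signal mass between conditions would bias
  stable domains' fold changes. TMM scaling is applied to RNA only,
  matching the emulated workflow.
- The broad/narrow caller is a calibrated simplification, not a numerical
  reproduction of MACS2; MFOLD model-building options have no analogue
  because model building is replaced by the fixed 200-bp extension.
- k = 25 is a convention, not a model-selection result; the cluster-letter
  canonicalisation makes labels stable but their biological reading still
  requires inspecting centroids.
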