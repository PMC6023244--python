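"""End-to-end orchestration: simulate -> tracks -> peaks -> differential ->
genes -> profiles -> gsea -> integrate, with deterministic report tables.

``run_pipeline`` executes the whole analysis on a simulated experiment and
returns a :class:`PipelineResult`; with an output directory it also writes
every stage's table as TSV (stable ordering and float formatting, so repeated
runs are byte-identical given the same configuration).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .differential import (
    DiffResult,
    classify_dynamic,
    count_in_peaks,
    nb_glm_test,
    normalized_peak_levels,
    timepoint_contrast,
)
from .genes import AnnotationSet, GeneAssignment, assign_peaks
from .gsea import GseaResult, RankedList, membership_by_overlap, permutation_significance
from .integrate import (
    ChangeCorrelation,
    LengthTrend,
    OverlapPartition,
    RecoveryReport,
    aggregate_peak_logfc,
    correlate_changes,
    length_trend,
    overlap_partition,
    recover_truth,
    rna_differential,
)
from .peaks import PeakCallParams, PeakSet, call_peaks, merge_peaksets, replicate_consistency
from .profiles import (
    ClusterAssignment,
    cluster_enrichment,
    concat_timepoints,
    group_contrast,
    kmeans_cluster,
    metagene_matrix,
)
from .simdata import SimConfig, SimulatedExperiment, simulate_experiment
from .tracks import CoverageTrack, normalize_subtract, qc_correlation_pca, window_matrix

FLOAT_FMT = "%.6g"


@dataclass
class PipelineResult:
    config: SimConfig
    experiment: SimulatedExperiment
    peaks: PeakSet
    diff: DiffResult
    onset: DiffResult
    assignment: GeneAssignment
    clusters: ClusterAssignment
    cluster_enrich: pd.DataFrame
    body_clusters: list
    body_contrast: tuple
    gsea: GseaResult
    rna: object
    correlation: ChangeCorrelation
    venn: OverlapPartition
    trend: LengthTrend
    recovery: RecoveryReport
    qc: object
    extras: dict = field(default_factory=dict)


def pooled_track(exp: SimulatedExperiment, antibody: str, timepoint: str) -> CoverageTrack:
    reps = [
        t for (ab, tp, _), t in exp.tracks.items() if ab == antibody and tp == timepoint
    ]
    data = {
        c: np.sum([t.data[c] for t in reps], axis=0).astype(np.int64)
        for c in reps[0].chroms
    }
    return CoverageTrack(reps[0].bin_size, data)


def gene_body_clusters(clusters: ClusterAssignment, prefix: str | None = None) -> list:
    """Clusters whose centroid signal spreads over the gene body.

    Heuristic on the centroid: the mean over the distal gene-body bins must be
    at least half the mean around the TSS and above the median centroid level,
    the profile of a body-spanning (rather than TSS-peaked) domain.
    """
    cent = clusters.centroids
    if prefix is not None:
        cent = cent[[c for c in cent.columns if c.startswith(prefix)]]
    cols = [c.split("_", 1)[-1] for c in cent.columns]
    tss_cols = [
        c for c, n in zip(cent.columns, cols)
        if (n.startswith("u") and n >= "u45") or (n.startswith("b") and n < "b010")
    ]
    body_cols = [
        c for c, n in zip(cent.columns, cols) if n.startswith("b") and n >= "b030"
    ]
    tss_sig = cent[tss_cols].mean(axis=1)
    body_sig = cent[body_cols].mean(axis=1)
    overall = cent.mean(axis=1)
    thresh = overall.median()
    out = [
        name
        for name in cent.index
        if body_sig[name] >= 0.5 * tss_sig[name] and body_sig[name] > thresh
    ]
    return out


def run_pipeline(
    config: SimConfig | None = None,
    outdir: str | None = None,
    peak_params: PeakCallParams | None = None,
    k: int = 25,
    fdr: float = 0.05,
    min_fc: float = 1.3,
    min_ratio: float = 1.0,
    n_perm: int = 1000,
) -> PipelineResult:
    """Run the full analysis on a simulated experiment."""
    if config is None:
        config = SimConfig()
    if peak_params is None:
        peak_params = PeakCallParams()
    exp = simulate_experiment(config)

    # --- tracks & QC -------------------------------------------------------
    pooled = {
        (ab, tp): pooled_track(exp, ab, tp)
        for ab in ("H3K4me3", "H3")
        for tp in config.timepoints
    }
    pairs, names = [], []
    for (ab, tp, rep), tr in sorted(exp.tracks.items()):
        if ab != "H3K4me3":
            continue
        pairs.append((tr, exp.tracks[("H3", tp, rep)]))
        names.append(f"{tp}_r{rep}")
    wm = window_matrix(pairs, window=2000, names=names)
    qc = qc_correlation_pca(
        wm, threshold=0.8, groups={n: n.rsplit("_", 1)[0] for n in names}
    )

    # --- peak calling ------------------------------------------------------
    merged: PeakSet | None = None
    for tp in ("D2", "D12"):
        for mode in ("narrow", "broad"):
            ps = call_peaks(pooled[("H3K4me3", tp)], pooled[("H3", tp)], peak_params, mode)
            merged = ps if merged is None else merge_peaksets(merged, ps)
    consistent = None
    for tp in ("D2", "D12"):
        marks = [exp.tracks[("H3K4me3", tp, r)] for r in range(1, config.n_chip_reps + 1)]
        ctrls = [exp.tracks[("H3", tp, r)] for r in range(1, config.n_chip_reps + 1)]
        kept = replicate_consistency(merged, marks, ctrls, min_reps=2)
        consistent = kept if consistent is None else merge_peaksets(consistent, kept)
    peaks = consistent

    # --- differential binding ---------------------------------------------
    counts = count_in_peaks(peaks, exp.tracks)
    levels = normalized_peak_levels(counts)
    meta = counts.meta
    adult_libs = meta.index[
        (meta["antibody"] == "H3K4me3") & meta["timepoint"].isin(["D2", "D12"])
    ]
    order = np.argsort([(0 if meta.loc[l, "timepoint"] == "D2" else 1) for l in adult_libs],
                       kind="stable")
    adult_libs = adult_libs[order]
    diff_raw = nb_glm_test(
        counts.counts[adult_libs],
        meta.loc[adult_libs, "timepoint"].to_numpy(),
        counts.library_sizes[adult_libs],
    )
    adult_levels = levels.loc[:, levels.columns.get_level_values("timepoint").isin(["D2", "D12"])]
    diff = classify_dynamic(diff_raw, adult_levels, fdr=fdr, min_fc=min_fc, min_ratio=min_ratio)
    onset = timepoint_contrast(counts, levels, ("L3", "D2"),
                               fdr=fdr, min_fc=min_fc, min_ratio=min_ratio)

    # --- gene assignment ---------------------------------------------------
    assignment = assign_peaks(peaks, exp.annotation)

    # --- metagene clustering ----------------------------------------------
    coding = exp.annotation.genes["biotype"] == "protein_coding"
    marked_genes = set(assignment.table["gene_id"])
    flankable = (
        (exp.annotation.genes["start"] >= 2000)
        & (exp.annotation.genes["end"] + 2000 <= config.chrom_length)
    )
    keep = coding & flankable & exp.annotation.genes["gene_id"].isin(marked_genes)
    sub_ann = AnnotationSet(exp.annotation.genes[keep].copy())
    mats = []
    for tp in ("D2", "D12"):
        norm = normalize_subtract(pooled[("H3K4me3", tp)], pooled[("H3", tp)])
        mats.append(metagene_matrix(sub_ann, norm, flank=2000, timepoint=tp))
    matrix = concat_timepoints(mats)
    clusters = kmeans_cluster(matrix, k=min(k, len(matrix)), seed=config.seed)

    dyn_peaks = PeakSet(
        [p for p in peaks if diff.table.loc[p.id, "class"] != "stable"],
        provenance="dynamic",
    )
    dyn_genes = set(
        assignment.table.loc[assignment.table["peak_id"].isin(dyn_peaks.ids()), "gene_id"]
    )
    flag = pd.Series(
        [g in dyn_genes for g in clusters.labels.index],
        index=clusters.labels.index, name="dynamic",
    )
    enrich = cluster_enrichment(clusters, flag).table
    body = gene_body_clusters(clusters, prefix="D2_")
    if 0 < len(body) < clusters.k:
        body_contrast = group_contrast(clusters, body, flag)
    else:
        body_contrast = (float("nan"), float("nan"))

    # --- GSEA: D2-vs-L3 ranking against age-dynamic membership -------------
    cpm = counts.cpm()
    lv = {}
    for tp in ("D2", "L3"):
        libs = meta.index[(meta["antibody"] == "H3K4me3") & (meta["timepoint"] == tp)]
        lv[tp] = cpm[libs].mean(axis=1) + 0.5
    coords = pd.DataFrame(
        {"chrom": [p.chrom for p in peaks], "start": [p.start for p in peaks],
         "end": [p.end for p in peaks]},
        index=peaks.ids(),
    )
    ranked = RankedList.from_scores(
        np.log2(lv["D2"] / lv["L3"]).to_dict(), coords=coords
    )
    if len(dyn_peaks):
        members = membership_by_overlap(ranked, dyn_peaks)
        gsea_res = permutation_significance(ranked, members, n_perm=n_perm, seed=config.seed)
    else:
        gsea_res = GseaResult(float("nan"), np.zeros(1))

    # --- RNA integration ---------------------------------------------------
    rna_cols = sorted(exp.rna_counts.columns, key=lambda c: (c[0] != "D2", c[1]))
    rna_counts = exp.rna_counts[rna_cols]
    rna_counts.columns = [f"{tp}_r{r}" for tp, r in rna_cols]
    rna = rna_differential(rna_counts, [tp for tp, _ in rna_cols], fdr=fdr)

    depth_w = pd.Series(cpm[adult_libs].mean(axis=1), index=cpm.index)
    dyn_assign = GeneAssignment(
        assignment.table[assignment.table["peak_id"].isin(dyn_peaks.ids())]
    )
    k4_gene_lfc = aggregate_peak_logfc(
        dyn_assign, diff.table["logFC"], weights=depth_w
    )
    correlation = None
    try:
        correlation = correlate_changes(k4_gene_lfc, rna.table["logFC"])
    except ValueError:
        correlation = ChangeCorrelation(float("nan"), float("nan"), 0, pd.DataFrame())

    universe = set(exp.annotation.genes.loc[coding, "gene_id"])
    dyn_k4_dir = {
        g: ("up" if k4_gene_lfc.get(g, 0) > 0 else "down")
        for g in dyn_genes if g in universe
    }
    dyn_rna_dir = {
        g: rna.table.loc[g, "class"]
        for g in rna.changed if g in universe
    }
    venn = overlap_partition(
        marked_genes & universe, dyn_k4_dir, dyn_rna_dir, universe
    )

    single = dyn_assign.table.groupby("peak_id")["gene_id"].nunique()
    single_peaks = single.index[single == 1]
    plens = pd.Series(
        {p.id: p.length for p in dyn_peaks if p.id in set(single_peaks)}
    )
    changed_genes = set(rna.changed)
    pk2gene = dyn_assign.table.set_index("peak_id")["gene_id"]
    if len(plens):
        changed_flag = pd.Series(
            [pk2gene.loc[pid] in changed_genes for pid in plens.index], index=plens.index
        )
        trend = length_trend(plens, changed_flag, seed=config.seed)
    else:
        trend = LengthTrend(pd.DataFrame(), float("nan"), float("nan"), note="no single-gene dynamic peaks")

    recovery = recover_truth(diff, assignment, exp.truth, onset_result=onset)

    result = PipelineResult(
        config, exp, peaks, diff, onset, assignment, clusters, enrich, body,
        body_contrast, gsea_res, rna, correlation, venn, trend, recovery, qc,
        extras={"window_matrix": wm, "metagene": matrix, "counts": counts,
                "levels": levels, "dynamic_peaks": dyn_peaks,
                "k4_gene_logfc": k4_gene_lfc},
    )
    if outdir is not None:
        write_report(result, outdir)
    return result


def write_report(res: PipelineResult, outdir: str) -> None:
    """Write all stage tables as TSV with stable ordering and formats."""
    os.makedirs(outdir, exist_ok=True)

    def path(name: str) -> str:
        return os.path.join(outdir, name)

    res.peaks.to_bed(path("peaks.bed"))
    res.diff.to_tsv(path("differential.tsv"), res.peaks)
    res.onset.to_tsv(path("onset_contrast.tsv"), res.peaks)
    res.assignment.table.to_csv(path("assignment.tsv"), sep="\t", index=False)
    res.clusters.labels.sort_index().to_csv(path("clusters.tsv"), sep="\t")
    res.cluster_enrich.to_csv(path("cluster_enrichment.tsv"), sep="\t",
                              float_format=FLOAT_FMT)
    res.rna.table.sort_index().to_csv(path("rna_differential.tsv"), sep="\t",
                                      index_label="gene_id", float_format=FLOAT_FMT)
    res.correlation.pairs.sort_index().to_csv(path("change_pairs.tsv"), sep="\t",
                                              index_label="gene_id", float_format=FLOAT_FMT)
    if len(res.trend.table):
        res.trend.table.to_csv(path("length_trend.tsv"), sep="\t", index=False,
                               float_format=FLOAT_FMT)
    res.qc.correlation.to_csv(path("qc_correlation.tsv"), sep="\t", float_format=FLOAT_FMT)
    res.recovery.to_frame().to_csv(path("recovery.tsv"), sep="\t", index=False,
                                   float_format=FLOAT_FMT)

    cells = {"".join("MKR"[i] for i in range(3) if key[i]) or "none": v
             for key, v in res.venn.cells.items()}
    summary = {
        "version": __version__,
        "config_sha1": hashlib.sha1(
            json.dumps(res.config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": res.config.seed,
        "n_peaks": len(res.peaks),
        "n_dynamic_peaks": int((res.diff.table["class"] != "stable").sum()),
        "dynamic_fraction": float((res.diff.table["class"] != "stable").mean()),
        "gsea_es": res.gsea.es,
        "gsea_p": res.gsea.p,
        "spearman_rho": res.correlation.rho,
        "body_clusters": res.body_clusters,
        "body_contrast_odds": res.body_contrast[0],
        "body_contrast_p": res.body_contrast[1],
        "venn": cells,
        "concordant_up": res.venn.concordant_up,
        "concordant_down": res.venn.concordant_down,
        "discordant": res.venn.discordant,
        "precision": res.recovery.precision,
        "recall": res.recovery.recall,
        "onset_recall": res.recovery.onset_recall,
        "length_trend_rho": res.trend.rho,
    }
    with open(path("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
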