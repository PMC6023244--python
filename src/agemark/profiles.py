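"""Metagene profiles, k-means clustering and cluster enrichment tests.

Each gene is summarised as a 200-bin signal vector: 50 fixed-width bins over
the 2-kb upstream flank, 100 length-scaled bins over the gene body, and 50
bins over the downstream flank, oriented 5'->3' along the gene strand.
Profiles at two adult timepoints are concatenated column-wise and partitioned
with k-means (k = 25 by default, labels 'a'..'y' ordered by descending
centroid mean signal).  Per-cluster association with any binary gene flag is
tested with two-sided Fisher exact tests, BH-corrected across clusters.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genes import AnnotationSet
from .tracks import NormalizedTrack

N_FLANK_BINS = 50
N_BODY_BINS = 100


@dataclass
class MetageneMatrix:
    """Genes x 200 position-bin matrix of normalized signal for one timepoint."""

    values: pd.DataFrame
    flank: int = 2000
    timepoint: str = ""

    @property
    def body_columns(self) -> list[str]:
        return [c for c in self.values.columns if c.startswith("b")]


def _interval_means(
    vals: np.ndarray, bin_size: int, edges: np.ndarray
) -> np.ndarray:
    """Mean of a per-bin step function over arbitrary float [edge_i, edge_{i+1}) windows.

    Uses the linear-in-position integral of the step function, so fractional
    bin overlap is exact and rebinning conserves the per-gene mean.
    """
    cum = np.concatenate([[0.0], np.cumsum(vals)]) * bin_size

    def integral(x: np.ndarray) -> np.ndarray:
        x = np.clip(x, 0, len(vals) * bin_size)
        k = np.minimum((x // bin_size).astype(int), len(vals) - 1)
        return cum[k] + vals[k] * (x - k * bin_size)

    upper = integral(edges[1:])
    lower = integral(edges[:-1])
    widths = edges[1:] - edges[:-1]
    return (upper - lower) / widths


def metagene_matrix(
    annotation: AnnotationSet,
    track: NormalizedTrack,
    flank: int = 2000,
    min_gene_len: int = 200,
    timepoint: str = "",
) -> MetageneMatrix:
    """Strand-oriented flank/body/flank signal matrix from a normalized track."""
    cols = (
        [f"u{i:02d}" for i in range(N_FLANK_BINS)]
        + [f"b{i:03d}" for i in range(N_BODY_BINS)]
        + [f"d{i:02d}" for i in range(N_FLANK_BINS)]
    )
    rows, ids = [], []
    for _, g in annotation.genes.iterrows():
        if g.end - g.start < min_gene_len:
            warnings.warn(f"gene {g.gene_id} shorter than {min_gene_len} bp, skipped")
            continue
        vals = track.data[g.chrom]
        if g.start - flank < 0 or g.end + flank > len(vals) * track.bin_size:
            raise ValueError(f"gene {g.gene_id} (with flank) outside track bounds")
        up_edges = np.linspace(g.start - flank, g.start, N_FLANK_BINS + 1)
        body_edges = np.linspace(g.start, g.end, N_BODY_BINS + 1)
        down_edges = np.linspace(g.end, g.end + flank, N_FLANK_BINS + 1)
        prof = np.concatenate(
            [
                _interval_means(vals, track.bin_size, up_edges),
                _interval_means(vals, track.bin_size, body_edges),
                _interval_means(vals, track.bin_size, down_edges),
            ]
        )
        if g.strand == "-":
            prof = prof[::-1]
        rows.append(prof)
        ids.append(g.gene_id)
    values = pd.DataFrame(np.asarray(rows), index=pd.Index(ids, name="gene_id"), columns=cols)
    return MetageneMatrix(values, flank=flank, timepoint=timepoint)


def concat_timepoints(matrices: list[MetageneMatrix]) -> pd.DataFrame:
    """Column-wise concatenation of per-timepoint matrices on the shared genes."""
    common = matrices[0].values.index
    for m in matrices[1:]:
        common = common.intersection(m.values.index)
    parts = [
        m.values.loc[common].add_prefix(f"{m.timepoint or i}_")
        for i, m in enumerate(matrices)
    ]
    return pd.concat(parts, axis=1)


@dataclass
class ClusterAssignment:
    labels: pd.Series            # gene -> cluster letter
    centroids: pd.DataFrame      # cluster letter x columns
    inertia: float
    k: int
    seed: int

    def members(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]

    @property
    def cluster_names(self) -> list[str]:
        return list(self.centroids.index)


def kmeans_cluster(matrix: pd.DataFrame, k: int = 25, seed: int = 0) -> ClusterAssignment:
    """Euclidean k-means (k-means++ init, 10 restarts, best inertia kept).

    Cluster letters are assigned in order of descending centroid mean signal,
    so 'a' is always the strongest-signal cluster regardless of init.
    """
    from sklearn.cluster import KMeans

    if len(matrix) < k:
        raise ValueError(f"{len(matrix)} rows < k={k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw = km.fit_predict(matrix.to_numpy())
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable")
    letters = _cluster_letters(k)
    relabel = {int(old): letters[rank] for rank, old in enumerate(order)}
    labels = pd.Series([relabel[int(r)] for r in raw], index=matrix.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=letters, columns=matrix.columns
    )
    return ClusterAssignment(labels, centroids, float(km.inertia_), k, seed)


def _cluster_letters(k: int) -> list[str]:
    base = string.ascii_lowercase
    if k <= len(base):
        return list(base[:k])
    return [base[i % 26] + str(i // 26) for i in range(k)]


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of table [[a, b], [c, d]] -> (odds ratio, p)."""
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


@dataclass
class ClusterEnrichment:
    table: pd.DataFrame  # per cluster: n_flagged, n_total, odds, p, p_adj
    notes: list[str] = field(default_factory=list)


def cluster_enrichment(
    assignment: ClusterAssignment, flag: pd.Series
) -> ClusterEnrichment:
    """Per-cluster 2x2 Fisher test of a binary gene flag vs cluster membership."""
    flag = flag.reindex(assignment.labels.index)
    if flag.isna().any():
        raise ValueError("flag undefined for some clustered genes")
    flag = flag.astype(bool)
    total_flagged = int(flag.sum())
    total = len(flag)
    rows, notes = [], []
    for name in assignment.cluster_names:
        members = assignment.members(name)
        n_total = len(members)
        if n_total == 0:
            notes.append(f"cluster {name} empty, skipped")
            continue
        n_flagged = int(flag.loc[members].sum())
        a = n_flagged
        b = n_total - n_flagged
        c = total_flagged - n_flagged
        d = (total - n_total) - c
        odds, p = fisher_2x2(a, b, c, d)
        rows.append(
            {"cluster": name, "n_flagged": n_flagged, "n_total": n_total,
             "odds_ratio": odds, "p": p}
        )
    table = pd.DataFrame(rows).set_index("cluster")
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return ClusterEnrichment(table, notes)


def group_contrast(
    assignment: ClusterAssignment, group_a: list[str], flag: pd.Series
) -> tuple[float, float]:
    """Single Fisher test of the flag for a cluster group vs all other clusters."""
    names = set(assignment.cluster_names)
    ga = set(group_a)
    if not ga:
        raise ValueError("group_a empty")
    if not ga < names:
        raise ValueError("group_a must be a proper subset of cluster labels")
    flag = flag.reindex(assignment.labels.index).astype(bool)
    in_a = assignment.labels.isin(ga)
    a = int((flag & in_a).sum())
    b = int((~flag & in_a).sum())
    c = int((flag & ~in_a).sum())
    d = int((~flag & ~in_a).sum())
    return fisher_2x2(a, b, c, d)


def average_profile(
    matrix: pd.DataFrame, genes: pd.Index | list
) -> pd.DataFrame:
    """Column-wise mean with an interquartile dispersion band for a gene subset."""
    sub = matrix.loc[list(genes)]
    if len(sub) == 0:
        raise ValueError("empty gene subset")
    return pd.DataFrame(
        {
            "mean": sub.mean(axis=0),
            "q25": sub.quantile(0.25, axis=0),
            "q75": sub.quantile(0.75, axis=0),
        }
    )
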