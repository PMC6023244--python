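"""RNA differential expression and mark/expression integration statistics.

RNA counts go through TMM library scaling and the same NB-GLM machinery as
the differential-binding stage.  Integration covers: Spearman correlation of
per-gene mark and expression log-fold-changes, three-set Venn partitions with
direction-resolved concordance, the peak-length vs expression-change trend,
generic gene-set Fisher tests, and parameter-recovery scoring against the
simulator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .differential import nb_glm_test
from .profiles import fisher_2x2


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (product normalised to 1).

    The reference library is the one whose upper-quartile/library-size ratio is
    closest to the mean; per-library factors are the weighted mean of per-gene
    log ratios after trimming the most extreme 30% of M values and 5% of A
    values, with inverse-variance (delta-method) weights.
    """
    y = counts.to_numpy(dtype=float)
    lib = y.sum(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f75 = np.array(
            [np.quantile(y[:, j][y[:, j] > 0], 0.75) for j in range(y.shape[1])]
        ) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    yr, nr = y[:, ref], lib[ref]
    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        yj, nj = y[:, j], lib[j]
        ok = (yj > 0) & (yr > 0)
        if ok.sum() < 10:
            continue
        m = np.log2((yj[ok] / nj) / (yr[ok] / nr))
        a = 0.5 * np.log2((yj[ok] / nj) * (yr[ok] / nr))
        w = 1.0 / ((nj - yj[ok]) / (nj * yj[ok]) + (nr - yr[ok]) / (nr * yr[ok]))
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [sum_trim, 1 - sum_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0:
            continue
        factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm")


@dataclass
class RnaDiffResult:
    table: pd.DataFrame  # index gene; logFC, p, FDR, class in {up, down, stable}

    def classed(self, label: str) -> pd.Index:
        return self.table.index[self.table["class"] == label]

    @property
    def changed(self) -> pd.Index:
        return self.table.index[self.table["class"] != "stable"]


def rna_differential(
    counts: pd.DataFrame, groups: Sequence[str], fdr: float = 0.05
) -> RnaDiffResult:
    """TMM-scaled NB-GLM differential expression between two groups."""
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("raw integer counts required")
    factors = tmm_factors(counts)
    eff_lib = counts.sum(0) * factors
    diff = nb_glm_test(counts, groups, eff_lib)
    fdr_vals = multipletests(diff["p"].to_numpy(), method="fdr_bh")[1]
    cls = np.where(
        fdr_vals < fdr,
        np.where(diff["logFC"].to_numpy() > 0, "up", "down"),
        "stable",
    )
    table = pd.DataFrame(
        {"logFC": diff["logFC"], "p": diff["p"], "FDR": fdr_vals, "class": cls},
        index=counts.index,
    )
    return RnaDiffResult(table)


# ---------------------------------------------------------------------------
# coupling statistics


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Exact two-sided permutation p for Spearman rho at small n."""
    ry = stats.rankdata(y)
    rx = stats.rankdata(x)
    n = len(x)
    obs = abs(rho)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = stats.pearsonr(rx, ry[list(perm)]).statistic
        count += abs(r) >= obs - 1e-12
        total += 1
    return count / total


@dataclass
class ChangeCorrelation:
    rho: float
    p: float
    n: int
    pairs: pd.DataFrame  # gene x (k4_logfc, rna_logfc)


def aggregate_peak_logfc(
    assignment, peak_logfc: pd.Series, weights: pd.Series | None = None
) -> pd.Series:
    """Summarise multi-peak genes by the (depth-)weighted mean peak logFC."""
    t = assignment.table[["peak_id", "gene_id"]].copy()
    t["logfc"] = t["peak_id"].map(peak_logfc)
    t = t.dropna(subset=["logfc"])
    t["w"] = t["peak_id"].map(weights) if weights is not None else 1.0
    t["w"] = t["w"].fillna(1.0).clip(lower=1e-12)
    grp = t.groupby("gene_id")
    return grp.apply(
        lambda d: np.average(d["logfc"], weights=d["w"]), include_groups=False
    ).rename("k4_logfc")


def correlate_changes(
    k4_logfc: pd.Series,
    rna_logfc: pd.Series,
    restrict: Sequence[str] | pd.Index | None = None,
) -> ChangeCorrelation:
    """Spearman correlation of per-gene mark and expression log fold changes.

    Average ranks for ties; exact permutation p for n <= 8, t-approximation
    otherwise.
    """
    common = k4_logfc.index.intersection(rna_logfc.index)
    if restrict is not None:
        common = common.intersection(pd.Index(restrict))
    if len(common) < 3:
        raise ValueError("fewer than 3 genes in the intersection")
    x = k4_logfc.loc[common].to_numpy(dtype=float)
    y = rna_logfc.loc[common].to_numpy(dtype=float)
    sr = stats.spearmanr(x, y)
    rho = float(sr.statistic)
    if len(common) <= 8:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(sr.pvalue)
    pairs = pd.DataFrame({"k4_logfc": x, "rna_logfc": y}, index=common)
    return ChangeCorrelation(rho, p, len(common), pairs)


# ---------------------------------------------------------------------------
# set partitions and trends


@dataclass
class OverlapPartition:
    cells: dict            # (in_marked, in_dynK4, in_dynRNA) bools -> count
    concordant_up: int
    concordant_down: int
    discordant: int

    def cell(self, marked: bool, dyn_k4: bool, dyn_rna: bool) -> int:
        return self.cells[(marked, dyn_k4, dyn_rna)]


def overlap_partition(
    marked: set,
    dyn_k4: Mapping[str, str],
    dyn_rna: Mapping[str, str],
    universe: set,
) -> OverlapPartition:
    """All 8 Venn cells plus direction-resolved concordance counts.

    ``dyn_k4`` / ``dyn_rna`` map gene -> direction ('up'/'down'/'increased'/
    'decreased'); their keys are the dynamic sets.
    """
    for s in (marked, set(dyn_k4), set(dyn_rna)):
        extra = s - universe
        if extra:
            raise ValueError(f"genes outside universe: {sorted(extra)[:5]}")
    up = {"up", "increased"}
    k4set, rnaset = set(dyn_k4), set(dyn_rna)
    cells = {}
    for a in (True, False):
        for b in (True, False):
            for c in (True, False):
                cells[(a, b, c)] = sum(
                    1
                    for g in universe
                    if (g in marked) == a and (g in k4set) == b and (g in rnaset) == c
                )
    both = k4set & rnaset
    cu = sum(1 for g in both if (dyn_k4[g] in up) and (dyn_rna[g] in up))
    cd = sum(1 for g in both if (dyn_k4[g] not in up) and (dyn_rna[g] not in up))
    return OverlapPartition(cells, cu, cd, len(both) - cu - cd)


@dataclass
class LengthTrend:
    table: pd.DataFrame        # per length bin: n, fraction changed, midpoint
    rho: float
    p: float
    note: str = ""


def length_trend(
    peak_lengths: pd.Series,
    rna_changed: pd.Series,
    bin_edges: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> LengthTrend:
    """Fraction of peaks whose gene changes expression, by peak-length bin.

    Trend statistic: Spearman rho between the per-peak length-bin midpoint and
    the bin's changed-fraction, with a permutation p (flags shuffled over
    peaks).  Only single-gene peaks should be passed in.
    """
    if bin_edges is None:
        bin_edges = np.geomspace(200, 10_000, 8)
    lengths = peak_lengths.to_numpy(dtype=float)
    changed = rna_changed.reindex(peak_lengths.index).astype(bool).to_numpy()
    idx = np.digitize(lengths, bin_edges)

    def bin_table(ch: np.ndarray) -> pd.DataFrame:
        rows = []
        for b in range(len(bin_edges) + 1):
            sel = idx == b
            if sel.sum() == 0:
                continue
            lo = bin_edges[b - 1] if b > 0 else lengths[sel].min()
            hi = bin_edges[b] if b < len(bin_edges) else lengths[sel].max()
            rows.append(
                {"bin": b, "lo": lo, "hi": hi, "midpoint": 0.5 * (lo + hi),
                 "n": int(sel.sum()), "fraction_changed": float(ch[sel].mean())}
            )
        return pd.DataFrame(rows)

    table = bin_table(changed)

    def trend_stat(ch: np.ndarray) -> float:
        t = bin_table(ch)
        if len(t) < 2 or t["fraction_changed"].nunique() == 1:
            return np.nan
        return float(stats.spearmanr(t["midpoint"], t["fraction_changed"]).statistic)

    rho = trend_stat(changed)
    if np.isnan(rho):
        return LengthTrend(table, float("nan"), float("nan"),
                           note="degenerate: trend not applicable")
    rng = np.random.default_rng(seed)
    null = np.array(
        [trend_stat(rng.permutation(changed)) for _ in range(n_perm)]
    )
    null = null[~np.isnan(null)]
    p = float((1 + np.sum(np.abs(null) >= abs(rho))) / (1 + len(null)))
    return LengthTrend(table, rho, p)


def geneset_overlap_test(
    flag: pd.Series, target_set: Sequence[str], universe: Sequence[str]
) -> tuple[float, float]:
    """Two-sided Fisher test of a binary gene flag against a target gene set."""
    universe = pd.Index(universe)
    target = set(target_set)
    if not target:
        raise ValueError("empty target set")
    if not target <= set(universe):
        raise ValueError("target_set must be a subset of the universe")
    flag = flag.reindex(universe).fillna(False).astype(bool)
    in_t = universe.isin(target)
    a = int((flag & in_t).sum())
    b = int((~flag & in_t).sum())
    c = int((flag & ~in_t).sum())
    d = int((~flag & ~in_t).sum())
    return fisher_2x2(a, b, c, d)


# ---------------------------------------------------------------------------
# truth recovery


@dataclass
class RecoveryReport:
    precision: float
    recall: float
    n_true_dynamic: int
    n_called_dynamic: int
    onset_recall: float
    logfc_correlation: float
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "precision", "recall", "n_true_dynamic", "n_called_dynamic",
                    "onset_recall", "logfc_correlation",
                ],
                "value": [
                    self.precision, self.recall, self.n_true_dynamic,
                    self.n_called_dynamic, self.onset_recall, self.logfc_correlation,
                ],
            }
        )


def recover_truth(
    diff_result,
    assignment,
    truth,
    onset_result=None,
) -> RecoveryReport:
    """Score pipeline calls against simulated ground truth.

    A truth-dynamic gene counts as recovered when any peak assigned to it is
    called in the matching direction.  Precision is over genes carrying at
    least one dynamic peak call.  ``onset_result`` (an L3-vs-D2 contrast)
    yields the adult-onset classification recall.
    """
    notes: list[str] = []
    t = assignment.table[["peak_id", "gene_id"]].copy()
    cls = diff_result.table["class"]
    t["class"] = t["peak_id"].map(cls)
    t["logFC"] = t["peak_id"].map(diff_result.table["logFC"])
    up_labels = {"increased", "up"}
    down_labels = {"decreased", "down"}

    gene_call: dict[str, str] = {}
    gene_lfc: dict[str, float] = {}
    for gene, d in t.groupby("gene_id"):
        calls = set(d["class"]) - {"stable", "ns"}
        if calls & up_labels:
            gene_call[gene] = "up"
        elif calls & down_labels:
            gene_call[gene] = "down"
        dyn = d[~d["class"].isin(["stable", "ns"])]
        use = dyn if len(dyn) else d
        gene_lfc[gene] = float(use["logFC"].mean())

    tt = truth.table
    true_dyn = tt[tt["trend"] != "stable"]
    n_true = len(true_dyn)
    called = set(gene_call)
    n_called = len(called)
    if n_true == 0:
        recall = float("nan")
        notes.append("no dynamic genes in truth; recall undefined")
    else:
        hits = sum(
            1 for g, row in true_dyn.iterrows() if gene_call.get(g) == row["trend"]
        )
        recall = hits / n_true
    if n_called == 0:
        precision = float("nan")
        notes.append("no dynamic calls; precision undefined")
    else:
        correct = sum(
            1
            for g, call in gene_call.items()
            if g in tt.index and tt.loc[g, "trend"] == call
        )
        precision = correct / n_called

    onset_recall = float("nan")
    if onset_result is not None:
        adult = tt.index[(tt["onset"] == "adult")]
        t2 = assignment.table[["peak_id", "gene_id"]].copy()
        oc = onset_result.table["class"]
        t2["class"] = t2["peak_id"].map(oc)
        gained = set(t2.loc[t2["class"] == "D2>L3", "gene_id"])
        covered = adult.intersection(set(t2["gene_id"]))
        if len(covered):
            onset_recall = sum(1 for g in covered if g in gained) / len(covered)
        else:
            notes.append("no adult-onset genes covered by peaks")

    common = [g for g in gene_lfc if g in tt.index]
    if len(common) >= 3:
        est = np.array([gene_lfc[g] for g in common])
        inj = tt.loc[common, "effect"].to_numpy(dtype=float)
        logfc_corr = float(stats.pearsonr(est, inj).statistic) if np.std(inj) > 0 else float("nan")
    else:
        logfc_corr = float("nan")
    return RecoveryReport(precision, recall, n_true, n_called, onset_recall, logfc_corr, notes)
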