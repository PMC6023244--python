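"""Differential binding: peak counting, NB GLM testing and dynamic classification.

The test is an edgeR-style negative-binomial log-linear model per peak with a
two-group design and full library sizes as offsets: a common dispersion is
estimated by maximising the Cox-Reid adjusted profile likelihood summed over
all peaks, per-peak dispersions are shrunk toward it by weighted likelihood
(prior degrees of freedom 10), and each peak gets a likelihood-ratio chi^2
p-value for the group effect.

Classification then applies the domain filters: BH FDR < 0.05, fold change of
the normalized mark level of at least 30% (``min_fc`` = 1.3), and a
mark/occupancy-control ratio above 1 in every replicate of at least one
timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .peaks import PeakSet
from .tracks import CoverageTrack


def peak_bin_counts(peaks: PeakSet, track: CoverageTrack) -> np.ndarray:
    """Raw reads per peak; partial bins pro-rated by overlap fraction."""
    bs = track.bin_size
    out = np.empty(len(peaks))
    cum = {c: np.concatenate([[0.0], np.cumsum(track.data[c])]) for c in track.chroms}
    for i, p in enumerate(peaks):
        if p.chrom not in track.data:
            raise ValueError(f"peak on unknown chromosome {p.chrom}")
        n = track.n_bins(p.chrom)
        if p.end > n * bs:
            raise ValueError(f"peak {p.id} outside chromosome bounds")
        c = cum[p.chrom]
        arr = track.data[p.chrom]

        def integral(x: float) -> float:
            k = int(x // bs)
            frac = (x - k * bs) / bs
            return c[k] + (arr[k] * frac if frac > 0 else 0.0)

        out[i] = integral(p.end) - integral(p.start)
    return out


@dataclass
class PeakCountMatrix:
    """Peaks x libraries raw counts plus library sizes and column metadata."""

    counts: pd.DataFrame           # index: peak ids; columns: library labels
    library_sizes: pd.Series       # per library (full library size)
    meta: pd.DataFrame             # per library: antibody, timepoint, replicate

    def cpm(self) -> pd.DataFrame:
        return self.counts * (1e6 / self.library_sizes)


def count_in_peaks(
    peaks: PeakSet, tracks: Mapping[object, CoverageTrack]
) -> PeakCountMatrix:
    """Count each library's reads within each peak (depth kept separately)."""
    cols, meta_rows, labels = {}, [], []
    sizes = {}
    for key, track in tracks.items():
        if isinstance(key, tuple):
            label = "_".join(str(k) for k in key)
            ab, tp, rep = (list(key) + [None, None, None])[:3]
        else:
            label, ab, tp, rep = str(key), None, None, None
        labels.append(label)
        cols[label] = peak_bin_counts(peaks, track)
        sizes[label] = track.library_size
        meta_rows.append({"library": label, "antibody": ab, "timepoint": tp, "replicate": rep})
    counts = pd.DataFrame(cols, index=peaks.ids())
    meta = pd.DataFrame(meta_rows).set_index("library")
    return PeakCountMatrix(counts, pd.Series(sizes), meta)


# ---------------------------------------------------------------------------
# NB GLM machinery


def _nb_loglik(y: np.ndarray, mu: np.ndarray, disp: float) -> np.ndarray:
    """Row-wise NB log-likelihood for matrix y against means mu."""
    if disp <= 0:
        return (-mu + y * np.log(np.maximum(mu, 1e-300)) - special.gammaln(y + 1)).sum(1)
    r = 1.0 / disp
    mu = np.maximum(mu, 1e-300)
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    ).sum(1)


def _fit_group_means(
    y: np.ndarray, m: np.ndarray, disp: float, n_iter: int = 8
) -> np.ndarray:
    """MLE of per-peak rate lambda (mean_ij = lambda_i * m_j) by Newton steps.

    y: peaks x libs; m: lib sizes.  At disp=0 the closed form sum(y)/sum(m)
    is exact; NB requires iteration.
    """
    lam = np.maximum(y.sum(1) / m.sum(), 1e-12)
    if disp <= 0:
        return lam
    for _ in range(n_iter):
        mu = lam[:, None] * m[None, :]
        denom = 1.0 + disp * mu
        score = ((y - mu) / (lam[:, None] * denom)).sum(1)
        info = (mu / (lam[:, None] ** 2 * denom)).sum(1)
        step = score / np.maximum(info, 1e-12)
        lam = np.maximum(lam + step, 1e-12)
    return lam


def _group_loglik(
    y: np.ndarray, m: np.ndarray, groups: np.ndarray, disp: float, adjust: bool
) -> np.ndarray:
    """Per-peak profile log-likelihood with per-group fitted means.

    With ``adjust`` the Cox-Reid term -0.5*log Fisher-information per fitted
    group coefficient is subtracted (adjusted profile likelihood).
    """
    ll = np.zeros(y.shape[0])
    for g in np.unique(groups):
        sel = groups == g
        lam = _fit_group_means(y[:, sel], m[sel], disp)
        mu = lam[:, None] * m[sel][None, :]
        ll += _nb_loglik(y[:, sel], mu, disp)
        if adjust:
            info = (mu / (1.0 + disp * mu)).sum(1)  # info wrt log-lambda
            ll -= 0.5 * np.log(np.maximum(info, 1e-12))
    return ll


def estimate_dispersions(
    counts: np.ndarray,
    lib_sizes: np.ndarray,
    groups: np.ndarray,
    prior_df: float = 10.0,
    grid: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Common + shrunken tagwise dispersions on a log-spaced grid.

    The common dispersion maximises the summed adjusted profile likelihood;
    tagwise values maximise ``APL_i + w * mean(APL)`` where the weight is
    prior_df / residual df, shrinking sparse per-peak information toward the
    common value.
    """
    if grid is None:
        grid = np.concatenate([[1e-6], np.geomspace(1e-4, 5.0, 40)])
    apl = np.empty((counts.shape[0], len(grid)))
    for j, d in enumerate(grid):
        apl[:, j] = _group_loglik(counts, lib_sizes, groups, float(d), adjust=True)
    common = float(grid[np.argmax(apl.sum(0))])
    resid_df = counts.shape[1] - len(np.unique(groups))
    weight = prior_df / max(resid_df, 1)
    shared = apl.mean(0)
    tag_idx = np.argmax(apl + weight * shared[None, :], axis=1)
    return common, grid[tag_idx].astype(float)


@dataclass
class DiffResult:
    """Per-peak differential call: logFC, p, FDR and dynamic class."""

    table: pd.DataFrame  # index peak ids; logFC, p, FDR, class
    contrast: tuple[str, str] = ("D2", "D12")

    def classed(self, label: str) -> pd.Index:
        return self.table.index[self.table["class"] == label]

    def to_tsv(self, path, peaks: PeakSet | None = None) -> None:
        t = self.table.copy()
        if peaks is not None:
            coords = pd.DataFrame(
                {"chrom": [p.chrom for p in peaks], "start": [p.start for p in peaks],
                 "end": [p.end for p in peaks]},
                index=peaks.ids(),
            )
            t = coords.join(t, how="right")
        t.to_csv(path, sep="\t", index_label="peak_id", float_format="%.6g")


def nb_glm_test(
    counts: pd.DataFrame,
    groups: Sequence[str],
    lib_sizes: pd.Series | np.ndarray,
    prior_df: float = 10.0,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """NB GLM likelihood-ratio test per peak for a two-group contrast.

    ``counts`` must be raw (unscaled); depth enters via ``lib_sizes`` offsets.
    A fixed ``dispersion`` bypasses estimation (0 gives the exact Poisson
    two-sample likelihood-ratio test).  Returns a DataFrame (logFC base 2 of
    group2 vs group1, p).
    """
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    for g in uniq:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has < 2 replicates")
    y = counts.to_numpy(dtype=float)
    m = np.asarray(lib_sizes, dtype=float)
    if y.shape[1] != len(m):
        raise ValueError("lib_sizes length mismatch")

    if dispersion is not None:
        common = float(dispersion)
        tagwise = np.full(y.shape[0], common)
    else:
        common, tagwise = estimate_dispersions(y, m, groups, prior_df=prior_df)

    sel1, sel2 = groups == uniq[0], groups == uniq[1]
    n = y.shape[0]
    ll_full = np.zeros(n)
    ll_null = np.zeros(n)
    lam1 = np.zeros(n)
    lam2 = np.zeros(n)
    # group dispersions vary per peak: loop over unique tagwise values (grid-valued)
    for d in np.unique(tagwise):
        rows = tagwise == d
        yd = y[rows]
        l1 = _fit_group_means(yd[:, sel1], m[sel1], d)
        l2 = _fit_group_means(yd[:, sel2], m[sel2], d)
        l0 = _fit_group_means(yd, m, d)
        ll_full[rows] = _nb_loglik(yd[:, sel1], l1[:, None] * m[sel1][None, :], d) + _nb_loglik(
            yd[:, sel2], l2[:, None] * m[sel2][None, :], d
        )
        ll_null[rows] = _nb_loglik(yd, l0[:, None] * m[None, :], d)
        lam1[rows], lam2[rows] = l1, l2

    lr = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = stats.chi2.sf(lr, df=1)
    # shrunk logFC: half-read prior pseudo-rate avoids infinities at zero counts
    prior = 0.5 / m.sum()
    logfc = np.log2((lam2 + prior) / (lam1 + prior))
    return pd.DataFrame(
        {"logFC": logfc, "p": p, "dispersion": tagwise},
        index=counts.index,
    ).assign(common_dispersion=common)


def normalized_peak_levels(
    counts: PeakCountMatrix, mark: str = "H3K4me3", control: str = "H3"
) -> pd.DataFrame:
    """Per peak, per (timepoint, replicate): depth-normalized mark/control ratio."""
    meta = counts.meta
    cpm = counts.cpm()
    out = {}
    for (tp, rep), grp in meta.groupby(["timepoint", "replicate"]):
        mark_lib = grp.index[grp["antibody"] == mark]
        ctrl_lib = grp.index[grp["antibody"] == control]
        if len(mark_lib) != 1 or len(ctrl_lib) != 1:
            continue
        denom = cpm[ctrl_lib[0]]
        ratio = cpm[mark_lib[0]] / denom.where(denom > 0)
        out[(tp, rep)] = ratio
    levels = pd.DataFrame(out)
    levels.columns = pd.MultiIndex.from_tuples(levels.columns, names=["timepoint", "replicate"])
    return levels


def classify_dynamic(
    diff: pd.DataFrame,
    levels: pd.DataFrame,
    fdr: float = 0.05,
    min_fc: float = 1.3,
    min_ratio: float = 1.0,
    labels: tuple[str, str, str] = ("increased", "decreased", "stable"),
) -> DiffResult:
    """Apply the FDR, fold-change and replicate-ratio filters.

    increased: FDR < fdr, fold >= min_fc, and mark/control ratio > min_ratio in
    every replicate of at least one timepoint; decreased symmetric.
    """
    if not diff.index.equals(levels.index):
        missing = diff.index.difference(levels.index)
        if len(missing):
            raise ValueError(f"levels missing rows for {len(missing)} peaks")
        levels = levels.loc[diff.index]
    up, down, stable = labels
    fdr_vals = multipletests(diff["p"].to_numpy(), method="fdr_bh")[1]
    fold = 2.0 ** diff["logFC"].to_numpy()

    ratio_ok = np.zeros(len(diff), dtype=bool)
    for tp in levels.columns.get_level_values("timepoint").unique():
        sub = levels[tp]
        ratio_ok |= (sub > min_ratio).all(axis=1).to_numpy()

    cls = np.full(len(diff), stable, dtype=object)
    sig = (fdr_vals < fdr) & ratio_ok
    cls[sig & (fold >= min_fc)] = up
    cls[sig & (fold <= 1.0 / min_fc)] = down
    table = pd.DataFrame(
        {"logFC": diff["logFC"], "p": diff["p"], "FDR": fdr_vals, "class": cls},
        index=diff.index,
    )
    return DiffResult(table)


def timepoint_contrast(
    counts: PeakCountMatrix,
    levels: pd.DataFrame,
    timepoints: tuple[str, str] = ("L3", "D2"),
    mark: str = "H3K4me3",
    fdr: float = 0.05,
    min_fc: float = 1.3,
    min_ratio: float = 1.0,
) -> DiffResult:
    """Differential call between two timepoints (e.g. larval vs young adult).

    Classes are labelled '<b>><a>', '<b><<a>' and 'ns' for contrast (a, b).
    """
    a, b = timepoints
    meta = counts.meta
    libs = meta.index[(meta["antibody"] == mark) & meta["timepoint"].isin([a, b])]
    sub = counts.counts[libs]
    groups = meta.loc[libs, "timepoint"].to_numpy()
    # order groups so logFC is b vs a
    order = np.argsort([0 if g == a else 1 for g in groups], kind="stable")
    libs = libs[order]
    sub = sub[libs]
    groups = meta.loc[libs, "timepoint"].to_numpy()
    diff = nb_glm_test(sub, groups, counts.library_sizes[libs])
    lvl = levels.loc[:, levels.columns.get_level_values("timepoint").isin([a, b])]
    res = classify_dynamic(
        diff, lvl, fdr=fdr, min_fc=min_fc, min_ratio=min_ratio,
        labels=(f"{b}>{a}", f"{b}<{a}", "ns"),
    )
    res.contrast = (a, b)
    return res
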