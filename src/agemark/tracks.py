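"""Binned genome coverage: containers, bedGraph I/O, control normalization and replicate QC.

A :class:`CoverageTrack` holds per-chromosome read counts in fixed-width bins
(default 25 bp), the resolution at which all downstream stages (normalization,
peak calling, metagene profiles) operate.  Coordinates are 0-based half-open
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed input file (names the offending line where possible)."""


class NormalizationError(ValueError):
    pass


@dataclass
class CoverageTrack:
    """Per-chromosome binned read counts for one sequencing library."""

    bin_size: int
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, arr in self.data.items():
            arr = np.asarray(arr)
            if np.any(arr < 0):
                raise ValueError(f"negative counts on {chrom}")
            self.data[chrom] = arr

    @property
    def library_size(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def n_bins(self, chrom: str) -> int:
        return len(self.data[chrom])

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom]) * self.bin_size

    @property
    def total_bins(self) -> int:
        return int(sum(len(a) for a in self.data.values()))

    def same_grid(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and set(self.data) == set(other.data)
            and all(len(self.data[c]) == len(other.data[c]) for c in self.data)
        )

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(self.bin_size, {c: a.copy() for c, a in self.data.items()})


@dataclass
class NormalizedTrack:
    """Per-bin RPKM(mark) - RPKM(control) signal; float valued, may be negative."""

    bin_size: int
    data: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return list(self.data)


def read_bedgraph(
    path, bin_size: int, chrom_sizes: Mapping[str, int] | None = None
) -> CoverageTrack:
    """Read a 4-column bedGraph into a binned track.

    Intervals must be sorted, non-overlapping and aligned to ``bin_size``
    boundaries; bins absent from the file read as zero.  An interval may span
    several bins (constant value per bin).
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if s % bin_size or e % bin_size:
                raise FormatError(
                    f"{path}:{lineno}: interval [{s},{e}) not aligned to bin_size={bin_size}"
                )
            if e <= s:
                raise FormatError(f"{path}:{lineno}: empty or inverted interval")
            ivs = per_chrom.setdefault(chrom, [])
            if ivs and s < ivs[-1][1]:
                raise FormatError(f"{path}:{lineno}: unsorted or overlapping interval")
            ivs.append((s, e, v))

    data: dict[str, np.ndarray] = {}
    for chrom, ivs in per_chrom.items():
        length = ivs[-1][1]
        if chrom_sizes is not None:
            length = max(length, chrom_sizes[chrom])
        arr = np.zeros(length // bin_size, dtype=np.int64)
        for s, e, v in ivs:
            arr[s // bin_size : e // bin_size] = int(round(v))
        data[chrom] = arr
    if chrom_sizes is not None:
        for chrom, size in chrom_sizes.items():
            if chrom not in data:
                data[chrom] = np.zeros(size // bin_size, dtype=np.int64)
    return CoverageTrack(bin_size, data)


def write_bedgraph(track: CoverageTrack, path, write_zeros: bool = False) -> None:
    """Write a track as bedGraph, run-length collapsing equal adjacent bins."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in track.chroms:
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            # boundaries of runs of equal value
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0 and not write_zeros:
                    continue
                fh.write(f"{chrom}\t{s * bs}\t{e * bs}\t{int(v)}\n")


def _rpkm(arr: np.ndarray, library_size: float, bin_size: int) -> np.ndarray:
    return arr * (1e9 / (library_size * bin_size))


def normalize_subtract(mark: CoverageTrack, control: CoverageTrack) -> NormalizedTrack:
    """Per-bin RPKM(mark) - RPKM(control), the control-subtracted signal track."""
    if not mark.same_grid(control):
        raise NormalizationError("mark and control tracks are on different grids")
    lm, lc = mark.library_size, control.library_size
    if lm == 0 or lc == 0:
        raise NormalizationError("zero library size")
    data = {
        c: _rpkm(mark.data[c].astype(float), lm, mark.bin_size)
        - _rpkm(control.data[c].astype(float), lc, mark.bin_size)
        for c in mark.chroms
    }
    return NormalizedTrack(mark.bin_size, data)


@dataclass
class WindowMatrix:
    """Genomic windows x libraries matrix of log2 CPM(mark) - log2 CPM(control)."""

    values: pd.DataFrame  # index: (chrom, start); columns: library names
    window: int

    @property
    def libraries(self) -> list[str]:
        return list(self.values.columns)


def window_matrix(
    pairs: Sequence[tuple[CoverageTrack, CoverageTrack]],
    window: int = 2000,
    names: Sequence[str] | None = None,
    pseudocount_cpm: float = 0.5,
) -> WindowMatrix:
    """Tile the genome into fixed windows and compute per-library log2 CPM ratios.

    Each value is ``log2(CPM_mark + eps) - log2(CPM_control + eps)`` over the
    window, the replicate-comparison statistic used for correlation QC.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 (mark, control) pairs")
    ref = pairs[0][0]
    if window % ref.bin_size:
        raise ValueError("window must be a multiple of bin_size")
    for m, c in pairs:
        if not m.same_grid(ref) or not c.same_grid(ref):
            raise ValueError("all tracks must share the binning grid")
    if names is None:
        names = [f"lib{i}" for i in range(len(pairs))]
    per_win = window // ref.bin_size

    index = []
    cols = {n: [] for n in names}
    for chrom in ref.chroms:
        nbin = ref.n_bins(chrom)
        nwin = int(np.ceil(nbin / per_win))
        for name, (m, c) in zip(names, pairs):
            pad = nwin * per_win - nbin
            mv = np.pad(m.data[chrom].astype(float), (0, pad)).reshape(nwin, per_win).sum(1)
            cv = np.pad(c.data[chrom].astype(float), (0, pad)).reshape(nwin, per_win).sum(1)
            cpm_m = mv * 1e6 / m.library_size
            cpm_c = cv * 1e6 / c.library_size
            cols[name].append(
                np.log2(cpm_m + pseudocount_cpm) - np.log2(cpm_c + pseudocount_cpm)
            )
        index.extend((chrom, int(i * window)) for i in range(nwin))
    values = pd.DataFrame(
        {n: np.concatenate(v) for n, v in cols.items()},
        index=pd.MultiIndex.from_tuples(index, names=["chrom", "start"]),
    )
    return WindowMatrix(values, window)


@dataclass
class QCReport:
    correlation: pd.DataFrame       # symmetric Pearson matrix, unit diagonal
    passed: pd.Series               # per library: min off-diagonal r >= threshold
    pca: pd.DataFrame               # libraries x (PC1, PC2)
    explained_variance: np.ndarray  # ratio per component, non-increasing
    threshold: float
    notes: list[str] = field(default_factory=list)


def qc_correlation_pca(
    matrix: WindowMatrix,
    threshold: float = 0.8,
    groups: Mapping[str, str] | None = None,
) -> QCReport:
    """Pairwise Pearson correlation over windows plus a PCA of library profiles.

    A replicate passes when its correlation with every other library of its
    replicate group (same ``groups`` value; all libraries when ``groups`` is
    None) reaches ``threshold``.  A constant (zero-variance) column cannot be
    correlated and is reported as a failing library.
    """
    from sklearn.decomposition import PCA

    vals = matrix.values
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 libraries")
    libs = list(vals.columns)
    notes: list[str] = []
    sd = vals.std(axis=0, ddof=0)
    constant = sd[sd == 0].index.tolist()
    for lib in constant:
        notes.append(f"library {lib}: constant profile, correlation undefined")

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(vals.to_numpy().T)
    corr = pd.DataFrame(corr, index=libs, columns=libs)
    for lib in constant:
        corr.loc[lib, :] = 0.0
        corr.loc[:, lib] = 0.0
    np.fill_diagonal(corr.values, 1.0)

    mask = ~np.eye(len(libs), dtype=bool)
    if groups is not None:
        grp = np.array([groups[l] for l in libs])
        mask &= grp[:, None] == grp[None, :]
    off = corr.where(mask)
    passed = (off.min(axis=1) >= threshold) & ~pd.Index(libs).isin(constant)
    passed = pd.Series(passed.to_numpy(), index=libs, name="passed")

    X = vals.to_numpy().T  # libraries as observations
    X = X - X.mean(axis=0)
    ncomp = min(len(libs), 2)
    pca_model = PCA(n_components=ncomp, svd_solver="full")
    coords = pca_model.fit_transform(X)
    pca = pd.DataFrame(coords, index=libs, columns=[f"PC{i+1}" for i in range(ncomp)])
    return QCReport(corr, passed, pca, pca_model.explained_variance_ratio_, threshold, notes)
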