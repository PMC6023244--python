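"""Enrichment-domain calling against a local Poisson background.

A simplified dual-mode caller in the MACS2 tradition operating directly on
binned counts: mark counts are smoothed with a fragment-size moving sum, the
background rate is the depth-scaled maximum of genome-wide, small-local
(1 kb) and large-local (10 kb) control rates, and each bin gets a Poisson
upper-tail p-value.  ``narrow`` mode keeps Benjamini-Hochberg q < 0.01 bins;
``broad`` mode keeps p < 0.05 cores extended through p < 0.1 linking bins.
Significant bins are merged into domains.  Model building / fragment-shift
estimation is deliberately absent (fixed extension size instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .tracks import CoverageTrack


@dataclass
class PeakCallParams:
    extsize: int = 200
    narrow_q: float = 0.01
    broad_p: float = 0.05
    broad_link_p: float = 0.1
    slocal: int = 1_000
    llocal: int = 10_000
    min_len: int = 200
    merge_gap: int = 25

    def __post_init__(self) -> None:
        if self.broad_link_p < self.broad_p:
            raise ValueError("broad_link_p must be >= broad_p")
        for name in ("extsize", "slocal", "llocal", "min_len", "merge_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    score: float  # -log10(q) at summit
    fold: float   # smoothed mark / local lambda at summit
    mode: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("peak with start >= end")
        if not self.start <= self.summit < self.end:
            raise ValueError("summit outside peak")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class PeakSet:
    """Sorted, internally non-overlapping peaks with a parameter fingerprint."""

    def __init__(self, peaks: Iterable[Peak], provenance: str = ""):
        self.peaks = sorted(peaks, key=lambda p: (p.chrom, p.start))
        self.provenance = provenance
        prev: Peak | None = None
        for p in self.peaks:
            if prev is not None and prev.chrom == p.chrom and p.start < prev.end:
                raise ValueError(f"overlapping peaks within set at {p.chrom}:{p.start}")
            prev = p

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i) -> Peak:
        return self.peaks[i]

    def total_bp(self) -> int:
        return sum(p.length for p in self.peaks)

    def ids(self) -> list[str]:
        return [p.id for p in self.peaks]

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, p in enumerate(self.peaks):
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t{p.score:.4f}\t.\t"
                    f"{p.fold:.4f}\t{p.summit}\t{p.mode}\n"
                )

    @staticmethod
    def from_bed(path) -> "PeakSet":
        peaks = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                start, end = int(f[1]), int(f[2])
                score = float(f[4]) if len(f) > 4 else 0.0
                fold = float(f[6]) if len(f) > 6 else 0.0
                summit = int(f[7]) if len(f) > 7 else start
                mode = f[8] if len(f) > 8 else "imported"
                peaks.append(Peak(f[0], start, end, summit, score, fold, mode))
        return PeakSet(peaks, provenance=f"from_bed:{path}")


def _moving_sum(arr: np.ndarray, w: int) -> np.ndarray:
    """Centred moving sum; windows truncated at chromosome edges."""
    w = min(w, len(arr))
    return np.convolve(arr, np.ones(w), mode="same")


def _bin_pvalues(
    mark: CoverageTrack, control: CoverageTrack | None, params: PeakCallParams
):
    """Per-bin Poisson upper-tail p-values of the smoothed mark vs local lambda."""
    bs = mark.bin_size
    if params.extsize < bs:
        raise ValueError("extsize must be >= bin_size")
    w = max(1, params.extsize // bs)
    mark_total = mark.library_size
    total_bins = mark.total_bins

    if control is not None:
        if not mark.same_grid(control):
            raise ValueError("mark and control tracks on different grids")
        ctrl_total = control.library_size
        ratio = mark_total / ctrl_total if ctrl_total > 0 else 0.0

    pvals, signal, lam_all = {}, {}, {}
    for chrom in mark.chroms:
        m = mark.data[chrom].astype(float)
        sm = _moving_sum(m, w)
        if control is None or control.library_size == 0:
            lam = np.full(len(m), mark_total / total_bins * w)
        else:
            c = control.data[chrom].astype(float)
            lam_bg = ctrl_total / total_bins * w
            ws = max(w, params.slocal // bs)
            wl = max(w, params.llocal // bs)
            lam_s = _moving_sum(c, ws) * (w / ws)
            lam_l = _moving_sum(c, wl) * (w / wl)
            lam = np.maximum(lam_bg, np.maximum(lam_s, lam_l)) * ratio
        lam = np.maximum(lam, 1e-12)
        pvals[chrom] = stats.poisson.sf(np.round(sm) - 1, lam)
        signal[chrom] = sm
        lam_all[chrom] = lam
    return pvals, signal, lam_all


def _bh_q(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def _runs_from_mask(mask: np.ndarray):
    """(start, end) bin index pairs of True runs."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts, ends))


def _merge_runs(runs, gap_bins: int):
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= gap_bins:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return merged


def call_peaks(
    mark: CoverageTrack,
    control: CoverageTrack | None,
    params: PeakCallParams | None = None,
    mode: str = "narrow",
) -> PeakSet:
    """Call enrichment domains on one library pair.

    Returns an empty set (not an error) when nothing is significant.
    """
    if params is None:
        params = PeakCallParams()
    if mode not in ("narrow", "broad"):
        raise ValueError("mode must be 'narrow' or 'broad'")
    pvals, signal, lam_all = _bin_pvalues(mark, control, params)

    bs = mark.bin_size
    gap_bins = max(0, params.merge_gap // bs)
    min_bins = max(1, params.min_len // bs)
    peaks: list[Peak] = []

    if mode == "narrow":
        chroms = list(pvals)
        flat = np.concatenate([pvals[c] for c in chroms])
        qflat = _bh_q(flat)
        offset = 0
        qvals = {}
        for c in chroms:
            n = len(pvals[c])
            qvals[c] = qflat[offset : offset + n]
            offset += n
        for chrom in chroms:
            sig = qvals[chrom] < params.narrow_q
            for s, e in _merge_runs(_runs_from_mask(sig), gap_bins):
                if e - s < min_bins:
                    continue
                seg = signal[chrom][s:e]
                sbin = s + int(np.argmax(seg))  # leftmost max
                q = max(qvals[chrom][sbin], 1e-300)
                peaks.append(
                    Peak(
                        chrom,
                        int(s * bs),
                        int(e * bs),
                        int(sbin * bs + bs // 2),
                        float(-np.log10(q)),
                        float(signal[chrom][sbin] / lam_all[chrom][sbin]),
                        "narrow",
                    )
                )
    else:
        for chrom in pvals:
            p = pvals[chrom]
            core = p < params.broad_p
            link = p < params.broad_link_p
            link_runs = _runs_from_mask(link)
            kept = [(s, e) for s, e in link_runs if core[s:e].any()]
            for s, e in _merge_runs(kept, gap_bins):
                if e - s < min_bins:
                    continue
                seg = signal[chrom][s:e]
                sbin = s + int(np.argmax(seg))
                pv = max(p[sbin], 1e-300)
                peaks.append(
                    Peak(
                        chrom,
                        int(s * bs),
                        int(e * bs),
                        int(sbin * bs + bs // 2),
                        float(-np.log10(pv)),
                        float(signal[chrom][sbin] / lam_all[chrom][sbin]),
                        "broad",
                    )
                )
    fingerprint = f"mode={mode};{params}"
    return PeakSet(peaks, provenance=fingerprint)


def merge_peaksets(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> PeakSet:
    """Union-merge: intervals overlapping by >= min_overlap bp coalesce to their hull.

    Idempotent and commutative; the merged peak keeps the max score and the
    summit of its highest-scoring constituent; mode is "merged" when mixed.
    """
    allp = sorted(list(a) + list(b), key=lambda p: (p.chrom, p.start))
    out: list[Peak] = []
    for p in allp:
        if (
            out
            and out[-1].chrom == p.chrom
            and min(out[-1].end, p.end) - max(out[-1].start, p.start) >= min_overlap
        ):
            prev = out[-1]
            best = prev if prev.score >= p.score else p
            out[-1] = Peak(
                prev.chrom,
                min(prev.start, p.start),
                max(prev.end, p.end),
                best.summit,
                max(prev.score, p.score),
                max(prev.fold, p.fold),
                prev.mode if prev.mode == p.mode else "merged",
            )
        else:
            out.append(replace(p))
    return PeakSet(out, provenance=f"merge({a.provenance} | {b.provenance})")


def _poisson_enrichment_p(
    mark_count: float, ctrl_count: float, depth_ratio: float, floor_lam: float
) -> float:
    lam = max(ctrl_count * depth_ratio, floor_lam)
    return float(stats.poisson.sf(round(mark_count) - 1, lam))


def replicate_consistency(
    peaks: PeakSet,
    per_rep_mark: Sequence[CoverageTrack],
    per_rep_control: Sequence[CoverageTrack],
    min_reps: int = 2,
    alpha: float = 0.05,
    test: Callable | None = None,
) -> PeakSet:
    """Keep peaks significantly enriched (q < alpha) in >= min_reps replicates.

    Default per-replicate test: Poisson upper tail of the mark count in the
    peak interval against the depth-scaled control count (floored at the
    genome-wide control rate).  ``test`` may override it with any callable
    ``(mark_count, ctrl_count, depth_ratio, floor_lam) -> p``.
    """
    if len(per_rep_mark) != len(per_rep_control):
        raise ValueError("mark and control replicate lists differ in length")
    if len(per_rep_mark) < min_reps:
        raise ValueError("fewer replicates than min_reps")
    if test is None:
        test = _poisson_enrichment_p
    from statsmodels.stats.multitest import multipletests

    from .differential import peak_bin_counts

    n_ok = np.zeros(len(peaks), dtype=int)
    for mark, ctrl in zip(per_rep_mark, per_rep_control):
        mark_counts = peak_bin_counts(peaks, mark)
        ctrl_counts = peak_bin_counts(peaks, ctrl)
        ratio = mark.library_size / ctrl.library_size
        rate = ctrl.library_size / ctrl.total_bins / ctrl.bin_size  # per bp
        ps = np.array(
            [
                test(mc, cc, ratio, rate * p.length * ratio)
                for mc, cc, p in zip(mark_counts, ctrl_counts, peaks)
            ]
        )
        if len(ps) == 0:
            continue
        q = multipletests(ps, method="fdr_bh")[1]
        n_ok += q < alpha
    kept = [p for p, n in zip(peaks, n_ok) if n >= min_reps]
    return PeakSet(kept, provenance=f"{peaks.provenance};consistency>={min_reps}")
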