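"""Pre-ranked gene-set enrichment: weighted KS running sum and permutation p.

Items (peaks or genes) are ranked by a real-valued score, descending.  Set
membership may be given directly or derived from >= 1-bp interval overlap
with a peak set.  The enrichment score is the signed maximum deviation of the
running sum in which member hits increment by |score|^weight (normalised over
members) and misses decrement by 1/(N - N_members).  Significance comes from
random-membership permutations with an add-one rule, so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

from .peaks import PeakSet


@dataclass
class RankedList:
    """Ordered item ids with descending rank scores; ties broken by id."""

    ids: list[str]
    scores: np.ndarray
    coords: pd.DataFrame | None = None  # optional: chrom/start/end per id

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate ids in ranked list")
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores not in descending order")

    def __len__(self) -> int:
        return len(self.ids)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"id": self.ids, "score": self.scores}).to_csv(
            path, sep="\t", index=False
        )

    @staticmethod
    def from_scores(scores: Mapping[str, float], coords: pd.DataFrame | None = None) -> "RankedList":
        items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return RankedList([k for k, _ in items], np.array([v for _, v in items]), coords)


def rank_by_difference(levels_a: pd.Series, levels_b: pd.Series) -> RankedList:
    """Rank items by log2(a/b) of their signal levels, highest ratio first."""
    common = levels_a.index.intersection(levels_b.index)
    a = levels_a.loc[common]
    b = levels_b.loc[common]
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("levels must be positive (apply a pseudocount upstream)")
    score = np.log2(a / b)
    return RankedList.from_scores(score.to_dict())


def membership_by_overlap(
    ranked: RankedList, set_peaks: PeakSet, min_overlap: int = 1
) -> set[str]:
    """Ids of ranked peaks overlapping the set by >= min_overlap bp."""
    if ranked.coords is None:
        raise ValueError("ranked list carries no coordinates")
    by_chrom: dict[str, list] = {}
    for p in set_peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    members = set()
    for item_id in ranked.ids:
        row = ranked.coords.loc[item_id]
        for s, e in by_chrom.get(row["chrom"], ()):
            if min(row["end"], e) - max(row["start"], s) >= min_overlap:
                members.add(item_id)
                break
    return members


@dataclass
class GseaResult:
    es: float
    running_sum: np.ndarray
    leading_edge: list[str] = field(default_factory=list)
    nes: float = float("nan")
    p: float = float("nan")
    fdr: float = float("nan")
    n_perm: int = 0


def _es_from_hits(scores: np.ndarray, hit: np.ndarray, weight: float) -> tuple[float, np.ndarray]:
    n = len(scores)
    n_hit = int(hit.sum())
    w = np.abs(scores) ** weight
    denom = w[hit].sum()
    if denom <= 0:  # all member scores zero: fall back to equal hit weights
        inc = hit / n_hit
    else:
        inc = np.where(hit, w / denom, 0.0)
    if n_hit == n:
        steps = inc
    else:
        steps = inc - (~hit) / (n - n_hit)
    running = np.concatenate([[0.0], np.cumsum(steps)])
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def enrichment_score(
    ranked: RankedList, members: Sequence[str] | set, weight: float = 1.0
) -> GseaResult:
    """Weighted KS enrichment score of a member set along the ranked list."""
    members = set(members)
    if not members:
        raise ValueError("empty member set")
    unknown = members - set(ranked.ids)
    if unknown:
        raise ValueError(f"members not in ranked list: {sorted(unknown)[:5]}")
    hit = np.array([i in members for i in ranked.ids])
    if hit.all() and weight > 0:
        warnings.warn("member set covers the whole list: ES = 1 by construction")
    es, running = _es_from_hits(ranked.scores, hit, weight)
    if es >= 0:
        peak = int(np.argmax(running))
        leading = [i for i, h in zip(ranked.ids[:peak], hit[:peak]) if h]
    else:
        trough = int(np.argmin(running))
        leading = [i for i, h in zip(ranked.ids[trough:], hit[trough:]) if h]
    return GseaResult(es, running, leading)


def permutation_significance(
    ranked: RankedList,
    members: Sequence[str] | set,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> GseaResult:
    """Permutation null (random member sets of equal size) for p, NES and FDR."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    res = enrichment_score(ranked, members, weight=weight)
    n = len(ranked)
    n_hit = len(set(members))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    hit = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        hit[:] = False
        hit[rng.choice(n, size=n_hit, replace=False)] = True
        null[i], _ = _es_from_hits(ranked.scores, hit, weight)
    res.n_perm = n_perm
    res.p = float((1 + np.sum(np.abs(null) >= abs(res.es))) / (1 + n_perm))
    same_sign = null[np.sign(null) == np.sign(res.es)] if res.es != 0 else null
    denom = np.mean(np.abs(same_sign)) if len(same_sign) else np.mean(np.abs(null))
    res.nes = float(res.es / denom) if denom > 0 else float("nan")
    # single-set FDR: fraction of |null NES| exceeding |NES| (clipped to [p, 1])
    if denom > 0:
        null_nes = np.abs(null) / denom
        res.fdr = float(min(1.0, max(res.p, np.mean(null_nes >= abs(res.nes)))))
    return res
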