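"""Synthetic ChIP-seq / RNA-seq experiment generator with per-gene ground truth.

Emulates the design of an aging histone-mark study in *C. elegans* somatic
tissue: three ChIP replicates per timepoint (larval L3, adult day 2 and day
12) for the mark (H3K4me3) and a histone-occupancy control (H3), plus two
RNA-seq replicates at D2/D12.  Every gene carries a marking regime —

* ``pattern``: ``tss`` (mark concentrated around the transcription start
  site) or ``gene_body`` (a plateau spanning TSS..TES);
* ``level``: low / mid / high enrichment over background;
* ``onset``: ``larval`` (present from L3 on) or ``adult`` (near-absent at L3);
* ``trend``: up / down / stable across adult aging (applied at D12), with a
  matched RNA trend with probability ``coupling``.

Truth assignment builds in the study's association: gene-body, adult-onset
marking is preferentially age-dynamic.  Counts are negative-binomial per
25-bp bin around a smooth mean surface, so the downstream NB-GLM differential
stage is well-posed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tracks import CoverageTrack, write_bedgraph
from .genes import AnnotationSet, write_gff3

CHIP_TIMEPOINTS = ("L3", "D2", "D12")
RNA_TIMEPOINTS = ("D2", "D12")
ANTIBODIES = ("H3K4me3", "H3")

LEVEL_MULT = {"low": 2.0, "mid": 4.0, "high": 8.0}


class ConfigError(ValueError):
    pass


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent, call-order-free RNG substream keyed by a label string."""
    key = zlib.crc32(label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass
class SimConfig:
    """Parameters of the simulated experiment (defaults are the study design)."""

    n_chrom: int = 1
    chrom_length: int = 5_000_000
    n_genes: int = 500
    bin_size: int = 25
    frag_len: int = 200
    chip_depth: float = 2_000_000.0   # expected total reads per ChIP library
    rna_depth: float = 1_000_000.0    # expected total counts per RNA library
    n_chip_reps: int = 3
    n_rna_reps: int = 2
    timepoints: tuple = CHIP_TIMEPOINTS
    nb_dispersion: float = 0.1     # per-bin ChIP overdispersion
    rna_dispersion: float = 0.02   # per-gene RNA overdispersion: biological
    #                                CV ~0.14, conventional for isogenic worm populations
    coupling: float = 0.8
    seed: int = 7
    # truth proportions
    pattern_probs: dict = field(default_factory=lambda: {"tss": 0.6, "gene_body": 0.4})
    # marking level conditional on deposition onset: adult-acquired domains are
    # low-to-mid level; high-level marking is established by L3 and stable
    level_probs: dict = field(
        default_factory=lambda: {
            "larval": {"low": 0.25, "mid": 0.35, "high": 0.40},
            "adult": {"low": 0.60, "mid": 0.40, "high": 0.0},
        }
    )
    onset_probs: dict = field(
        default_factory=lambda: {
            "tss": {"larval": 0.9, "adult": 0.1},
            "gene_body": {"larval": 0.3, "adult": 0.7},
        }
    )
    dynamic_fraction: float = 0.30
    # relative propensity to be age-dynamic per (pattern, onset) stratum;
    # rescaled so the marginal dynamic fraction is exact
    dynamic_weights: dict = field(
        default_factory=lambda: {
            ("gene_body", "adult"): 3.0,
            ("gene_body", "larval"): 1.5,
            ("tss", "adult"): 1.5,
            ("tss", "larval"): 1.0,
        }
    )
    effect_size: float = 1.0       # |log2 FC| of dynamic mark changes (D12 vs D2)
    rna_effect_size: float = 1.0   # |log2 FC| of coupled RNA changes
    l3_attenuation: float = 0.1    # adult-onset enrichment at L3, as fraction of D2
    tss_kernel_sd: float = 300.0   # bp, width of the TSS-centred marking kernel
    min_gene_len: int = 500
    max_gene_len: int = 6000
    min_gap: int = 1000
    protein_coding_fraction: float = 0.95

    def validate(self) -> None:
        if self.chrom_length * self.n_chrom < self.n_genes * 4000:
            raise ConfigError("genome too small: need >= 4 kb per gene")
        for name in ("chip_depth", "rna_depth", "effect_size", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if not 0 <= self.coupling <= 1:
            raise ConfigError("coupling must be in [0, 1]")
        for probs in (self.pattern_probs, *self.level_probs.values(),
                      *self.onset_probs.values()):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"proportions do not sum to 1: {probs}")
        if not 0 <= self.dynamic_fraction <= 1:
            raise ConfigError("dynamic_fraction must be in [0, 1]")
        # marginal P(pattern, onset) and the exact rescaling of dynamic weights
        for (pat, onset), p in self._dynamic_probs().items():
            if p > 1:
                raise ConfigError(
                    f"dynamic propensity for ({pat}, {onset}) exceeds 1; "
                    "lower dynamic_fraction or flatten dynamic_weights"
                )

    def _stratum_probs(self) -> dict:
        return {
            (pat, onset): self.pattern_probs[pat] * self.onset_probs[pat][onset]
            for pat in self.pattern_probs
            for onset in self.onset_probs[pat]
        }

    def _dynamic_probs(self) -> dict:
        """P(trend != stable | pattern, onset), marginalising exactly to dynamic_fraction."""
        strata = self._stratum_probs()
        norm = sum(p * self.dynamic_weights[k] for k, p in strata.items())
        scale = self.dynamic_fraction / norm if norm > 0 else 0.0
        return {k: scale * self.dynamic_weights[k] for k in strata}

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def n_bins_per_chrom(self) -> int:
        return self.chrom_length // self.bin_size

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dynamic_weights"] = {f"{p}|{o}": v for (p, o), v in self.dynamic_weights.items()}
        return d


@dataclass
class TruthTable:
    """Per-gene simulated ground truth (the recovery target of the pipeline)."""

    table: pd.DataFrame  # index gene_id; pattern, level, onset, trend, effect,
    #                      rna_trend, rna_effect, rna_baseline

    def __len__(self) -> int:
        return len(self.table)

    @property
    def dynamic_genes(self) -> pd.Index:
        return self.table.index[self.table["trend"] != "stable"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class SimulatedExperiment:
    config: SimConfig
    annotation: AnnotationSet
    truth: TruthTable
    tracks: dict  # (antibody, timepoint, replicate) -> CoverageTrack
    rna_counts: pd.DataFrame  # genes x MultiIndex (timepoint, replicate)


def generate_annotation(config: SimConfig) -> AnnotationSet:
    """Lay out non-overlapping genes with >= min_gap intergenic spacing."""
    config.validate()
    rng = _substream(config.seed, "annotation")
    if config.n_genes == 0:
        return AnnotationSet(pd.DataFrame(columns=list(AnnotationSet.REQUIRED)))

    # distribute genes across chromosomes as evenly as possible
    per_chrom = np.full(config.n_chrom, config.n_genes // config.n_chrom)
    per_chrom[: config.n_genes % config.n_chrom] += 1

    rows = []
    gidx = 0
    for chrom, n in zip(config.chrom_names, per_chrom):
        n = int(n)
        if n == 0:
            continue
        lengths = rng.integers(config.min_gene_len, config.max_gene_len + 1, size=n)
        required = int(lengths.sum()) + (n + 1) * config.min_gap
        leftover = config.chrom_length - required
        if leftover < 0:
            raise ConfigError(
                f"{chrom}: genome too small for {n} genes (need {required} bp)"
            )
        extra = rng.multinomial(leftover, np.full(n + 1, 1.0 / (n + 1)))
        gaps = config.min_gap + extra
        strands = rng.choice(["+", "-"], size=n)
        coding = rng.random(n) < config.protein_coding_fraction
        pos = 0
        for i in range(n):
            pos += int(gaps[i])
            start, end = pos, pos + int(lengths[i])
            rows.append(
                {
                    "gene_id": f"g{gidx:05d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strands[i],
                    "biotype": "protein_coding" if coding[i] else "ncRNA",
                }
            )
            pos = end
            gidx += 1
    return AnnotationSet(pd.DataFrame(rows))


def assign_truth(annotation: AnnotationSet, config: SimConfig) -> TruthTable:
    """Sample marking regimes per gene from the configured proportions."""
    config.validate()
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    rng = _substream(config.seed, "truth")
    n = len(annotation)
    gene_ids = annotation.genes["gene_id"].to_numpy()

    pats = list(config.pattern_probs)
    pattern = rng.choice(pats, size=n, p=[config.pattern_probs[p] for p in pats])
    onset = np.empty(n, dtype=object)
    for pat in pats:
        m = pattern == pat
        opts = list(config.onset_probs[pat])
        onset[m] = rng.choice(opts, size=m.sum(), p=[config.onset_probs[pat][o] for o in opts])
    level = np.empty(n, dtype=object)
    for ons, probs in config.level_probs.items():
        m = onset == ons
        lvls = list(probs)
        level[m] = rng.choice(lvls, size=m.sum(), p=[probs[lv] for lv in lvls])

    dyn_probs = config._dynamic_probs()
    p_dyn = np.array([dyn_probs[(p, o)] for p, o in zip(pattern, onset)])
    is_dyn = rng.random(n) < p_dyn
    direction = rng.choice(["up", "down"], size=n)
    trend = np.where(is_dyn, direction, "stable")
    effect = np.where(
        trend == "up", config.effect_size, np.where(trend == "down", -config.effect_size, 0.0)
    )

    coupled = rng.random(n) < config.coupling
    rna_trend = np.where(is_dyn & coupled, trend, "stable")
    rna_effect = np.where(
        rna_trend == "up",
        config.rna_effect_size,
        np.where(rna_trend == "down", -config.rna_effect_size, 0.0),
    )
    rna_baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    rna_baseline *= config.rna_depth / rna_baseline.sum()

    table = pd.DataFrame(
        {
            "pattern": pattern,
            "level": level,
            "onset": onset,
            "trend": trend,
            "effect": effect,
            "rna_trend": rna_trend,
            "rna_effect": rna_effect,
            "rna_baseline": rna_baseline,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return TruthTable(table)


def expected_chip_intensity(
    truth: TruthTable,
    annotation: AnnotationSet,
    config: SimConfig,
    antibody: str,
    timepoint: str,
) -> dict[str, np.ndarray]:
    """Unnormalised per-bin mean surface (background = 1) before depth scaling.

    The H3 control is flat over chromatin; the mark adds, per gene, either a
    Gaussian kernel at the TSS or a plateau over the gene span, scaled by
    level, onset (L3 attenuation for adult-onset genes) and trend (applied at
    D12).  A fragment-length moving average stands in for read extension.
    """
    if antibody not in ANTIBODIES:
        raise ValueError(f"unknown antibody {antibody!r}")
    if timepoint not in CHIP_TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    bs = config.bin_size
    nb = config.n_bins_per_chrom
    intensity = {c: np.ones(nb) for c in config.chrom_names}
    if antibody == "H3":
        return intensity

    tt = truth.table
    for _, g in annotation.genes.iterrows():
        row = tt.loc[g.gene_id]
        amp = LEVEL_MULT[row.level]
        if timepoint == "L3" and row.onset == "adult":
            amp *= config.l3_attenuation
        if timepoint == "D12" and row.trend != "stable":
            amp *= 2.0 ** row.effect
        arr = intensity[g.chrom]
        if row.pattern == "tss":
            tss = g.start if g.strand == "+" else g.end - 1
            sd_bins = config.tss_kernel_sd / bs
            half = int(np.ceil(4 * sd_bins))
            c = tss // bs
            lo, hi = max(0, c - half), min(nb, c + half + 1)
            x = np.arange(lo, hi) - c
            arr[lo:hi] += amp * np.exp(-0.5 * (x / sd_bins) ** 2)
        else:
            lo, hi = g.start // bs, min(nb, -(-g.end // bs))
            arr[lo:hi] += amp

    # fragment-extension smoothing
    w = max(1, config.frag_len // bs)
    kernel = np.full(w, 1.0 / w)
    for c in intensity:
        intensity[c] = np.convolve(intensity[c], kernel, mode="same")
    return intensity


def expected_chip_mean(
    truth, annotation, config, antibody: str, timepoint: str
) -> dict[str, np.ndarray]:
    """Per-bin expected counts: intensity normalised to sum to chip_depth."""
    intensity = expected_chip_intensity(truth, annotation, config, antibody, timepoint)
    total = sum(a.sum() for a in intensity.values())
    return {c: a * (config.chip_depth / total) for c, a in intensity.items()}


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = 1.0 / (1.0 + dispersion * mean)
    return rng.negative_binomial(r, p)


def simulate_chip(
    truth: TruthTable,
    annotation: AnnotationSet,
    config: SimConfig,
    antibody: str,
    timepoint: str,
    replicate: int,
    _mean_cache: dict | None = None,
) -> CoverageTrack:
    """One ChIP library: NB counts per bin around the expected mean surface."""
    key = (antibody, timepoint)
    if _mean_cache is not None and key in _mean_cache:
        means = _mean_cache[key]
    else:
        means = expected_chip_mean(truth, annotation, config, antibody, timepoint)
        if _mean_cache is not None:
            _mean_cache[key] = means
    rng = _substream(config.seed, f"chip:{antibody}:{timepoint}:{replicate}")
    data = {c: _nb_sample(rng, m, config.nb_dispersion).astype(np.int64) for c, m in means.items()}
    return CoverageTrack(config.bin_size, data)


def expected_rna_mean(truth: TruthTable, config: SimConfig, timepoint: str) -> pd.Series:
    if timepoint not in RNA_TIMEPOINTS:
        raise ValueError(f"unknown RNA timepoint {timepoint!r}")
    tt = truth.table
    mean = tt["rna_baseline"].copy()
    if timepoint == "D12":
        mean = mean * 2.0 ** tt["rna_effect"]
    return mean


def simulate_rna(
    truth: TruthTable, config: SimConfig, timepoint: str, replicate: int
) -> pd.Series:
    """One RNA-seq library: NB gene counts around baseline x 2^effect."""
    mean = expected_rna_mean(truth, config, timepoint)
    rng = _substream(config.seed, f"rna:{timepoint}:{replicate}")
    counts = _nb_sample(rng, mean.to_numpy(), config.rna_dispersion)
    return pd.Series(counts, index=mean.index, name=f"{timepoint}_r{replicate}")


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Generate the full design: all ChIP libraries, RNA tables, and truth."""
    config.validate()
    annotation = generate_annotation(config)
    truth = assign_truth(annotation, config)
    cache: dict = {}
    tracks = {}
    for ab in ANTIBODIES:
        for tp in config.timepoints:
            for rep in range(1, config.n_chip_reps + 1):
                tracks[(ab, tp, rep)] = simulate_chip(
                    truth, annotation, config, ab, tp, rep, _mean_cache=cache
                )
    rna = {}
    for tp in RNA_TIMEPOINTS:
        for rep in range(1, config.n_rna_reps + 1):
            rna[(tp, rep)] = simulate_rna(truth, config, tp, rep)
    rna_counts = pd.DataFrame(rna)
    rna_counts.columns = pd.MultiIndex.from_tuples(rna_counts.columns, names=["timepoint", "replicate"])
    return SimulatedExperiment(config, annotation, truth, tracks, rna_counts)


def expected_coupling_rho(
    config: SimConfig | None = None, n_draws: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo oracle for the coupling-induced mark/RNA change correlation.

    Draws dynamic genes from the generator's own law — mark trend +-effect_size
    with equal sign probability, RNA effect matching with probability
    ``coupling`` (else 0) — and pushes both through the measurement process the
    pipeline applies: replicate NB counts at the configured depths and
    dispersion, peak counts diluted by within-peak background, and log2 ratio
    estimates from replicate sums.  Returns the Spearman correlation of the
    estimated changes, the value ``correlate_changes`` should recover on a
    simulated experiment with this configuration.
    """
    from scipy.stats import spearmanr

    cfg = config if config is not None else SimConfig()
    rng = np.random.default_rng(seed)

    def nb(mean: np.ndarray, disp: float) -> np.ndarray:
        return _nb_sample(rng, mean, disp)

    # --- truth draws -------------------------------------------------------
    sign = rng.choice([-1.0, 1.0], size=n_draws)
    k4_eff = sign * cfg.effect_size
    coupled = rng.random(n_draws) < cfg.coupling
    rna_eff = np.where(coupled, sign * cfg.rna_effect_size, 0.0)

    pats = list(cfg.pattern_probs)
    pattern = rng.choice(pats, size=n_draws, p=[cfg.pattern_probs[p] for p in pats])
    onset = np.empty(n_draws, dtype=object)
    for pat in pats:
        m = pattern == pat
        opts = list(cfg.onset_probs[pat])
        onset[m] = rng.choice(opts, size=m.sum(), p=[cfg.onset_probs[pat][o] for o in opts])
    amp = np.empty(n_draws)
    for ons, probs in cfg.level_probs.items():
        m = onset == ons
        lvls = list(probs)
        drawn = rng.choice(lvls, size=m.sum(), p=[probs[lv] for lv in lvls])
        amp[m] = [LEVEL_MULT[lv] for lv in drawn]

    # --- ChIP measurement: peak counts = background + enrichment -----------
    bg = cfg.chip_depth / (cfg.n_chrom * cfg.n_bins_per_chrom)  # per bin
    kern_bins = np.sqrt(2 * np.pi) * cfg.tss_kernel_sd / cfg.bin_size
    gene_bins = rng.uniform(cfg.min_gene_len, cfg.max_gene_len, n_draws) / cfg.bin_size
    span_bins = np.where(pattern == "tss", 2 * 4 * cfg.tss_kernel_sd / cfg.bin_size, gene_bins)
    enrich_bins = np.where(pattern == "tss", kern_bins, gene_bins)
    mu_d2 = bg * (span_bins + amp * enrich_bins)
    mu_d12 = bg * (span_bins + amp * (2.0 ** k4_eff) * enrich_bins)
    reps = cfg.n_chip_reps
    d2 = sum(nb(mu_d2, cfg.nb_dispersion) for _ in range(reps))
    d12 = sum(nb(mu_d12, cfg.nb_dispersion) for _ in range(reps))
    x = np.log2((d12 + 0.5) / (d2 + 0.5))

    # --- RNA measurement ---------------------------------------------------
    base = rng.lognormal(0.0, 1.0, n_draws)
    base *= (cfg.rna_depth / cfg.n_genes) / base.mean()
    r2 = sum(nb(base, cfg.rna_dispersion) for _ in range(cfg.n_rna_reps))
    r12 = sum(nb(base * 2.0 ** rna_eff, cfg.rna_dispersion) for _ in range(cfg.n_rna_reps))
    y = np.log2((r12 + 0.5) / (r2 + 0.5))
    return float(spearmanr(x, y).statistic)


def write_experiment(exp: SimulatedExperiment, outdir) -> None:
    """Write bedGraph per library, GFF3 annotation, truth and RNA TSVs."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for (ab, tp, rep), track in exp.tracks.items():
        write_bedgraph(track, os.path.join(outdir, f"{ab}_{tp}_rep{rep}.bedgraph"))
    write_gff3(exp.annotation, os.path.join(outdir, "genes.gff3"))
    exp.truth.to_tsv(os.path.join(outdir, "truth.tsv"))
    flat = exp.rna_counts.copy()
    flat.columns = [f"{tp}_r{rep}" for tp, rep in flat.columns]
    flat.to_csv(os.path.join(outdir, "rna_counts.tsv"), sep="\t", index_label="gene_id")
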