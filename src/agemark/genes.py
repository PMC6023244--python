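"""Gene models, annotation I/O, and peak-to-gene assignment.

Assignment follows the closest-feature convention used for promoter marks:
a peak overlapping one or more gene spans belongs to all of them; a wholly
intergenic peak is assigned to the nearest gene for which it lies upstream
(5') in that gene's reading orientation; candidates where the peak sits
entirely beyond a gene's transcription end site are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class AnnotationSet:
    """Non-overlapping gene models as a sorted DataFrame.

    Columns: gene_id, chrom, start, end (0-based half-open), strand, biotype.
    TSS/TES follow strand: for '-' genes the TSS is at ``end`` and the TES at
    ``start``.
    """

    genes: pd.DataFrame

    REQUIRED = ("gene_id", "chrom", "start", "end", "strand", "biotype")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.genes.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        self.genes = self.genes.sort_values(["chrom", "start"]).reset_index(drop=True)
        if (self.genes["end"] <= self.genes["start"]).any():
            raise ValueError("gene with non-positive length")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.genes["chrom"].unique())

    def by_chrom(self, chrom: str) -> pd.DataFrame:
        return self.genes[self.genes["chrom"] == chrom]

    def tss(self) -> pd.Series:
        g = self.genes
        return pd.Series(
            np.where(g["strand"] == "+", g["start"], g["end"] - 1),
            index=g["gene_id"],
            name="tss",
        )

    def spans(self) -> pd.DataFrame:
        return self.genes.set_index("gene_id")[["chrom", "start", "end", "strand"]]


def read_gff3(path) -> AnnotationSet:
    """Read gene features from GFF3 (1-based closed -> 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "gene_id": attrs.get("ID", attrs.get("gene_id", f"gene{len(rows)}")),
                    "chrom": f[0],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6],
                    "biotype": attrs.get("biotype", "protein_coding"),
                }
            )
    return AnnotationSet(pd.DataFrame(rows, columns=list(AnnotationSet.REQUIRED)))


def write_gff3(annotation: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in annotation.genes.iterrows():
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            fh.write(
                f"{g.chrom}\tagemark\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_bed12(path) -> AnnotationSet:
    """Read gene spans from BED12 (thick/block fields ignored)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            rows.append(
                {
                    "gene_id": f[3],
                    "chrom": f[0],
                    "start": int(f[1]),
                    "end": int(f[2]),
                    "strand": f[5] if len(f) > 5 else "+",
                    "biotype": "protein_coding",
                }
            )
    return AnnotationSet(pd.DataFrame(rows, columns=list(AnnotationSet.REQUIRED)))


@dataclass
class GeneAssignment:
    """peak id -> list of (gene_id, relation, distance)."""

    table: pd.DataFrame  # columns: peak_id, gene_id, relation, distance

    def genes_for(self, peak_id) -> list[str]:
        t = self.table
        return t.loc[t["peak_id"] == peak_id, "gene_id"].tolist()

    @property
    def assigned_peaks(self) -> set:
        return set(self.table["peak_id"])

    def gene_set(self, biotypes: set[str] | None = None, annotation: AnnotationSet | None = None):
        genes = set(self.table["gene_id"])
        if biotypes is not None:
            if annotation is None:
                raise ValueError("annotation required for biotype filtering")
            keep = set(
                annotation.genes.loc[
                    annotation.genes["biotype"].isin(biotypes), "gene_id"
                ]
            )
            genes &= keep
        return genes


def assign_peaks(peaks, annotation: AnnotationSet) -> GeneAssignment:
    """Assign each peak to gene(s): overlap first, else nearest upstream-of-gene.

    Relations: ``overlap`` (>= 1 bp with the gene span, distance 0) or
    ``upstream_intergenic`` (the peak lies 5' of the gene's TSS in its reading
    orientation; distance is the end-to-start gap in bp).  Candidates with the
    peak entirely 3' of the TES are dropped; equidistant genes on both sides
    are all retained.
    """
    rows = []
    for chrom in sorted({p.chrom for p in peaks}):
        genes = annotation.by_chrom(chrom)
        gstart = genes["start"].to_numpy()
        gend = genes["end"].to_numpy()
        gstrand = genes["strand"].to_numpy()
        gid = genes["gene_id"].to_numpy()
        if len(genes) and np.any(np.diff(gstart) < 0):
            raise ValueError("annotation not sorted")
        for peak in (p for p in peaks if p.chrom == chrom):
            pid = peak.id
            if len(genes) == 0:
                continue
            ov = (gstart < peak.end) & (gend > peak.start)
            if ov.any():
                for g in gid[ov]:
                    rows.append((pid, g, "overlap", 0))
                continue
            # intergenic: peak upstream of the gene in gene orientation,
            # i.e. before the TSS and not past the TES
            plus_ok = (gstrand == "+") & (gstart >= peak.end)
            minus_ok = (gstrand == "-") & (gend <= peak.start)
            dist = np.where(
                plus_ok, gstart - peak.end, np.where(minus_ok, peak.start - gend, -1)
            )
            cand = dist >= 0
            if not cand.any():
                continue
            dmin = dist[cand].min()
            for g, d in zip(gid[cand], dist[cand]):
                if d == dmin:
                    rows.append((pid, g, "upstream_intergenic", int(d)))
    table = pd.DataFrame(rows, columns=["peak_id", "gene_id", "relation", "distance"])
    return GeneAssignment(table)


def overlap_fraction(query, reference, min_overlap: int = 1) -> float:
    """Fraction of query peaks overlapping any reference interval by >= min_overlap bp."""
    qlist = list(query)
    if len(qlist) == 0:
        raise ValueError("empty query peak set")
    by_chrom: dict[str, list] = {}
    for r in reference:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    hits = 0
    for q in qlist:
        for s, e in by_chrom.get(q.chrom, ()):
            if min(q.end, e) - max(q.start, s) >= min_overlap:
                hits += 1
                break
    return hits / len(qlist)


def write_assignment_tsv(assignment: GeneAssignment, path) -> None:
    assignment.table.to_csv(path, sep="\t", index=False)
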