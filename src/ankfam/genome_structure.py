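"""Chromosomal placement, density clusters and exon/intron summaries.

Gene models are 1-based inclusive (the GFF3 convention) both on disk and in
memory; BED exports convert to 0-based half-open. A seq_id is treated as a
scaffold whenever it is not in the declared chromosome list of the assembly.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import config

__all__ = ["GeneModel", "DensityCluster", "StructureSummary", "read_gff3",
           "map_to_chromosomes", "density_clusters", "structure_summary",
           "to_bed_interval"]


@dataclass
class GeneModel:
    gene_id: str
    seq_id: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    is_scaffold: bool = False
    cds_start: int | None = None  # genomic coordinate of the first CDS base

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("a gene model needs at least one exon")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon {s}..{e} reversed")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
                for i in range(len(self.exons) - 1)]


@dataclass
class DensityCluster:
    seq_id: str
    start: int
    end: int
    gene_ids: list[str]

    @property
    def count(self) -> int:
        return len(self.gene_ids)


@dataclass
class StructureSummary:
    gene_id: str
    exon_count: int
    intron_count: int
    exon_lengths: list[int]
    intron_lengths: list[int]
    total_span: int


def read_gff3(path, gene_id_attr: str = "ID",
              chromosomes: Sequence[str] | None = None) -> list[GeneModel]:
    """Load gene models (gene + exon features) from a GFF3 file.

    Exons are collected from each gene's descendants; single-exon genes with
    no exon feature fall back to the gene span. ``chromosomes`` marks which
    seq_ids count as assembled chromosomes; everything else is a scaffold.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    models = []
    for gene in db.features_of_type("gene"):
        exons = sorted((f.start, f.end) for f in db.children(gene, featuretype="exon"))
        if not exons:
            exons = [(gene.start, gene.end)]
        gid = gene.attributes.get(gene_id_attr, [gene.id])[0]
        cds = sorted((f.start, f.end) for f in db.children(gene, featuretype="CDS"))
        cds_start = None
        if cds:
            cds_start = cds[0][0] if gene.strand == "+" else cds[-1][1]
        models.append(GeneModel(
            gene_id=gid, seq_id=gene.seqid, strand=gene.strand,
            start=gene.start, end=gene.end, exons=exons,
            is_scaffold=(chromosomes is not None and gene.seqid not in chromosomes),
            cds_start=cds_start))
    return models


def map_to_chromosomes(models: Iterable[GeneModel]) -> tuple[dict[str, int], int, int]:
    """Per-chromosome gene counts, scaffold tally and grand total."""
    counts: dict[str, int] = {}
    scaffold = 0
    total = 0
    for m in models:
        total += 1
        if m.is_scaffold:
            scaffold += 1
        else:
            counts[m.seq_id] = counts.get(m.seq_id, 0) + 1
    return counts, scaffold, total


def density_clusters(models: Iterable[GeneModel],
                     window_bp: int = config.CLUSTER_WINDOW_BP,
                     step_bp: int = config.CLUSTER_STEP_BP,
                     min_genes: int = config.CLUSTER_MIN_GENES) -> list[DensityCluster]:
    """Sliding-window gene clusters per seq_id.

    A window of ``window_bp`` slides in ``step_bp`` increments; windows
    holding >= ``min_genes`` gene midpoints are merged while they overlap and
    each maximal merged interval is reported with its member genes.
    """
    if not (window_bp >= step_bp > 0):
        raise ValueError("require window_bp >= step_bp > 0")
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")

    by_seq: dict[str, list[GeneModel]] = {}
    for m in models:
        by_seq.setdefault(m.seq_id, []).append(m)

    clusters = []
    for seq_id in sorted(by_seq):
        genes = sorted(by_seq[seq_id], key=lambda m: m.midpoint)
        mids = [m.midpoint for m in genes]
        qualifying: list[tuple[int, int]] = []
        pos = 1
        last_start = max(1, int(mids[-1]))
        while pos <= last_start:
            lo, hi = pos, pos + window_bp - 1
            n = bisect.bisect_right(mids, hi) - bisect.bisect_left(mids, lo)
            if n >= min_genes:
                if qualifying and lo <= qualifying[-1][1] + 1:
                    qualifying[-1] = (qualifying[-1][0], hi)
                else:
                    qualifying.append((lo, hi))
            pos += step_bp
        for lo, hi in qualifying:
            members = [g.gene_id for g in genes if lo <= g.midpoint <= hi]
            clusters.append(DensityCluster(seq_id=seq_id, start=lo, end=hi,
                                           gene_ids=members))
    return clusters


def structure_summary(model: GeneModel) -> StructureSummary:
    """Exon/intron counts and lengths, numbered from the transcription start.

    On the minus strand exon 1 is the rightmost exon, so the reported length
    lists run 5' to 3' of the transcript.
    """
    exon_lengths = [e - s + 1 for s, e in model.exons]
    intron_lengths = [e - s + 1 for s, e in model.introns]
    if model.strand == "-":
        exon_lengths = exon_lengths[::-1]
        intron_lengths = intron_lengths[::-1]
    return StructureSummary(
        gene_id=model.gene_id,
        exon_count=len(exon_lengths),
        intron_count=len(intron_lengths),
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
        total_span=model.end - model.start + 1,
    )


def to_bed_interval(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to BED 0-based half-open."""
    return start_1based - 1, end_inclusive
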