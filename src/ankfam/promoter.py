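"""Promoter extraction and degenerate cis-element scanning.

Promoters are the fixed-width windows immediately 5' of the start codon in
the gene's coding orientation (reverse-complemented for minus-strand genes).
Elements are exact-match IUPAC patterns scanned on both strands; positions
are 1-based offsets of the match window within the promoter.

An ``N`` in the subject sequence is matched only by the pattern character
``N`` (unknown bases never satisfy an informative pattern position).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

from . import config
from .genome_structure import GeneModel

__all__ = ["CisElementDef", "PromoterHit", "PromoterWindow", "IUPAC_SETS",
           "reverse_complement", "load_catalog", "extract_promoter",
           "scan_elements", "element_census"]

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CisElementDef:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"element {self.name!r}: empty pattern")
        bad = set(self.pattern.upper()) - set(IUPAC_SETS)
        if bad:
            raise ValueError(
                f"element {self.name!r}: invalid IUPAC characters {sorted(bad)}")


@dataclass(frozen=True)
class PromoterHit:
    gene_id: str
    element: str
    position: int  # 1-based leftmost offset of the match window in the promoter
    strand: str


@dataclass
class PromoterWindow:
    gene_id: str
    sequence: str
    truncated: bool


def load_catalog(path=None) -> list[CisElementDef]:
    """Element catalog as (name, IUPAC pattern) records.

    With no path, the packaged catalog of elements highlighted by promoter
    surveys of this family is returned; supply your own TSV (columns
    name, pattern) for a fuller database.
    """
    import pandas as pd

    if path is None:
        ref = resources.files("ankfam.data") / "place_elements.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [CisElementDef(row["name"], row["pattern"]) for _, row in df.iterrows()]


def extract_promoter(genome: Mapping[str, str], model: GeneModel,
                     window: int = config.PROMOTER_WINDOW) -> PromoterWindow:
    """Window of bases immediately upstream of the start codon.

    Uses the model's declared CDS start when present, else the gene span
    boundary. Truncates (with a flag) at contig edges; a gene flush with the
    contig start yields an empty, flagged window.
    """
    contig = genome[model.seq_id]
    if model.strand == "+":
        cds_start = model.cds_start if model.cds_start is not None else model.start
        lo = max(0, cds_start - 1 - window)
        seq = contig[lo: cds_start - 1]
        truncated = len(seq) < window
    else:
        cds_start = model.cds_start if model.cds_start is not None else model.end
        seq = reverse_complement(contig[cds_start: cds_start + window])
        truncated = len(seq) < window
    return PromoterWindow(gene_id=model.gene_id, sequence=seq.upper(),
                          truncated=truncated)


def _matches_at(seq: str, pattern: str, pos0: int) -> bool:
    for j, pc in enumerate(pattern):
        if seq[pos0 + j] not in IUPAC_SETS[pc]:
            return False
    return True


def scan_elements(promoter: str | PromoterWindow,
                  element_defs: Iterable[CisElementDef],
                  gene_id: str | None = None,
                  dedupe_palindromes: bool = False) -> list[PromoterHit]:
    """All element occurrences on both strands of a promoter.

    A minus-strand hit at position p means the reverse complement of the
    pattern matches the forward sequence with its leftmost base at p, i.e.
    the element itself reads 5'->3' on the opposite strand. Overlapping
    matches are all reported; ``dedupe_palindromes`` drops the minus-strand
    copy of a hit whose pattern is its own reverse complement.
    """
    if isinstance(promoter, PromoterWindow):
        seq = promoter.sequence
        gid = promoter.gene_id
    else:
        seq = promoter.upper()
        gid = gene_id or "promoter"

    hits: list[PromoterHit] = []
    for element in element_defs:
        pattern = element.pattern.upper()
        rc = reverse_complement(pattern)
        k = len(pattern)
        palindrome = rc == pattern
        for i in range(len(seq) - k + 1):
            if _matches_at(seq, pattern, i):
                hits.append(PromoterHit(gid, element.name, i + 1, "+"))
            if _matches_at(seq, rc, i) and not (palindrome and dedupe_palindromes):
                hits.append(PromoterHit(gid, element.name, i + 1, "-"))
    hits.sort(key=lambda h: (h.element, h.position, h.strand))
    return hits


def element_census(hits_by_gene: Mapping[str, Sequence[PromoterHit]]):
    """Elements present in every gene, plus per-element gene counts.

    Returns ``(common, gene_counts)``: ``common`` is the sorted list of
    element names with at least one hit in *every* gene's promoter (the
    strict reading of "common"); ``gene_counts`` maps each element to the
    number of genes carrying it, in descending count order, which supports
    the looser "recurrent" reading.
    """
    genes = list(hits_by_gene)
    counts: dict[str, int] = {}
    for gene in genes:
        for name in {h.element for h in hits_by_gene[gene]}:
            counts[name] = counts.get(name, 0) + 1
    common = sorted(name for name, c in counts.items() if c == len(genes)) if genes else []
    gene_counts = dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return common, gene_counts
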