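"""Duplicated-pair detection, NG86 Ka/Ks estimation, selection and dating.

Ka/Ks follows the Nei-Gojobori (1986) counting method: fractional
synonymous/non-synonymous site counts per codon, pathway-averaged difference
counts between codons, and a Jukes-Cantor multiple-hit correction
d = -(3/4) ln(1 - 4p/3) applied to the proportions. Site and difference
counting is done in exact rational arithmetic so the S + N = 3L identity
holds to the bit.

Duplication dating uses T = Ks / (2 lambda) with a configurable clock rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from importlib import resources
from itertools import combinations, permutations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from . import config
from .genome_structure import GeneModel

__all__ = [
    "ParalogPair", "KaKsResult", "PairTableSummary",
    "detect_paralogs", "classify_duplication",
    "count_sites_ng86", "codon_sites", "codon_differences",
    "kaks_ng86", "jukes_cantor", "classify_selection",
    "estimate_divergence_time", "pair_table_summary",
    "load_printed_pairs", "omega_consistent_with_rounding",
    "SENSE_CODONS", "STOP_CODONS", "translate_codon",
]

_BASES = "ACGT"
_CODE = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(_CODE))


def translate_codon(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop codon."""
    return _CODE.get(codon)


@dataclass
class ParalogPair:
    gene_a: str
    gene_b: str
    coverage: float
    identity: float
    duplication_class: str | None = None
    scope: str | None = None
    chrom_a: str | None = None
    chrom_b: str | None = None

    def __post_init__(self) -> None:
        for v in (self.coverage, self.identity):
            if not 0.0 <= v <= 100.0:
                raise ValueError("coverage/identity must be percentages in [0, 100]")


@dataclass
class KaKsResult:
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ka: float
    ks: float | None
    omega: float | None
    selection: str | None
    t_mya: float | None
    clock_lambda: float
    n_codons: int


@dataclass
class PairTableSummary:
    n_pairs: int
    omega_min: float
    omega_max: float
    omega_mean: float
    t_min: float
    t_max: float
    t_mean: float
    selection_counts: dict[str, int]


# ---------------------------------------------------------------------------
# NG86 site and difference counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[Fraction, Fraction]:
    """Fractional (synonymous, non-synonymous) sites of one sense codon.

    Each of the nine single-nucleotide neighbours contributes 1/3 site to the
    synonymous class when it preserves the amino acid, otherwise to the
    non-synonymous class; changes that create a stop codon count as
    non-synonymous.
    """
    aa = _CODE.get(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    syn = Fraction(0)
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _CODE.get(alt) == aa:
                syn += Fraction(1, 3)
    return syn, Fraction(3) - syn


def _validate_cds(seq: str, allow_ambiguous: bool = True) -> list[str | None]:
    """Split a CDS into codons; ambiguous codons become None (with a warning)."""
    if len(seq) % 3 != 0:
        raise ValueError("sequence length must be divisible by 3")
    codons: list[str | None] = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3].upper()
        if any(b not in _BASES for b in codon):
            if not allow_ambiguous:
                raise ValueError(f"ambiguous codon {codon!r}")
            warnings.warn(f"ambiguous codon {codon!r} at position {i + 1} skipped")
            codons.append(None)
            continue
        if codon in STOP_CODONS and i + 3 < len(seq):
            raise ValueError(f"internal stop codon {codon!r} at position {i + 1}")
        codons.append(codon)
    return codons


def count_sites_ng86(codon_sequence: str) -> tuple[Fraction, Fraction]:
    """Total (S_sites, N_sites) of a coding sequence, exact rationals.

    The terminal codon may be a stop and is then excluded from the counts.
    """
    codons = _validate_cds(codon_sequence)
    s = n = Fraction(0)
    for codon in codons:
        if codon is None or codon in STOP_CODONS:
            continue
        cs, cn = codon_sites(codon)
        s += cs
        n += cn
    return s, n


@lru_cache(maxsize=None)
def codon_differences(codon_a: str, codon_b: str) -> tuple[Fraction, Fraction]:
    """Pathway-averaged (synonymous, non-synonymous) differences between codons.

    All minimal substitution pathways (orderings of the differing positions)
    are weighted equally; pathways passing through a stop codon are excluded.
    In the degenerate case where every pathway is blocked by stops, all
    pathways are used with steps into/out of stops counted as non-synonymous.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return Fraction(0), Fraction(0)

    def walk(order: tuple[int, ...]) -> tuple[int, int, bool]:
        syn = non = 0
        current = codon_a
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS or current in STOP_CODONS:
                blocked = True
                non += 1
            elif _CODE[current] == _CODE[nxt]:
                syn += 1
            else:
                non += 1
            current = nxt
        return syn, non, blocked

    walks = [walk(order) for order in permutations(diff_positions)]
    open_walks = [w for w in walks if not w[2]]
    use = open_walks if open_walks else walks
    k = len(use)
    sd = Fraction(sum(w[0] for w in use), k)
    nd = Fraction(sum(w[1] for w in use), k)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Multiple-hit corrected distance d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        raise ValueError("divergence saturates JC correction (p >= 3/4)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks_ng86(seq_a: str, seq_b: str,
              clock_lambda: float = config.CLOCK_LAMBDA) -> KaKsResult:
    """NG86 Ka/Ks for a pairwise codon alignment.

    The two sequences must have equal, codon-sized lengths; codons containing
    a gap in either sequence are dropped pairwise, as are ambiguous codons.
    omega is left undefined (None) when Ks is 0 or undefined.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal lengths")
    kept_a: list[str] = []
    kept_b: list[str] = []
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3].upper(), seq_b[i:i + 3].upper()
        if "-" in ca or "-" in cb:
            continue
        kept_a.append(ca)
        kept_b.append(cb)
    a = "".join(kept_a)
    b = "".join(kept_b)
    codons_a = _validate_cds(a)
    codons_b = _validate_cds(b)

    s_sites = n_sites = Fraction(0)
    sd = nd = Fraction(0)
    n_codons = 0
    for ca, cb in zip(codons_a, codons_b):
        if ca is None or cb is None or ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        n_codons += 1
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        s_sites += (sa + sb) / 2
        n_sites += (na + nb) / 2
        dsd, dnd = codon_differences(ca, cb)
        sd += dsd
        nd += dnd

    if n_codons == 0:
        raise ValueError("no comparable codons after gap/ambiguity removal")

    ks: float | None
    if s_sites == 0:
        ks = None
    else:
        ks = jukes_cantor(float(sd / s_sites))
    ka = jukes_cantor(float(nd / n_sites)) if n_sites > 0 else 0.0

    omega = None
    selection = None
    if ks is not None and ks > 0:
        omega = ka / ks
        selection = classify_selection(omega)
    t_mya = None
    if ks is not None:
        _, t_mya = estimate_divergence_time(ks, clock_lambda)
    return KaKsResult(
        s_sites=float(s_sites), n_sites=float(n_sites),
        sd=float(sd), nd=float(nd), ka=ka, ks=ks,
        omega=omega, selection=selection, t_mya=t_mya,
        clock_lambda=clock_lambda, n_codons=n_codons)


# ---------------------------------------------------------------------------
# Duplication detection and classification
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(config.ALIGN_MATRIX)
    aligner.open_gap_score = config.ALIGN_GAP_OPEN
    aligner.extend_gap_score = config.ALIGN_GAP_EXTEND
    return aligner


def align_pair_stats(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(coverage %, identity %) of the best global alignment of two proteins.

    Coverage is the fraction of alignment columns where both sequences have a
    residue; identity is the fraction of those aligned columns that match.
    """
    aligner = _make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    length = alignment.shape[1]
    aligned_cols = 0
    identical = 0
    for (s1, e1), (s2, e2) in zip(*alignment.aligned):
        aligned_cols += e1 - s1
        for x, y in zip(seq_a[s1:e1], seq_b[s2:e2]):
            if x == y:
                identical += 1
    coverage = 100.0 * aligned_cols / length if length else 0.0
    identity = 100.0 * identical / aligned_cols if aligned_cols else 0.0
    return coverage, identity


def detect_paralogs(sequences: Mapping[str, str],
                    min_coverage: float = config.MIN_COVERAGE_PCT,
                    min_identity: float = config.MIN_IDENTITY_PCT,
                    min_events: int = config.MIN_DUPLICATION_EVENTS) -> list[ParalogPair]:
    """Duplicated gene pairs by alignment coverage/identity thresholds.

    Pairs must exceed both percentage thresholds; pairs are then kept only if
    they lie in a connected component of the qualifying-pair graph containing
    at least ``min_events`` edges (the "minimum number of duplication
    events" rule).
    """
    ids = sorted(sequences)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    graph = nx.Graph()
    stats: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in combinations(ids, 2):
        coverage, identity = align_pair_stats(sequences[a], sequences[b])
        if coverage > min_coverage and identity > min_identity:
            graph.add_edge(a, b)
            stats[(a, b)] = (coverage, identity)

    pairs = []
    for component in nx.connected_components(graph):
        sub = graph.subgraph(component)
        if sub.number_of_edges() < min_events:
            continue
        for a, b in sorted(tuple(sorted(e)) for e in sub.edges):
            coverage, identity = stats[(a, b)]
            pairs.append(ParalogPair(gene_a=a, gene_b=b,
                                     coverage=coverage, identity=identity))
    return pairs


def classify_duplication(pair: ParalogPair, gene_models: Mapping[str, GeneModel],
                         max_intervening_genes: int = config.MAX_INTERVENING_GENES) -> str:
    """Label a pair tandem or segmental from genomic positions.

    Tandem means same seq_id with at most ``max_intervening_genes`` family
    members between the two genes in genomic order; anything else (including
    different chromosomes) is segmental.
    """
    try:
        ma = gene_models[pair.gene_a]
        mb = gene_models[pair.gene_b]
    except KeyError as exc:
        raise KeyError(f"missing gene model for {exc.args[0]!r}") from exc
    pair.chrom_a, pair.chrom_b = ma.seq_id, mb.seq_id
    if ma.seq_id != mb.seq_id:
        pair.duplication_class = "segmental"
        return "segmental"
    lo, hi = sorted([ma.midpoint, mb.midpoint])
    intervening = sum(
        1 for m in gene_models.values()
        if m.seq_id == ma.seq_id and lo < m.midpoint < hi
        and m.gene_id not in (pair.gene_a, pair.gene_b)
    )
    pair.duplication_class = "tandem" if intervening <= max_intervening_genes else "segmental"
    return pair.duplication_class


# ---------------------------------------------------------------------------
# Selection, dating, summaries
# ---------------------------------------------------------------------------

def classify_selection(omega: float, neutral_band: float = 0.0) -> str:
    """omega < 1 - band: purifying; > 1 + band: positive; else neutral."""
    if omega is None:
        raise ValueError("omega is undefined")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if omega < 1.0 - neutral_band:
        return "purifying"
    if omega > 1.0 + neutral_band:
        return "positive"
    return "neutral"


def estimate_divergence_time(ks: float,
                             clock_lambda: float = config.CLOCK_LAMBDA) -> tuple[float, float]:
    """Duplication age T = Ks / (2 lambda), returned as (years, MYA)."""
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    if clock_lambda <= 0:
        raise ValueError("clock rate must be positive")
    t = ks / (2.0 * clock_lambda)
    return t, t / 1e6


def pair_table_summary(records: Sequence) -> PairTableSummary:
    """Min/max/mean of omega and duplication time plus selection counts.

    ``records`` may be objects with ``omega``/``t_mya`` attributes (e.g.
    :class:`KaKsResult`) or mappings with those keys.
    """
    def get(r, key):
        return r[key] if isinstance(r, Mapping) else getattr(r, key)

    records = list(records)
    if not records:
        raise ValueError("need at least one result")
    omegas = [float(get(r, "omega")) for r in records]
    times = [float(get(r, "t_mya")) for r in records]
    counts: dict[str, int] = {"purifying": 0, "neutral": 0, "positive": 0}
    for w in omegas:
        counts[classify_selection(w)] += 1
    return PairTableSummary(
        n_pairs=len(records),
        omega_min=min(omegas), omega_max=max(omegas),
        omega_mean=sum(omegas) / len(omegas),
        t_min=min(times), t_max=max(times),
        t_mean=sum(times) / len(times),
        selection_counts=counts)


def load_printed_pairs() -> pd.DataFrame:
    """The packaged 23-row syntenic paralog table (printed Ka/Ks fixture)."""
    ref = resources.files("ankfam.data") / "table2_paralogs.tsv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def omega_consistent_with_rounding(ka: float, ks: float, omega: float,
                                   decimals: int = 2) -> bool:
    """Could the printed omega be Ka/Ks given that all three were rounded?

    Checks whether the interval of ratios compatible with the rounded Ka and
    Ks intersects the interval of values that round to the printed omega.
    """
    h = 0.5 * 10 ** (-decimals)
    ka_lo, ka_hi = max(ka - h, 0.0), ka + h
    ks_lo, ks_hi = max(ks - h, 0.0), ks + h
    ratio_lo = ka_lo / ks_hi if ks_hi > 0 else 0.0
    ratio_hi = math.inf if ks_lo <= 0 else ka_hi / ks_lo
    return (omega - h) <= ratio_hi and (omega + h) >= ratio_lo
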