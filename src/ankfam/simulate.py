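"""Seeded synthetic inputs with known truth for every pipeline stage.

These generators stand in for the pepper genome assemblies and the archived
sequencing reads of the original survey: proteomes with planted ~33-residue
tandem repeats plus shuffled decoys, paralogous coding-sequence pairs
diverged under a chosen omega and Ks, negative-binomial count tables with
known expected RPKM, and promoter windows with planted degenerate elements.

Every generator is a pure function of its spec (seed included): the same
spec yields byte-identical output, and each emits a truth table that the
corresponding stage's recovery tests consume verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import config
from .evolution import SENSE_CODONS, STOP_CODONS, translate_codon
from .family_scan import DomainHit, RepeatProfile, default_profile
from .genome_structure import GeneModel

__all__ = ["FamilySimSpec", "CodonSimSpec", "SimulatedFamily",
           "simulate_family", "simulate_paralog_pair", "simulate_counts",
           "simulate_promoters", "simulate_gene_models", "write_fasta"]

_BASES = "ACGT"


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    """Single-line-per-sequence FASTA writer (deterministic byte layout)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Family proteome
# ---------------------------------------------------------------------------

@dataclass
class FamilySimSpec:
    n_members: int = 100
    n_decoys: int = 100
    repeat_count_distribution: dict[int, float] = field(
        # repeat counts 1..19 occur in real families; 2-5 dominate
        default_factory=lambda: {1: 0.10, 2: 0.22, 3: 0.22, 4: 0.16, 5: 0.12,
                                 6: 0.06, 7: 0.04, 8: 0.03, 10: 0.02, 12: 0.01,
                                 14: 0.01, 19: 0.01})
    flank_length: int = 60
    noise: float = 0.1          # per-position substitution rate off the consensus
    extra_domain_assignments: Mapping[int, Sequence[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 0 or self.n_decoys < 0:
            raise ValueError("counts must be >= 0")
        total = sum(self.repeat_count_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("repeat-count probabilities must sum to 1")
        if any(k < 1 for k in self.repeat_count_distribution):
            raise ValueError("repeat counts must be >= 1")


@dataclass
class SimulatedFamily:
    proteins: list[tuple[str, str]]                 # (id, sequence), members then decoys
    domain_hits: dict[str, list[DomainHit]]         # emitted annotations (truth-based)
    truth_repeats: pd.DataFrame                     # protein_id, repeat_index, start, end
    truth_subfamily_domains: dict[str, list[str]]   # member id -> non-repeat domain labels
    truth_repeat_counts: dict[str, int]

    @property
    def member_ids(self) -> list[str]:
        return [pid for pid, _ in self.proteins if pid.startswith("MEM")]

    @property
    def decoy_ids(self) -> list[str]:
        return [pid for pid, _ in self.proteins if pid.startswith("DEC")]


def simulate_family(spec: FamilySimSpec,
                    profile: RepeatProfile | None = None) -> SimulatedFamily:
    """Proteome with planted tandem repeats, decoys, and a truth table.

    Members are noisy copies of the profile consensus concatenated in tandem
    between random flanks; decoys are shuffled member sequences (identical
    composition, no tandem structure). Extra non-repeat domains are recorded
    as annotations only, anchored in the N-terminal flank.
    """
    if profile is None:
        profile = default_profile()
    if profile.width < 1:
        raise ValueError("impossible spec: zero-width profile")
    rng = np.random.default_rng(spec.seed)
    aa = list(config.AMINO_ACIDS)
    counts = sorted(spec.repeat_count_distribution)
    probs = [spec.repeat_count_distribution[k] for k in counts]

    proteins: list[tuple[str, str]] = []
    hits: dict[str, list[DomainHit]] = {}
    truth_rows = []
    truth_counts: dict[str, int] = {}
    truth_domains: dict[str, list[str]] = {}

    for i in range(spec.n_members):
        pid = f"MEM{i + 1:04d}"
        k = int(rng.choice(counts, p=probs))
        flank5 = "".join(rng.choice(aa, size=spec.flank_length))
        flank3 = "".join(rng.choice(aa, size=spec.flank_length))
        repeats = []
        for _ in range(k):
            copy = list(profile.consensus)
            for pos in range(profile.width):
                if rng.random() < spec.noise:
                    copy[pos] = aa[int(rng.integers(20))]
            repeats.append("".join(copy))
        seq = flank5 + "".join(repeats) + flank3
        proteins.append((pid, seq))
        truth_counts[pid] = k
        hits[pid] = []
        for r in range(k):
            start = spec.flank_length + r * profile.width + 1
            end = start + profile.width - 1
            truth_rows.append((pid, r + 1, start, end))
            hits[pid].append(DomainHit(pid, "ANK", start, end))
        extra = list(spec.extra_domain_assignments.get(i, []))
        truth_domains[pid] = extra
        for label in extra:
            hits[pid].append(DomainHit(pid, label, 1,
                                       min(10, spec.flank_length or 1)))

    member_seqs = [s for _, s in proteins]
    for j in range(spec.n_decoys):
        pid = f"DEC{j + 1:04d}"
        if member_seqs:
            base = list(member_seqs[j % len(member_seqs)])
            rng.shuffle(base)
            seq = "".join(base)
        else:
            seq = "".join(rng.choice(aa, size=2 * spec.flank_length + profile.width))
        proteins.append((pid, seq))
        hits[pid] = []

    truth = pd.DataFrame(truth_rows,
                         columns=["protein_id", "repeat_index", "start", "end"])
    return SimulatedFamily(proteins=proteins, domain_hits=hits,
                           truth_repeats=truth,
                           truth_subfamily_domains=truth_domains,
                           truth_repeat_counts=truth_counts)


# ---------------------------------------------------------------------------
# Diverged coding-sequence pairs
# ---------------------------------------------------------------------------

@dataclass
class CodonSimSpec:
    n_codons: int = 300
    true_omega: float = 0.5
    true_ks: float = 0.3  # expected synonymous substitutions per synonymous site
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 10:
            raise ValueError("need at least 10 codons")
        if self.true_omega < 0 or self.true_ks < 0:
            raise ValueError("omega and Ks must be >= 0")


def simulate_paralog_pair(spec: CodonSimSpec) -> tuple[str, str, dict]:
    """A codon-aligned sequence pair diverged by proposal/acceptance.

    Candidate single-nucleotide mutations are proposed uniformly over sites
    at an intensity of ``true_ks`` proposals per site, which makes the
    expected accepted synonymous divergence per synonymous site equal
    ``true_ks``. Synonymous proposals are always accepted, non-synonymous
    ones with probability ``true_omega`` (capped at 1), and proposals that
    would create a stop codon are discarded, so the pair stays readable.
    """
    rng = np.random.default_rng(spec.seed)
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS),
                                                    size=spec.n_codons)]
    ancestor = "".join(codons)
    derived = list(ancestor)
    n_sites = 3 * spec.n_codons
    n_events = int(rng.poisson(spec.true_ks * n_sites))
    accept_nonsyn = min(1.0, spec.true_omega)
    for _ in range(n_events):
        pos = int(rng.integers(n_sites))
        current = derived[pos]
        alt = _BASES[int(rng.integers(4))]
        if alt == current:
            alt = _BASES[(_BASES.index(current) + 1 + int(rng.integers(3))) % 4]
        codon_start = 3 * (pos // 3)
        old_codon = "".join(derived[codon_start:codon_start + 3])
        new_codon = old_codon[:pos % 3] + alt + old_codon[pos % 3 + 1:]
        if new_codon in STOP_CODONS:
            continue
        if translate_codon(old_codon) != translate_codon(new_codon):
            if rng.random() >= accept_nonsyn:
                continue
        derived[pos] = alt
    truth = {"omega": spec.true_omega, "ks": spec.true_ks,
             "n_codons": spec.n_codons, "seed": spec.seed}
    return ancestor, "".join(derived), truth


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def simulate_counts(n_genes: int, samples: Sequence[str],
                    mean_rpkm: float | Sequence[float] = 20.0,
                    dispersion: float = 0.2, seed: int = 0,
                    length_range: tuple[int, int] = (500, 3000),
                    library_size_range: tuple[int, int] = (2_000_000, 20_000_000)):
    """Gamma-Poisson count table whose expected RPKM is known.

    Returns (counts, gene_lengths, library_sizes, truth_rpkm). Counts are
    drawn from a negative-binomial-type law: Poisson with a Gamma-mixed mean
    whose expectation is truth_rpkm * length * library_size / 1e9.
    """
    if n_genes <= 0 or not samples:
        raise ValueError("need positive gene and sample counts")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    lengths = pd.Series(rng.integers(length_range[0], length_range[1] + 1,
                                     size=n_genes), index=genes, name="length_bp")
    libs = pd.Series(rng.integers(library_size_range[0], library_size_range[1] + 1,
                                  size=len(samples)), index=list(samples),
                     name="library_size")
    truth = np.broadcast_to(np.atleast_1d(np.asarray(mean_rpkm, dtype=float)),
                            (n_genes,)) if np.ndim(mean_rpkm) <= 1 else None
    if truth is None or truth.shape != (n_genes,):
        raise ValueError("mean_rpkm must be a scalar or a length-n_genes vector")
    truth_rpkm = pd.DataFrame(np.tile(truth[:, None], (1, len(samples))),
                              index=genes, columns=list(samples))
    mu = truth_rpkm.values * lengths.values[:, None] * libs.values[None, :] / 1e9
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = pd.DataFrame(rng.poisson(lam), index=genes, columns=list(samples))
    return counts, lengths, libs, truth_rpkm


# ---------------------------------------------------------------------------
# Promoters with planted elements
# ---------------------------------------------------------------------------

def simulate_promoters(n_genes: int, plants: Sequence[tuple[str, str, int, str]],
                       window: int = config.PROMOTER_WINDOW,
                       background_gc: float = 0.4, seed: int = 0):
    """Promoter windows with degenerate elements spliced at known positions.

    ``plants`` lists (element_name, IUPAC pattern, 1-based position, strand);
    each is instantiated to a concrete sequence (degenerate letters resolved
    at random) and planted in every gene. Returns (promoters, truth) where
    promoters maps gene id -> sequence and truth is a DataFrame of rows
    (gene_id, element, position, strand).
    """
    from .promoter import IUPAC_SETS, reverse_complement

    intervals = []
    for name, pattern, pos, strand in plants:
        if strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not (1 <= pos and pos + len(pattern) - 1 <= window):
            raise ValueError(f"plant {name!r} does not fit in the window")
        intervals.append((pos, pos + len(pattern) - 1, name))
    for (s1, e1, n1), (s2, e2, n2) in (
            (a, b) for i, a in enumerate(intervals) for b in intervals[i + 1:]):
        if s1 <= e2 and s2 <= e1:
            raise ValueError(f"overlapping plants {n1!r} and {n2!r}")

    rng = np.random.default_rng(seed)
    gc = background_gc / 2.0
    at = (1.0 - background_gc) / 2.0
    bases = np.array(list("ACGT"))
    probs = np.array([at, gc, gc, at])

    promoters: dict[str, str] = {}
    truth_rows = []
    for i in range(n_genes):
        gid = f"PROM{i + 1:04d}"
        seq = list(rng.choice(bases, size=window, p=probs))
        for name, pattern, pos, strand in plants:
            concrete = "".join(
                c if c in "ACGT" else
                str(rng.choice(list(IUPAC_SETS[c].replace("N", "") or "ACGT")))
                for c in pattern.upper())
            if strand == "-":
                concrete = reverse_complement(concrete)
            seq[pos - 1: pos - 1 + len(concrete)] = list(concrete)
            truth_rows.append((gid, name, pos, strand))
        promoters[gid] = "".join(seq)
    truth = pd.DataFrame(truth_rows,
                         columns=["gene_id", "element", "position", "strand"])
    return promoters, truth


# ---------------------------------------------------------------------------
# Random gene models (for structure/plumbing tests)
# ---------------------------------------------------------------------------

def simulate_gene_models(n: int, seed: int = 0,
                         seq_ids: Sequence[str] = ("chr1", "chr2", "chr3"),
                         scaffold_fraction: float = 0.1,
                         max_exons: int = 10) -> list[GeneModel]:
    """Random valid gene models spread over chromosomes and scaffolds."""
    rng = np.random.default_rng(seed)
    models = []
    for i in range(n):
        scaffold = rng.random() < scaffold_fraction
        seq_id = (f"scaffold_{int(rng.integers(1, 50))}" if scaffold
                  else str(rng.choice(list(seq_ids))))
        start = int(rng.integers(1, 5_000_000))
        n_exons = int(rng.integers(1, max_exons + 1))
        exons = []
        pos = start
        for j in range(n_exons):
            length = int(rng.integers(50, 1000))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(60, 2000))  # intron gap
        end = exons[-1][1]
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel(gene_id=f"SIM{i + 1:04d}", seq_id=seq_id,
                                strand=strand, start=start, end=end,
                                exons=exons, is_scaffold=scaffold))
    return models
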