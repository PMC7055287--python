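"""Identification of tandem-repeat family members in a proteome.

The detector is a position-specific scoring matrix (PSSM) built from a
gapless seed alignment of repeat instances (default width 33, the canonical
ankyrin repeat length). Every window of a protein is scored as the sum of
per-position log-odds; non-overlapping windows above a bit-score threshold
are selected greedily in descending score order, which matches the tandem
arrangement of the repeats. Hit significance is an empirical expectation
estimated from window scores of shuffled copies of the same protein.

Coordinates are 1-based inclusive throughout protein space.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import config

__all__ = [
    "ProteinRecord",
    "RepeatProfile",
    "DomainHit",
    "build_profile",
    "load_seed_alignment",
    "default_profile",
    "scan_protein",
    "filter_candidates",
    "compute_physchem",
    "net_charge",
    "repeat_count_histogram",
]

_AA_INDEX = {a: i for i, a in enumerate(config.AMINO_ACIDS)}


@dataclass
class DomainHit:
    """A domain occurrence on a protein, 1-based inclusive coordinates."""

    protein_id: str
    label: str
    start: int
    end: int
    score: float = 0.0
    significance: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid hit coordinates {self.start}..{self.end}")
        if self.significance < 0:
            raise ValueError("significance must be >= 0")


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    species_tag: str = ""
    length: int = 0
    mw: float = 0.0
    pi: float = 0.0

    @classmethod
    def from_sequence(cls, id: str, sequence: str, species_tag: str = "") -> "ProteinRecord":
        length, mw, pi = compute_physchem(sequence)
        return cls(id=id, sequence=sequence, species_tag=species_tag,
                   length=length, mw=mw, pi=pi)


@dataclass
class RepeatProfile:
    """Log-odds profile over a fixed repeat width.

    ``log_odds`` is a (width, 20) array in bits, columns indexed by
    :data:`ankfam.config.AMINO_ACIDS`; ``background`` holds the residue
    frequencies the odds are taken against.
    """

    width: int
    log_odds: np.ndarray
    background: Mapping[str, float]
    consensus: str = field(default="")

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.log_odds.shape != (self.width, 20):
            raise ValueError("log_odds must be width x 20")
        total = sum(self.background.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if not self.consensus:
            self.consensus = "".join(
                config.AMINO_ACIDS[j] for j in self.log_odds.argmax(axis=1)
            )

    def encode(self, sequence: str) -> np.ndarray:
        try:
            return np.fromiter((_AA_INDEX[a] for a in sequence), dtype=np.intp,
                               count=len(sequence))
        except KeyError as exc:
            raise ValueError(f"non-canonical residue {exc.args[0]!r}") from exc

    def score_window(self, sequence: str, start: int) -> float:
        """Bit score of the width-long window beginning at 1-based ``start``."""
        codes = self.encode(sequence[start - 1: start - 1 + self.width])
        if len(codes) != self.width:
            raise ValueError("window extends past the end of the sequence")
        return float(self.log_odds[np.arange(self.width), codes].sum())

    def score_all_windows(self, sequence: str) -> np.ndarray:
        """Scores of every window, index i = window starting at residue i+1."""
        codes = self.encode(sequence)
        n = len(codes) - self.width + 1
        if n <= 0:
            return np.empty(0)
        scores = np.zeros(n)
        for offset in range(self.width):
            scores += self.log_odds[offset, codes[offset: offset + n]]
        return scores

    @property
    def max_self_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


def build_profile(
    seed_alignment: Sequence[str],
    pseudocount: float = config.PROFILE_PSEUDOCOUNT,
    background: Mapping[str, float] | None = None,
) -> RepeatProfile:
    """Build a log-odds profile from a gapless fixed-width alignment.

    log_odds[i][a] = log2( (count(a at i) + pc*bg[a]) / (rows + pc) / bg[a] ).
    """
    rows = list(seed_alignment)
    if not rows:
        raise ValueError("seed alignment must contain at least one row")
    width = len(rows[0])
    if width < 2:
        raise ValueError("alignment width must be >= 2")
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment: all rows must have the same width")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if background is None:
        background = {a: 1.0 / 20.0 for a in config.AMINO_ACIDS}

    n = len(rows)
    counts = np.zeros((width, 20))
    for row in rows:
        for i, a in enumerate(row):
            if a not in _AA_INDEX:
                raise ValueError(f"non-residue character {a!r} in seed alignment")
            counts[i, _AA_INDEX[a]] += 1
    bg = np.array([background[a] for a in config.AMINO_ACIDS])
    freq = (counts + pseudocount * bg) / (n + pseudocount)
    log_odds = np.log2(freq / bg)
    return RepeatProfile(width=width, log_odds=log_odds, background=dict(background))


def load_seed_alignment(path=None) -> list[str]:
    """Rows of the seed alignment FASTA (the packaged synthetic seed by default)."""
    from Bio import SeqIO

    if path is None:
        ref = resources.files("ankfam.data") / "ank_seed_synthetic.fasta"
        with resources.as_file(ref) as p:
            return [str(rec.seq) for rec in SeqIO.parse(str(p), "fasta")]
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def default_profile() -> RepeatProfile:
    return build_profile(load_seed_alignment())


def _greedy_select(scores: np.ndarray, width: int, threshold: float) -> list[int]:
    """Greedy non-overlapping window selection, ties broken by smaller start.

    Returns selected 0-based window start indices.
    """
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    taken: list[int] = []
    for i in order:
        if scores[i] < threshold:
            break
        if all(abs(i - j) >= width for j in taken):
            taken.append(i)
    return sorted(taken)


def scan_protein(
    protein: ProteinRecord | str,
    profile: RepeatProfile,
    score_threshold: float = config.SCAN_SCORE_THRESHOLD,
    n_null: int = config.NULL_WINDOWS,
    null_seed: int = 0,
    protein_id: str | None = None,
) -> list[DomainHit]:
    """Scan one protein for tandem repeat hits (label ``"ANK"``).

    Significance of a hit with score s is the fraction of >= ``n_null``
    window scores from shuffled copies of the same sequence that reach s;
    a hit above every shuffled window therefore has significance 0.
    """
    if isinstance(protein, ProteinRecord):
        seq, pid = protein.sequence, protein.id
    else:
        seq, pid = protein, (protein_id or "protein")
    if len(seq) < profile.width:
        warnings.warn(f"{pid}: sequence shorter than profile width, no scan performed")
        return []

    scores = profile.score_all_windows(seq)
    starts0 = _greedy_select(scores, profile.width, score_threshold)
    if not starts0:
        return []

    null_scores = _null_window_scores(seq, profile, n_null, null_seed)
    hits = []
    for i in starts0:
        sig = float(np.count_nonzero(null_scores >= scores[i])) / len(null_scores)
        hits.append(DomainHit(protein_id=pid, label="ANK",
                              start=i + 1, end=i + profile.width,
                              score=float(scores[i]), significance=sig))
    return hits


def _null_window_scores(seq: str, profile: RepeatProfile, n_null: int, seed: int) -> np.ndarray:
    rng = random.Random(seed)
    letters = list(seq)
    collected: list[np.ndarray] = []
    total = 0
    # cap shuffles defensively; one shuffle of a long protein may suffice
    for _ in range(max(1, math.ceil(n_null / max(1, len(seq) - profile.width + 1)))):
        rng.shuffle(letters)
        s = profile.score_all_windows("".join(letters))
        collected.append(s)
        total += len(s)
        if total >= n_null:
            break
    return np.concatenate(collected)


def filter_candidates(
    proteins: Iterable[ProteinRecord],
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    significance_cutoff: float = config.SIGNIFICANCE_CUTOFF,
) -> tuple[list[ProteinRecord], list[tuple[str, str]]]:
    """Drop weak and redundant candidates.

    A protein is dropped when its best (lowest-significance) hit exceeds the
    cutoff, or when an identical sequence with a lexicographically smaller id
    exists. Returns (retained, dropped) where dropped pairs are (id, reason).
    """
    proteins = list(proteins)
    dropped: list[tuple[str, str]] = []
    by_seq: dict[str, str] = {}
    for p in sorted(proteins, key=lambda p: p.id):
        by_seq.setdefault(p.sequence, p.id)

    retained = []
    for p in sorted(proteins, key=lambda p: p.id):
        hits = hits_by_protein.get(p.id, [])
        if not hits:
            dropped.append((p.id, "no repeat hit"))
            continue
        best = min(h.significance for h in hits)
        if best > significance_cutoff:
            dropped.append((p.id, f"best hit significance {best:g} > cutoff"))
            continue
        if by_seq[p.sequence] != p.id:
            dropped.append((p.id, f"redundant with {by_seq[p.sequence]}"))
            continue
        retained.append(p)
    return retained, dropped


def net_charge(sequence: str, ph: float) -> float:
    """Net protein charge at a given pH (Henderson-Hasselbalch, termini included)."""
    pos = 1.0 / (1.0 + 10 ** (ph - config.PKA_POSITIVE["NTERM"]))
    neg = 1.0 / (1.0 + 10 ** (config.PKA_NEGATIVE["CTERM"] - ph))
    for a in sequence:
        if a in config.PKA_POSITIVE:
            pos += 1.0 / (1.0 + 10 ** (ph - config.PKA_POSITIVE[a]))
        elif a in config.PKA_NEGATIVE:
            neg += 1.0 / (1.0 + 10 ** (config.PKA_NEGATIVE[a] - ph))
    return pos - neg


def compute_physchem(sequence: str) -> tuple[int, float, float]:
    """Length (residues), molecular weight (Da, average masses) and pI.

    pI is the pH at which the net charge crosses zero, found by bisection on
    [0, 14] to 0.01 pH units.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set(config.AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-canonical residues: {sorted(bad)}")
    mw = sum(config.RESIDUE_MASS[a] for a in sequence) + config.WATER_MASS

    lo, hi = 0.0, 14.0
    while hi - lo > 0.005:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    pi = round((lo + hi) / 2.0, 2)
    return len(sequence), mw, pi


def repeat_count_histogram(
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
) -> tuple[dict[int, int], int | None]:
    """Map repeat-count -> number of proteins, plus the modal count.

    Proteins enter the bin equal to their number of "ANK"-labelled hits.
    """
    hist: dict[int, int] = {}
    for pid, hits in hits_by_protein.items():
        k = sum(1 for h in hits if h.label == "ANK")
        hist[k] = hist.get(k, 0) + 1
    if not hist:
        return {}, None
    mode = max(hist, key=lambda k: (hist[k], -k))
    return dict(sorted(hist.items())), mode
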