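"""Subfamily assignment from domain architecture and census tables.

Family members are classified by the non-repeat domains that co-occur with
the repeat array: a protein with only the repeat domain is ANK-U; otherwise
the highest-priority recognized domain names the subfamily (ANK-TM, ANK-PK,
...); anything else falls into ANK-O. The priority order is a declared
convention (see :data:`ankfam.config.SUBFAMILY_PRIORITY`), exposed because a
protein may carry several non-repeat domains.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import config
from .family_scan import DomainHit

__all__ = ["SubfamilyAssignment", "SubfamilyCensus", "classify", "census",
           "percent_of_proteome", "load_printed_census"]


@dataclass
class SubfamilyAssignment:
    protein_id: str
    subfamily: str
    evidence: list[str]

    def __post_init__(self) -> None:
        if self.subfamily not in config.SUBFAMILY_VOCAB:
            raise ValueError(f"unknown subfamily {self.subfamily!r}")
        if (self.subfamily == "ANK-U") != (len(self.evidence) == 0):
            raise ValueError("ANK-U iff evidence is empty")


@dataclass
class SubfamilyCensus:
    counts: dict[str, int]
    family_size: int
    proteome_size: int
    percent_of_proteome: float

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.family_size:
            raise ValueError("subfamily counts must sum to family size")


def classify(protein_id: str, domain_hits: Sequence[DomainHit]) -> SubfamilyAssignment:
    """Assign one protein to a subfamily from its domain hits.

    Requires at least one "ANK" hit; raises otherwise since the protein is
    then not a family member at all.
    """
    labels = [h.label for h in domain_hits]
    if "ANK" not in labels:
        raise ValueError(f"{protein_id}: not a family member (no ANK domain hit)")
    evidence = sorted({l for l in labels if l != "ANK"})
    if not evidence:
        return SubfamilyAssignment(protein_id, "ANK-U", [])
    for dom in config.SUBFAMILY_PRIORITY:
        if dom in evidence:
            return SubfamilyAssignment(protein_id, f"ANK-{dom}", evidence)
    return SubfamilyAssignment(protein_id, "ANK-O", evidence)


def percent_of_proteome(family_size: int, proteome_size: int) -> float:
    """100 * family / proteome, rounded half-away-from-zero to 2 decimals.

    Computed on exact rationals so ties never depend on float representation.
    """
    if proteome_size <= 0:
        raise ValueError("proteome size must be positive")
    p = Fraction(10000 * family_size, proteome_size)  # percent * 100
    rounded = (p + Fraction(1, 2)).__floor__()  # half away from zero (p >= 0)
    return float(Fraction(rounded, 100))


def census(assignments: Iterable[SubfamilyAssignment], proteome_size: int) -> SubfamilyCensus:
    """Table-style census: per-subfamily counts and percent of the proteome."""
    assignments = list(assignments)
    counts = {s: 0 for s in config.SUBFAMILY_VOCAB}
    for a in assignments:
        counts[a.subfamily] += 1
    family = len(assignments)
    if proteome_size <= 0:
        raise ValueError("proteome size must be positive")
    if family > proteome_size:
        raise ValueError("family cannot exceed the proteome")
    return SubfamilyCensus(counts=counts, family_size=family,
                           proteome_size=proteome_size,
                           percent_of_proteome=percent_of_proteome(family, proteome_size))


def load_printed_census() -> pd.DataFrame:
    """Packaged cross-species census table (members, proteome sizes, percents)."""
    ref = resources.files("ankfam.data") / "table1_census.tsv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")
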