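"""Expression quantification: RPKM, log matrices, tissue partitions, ddCt.

RPKM[g, s] = 1e9 * counts[g, s] / (library_size[s] * gene_length_bp[g]).
Tissue-specificity is summarized as the membership partition of the
expressed gene sets (Venn cells). qPCR relative expression follows the
2^-ddCt convention with arithmetic-mean Ct aggregation over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import config

__all__ = ["CtTable", "ExpressionPartition", "rpkm", "log_matrix",
           "expression_partition", "cluster_orders", "ddct", "ddct_from_frame"]


@dataclass
class CtTable:
    """Replicate Ct measurements of one target and one reference gene."""

    sample: str
    target_cts: list[float]
    reference_cts: list[float]

    def __post_init__(self) -> None:
        if not self.target_cts or not self.reference_cts:
            raise ValueError("need at least one replicate for target and reference")
        for ct in list(self.target_cts) + list(self.reference_cts):
            if not 0.0 < ct < 45.0:
                raise ValueError(f"Ct {ct} outside the plausible cycle range (0, 45)")

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.target_cts) - np.mean(self.reference_cts))


@dataclass
class ExpressionPartition:
    threshold: float
    expressed: dict[str, set[str]]           # per-sample expressed gene sets
    union: set[str]
    intersection: set[str]
    exclusive: dict[str, set[str]]           # expressed in exactly one sample
    cells: dict[frozenset, set[str]]         # full membership partition


def rpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
         library_sizes: pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads (genes x samples).

    ``gene_lengths`` are bp indexed by gene, ``library_sizes`` total mapped
    reads indexed by sample.
    """
    counts = counts.astype(float)
    lengths = gene_lengths.reindex(counts.index)
    libs = library_sizes.reindex(counts.columns)
    if lengths.isna().any():
        raise ValueError(f"missing gene lengths: {list(lengths[lengths.isna()].index)}")
    if libs.isna().any():
        raise ValueError(f"missing library sizes: {list(libs[libs.isna()].index)}")
    bad = lengths[lengths <= 0]
    if len(bad):
        raise ValueError(f"non-positive gene length for {list(bad.index)}")
    bad = libs[libs <= 0]
    if len(bad):
        raise ValueError(f"non-positive library size for {list(bad.index)}")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    return 1e9 * counts.div(libs, axis=1).div(lengths, axis=0)


def log_matrix(rpkm_matrix: pd.DataFrame,
               pseudocount: float = config.LOG_PSEUDOCOUNT) -> pd.DataFrame:
    """Element-wise log2(rpkm + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (rpkm_matrix.values < 0).any():
        raise ValueError("RPKM values must be non-negative")
    return np.log2(rpkm_matrix + pseudocount)


def expression_partition(rpkm_matrix: pd.DataFrame,
                         threshold: float = config.RPKM_EXPRESSED_THRESHOLD
                         ) -> ExpressionPartition:
    """Venn-style partition of per-sample expressed gene sets.

    A gene is expressed in a sample when its RPKM is strictly above the
    threshold. The ``cells`` partition is keyed by the frozenset of samples a
    gene is expressed in; cell sizes sum to the size of the union.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    samples = list(rpkm_matrix.columns)
    expressed = {s: set(rpkm_matrix.index[rpkm_matrix[s] > threshold]) for s in samples}
    union = set().union(*expressed.values()) if samples else set()
    intersection = set.intersection(*expressed.values()) if samples else set()
    cells: dict[frozenset, set[str]] = {}
    for gene in union:
        key = frozenset(s for s in samples if gene in expressed[s])
        cells.setdefault(key, set()).add(gene)
    exclusive = {s: cells.get(frozenset([s]), set()) for s in samples}
    return ExpressionPartition(threshold=threshold, expressed=expressed,
                               union=union, intersection=intersection,
                               exclusive=exclusive, cells=cells)


def cluster_orders(matrix: pd.DataFrame) -> tuple[list, list]:
    """Row and column orderings from average-linkage hierarchical clustering
    on Euclidean distance (the common heatmap default)."""
    from scipy.cluster.hierarchy import leaves_list, linkage

    def order(data):
        if data.shape[0] < 3:
            return list(range(data.shape[0]))
        return list(leaves_list(linkage(data, method="average", metric="euclidean")))

    rows = order(matrix.values)
    cols = order(matrix.values.T)
    return [matrix.index[i] for i in rows], [matrix.columns[j] for j in cols]


def ddct(sample: CtTable, calibrator: CtTable) -> float:
    """Relative expression fold 2^-(dCt_sample - dCt_calibrator)."""
    return float(2.0 ** (-(sample.delta_ct - calibrator.delta_ct)))


def ddct_from_frame(frame: pd.DataFrame, calibrator: str) -> pd.Series:
    """Fold changes per sample from a long Ct table.

    Expects columns ``sample``, ``role`` (target/reference) and ``ct``.
    The calibrator sample's fold is 1 by construction.
    """
    tables = {}
    for sample, grp in frame.groupby("sample"):
        target = grp.loc[grp["role"] == "target", "ct"].tolist()
        reference = grp.loc[grp["role"] == "reference", "ct"].tolist()
        if not reference:
            raise ValueError(f"sample {sample!r}: missing reference gene measurements")
        tables[sample] = CtTable(sample=str(sample), target_cts=target,
                                 reference_cts=reference)
    if calibrator not in tables:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")
    cal = tables[calibrator]
    return pd.Series({s: ddct(t, cal) for s, t in tables.items()}).sort_index()
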