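"""Anchor profiling, the peak-sample expression filter, nearest-neighbour
co-expression and Venn partitioning of neighbour sets.

An *anchor* is a gene of interest (for the motivating barley study, the
Btr1-like / Btr2-like copies) whose expression profile seeds the search.
The procedure on a replicate-averaged TPM compendium is:

1. profile the anchor: peak sample, peak TPM, and the set of samples
   where it clears the expression threshold (1 TPM by default);
2. drop every gene whose TPM at the anchor's peak sample is *below* the
   threshold (a gene at exactly 1.0 TPM survives);
3. rank the remaining genes by Pearson correlation with the anchor row
   and keep those at or above ``r_min`` (0.95 by default, inclusive);
4. for two anchors, partition the neighbour sets into only-A / only-B /
   both by plain set algebra.

Correlations are computed on raw TPM; a log2(TPM+1) option exists but is
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import ExpressionCompendium

DEFAULT_EXPRESSION_THRESHOLD = 1.0
DEFAULT_R_MIN = 0.95


@dataclass
class AnchorProfile:
    """Tissue-specificity summary of one anchor gene."""

    anchor_id: str
    peak_sample_id: str
    peak_tpm: float
    expressed_samples: frozenset[str]


@dataclass
class CoexpressionResult:
    """Genes correlated with one anchor at or above ``r_min``.

    ``neighbours`` is sorted by r descending, gene id ascending; the
    anchor itself is excluded.  ``n_genes_filtered_out`` counts
    zero-variance genes skipped because r is undefined for them, so
    ``n_genes_tested + n_genes_filtered_out == total genes - 1``.
    """

    anchor_id: str
    neighbours: list[tuple[str, float]]
    r_min: float
    n_genes_tested: int
    n_genes_filtered_out: int

    @property
    def gene_ids(self) -> set[str]:
        return {g for g, _ in self.neighbours}


@dataclass
class VennPartition:
    only_a: set[str]
    only_b: set[str]
    both: set[str]

    def __post_init__(self) -> None:
        if self.only_a & self.both or self.only_b & self.both or self.only_a & self.only_b:
            raise ValueError("Venn cells must be pairwise disjoint")

    @property
    def union_size(self) -> int:
        return len(self.only_a) + len(self.only_b) + len(self.both)


def anchor_profile(comp: ExpressionCompendium, anchor_id: str,
                   expression_threshold: float = DEFAULT_EXPRESSION_THRESHOLD) -> AnchorProfile:
    """Peak sample (arg-max, first sample wins ties) and expressed-sample set."""
    if anchor_id not in comp.values.index:
        raise KeyError(f"anchor gene {anchor_id!r} not in compendium")
    row = comp.values.loc[anchor_id].to_numpy(dtype=float)
    peak_idx = int(np.argmax(row))  # argmax returns the first maximal index
    expressed = frozenset(
        sid for sid, v in zip(comp.sample_ids, row) if v >= expression_threshold)
    return AnchorProfile(anchor_id, comp.sample_ids[peak_idx], float(row[peak_idx]), expressed)


def filter_by_peak_expression(comp: ExpressionCompendium, profile: AnchorProfile,
                              min_tpm: float = DEFAULT_EXPRESSION_THRESHOLD
                              ) -> tuple[ExpressionCompendium, int]:
    """Remove genes expressed below ``min_tpm`` at the anchor's peak sample.

    The comparison is strict ("below one TPM ... removed"), so a gene at
    exactly ``min_tpm`` is kept.  Returns the filtered compendium and the
    number of genes removed; kept + removed always equals the input count.
    """
    if profile.peak_sample_id not in comp.values.columns:
        raise KeyError(f"peak sample {profile.peak_sample_id!r} not in compendium")
    keep = comp.values[profile.peak_sample_id] >= min_tpm
    filtered = ExpressionCompendium(values=comp.values.loc[keep].copy(),
                                    samples=comp.samples, is_tpm=comp.is_tpm)
    return filtered, int((~keep).sum())


def nearest_neighbours(comp: ExpressionCompendium, anchor_id: str,
                       r_min: float = DEFAULT_R_MIN,
                       log_transform: bool = False) -> CoexpressionResult:
    """Genes whose profile correlates with the anchor at r >= ``r_min``.

    Pearson r is computed between the anchor row and every other gene row
    over the (replicate-averaged) sample columns.  Zero-variance genes
    are skipped — r is undefined for them — and counted in
    ``n_genes_filtered_out``.  The threshold is inclusive.
    """
    if not -1.0 <= r_min <= 1.0:
        raise ValueError(f"r_min must be in [-1, 1], got {r_min}")
    if anchor_id not in comp.values.index:
        raise KeyError(f"anchor gene {anchor_id!r} not in compendium")
    mat = comp.values.to_numpy(dtype=float)
    if log_transform:
        mat = np.log2(mat + 1.0)
    genes = list(comp.values.index)
    a = mat[genes.index(anchor_id)]
    a_c = a - a.mean()
    a_ss = float(a_c @ a_c)
    if a_ss == 0.0:
        raise ValueError(f"anchor {anchor_id!r} has zero variance across samples")
    centred = mat - mat.mean(axis=1, keepdims=True)
    ss = (centred * centred).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centred @ a_c) / np.sqrt(ss * a_ss)
    neighbours: list[tuple[str, float]] = []
    n_skipped = 0
    for gid, ssg, rv in zip(genes, ss, r):
        if gid == anchor_id:
            continue
        if ssg == 0.0:
            n_skipped += 1
            continue
        if rv >= r_min:
            neighbours.append((gid, float(rv)))
    neighbours.sort(key=lambda t: (-t[1], t[0]))
    n_tested = len(genes) - 1 - n_skipped
    return CoexpressionResult(anchor_id, neighbours, r_min, n_tested, n_skipped)


def venn_partition(result_a: CoexpressionResult | Iterable[str],
                   result_b: CoexpressionResult | Iterable[str]) -> VennPartition:
    """Partition two neighbour gene sets into only-A, only-B and both."""
    set_a = result_a.gene_ids if isinstance(result_a, CoexpressionResult) else set(result_a)
    set_b = result_b.gene_ids if isinstance(result_b, CoexpressionResult) else set(result_b)
    return VennPartition(only_a=set_a - set_b, only_b=set_b - set_a, both=set_a & set_b)
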