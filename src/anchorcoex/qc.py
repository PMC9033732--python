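"""TPM normalisation, replicate-coherence QC and replicate averaging.

The QC step mirrors a standard bulk RNA-seq sanity check: hierarchically
cluster samples on 1 - Pearson's r and require every replicate group to
occupy an exclusive subtree of the dendrogram.  Groups that fail are
removed wholesale, and surviving replicate groups are collapsed to their
arithmetic mean column before any co-expression search.

Agglomerative clustering is implemented here directly (UPGMA via the
Lance-Williams update) so that the tie rule is explicit: among pairs at
the minimal merge distance, the pair with the smallest (creation-order)
cluster indices merges first.  The linkage method defaults to average
and can be switched to complete or single.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionCompendium, SampleMeta

METADATA_FIELDS = ("sample_id", "project", "tissue", "stage", "replicate_group", "condition")


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: the two clusters joined and the height."""

    left: frozenset[str]
    right: frozenset[str]
    height: float

    @property
    def members(self) -> frozenset[str]:
        return self.left | self.right


@dataclass
class QcReport:
    flagged_replicate_groups: list[tuple[str, str]]
    removed_sample_ids: list[str]
    kept_sample_ids: list[str]
    dendrogram: list[Merge]

    def __post_init__(self) -> None:
        if set(self.removed_sample_ids) & set(self.kept_sample_ids):
            raise ValueError("a sample cannot be both removed and kept")


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def tpm_from_counts(counts: pd.DataFrame, lengths: Mapping[str, int],
                    samples: Sequence[SampleMeta] | None = None) -> ExpressionCompendium:
    """Normalise a gene x sample read-count matrix to transcripts per million.

    Per sample the per-gene read rate ``count / length`` is rescaled so the
    column sums to 10^6::

        TPM_g = 1e6 * (count_g / length_g) / sum_j (count_j / length_j)

    Parameters
    ----------
    counts
        Non-negative integer counts, genes in rows, samples in columns.
    lengths
        Effective transcript length in bp per gene id; all must be > 0.
    samples
        Optional metadata; synthesised minimally when omitted.
    """
    missing = [g for g in counts.index if g not in lengths]
    if missing:
        raise ValueError(f"no length for gene(s) {missing[:5]}")
    lens = np.array([float(lengths[g]) for g in counts.index])
    if (lens <= 0).any():
        bad = counts.index[lens <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("negative counts")
    rates = mat / lens[:, None]
    totals = rates.sum(axis=0)
    if (totals <= 0).any():
        bad = counts.columns[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has an all-zero count column")
    tpm = 1e6 * rates / totals
    if samples is None:
        samples = [SampleMeta(c, "NA", "NA", "NA", c) for c in counts.columns]
    return ExpressionCompendium(
        values=pd.DataFrame(tpm, index=counts.index, columns=counts.columns),
        samples=list(samples),
    )


# ---------------------------------------------------------------------------
# Correlation distance
# ---------------------------------------------------------------------------

def correlation_distance_matrix(comp: ExpressionCompendium,
                                gene_subset: Iterable[str] | None = None,
                                log_transform: bool = False) -> pd.DataFrame:
    """Sample x sample distance matrix, d = 1 - Pearson's r between columns.

    Distances lie in [0, 2] with an exactly zero diagonal.  QC correlations
    are computed on raw TPM by default; ``log_transform`` switches to
    log2(TPM + 1).
    """
    values = comp.values if gene_subset is None else comp.values.loc[list(gene_subset)]
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = values.to_numpy(dtype=float)
    if log_transform:
        mat = np.log2(mat + 1.0)
    sd = mat.std(axis=0)
    if (sd == 0).any():
        bad = values.columns[sd == 0][0]
        raise ValueError(f"sample {bad!r} has zero variance across the gene set used")
    r = np.corrcoef(mat, rowvar=False)
    d = 1.0 - r
    d = np.clip(d, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


# ---------------------------------------------------------------------------
# Agglomerative clustering (UPGMA / complete / single) with explicit ties
# ---------------------------------------------------------------------------

def linkage_merges(dist: pd.DataFrame, method: str = "average") -> list[Merge]:
    """All n-1 agglomerative merges on a symmetric distance matrix.

    Inter-cluster distances follow the Lance-Williams recurrences, which
    for ``average`` reproduce the mean over all original leaf pairs
    (UPGMA).  Ties at the minimal distance are broken by the smallest
    (creation-order) pair of cluster indices, so the merge list is a pure
    function of the input.
    """
    if method not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage method {method!r}")
    labels = list(dist.index)
    n = len(labels)
    d: dict[tuple[int, int], float] = {}
    arr = dist.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = arr[i, j]
    members: dict[int, frozenset[str]] = {i: frozenset([labels[i]]) for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    active = list(range(n))
    next_id = n
    merges: list[Merge] = []
    while len(active) > 1:
        best = min(
            ((d[(min(a, b), max(a, b))], a, b)
             for idx, a in enumerate(active) for b in active[idx + 1:]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        h, a, b = best
        merges.append(Merge(members[a], members[b], h))
        new = next_id
        next_id += 1
        for c in active:
            if c in (a, b):
                continue
            dac = d[(min(a, c), max(a, c))]
            dbc = d[(min(b, c), max(b, c))]
            if method == "average":
                val = (sizes[a] * dac + sizes[b] * dbc) / (sizes[a] + sizes[b])
            elif method == "complete":
                val = max(dac, dbc)
            else:
                val = min(dac, dbc)
            d[(min(new, c), max(new, c))] = val
        members[new] = members[a] | members[b]
        sizes[new] = sizes[a] + sizes[b]
        active = [c for c in active if c not in (a, b)] + [new]
    return merges


def cluster_and_flag_replicates(dist: pd.DataFrame,
                                samples: Sequence[SampleMeta],
                                method: str = "average") -> QcReport:
    """Flag replicate groups that do not form an exclusive dendrogram subtree.

    A group of size >= 2 is coherent iff some node of the dendrogram has a
    leaf set equal to exactly that group; singleton groups are exempt.
    All members of a flagged group are removed (a stray replicate taints
    the whole group's average).
    """
    by_id = {s.sample_id: s for s in samples}
    unknown = [sid for sid in dist.index if sid not in by_id]
    if unknown:
        raise ValueError(f"sample(s) {unknown} missing from metadata")
    merges = linkage_merges(dist, method=method)
    subtrees: set[frozenset[str]] = {frozenset([sid]) for sid in dist.index}
    subtrees.update(m.members for m in merges)
    groups: dict[str, set[str]] = {}
    for sid in dist.index:
        groups.setdefault(by_id[sid].replicate_group, set()).add(sid)
    flagged: list[tuple[str, str]] = []
    removed: list[str] = []
    for gid in sorted(groups):
        mem = groups[gid]
        if len(mem) == 1:
            continue
        if frozenset(mem) not in subtrees:
            flagged.append((gid, "replicates do not form an exclusive subtree"))
            removed.extend(sorted(mem))
    kept = [sid for sid in dist.index if sid not in set(removed)]
    return QcReport(flagged, removed, kept, merges)


# ---------------------------------------------------------------------------
# Pruning and replicate averaging
# ---------------------------------------------------------------------------

def _match_rule(meta: SampleMeta, rule: Mapping[str, object]) -> bool:
    for fld, want in rule.items():
        if fld not in METADATA_FIELDS:
            raise ValueError(f"keep_rules reference unknown metadata field {fld!r}")
        have = getattr(meta, fld)
        if isinstance(want, str):
            wanted = [w.strip() for w in want.split(",")]
        else:
            wanted = [str(w) for w in want]
        if have not in wanted:
            return False
    return True


def prune_and_average(comp: ExpressionCompendium,
                      keep_rules: Mapping[str, Sequence[Mapping[str, object]]] | None = None,
                      drop_sample_ids: Iterable[str] = ()) -> ExpressionCompendium:
    """Drop samples per declarative rules, then average replicate groups.

    ``keep_rules`` holds two optional lists of field=value rules, e.g.::

        {"deny": [{"stage": "0h,16h,24h,32h,40h"}],
         "allow": [{"project": "germination"}]}

    A sample survives when it matches no deny rule and, if allow rules are
    present, at least one of them.  Surviving replicate groups collapse to
    their arithmetic mean column, with the replicate group id as the new
    sample id — so averaging an already-averaged compendium is a no-op.
    """
    keep_rules = keep_rules or {}
    allow = list(keep_rules.get("allow", []))
    deny = list(keep_rules.get("deny", []))
    extra = set(keep_rules) - {"allow", "deny"}
    if extra:
        raise ValueError(f"keep_rules sections must be 'allow'/'deny', got {sorted(extra)}")
    drop = set(drop_sample_ids)
    kept: list[SampleMeta] = []
    for m in comp.samples:
        if m.sample_id in drop:
            continue
        if any(_match_rule(m, r) for r in deny):
            continue
        if allow and not any(_match_rule(m, r) for r in allow):
            continue
        kept.append(m)
    if not kept:
        raise ValueError("keep_rules removed every sample")
    order: list[str] = []
    group_members: dict[str, list[SampleMeta]] = {}
    for m in kept:
        if m.replicate_group not in group_members:
            order.append(m.replicate_group)
        group_members.setdefault(m.replicate_group, []).append(m)
    cols = {}
    metas: list[SampleMeta] = []
    for gid in order:
        mem = group_members[gid]
        cols[gid] = comp.values[[m.sample_id for m in mem]].mean(axis=1)
        first = mem[0]
        metas.append(SampleMeta(gid, first.project, first.tissue, first.stage,
                                gid, first.condition))
    return ExpressionCompendium(values=pd.DataFrame(cols, index=comp.values.index),
                                samples=metas, is_tpm=comp.is_tpm)
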