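"""Cross-species orthologue triage.

Candidate orthologues of the co-expressed genes are found by a local
nucleotide alignment search of each query CDS against a target-species
CDS database, keeping only the single top hit per query, and then gating
each top hit on four independent criteria:

1. E-value at most ``e_max`` (default 1e-3, inclusive);
2. alignment score — the length-coverage percentage
   ``100 * alignment_length / query_length`` — strictly above 60;
3. expression of the target gene in a designated tissue (FPKM strictly
   above 0);
4. presence of the target gene in a functional-annotation table.

The search itself is a seeded local aligner in the blastn mould: exact
``word_size``-mer seeds located by hashing, grouped by diagonal, then
extended with affine-gap Smith-Waterman dynamic programming in a band
around the seed diagonals.  Hit significance uses the Karlin-Altschul
form ``E = K * m * n * exp(-lambda * S)`` with m the query length and n
the total database length; ``K`` and ``lambda`` are pinned in
:class:`AlignerParams` so E-values are reproducible.  Default scoring is
the classic blastn set: match +2, mismatch -3, gap open 5, gap extend 2
(a gap of length L costs ``open + L * extend``), word size 11.  ``N``
never matches.

Percent-identity matrices for protein (or nucleotide) sets are computed
from global affine-gap alignments via Bio.Align.PairwiseAligner; both
identity denominators found in practice (columns where both sequences
have residues, and all alignment columns) are supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import AlignmentHit, AnnotationRecord, FpkmTable

NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignerParams:
    """Scoring and statistics constants for the local search."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 11
    karlin_K: float = 0.41
    karlin_lambda: float = 0.625  # nats per raw-score unit
    e_max: float = 1e-3
    band_pad: int = 16

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("need match > 0 and mismatch < 0")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("need gap_open >= 0 and gap_extend > 0")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.karlin_K <= 0 or self.karlin_lambda <= 0:
            raise ValueError("Karlin parameters must be positive")
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")


@dataclass(frozen=True)
class GateThresholds:
    e_max: float = 1e-3
    score_min: float = 60.0
    fpkm_min: float = 0.0


@dataclass(frozen=True)
class OrthologCandidate:
    """A query-target pair with its four gate outcomes."""

    query_id: str
    subject_id: str
    e_value: float
    alignment_score_pct: float
    fpkm_in_target_tissue: float
    has_functional_record: bool
    gate_evalue: bool
    gate_score: bool
    gate_fpkm: bool
    gate_annotation: bool
    passes_all: bool
    synteny: str = "-"

    def __post_init__(self) -> None:
        expected = (self.gate_evalue and self.gate_score
                    and self.gate_fpkm and self.gate_annotation)
        if self.passes_all != expected:
            raise ValueError("passes_all must be the conjunction of the four gates")
        if self.alignment_score_pct < 0:
            raise ValueError("alignment score cannot be negative")

    @property
    def passes_criteria_123(self) -> bool:
        return self.gate_evalue and self.gate_score and self.gate_fpkm


@dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, % identity, diagonal 100

    def identity(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.ids.index(id_a), self.ids.index(id_b)])


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics
# ---------------------------------------------------------------------------

def evalue(raw_score: int, query_length: int, database_length: int,
           params: AlignerParams) -> float:
    """Expected chance hits scoring >= ``raw_score``: K * m * n * e^(-lambda*S)."""
    return (params.karlin_K * query_length * database_length
            * math.exp(-params.karlin_lambda * raw_score))


def bit_score(raw_score: int, params: AlignerParams) -> float:
    return (params.karlin_lambda * raw_score - math.log(params.karlin_K)) / math.log(2)


# ---------------------------------------------------------------------------
# Banded affine-gap Smith-Waterman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment of one sequence pair (0-based half-open spans)."""

    score: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    alignment_length: int
    identities: int
    gap_columns: int


def smith_waterman(query: str, subject: str, params: AlignerParams,
                   diag_lo: int | None = None, diag_hi: int | None = None
                   ) -> LocalAlignment | None:
    """Affine-gap local alignment restricted to diagonals ``j - i`` in
    [diag_lo, diag_hi]; defaults cover the full matrix (exhaustive DP).

    Returns ``None`` when no positive-scoring local alignment exists.
    Ties resolve to the first-seen maximal cell in row-major order, then
    a deterministic traceback (diagonal preferred over gaps).
    """
    m, n = len(query), len(subject)
    if m == 0 or n == 0:
        raise ValueError("empty sequence")
    lo = -m if diag_lo is None else max(diag_lo, -m)
    hi = n if diag_hi is None else min(diag_hi, n)
    if lo > hi:
        raise ValueError("empty diagonal band")
    w = hi - lo + 1
    open_cost = params.gap_open + params.gap_extend
    ext_cost = params.gap_extend

    M = np.full((m + 1, w), NEG_INF)
    Ix = np.full((m + 1, w), NEG_INF)  # gap in subject (consumes query)
    Iy = np.full((m + 1, w), NEG_INF)  # gap in query (consumes subject)
    # start-anywhere: a cell may open a fresh alignment at score 0
    ptr_m = np.zeros((m + 1, w), dtype=np.uint8)   # 0 start, 1 M, 2 Ix, 3 Iy
    ptr_ix = np.zeros((m + 1, w), dtype=np.uint8)  # 1 from M, 2 from Ix
    ptr_iy = np.zeros((m + 1, w), dtype=np.uint8)  # 1 from M, 3 from Iy

    best = 0
    best_cell = None
    q = query
    s = subject
    for i in range(0, m + 1):
        for k in range(w):
            j = i + lo + k
            if j < 0 or j > n:
                continue
            if i > 0 and j > 0:
                a, b = q[i - 1], s[j - 1]
                sub = params.match if (a == b and a != "N") else params.mismatch
                prev_m = M[i - 1, k] if 0 <= k < w else NEG_INF
                prev_ix = Ix[i - 1, k]
                prev_iy = Iy[i - 1, k]
                cand = 0.0
                src = 0
                if prev_m > cand:
                    cand, src = prev_m, 1
                if prev_ix > cand:
                    cand, src = prev_ix, 2
                if prev_iy > cand:
                    cand, src = prev_iy, 3
                M[i, k] = cand + sub
                ptr_m[i, k] = src
                if M[i, k] > best:
                    best = M[i, k]
                    best_cell = (i, k)
            # Ix: from (i-1, j)  -> diagonal d+1 -> band index k+1 in row i-1
            if i > 0 and k + 1 < w:
                from_m = M[i - 1, k + 1] - open_cost
                from_ix = Ix[i - 1, k + 1] - ext_cost
                if from_m >= from_ix:
                    Ix[i, k] = from_m
                    ptr_ix[i, k] = 1
                else:
                    Ix[i, k] = from_ix
                    ptr_ix[i, k] = 2
            # Iy: from (i, j-1) -> diagonal d-1 -> band index k-1, same row
            if k - 1 >= 0 and i + lo + k - 1 >= 0:
                from_m = M[i, k - 1] - open_cost
                from_iy = Iy[i, k - 1] - ext_cost
                if from_m >= from_iy:
                    Iy[i, k] = from_m
                    ptr_iy[i, k] = 1
                else:
                    Iy[i, k] = from_iy
                    ptr_iy[i, k] = 3

    if best_cell is None or best <= 0:
        return None
    i, k = best_cell
    qend, send = i, i + lo + k
    state = 1  # in M
    identities = 0
    gap_columns = 0
    length = 0
    while True:
        j = i + lo + k
        if state == 1:
            length += 1
            if q[i - 1] == s[j - 1] and q[i - 1] != "N":
                identities += 1
            src = ptr_m[i, k]
            i -= 1  # diagonal: both indices retreat, band index unchanged
            if src == 0:
                break
            state = src
        elif state == 2:
            length += 1
            gap_columns += 1
            src = ptr_ix[i, k]
            i -= 1
            k += 1
            state = 1 if src == 1 else 2
        else:
            length += 1
            gap_columns += 1
            src = ptr_iy[i, k]
            k -= 1
            state = 1 if src == 1 else 3
    qstart, sstart = i, i + lo + k
    return LocalAlignment(int(round(best)), qstart, qend, sstart, send,
                          length, identities, gap_columns)


# ---------------------------------------------------------------------------
# Seeded search
# ---------------------------------------------------------------------------

def _seed_diagonals(query: str, subject_index: Mapping[str, list[int]],
                    word_size: int) -> list[int]:
    diags: set[int] = set()
    for qpos in range(len(query) - word_size + 1):
        word = query[qpos:qpos + word_size]
        if "N" in word:
            continue
        for spos in subject_index.get(word, ()):
            diags.add(spos - qpos)
    return sorted(diags)


def _cluster_diagonals(diags: Sequence[int], pad: int) -> list[tuple[int, int]]:
    bands: list[tuple[int, int]] = []
    start = prev = diags[0]
    for d in diags[1:]:
        if d - prev > 2 * pad:
            bands.append((start - pad, prev + pad))
            start = d
        prev = d
    bands.append((start - pad, prev + pad))
    return bands


def local_align_search(queries: Sequence[tuple[str, str]],
                       database: Sequence[tuple[str, str]],
                       params: AlignerParams = AlignerParams()) -> list[AlignmentHit]:
    """Search every query against the database; one best hit per pair.

    Hits with ``e_value > params.e_max`` are discarded.  Output is sorted
    by (query id, e-value ascending, raw score descending, subject id).
    """
    if not database:
        raise ValueError("empty database")
    short = [q for q, seq in queries if len(seq) < params.word_size]
    if short:
        raise ValueError(f"query shorter than word size: {short}")
    for name, seq in list(queries) + list(database):
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{name!r}: non-nucleotide symbol(s) {sorted(bad)}")
    db_total = sum(len(seq) for _, seq in database)
    indexes: dict[str, dict[str, list[int]]] = {}
    for sid, sseq in database:
        idx: dict[str, list[int]] = {}
        for pos in range(len(sseq) - params.word_size + 1):
            word = sseq[pos:pos + params.word_size]
            if "N" not in word:
                idx.setdefault(word, []).append(pos)
        indexes[sid] = idx

    hits: list[AlignmentHit] = []
    for qid, qseq in queries:
        for sid, sseq in database:
            diags = _seed_diagonals(qseq, indexes[sid], params.word_size)
            if not diags:
                continue
            best: LocalAlignment | None = None
            for lo, hi in _cluster_diagonals(diags, params.band_pad):
                aln = smith_waterman(qseq, sseq, params, lo, hi)
                if aln is not None and (best is None or aln.score > best.score):
                    best = aln
            if best is None:
                continue
            e = evalue(best.score, len(qseq), db_total, params)
            if e > params.e_max:
                continue
            hits.append(AlignmentHit(
                query_id=qid, subject_id=sid,
                raw_score=best.score, bit_score=bit_score(best.score, params),
                e_value=e, alignment_length=best.alignment_length,
                identities=best.identities,
                query_length=len(qseq), subject_length=len(sseq),
                query_span=(best.query_start + 1, best.query_end),
                subject_span=(best.subject_start + 1, best.subject_end),
            ))
    hits.sort(key=lambda h: (h.query_id, h.e_value, -h.raw_score, h.subject_id))
    return hits


def select_top_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit | None:
    """The single retained hit: minimal E-value, then maximal raw score,
    then lexicographically smallest subject id.  Empty in, ``None`` out."""
    if not hits:
        return None
    if len({h.query_id for h in hits}) > 1:
        raise ValueError("select_top_hit expects hits for a single query")
    return min(hits, key=lambda h: (h.e_value, -h.raw_score, h.subject_id))


def top_hits_per_query(hits: Sequence[AlignmentHit]) -> dict[str, AlignmentHit]:
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    return {q: select_top_hit(hs) for q, hs in sorted(by_query.items())}


# ---------------------------------------------------------------------------
# Alignment score and the four-criterion gate
# ---------------------------------------------------------------------------

def alignment_score(alignment_length: int, query_length: int) -> float:
    """Length-coverage percentage: 100 * alignment_length / query_length.

    Gapped alignments can exceed 100% because gap columns count toward
    the alignment length; no capping is applied.
    """
    if alignment_length <= 0 or query_length <= 0:
        raise ValueError("alignment_length and query_length must be positive")
    return 100.0 * alignment_length / query_length


def gate_candidates(top_hits: Sequence[AlignmentHit],
                    fpkm_table: FpkmTable,
                    target_tissue: str,
                    annotation: Mapping[str, AnnotationRecord],
                    thresholds: GateThresholds = GateThresholds()
                    ) -> list[OrthologCandidate]:
    """Evaluate the four criteria independently for each top hit.

    Gate comparisons: E-value inclusive (``e <= e_max``); alignment score
    strict (``> score_min``); FPKM strict (``> fpkm_min``); annotation is
    a presence test.  ``passes_all`` is their conjunction; the
    criteria-1-3 subset is recoverable via ``passes_criteria_123``.
    """
    if target_tissue not in fpkm_table.tissues:
        raise KeyError(f"unknown target tissue {target_tissue!r}; "
                       f"table has {sorted(fpkm_table.tissues)}")
    out: list[OrthologCandidate] = []
    for h in sorted(top_hits, key=lambda h: h.query_id):
        score_pct = alignment_score(h.alignment_length, h.query_length)
        fpkm = fpkm_table.fpkm(h.subject_id, target_tissue)
        g1 = h.e_value <= thresholds.e_max
        g2 = score_pct > thresholds.score_min
        g3 = fpkm > thresholds.fpkm_min
        g4 = h.subject_id in annotation
        out.append(OrthologCandidate(
            query_id=h.query_id, subject_id=h.subject_id, e_value=h.e_value,
            alignment_score_pct=score_pct, fpkm_in_target_tissue=fpkm,
            has_functional_record=g4,
            gate_evalue=g1, gate_score=g2, gate_fpkm=g3, gate_annotation=g4,
            passes_all=g1 and g2 and g3 and g4,
        ))
    return out


# ---------------------------------------------------------------------------
# Percent identity matrix
# ---------------------------------------------------------------------------

def _global_aligner(alphabet: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    elif alphabet == "nucleotide":
        aligner.match_score = 2
        aligner.mismatch_score = -3
    else:
        raise ValueError(f"alphabet must be 'protein' or 'nucleotide', got {alphabet!r}")
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_alignment_score(seq_a: str, seq_b: str, alphabet: str = "protein",
                           gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    """Optimal global affine-gap alignment score (Needleman-Wunsch/Gotoh)."""
    return float(_global_aligner(alphabet, gap_open, gap_extend).score(seq_a, seq_b))


def pairwise_identity(seq_a: str, seq_b: str, convention: str = "aligned",
                      alphabet: str = "protein",
                      gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    """% identity from one optimal global alignment.

    ``convention`` picks the denominator: ``"aligned"`` counts only
    columns where both sequences have residues; ``"all_columns"`` counts
    every alignment column including gaps.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if convention not in ("aligned", "all_columns"):
        raise ValueError(f"unknown identity convention {convention!r}")
    aligner = _global_aligner(alphabet, gap_open, gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    aligned_pairs = counts.identities + counts.mismatches
    denom = aligned_pairs if convention == "aligned" else aln.length
    return 100.0 * counts.identities / denom


def percent_identity_matrix(records: Sequence[tuple[str, str]],
                            convention: str = "aligned",
                            alphabet: str = "protein",
                            gap_open: float = 10.0, gap_extend: float = 1.0
                            ) -> IdentityMatrix:
    """Symmetric all-vs-all % identity from global alignments; diagonal 100."""
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [name for name, _ in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    n = len(records)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = pairwise_identity(records[i][1], records[j][1], convention,
                                    alphabet, gap_open, gap_extend)
            mat[i, j] = mat[j, i] = pid
    return IdentityMatrix(ids=ids, values=mat)


# ---------------------------------------------------------------------------
# Synteny join
# ---------------------------------------------------------------------------

def join_synteny(candidates: Sequence[OrthologCandidate],
                 synteny_table: Mapping[str, Mapping[str, str]]) -> list[OrthologCandidate]:
    """Left-join synteny-derived orthologue ids onto candidates.

    ``synteny_table`` maps query id -> {species -> ortholog id}.  Missing
    entries are recorded as "-" (absent), and the join is idempotent.
    """
    out = []
    for c in candidates:
        entry = synteny_table.get(c.query_id)
        if not entry:
            text = "-"
        else:
            text = ";".join(f"{sp}={entry[sp]}" for sp in sorted(entry))
        out.append(replace(c, synteny=text))
    return out
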