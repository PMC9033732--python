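"""Readers, writers and the tabular/sequence data model.

Every format the pipeline touches is plain text: expression matrices and
sample metadata as TSV, sequences as FASTA, alignment hits in the
12-column tab-separated layout (outfmt-6 compatible), FPKM and
annotation tables as TSV with documented headers.

Conventions fixed here and relied on everywhere else:

* expression matrices are genes-in-rows, samples-in-columns;
* hit-table intervals are 1-based inclusive, internal sequence indices
  are 0-based half-open — conversion happens only at this I/O boundary;
* minus-strand hits (``s.start > s.end``) are rejected rather than
  reverse-complemented: CDS-vs-CDS searches are plus-strand, and failing
  loudly beats guessing;
* missing values are not allowed in expression matrices (TPM matrices
  are dense by construction).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

METADATA_COLUMNS = ("sample_id", "project", "tissue", "stage", "replicate_group", "condition")

HITS_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gaps",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


class FormatError(ValueError):
    """A file violated the documented format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """Per-library metadata: one row of the sample sheet."""

    sample_id: str
    project: str
    tissue: str
    stage: str
    replicate_group: str
    condition: str = "control"

    def __post_init__(self) -> None:
        if not self.replicate_group:
            raise ValueError(f"sample {self.sample_id!r}: replicate_group must be non-empty")

    @property
    def group_key(self) -> tuple[str, str, str, str]:
        return (self.project, self.tissue, self.stage, self.condition)


@dataclass
class ExpressionCompendium:
    """A gene x sample expression matrix (TPM unless flagged raw counts).

    ``values`` is a DataFrame indexed by gene id with one column per
    sample id, in the same order as ``samples``.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    is_tpm: bool = True

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dup}")
        if list(self.values.columns) != ids:
            raise ValueError("matrix columns do not match the sample metadata order")
        if self.values.index.duplicated().any():
            dup = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise FormatError(f"duplicate gene id(s): {dup}")
        if self.values.isna().any().any():
            raise FormatError("missing values are not allowed in an expression matrix")
        neg = self.values.lt(0)
        if neg.any().any():
            gene = self.values.index[neg.any(axis=1)][0]
            col = self.values.columns[neg.any(axis=0)][0]
            raise FormatError(f"negative value at gene {gene!r}, sample {col!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class AlignmentHit:
    """One plus-strand local alignment between a query and a subject.

    Spans are 1-based inclusive, the tabular-hit convention;
    ``alignment_length`` counts all alignment columns including gaps.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    alignment_length: int
    identities: int
    query_length: int
    subject_length: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.identities > self.alignment_length:
            raise ValueError("identities exceed alignment length")
        if self.e_value < 0:
            raise ValueError("negative e-value")
        qs, qe = self.query_span
        ss, se = self.subject_span
        if not (1 <= qs <= qe <= self.query_length):
            raise ValueError(f"query span {self.query_span} outside 1..{self.query_length}")
        if not (1 <= ss <= se <= self.subject_length):
            raise ValueError(f"subject span {self.subject_span} outside 1..{self.subject_length}")

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identities / self.alignment_length


@dataclass(frozen=True)
class AnnotationRecord:
    """One functional-annotation row (funRiceGenes-style)."""

    target_gene_id: str
    gene_symbol: str
    function_text: str


@dataclass
class FpkmTable:
    """Target-species expression: gene id -> tissue -> FPKM."""

    values: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for gene, row in self.values.items():
            for tissue, fpkm in row.items():
                if fpkm < 0:
                    raise ValueError(f"negative FPKM for {gene!r} in {tissue!r}")

    @property
    def tissues(self) -> set[str]:
        out: set[str] = set()
        for row in self.values.values():
            out.update(row)
        return out

    def fpkm(self, gene_id: str, tissue: str) -> float:
        """FPKM of ``gene_id`` in ``tissue``; genes absent from the table count as 0."""
        if tissue not in self.tissues:
            raise KeyError(f"unknown tissue {tissue!r}; table has {sorted(self.tissues)}")
        return self.values.get(gene_id, {}).get(tissue, 0.0)


# ---------------------------------------------------------------------------
# Expression matrix + metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata {path}: missing column(s) {missing}")
    metas = [SampleMeta(**{c: row[c] for c in METADATA_COLUMNS}) for _, row in df.iterrows()]
    # each replicate group maps to exactly one (project, tissue, stage, condition)
    keys: dict[str, tuple] = {}
    for m in metas:
        prev = keys.setdefault(m.replicate_group, m.group_key)
        if prev != m.group_key:
            raise FormatError(
                f"replicate_group {m.replicate_group!r} spans distinct sample classes "
                f"{prev} and {m.group_key}"
            )
    return metas


def write_metadata(samples: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(s) for s in samples], columns=list(METADATA_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path: str | Path, meta_path: str | Path) -> ExpressionCompendium:
    """Read a gene x sample TSV plus its sample sheet into a compendium.

    The first column holds gene ids and the header row sample ids.  Every
    matrix sample must appear in the metadata; the converse is not
    required (extra metadata rows are ignored).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    metas = {m.sample_id: m for m in read_metadata(meta_path)}
    unknown = [c for c in df.columns if c not in metas]
    if unknown:
        raise FormatError(f"sample(s) {unknown} present in matrix but absent from metadata")
    ordered = [metas[c] for c in df.columns]
    return ExpressionCompendium(values=df.astype(float), samples=ordered)


def write_expression_matrix(comp: ExpressionCompendium, path: str | Path,
                            meta_path: str | Path | None = None) -> None:
    out = comp.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    if meta_path is not None:
        write_metadata(comp.samples, meta_path)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTA into ``(id, sequence)`` pairs.

    The id is the header token before the first whitespace; sequences are
    upper-cased.  Empty sequences and duplicate ids are format errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# Alignment hit tables (12-column, outfmt-6 compatible)
# ---------------------------------------------------------------------------

def write_hits_table(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column tab-separated layout, no header.

    Numbers are written at full precision so that write->read is lossless.
    The mismatch column is derived as aligned-pairs minus identities; the
    sixth column carries total gap columns (reader ignores both).
    """
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = h.query_span
            ss, se = h.subject_span
            pairs = (qe - qs + 1) + (se - ss + 1) - h.alignment_length
            gaps = h.alignment_length - pairs
            fh.write("\t".join([
                h.query_id, h.subject_id,
                f"{h.percent_identity:.12g}", str(h.alignment_length),
                str(pairs - h.identities), str(gaps),
                str(qs), str(qe), str(ss), str(se),
                f"{h.e_value:.17g}", f"{h.bit_score:.17g}",
            ]) + "\n")


def read_hits_table(path: str | Path,
                    query_lengths: Mapping[str, int],
                    subject_lengths: Mapping[str, int],
                    params=None) -> list[AlignmentHit]:
    """Parse a 12-column hit table into :class:`AlignmentHit` records.

    Sequence lengths are not part of the tabular format and must be
    supplied (typically measured from the query/database FASTA files).
    Identities are reconstructed as ``round(pident * length / 100)``.
    When ``params`` (an aligner parameter set with ``karlin_K`` and
    ``karlin_lambda``) is given, the raw score is recovered by inverting
    the bit-score formula; otherwise the rounded bit score stands in.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                q, s = parts[0], parts[1]
                pident = float(parts[2])
                length = int(parts[3])
                qstart, qend = int(parts[6]), int(parts[7])
                sstart, send = int(parts[8]), int(parts[9])
                evalue = float(parts[10])
                bits = float(parts[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed field ({exc})") from None
            if qend < qstart:
                raise FormatError(
                    f"{path}:{lineno}: q.end < q.start (minus-strand or malformed hit rejected)")
            if send < sstart:
                raise FormatError(
                    f"{path}:{lineno}: s.end < s.start (minus-strand hits are not supported)")
            if q not in query_lengths:
                raise FormatError(f"{path}:{lineno}: query {q!r} missing from query lengths")
            if s not in subject_lengths:
                raise FormatError(f"{path}:{lineno}: subject {s!r} missing from subject lengths")
            if params is not None:
                raw = int(round((bits * math.log(2) + math.log(params.karlin_K))
                                / params.karlin_lambda))
            else:
                raw = int(round(bits))
            hits.append(AlignmentHit(
                query_id=q, subject_id=s, raw_score=raw, bit_score=bits,
                e_value=evalue, alignment_length=length,
                identities=int(round(pident * length / 100.0)),
                query_length=int(query_lengths[q]), subject_length=int(subject_lengths[s]),
                query_span=(qstart, qend), subject_span=(sstart, send),
            ))
    return hits


# ---------------------------------------------------------------------------
# Generic record tables (annotation, FPKM, candidates, ...)
# ---------------------------------------------------------------------------

def write_table(records: Sequence, path: str | Path) -> None:
    """Write dataclass records of one schema as a deterministic TSV.

    Column order follows the dataclass field order; rows are sorted by the
    primary key (first field), then the remaining fields, so shuffled
    input produces a byte-identical file.  An empty list still needs a
    schema-bearing element type, so it yields a header-only file when the
    sequence is a typed empty view (``write_table.empty(cls, path)``).
    """
    if not records:
        raise ValueError("cannot infer a schema from an empty record list; "
                         "use write_empty_table(cls, path)")
    cls = type(records[0])
    names = [f.name for f in dataclasses.fields(cls)]
    rows = []
    for r in records:
        if type(r) is not cls:
            raise ValueError("records must share one schema")
        rows.append({n: _cell(getattr(r, n)) for n in names})
    df = pd.DataFrame(rows, columns=names)
    df = df.sort_values(by=names, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)


def write_empty_table(cls, path: str | Path) -> None:
    names = [f.name for f in dataclasses.fields(cls)]
    pd.DataFrame(columns=names).to_csv(path, sep="\t", index=False)


def _cell(value):
    if isinstance(value, float):
        return f"{value:.12g}"
    if isinstance(value, tuple):
        return ",".join(str(v) for v in value)
    return value


def read_annotation_table(path: str | Path) -> dict[str, AnnotationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"target_gene_id", "gene_symbol", "function_text"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation table {path}: needs columns {sorted(required)}")
    out: dict[str, AnnotationRecord] = {}
    for _, row in df.iterrows():
        gid = row["target_gene_id"]
        if gid in out:
            raise FormatError(f"annotation table {path}: duplicate target_gene_id {gid!r}")
        out[gid] = AnnotationRecord(gid, row["gene_symbol"], row["function_text"])
    return out


def write_annotation_table(records: Mapping[str, AnnotationRecord], path: str | Path) -> None:
    recs = [records[k] for k in sorted(records)]
    if recs:
        write_table(recs, path)
    else:
        write_empty_table(AnnotationRecord, path)


def read_fpkm_table(path: str | Path) -> FpkmTable:
    """Read a TSV with columns ``target_gene_id`` then one column per tissue."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dup = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"FPKM table {path}: duplicate gene id(s) {dup}")
    values = {str(g): {str(t): float(v) for t, v in row.items()} for g, row in df.iterrows()}
    return FpkmTable(values)


def write_fpkm_table(table: FpkmTable, path: str | Path) -> None:
    tissues = sorted(table.tissues)
    df = pd.DataFrame(
        [[table.values[g].get(t, 0.0) for t in tissues] for g in sorted(table.values)],
        index=sorted(table.values), columns=tissues,
    )
    df.index.name = "target_gene_id"
    df.to_csv(path, sep="\t")


def read_gene_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV ``gene_id<TAB>length_bp`` (header optional)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and not parts[1].isdigit():
                continue  # header row
            lengths[parts[0]] = int(parts[1])
    return lengths
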