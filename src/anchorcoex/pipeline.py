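"""End-to-end orchestration: QC -> averaging -> co-expression -> orthology.

Stages communicate only through the documented file formats, so any
stage can be re-run in isolation or substituted by an external tool
(e.g. a real blastn hit table via the ``hits`` input).  All randomness
flows from the single config seed, and no output embeds wall-clock
state, so a rerun with an identical config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import coexpress, orthology, qc
from .io import (AlignmentHit, ExpressionCompendium, read_annotation_table,
                 read_expression_matrix, read_fasta, read_fpkm_table,
                 read_hits_table, write_empty_table, write_expression_matrix,
                 write_table)
from .orthology import AlignerParams, GateThresholds, OrthologCandidate
from .simulate import SyntheticTruth

log = logging.getLogger("anchorcoex")


@dataclass
class PipelineConfig:
    """Everything one run needs; mirrors the CLI flags and the YAML file."""

    matrix: str
    metadata: str
    anchors: list[str]
    outdir: str
    query_fasta: str | None = None
    target_fasta: str | None = None
    fpkm: str | None = None
    annotation: str | None = None
    synteny: str | None = None
    hits: str | None = None
    peptides: str | None = None
    truth: str | None = None
    target_tissue: str = "pre-emergence inflorescence"
    min_tpm: float = 1.0
    r_min: float = 0.95
    e_max: float = 1e-3
    score_min: float = 60.0
    fpkm_min: float = 0.0
    keep_rules: dict = field(default_factory=dict)
    linkage: str = "average"
    identity_convention: str = "aligned"
    aligner: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not -1.0 <= self.r_min <= 1.0:
            raise ValueError(f"r_min must be in [-1, 1], got {self.r_min}")
        if self.min_tpm < 0:
            raise ValueError("min_tpm must be >= 0")
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")
        if not 0 < self.score_min:
            raise ValueError("score_min must be positive")
        if self.fpkm_min < 0:
            raise ValueError("fpkm_min must be >= 0")
        if not self.anchors:
            raise ValueError("at least one anchor gene id is required")
        if self.linkage not in ("average", "complete", "single"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        for name in ("matrix", "metadata", "query_fasta", "target_fasta", "fpkm",
                     "annotation", "synteny", "hits", "peptides", "truth"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    def aligner_params(self) -> AlignerParams:
        return AlignerParams(**{**self.aligner, "e_max": self.e_max})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def read_synteny_table(path: str | Path) -> dict[str, dict[str, str]]:
    """TSV with columns ``query_id``, ``species``, ``ortholog_id``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"query_id", "species", "ortholog_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"synteny table {path}: needs columns {sorted(required)}")
    out: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["query_id"], {})[row["species"]] = row["ortholog_id"]
    return out


@dataclass(frozen=True)
class _NeighbourRow:
    gene_id: str
    r: float


@dataclass(frozen=True)
class _VennRow:
    gene_id: str
    cell: str


@dataclass(frozen=True)
class _ProfileRow:
    anchor_id: str
    peak_sample_id: str
    peak_tpm: float
    n_expressed_samples: int
    expressed_samples: str


@dataclass(frozen=True)
class _QcRow:
    replicate_group: str
    status: str
    reason: str


@dataclass(frozen=True)
class _MergeRow:
    step: int
    left: str
    right: str
    height: float


@dataclass(frozen=True)
class _TruthRow:
    metric: str
    value: float


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the report directory; returns its path."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines: list[str] = [
        "anchorcoex run",
        f"seed={config.seed}",
        f"thresholds: min_tpm={config.min_tpm} r_min={config.r_min} "
        f"e_max={config.e_max} score_min={config.score_min} fpkm_min={config.fpkm_min}",
        f"linkage={config.linkage} identity_convention={config.identity_convention}",
    ]

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # --- load -------------------------------------------------------------
    comp = stage("load")(read_expression_matrix, config.matrix, config.metadata)
    lines.append(f"load: {comp.shape[0]} genes x {comp.shape[1]} samples")

    # --- replicate QC -----------------------------------------------------
    dist = stage("qc")(qc.correlation_distance_matrix, comp)
    report = stage("qc")(qc.cluster_and_flag_replicates, dist, comp.samples, config.linkage)
    groups = sorted({s.replicate_group for s in comp.samples})
    flagged = dict(report.flagged_replicate_groups)
    write_table([_QcRow(g, "flagged" if g in flagged else "pass", flagged.get(g, ""))
                 for g in groups], outdir / "qc_report.tsv")
    write_table([_MergeRow(i + 1, ";".join(sorted(m.left)), ";".join(sorted(m.right)), m.height)
                 for i, m in enumerate(report.dendrogram)], outdir / "dendrogram.tsv")
    lines.append(f"qc: {len(report.removed_sample_ids)} removed + "
                 f"{len(report.kept_sample_ids)} kept = {comp.shape[1]} samples; "
                 f"{len(flagged)} group(s) flagged")

    # --- prune + average --------------------------------------------------
    averaged = stage("average")(qc.prune_and_average, comp, config.keep_rules,
                                report.removed_sample_ids)
    write_expression_matrix(averaged, outdir / "averaged_matrix.tsv",
                            outdir / "averaged_metadata.tsv")
    lines.append(f"average: {averaged.shape[1]} replicate-group columns")

    # --- anchor profiling + peak filter ------------------------------------
    profiles = [stage("profile")(coexpress.anchor_profile, averaged, a, config.min_tpm)
                for a in config.anchors]
    write_table([_ProfileRow(p.anchor_id, p.peak_sample_id, p.peak_tpm,
                             len(p.expressed_samples), ";".join(sorted(p.expressed_samples)))
                 for p in profiles], outdir / "anchor_profiles.tsv")
    # all anchors are expected to share a peak sample; the first anchor's
    # peak defines the filter column (logged if they disagree)
    peaks = {p.peak_sample_id for p in profiles}
    if len(peaks) > 1:
        lines.append(f"warning: anchors peak in different samples {sorted(peaks)}; "
                     f"filtering on {profiles[0].peak_sample_id!r}")
    filtered, n_removed = stage("filter")(
        coexpress.filter_by_peak_expression, averaged, profiles[0], config.min_tpm)
    lines.append(f"filter: {n_removed} removed + {filtered.shape[0]} kept = "
                 f"{averaged.shape[0]} genes at peak sample {profiles[0].peak_sample_id!r}")

    # --- nearest neighbours -------------------------------------------------
    results = []
    for a in config.anchors:
        res = stage("coexpress")(coexpress.nearest_neighbours, filtered, a, config.r_min)
        results.append(res)
        rows = [_NeighbourRow(g, r) for g, r in res.neighbours]
        path = outdir / f"neighbours_{a}.tsv"
        if rows:
            write_table(rows, path)
        else:
            write_empty_table(_NeighbourRow, path)
        lines.append(f"coexpress[{a}]: {len(res.neighbours)} neighbours at r>={config.r_min} "
                     f"({res.n_genes_tested} tested, {res.n_genes_filtered_out} zero-variance)")

    venn = None
    if len(results) >= 2:
        venn = coexpress.venn_partition(results[0], results[1])
        a_id, b_id = results[0].anchor_id, results[1].anchor_id
        rows = ([_VennRow(g, f"only_{a_id}") for g in sorted(venn.only_a)]
                + [_VennRow(g, f"only_{b_id}") for g in sorted(venn.only_b)]
                + [_VennRow(g, "both") for g in sorted(venn.both)])
        if rows:
            write_table(rows, outdir / "venn.tsv")
        else:
            write_empty_table(_VennRow, outdir / "venn.tsv")
        lines.append(f"venn: only_a={len(venn.only_a)} only_b={len(venn.only_b)} "
                     f"both={len(venn.both)} union={venn.union_size}")

    coexpressed = sorted(set().union(*(r.gene_ids for r in results)))

    # --- orthology ----------------------------------------------------------
    candidates: list[OrthologCandidate] = []
    if config.fpkm is not None and config.annotation is not None and (
            config.hits is not None or
            (config.query_fasta is not None and config.target_fasta is not None)):
        params = config.aligner_params()
        queries = read_fasta(config.query_fasta) if config.query_fasta else []
        database = read_fasta(config.target_fasta) if config.target_fasta else []
        qmap = dict(queries)
        search_queries = [(g, qmap[g]) for g in coexpressed if g in qmap]
        lines.append(f"orthology: {len(search_queries)} of {len(coexpressed)} "
                     f"co-expressed genes have a CDS")
        if config.hits is not None:
            hits = stage("orthology")(
                read_hits_table, config.hits,
                {q: len(s) for q, s in queries}, {t: len(s) for t, s in database},
                params)
            wanted = set(coexpressed)
            hits = [h for h in hits if h.query_id in wanted]
        else:
            hits = stage("orthology")(orthology.local_align_search,
                                      search_queries, database, params)
        tops = orthology.top_hits_per_query(hits)
        fpkm_table = read_fpkm_table(config.fpkm)
        annotation = read_annotation_table(config.annotation)
        thresholds = GateThresholds(config.e_max, config.score_min, config.fpkm_min)
        candidates = stage("orthology")(
            orthology.gate_candidates, list(tops.values()), fpkm_table,
            config.target_tissue, annotation, thresholds)
        if config.synteny is not None:
            candidates = orthology.join_synteny(candidates, read_synteny_table(config.synteny))
        if candidates:
            write_table(candidates, outdir / "candidates.tsv")
        else:
            write_empty_table(OrthologCandidate, outdir / "candidates.tsv")
        crit123 = [c for c in candidates if c.passes_criteria_123]
        if crit123:
            write_table(crit123, outdir / "candidates_criteria123.tsv")
        else:
            write_empty_table(OrthologCandidate, outdir / "candidates_criteria123.tsv")
        n_all = sum(c.passes_all for c in candidates)
        lines.append(f"orthology: {len(hits)} hits, {len(tops)} top hits, "
                     f"{len(crit123)} pass criteria 1-3, {n_all} pass all four")

        # --- identity matrix ------------------------------------------------
        if config.peptides is not None:
            records = read_fasta(config.peptides)
            alphabet = "protein"
        else:
            # fall back to the CDS of criteria-1-3 pairs
            tmap = dict(database)
            wanted_ids = sorted({c.query_id for c in crit123} | {c.subject_id for c in crit123})
            records = [(i, qmap.get(i) or tmap.get(i)) for i in wanted_ids]
            records = [(i, s) for i, s in records if s]
            alphabet = "nucleotide"
        if len(records) >= 2:
            im = stage("identity")(orthology.percent_identity_matrix, records,
                                   config.identity_convention, alphabet)
            df = pd.DataFrame(im.values, index=im.ids, columns=im.ids)
            df.index.name = "sequence_id"
            df.round(2).to_csv(outdir / "identity_matrix.tsv", sep="\t")
            lines.append(f"identity: {len(records)} sequences, "
                         f"convention={config.identity_convention}")
        else:
            lines.append("identity: fewer than 2 sequences, matrix skipped")

    # --- truth evaluation ---------------------------------------------------
    if config.truth is not None:
        truth = SyntheticTruth.from_json(config.truth)
        rows = _evaluate_truth(truth, results, venn, candidates)
        write_table(rows, outdir / "truth_summary.tsv")
        lines.append("truth: " + " ".join(f"{r.metric}={r.value:.4g}" for r in rows))

    (outdir / "run_log.txt").write_text("\n".join(lines) + "\n")
    return outdir


def _evaluate_truth(truth: SyntheticTruth, results, venn, candidates) -> list[_TruthRow]:
    rows: list[_TruthRow] = []
    planted = truth.all_partner_ids
    if planted and results:
        found = set().union(*(r.gene_ids for r in results)) - set(truth.anchor_ids)
        tp = len(found & planted)
        rows.append(_TruthRow("partner_recall", tp / len(planted)))
        rows.append(_TruthRow("partner_precision", tp / len(found) if found else 0.0))
    if truth.shared_partner_ids and venn is not None:
        in_both = sum(1 for g in truth.shared_partner_ids if g in venn.both)
        rows.append(_TruthRow("shared_partner_in_both",
                              in_both / len(truth.shared_partner_ids)))
    if truth.ortholog_pairs and candidates:
        by_query = {c.query_id: c for c in candidates}
        full = [(q, t) for q, t, _ in truth.ortholog_pairs
                if t not in truth.truncated_target_ids and q in by_query]
        trunc = [(q, t) for q, t, _ in truth.ortholog_pairs
                 if t in truth.truncated_target_ids and q in by_query]
        if full:
            ok = sum(1 for q, t in full
                     if by_query[q].subject_id == t and by_query[q].passes_all)
            rows.append(_TruthRow("full_length_ortholog_pass_rate", ok / len(full)))
        if trunc:
            ok = sum(1 for q, t in trunc if not by_query[q].gate_score)
            rows.append(_TruthRow("truncated_ortholog_score_fail_rate", ok / len(trunc)))
        decoy_tops = sum(1 for c in candidates
                         if c.subject_id in set(truth.decoy_target_ids) and c.gate_evalue)
        rows.append(_TruthRow("decoy_top_hits_passing_evalue", float(decoy_tops)))
    return rows
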