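"""Synthetic compendia, sequence databases and target-species tables with
known ground truth.

The generator emulates the structure of a multi-project bulk RNA-seq
compendium: several projects with 2-3 replicates per distinct sample,
tissue classes spanning germination, vegetative and reproductive stages,
anchor genes expressed only inside a small reproductive-sample block
with a decaying profile peaking in one sample, co-expression partners
proportional to the anchor profile with multiplicative log-normal noise,
a majority of unrelated background genes with tissue-level zero
inflation, and (optionally) planted outlier replicates.

What it deliberately does not model: read-level sampling (no FASTQ),
library-size or GC biases, and the exact sample counts of any real
project.  Noise is multiplicative log-normal per cell, which keeps
values non-negative and makes TPM noise roughly scale-free.  Zero
inflation is applied per (gene, replicate group) to background genes
only: a silent gene is silent in all replicates of a sample, which is
the biologically coherent reading and keeps the generator's planted
guarantees (replicate coherence, partner correlations) intact.

Everything is a pure function of the config seed: identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionCompendium, SampleMeta, AnnotationRecord, FpkmTable

_PROJECT_NAMES = ("germination", "meiosis", "vegetative")
_GERM_STAGES = ("0h", "8h", "16h", "24h", "40h", "48h")
_MEIOSIS_STAGES = ("pre-meiosis", "leptotene-zygotene", "pachytene-diplotene",
                   "metaphase-tetrad")

DEFAULT_TARGET_TISSUE = "pre-emergence inflorescence"


@dataclass(frozen=True)
class CompendiumConfig:
    """Knobs of the expression-compendium generator.

    ``anchor_block`` indexes distinct samples (replicate groups), not
    replicate columns; ``peak_sample`` must be a member of the block.
    ``noise_sd`` is the standard deviation, on the natural-log scale, of
    the multiplicative per-cell noise.
    """

    n_projects: int = 3
    samples_per_project: int = 6
    replicates: int = 3
    n_background_genes: int = 500
    n_anchors: int = 2
    partners_per_anchor: int = 5
    shared_partners: int = 2
    anchor_block: tuple[int, ...] = (7, 8, 9, 10)
    peak_sample: int = 9
    anchor_peak_tpm: float = 200.0
    noise_sd: float = 0.15
    zero_inflation: float = 0.3
    n_outlier_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        n_samples = self.n_projects * self.samples_per_project
        if self.replicates not in (2, 3):
            raise ValueError("replicates must be 2 or 3")
        if self.shared_partners > self.partners_per_anchor:
            raise ValueError("shared_partners cannot exceed partners_per_anchor")
        if not self.anchor_block:
            raise ValueError("anchor_block must be non-empty")
        if max(self.anchor_block) >= n_samples or min(self.anchor_block) < 0:
            raise ValueError(
                f"anchor_block {self.anchor_block} outside 0..{n_samples - 1}")
        if self.peak_sample not in self.anchor_block:
            raise ValueError("peak_sample must lie inside anchor_block")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must be a probability")
        if self.n_anchors < 1:
            raise ValueError("need at least one anchor")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every synthetic fixture."""

    anchor_ids: list[str] = field(default_factory=list)
    partner_ids: dict[str, list[str]] = field(default_factory=dict)
    shared_partner_ids: list[str] = field(default_factory=list)
    outlier_sample_ids: list[str] = field(default_factory=list)
    ortholog_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    truncated_target_ids: list[str] = field(default_factory=list)
    decoy_target_ids: list[str] = field(default_factory=list)

    @property
    def all_partner_ids(self) -> set[str]:
        out: set[str] = set()
        for ids in self.partner_ids.values():
            out.update(ids)
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["ortholog_pairs"] = [tuple(p) for p in raw.get("ortholog_pairs", [])]
        return cls(**raw)


# ---------------------------------------------------------------------------
# Expression compendium
# ---------------------------------------------------------------------------

def _sample_sheet(cfg: CompendiumConfig) -> list[SampleMeta]:
    """Distinct samples (one per replicate group), project by project."""
    metas: list[SampleMeta] = []
    seen: set[str] = set()
    for p in range(cfg.n_projects):
        project = _PROJECT_NAMES[p] if p < len(_PROJECT_NAMES) else f"project{p + 1}"
        for s in range(cfg.samples_per_project):
            if project == "germination":
                tissue, stage, cond = "scutellum", _GERM_STAGES[s % len(_GERM_STAGES)], "control"
            elif project == "meiosis":
                tissue = "anther" if s < cfg.samples_per_project // 2 else "meiocyte"
                stage, cond = _MEIOSIS_STAGES[s % len(_MEIOSIS_STAGES)], "control"
            else:
                tissue = ("root", "shoot", "leaf")[s % 3]
                stage = "vegetative"
                cond = "control" if s < cfg.samples_per_project // 2 else "heat"
            group = f"{project}.{tissue}.{stage}.{cond}"
            if group in seen:  # disambiguate if the cycling collides
                group = f"{group}.{s}"
            seen.add(group)
            metas.append(SampleMeta(group, project, tissue, stage, group, cond))
    return metas


def _block_shape(cfg: CompendiumConfig, n_samples: int) -> np.ndarray:
    """Canonical anchor profile over distinct samples: a decaying peak
    inside the block, trace-level (< 1 TPM) expression elsewhere."""
    shape = np.full(n_samples, 2.5e-4)  # ~0.05 TPM after peak scaling
    for idx in cfg.anchor_block:
        shape[idx] = np.exp(-0.8 * abs(idx - cfg.peak_sample))
    return shape


def simulate_compendium(cfg: CompendiumConfig = CompendiumConfig()
                        ) -> tuple[ExpressionCompendium, SyntheticTruth]:
    """Generate a TPM compendium with planted anchors, partners and outliers.

    All anchors are scale variants of one canonical block profile, so
    with the default noise the anchor-anchor correlation sits near 0.99
    (mirroring a pair of paralogous anchors), and with ``noise_sd = 0``
    every planted partner - including shared ones - correlates with every
    anchor at exactly r = 1.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = _sample_sheet(cfg)
    n_groups = len(groups)
    shape = _block_shape(cfg, n_groups)

    gene_ids: list[str] = []
    base_rows: list[np.ndarray] = []
    truth = SyntheticTruth()

    # anchors: peak base value 1.3x the nominal peak TPM so the realised
    # (noisy, replicate-averaged) peak stays above it
    peak_base = 1.3 * cfg.anchor_peak_tpm
    for a in range(cfg.n_anchors):
        aid = f"ANCHOR_{a + 1}"
        truth.anchor_ids.append(aid)
        truth.partner_ids[aid] = []
        gene_ids.append(aid)
        base_rows.append((1.0 + 0.5 * a) * peak_base * shape)

    for k in range(cfg.shared_partners):
        pid = f"PARTNER_SHARED_{k + 1}"
        truth.shared_partner_ids.append(pid)
        gene_ids.append(pid)
        scale = float(np.exp(rng.normal(0.0, 0.7)))
        base_rows.append(scale * peak_base * shape)
        for aid in truth.anchor_ids:
            truth.partner_ids[aid].append(pid)
    n_specific = cfg.partners_per_anchor - cfg.shared_partners
    for a, aid in enumerate(truth.anchor_ids):
        for k in range(n_specific):
            pid = f"PARTNER_A{a + 1}_{k + 1}"
            truth.partner_ids[aid].append(pid)
            gene_ids.append(pid)
            scale = float(np.exp(rng.normal(0.0, 0.7)))
            base_rows.append(scale * peak_base * shape)

    # background: gene-level mean x per-(gene, group) tissue effect
    mu = rng.normal(np.log(30.0), 1.5, size=cfg.n_background_genes)
    eps = rng.normal(0.0, 0.8, size=(cfg.n_background_genes, n_groups))
    bg = np.exp(mu[:, None] + eps)
    silent = rng.random((cfg.n_background_genes, n_groups)) < cfg.zero_inflation
    bg[silent] = 0.0
    for g in range(cfg.n_background_genes):
        gene_ids.append(f"BG_{g + 1:04d}")
        base_rows.append(bg[g])

    base = np.vstack(base_rows)  # genes x distinct samples

    # expand to replicate columns with multiplicative log-normal noise
    cols: list[np.ndarray] = []
    metas: list[SampleMeta] = []
    for s, gm in enumerate(groups):
        for r in range(cfg.replicates):
            noise = (np.exp(rng.normal(0.0, cfg.noise_sd, size=base.shape[0]))
                     if cfg.noise_sd > 0 else np.ones(base.shape[0]))
            cols.append(base[:, s] * noise)
            metas.append(SampleMeta(f"{gm.replicate_group}.r{r + 1}", gm.project,
                                    gm.tissue, gm.stage, gm.replicate_group, gm.condition))
    mat = np.column_stack(cols)

    # planted outliers: a gene-permuted copy of an unrelated sample's profile,
    # confined to non-block groups so the planted co-expression signal survives
    non_block = [s for s in range(n_groups) if s not in cfg.anchor_block]
    if cfg.n_outlier_replicates > len(non_block):
        raise ValueError("more outlier replicates requested than non-block groups")
    victim_groups = rng.choice(len(non_block), size=cfg.n_outlier_replicates, replace=False)
    for vg in victim_groups:
        s = non_block[int(vg)]
        rep = int(rng.integers(cfg.replicates))
        col = s * cfg.replicates + rep
        others = [u for u in range(n_groups) if u != s]
        src = others[int(rng.integers(len(others)))]
        mat[:, col] = rng.permutation(base[:, src])
        truth.outlier_sample_ids.append(metas[col].sample_id)

    values = pd.DataFrame(mat, index=gene_ids, columns=[m.sample_id for m in metas])
    return ExpressionCompendium(values=values, samples=metas), truth


# ---------------------------------------------------------------------------
# Sequence database
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    out = list(seq)
    hit = rng.random(len(seq)) < divergence
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[int(rng.integers(3))]
    return "".join(out)


def simulate_sequence_db(n_orthologs: int = 10, n_decoys: int = 50,
                         divergence: float = 0.10, partial_fraction: float = 0.2,
                         seed: int = 0, query_ids: Sequence[str] | None = None,
                         length_range: tuple[int, int] = (450, 750),
                         truncate_to: float = 0.5
                         ) -> tuple[list[tuple[str, str]], list[tuple[str, str]], SyntheticTruth]:
    """Query CDS set plus a target database of planted orthologs and decoys.

    Each ortholog target is its query mutated i.i.d. per site at rate
    ``divergence``; a ``partial_fraction`` of them are truncated to
    ``truncate_to`` of the query length (default 50%, i.e. below the 60%
    length-coverage gate).  Decoys are i.i.d. uniform nucleotide
    sequences of comparable length.
    """
    for name, p in (("divergence", divergence), ("partial_fraction", partial_fraction),
                    ("truncate_to", truncate_to)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be a probability, got {p}")
    if query_ids is not None:
        query_ids = list(query_ids)
        n_orthologs = len(query_ids)
    rng = np.random.default_rng(seed)
    queries: list[tuple[str, str]] = []
    targets: list[tuple[str, str]] = []
    truth = SyntheticTruth()
    n_partial = int(round(partial_fraction * n_orthologs))
    partial_idx = set(rng.choice(n_orthologs, size=n_partial, replace=False).tolist()) \
        if n_partial else set()
    for i in range(n_orthologs):
        qid = query_ids[i] if query_ids is not None else f"Q{i + 1:04d}"
        tid = f"T{i + 1:04d}"
        qlen = int(rng.integers(length_range[0], length_range[1] + 1))
        qseq = _random_seq(rng, qlen)
        tseq = _mutate(rng, qseq, divergence)
        if i in partial_idx:
            tseq = tseq[: int(truncate_to * qlen)]
            truth.truncated_target_ids.append(tid)
        queries.append((qid, qseq))
        targets.append((tid, tseq))
        truth.ortholog_pairs.append((qid, tid, divergence))
    for d in range(n_decoys):
        did = f"D{d + 1:04d}"
        dlen = int(rng.integers(length_range[0], length_range[1] + 1))
        targets.append((did, _random_seq(rng, dlen)))
        truth.decoy_target_ids.append(did)
    return queries, targets, truth


# ---------------------------------------------------------------------------
# Target-species FPKM and annotation tables
# ---------------------------------------------------------------------------

def write_synthetic_inputs(outdir: str | Path,
                           cfg: CompendiumConfig = CompendiumConfig(),
                           divergence: float = 0.10, n_decoys: int = 50,
                           partial_fraction: float = 0.2,
                           expressed_fraction: float = 1.0,
                           annotated_fraction: float = 1.0) -> Path:
    """Emit a complete, mutually consistent input set for one pipeline run.

    The sequence database uses the planted co-expression partners as
    query ids, so the co-expression stage's output feeds the orthology
    stage exactly as a real run would.  Derived generators are seeded
    deterministically from ``cfg.seed``.
    """
    from .io import write_annotation_table, write_expression_matrix, write_fasta, \
        write_fpkm_table  # local import to avoid cycles at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comp, truth = simulate_compendium(cfg)
    partner_ids = sorted(truth.all_partner_ids)
    queries, targets, seq_truth = simulate_sequence_db(
        n_decoys=n_decoys, divergence=divergence, partial_fraction=partial_fraction,
        seed=cfg.seed + 1, query_ids=partner_ids)
    truth.ortholog_pairs = seq_truth.ortholog_pairs
    truth.truncated_target_ids = seq_truth.truncated_target_ids
    truth.decoy_target_ids = seq_truth.decoy_target_ids
    fpkm, annotation = simulate_rice_tables(
        truth, expressed_fraction=expressed_fraction, seed=cfg.seed + 2,
        annotated_fraction=annotated_fraction)
    write_expression_matrix(comp, outdir / "matrix.tsv", outdir / "metadata.tsv")
    write_fasta(queries, outdir / "queries.fasta")
    write_fasta(targets, outdir / "targets.fasta")
    write_fpkm_table(fpkm, outdir / "fpkm.tsv")
    write_annotation_table(annotation, outdir / "annotation.tsv")
    truth.to_json(outdir / "truth.json")
    return outdir


def simulate_rice_tables(truth: SyntheticTruth, expressed_fraction: float = 1.0,
                         seed: int = 0, annotated_fraction: float = 1.0,
                         target_tissue: str = DEFAULT_TARGET_TISSUE
                         ) -> tuple[FpkmTable, dict[str, AnnotationRecord]]:
    """FPKM and functional-annotation tables over the planted targets.

    Exactly ``floor(expressed_fraction * n)`` planted targets receive an
    FPKM > 0 in ``target_tissue``; likewise ``floor(annotated_fraction *
    n)`` receive an annotation record.  Decoys get random expression but
    never annotation.
    """
    for name, p in (("expressed_fraction", expressed_fraction),
                    ("annotated_fraction", annotated_fraction)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be a probability, got {p}")
    rng = np.random.default_rng(seed)
    planted = [t for _, t, _ in truth.ortholog_pairs]
    n_expr = int(np.floor(expressed_fraction * len(planted)))
    n_ann = int(np.floor(annotated_fraction * len(planted)))
    expressed = set(np.array(planted)[rng.choice(len(planted), n_expr, replace=False)]) \
        if planted and n_expr else set()
    annotated = list(np.array(planted)[np.sort(rng.choice(len(planted), n_ann, replace=False))]) \
        if planted and n_ann else []
    values: dict[str, dict[str, float]] = {}
    for t in planted:
        values[t] = {
            target_tissue: float(np.exp(rng.normal(1.0, 1.0))) if t in expressed else 0.0,
            "leaf": float(np.exp(rng.normal(0.0, 1.0))),
        }
    for d in truth.decoy_target_ids:
        values[d] = {
            target_tissue: float(np.exp(rng.normal(0.0, 1.0))) if rng.random() < 0.5 else 0.0,
            "leaf": float(np.exp(rng.normal(0.0, 1.0))),
        }
    annotation = {
        t: AnnotationRecord(t, f"OsGene{i + 1}",
                            "synthetic functional description for a planted orthologue")
        for i, t in enumerate(annotated)
    }
    return FpkmTable(values), annotation
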