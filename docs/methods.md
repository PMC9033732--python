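# Methods

This note records the models, parameter choices and numerical decisions
behind `anchorcoex`, and what the synthetic benchmarks do and do not
demonstrate.

## Expression units and normalisation

Input matrices are gene × sample and dense; missing values are rejected
rather than imputed because TPM matrices are dense by construction.
`tpm_from_counts` normalises per sample: the read rate `c_g/ℓ_g`
(counts over transcript length in bp) is rescaled so each column sums
to 10⁶. One length per gene id is taken as given; multi-transcript
genes must be resolved to an effective length upstream. Column sums are
guaranteed to 10⁻⁶ relative tolerance, and tested.

## Replicate QC

Samples are clustered agglomeratively on `d = 1 − r` (Pearson, over all
genes, raw TPM). Average linkage is the default — it is the common
default for correlation distances — with complete and single selectable.
The linkage is implemented directly (Lance–Williams recurrences) so the
tie rule is explicit: at equal merge distances, the pair with the
smallest creation-order cluster indices merges first. scipy's
implementation serves as an independent oracle in the tests, not as the
engine.

"Replicates cluster together" is formalised as *exclusive subtree
membership*: a replicate group passes iff some dendrogram node's leaf
set equals exactly that group. This is the strictest reading that is
decidable on a dendrogram. Singleton groups are exempt. A failing group
is removed wholesale — a stray replicate taints the group mean — and the
kept/removed partition always conserves the sample count.

Correlations for QC are computed on raw TPM (matching the common
heatmap-tool workflow); `log2(TPM+1)` is available behind a flag but off
by default. Which gene set feeds QC is configurable; the default is all
genes.

After QC, declarative allow/deny rules over (project, tissue, stage,
condition) prune samples — e.g. a deny rule on intermediate germination
stages keeps only the 8 h and 48 h time points — and surviving replicate
groups collapse to their arithmetic mean column, keyed by replicate
group, which makes averaging idempotent.

## Co-expression

The anchor's peak sample is the arg-max of its replicate-averaged row
(ties: first sample). The expression filter removes genes strictly
below 1 TPM *in the anchor's peak sample*; exactly 1.0 survives, per the
"below one TPM is removed" rule. When several anchors are profiled the
first anchor's peak column defines the filter (the motivating anchors
share their peak; a disagreement is logged). The averaged column is
used, not any single replicate.

Nearest neighbours are genes with Pearson `r ≥ 0.95` (inclusive)
against the anchor row on raw TPM of replicate-averaged columns;
log-space correlation is available behind a flag. Zero-variance genes
are skipped with a count rather than erroring: zero-inflated compendia
make them common and they carry no correlation signal. The anchor is
excluded from its own list. Multi-anchor Venn partitions are pairwise;
k-anchor partitions compose from repeated pairwise calls.

## Orthologue triage

The local search is a seeded aligner in the blastn mould: exact 11-mer
seeds located by hashing the database, seed diagonals clustered (gap
> 2×band_pad starts a new cluster), and each cluster extended by
affine-gap Smith–Waterman restricted to a diagonal band (default pad 16
around the seed diagonals; a band wide enough to cover the matrix makes
the DP exhaustive, which is how the oracle tests drive it). Scoring is
the classic nucleotide set +2/−3, gap open 5, extend 2, where a gap of
length L costs `open + L·extend`; `N` never matches. Significance uses
`E = K·m·n·e^(−λS)` with m the query length, n the total database
length, and pinned `K = 0.41`, `λ = 0.625` (the published constants for
this scoring set); no edge-effect correction is applied. Pinning the
constants makes E-values exactly reproducible without an external tool.
A Monte-Carlo null test checks calibration: random 200-nt queries
against unrelated databases produce no `E ≤ 10⁻³` hit in ≥95% of trials.

Per query only the single top hit is retained (minimal E-value, ties by
maximal raw score then lexicographic subject id — the ordering is a
declared convention, not an inference), even when a second hit would
pass every gate. The alignment score is the length-coverage percentage
`100 · alignment_length / query_length`, where alignment length counts
all columns including gaps, so gapped alignments can exceed 100%; no
capping. Gate strictness: `E ≤ 10⁻³` inclusive ("maximum E-value"),
score strictly > 60, FPKM strictly > 0, annotation presence boolean.
All four gates are recorded independently, so the criteria-1–3 superset
is always recoverable alongside the all-four set.

Minus-strand hit rows (`s.start > s.end`) in external hit tables are
rejected, not reverse-complemented: CDS-vs-CDS comparison is
plus-strand, and failing loudly beats guessing.

Percent-identity matrices come from global affine-gap alignments
(BLOSUM62, gap open 10 / extend 1 for proteins). Because published
identity tables do not always state their denominator, both conventions
are implemented: identical columns over columns where both sequences
have residues (default), or over all alignment columns; the choice is a
config field and is logged.

## Synthetic data: what it emulates and what it does not

The generator mimics a multi-project compendium: 3 projects × 6 distinct
samples × 3 replicates (54 columns) spanning germination, reproductive
and vegetative/stress classes; 500 background genes; 2 anchors; 5
partners per anchor of which 2 are shared. Anchors are scale variants
of one canonical profile that decays exponentially away from a peak
inside a four-sample reproductive block (peak ≈ 200 TPM, trace level
< 1 TPM outside the block). Partners are positive multiples of that
profile. Noise is multiplicative log-normal per cell with σ = 0.15 on
the log scale — preserving non-negativity and roughly scale-free TPM
noise; a 15% per-replicate noise level is an ordinary magnitude for
bulk RNA-seq on well-expressed genes, and replicate averaging is what
lifts the partner correlations above the 0.95 cut. Background genes get
a gene-level log-normal mean (ln 30 ± 1.5) plus a per-(gene, group)
tissue effect (σ = 0.8), so replicates cohere while groups separate.
Zero inflation (default 0.3) silences background genes per (gene,
group): per-cell zeros would break replicate coherence and planted
correlations, contradicting the generator's stated guarantees. Outlier
replicates are gene-permuted copies of an unrelated sample's profile —
breaking coherence under any linkage, unlike merely amplified noise —
and are confined to non-block groups so the planted co-expression
signal survives.

Because all anchors share one canonical shape, every planted partner
correlates with every anchor; anchor-specific versus shared partner
labels are bookkeeping for the Venn check, and under noise the
exclusive Venn cells are populated by near-threshold fluctuations. With
`noise_sd = 0` all partner–anchor correlations are exactly 1.

Sequence fixtures: queries are uniform random CDS-length nucleotide
sequences (450–750 nt); orthologue targets are per-site i.i.d.
substitutions at the configured divergence (default 0.10); a configured
fraction (default 20%) is truncated to 50% of the query to exercise the
score gate; decoys are uniform i.i.d. sequences, which makes their
E-value behaviour analytically predictable. FPKM/annotation tables mark
exactly `⌊fraction·n⌋` planted targets expressed/annotated.

Passing these benchmarks shows the machinery is correct under its own
assumptions — proportional partner profiles, substitution-only
divergence, clean replicate structure. It does not show robustness to
batch effects, indel-rich divergence, paralogue confusion or shallow
libraries, none of which the generator models.

## Problem sizes and numerics

The default test and acceptance runs use 20 generator seeds, 510-gene ×
54-sample compendia, and 10-orthologue/50-decoy databases — sizes at
which every stage's exhaustive oracle (full-matrix DP, brute-force
enumeration, scipy linkage) is also cheap to run. Floating-point
matrices round-trip exactly through TSV (shortest-repr writing,
round-trip parsing); hit tables are written at 17 significant digits so
write→read is lossless. All randomness flows from one integer seed per
generator call; the pipeline embeds no wall-clock state, so a rerun
with the same config is byte-identical.

## Known limitations

- The Karlin–Altschul statistics use fixed constants and no edge-effect
  or length-adjustment corrections; E-values are reproducible but only
  approximate those of a full BLAST implementation.
- The seeded aligner requires one exact 11-mer seed; very short or very
  diverged homologies (< ~70% identity) can be missed, as with blastn
  defaults.
- Translated searches, strand handling and GTF-based length derivation
  are out of scope by design.
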