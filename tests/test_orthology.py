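"""Local search, E-values, the four-criterion gate and identity matrices."""

import numpy as np
import pytest
from Bio import Align

from anchorcoex import (AlignerParams, AlignmentHit, AnnotationRecord, FpkmTable,
                        GateThresholds, alignment_score, evalue, gate_candidates,
                        join_synteny, local_align_search, pairwise_identity,
                        percent_identity_matrix, select_top_hit, simulate_rice_tables,
                        simulate_sequence_db, smith_waterman, top_hits_per_query)
from anchorcoex.simulate import _random_seq

TISSUE = "pre-emergence inflorescence"


def biopython_local_aligner(p: AlignerParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = p.match
    aligner.mismatch_score = p.mismatch
    aligner.open_gap_score = -(p.gap_open + p.gap_extend)
    aligner.extend_gap_score = -p.gap_extend
    return aligner


def make_hit(query_id="q", subject_id="s", e_value=1e-10, raw_score=100,
             alignment_length=700, query_length=1000):
    return AlignmentHit(query_id=query_id, subject_id=subject_id, raw_score=raw_score,
                        bit_score=float(raw_score), e_value=e_value,
                        alignment_length=alignment_length,
                        identities=alignment_length,
                        query_length=query_length, subject_length=2000,
                        query_span=(1, min(alignment_length, query_length)),
                        subject_span=(1, alignment_length))


class TestLocalSearch:
    def test_identical_subject_is_the_best_hit(self, rng):
        query = _random_seq(rng, 200)
        database = [("planted", query)] + [
            (f"bg{i}", _random_seq(rng, 200)) for i in range(5)]
        hits = local_align_search([("q", query)], database)
        best = hits[0]
        assert best.subject_id == "planted"
        assert best.alignment_length == 200
        assert best.identities == 200
        assert best.query_span == (1, 200) and best.subject_span == (1, 200)

    def test_random_queries_rarely_hit_at_1e_minus_3(self):
        # Monte-Carlo under the null: the Karlin-Altschul cutoff must make
        # chance hits rare
        params = AlignerParams()
        rng = np.random.default_rng(0)
        no_hit = 0
        for _ in range(100):
            q = [("q", _random_seq(rng, 200))]
            db = [(f"s{i}", _random_seq(rng, 300)) for i in range(20)]
            if not local_align_search(q, db, params):
                no_hit += 1
        assert no_hit >= 95

    def test_banded_score_never_exceeds_full_matrix(self, rng):
        params = AlignerParams()
        for _ in range(20):
            a = _random_seq(rng, int(rng.integers(15, 40)))
            b = _random_seq(rng, int(rng.integers(15, 40)))
            full = smith_waterman(a, b, params)
            banded = smith_waterman(a, b, params, diag_lo=-3, diag_hi=3)
            if banded is not None:
                assert full is not None
                assert banded.score <= full.score

    def test_n_bases_never_match(self):
        params = AlignerParams(word_size=4)
        aln = smith_waterman("ACGTNNNN", "ACGTNNNN", params)
        assert aln.identities == 4  # only the ACGT prefix counts

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            local_align_search([("q", "ACGTACGTACGTACGT")], [])

    def test_query_shorter_than_word_rejected(self):
        with pytest.raises(ValueError, match="word size"):
            local_align_search([("q", "ACGT")], [("s", "ACGTACGTACGTACGT")])


class TestEvalue:
    def test_strictly_decreasing_in_score(self):
        p = AlignerParams()
        es = [evalue(s, 500, 10000, p) for s in range(30, 40)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_doubling_database_doubles_evalue(self):
        p = AlignerParams()
        assert evalue(50, 500, 20000, p) == pytest.approx(2 * evalue(50, 500, 10000, p))


class TestTopHit:
    def test_lowest_evalue_wins(self):
        hits = [make_hit(e_value=1e-9), make_hit(subject_id="t", e_value=1e-50)]
        assert select_top_hit(hits).subject_id == "t"

    def test_equal_evalue_breaks_on_raw_score(self):
        hits = [make_hit(subject_id="lo", e_value=1e-9, raw_score=80),
                make_hit(subject_id="hi", e_value=1e-9, raw_score=90)]
        assert select_top_hit(hits).subject_id == "hi"

    def test_empty_gives_none(self):
        assert select_top_hit([]) is None

    def test_matches_sort_then_take_first(self, rng):
        for _ in range(50):
            hits = [make_hit(subject_id=f"s{i}",
                             e_value=float(rng.choice([1e-9, 1e-20, 1e-50])),
                             raw_score=int(rng.integers(50, 100)))
                    for i in range(int(rng.integers(1, 8)))]
            expected = sorted(hits, key=lambda h: (h.e_value, -h.raw_score, h.subject_id))[0]
            assert select_top_hit(hits) == expected

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError):
            select_top_hit([make_hit(query_id="a"), make_hit(query_id="b")])


class TestAlignmentScore:
    @pytest.mark.parametrize("length,qlen,expected", [
        (600, 1000, 60.0), (1000, 1000, 100.0), (110, 100, 110.0)])
    def test_formula(self, length, qlen, expected):
        assert alignment_score(length, qlen) == pytest.approx(expected)

    def test_sixty_percent_fails_the_strict_gate(self):
        assert not alignment_score(600, 1000) > 60.0

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            alignment_score(0, 100)
        with pytest.raises(ValueError):
            alignment_score(100, 0)


class TestGates:
    def _tables(self, fpkm=10.0, annotated=True):
        table = FpkmTable({"s": {TISSUE: fpkm, "leaf": 1.0}})
        ann = {"s": AnnotationRecord("s", "OsX", "does something")} if annotated else {}
        return table, ann

    def test_fully_passing_candidate(self):
        table, ann = self._tables()
        (c,) = gate_candidates([make_hit()], table, TISSUE, ann)
        assert c.passes_all
        assert (c.gate_evalue, c.gate_score, c.gate_fpkm, c.gate_annotation) == (
            True, True, True, True)

    def test_score_exactly_60_fails_gate(self):
        table, ann = self._tables()
        (c,) = gate_candidates([make_hit(alignment_length=600, query_length=1000)],
                               table, TISSUE, ann)
        assert c.alignment_score_pct == pytest.approx(60.0)
        assert not c.gate_score and not c.passes_all

    def test_zero_fpkm_passes_only_criteria_one_and_two(self):
        table, ann = self._tables(fpkm=0.0)
        (c,) = gate_candidates([make_hit()], table, TISSUE, ann)
        assert c.gate_evalue and c.gate_score
        assert not c.gate_fpkm and not c.passes_criteria_123 and not c.passes_all

    def test_missing_annotation_fails_only_gate_four(self):
        table, ann = self._tables(annotated=False)
        (c,) = gate_candidates([make_hit()], table, TISSUE, ann)
        assert c.passes_criteria_123 and not c.passes_all

    def test_criteria123_set_contains_all_pass_set(self, rng):
        hits = [make_hit(query_id=f"q{i}", subject_id="s",
                         e_value=float(rng.choice([1e-9, 1e-2])),
                         alignment_length=int(rng.integers(400, 1100)))
                for i in range(30)]
        table, ann = self._tables(annotated=bool(rng.integers(2)))
        cands = gate_candidates(hits, table, TISSUE, ann)
        n_123 = sum(c.passes_criteria_123 for c in cands)
        n_all = sum(c.passes_all for c in cands)
        assert n_123 >= n_all
        for c in cands:
            assert c.passes_all == (c.gate_evalue and c.gate_score
                                    and c.gate_fpkm and c.gate_annotation)

    def test_unknown_tissue_rejected(self):
        table, ann = self._tables()
        with pytest.raises(KeyError, match="shoot"):
            gate_candidates([make_hit()], table, "shoot", ann)

    def test_planted_ortholog_passes_end_to_end(self):
        queries, targets, truth = simulate_sequence_db(
            n_orthologs=3, n_decoys=5, divergence=0.05, partial_fraction=0.0, seed=21)
        tops = top_hits_per_query(local_align_search(queries, targets))
        fpkm, ann = simulate_rice_tables(truth, seed=22)
        cands = gate_candidates(list(tops.values()), fpkm, TISSUE, ann)
        assert len(cands) == 3
        assert all(c.passes_all for c in cands)


class TestIdentityMatrix:
    def test_identical_sequences_are_100(self):
        assert pairwise_identity("MKV", "MKV") == pytest.approx(100.0)

    def test_single_deletion_under_both_conventions(self):
        assert pairwise_identity("ACDEFG", "ACDFG", "aligned") == pytest.approx(100.0)
        assert pairwise_identity("ACDEFG", "ACDFG", "all_columns") == pytest.approx(500 / 6)

    def test_matrix_symmetric_with_unit_diagonal(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        recs = [(f"p{i}", "".join(rng.choice(aa, size=30))) for i in range(4)]
        im = percent_identity_matrix(recs)
        assert np.allclose(im.values, im.values.T)
        assert np.allclose(np.diag(im.values), 100.0)

    def test_values_invariant_under_input_order(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        recs = [(f"p{i}", "".join(rng.choice(aa, size=25))) for i in range(4)]
        im1 = percent_identity_matrix(recs)
        im2 = percent_identity_matrix(recs[::-1])
        for a in im1.ids:
            for b in im1.ids:
                assert im1.identity(a, b) == pytest.approx(im2.identity(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MKV")


class TestSynteny:
    def test_present_absent_and_idempotent(self):
        table, ann = FpkmTable({"s": {TISSUE: 1.0}}), {}
        cands = gate_candidates([make_hit(query_id="q1"),
                                 make_hit(query_id="q2", subject_id="s")],
                                table, TISSUE, ann)
        syn = {"q1": {"Brachypodium": "Bradi3g01901", "Sorghum": "Sb04g001650"}}
        joined = join_synteny(cands, syn)
        by_q = {c.query_id: c for c in joined}
        assert by_q["q1"].synteny == "Brachypodium=Bradi3g01901;Sorghum=Sb04g001650"
        assert by_q["q2"].synteny == "-"
        assert join_synteny(joined, syn) == joined
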