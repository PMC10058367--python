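import math

import numpy as np
import pytest

from anemotox.io_formats import PipelineConfig
from anemotox.orf_predictor import PredictedProtein
from anemotox.similarity_search import (
    AlignmentHit,
    ReferenceProtein,
    ScoringScheme,
    assign_family,
    karlin_altschul_evalue,
    search_toxin_db,
    simple_matrix,
    smith_waterman,
)
from oracles import sw_score_oracle

AA = "ACDEFGHIKLMNPQRSTVWY"


def toy_scheme():
    return ScoringScheme(matrix=simple_matrix(), gap_open=0.5, gap_extend=0.5)


class TestSmithWaterman:
    def test_identical_sequences_score_length_under_unit_matrix(self):
        hit = smith_waterman("MKVLAH", "MKVLAH", toy_scheme())
        assert hit.raw_score == 6
        assert hit.identity_pct == 100.0
        assert hit.query_span == (0, 6) and hit.subject_span == (0, 6)

    def test_nothing_aligns_locally(self):
        hit = smith_waterman("AAAA", "CCCC", toy_scheme())
        assert hit.raw_score == 0
        assert hit.query_span == (0, 0) and hit.subject_span == (0, 0)
        assert hit.identity_pct == 0.0

    def test_blosum62_affine_example_matches_oracle_value(self):
        # frozen from the recursion oracle before the DP was written
        hit = smith_waterman("HEAGAWGHEE", "PAWHEAE")
        assert hit.raw_score == 17

    def test_agrees_with_recursion_oracle_on_random_pairs(self):
        scheme = ScoringScheme()
        rng = np.random.default_rng(12)
        for _ in range(40):
            q = "".join(rng.choice(list(AA), size=int(rng.integers(1, 20))))
            s = "".join(rng.choice(list(AA), size=int(rng.integers(1, 20))))
            expected = sw_score_oracle(q, s, scheme.score, scheme.gap_open,
                                       scheme.gap_extend)
            assert smith_waterman(q, s, scheme).raw_score == int(round(max(expected, 0)))

    def test_agrees_with_biopython_aligner(self):
        """Independent cross-check against a second affine-gap implementation."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12  # open 11 + extend 1 for the first gap position
        aligner.extend_gap_score = -1
        aligner.mode = "local"
        rng = np.random.default_rng(13)
        for _ in range(15):
            q = "".join(rng.choice(list(AA), size=int(rng.integers(5, 40))))
            s = "".join(rng.choice(list(AA), size=int(rng.integers(5, 40))))
            ours = smith_waterman(q, s).raw_score
            theirs = aligner.score(q, s)
            assert ours == int(round(max(theirs, 0)))

    def test_score_symmetry_for_symmetric_matrix(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            q = "".join(rng.choice(list(AA), size=15))
            s = "".join(rng.choice(list(AA), size=12))
            assert smith_waterman(q, s).raw_score == smith_waterman(s, q).raw_score

    def test_invalid_residue_named(self):
        with pytest.raises(ValueError, match="'1'"):
            smith_waterman("MK1", "MK", toy_scheme())

    def test_identity_denominator_includes_gap_columns(self):
        # force one gap: query has an extra residue inside a perfect match
        hit = smith_waterman("MKKKKKWTTTTT", "MKKKKKTTTTT",
                             ScoringScheme(matrix=simple_matrix(match=5),
                                           gap_open=1, gap_extend=1))
        assert hit.n_columns == hit.n_identical + hit.n_mismatches + 1  # one gap col
        assert hit.identity_pct == pytest.approx(100 * hit.n_identical / hit.n_columns)


class TestEvalue:
    def test_closed_form_substitution(self):
        scheme = ScoringScheme(karlin_K=0.041, karlin_lambda=0.267)
        assert karlin_altschul_evalue(0, 100, 100, scheme) == pytest.approx(410.0)

    def test_monotone_decreasing_in_score(self):
        e = [karlin_altschul_evalue(s, 200, 1000) for s in range(0, 100, 5)]
        assert all(a > b for a, b in zip(e, e[1:]))

    def test_matches_direct_reevaluation(self):
        scheme = ScoringScheme()
        rng = np.random.default_rng(15)
        for _ in range(20):
            score = int(rng.integers(0, 300))
            m = int(rng.integers(1, 2000))
            n = int(rng.integers(1, 10**6))
            expected = scheme.karlin_K * m * n * math.exp(-scheme.karlin_lambda * score)
            got = karlin_altschul_evalue(score, m, n, scheme)
            assert abs(got - expected) <= 1e-12 * expected


def _query(pid, seq):
    return PredictedProtein(pid, pid, 1, 0, 3 * len(seq), seq, "complete")


def _db():
    return [
        ReferenceProtein("ref_a", "MKVLAHCWYPRDEFG" * 4, "fam A", "Cnidaria"),
        ReferenceProtein("ref_b", "GGSTNQHIKLMVVWY" * 4, "fam B", "Cnidaria"),
        ReferenceProtein("ref_c", "PPPLLLKKKDDDEEE" * 4, "fam C", "Arachnida"),
    ]


class TestSearch:
    def test_self_hit_is_top_with_full_identity(self, cfg):
        db = _db()
        hits = search_toxin_db([_query("q", db[0].sequence)], db, cfg)
        assert hits[0].subject_id == "ref_a"
        assert hits[0].identity_pct == 100.0
        assert hits[0].subject_family == "fam A"

    def test_evalue_cutoff_excludes_weak_hits(self):
        db = _db()
        strict = PipelineConfig(evalue_cutoff=1e-300)
        assert search_toxin_db([_query("q", db[0].sequence[:30])], db, strict) == []

    def test_taxon_filter_restricts_database(self, cfg):
        db = _db()
        hits = search_toxin_db([_query("q", db[2].sequence)], db, cfg,
                               taxon_filter="Arachnida")
        assert [h.subject_id for h in hits] == ["ref_c"]
        with pytest.raises(ValueError, match="empty"):
            search_toxin_db([_query("q", "MKVL")], db, cfg, taxon_filter="Aves")

    def test_top_hit_equals_all_pairs_bruteforce(self, cfg):
        """Two queries, three subjects: replicate the search as explicit
        all-pairs alignment plus the stated tie rules."""
        db = _db()
        queries = [_query("q1", db[0].sequence[:40]), _query("q2", db[1].sequence[:40])]
        got = search_toxin_db(queries, db, cfg)
        total = sum(len(e.sequence) for e in db)
        expected = []
        for q in queries:
            scored = []
            for entry in db:
                hit = smith_waterman(q.aa_sequence, entry.sequence,
                                     query_id=q.protein_id, subject_id=entry.id)
                ev = karlin_altschul_evalue(hit.raw_score, len(q.aa_sequence), total)
                if ev <= cfg.evalue_cutoff:
                    scored.append((-hit.raw_score, ev, entry.id))
            if scored:
                expected.append(min(scored)[2])
        assert [h.subject_id for h in got] == expected

    def test_filter_then_top_equals_top_then_filter_when_top_passes(self, cfg):
        db = _db()
        q = _query("q", db[0].sequence)
        top = search_toxin_db([q], db, cfg)[0]
        everything = search_toxin_db([q], db, PipelineConfig(evalue_cutoff=1e6),
                                     keep_all=True)
        best_then_filter = [h for h in everything[:1] if h.evalue <= cfg.evalue_cutoff]
        assert best_then_filter[0].subject_id == top.subject_id


class TestAssignFamily:
    def test_bds_family_is_neurotoxin(self):
        hit = AlignmentHit("q", "s", 10, 50.0, (0, 1), (0, 1),
                           subject_family="Sea anemone type 3 (BDS) potassium channel toxin")
        assert assign_family(hit) == (hit.subject_family, "neurotoxin")

    def test_phospholipase_is_mixed_function_enzyme(self):
        hit = AlignmentHit("q", "s", 10, 50.0, (0, 1), (0, 1),
                           subject_family="Phospholipase A2")
        assert assign_family(hit)[1] == "mixed-function enzyme"

    def test_unannotated_family_falls_into_unknown(self):
        hit = AlignmentHit("q", "s", 10, 50.0, (0, 1), (0, 1),
                           subject_family="never heard of it")
        assert assign_family(hit)[1] == "unknown"
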