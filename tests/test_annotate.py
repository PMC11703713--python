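import random

import pytest

from ighvkit.annotate import (
    align_glocal,
    assign_germline,
    annotate_and_trim,
    productivity_check,
    refine_v_end,
    trim_to_v,
)
from ighvkit.model import AlleleName, GermlineAllele, NucSeq, ReferenceDatabase

from oracles import affine_glocal_score


def _rand_flank(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestAssignGermline:
    def test_identity_on_self_over_whole_database(self, toy_db):
        for a in toy_db:
            ann = assign_germline(a.seq, toy_db)
            assert ann.best_allele == a.name
            assert ann.identity_pct == pytest.approx(100.0)

    def test_flanked_query_still_exact(self, toy_db):
        rng = random.Random(3)
        a = list(toy_db)[10]
        q = _rand_flank(rng, 20) + str(a.seq) + _rand_flank(rng, 20)
        ann = assign_germline(q, toy_db)
        assert ann.best_allele == a.name
        assert ann.identity_pct == pytest.approx(100.0)
        assert ann.query_v_start == 20
        assert ann.query_v_end == 20 + len(a.seq)

    def test_single_substitution_identity(self, toy_db):
        a = list(toy_db)[5]
        s = list(str(a.seq))
        s[150] = "A" if s[150] != "A" else "C"
        ann = assign_germline("".join(s), toy_db)
        expected = 100.0 * (len(s) - 1) / len(s)
        assert ann.identity_pct == pytest.approx(expected, abs=1e-6)
        assert ann.n_mismatch == 1

    def test_random_sequence_is_no_hit(self, toy_db):
        rng = random.Random(11)
        junk = _rand_flank(rng, 320)
        ann = assign_germline(junk, toy_db)
        assert ann.best_allele is None
        assert ann.fail_reason == "NO_HIT"

    def test_short_query_rejected(self, toy_db):
        with pytest.raises(ValueError, match="shorter"):
            assign_germline("ACGT" * 20, toy_db)

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            assign_germline("A" * 300, ReferenceDatabase("e", []))

    def test_prescreen_agrees_with_exhaustive_scoring(self, toy_db):
        rng = random.Random(23)
        for _ in range(10):
            a = rng.choice(list(toy_db))
            s = list(str(a.seq))
            for _ in range(rng.randint(0, 4)):
                i = rng.randrange(len(s))
                s[i] = rng.choice("ACGT")
            q = _rand_flank(rng, 10) + "".join(s) + _rand_flank(rng, 10)
            fast = assign_germline(q, toy_db)
            slow = assign_germline(q, toy_db, candidate_margin=None)
            assert fast.best_allele == slow.best_allele
            assert fast.score == slow.score


class TestAlignmentScoreOracle:
    def test_affine_score_matches_bruteforce_dp(self):
        rng = random.Random(41)
        for _ in range(200):
            q = _rand_flank(rng, rng.randint(5, 40))
            r = _rand_flank(rng, rng.randint(5, 40))
            assert align_glocal(q, r).score == pytest.approx(
                affine_glocal_score(q, r), abs=1e-9
            )


class TestTrimToV:
    def test_three_prime_tail_removed(self, toy_db):
        a = list(toy_db)[0]
        trimmed, ann = annotate_and_trim(str(a.seq) + "ACGTACGT", toy_db)
        assert trimmed == a.seq
        assert not ann.truncated

    def test_truncated_query_flagged(self, toy_db):
        a = list(toy_db)[0]
        trimmed, ann = annotate_and_trim(str(a.seq)[:-12], toy_db)
        assert trimmed == str(a.seq)[:-12]
        assert ann.truncated

    def test_five_prime_flank_removed_only(self, toy_db):
        a = list(toy_db)[0]
        trimmed, _ = annotate_and_trim("GGGGGGGGGG" + str(a.seq), toy_db)
        assert trimmed == a.seq

    def test_idempotent(self, toy_db):
        a = list(toy_db)[3]
        rng = random.Random(2)
        q = _rand_flank(rng, 15) + str(a.seq) + _rand_flank(rng, 15)
        once, _ = annotate_and_trim(q, toy_db)
        twice, _ = annotate_and_trim(str(once), toy_db)
        assert twice == once

    def test_no_hit_cannot_be_trimmed(self, toy_db):
        from ighvkit.annotate import VAnnotation

        with pytest.raises(ValueError):
            trim_to_v("A" * 300, VAnnotation(best_allele=None), list(toy_db)[0])


class TestProductivity:
    def test_reference_alleles_are_productive(self, toy_db):
        for a in list(toy_db)[:20]:
            trimmed, ann = annotate_and_trim(a.seq, toy_db)
            assert ann.productive, ann.fail_reason

    def test_inframe_stop_detected(self, toy_db):
        a = list(toy_db)[0]
        s = list(str(a.seq))
        s[147:150] = "TAA"  # codon 50
        trimmed, ann = annotate_and_trim("".join(s), toy_db)
        assert not ann.productive and ann.fail_reason == "STOP"

    def test_single_deletion_is_frameshift(self, toy_db):
        a = list(toy_db)[0]
        s = str(a.seq)[:140] + str(a.seq)[141:]
        trimmed, ann = annotate_and_trim(s, toy_db)
        assert not ann.productive and ann.fail_reason == "FRAMESHIFT"

    def test_codon_deletion_stays_productive(self, toy_db):
        a = list(toy_db)[0]
        s = str(a.seq)[:141] + str(a.seq)[144:]
        trimmed, ann = annotate_and_trim(s, toy_db)
        assert ann.fail_reason != "FRAMESHIFT"

    def test_ambiguous_base_detected(self, toy_db):
        a = list(toy_db)[0]
        s = str(a.seq)[:100] + "N" + str(a.seq)[101:]
        ann_seq = NucSeq(s)
        trimmed, ann = annotate_and_trim(ann_seq, toy_db)
        assert ann.fail_reason == "AMBIGUOUS_BASE"


class TestRefineVEnd:
    def test_full_alignment_untouched(self, toy_db):
        a = list(toy_db)[0]
        pa = align_glocal(str(a.seq), str(a.seq))
        assert refine_v_end(pa, str(a.seq), str(a.seq)) == (len(a.seq), len(a.seq))

    def test_junctional_tail_stripped(self, toy_db):
        # a 3'-trimmed V followed by junk: absorbed terminal mismatches must go
        a = list(toy_db)[0]
        rng = random.Random(8)
        v_part = str(a.seq)[:-4]
        q = v_part + "TTTTTTTT"
        pa = align_glocal(q, str(a.seq))
        q_end, r_end = refine_v_end(pa, q, str(a.seq))
        assert r_end <= len(v_part)
        assert q[:q_end] == v_part[:q_end]
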