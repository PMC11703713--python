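import random

import numpy as np
import pytest

from ighvkit.compare import (
    cluster_similarity,
    evidence_summary,
    jaccard,
    jaccard_matrix,
    pairwise_identity_best,
    pct,
    validation_rate,
    venn_counts,
)
from ighvkit.model import AlleleName, GermlineAllele, NucSeq, Source, SubjectCallSet

from oracles import jaccard_oracle, venn_oracle


class TestJaccard:
    def test_identical_nonempty(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_one_third(self):
        assert jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_one(self):
        assert jaccard(set(), set()) == 1.0

    def test_matches_oracle_and_symmetry(self):
        rng = random.Random(61)
        universe = [f"s{i}" for i in range(30)]
        for _ in range(100):
            a = set(rng.sample(universe, rng.randint(0, 20)))
            b = set(rng.sample(universe, rng.randint(0, 20)))
            assert jaccard(a, b) == pytest.approx(jaccard_oracle(a, b))
            assert jaccard(a, b) == jaccard(b, a)
            assert jaccard(a, a) == 1.0


class TestValidationRate:
    def test_subset_is_hundred(self):
        n, p = validation_rate({"a", "b"}, [{"a", "b", "c"}])
        assert (n, p) == (2, 100)

    def test_empty_set_reports_na(self):
        assert validation_rate(set(), [{"a"}]) == (0, None)

    @pytest.mark.parametrize(
        "num,den,expected",
        [
            (116, 197, 59),
            (143, 197, 73),
            (527, 774, 68),
            (61, 84, 73),
            (76, 92, 83),
            (25, 31, 81),
            (84, 107, 79),
            (73, 83, 88),
            (90, 92, 98),
            (97, 107, 91),
            (77, 83, 93),
        ],
    )
    def test_reported_study_scale_percentages(self, num, den, expected):
        s = {f"x{i}" for i in range(den)}
        other = {f"x{i}" for i in range(num)} | {f"y{i}" for i in range(50)}
        n, p = validation_rate(s, [other])
        assert (n, p) == (num, expected)


class TestVennCounts:
    def test_identical_pair(self):
        out = venn_counts({"A": {"a"}, "B": {"a"}})
        assert out[frozenset({"A", "B"})] == 1
        assert out[frozenset({"A"})] == 0 and out[frozenset({"B"})] == 0

    def test_disjoint_pair(self):
        out = venn_counts({"A": {"a"}, "B": {"b"}})
        assert out[frozenset({"A", "B"})] == 0
        assert out[frozenset({"A"})] == 1 and out[frozenset({"B"})] == 1

    def test_three_sets_center(self):
        out = venn_counts({"A": {"x", "a"}, "B": {"x", "b"}, "C": {"x"}})
        assert out[frozenset({"A", "B", "C"})] == 1

    def test_set_count_bounds(self):
        with pytest.raises(ValueError):
            venn_counts({"A": set()})
        with pytest.raises(ValueError):
            venn_counts({k: set() for k in "ABCDE"})

    def test_regions_sum_to_union_and_match_oracle(self):
        rng = random.Random(71)
        universe = [f"e{i}" for i in range(25)]
        for k in (2, 3, 4):
            named = {
                f"S{i}": set(rng.sample(universe, rng.randint(0, 15))) for i in range(k)
            }
            out = venn_counts(named)
            assert sum(out.values()) == len(set().union(*named.values()))
            assert out == venn_oracle(named)


class TestPairwiseIdentityBest:
    def test_exact_partner(self, toy_db):
        seqs = [str(a.seq) for a in list(toy_db)[:5]]
        out = pairwise_identity_best(seqs[:2], seqs)
        for a, b, ident in out:
            assert a == b and ident == 100.0

    def test_single_mismatch_identity(self, toy_db):
        a = list(toy_db)[0]
        s = list(str(a.seq))
        s[100] = "A" if s[100] != "A" else "C"
        ((_, best, ident),) = pairwise_identity_best(["".join(s)], [str(a.seq)])
        assert best == str(a.seq)
        assert ident == pytest.approx(100.0 * (len(s) - 1) / len(s), abs=1e-6)

    def test_empty_b_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity_best({"ACGT"}, set())


def _cs(subject, method, seqs):
    alleles = [
        GermlineAllele(AlleleName.parse(f"IGHV1-{i + 1}*01"), NucSeq(s))
        for i, s in enumerate(seqs)
    ]
    return SubjectCallSet(subject, method, alleles)


class TestEvidenceSummary:
    def test_three_methods_one_subject(self):
        seq = "ATGGCC"
        sets = [
            _cs("m1", Source.GDNA_MISEQ, [seq]),
            _cs("m1", Source.TOPO, [seq]),
            _cs("m1", Source.MRNA_INFER, [seq]),
        ]
        summ = evidence_summary(sets)
        assert summ.n_novel == 1
        assert summ.n_novel_ge2_methods == 1
        assert summ.n_novel_ge2_subjects == 0
        # gDNA and mRNA are two biological sources within one subject
        assert summ.n_novel_ge2_subjects_or_sources == 1

    def test_two_subjects_one_method_each(self):
        seq = "ATGGCC"
        sets = [
            _cs("m1", Source.TOPO, [seq]),
            _cs("m2", Source.TOPO, [seq]),
        ]
        summ = evidence_summary(sets)
        assert summ.n_novel_ge2_methods == 0
        assert summ.n_novel_ge2_subjects == 1
        assert summ.n_novel_ge2_subjects_or_sources == 1

    def test_two_gdna_routes_are_one_source(self):
        seq = "ATGGCC"
        sets = [
            _cs("m1", Source.GDNA_MISEQ, [seq]),
            _cs("m1", Source.TOPO, [seq]),
        ]
        summ = evidence_summary(sets)
        assert summ.n_novel_ge2_methods == 1
        assert summ.n_novel_ge2_subjects_or_sources == 0

    def test_reference_db_membership_disqualifies_novelty(self, toy_db):
        known = str(list(toy_db)[0].seq)
        sets = [_cs("m1", Source.TOPO, [known])]
        summ = evidence_summary(sets, [toy_db])
        assert summ.n_novel == 0 and summ.n_total == 1

    def test_permutation_invariance_against_set_algebra_oracle(self):
        rng = random.Random(91)
        pool = ["".join(rng.choice("ACGT") for _ in range(9)) for _ in range(30)]
        sets = []
        for subject in ("m1", "m2", "m3"):
            for method in (Source.GDNA_MISEQ, Source.TOPO, Source.MRNA_INFER):
                seqs = rng.sample(pool, rng.randint(1, 12))
                sets.append(_cs(subject, method, seqs))
        summ1 = evidence_summary(sets)
        shuffled = sets[:]
        rng.shuffle(shuffled)
        summ2 = evidence_summary(shuffled)
        assert summ1.n_novel == summ2.n_novel == len(
            {s for cs in sets for s in cs.seqs()}
        )
        assert summ1.n_novel_ge2_methods == summ2.n_novel_ge2_methods
        # oracle: brute-force method count per sequence
        per_seq_methods = {}
        for cs in sets:
            for s in cs.seqs():
                per_seq_methods.setdefault(str(s), set()).add(cs.method.value)
        assert summ1.n_novel_ge2_methods == sum(
            1 for v in per_seq_methods.values() if len(v) >= 2
        )


class TestClusterSimilarity:
    def test_identical_sets_cluster_first(self):
        m, labels = jaccard_matrix({"A": {"x", "y"}, "B": {"x", "y"}, "C": {"z"}})
        res = cluster_similarity(m, labels)
        assert "(A:0.000000,B:0.000000)" in res.newick

    def test_topology_pair_vs_outlier(self):
        m, labels = jaccard_matrix({"A": {"x"}, "B": {"x"}, "C": {"q", "r"}})
        res = cluster_similarity(m, labels)
        assert res.newick.startswith("((A") or "(A:0.000000,B:0.000000)" in res.newick
        assert set(res.leaf_order) == {"A", "B", "C"}

    def test_rejects_malformed_matrices(self):
        with pytest.raises(ValueError):
            cluster_similarity(np.array([[1.0, 0.5], [0.4, 1.0]]), ["a", "b"])
        with pytest.raises(ValueError):
            cluster_similarity(np.array([[0.9, 0.5], [0.5, 0.9]]), ["a", "b"])


def test_pct_round_half_up():
    assert pct(1, 8) == 13  # 12.5 rounds up
    assert pct(0, 0) is None
    assert pct(59, 100) == 59
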