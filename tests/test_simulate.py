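import json

import numpy as np
import pytest

from ighvkit.qc import merge_pair
from ighvkit.simulate import (
    SimParams,
    load_toy_db,
    load_toy_jdb,
    simulate_gdna_run,
    simulate_naive_repertoire,
    simulate_sanger_colonies,
    simulate_subject,
    toy_reference,
)


class TestToyReference:
    def test_bundled_fixtures_match_seeded_builder(self, toy_db, toy_jdb):
        v, j = toy_reference()
        assert {str(a.seq) for a in v} == {str(a.seq) for a in toy_db}
        assert {str(a.seq) for a in j} == {str(a.seq) for a in toy_jdb}

    def test_seven_families_and_anchored_js(self, toy_db, toy_jdb):
        fams = {a.name.family for a in toy_db}
        assert fams == {f"IGHV{i}" for i in range(1, 8)}
        for j in toy_jdb:
            assert j.anchor == 12
            assert str(j.seq)[12:15] == "TGG"  # conserved Trp codon

    def test_lengths_are_codon_multiples(self, toy_db):
        assert all(len(a.seq) % 3 == 0 for a in toy_db)


class TestSimulateSubject:
    def test_deterministic_given_seed(self, toy_db):
        p = SimParams(n_alleles=40, novel_fraction=0.25)
        t1 = simulate_subject(toy_db, p, seed=7)
        t2 = simulate_subject(toy_db, p, seed=7)
        assert json.dumps(t1.to_json(), sort_keys=True) == json.dumps(
            t2.to_json(), sort_keys=True
        )

    def test_zero_novel_fraction_all_from_base(self, toy_db):
        t = simulate_subject(toy_db, SimParams(n_alleles=50, novel_fraction=0.0), seed=3)
        base = toy_db.seqs()
        assert all(a.seq in base for a in t.alleles)
        assert not any(a.novel for a in t.alleles)

    def test_novel_count_rounding_rule(self, toy_db):
        t = simulate_subject(toy_db, SimParams(n_alleles=120, novel_fraction=0.2), seed=3)
        assert sum(a.novel for a in t.alleles) == 24

    def test_novel_alleles_distinct_from_base_and_protect_termini(self, toy_db):
        t = simulate_subject(
            toy_db, SimParams(n_alleles=30, novel_fraction=0.5, snp_per_novel=2), seed=9
        )
        base_by_name = {a.name.render(): a for a in toy_db}
        base_seqs = toy_db.seqs()
        for a in t.alleles:
            if not a.novel:
                continue
            assert a.seq not in base_seqs
            template = base_by_name[a.name.base().render()]
            assert str(a.seq)[:6] == str(template.seq)[:6]
            assert str(a.seq)[-6:] == str(template.seq)[-6:]

    def test_weights_form_distribution(self, small_truth):
        w = small_truth.usage_weights
        assert np.all(w >= 0) and abs(w.sum() - 1) < 1e-9

    def test_small_pool_rejected(self, toy_db):
        with pytest.raises(ValueError, match="n_alleles"):
            simulate_subject(toy_db, SimParams(n_alleles=1000), seed=1)


class TestGdnaRun:
    def test_pair_count_equals_sum_of_depths_and_ledger_conserved(self, small_truth):
        p = SimParams(n_alleles=30, depth_log_mean=2.0, per_base_error=0.0)
        run = simulate_gdna_run(small_truth, p, seed=5)
        assert len(run.pairs) == sum(run.sampled_depths.values())
        assert len(run.ledger) == len(run.pairs)
        ids = [f.id for f, _ in run.pairs]
        assert set(ids) == set(run.ledger)

    def test_error_free_pairs_merge_to_exact_amplicons(self, small_truth):
        p = SimParams(n_alleles=30, depth_log_mean=1.0, per_base_error=0.0)
        run = simulate_gdna_run(small_truth, p, seed=5)
        truth_by_name = {a.name.render(): str(a.seq) for a in small_truth.alleles}
        for fwd, rev in run.pairs[:25]:
            m = merge_pair(fwd, rev)
            assert m is not None
            inner = truth_by_name[run.ledger[fwd.id]]
            assert inner in str(m.seq)

    def test_read_length_precondition(self, small_truth):
        with pytest.raises(ValueError, match="read_len"):
            simulate_gdna_run(small_truth, SimParams(n_alleles=30, read_len=120), seed=5)

    def test_total_rescaling_target(self, small_truth):
        p = SimParams(n_alleles=30, depth_log_mean=4.0, n_read_pairs=500)
        run = simulate_gdna_run(small_truth, p, seed=6)
        assert abs(len(run.pairs) - 500) <= 60  # rounding of per-allele depths


class TestSangerRun:
    def test_all_colonies_ambiguous_at_rate_one(self, small_truth):
        p = SimParams(n_alleles=30, n_colonies=40, ambiguous_base_rate=1.0)
        run = simulate_sanger_colonies(small_truth, p, seed=4)
        assert all("N" in seq for _, seq in run.colonies)

    def test_zero_colonies_empty(self, small_truth):
        run = simulate_sanger_colonies(
            small_truth, SimParams(n_alleles=30, n_colonies=0), seed=4
        )
        assert run.colonies == [] and run.ledger == {}

    def test_zero_weight_allele_never_sampled(self, toy_db):
        t = simulate_subject(toy_db, SimParams(n_alleles=20, novel_fraction=0.0), seed=13)
        w = np.array(t.usage_weights)
        w[0] = 0.0
        w /= w.sum()
        t.usage_weights = w
        run = simulate_sanger_colonies(
            t, SimParams(n_alleles=20, n_colonies=300, ambiguous_base_rate=0.0), seed=14
        )
        banned = t.alleles[0].name.render()
        assert banned not in set(run.ledger.values())


class TestRepertoireRun:
    def test_ledger_conservation_and_truth_v(self, toy_db, toy_jdb):
        p = SimParams(n_alleles=25, novel_fraction=0.2, n_repertoire_reads=400)
        t = simulate_subject(toy_db, p, seed=17)
        run = simulate_naive_repertoire(t, toy_jdb, p, seed=18)
        assert len(run.reads) == 400
        assert {rid for rid, _ in run.reads} == set(run.ledger)
        names = {a.name.render() for a in t.alleles}
        assert all(rec["v"] in names for rec in run.ledger.values())

    def test_clean_setting_preserves_v_prefix(self, toy_db, toy_jdb):
        p = SimParams(
            n_alleles=25, novel_fraction=0.0, n_repertoire_reads=150,
            shm_rate=0.0, v_trim_max=0, j_trim_max=0, n_additions_max=0,
        )
        t = simulate_subject(toy_db, p, seed=19)
        run = simulate_naive_repertoire(t, toy_jdb, p, seed=20)
        by_name = {a.name.render(): str(a.seq) for a in t.alleles}
        for rid, seq in run.reads:
            v = by_name[run.ledger[rid]["v"]]
            assert seq[10 : 10 + len(v)] == v  # after the constant 10-nt 5' flank

    def test_cdr3_diversity_grows_with_read_count_at_high_clonality(self, toy_db, toy_jdb):
        def distinct_cdr3_per_v(n_reads):
            p = SimParams(
                n_alleles=20, novel_fraction=0.0, n_repertoire_reads=n_reads,
                clonality=1e6, shm_rate=0.0,
            )
            t = simulate_subject(toy_db, p, seed=29)
            run = simulate_naive_repertoire(t, toy_jdb, p, seed=30)
            per_v = {}
            for rec in run.ledger.values():
                per_v.setdefault(rec["v"], set()).add(rec["cdr3"])
            return np.mean([len(s) for s in per_v.values()])

        assert distinct_cdr3_per_v(2000) > distinct_cdr3_per_v(200)

    def test_deterministic(self, toy_db, toy_jdb):
        p = SimParams(n_alleles=20, n_repertoire_reads=100)
        t = simulate_subject(toy_db, p, seed=33)
        r1 = simulate_naive_repertoire(t, toy_jdb, p, seed=34)
        r2 = simulate_naive_repertoire(t, toy_jdb, p, seed=34)
        assert r1.reads == r2.reads
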