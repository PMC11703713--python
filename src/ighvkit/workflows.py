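"""End-to-end experiment workflows: simulate a subject, run a calling route,
and score the result against the simulator's ground truth.

Sensitivity and precision are always measured on exact nucleotide sequences.
For each route the sensitivity denominator is the set of truth alleles the
route could in principle observe:

* gDNA MiSeq — truth alleles whose sampled read depth cleared the relative
  depth cutoff (with errors, the error-free fraction of that depth);
* Sanger — truth alleles sampled by at least one ambiguity-free colony;
* IgM inference — truth alleles supported, among unmutated reads with
  acceptable 3' truncation, by at least the candidate thresholds (reads,
  distinct CDR3 clones, distinct Js) including one untrimmed exemplar.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np

from .calling import call_gdna_alleles, call_sanger_alleles
from .model import GermlineAllele, NucSeq, ReferenceDatabase, SubjectCallSet
from .mrna import annotate_repertoire, infer_germlines
from .qc import merge_pairs
from .simulate import (
    SimParams,
    SimTruth,
    simulate_gdna_run,
    simulate_naive_repertoire,
    simulate_sanger_colonies,
    simulate_subject,
)


@dataclass
class RouteResult:
    truth: SimTruth
    call_set: SubjectCallSet
    expected: set[NucSeq]  # truth alleles the route could observe
    called: set[NucSeq]

    @property
    def true_positives(self) -> int:
        return len(self.called & self.truth.seqs())

    @property
    def precision(self) -> float:
        return self.true_positives / len(self.called) if self.called else 1.0

    @property
    def sensitivity(self) -> float:
        if not self.expected:
            return 1.0
        return len(self.called & self.expected) / len(self.expected)


def population_pool(
    base_db: ReferenceDatabase,
    seed: int,
    novel_fraction: float = 0.25,
    snp_per_novel: int = 2,
) -> list[GermlineAllele]:
    """A population allele pool: the reference plus shared novel variants.

    Real cohorts draw their germline sets from a population in which many
    alleles are simply missing from the reference database; subjects sampled
    from the same pool therefore share novel alleles, which is what makes
    cross-subject validation informative.
    """
    from .simulate import _mutate

    rng = np.random.default_rng(seed)
    base = sorted(base_db, key=lambda a: a.name.render())
    n_novel = round(len(base) * novel_fraction)
    idx = rng.choice(len(base), size=n_novel, replace=False)
    taken = {str(a.seq) for a in base}
    pool = list(base)
    for k, i in enumerate(sorted(idx)):
        t = base[int(i)]
        for _ in range(100):
            mut = _mutate(rng, str(t.seq), snp_per_novel, protect_head=6, protect_tail=6)
            if mut not in taken:
                break
        taken.add(mut)
        pool.append(
            GermlineAllele(
                name=replace(t.name.base(), extra=f"_p{k:03d}"),
                seq=NucSeq(mut),
                sources=set(),
                novel=True,
            )
        )
    return pool


def run_gdna_route(
    base_db: ReferenceDatabase,
    params: SimParams,
    seed: int,
    subject_id: str = "S1",
    fraction: float = 0.0067,
    pool: list[GermlineAllele] | None = None,
) -> RouteResult:
    truth = simulate_subject(base_db, params, seed, subject_id=subject_id, pool=pool)
    run = simulate_gdna_run(truth, params, seed + 1)
    merged, _ = merge_pairs(run.pairs)
    cs = call_gdna_alleles(merged, base_db, subject_id=subject_id, fraction=fraction)
    cutoff = cs.tally.get("cutoff", 0.0)
    expected = {
        a.seq
        for a in truth.alleles
        if run.sampled_depths[a.name.render()] > cutoff
    }
    return RouteResult(truth, cs, expected, cs.seqs())


def run_sanger_route(
    base_db: ReferenceDatabase,
    params: SimParams,
    seed: int,
    subject_id: str = "S1",
    truth: SimTruth | None = None,
) -> RouteResult:
    if truth is None:
        truth = simulate_subject(base_db, params, seed, subject_id=subject_id)
    run = simulate_sanger_colonies(truth, params, seed + 2)
    cs = call_sanger_alleles(run.colonies, base_db, subject_id=subject_id)
    by_name = {a.name.render(): a.seq for a in truth.alleles}
    clean = {
        run.ledger[cid] for cid, seq in run.colonies if "N" not in seq
    }
    expected = {by_name[n] for n in clean}
    return RouteResult(truth, cs, expected, cs.seqs())


def mrna_eligible_truth(truth: SimTruth, ledger: dict, min_reads: int = 5,
                        min_cdr3: int = 3, min_j: int = 2,
                        max_v_truncation: int = 12) -> set[NucSeq]:
    """Truth alleles whose unmutated-read support meets the candidate thresholds."""
    support: dict[str, dict] = defaultdict(
        lambda: {"reads": 0, "cdr3": set(), "j": set(), "full": 0}
    )
    for rec in ledger.values():
        if rec["n_shm"] == 0 and rec["v_trim"] <= max_v_truncation:
            s = support[rec["v_seq"]]
            s["reads"] += 1
            s["cdr3"].add(rec["cdr3"])
            s["j"].add(rec["j"])
            if rec["v_trim"] == 0:
                s["full"] += 1
    return {
        NucSeq(seq)
        for seq, s in support.items()
        if s["reads"] >= min_reads
        and len(s["cdr3"]) >= min_cdr3
        and len(s["j"]) >= min_j
        and s["full"] >= 1
    }


def run_mrna_route(
    base_db: ReferenceDatabase,
    j_db: ReferenceDatabase,
    params: SimParams,
    seed: int,
    subject_id: str = "S1",
    truth: SimTruth | None = None,
):
    if truth is None:
        truth = simulate_subject(base_db, params, seed, subject_id=subject_id)
    run = simulate_naive_repertoire(truth, j_db, params, seed + 3)
    annotated, _ = annotate_repertoire(run.reads, base_db, j_db)
    cs = infer_germlines(annotated, base_db, subject_id=subject_id)
    expected = mrna_eligible_truth(truth, run.ledger)
    return RouteResult(truth, cs, expected, cs.seqs()), run, annotated


def structured_cohort_sets(
    base_db: ReferenceDatabase,
    seed: int,
    n_alleles: int = 50,
    pool_size: int = 90,
    n_per_pool: int = 2,
) -> dict[str, set[str]]:
    """Truth allele sets for a two-population cohort with partial pool overlap."""
    alleles = list(base_db)
    pools = {
        "P1": alleles[:pool_size],
        "P2": alleles[len(alleles) - pool_size :],
    }
    params = SimParams(n_alleles=n_alleles, novel_fraction=0.0, n_repertoire_reads=0)
    sets: dict[str, set[str]] = {}
    for p, (pname, pool) in enumerate(pools.items()):
        for k in range(n_per_pool):
            sid = f"{pname}_s{k + 1}"
            t = simulate_subject(
                base_db, params, seed + 10 * p + k, subject_id=sid, pool=pool
            )
            sets[sid] = {str(s) for s in t.seqs()}
    return sets
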