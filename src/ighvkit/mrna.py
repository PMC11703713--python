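"""Germline V inference from naive (IgM) repertoire reads.

A deliberately explicit, single-pass inference: reads are annotated with
their best V and J, grouped by assigned V and then by the exact V-region
string they carry, and a sub-group is promoted to a germline candidate only
when it is supported by enough reads, enough distinct CDR3s and enough
distinct J alleles — the diversity evidence that separates true germline
polymorphism from clonally shared somatic hypermutation. There is no
windowed consensus and no re-assignment iteration.

CDR3 is bounded by the conserved V-end Cys-containing motif (the final three
codons of the V reference) and the conserved J Trp codon (the ``anchor``
annotated on J references).
"""

from __future__ import annotations

import edlib

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .annotate import (
    MIN_QUERY_LEN,
    align_glocal,
    assign_germline,
    refine_v_end,
)
from .calling import _provisional_name
from .model import (
    AlleleName,
    GermlineAllele,
    NucSeq,
    ReferenceDatabase,
    Source,
    SubjectCallSet,
)

V_MOTIF_CODONS = 3  # terminal conserved C-x-x motif retained on V references


@dataclass
class RepertoireRead:
    """An expressed V(D)J read with assigned V/J and extracted CDR3."""

    id: str
    seq: NucSeq
    v_assign: AlleleName
    v_identity: float
    v_region: NucSeq
    v_truncation: int  # nt of reference 3' end not covered by the read
    j_assign: Optional[AlleleName] = None
    cdr3_nt: NucSeq = NucSeq("")


@dataclass
class CandidateAllele:
    consensus_seq: NucSeq
    template: AlleleName
    n_reads: int
    n_distinct_cdr3: int
    n_distinct_j: int
    is_novel: bool
    read_ids: list[str] = field(default_factory=list, repr=False)


def annotate_vdj(
    read: tuple[str, str],
    v_db: ReferenceDatabase,
    j_db: ReferenceDatabase,
    candidate_margin: Optional[int] = 3,
) -> Optional[RepertoireRead]:
    """Annotate one (id, seq) read with V, J and CDR3; None when V has no hit."""
    rid, seq = read
    seq = NucSeq(seq)
    if len(seq) < MIN_QUERY_LEN:
        return None
    ann = assign_germline(seq, v_db, candidate_margin=candidate_margin)
    if ann.best_allele is None:
        return None
    v_ref = v_db.by_name[ann.best_allele.render()]
    # junctional bases can be absorbed into the V alignment as terminal
    # mismatches; refine the V 3' end to the last clean run of matches
    refined = refine_v_end(ann.alignment, str(seq), str(v_ref.seq))
    if refined is None:
        return None
    q_end, r_end = refined
    v_region = NucSeq(seq[ann.query_v_start : q_end])
    out = RepertoireRead(
        id=rid,
        seq=seq,
        v_assign=ann.best_allele,
        v_identity=ann.identity_pct,
        v_region=v_region,
        v_truncation=len(v_ref.seq) - r_end,
    )
    # J assignment on the region 3' of the V alignment (edlib pre-ranked)
    tail_start = q_end
    tail = str(seq[tail_start:])
    j_best: Optional[tuple[float, str, GermlineAllele, object]] = None
    if len(tail) >= 12:
        dists = [
            (edlib.align(str(j.seq), tail, mode="HW", task="distance")["editDistance"], j)
            for j in j_db
        ]
        dmin = min(d for d, _ in dists)
        for d, j in dists:
            if d > dmin + 3:
                continue
            pa = align_glocal(tail, str(j.seq))
            key = (pa.score, j.name.render())
            if j_best is None or key[0] > j_best[0] or (key[0] == j_best[0] and key[1] < j_best[1]):
                j_best = (pa.score, key[1], j, pa)
    if j_best is None:
        return out
    _, _, j_allele, j_pa = j_best
    if j_pa.columns == 0 or j_pa.identity_pct < 60.0:
        return out
    out.j_assign = j_allele.name
    # CDR3: conserved Cys motif start on V through the J Trp codon end
    v_anchor = len(v_ref.seq) - 3 * V_MOTIF_CODONS
    start = ann.alignment.map_ref_to_query(v_anchor) if ann.alignment else None
    end = None
    if j_allele.anchor is not None:
        last = j_pa.map_ref_to_query(j_allele.anchor + 2)
        if last is not None:
            end = tail_start + last + 1
    if start is not None and end is not None and end > start:
        out.cdr3_nt = NucSeq(seq[start:end])
    return out


def annotate_repertoire(
    reads: Iterable[tuple[str, str]],
    v_db: ReferenceDatabase,
    j_db: ReferenceDatabase,
    candidate_margin: Optional[int] = 3,
) -> tuple[list[RepertoireRead], int]:
    """Annotate many reads; returns (annotated, n_dropped_no_v_hit)."""
    out: list[RepertoireRead] = []
    dropped = 0
    for read in reads:
        ann = annotate_vdj(read, v_db, j_db, candidate_margin=candidate_margin)
        if ann is None:
            dropped += 1
        else:
            out.append(ann)
    return out, dropped


def candidate_alleles(
    reads: Iterable[RepertoireRead],
    v_db: ReferenceDatabase,
    min_reads: int = 5,
    min_cdr3: int = 3,
    min_j: int = 2,
    max_v_truncation: int = 12,
) -> list[CandidateAllele]:
    """Group annotated reads into supported germline V candidates.

    Reads 3'-truncated by more than ``max_v_truncation`` nt are ignored;
    shorter truncations join a full-length sub-group only when exactly one
    full-length exemplar has the truncated V region as a prefix. The
    candidate consensus is the shared full-length V region itself; it is
    never extended by inferred (non-exemplar) bases.
    """
    by_v: dict[str, list[RepertoireRead]] = defaultdict(list)
    for r in reads:
        if r.v_truncation <= max_v_truncation:
            by_v[r.v_assign.render()].append(r)
    candidates: list[CandidateAllele] = []
    for _, group in sorted(by_v.items()):
        full: dict[str, list[RepertoireRead]] = defaultdict(list)
        truncated: list[RepertoireRead] = []
        for r in group:
            if r.v_truncation == 0:
                full[str(r.v_region)].append(r)
            else:
                truncated.append(r)
        keys = sorted(full)
        for r in truncated:
            owners = [k for k in keys if k.startswith(str(r.v_region))]
            if len(owners) == 1:
                full[owners[0]].append(r)
        for key in keys:
            members = full[key]
            cdr3s = {str(r.cdr3_nt) for r in members if r.cdr3_nt}
            js = {r.j_assign.render() for r in members if r.j_assign is not None}
            if len(members) >= min_reads and len(cdr3s) >= min_cdr3 and len(js) >= min_j:
                candidates.append(
                    CandidateAllele(
                        consensus_seq=NucSeq(key),
                        template=members[0].v_assign,
                        n_reads=len(members),
                        n_distinct_cdr3=len(cdr3s),
                        n_distinct_j=len(js),
                        is_novel=key not in v_db,
                        read_ids=[r.id for r in members],
                    )
                )
    candidates.sort(key=lambda c: (str(c.consensus_seq)))
    return candidates


def infer_germlines(
    reads: Iterable[RepertoireRead],
    v_db: ReferenceDatabase,
    subject_id: str = "subject",
    min_reads: int = 5,
    min_cdr3: int = 3,
    min_j: int = 2,
    max_v_truncation: int = 12,
) -> SubjectCallSet:
    """Emit the supported candidates (known confirmations and novel alleles) as a call set."""
    cands = candidate_alleles(
        reads, v_db, min_reads=min_reads, min_cdr3=min_cdr3, min_j=min_j,
        max_v_truncation=max_v_truncation,
    )
    name_counter: dict[str, int] = {}
    alleles = []
    for c in cands:
        name = (
            v_db.by_seq[c.consensus_seq].name
            if not c.is_novel
            else _provisional_name(c.template, name_counter)
        )
        alleles.append(
            GermlineAllele(
                name=name,
                seq=c.consensus_seq,
                sources={Source.MRNA_INFER},
                subject_id=subject_id,
                depth=c.n_reads,
                novel=c.is_novel,
            )
        )
    tally = {
        "n_candidates": len(cands),
        "n_novel": sum(c.is_novel for c in cands),
        "candidate_support": Counter(
            (c.n_reads, c.n_distinct_cdr3, c.n_distinct_j) for c in cands
        ),
    }
    return SubjectCallSet(
        subject_id=subject_id,
        method=Source.MRNA_INFER,
        alleles=alleles,
        params={"min_reads": min_reads, "min_cdr3": min_cdr3, "min_j": min_j,
                "max_v_truncation": max_v_truncation},
        tally=tally,
    )
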