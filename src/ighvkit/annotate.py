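"""Best-reference assignment, V-region trimming and productivity calls.

The reference is aligned glocally: the full reference may align anywhere
inside the query (primer/UTR flanks on the query are free), and a query that
stops short of the reference 3' end is reported as truncated rather than
penalised. Scoring is affine (match +1, mismatch -2, gap open -4, gap
extend -1, where a length-k gap costs 4 + (k-1)).

Candidate references are pre-ranked by edit distance with edlib (infix mode)
and only near-best candidates are re-scored with the affine aligner; pass
``candidate_margin=None`` to score every reference exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
from Bio import Align

from .model import (
    AlleleName,
    GermlineAllele,
    NucSeq,
    ReferenceDatabase,
    STOP_CODONS,
)

MATCH = 1
MISMATCH = -2
GAP_OPEN = -4
GAP_EXTEND = -1

MIN_IDENTITY_PCT = 60.0
MIN_QUERY_LEN = 100


def make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    # free end gaps on both sequences: query flanks and reference overhangs
    try:
        a.open_end_insertion_score = 0
        a.extend_end_insertion_score = 0
        a.open_end_deletion_score = 0
        a.extend_end_deletion_score = 0
    except AttributeError:  # older attribute names
        a.target_end_open_gap_score = 0
        a.target_end_extend_gap_score = 0
        a.query_end_open_gap_score = 0
        a.query_end_extend_gap_score = 0
    return a


_ALIGNER = make_aligner()


@dataclass
class PairAlignment:
    """Summary of one glocal alignment of a reference inside a query."""

    score: float
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    n_match: int
    n_mismatch: int
    n_gap: int
    gap_runs: list[int]
    blocks: list[tuple[int, int, int, int]]  # (q0, q1, r0, r1) aligned runs

    @property
    def columns(self) -> int:
        return self.n_match + self.n_mismatch + self.n_gap

    @property
    def identity_pct(self) -> float:
        if self.columns == 0:
            return 0.0
        return 100.0 * self.n_match / self.columns

    def map_ref_to_query(self, ref_pos: int) -> Optional[int]:
        """Query coordinate aligned to a reference coordinate, or None in a gap."""
        for q0, q1, r0, r1 in self.blocks:
            if r0 <= ref_pos < r1:
                return q0 + (ref_pos - r0)
        return None


def align_glocal(query: str, ref: str) -> PairAlignment:
    """Align ``ref`` inside ``query`` with the module's affine scoring."""
    aln = _ALIGNER.align(query, ref)[0]
    q_blocks, r_blocks = aln.aligned
    blocks: list[tuple[int, int, int, int]] = []
    n_match = n_mismatch = 0
    gap_runs: list[int] = []
    prev_q = prev_r = None
    for (q0, q1), (r0, r1) in zip(q_blocks, r_blocks):
        if prev_q is not None:
            dq = q0 - prev_q
            dr = r0 - prev_r
            if dq > 0:
                gap_runs.append(dq)
            if dr > 0:
                gap_runs.append(dr)
        for qc, rc in zip(query[q0:q1], ref[r0:r1]):
            if qc == rc:
                n_match += 1
            else:
                n_mismatch += 1
        blocks.append((int(q0), int(q1), int(r0), int(r1)))
        prev_q, prev_r = q1, r1
    if not blocks:
        return PairAlignment(aln.score, 0, 0, 0, 0, 0, 0, 0, [], [])
    return PairAlignment(
        score=float(aln.score),
        query_start=blocks[0][0],
        query_end=blocks[-1][1],
        ref_start=blocks[0][2],
        ref_end=blocks[-1][3],
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_gap=sum(gap_runs),
        gap_runs=gap_runs,
        blocks=blocks,
    )


@dataclass
class VAnnotation:
    """Best-reference assignment for one query sequence."""

    best_allele: Optional[AlleleName]
    identity_pct: float = 0.0
    n_mismatch: int = 0
    n_gap: int = 0
    query_v_start: int = 0
    query_v_end: int = 0
    ref_start: int = 0
    ref_end: int = 0
    frame_offset: int = 0
    score: float = 0.0
    truncated: bool = False
    productive: bool = False
    fail_reason: Optional[str] = None  # STOP | FRAMESHIFT | NO_HIT | AMBIGUOUS_BASE
    alignment: Optional[PairAlignment] = field(default=None, repr=False)


def _prescreen(seq: str, db: ReferenceDatabase, margin: int) -> list[GermlineAllele]:
    # staged distance bound: most queries sit close to one reference, so a
    # tight k lets edlib bail out early on the rest of the database
    for k in (12, 48, -1):
        scored = []
        for a in db:
            d = edlib.align(str(a.seq), seq, mode="HW", task="distance", k=k)["editDistance"]
            if d >= 0:
                scored.append((d, a))
        if scored:
            best = min(d for d, _ in scored)
            if k < 0 or best + margin <= k:
                return [a for d, a in scored if d <= best + margin]
    return list(db)


def assign_germline(
    seq: str,
    db: ReferenceDatabase,
    candidate_margin: Optional[int] = 5,
    min_len: int = MIN_QUERY_LEN,
) -> VAnnotation:
    """Assign the best-scoring reference allele to ``seq``.

    Ties in affine score break to the lexicographically smallest allele name.
    A best hit below 60% identity is reported as NO_HIT.
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    if len(seq) < min_len:
        raise ValueError(f"query shorter than {min_len} nt ({len(seq)})")
    if candidate_margin is None:
        candidates: Sequence[GermlineAllele] = list(db)
    else:
        candidates = _prescreen(str(seq), db, candidate_margin)
    best: Optional[tuple[float, str, GermlineAllele, PairAlignment]] = None
    for a in candidates:
        pa = align_glocal(str(seq), str(a.seq))
        key = (pa.score, a.name.render())
        if best is None or pa.score > best[0] or (pa.score == best[0] and key[1] < best[1]):
            best = (pa.score, a.name.render(), a, pa)
    assert best is not None
    _, _, allele, pa = best
    if pa.identity_pct < MIN_IDENTITY_PCT:
        return VAnnotation(best_allele=None, fail_reason="NO_HIT")
    return VAnnotation(
        best_allele=allele.name,
        identity_pct=pa.identity_pct,
        n_mismatch=pa.n_mismatch,
        n_gap=pa.n_gap,
        query_v_start=pa.query_start,
        query_v_end=pa.query_end,
        ref_start=pa.ref_start,
        ref_end=pa.ref_end,
        frame_offset=(3 - pa.ref_start % 3) % 3,
        score=pa.score,
        truncated=pa.ref_end < len(allele.seq),
        alignment=pa,
    )


def refine_v_end(
    pa: PairAlignment, query: str, ref: str, min_terminal_matches: int = 6
) -> Optional[tuple[int, int]]:
    """3' end of the V alignment after stripping an unreliable terminal segment.

    With free end gaps, a query whose V segment is 3'-trimmed (a V(D)J
    junction) can have its first junctional bases absorbed into the V
    alignment as terminal mismatches. This walks back until the alignment
    ends in at least ``min_terminal_matches`` consecutive matching columns
    and returns the refined (query_end, ref_end), or None when no such run
    exists.
    """
    cols: list[tuple[bool, int, int]] = []  # (is_match, q_end, r_end) per column
    prev_q = prev_r = None
    for q0, q1, r0, r1 in pa.blocks:
        if prev_q is not None and (q0 > prev_q or r0 > prev_r):
            cols.append((False, q0, r0))  # gap region: one unreliable column marker
        for i in range(q1 - q0):
            cols.append((query[q0 + i] == ref[r0 + i], q0 + i + 1, r0 + i + 1))
        prev_q, prev_r = q1, r1
    run = 0
    for idx in range(len(cols) - 1, -1, -1):
        run = run + 1 if cols[idx][0] else 0
        if run >= min_terminal_matches:
            end_idx = idx + run - 1
            return cols[end_idx][1], cols[end_idx][2]
    return None


def trim_to_v(seq: str, ann: VAnnotation, ref_allele: GermlineAllele) -> NucSeq:
    """Cut ``seq`` to the segment aligned to the reference V region.

    References are stored already ending at the conserved 3' motif, so the
    trim point is simply the query coordinate aligned to the reference's last
    base; an alignment stopping earlier marks the annotation as truncated.
    """
    if ann.best_allele is None:
        raise ValueError("cannot trim a NO_HIT annotation")
    ann.truncated = ann.ref_end < len(ref_allele.seq)
    return NucSeq(seq[ann.query_v_start : ann.query_v_end])


def productivity_check(trimmed: str, ann: VAnnotation) -> tuple[bool, Optional[str]]:
    """Frame/stop/ambiguity verdict for a trimmed V region.

    Frameshift: total gap length not 0 mod 3, or any single gap run not a
    multiple of 3. Stop: any in-frame codon (frame from reference codon 1)
    in {TAA, TAG, TGA}. Ambiguity: any N. Updates ``ann`` in place and
    returns (productive, fail_reason).
    """
    reason: Optional[str] = None
    runs = ann.alignment.gap_runs if ann.alignment is not None else []
    if ann.n_gap % 3 != 0 or any(r % 3 != 0 for r in runs):
        reason = "FRAMESHIFT"
    else:
        off = ann.frame_offset
        for i in range(off, len(trimmed) - 2, 3):
            if trimmed[i : i + 3] in STOP_CODONS:
                reason = "STOP"
                break
        if reason is None and "N" in trimmed:
            reason = "AMBIGUOUS_BASE"
    ann.productive = reason is None
    ann.fail_reason = reason
    return ann.productive, reason


def annotate_and_trim(
    seq: str, db: ReferenceDatabase, candidate_margin: Optional[int] = 5
) -> tuple[Optional[NucSeq], VAnnotation]:
    """Convenience: assign, trim and judge productivity in one step.

    Returns (trimmed V region or None on NO_HIT, annotation).
    """
    ann = assign_germline(seq, db, candidate_margin=candidate_margin)
    if ann.best_allele is None:
        return None, ann
    trimmed = trim_to_v(seq, ann, db.by_name[ann.best_allele.render()])
    productivity_check(trimmed, ann)
    return trimmed, ann
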