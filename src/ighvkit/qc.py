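"""Paired-end merging and quality filtering of amplicon reads.

A merged read keeps per-base Phred scores and its expected number of
miscalls, the sum over bases of 10^(-Q/10); reads longer than the amplicon
filters (>= 300 nt) with at most 10 expected miscalls survive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import NucSeq, QualifiedRead, revcomp

REASON_SHORT = "SHORT"
REASON_MISCALLS = "MISCALLS"


@dataclass
class MergedRead:
    id: str
    seq: NucSeq
    quals: Sequence[int]
    expected_miscalls: float

    def __len__(self) -> int:
        return len(self.seq)


def expected_miscalls(quals: Sequence[int]) -> float:
    """Expected number of base-call errors: sum of 10^(-Q/10)."""
    q = np.asarray(quals, dtype=float)
    if q.size and q.min() < 0:
        raise ValueError("negative Phred quality")
    return float(np.sum(10.0 ** (-q / 10.0)))


def merge_pair(
    fwd: QualifiedRead,
    rev: QualifiedRead,
    min_overlap: int = 16,
    max_overlap_mismatch_frac: float = 0.1,
    _overlap_cache: Optional[dict] = None,
) -> Optional[MergedRead]:
    """Merge a forward read with a raw reverse read by their best ungapped overlap.

    ``rev`` is reverse-complemented internally. All suffix(fwd)/prefix(revcomp)
    overlaps of length >= ``min_overlap`` with mismatch fraction <=
    ``max_overlap_mismatch_frac`` are scored as matches - mismatches; the
    highest score wins, ties going to the longest overlap. At overlap
    positions the base with the higher Q is kept and the merged Q is the max
    of the two. Returns None when no acceptable overlap exists.
    """
    if min_overlap < 8:
        raise ValueError("min_overlap must be >= 8")
    a = np.frombuffer(str(fwd.seq).encode(), dtype=np.uint8)
    b = np.frombuffer(revcomp(str(rev.seq)).encode(), dtype=np.uint8)
    qa = np.asarray(fwd.quals, dtype=np.int16)
    qb = np.asarray(rev.quals, dtype=np.int16)[::-1]
    la, lb = len(a), len(b)
    if _overlap_cache is not None and (str(fwd.seq), str(rev.seq)) in _overlap_cache:
        ov = _overlap_cache[(str(fwd.seq), str(rev.seq))]
        if ov < 0:
            return None
    else:
        best: Optional[tuple[int, int]] = None  # (score, overlap)
        for ov in range(min_overlap, min(la, lb) + 1):
            mism = int(np.count_nonzero(a[la - ov :] != b[:ov]))
            if mism > max_overlap_mismatch_frac * ov:
                continue
            score = ov - 2 * mism
            if best is None or score > best[0] or (score == best[0] and ov > best[1]):
                best = (score, ov)
        ov = -1 if best is None else best[1]
        if _overlap_cache is not None:
            _overlap_cache[(str(fwd.seq), str(rev.seq))] = ov
        if best is None:
            return None
    sa, sb = a[la - ov :].copy(), b[:ov]
    oqa, oqb = qa[la - ov :], qb[:ov]
    take_b = oqb > oqa
    sa[take_b] = sb[take_b]
    merged_seq = a[: la - ov].tobytes().decode() + sa.tobytes().decode() + b[ov:].tobytes().decode()
    merged_q = np.concatenate([qa[: la - ov], np.maximum(oqa, oqb), qb[ov:]]).astype(int)
    return MergedRead(
        id=fwd.id,
        seq=NucSeq(merged_seq),
        quals=merged_q,
        expected_miscalls=expected_miscalls(merged_q),
    )


def merge_pairs(
    pairs: Iterable[tuple[QualifiedRead, QualifiedRead]],
    min_overlap: int = 16,
    max_overlap_mismatch_frac: float = 0.1,
) -> tuple[list[MergedRead], int]:
    """Merge many pairs; returns (merged reads, number of unmergeable pairs).

    The overlap search depends only on the sequence pair, so it is cached
    across duplicate molecules (exact PCR duplicates dominate amplicon runs).
    """
    cache: dict = {}
    merged: list[MergedRead] = []
    failed = 0
    for fwd, rev in pairs:
        m = merge_pair(fwd, rev, min_overlap, max_overlap_mismatch_frac, _overlap_cache=cache)
        if m is None:
            failed += 1
        else:
            merged.append(m)
    return merged, failed


def qc_filter(
    merged: Iterable[MergedRead],
    min_len: int = 300,
    max_miscalls: float = 10.0,
) -> tuple[list[MergedRead], list[tuple[MergedRead, str]]]:
    """Partition merged reads into (kept, rejected-with-reason).

    A read is kept iff its length is >= ``min_len`` and its expected miscall
    count is <= ``max_miscalls`` (the bound is inclusive: exactly 10 expected
    miscalls survives, only "more than 10" is excluded).
    """
    kept: list[MergedRead] = []
    rejected: list[tuple[MergedRead, str]] = []
    for r in merged:
        if len(r) < min_len:
            rejected.append((r, REASON_SHORT))
        elif r.expected_miscalls > max_miscalls:
            rejected.append((r, REASON_MISCALLS))
        else:
            kept.append(r)
    return kept, rejected
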