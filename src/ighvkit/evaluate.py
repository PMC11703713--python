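"""Evaluation of germline databases and call sets.

Somatic-hypermutation (SHM) profiles measure how far expressed reads sit
from their best database hit: a more complete germline database can only
lower a read's distance, so SHM distributions rank candidate databases.
Usage tables give per-allele assigned-read fractions. Family-level trees
are neighbor-joining over Jukes-Cantor-transformed pairwise distances — a
distance-based stand-in within the GTR model family for full
maximum-likelihood estimation, adequate for the family-clade topology that
is the only property asserted here.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .annotate import align_glocal, assign_germline
from .model import GermlineAllele, NucSeq, ReferenceDatabase

GTR_DISTANCE_CAP = 10.0


@dataclass
class ShmProfile:
    """Distribution of per-read percent distance to the best database hit."""

    db_name: str
    shm_pct: np.ndarray
    n_unassignable: int

    @property
    def median(self) -> float:
        return float(np.median(self.shm_pct)) if self.shm_pct.size else float("nan")

    @property
    def mean(self) -> float:
        return float(np.mean(self.shm_pct)) if self.shm_pct.size else float("nan")

    @property
    def frac_le_1pct(self) -> float:
        if not self.shm_pct.size:
            return float("nan")
        return float(np.mean(self.shm_pct <= 1.0))


def shm_profile(
    reads: Iterable[tuple[str, str]],
    db: ReferenceDatabase,
    candidate_margin: Optional[int] = 5,
) -> ShmProfile:
    """Per-read SHM% = 100 - identity of the best V hit (gaps count as mismatch)."""
    if len(db) == 0:
        raise ValueError("database is empty")
    vals: list[float] = []
    unassignable = 0
    for _, seq in reads:
        try:
            ann = assign_germline(seq, db, candidate_margin=candidate_margin)
        except ValueError:
            unassignable += 1
            continue
        if ann.best_allele is None:
            unassignable += 1
            continue
        vals.append(100.0 - ann.identity_pct)
    return ShmProfile(db_name=db.name, shm_pct=np.asarray(vals), n_unassignable=unassignable)


@dataclass
class UsageTable:
    """Fraction of assigned reads per best-hit allele for one subject."""

    subject_id: str
    db_name: str
    frequencies: dict[str, float]
    n_assigned: int
    n_unassignable: int

    def top(self, k: int = 10) -> list[tuple[str, float]]:
        return sorted(self.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def usage_frequencies(
    reads: Iterable[tuple[str, str]],
    db: ReferenceDatabase,
    subject_id: str = "subject",
    candidate_margin: Optional[int] = 5,
) -> UsageTable:
    """Per-allele fraction of assignable reads (best hit, name tie-break)."""
    if len(db) == 0:
        raise ValueError("database is empty")
    counts: Counter[str] = Counter()
    unassignable = 0
    for _, seq in reads:
        try:
            ann = assign_germline(seq, db, candidate_margin=candidate_margin)
        except ValueError:
            unassignable += 1
            continue
        if ann.best_allele is None:
            unassignable += 1
            continue
        counts[ann.best_allele.render()] += 1
    total = sum(counts.values())
    freqs = {k: v / total for k, v in counts.items()} if total else {}
    return UsageTable(
        subject_id=subject_id,
        db_name=db.name,
        frequencies=freqs,
        n_assigned=total,
        n_unassignable=unassignable,
    )


def gtr_distance(a: str, b: str) -> float:
    """Jukes-Cantor-corrected pairwise distance between two alignable sequences.

    p is the mismatch fraction over match+mismatch columns of the glocal
    alignment (gap columns excluded); p >= 0.75 is capped at 10.0.
    Sequences aligning below 60% identity are considered unalignable.
    """
    if a == b:
        return 0.0
    pa = align_glocal(str(a), str(b))
    # unrelated sequences align only a short opportunistic core under
    # free-end-gap scoring, so require coverage as well as identity
    span = pa.ref_end - pa.ref_start
    if pa.columns == 0 or pa.identity_pct < 60.0 or span < 0.6 * min(len(a), len(b)):
        raise ValueError("sequences are not alignable (identity < 60%)")
    sites = pa.n_match + pa.n_mismatch
    p = pa.n_mismatch / sites if sites else 1.0
    if p >= 0.75:
        return GTR_DISTANCE_CAP
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def build_tree(alleles: Iterable[GermlineAllele]) -> str:
    """Neighbor-joining Newick tree over JC-distances; leaf labels are allele names."""
    alleles = sorted(alleles, key=lambda x: x.name.render())
    if len(alleles) < 3:
        raise ValueError("need at least 3 alleles to build a tree")
    labels = [a.name.render() for a in alleles]
    if len(set(labels)) != len(labels):
        raise ValueError("allele names must be unique for tree labels")
    n = len(alleles)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = gtr_distance(alleles[i].seq, alleles[j].seq)
    dm = DistanceMatrix(m, ids=labels)
    tree = nj(dm)
    return str(tree).strip()
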