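"""Cross-method and cross-subject comparison of germline call sets.

All set algebra is over exact nucleotide sequences: alleles one nucleotide
apart are distinct elements, and identical sequences carrying different
names in different databases are the same element. Percentages are rounded
half-up to integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .annotate import align_glocal
from .model import NucSeq, ReferenceDatabase, SubjectCallSet


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def pct(numerator: int, denominator: int) -> Optional[int]:
    """Integer percentage under round-half-up; None for an empty denominator."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator)


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Intersection-over-union of two sequence sets; both empty -> 1.0."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)


def validation_rate(
    call_set: Iterable[str], others: Sequence[Iterable[str]]
) -> tuple[int, Optional[int]]:
    """How many elements of a call set recur in the union of other sets.

    Returns (n_validated, integer percentage or None when the set is empty).
    """
    s = set(call_set)
    pool: set[str] = set()
    for o in others:
        pool |= set(o)
    n = len(s & pool)
    return n, pct(n, len(s))


def venn_counts(named_sets: dict[str, Iterable[str]]) -> dict[frozenset, int]:
    """Exclusive region counts for 2-4 named sets.

    Keys are frozensets of the names whose sets (and only whose sets)
    contain the region's elements; region counts sum to the union size.
    """
    if not 2 <= len(named_sets) <= 4:
        raise ValueError("venn_counts requires between 2 and 4 sets")
    sets = {k: set(v) for k, v in named_sets.items()}
    names = list(sets)
    out: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            for other in names:
                if other not in combo:
                    inside -= sets[other]
            out[frozenset(combo)] = len(inside)
    return out


def pairwise_identity_best(
    a_set: Iterable[str], b_set: Iterable[str]
) -> list[tuple[NucSeq, NucSeq, float]]:
    """For each sequence in A, its highest-identity partner in B.

    Identity is the module-wide glocal alignment identity (gap columns count
    against it). Exact matches short-circuit at 100%.
    """
    bs = sorted(set(str(x) for x in b_set))
    if not bs:
        raise ValueError("B must be non-empty")
    out = []
    for a in sorted(set(str(x) for x in a_set)):
        if a in bs:
            out.append((NucSeq(a), NucSeq(a), 100.0))
            continue
        best_b, best_id = None, -1.0
        for b in bs:
            ident = align_glocal(a, b).identity_pct
            if ident > best_id:
                best_b, best_id = b, ident
        out.append((NucSeq(a), NucSeq(best_b), best_id))
    return out


@dataclass
class EvidenceTable:
    """Per-sequence evidence: which subjects, methods and databases hold it."""

    rows: dict[NucSeq, dict] = field(default_factory=dict)

    def novel_seqs(self) -> list[NucSeq]:
        return [s for s, r in self.rows.items() if not r["databases"]]


@dataclass
class EvidenceSummary:
    table: EvidenceTable
    n_total: int
    n_novel: int
    n_novel_ge2_methods: int
    n_novel_ge2_subjects: int
    n_novel_ge2_subjects_or_sources: int
    pct_novel_ge2_methods: Optional[int]
    pct_novel_ge2_subjects_or_sources: Optional[int]
    per_method_validation: dict[str, dict]


# sample material behind each calling method: TOPO and MiSeq both consume the
# gDNA amplicons, repertoire inference consumes mRNA
_METHOD_MATERIAL = {"GDNA_MISEQ": "gDNA", "TOPO": "gDNA", "MRNA_INFER": "mRNA"}


def evidence_summary(
    call_sets: Sequence[SubjectCallSet],
    reference_dbs: Sequence[ReferenceDatabase] = (),
) -> EvidenceSummary:
    """Tabulate multi-evidence support for every called sequence.

    Novel = absent from every reference database. "Two subjects or two
    sample sources" counts sequences seen in >= 2 subjects, or in >= 2
    distinct biological sources (gDNA vs mRNA) within one subject — the
    two gDNA routes share one source. Per-method validation is reported in
    both decompositions: by the other methods alone, and by other methods
    or any reference database.
    """
    table = EvidenceTable()
    for cs in call_sets:
        for a in cs.alleles:
            row = table.rows.setdefault(
                a.seq, {"subjects": set(), "methods": set(), "sources": set(),
                        "databases": set()}
            )
            row["subjects"].add(cs.subject_id)
            row["methods"].add(cs.method.value)
            row["sources"].add(
                (cs.subject_id, _METHOD_MATERIAL.get(cs.method.value, cs.method.value))
            )
    for db in reference_dbs:
        for seq in db.seqs():
            if seq in table.rows:
                table.rows[seq]["databases"].add(db.name)
    novel = table.novel_seqs()
    ge2_methods = [s for s in novel if len(table.rows[s]["methods"]) >= 2]
    ge2_subjects = [s for s in novel if len(table.rows[s]["subjects"]) >= 2]
    ge2_sources = [
        s for s in novel
        if len(table.rows[s]["subjects"]) >= 2 or len(table.rows[s]["sources"]) >= 2
    ]
    per_method: dict[str, dict] = {}
    methods = sorted({cs.method.value for cs in call_sets})
    db_pool: set[NucSeq] = set()
    for db in reference_dbs:
        db_pool |= db.seqs()
    for m in methods:
        mine = {s for s, r in table.rows.items() if m in r["methods"]}
        by_others = {s for s in mine if len(table.rows[s]["methods"]) >= 2}
        by_any = {s for s in mine if len(table.rows[s]["methods"]) >= 2 or s in db_pool}
        per_method[m] = {
            "n": len(mine),
            "n_validated_by_other_methods": len(by_others),
            "pct_validated_by_other_methods": pct(len(by_others), len(mine)),
            "n_validated_by_methods_or_dbs": len(by_any),
            "pct_validated_by_methods_or_dbs": pct(len(by_any), len(mine)),
        }
    return EvidenceSummary(
        table=table,
        n_total=len(table.rows),
        n_novel=len(novel),
        n_novel_ge2_methods=len(ge2_methods),
        n_novel_ge2_subjects=len(ge2_subjects),
        n_novel_ge2_subjects_or_sources=len(ge2_sources),
        pct_novel_ge2_methods=pct(len(ge2_methods), len(novel)),
        pct_novel_ge2_subjects_or_sources=pct(len(ge2_sources), len(novel)),
        per_method_validation=per_method,
    )


@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str


def _linkage_to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _linkage_to_newick(node.get_left(), labels)
    right = _linkage_to_newick(node.get_right(), labels)
    return f"({left}:{node.dist / 2:.6f},{right}:{node.dist / 2:.6f})"


def cluster_similarity(matrix: np.ndarray, labels: Sequence[str]) -> ClusterResult:
    """Average-linkage hierarchical clustering of a Jaccard similarity matrix.

    Distance is 1 - Jaccard. Labels are pre-sorted so equal-distance merges
    break ties deterministically by label order.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-12):
        raise ValueError("similarity matrix must have unit diagonal")
    order = np.argsort(np.asarray(labels, dtype=object))
    labels_sorted = [labels[i] for i in order]
    m = m[np.ix_(order, order)]
    dist = squareform(1.0 - m, checks=False)
    link = hierarchy.linkage(dist, method="average")
    tree = hierarchy.to_tree(link)
    dendro = hierarchy.dendrogram(link, no_plot=True, labels=labels_sorted)
    newick = _linkage_to_newick(tree, labels_sorted) + ";"
    return ClusterResult(
        labels=labels_sorted,
        linkage=link,
        leaf_order=list(dendro["ivl"]),
        newick=newick,
    )


def jaccard_matrix(named_sets: dict[str, Iterable[str]]) -> tuple[np.ndarray, list[str]]:
    """Pairwise Jaccard similarity over labelled sequence sets (sorted labels)."""
    labels = sorted(named_sets)
    sets = [set(named_sets[k]) for k in labels]
    n = len(labels)
    m = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = jaccard(sets[i], sets[j])
    return m, labels
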