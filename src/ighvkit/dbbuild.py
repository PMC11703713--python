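"""Merging reference databases and naming novel alleles (W-series).

A newly discovered allele is named after its nearest reference allele (the
gene template) plus a ``W`` suffix with four digits. The original study
does not document how its four-digit codes were chosen; here they derive
deterministically from a checksum of the sequence (with linear probing on
collision) so that rebuilding the database reproduces every name.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .annotate import assign_germline
from .model import (
    AlleleName,
    GermlineAllele,
    NucSeq,
    ReferenceDatabase,
    Source,
)


def _checksum_code(seq: str) -> int:
    digest = hashlib.sha256(seq.encode()).hexdigest()
    return int(digest, 16) % 10000


@dataclass
class NamingLedger:
    """Deterministic record of novel-sequence naming and cross-db synonyms."""

    assigned: dict[NucSeq, AlleleName] = field(default_factory=dict)
    collisions: list[tuple[NucSeq, str, str]] = field(default_factory=list)
    synonyms: dict[str, list[str]] = field(default_factory=dict)  # canonical -> other names


def name_novel(
    seq: str,
    db: ReferenceDatabase,
    taken: Optional[set[str]] = None,
    ledger: Optional[NamingLedger] = None,
) -> AlleleName:
    """W-series name for a novel sequence: nearest-template + W + 4 digits.

    The four digits come from a SHA-256 checksum of the sequence modulo
    10000, incremented modulo 10000 until the name is free.
    """
    seq = NucSeq(seq)
    if seq in db:
        raise ValueError(
            f"sequence already present in database as {db.by_seq[seq].name.render()}"
        )
    ann = assign_germline(seq, db)
    if ann.best_allele is None:
        raise ValueError("novel sequence has no alignable template in the database")
    template = ann.best_allele.base()
    taken_names = set(db.by_name) | (taken or set())
    code = _checksum_code(seq)
    first = None
    for _ in range(10000):
        name = replace(template, w_suffix=f"W{code:04d}")
        rendered = name.render()
        if rendered not in taken_names:
            if first is not None and ledger is not None:
                ledger.collisions.append((seq, first, rendered))
            if ledger is not None:
                ledger.assigned[seq] = name
            return name
        if first is None:
            first = rendered
        code = (code + 1) % 10000
    raise RuntimeError("exhausted W-series code space for template " + template.render())


def union_dbs(
    dbs: Sequence[ReferenceDatabase],
    novel: Sequence[tuple[str, Optional[str]]] = (),
    name: str = "union",
) -> tuple[ReferenceDatabase, NamingLedger]:
    """Sequence-level union of databases plus W-series-named novel alleles.

    When the same sequence appears under different names, the earliest
    database in the input order owns the name and the others are recorded as
    synonyms. Novel (sequence, subject) entries absent from the merged
    reference are named via :func:`name_novel` against it.
    """
    ledger = NamingLedger()
    merged: dict[NucSeq, GermlineAllele] = {}
    names_taken: set[str] = set()
    deferred: list[tuple[NucSeq, Optional[str]]] = []
    for db in dbs:
        for a in db:
            if a.seq in merged:
                canon = merged[a.seq].name.render()
                if a.name.render() != canon:
                    ledger.synonyms.setdefault(canon, []).append(a.name.render())
                continue
            if a.name.render() in names_taken:
                # same name, different sequence across databases: the first
                # owner keeps the name, the newcomer is renamed like a novel
                ledger.synonyms.setdefault(a.name.render(), []).append(
                    f"{db.name}:{a.name.render()} (renamed)"
                )
                deferred.append((a.seq, a.subject_id))
                continue
            merged[a.seq] = GermlineAllele(
                name=a.name, seq=a.seq, sources=set(a.sources) or {Source.REFERENCE},
                subject_id=a.subject_id, anchor=a.anchor,
            )
            names_taken.add(a.name.render())
    base = ReferenceDatabase(name, list(merged.values()))
    for seq, subject in list(deferred) + [(NucSeq(s), subj) for s, subj in novel]:
        seq = NucSeq(seq)
        if seq in merged:
            continue
        aname = name_novel(seq, base, taken=names_taken, ledger=ledger)
        names_taken.add(aname.render())
        merged[seq] = GermlineAllele(
            name=aname, seq=seq, sources=set(), subject_id=subject, novel=True
        )
    return ReferenceDatabase(name, list(merged.values())), ledger
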