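"""Germline allele calling from gDNA amplicon reads and Sanger clones.

The MiSeq route separates real alleles from PCR/sequencing error sequences
purely by depth: unique full-length sequences are ranked by read depth and
only those strictly above a fraction (default 0.67%) of the maximum depth
are annotated, trimmed and productivity-checked. The Sanger route has no
depth threshold (every clean unique clone is a call) but excludes any clone
with an ambiguous base, the computational proxy for chromatogram double
peaks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .annotate import annotate_and_trim
from .model import (
    AlleleName,
    GermlineAllele,
    NucSeq,
    ReferenceDatabase,
    Source,
    SubjectCallSet,
    UniqueSequence,
)
from .qc import MergedRead, qc_filter

DEFAULT_FRACTION = 0.0067


def dedup_count(seqs: Iterable[str]) -> list[UniqueSequence]:
    """Collapse sequences at 100% identity; depth = group size.

    Ranked by depth descending, ties by sequence lexicographic order; rank 1
    is the deepest.
    """
    counts = Counter(str(s) for s in seqs)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        UniqueSequence(seq=NucSeq(s), depth=d, rank=i + 1)
        for i, (s, d) in enumerate(ordered)
    ]


def depth_cutoff(uniques: Sequence[UniqueSequence], fraction: float = DEFAULT_FRACTION) -> float:
    """Depth cutoff = fraction x maximum depth; sequences strictly above it are confident."""
    if not uniques:
        raise ValueError("no unique sequences: cannot set a depth cutoff")
    max_depth = max(u.depth for u in uniques)
    return fraction * max_depth


@dataclass
class DepthProfile:
    ranked: list[UniqueSequence]
    max_depth: int
    cutoff: float

    @classmethod
    def from_uniques(
        cls, uniques: Sequence[UniqueSequence], fraction: float = DEFAULT_FRACTION
    ) -> "DepthProfile":
        cut = depth_cutoff(uniques, fraction)
        return cls(ranked=list(uniques), max_depth=max(u.depth for u in uniques), cutoff=cut)

    def confident(self) -> list[UniqueSequence]:
        return [u for u in self.ranked if u.depth > self.cutoff]

    def knee_rank(self, max_rank: int = 300) -> Optional[int]:
        """Rank before the largest relative depth drop in the top ranks (diagnostic)."""
        top = self.ranked[:max_rank]
        if len(top) < 2:
            return None
        drops = [
            (top[i].depth - top[i + 1].depth) / top[i].depth for i in range(len(top) - 1)
        ]
        return drops.index(max(drops)) + 1


def _provisional_name(template: AlleleName, counter: dict[str, int]) -> AlleleName:
    """Name a called sequence after its template, disambiguating novel variants.

    Final W-series names are assigned by the database builder; call sets use
    the template name with a ``_v<k>`` decoration for sequence-distinct
    variants of the same template.
    """
    base = template.base()
    k = counter.get(base.render(), 0)
    counter[base.render()] = k + 1
    if k == 0:
        return base
    from dataclasses import replace

    return replace(base, extra=f"_v{k}")


def call_gdna_alleles(
    merged_reads: Iterable[MergedRead],
    db: ReferenceDatabase,
    subject_id: str = "subject",
    fraction: float = DEFAULT_FRACTION,
    min_len: int = 300,
    max_miscalls: float = 10.0,
    min_depth: float = 0.0,
    candidate_margin: Optional[int] = 5,
) -> SubjectCallSet:
    """Call germline alleles from merged gDNA amplicon reads.

    Pipeline: QC filter -> exact dedup -> depth cutoff -> per-confident
    sequence reference assignment, V trimming and productivity check ->
    re-deduplication of trimmed sequences with depths summed. ``min_depth``
    is an optional absolute depth floor applied on top of the relative
    cutoff (off by default). The returned call set's ``tally`` accounts for
    every input read exactly once.
    """
    merged = list(merged_reads)
    kept, rejected = qc_filter(merged, min_len=min_len, max_miscalls=max_miscalls)
    uniques = dedup_count(r.seq for r in kept)
    tally = {
        "input_reads": len(merged),
        "qc_rejected": Counter(reason for _, reason in rejected),
        "qc_kept": len(kept),
        "unique_sequences": len(uniques),
    }
    if not uniques:
        tally.update(below_cutoff_reads=0, nonproductive_reads=0, contributing_reads=0)
        return SubjectCallSet(
            subject_id=subject_id,
            method=Source.GDNA_MISEQ,
            alleles=[],
            params={"fraction": fraction, "min_len": min_len, "max_miscalls": max_miscalls},
            tally=tally,
        )
    profile = DepthProfile.from_uniques(uniques, fraction)
    tally["max_depth"] = profile.max_depth
    tally["cutoff"] = profile.cutoff
    confident = [u for u in uniques if u.depth > profile.cutoff and u.depth > min_depth]
    tally["below_cutoff_reads"] = sum(u.depth for u in uniques) - sum(
        u.depth for u in confident
    )
    tally["confident_uniques"] = len(confident)

    trimmed_depth: Counter[NucSeq] = Counter()
    trimmed_template: dict[NucSeq, AlleleName] = {}
    nonproductive_reads = 0
    nonproductive_reasons: Counter[str] = Counter()
    for u in confident:
        trimmed, ann = annotate_and_trim(u.seq, db, candidate_margin=candidate_margin)
        if trimmed is None or not ann.productive:
            nonproductive_reads += u.depth
            nonproductive_reasons[ann.fail_reason or "NO_HIT"] += 1
            continue
        trimmed_depth[trimmed] += u.depth
        trimmed_template.setdefault(trimmed, ann.best_allele)
    tally["nonproductive_reads"] = nonproductive_reads
    tally["nonproductive_reasons"] = nonproductive_reasons
    tally["contributing_reads"] = sum(trimmed_depth.values())

    name_counter: dict[str, int] = {}
    alleles = []
    for seq, depth in sorted(trimmed_depth.items(), key=lambda kv: (-kv[1], kv[0])):
        in_db = seq in db
        name = db.by_seq[seq].name if in_db else _provisional_name(trimmed_template[seq], name_counter)
        alleles.append(
            GermlineAllele(
                name=name,
                seq=seq,
                sources={Source.GDNA_MISEQ},
                subject_id=subject_id,
                depth=depth,
                novel=not in_db,
            )
        )
    return SubjectCallSet(
        subject_id=subject_id,
        method=Source.GDNA_MISEQ,
        alleles=alleles,
        params={"fraction": fraction, "min_len": min_len, "max_miscalls": max_miscalls,
                "min_depth": min_depth},
        tally=tally,
    )


def call_sanger_alleles(
    clones: Iterable[tuple[str, str]],
    db: ReferenceDatabase,
    subject_id: str = "subject",
    candidate_margin: Optional[int] = 5,
) -> SubjectCallSet:
    """Call germline alleles from Sanger clone sequences (name, seq pairs).

    Clones containing any character outside ACGT are excluded outright (the
    double-peak proxy); the survivors are assigned, trimmed and
    productivity-checked, then deduplicated. Every surviving unique sequence
    is a call — Sanger depth carries no error-separating information at
    colony scale.
    """
    clones = list(clones)
    ambiguous = 0
    clean: list[str] = []
    for _, seq in clones:
        if set(str(seq).upper()) - set("ACGT"):
            ambiguous += 1
        else:
            clean.append(str(seq).upper())
    trimmed_depth: Counter[NucSeq] = Counter()
    trimmed_template: dict[NucSeq, AlleleName] = {}
    nonproductive = 0
    for u in dedup_count(clean):
        trimmed, ann = annotate_and_trim(u.seq, db, candidate_margin=candidate_margin)
        if trimmed is None or not ann.productive:
            nonproductive += u.depth
            continue
        trimmed_depth[trimmed] += u.depth
        trimmed_template.setdefault(trimmed, ann.best_allele)
    name_counter: dict[str, int] = {}
    alleles = []
    for seq, depth in sorted(trimmed_depth.items(), key=lambda kv: (-kv[1], kv[0])):
        in_db = seq in db
        name = db.by_seq[seq].name if in_db else _provisional_name(trimmed_template[seq], name_counter)
        alleles.append(
            GermlineAllele(
                name=name,
                seq=seq,
                sources={Source.TOPO},
                subject_id=subject_id,
                depth=depth,
                novel=not in_db,
            )
        )
    tally = {
        "input_clones": len(clones),
        "ambiguous_excluded": ambiguous,
        "nonproductive_reads": nonproductive,
        "contributing_reads": sum(trimmed_depth.values()),
    }
    return SubjectCallSet(
        subject_id=subject_id,
        method=Source.TOPO,
        alleles=alleles,
        params={},
        tally=tally,
    )
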