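"""Readers and writers: FASTQ (Phred+33), FASTA, call-set TSV, JSON summaries.

FASTA goes through Bio.SeqIO. FASTQ records are read with a small four-line
reader so malformed input can be reported with the offending line number,
which the calling pipelines rely on when rejecting whole runs.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

from .model import (
    AlleleName,
    GermlineAllele,
    NucSeq,
    QualifiedRead,
    ReferenceDatabase,
    Source,
    SubjectCallSet,
)

PathLike = Union[str, Path]


class FastqParseError(ValueError):
    pass


def read_fastq(path: PathLike) -> list[QualifiedRead]:
    """Read a Phred+33 FASTQ file into :class:`QualifiedRead` records.

    Raises :class:`FastqParseError` naming the 1-based line number of the
    first malformed line.
    """
    reads: list[QualifiedRead] = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            if not header.startswith("@"):
                raise FastqParseError(
                    f"{path}: line {lineno}: expected '@' header, got {header[:20]!r}"
                )
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise FastqParseError(f"{path}: line {lineno}: truncated record")
            lineno += 3
            if not plus.startswith("+"):
                raise FastqParseError(f"{path}: line {lineno - 1}: expected '+' line")
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: line {lineno}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int) - 33
            if len(quals) and quals.min() < 0:
                raise FastqParseError(
                    f"{path}: line {lineno}: quality character below Phred+33 range"
                )
            reads.append(QualifiedRead(header[1:].split()[0], NucSeq(seq), quals))
    return reads


def write_fastq(reads: Iterable[QualifiedRead], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def read_fasta(path: PathLike) -> list[tuple[str, NucSeq]]:
    """Read FASTA into (full header description, sequence) pairs."""
    return [
        (rec.description, NucSeq(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[tuple[str, str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def _parse_anchor(description: str) -> Optional[int]:
    for tok in description.split()[1:]:
        if tok.startswith("anchor="):
            return int(tok.split("=", 1)[1])
    return None


def read_reference_fasta(path: PathLike, name: Optional[str] = None) -> ReferenceDatabase:
    """Parse a germline reference FASTA whose header first token is the allele name.

    Duplicate sequences are collapsed (keeping the first name) with a warning;
    duplicate names raise. J references may carry an ``anchor=<int>`` token
    giving the conserved-Trp codon offset.
    """
    alleles: list[GermlineAllele] = []
    seen_names: set[str] = set()
    seen_seqs: dict[NucSeq, str] = {}
    for desc, seq in read_fasta(path):
        token = desc.split()[0]
        try:
            aname = AlleleName.parse(token)
        except ValueError as e:
            raise ValueError(f"{path}: unparseable allele header '>{desc}'") from e
        rendered = aname.render()
        if rendered in seen_names:
            raise ValueError(f"{path}: duplicate allele name {rendered}")
        seen_names.add(rendered)
        if seq in seen_seqs:
            warnings.warn(
                f"{path}: sequence of {rendered} identical to {seen_seqs[seq]}; collapsed"
            )
            continue
        seen_seqs[seq] = rendered
        alleles.append(
            GermlineAllele(
                name=aname,
                seq=seq,
                sources={Source.REFERENCE},
                anchor=_parse_anchor(desc),
            )
        )
    return ReferenceDatabase(name or Path(path).stem, alleles)


def write_reference_fasta(db: ReferenceDatabase, path: PathLike) -> None:
    with open(path, "w") as fh:
        for a in db:
            anchor = f" anchor={a.anchor}" if a.anchor is not None else ""
            fh.write(f">{a.name.render()}{anchor}\n{a.seq}\n")


CALLSET_COLUMNS = ("subject", "method", "name", "depth", "sources", "seq")


def write_call_set_tsv(callset: SubjectCallSet, path: PathLike) -> None:
    """One tab-separated row per allele, sorted by rendered name."""
    with open(path, "w") as fh:
        fh.write("\t".join(CALLSET_COLUMNS) + "\n")
        for a in sorted(callset.alleles, key=lambda a: a.name.render()):
            sources = ";".join(sorted(s.value for s in a.sources))
            depth = "" if a.depth is None else str(a.depth)
            fh.write(
                f"{callset.subject_id}\t{callset.method.value}\t"
                f"{a.name.render()}\t{depth}\t{sources}\t{a.seq}\n"
            )


def read_call_set_tsv(path: PathLike) -> SubjectCallSet:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CALLSET_COLUMNS:
            raise ValueError(f"{path}: unexpected call-set columns {header}")
        alleles: list[GermlineAllele] = []
        subject = ""
        method = None
        for line in fh:
            subject, meth, name, depth, sources, seq = line.rstrip("\n").split("\t")
            method = Source(meth)
            alleles.append(
                GermlineAllele(
                    name=AlleleName.parse(name),
                    seq=NucSeq(seq),
                    sources={Source(s) for s in sources.split(";") if s},
                    subject_id=subject,
                    depth=int(depth) if depth else None,
                )
            )
    if method is None:
        raise ValueError(f"{path}: empty call set file has no method column value")
    return SubjectCallSet(subject_id=subject, method=method, alleles=alleles)


def write_json(obj: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
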