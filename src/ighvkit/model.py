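"""Core domain types for germline IGHV discovery.

Sequences are plain uppercase nucleotide strings (:class:`NucSeq`); allele
identity throughout the package is *by exact nucleotide sequence*, never by
name, because the same germline sequence carries different names in different
databases. Names follow the rhesus IGHV convention
``IGHV<family><gene-part>*<allele-id>`` optionally extended by a W-series
suffix (``_W`` + four digits) used for newly discovered alleles.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

_VALID_BASES = frozenset("ACGTN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class NucSeq(str):
    """An uppercase nucleotide string over {A, C, G, T, N}.

    Subclasses :class:`str` so it can be used anywhere a string is expected;
    construction validates the alphabet and normalises case.
    """

    def __new__(cls, s: str) -> "NucSeq":
        up = str(s).upper()
        bad = set(up) - _VALID_BASES
        if bad:
            raise ValueError(
                f"invalid nucleotide characters {sorted(bad)} in sequence"
            )
        return str.__new__(cls, up)

    def revcomp(self) -> "NucSeq":
        return NucSeq(self.translate(_COMPLEMENT)[::-1])


def revcomp(s: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return s.upper().translate(_COMPLEMENT)[::-1]


class Source(enum.Enum):
    """Evidence route through which an allele was observed."""

    GDNA_MISEQ = "GDNA_MISEQ"
    TOPO = "TOPO"
    MRNA_INFER = "MRNA_INFER"
    REFERENCE = "REFERENCE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_NAME_RE = re.compile(
    r"^IGH(?P<segment>[VJ])"
    r"(?P<gene>[1-7][^*]*)"
    r"\*(?P<allele_id>[0-9A-Za-z]+)"
    r"(?:_(?P<w>W\d{4}))?"
    r"(?P<extra>.*)$"
)


@dataclass(frozen=True, order=True)
class AlleleName:
    """Structured allele name, e.g. ``IGHV4-NL_33*01_W8423``.

    ``gene`` includes the leading family digit ("6-1", "4-NL_33"); ``extra``
    preserves any unrecognised decoration after the allele id verbatim so that
    parse/render round-trips losslessly.
    """

    gene: str
    allele_id: str
    w_suffix: Optional[str] = None
    segment: str = "V"
    extra: str = ""

    def __post_init__(self) -> None:
        if self.segment not in ("V", "J"):
            raise ValueError(f"segment must be V or J, got {self.segment!r}")
        if not self.gene or self.gene[0] not in "1234567":
            raise ValueError(f"gene must start with family digit 1-7: {self.gene!r}")
        if "*" in self.gene:
            raise ValueError("gene part may not contain '*'")
        if self.w_suffix is not None and not re.fullmatch(r"W\d{4}", self.w_suffix):
            raise ValueError(f"w_suffix must be 'W' + 4 digits: {self.w_suffix!r}")

    @property
    def family(self) -> str:
        """Family label, e.g. ``IGHV4``."""
        return f"IGH{self.segment}{self.gene[0]}"

    def render(self) -> str:
        s = f"IGH{self.segment}{self.gene}*{self.allele_id}"
        if self.w_suffix:
            s += f"_{self.w_suffix}"
        return s + self.extra

    def base(self) -> "AlleleName":
        """The name stripped of W-suffix and decorations (the gene template)."""
        return replace(self, w_suffix=None, extra="")

    @classmethod
    def parse(cls, text: str) -> "AlleleName":
        m = _NAME_RE.match(text)
        if m is None:
            raise ValueError(f"cannot parse allele name {text!r}")
        return cls(
            gene=m.group("gene"),
            allele_id=m.group("allele_id"),
            w_suffix=m.group("w"),
            segment=m.group("segment"),
            extra=m.group("extra") or "",
        )

    def __str__(self) -> str:
        return self.render()


@dataclass
class GermlineAllele:
    """A named germline V (or J) region nucleotide sequence with provenance.

    ``depth`` is the supporting read count where the calling route counts
    reads; ``anchor`` is only set on J references and gives the 0-based offset
    of the conserved Trp codon used as the CDR3 3' boundary.
    """

    name: AlleleName
    seq: NucSeq
    sources: set[Source] = field(default_factory=set)
    subject_id: Optional[str] = None
    depth: Optional[int] = None
    novel: bool = False
    anchor: Optional[int] = None

    def __post_init__(self) -> None:
        self.seq = NucSeq(self.seq)
        if len(self.seq) == 0:
            raise ValueError("allele sequence must be non-empty")


class ReferenceDatabase:
    """An ordered, name- and sequence-unique collection of germline alleles.

    Iteration order is deterministic (sorted by rendered name).
    """

    def __init__(self, name: str, alleles: Iterable[GermlineAllele]):
        self.name = name
        alleles = sorted(alleles, key=lambda a: a.name.render())
        self.by_name: dict[str, GermlineAllele] = {}
        self.by_seq: dict[NucSeq, GermlineAllele] = {}
        for a in alleles:
            key = a.name.render()
            if key in self.by_name:
                raise ValueError(f"duplicate allele name in database: {key}")
            if a.seq in self.by_seq:
                raise ValueError(
                    f"duplicate allele sequence in database: {key} vs "
                    f"{self.by_seq[a.seq].name.render()}"
                )
            self.by_name[key] = a
            self.by_seq[a.seq] = a
        self.alleles: list[GermlineAllele] = alleles

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self):
        return iter(self.alleles)

    def __contains__(self, seq: str) -> bool:
        return seq in self.by_seq

    def seqs(self) -> set[NucSeq]:
        return set(self.by_seq)


@dataclass
class QualifiedRead:
    """A read with per-base Phred qualities (Q, 0-60)."""

    id: str
    seq: NucSeq
    quals: Sequence[int]

    def __post_init__(self) -> None:
        self.seq = NucSeq(self.seq)
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.id}: quality length {len(self.quals)} != "
                f"sequence length {len(self.seq)}"
            )


@dataclass(frozen=True)
class UniqueSequence:
    """A deduplicated sequence with its read-depth count and depth rank."""

    seq: NucSeq
    depth: int
    rank: int


@dataclass
class SubjectCallSet:
    """The set of germline alleles called for one subject by one method.

    ``tally`` carries the conservation accounting of the calling pipeline
    (reads rejected at QC, uniques below the depth cutoff, non-productive,
    contributing) so every input read is accounted for exactly once.
    """

    subject_id: str
    method: Source
    alleles: list[GermlineAllele]
    params: dict = field(default_factory=dict)
    tally: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seqs = [a.seq for a in self.alleles]
        if len(set(seqs)) != len(seqs):
            raise ValueError("call set alleles must be pairwise sequence-distinct")
        for a in self.alleles:
            a.sources.add(self.method)

    def seqs(self) -> set[NucSeq]:
        return {a.seq for a in self.alleles}
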