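"""Synthetic IGHV locus and repertoire generator with known ground truth.

Every pipeline route is testable by truth recovery: the generator draws a
per-subject germline allele set (optionally including novel polymorphic
alleles absent from the base database), then emits

* gDNA amplicon read pairs with lognormal per-allele depth, a long
  low-depth tail of substitution-error uniques, and two-state Phred scores;
* Sanger colony sequences with occasional ambiguous bases (the proxy for
  chromatogram double peaks);
* naive V(D)J repertoire reads with junctional trimming, N additions, a
  Dirichlet clone-size structure over CDR3 clones, and near-zero somatic
  hypermutation;

together with ledgers mapping every emitted record to its source allele.
All generators are deterministic given (params, seed).

The bundled toy reference (~150 V alleles across the 7 rhesus IGHV
families, 6 J alleles with annotated Trp anchors) is produced once by
:func:`toy_reference` from a fixed seed and shipped as FASTA fixtures.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from typing import Optional

import numpy as np

from .io import read_reference_fasta
from .model import (
    AlleleName,
    GermlineAllele,
    NucSeq,
    QualifiedRead,
    ReferenceDatabase,
    STOP_CODONS,
    Source,
    revcomp,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_B2I = {b: i for i, b in enumerate("ACGT")}

USAGE_DIRICHLET_ALPHA = 0.6  # skew of per-allele usage weights
FLANK_LEN = 12  # constant primer/UTR flank length on amplicons
Q_HIGH, Q_LOW = 38, 12  # two-state per-base quality model
TOY_DB_SEED = 20240915


# ---------------------------------------------------------------------------
# toy reference construction


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame sequence with no stop codons."""
    codons = []
    for _ in range(n_codons):
        while True:
            c = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
            if c not in STOP_CODONS:
                codons.append(c)
                break
    return "".join(codons)


def _mutate(
    rng: np.random.Generator,
    seq: str,
    n_sub: int,
    protect_head: int = 6,
    protect_tail: int = 9,
    avoid_stops: bool = True,
) -> str:
    """Apply n_sub substitutions avoiding protected termini and stop creation."""
    s = list(seq)
    eligible = list(range(protect_head, len(s) - protect_tail))
    rng.shuffle(eligible)
    done = 0
    for pos in eligible:
        if done == n_sub:
            break
        old = s[pos]
        alts = [b for b in "ACGT" if b != old]
        rng.shuffle(alts)
        for b in alts:
            s[pos] = b
            if avoid_stops:
                c0 = pos - pos % 3
                if "".join(s[c0 : c0 + 3]) in STOP_CODONS:
                    s[pos] = old
                    continue
            done += 1
            break
    if done < n_sub:
        raise ValueError("could not place requested substitutions")
    return "".join(s)


_FAMILY_GENES = {1: 8, 2: 5, 3: 20, 4: 13, 5: 2, 6: 1, 7: 2}
_CAR_MOTIF = "TGTGCCAGA"  # conserved terminal Cys-Ala-Arg codons


def toy_reference(seed: int = TOY_DB_SEED) -> tuple[ReferenceDatabase, ReferenceDatabase]:
    """Build the bundled toy V and J reference databases from a fixed seed.

    Families descend from one ancestor (inter-family divergence ~12%,
    intra-family gene divergence ~4%, alleles 1-3 SNPs apart) so that
    family-level clades are recoverable and all pairs stay alignable.
    """
    rng = np.random.default_rng(seed)
    n_codons = 97  # 291 nt body + 9 nt terminal motif = 300 nt
    ancestor = _random_orf(rng, n_codons) + _CAR_MOTIF
    seen: set[str] = set()
    v_alleles: list[GermlineAllele] = []
    for fam, n_genes in _FAMILY_GENES.items():
        founder = _mutate(rng, ancestor, int(0.12 * len(ancestor)))
        for g in range(1, n_genes + 1):
            gene_seq = _mutate(rng, founder, int(0.04 * len(founder)))
            # occasional codon-level indel keeps lengths realistic
            r = rng.random()
            if r < 0.25:
                cut = 3 * int(rng.integers(12, n_codons - 12))
                gene_seq = gene_seq[:cut] + gene_seq[cut + 3 :]
            elif r < 0.40:
                cut = 3 * int(rng.integers(12, n_codons - 12))
                ins = _random_orf(rng, 1)
                gene_seq = gene_seq[:cut] + ins + gene_seq[cut:]
            n_all = int(rng.choice([2, 3, 4], p=[0.4, 0.35, 0.25]))
            allele_seq = gene_seq
            for a in range(1, n_all + 1):
                if a > 1:
                    for _ in range(50):
                        allele_seq = _mutate(rng, gene_seq, int(rng.integers(1, 4)))
                        if allele_seq not in seen:
                            break
                if allele_seq in seen:
                    continue
                seen.add(allele_seq)
                v_alleles.append(
                    GermlineAllele(
                        name=AlleleName(gene=f"{fam}-{g}", allele_id=f"{a:02d}"),
                        seq=NucSeq(allele_seq),
                        sources={Source.REFERENCE},
                    )
                )
    j_ancestor = _random_orf(rng, 4) + "TGG" + _random_orf(rng, 11)  # Trp codon at 12..14
    j_alleles = []
    j_seen: set[str] = set()
    for j in range(1, 7):
        for _ in range(50):
            # mutate only 3' of the conserved Trp codon so the anchor is shared
            j_seq = _mutate(rng, j_ancestor, 5, protect_head=15, protect_tail=3,
                            avoid_stops=False)
            if j_seq not in j_seen:
                break
        j_seen.add(j_seq)
        j_alleles.append(
            GermlineAllele(
                name=AlleleName(gene=f"{j}-1", allele_id="01", segment="J"),
                seq=NucSeq(j_seq),
                sources={Source.REFERENCE},
                anchor=12,
            )
        )
    return (
        ReferenceDatabase("toy_ighv", v_alleles),
        ReferenceDatabase("toy_ighj", j_alleles),
    )


def load_toy_db() -> ReferenceDatabase:
    """The bundled toy IGHV reference database."""
    with resources.as_file(resources.files("ighvkit.data") / "toy_ighv_v.fasta") as p:
        return read_reference_fasta(p, name="toy_ighv")


def load_toy_jdb() -> ReferenceDatabase:
    """The bundled toy IGHJ reference database (with CDR3 Trp anchors)."""
    with resources.as_file(resources.files("ighvkit.data") / "toy_ighj.fasta") as p:
        return read_reference_fasta(p, name="toy_ighj")


# ---------------------------------------------------------------------------
# simulation parameters and truth


@dataclass
class SimParams:
    """Generative settings for one simulated subject.

    Defaults state the study conditions being emulated: per-subject allele
    sets of ~120 with one fifth novel, lognormal amplicon depth with a sharp
    rank drop, low substitution error, 2x300 reads, a few hundred Sanger
    colonies, and a naive repertoire with near-zero SHM.
    """

    n_alleles: int = 120
    novel_fraction: float = 0.2
    snp_per_novel: int = 2
    depth_log_mean: float = 9.0
    depth_log_sd: float = 1.0
    per_base_error: float = 0.002
    read_len: int = 300
    n_read_pairs: int = 0  # 0 = use sampled depths; else rescale total to this
    n_colonies: int = 280
    ambiguous_base_rate: float = 0.1
    n_repertoire_reads: int = 20_000
    shm_rate: float = 0.001
    n_additions_max: int = 6
    v_trim_max: int = 6
    j_trim_max: int = 6
    clonality: float = 5.0  # Dirichlet concentration over CDR3 clone sizes

    def __post_init__(self) -> None:
        for name in ("novel_fraction", "per_base_error", "ambiguous_base_rate", "shm_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in (
            "n_alleles", "snp_per_novel", "read_len", "n_read_pairs", "n_colonies",
            "n_repertoire_reads", "n_additions_max", "v_trim_max", "j_trim_max",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.snp_per_novel < 1:
            raise ValueError("snp_per_novel must be >= 1")


@dataclass
class SimTruth:
    """Ground truth for one subject: allele set, usage weights, parameters."""

    subject_id: str
    alleles: list[GermlineAllele]
    usage_weights: np.ndarray
    params: SimParams
    seed: int

    def __post_init__(self) -> None:
        w = np.asarray(self.usage_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("usage weights must be >= 0 and sum to 1")
        self.usage_weights = w

    def seqs(self) -> set[NucSeq]:
        return {a.seq for a in self.alleles}

    def to_json(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "seed": self.seed,
            "params": asdict(self.params),
            "alleles": [
                {
                    "name": a.name.render(),
                    "seq": str(a.seq),
                    "novel": a.novel,
                    "weight": float(w),
                }
                for a, w in zip(self.alleles, self.usage_weights)
            ],
        }


def simulate_subject(
    base_db: ReferenceDatabase,
    params: SimParams,
    seed: int,
    subject_id: str = "S1",
    pool: Optional[list[GermlineAllele]] = None,
) -> SimTruth:
    """Draw a subject's germline allele set and usage weights.

    ``round(n_alleles * novel_fraction)`` sampled alleles are replaced by
    novel variants carrying ``snp_per_novel`` substitutions that avoid the
    terminal hexamers, never create a stop codon, and differ from every base
    database sequence. ``pool`` restricts sampling to a sub-population
    allele pool (for population-structured cohorts).
    """
    rng = np.random.default_rng(seed)
    source = sorted(pool if pool is not None else list(base_db), key=lambda a: a.name.render())
    if len(source) < params.n_alleles:
        raise ValueError(
            f"base pool has {len(source)} alleles < n_alleles={params.n_alleles}"
        )
    idx = rng.choice(len(source), size=params.n_alleles, replace=False)
    chosen = [source[i] for i in sorted(idx)]
    n_novel = round(params.n_alleles * params.novel_fraction)
    novel_idx = set(rng.choice(params.n_alleles, size=n_novel, replace=False).tolist())
    base_seqs = base_db.seqs()
    taken = set(base_seqs)
    alleles: list[GermlineAllele] = []
    for i, a in enumerate(chosen):
        if i in novel_idx:
            for _ in range(100):
                mut = _mutate(
                    rng, str(a.seq), params.snp_per_novel,
                    protect_head=6, protect_tail=6,
                )
                if mut not in taken:
                    break
            else:  # pragma: no cover - essentially impossible
                raise RuntimeError("failed to generate a distinct novel allele")
            taken.add(mut)
            alleles.append(
                GermlineAllele(
                    name=replace(a.name.base(), extra=f"_n{i:03d}"),
                    seq=NucSeq(mut),
                    sources=set(),
                    subject_id=subject_id,
                    novel=True,
                )
            )
        else:
            alleles.append(
                GermlineAllele(
                    name=a.name,
                    seq=a.seq,
                    sources=set(),
                    subject_id=subject_id,
                    novel=False,
                )
            )
    weights = rng.dirichlet([USAGE_DIRICHLET_ALPHA] * params.n_alleles)
    return SimTruth(
        subject_id=subject_id,
        alleles=alleles,
        usage_weights=weights,
        params=params,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# error machinery


_LUT = np.zeros(256, dtype=np.uint8)
for _b, _i in _B2I.items():
    _LUT[ord(_b)] = _i


def _apply_substitutions(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    """Substitution errors at ``rate`` per base on a uint8 ACGT array (copy)."""
    out = arr.copy()
    if rate <= 0:
        return out
    n_err = rng.binomial(len(arr), rate)
    if n_err == 0:
        return out
    pos = rng.choice(len(arr), size=n_err, replace=False)
    shift = rng.integers(1, 4, size=n_err)
    out[pos] = BASES[(_LUT[out[pos]] + shift) % 4]
    return out


def _quals(rng: np.random.Generator, n: int) -> np.ndarray:
    """Two-state per-base quality with a read-level low-quality propensity."""
    low_frac = rng.beta(1.0, 9.0)
    low = rng.random(n) < low_frac
    return np.where(low, Q_LOW, Q_HIGH).astype(int)


def _rand_flank(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# gDNA amplicon route


@dataclass
class GdnaRun:
    pairs: list[tuple[QualifiedRead, QualifiedRead]]
    ledger: dict[str, str] = field(repr=False)  # read id -> source allele name
    sampled_depths: dict[str, int] = field(default_factory=dict)


def simulate_gdna_run(truth: SimTruth, params: SimParams, seed: int) -> GdnaRun:
    """Emit overlapping amplicon read pairs per allele with lognormal depth.

    Each molecule is an allele flanked by constant 12-nt primer/UTR context
    with independent substitution errors at ``per_base_error``; reads are the
    first/last ``read_len`` bases (reverse read reverse-complemented).
    """
    rng = np.random.default_rng(seed)
    max_len = max(len(a.seq) for a in truth.alleles)
    if params.read_len * 2 < max_len + 20:
        raise ValueError("read_len*2 must be >= max allele length + 20 for overlap")
    depths = np.ceil(
        rng.lognormal(params.depth_log_mean, params.depth_log_sd, len(truth.alleles))
    ).astype(int)
    if params.n_read_pairs > 0:
        scale = params.n_read_pairs / depths.sum()
        depths = np.maximum(1, np.round(depths * scale)).astype(int)
    flank5 = _rand_flank(rng, FLANK_LEN)
    flank3 = _rand_flank(rng, FLANK_LEN)
    pairs: list[tuple[QualifiedRead, QualifiedRead]] = []
    ledger: dict[str, str] = {}
    sampled: dict[str, int] = {}
    for a, depth in zip(truth.alleles, depths):
        amplicon = np.frombuffer((flank5 + str(a.seq) + flank3).encode(), dtype=np.uint8)
        sampled[a.name.render()] = int(depth)
        for m in range(int(depth)):
            mol = _apply_substitutions(rng, amplicon, params.per_base_error)
            rid = f"{truth.subject_id}:{a.name.render()}:{m}"
            fwd_seq = mol[: params.read_len].tobytes().decode()
            rev_seq = revcomp(mol[-params.read_len :].tobytes().decode())
            fwd = QualifiedRead(rid, NucSeq(fwd_seq), _quals(rng, len(fwd_seq)))
            rev = QualifiedRead(rid, NucSeq(rev_seq), _quals(rng, len(rev_seq)))
            pairs.append((fwd, rev))
            ledger[rid] = a.name.render()
    return GdnaRun(pairs=pairs, ledger=ledger, sampled_depths=sampled)


# ---------------------------------------------------------------------------
# Sanger colony route


@dataclass
class SangerRun:
    colonies: list[tuple[str, str]]  # (colony id, sequence)
    ledger: dict[str, str]  # colony id -> source allele name


def simulate_sanger_colonies(truth: SimTruth, params: SimParams, seed: int) -> SangerRun:
    """Sample colonies by usage weight; a fraction carry one ambiguous N base."""
    rng = np.random.default_rng(seed)
    flank5 = _rand_flank(rng, FLANK_LEN)
    flank3 = _rand_flank(rng, FLANK_LEN)
    colonies: list[tuple[str, str]] = []
    ledger: dict[str, str] = {}
    if params.n_colonies == 0:
        return SangerRun(colonies, ledger)
    picks = rng.choice(len(truth.alleles), size=params.n_colonies, p=truth.usage_weights)
    for c, i in enumerate(picks):
        a = truth.alleles[int(i)]
        seq = flank5 + str(a.seq) + flank3
        if rng.random() < params.ambiguous_base_rate:
            pos = int(rng.integers(0, len(seq)))
            seq = seq[:pos] + "N" + seq[pos + 1 :]
        cid = f"{truth.subject_id}:colony{c:04d}"
        colonies.append((cid, seq))
        ledger[cid] = a.name.render()
    return SangerRun(colonies, ledger)


# ---------------------------------------------------------------------------
# naive IgM repertoire route


@dataclass
class RepertoireRun:
    reads: list[tuple[str, str]]
    ledger: dict[str, dict] = field(repr=False)  # read id -> truth record


def simulate_naive_repertoire(
    truth: SimTruth,
    j_db: ReferenceDatabase,
    params: SimParams,
    seed: int,
) -> RepertoireRun:
    """Emit naive V(D)J reads with clone structure and near-zero SHM.

    Clones (one V, one J, one junction and hence one CDR3 each) are drawn
    first — trims follow a geometric law favouring no trimming, N additions
    are uniform — then reads are multinomially allocated to clones with
    Dirichlet(``clonality``) clone sizes. SHM substitutions are applied per
    read over the full sequence. The ledger records the true V, J, CDR3,
    V-trim and SHM count of every read.
    """
    rng = np.random.default_rng(seed)
    if len(j_db) == 0:
        raise ValueError("J database is empty")
    n_reads = params.n_repertoire_reads
    reads: list[tuple[str, str]] = []
    ledger: dict[str, dict] = {}
    if n_reads == 0:
        return RepertoireRun(reads, ledger)
    n_clones = max(1, n_reads // 10)
    j_list = list(j_db)
    v_idx = rng.choice(len(truth.alleles), size=n_clones, p=truth.usage_weights)
    j_idx = rng.integers(0, len(j_list), size=n_clones)
    flank5 = _rand_flank(rng, 10)

    def geom_trim(mx: int) -> int:
        return min(int(rng.geometric(0.4)) - 1, mx)

    clones = []
    for k in range(n_clones):
        v = truth.alleles[int(v_idx[k])]
        j = j_list[int(j_idx[k])]
        v_trim = geom_trim(params.v_trim_max)
        j_trim = min(geom_trim(params.j_trim_max), (j.anchor or len(j.seq)))
        n1 = _rand_flank(rng, int(rng.integers(0, params.n_additions_max + 1)))
        d = _rand_flank(rng, int(rng.integers(0, 11)))
        n2 = _rand_flank(rng, int(rng.integers(0, params.n_additions_max + 1)))
        vs = str(v.seq)
        js = str(j.seq)
        body = vs[: len(vs) - v_trim] + n1 + d + n2 + js[j_trim:]
        anchor_end = (j.anchor or 0) + 3 - j_trim
        cdr3 = vs[len(vs) - 9 : len(vs) - v_trim] + n1 + d + n2 + js[j_trim:][:anchor_end]
        clones.append((v, j, v_trim, body, cdr3))
    sizes = rng.multinomial(n_reads, rng.dirichlet([params.clonality] * n_clones))
    r = 0
    for k, size in enumerate(sizes):
        v, j, v_trim, body, cdr3 = clones[k]
        base = np.frombuffer((flank5 + body).encode(), dtype=np.uint8)
        for _ in range(int(size)):
            arr = _apply_substitutions(rng, base, params.shm_rate)
            n_shm = int(np.count_nonzero(arr != base))
            rid = f"{truth.subject_id}:r{r:06d}"
            reads.append((rid, arr.tobytes().decode()))
            ledger[rid] = {
                "v": v.name.render(),
                "v_seq": str(v.seq),
                "j": j.name.render(),
                "cdr3": cdr3,
                "clone": k,
                "v_trim": v_trim,
                "n_shm": n_shm,
            }
            r += 1
    return RepertoireRun(reads, ledger)
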