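# ighvkit

Germline IGHV allele discovery for rhesus macaque B-cell receptor studies:
calling immunoglobulin heavy-chain variable (IGHV) germline alleles from
three independent data routes, cross-validating them against each other,
and curating the results into an updated reference database.

Rhesus macaque IG germline loci are highly polymorphic — an individual
animal carries on the order of 100–140 IGHV alleles, and a substantial
fraction of them is missing from any current reference database. Accurate
antibody-lineage analysis (somatic hypermutation levels, clonal ontogeny)
depends on knowing each animal's personal germline set. `ighvkit`
implements the three complementary discovery routes and everything around
them:

1. **gDNA amplicon sequencing** — merge 2×300 paired reads, drop reads
   shorter than 300 nt or with more than 10 expected miscalls
   (Σ 10^(−Q/10)), collapse identical reads, rank unique sequences by depth
   and keep those above a relative depth threshold (default 0.67% of the
   maximum depth), assign each to its closest reference allele with affine
   glocal alignment, trim to the V region ending at the conserved C-terminal
   motif, and discard frameshifted/stop-containing sequences.
2. **Sanger colonies (TOPO route)** — individual cloned molecules; no depth
   threshold, but any clone with an ambiguous base (the computational proxy
   for a chromatogram double peak) is excluded.
3. **Naive IgM repertoire inference** — expressed V(D)J transcripts are
   annotated with V, J and CDR3; a candidate germline allele must be
   supported by ≥5 reads, ≥3 distinct CDR3s and ≥2 distinct J alleles, the
   diversity evidence that separates true germline polymorphism from
   clonally shared somatic hypermutation.

On top of the routes: cross-method/subject comparison (Jaccard similarity,
Venn regions, validation rates, evidence tables, average-linkage
clustering), deterministic W-series naming (`IGHV4-NL_33*01_W8423`-style:
nearest gene template + `W` + four digits) and sequence-level database
union, plus evaluation (SHM profiles against candidate databases, allele
usage frequencies, neighbor-joining family trees over Jukes–Cantor
distances).

A first-class **synthetic data generator** emulates all three data types
from a known per-subject truth (lognormal amplicon depth with an error
tail, Phred-scored substitution errors, junctional trimming/N-additions,
Dirichlet clone structure, skewed V usage), so every pipeline stage is
testable by truth recovery. A ~150-allele toy reference across the seven
rhesus IGHV families is bundled.

## Worked example

`examples/01_gdna_calling.py` simulates one subject (60 alleles, 20% of
them absent from the reference) and runs the full gDNA route:

```
read pairs sequenced : 18488
unique sequences     : 8290
depth cutoff         : 5.7 (max depth 857)
confident uniques    : 60
alleles called       : 60
sensitivity          : 1.000
precision            : 1.000
novel (not in db)    : 12
```

The ~8,000 unique sequences are dominated by the low-depth error tail; the
relative depth cutoff reduces them to exactly the 60 confident sequences,
which after trimming and productivity checks reproduce the subject's true
allele set, including all 12 novel alleles. The other examples cover the
Sanger and repertoire routes (`02`), cross-validation and W-series database
building (`03`), and SHM/usage/tree evaluation (`04`); each prints the
numbers it computes and what they mean.

There is also a thin CLI (`ighvkit simulate|qc|call-gdna|call-sanger|
infer-mrna|compare|build-db|evaluate|run-all`) over the same library
functions; `ighvkit run-all --config cfg.yaml` chains the whole pipeline
for a simulated cohort and writes per-stage call sets plus a JSON manifest.

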