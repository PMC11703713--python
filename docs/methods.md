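# Methods

This note documents the models, algorithms, parameter defaults and
simulation scales behind `ighvkit`, and what the passing test suite does
and does not establish about real data.

## Sequence identity is the unit of account

Alleles are compared by exact nucleotide sequence everywhere: two alleles
one substitution apart are distinct, and the same sequence carried under
different names in different databases is one allele. Call sets, evidence
tables, Venn/Jaccard comparisons and database unions all operate on
sequence sets; names are presentation. This matches how germline databases
are reconciled in practice and avoids any dependence on nomenclature.

## Alignment engine

All assignment, trimming and identity measurement goes through one glocal
(semi-global) affine alignment: the reference may align anywhere inside the
query and either sequence's overhangs are free. Scoring is match +1,
mismatch −2, gap open −4, gap extend −1 (a length-k gap costs 4 + (k−1)).
These are declared defaults, not fitted values. Identity is
matches / aligned columns, with internal gap columns counting against it.
Best-hit ties break to the lexicographically smallest allele name so every
run is reproducible.

For speed, candidate references are pre-ranked by edlib edit distance
(infix mode, staged distance bounds) and only candidates within a small
margin of the best are re-scored with the affine aligner. With
substitution-dominated data the two rankings agree; `candidate_margin=None`
forces exhaustive affine scoring, and the test suite checks the affine
score against an independent brute-force dynamic-programming oracle and
the pre-screened assignment against exhaustive scoring.

One subtlety is the V 3′ boundary on V(D)J rearranged reads. With
edge-based free end gaps, the cheapest path for a 3′-trimmed V is often to
absorb the first junctional bases as terminal mismatches (−2 each) rather
than leave the reference tail unaligned behind an interior deletion (−4).
The repertoire annotator therefore refines the V end to the last run of at
least 6 consecutive matching columns; 6 because junctions occasionally
chance-match the conserved 3-nt terminal motif, which defeats a shorter
run. gDNA amplicon reads contain the complete V region and are trimmed at
the plain alignment end.

## V-region trimming and productivity

Reference alleles are stored already ending at the conserved C-terminal
motif (the Cys-containing final codons), so "trim to the V region" is
"cut the query at the coordinate aligned to the reference's last base"; a
query whose alignment stops earlier is flagged truncated rather than
guessed at. A trimmed sequence is productive when its alignment gaps total
a multiple of 3 with every gap run a multiple of 3 (no frameshift), no
in-frame codon — frame taken from reference codon 1 — is TAA/TAG/TGA, and
no ambiguous base is present.

## gDNA route: the depth threshold

After QC (length ≥ 300 nt, expected miscalls Σ 10^(−Q/10) ≤ 10 — the bound
is inclusive, only *more than* 10 is excluded) and exact deduplication,
unique sequences are ranked by depth and only those **strictly above**
`fraction × max_depth` (default fraction 0.0067) are annotated. No
error-clustering of near-identical sequences is attempted: the threshold
alone separates errors, which is exactly the regime the route is designed
for — deep amplicon sequencing where a real allele's depth is orders of
magnitude above any specific error variant's. Post-trim re-deduplication
merges uniques differing only in primer/UTR flanks, summing depths.
An optional absolute floor (`min_depth`) is exposed separately because a
fixed fraction and a fixed read count disagree as soon as per-run maxima
vary; the fraction is authoritative, the floor off by default. A `knee`
diagnostic reports the largest relative depth drop in the top ranks for
comparison with the fixed fraction.

## Sanger route

Any clone containing a character outside ACGT is discarded outright — the
computational proxy for double-peak chromatogram review. Survivors go
through the same assignment/trim/productivity machinery; every surviving
unique sequence is a call, because colony counts carry no error-separating
information at this scale.

## Repertoire route

Single pass, deliberately explicit: reads are grouped by assigned V and
then sub-grouped by their exact observed V-region string. Sub-groups whose
exemplar covers the full reference become candidates when supported by
≥ `min_reads` = 5 reads with ≥ `min_cdr3` = 3 distinct CDR3s and
≥ `min_j` = 2 distinct J alleles. Reads 3′-truncated by more than 12 nt are
ignored; shorter truncations join a full-length sub-group only when exactly
one exemplar has them as a prefix (ambiguous prefixes are conservatively
dropped). The candidate consensus is the shared full-length V region
itself — never extended by inferred bases. CDR3 runs from the reference's
final three codons (the conserved Cys motif) to the conserved J tryptophan
codon, whose offset is annotated on each J reference (`anchor=` header
token). This is a simplified stand-in for iterative windowed-consensus
tools; the simplification is safe here because IgM reads are near-germline
and the simulator emits substitution-only errors, and it is the route's
main documented limitation for real data.

## W-series naming and database union

A novel allele is named after its nearest reference allele (the gene
template, by the same alignment), with suffix `W` + four digits derived
from a SHA-256 checksum of the sequence modulo 10000, linearly probed on
collision. How the original four-digit codes were chosen is not documented
anywhere; a checksum makes reruns reproduce every name, which we consider
the property worth guaranteeing. Unions are sequence-level: the earliest
input database owns the name of a shared sequence, other names become
synonyms; same-name/different-sequence clashes keep the first owner and
rename the newcomer as if novel.

## Evaluation

SHM% of a read is 100 − identity of its best V hit, gaps counted as
mismatches so indel-bearing reads are penalised rather than favoured.
Adding alleles to a database can only lower a read's SHM% (minimum over a
larger set) — this monotonicity is the mechanism by which a more complete
database "reduces SHM" and is asserted as a property test. Trees are
neighbor joining over Jukes–Cantor-transformed p-distances (mismatch
fraction over matched columns, p ≥ 0.75 capped at 10.0) — a distance-based
stand-in within the general-time-reversible model family. Full
maximum-likelihood optimisation is deliberately out of scope; the only
asserted tree property is family-level clading, which NJ recovers.

Percentages in comparison summaries are rounded half-up to integers.
"Validated by ≥2 methods" counts calling routes; "found in ≥2 subjects or
two sample sources" counts distinct subjects, or distinct biological
materials within a subject (the two gDNA routes share one material, the
repertoire route is the other).

## Synthetic data generator

The generator defines the study conditions the pipeline is tested under.

* **Subject truth** — `n_alleles` = 120 drawn without replacement from the
  base (or population-pool) database; `novel_fraction` (default 0.2,
  rounded) of them replaced by variants carrying `snp_per_novel` = 2
  substitutions that avoid the terminal hexamers and never create stops.
  Usage weights are Dirichlet(0.6), giving the skewed per-allele expression
  seen in real repertoires (top allele ~5–9%).
* **Population pools** — for cohort experiments, novel variants are added
  to a shared pool first and subjects sample from the pool, so novel
  alleles recur across subjects the way database-absent germline alleles
  do in a real population.
* **gDNA amplicons** — per-allele depth is lognormal(`depth_log_mean`,
  `depth_log_sd` = 1), ceiling-rounded: a heavy top and a long shallow
  tail, reproducing the sharp rank-depth drop near the true allele count.
  Molecules are the allele plus constant 12-nt flanks with independent
  substitution errors at `per_base_error` = 0.002; reads are the first/last
  `read_len` = 300 bases. Per-base Phred scores follow a two-state model
  (Q38/Q12) with a Beta(1,9) per-read low-quality propensity; error
  positions are drawn independently of the simulated Q scores — the Q model
  exists to exercise the miscall filter, not to correlate with errors.
* **Sanger colonies** — alleles sampled by usage weight; with probability
  `ambiguous_base_rate` = 0.1 a colony carries one N; no other errors.
* **Repertoire** — clones (one V, J, junction and hence CDR3 each) are
  drawn first: geometric junctional trims favouring zero (capped at
  `v_trim_max`/`j_trim_max` = 6), uniform N-additions up to 6 nt and a 0–10
  nt D fragment; clone sizes are Dirichlet(`clonality`)-multinomial over
  reads, and SHM substitutions hit each read at `shm_rate` = 0.001/base.

All generators are deterministic given (params, seed), and every emitted
record appears exactly once in a truth ledger.

### Problem sizes used in tests and the acceptance script

The default `depth_log_mean` of 9 states the depth regime of deep MiSeq
amplicon runs (per-allele depths in the thousands, maxima near 10^5). The
bundled experiments run at `depth_log_mean` = 5.5 (≈45,000 read pairs per
subject): the depth threshold is *relative*, so what matters for the
calling behaviour is the ratio between the cutoff (0.0067 × max depth) and
the expected depth of any specific single-error variant
(≈ max_depth × per_base_error ⁄ 3). At log-mean 5.5 that ratio is ≈10,
the same operating regime as the deep runs, while a much smaller log-mean
would collapse it and make the threshold fail for reasons that are pure
scale artifacts. The acceptance script uses 4 subjects × 120 alleles for
the gDNA and Sanger routes, 20,000 IgM reads for the repertoire route, and
a 1,500-read clonal-dominance control; the test suite uses the same
conditions with a smaller repertoire (8,000 reads).

Truth-recovery metrics are measured against what each route could in
principle observe: alleles whose sampled depth cleared the cutoff (gDNA),
alleles hit by at least one ambiguity-free colony (Sanger), and alleles
supported by unmutated reads at the candidate thresholds including one
untrimmed exemplar (repertoire).

## What the simulations do not capture

No PCR chimeras, no indel sequencing errors (substitution-only), no primer
or isotype artifacts, no correlation between quality scores and errors, no
genomic context (the gene-vs-allele question is out of scope without locus
positions). Passing truth-recovery tests therefore demonstrates the
pipeline logic — filtering, thresholding, grouping, naming, accounting —
under the stated generative assumptions, not robustness to every failure
mode of real libraries. The repertoire inference is an explicit
simplification of iterative consensus-based tools and is expected to be
less sensitive than they are on noisy real data; the exact-substring
sub-grouping is the first thing to revisit if indel errors matter.

The bundled toy reference (~150 V alleles, 7 families, one ancestor with
~12% inter-family, ~4% intra-family gene and 1–3 SNP allele divergence;
6 J alleles sharing a conserved Trp anchor at offset 12) is generated once
from a fixed seed and shipped as FASTA; a test asserts the shipped files
match the seeded builder.
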