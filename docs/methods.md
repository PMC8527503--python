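# Methods

This note documents the models and procedures ctenokit implements, the
parameters that matter, the numerical conventions, and what the
synthetic-data generators do and do not emulate.

## Coordinates and formats

All internal coordinates are 0-based, half-open, on every data type.
GFF3 (1-based inclusive) and pileup positions (1-based) are converted at
the I/O boundary; BED passes through unchanged. One convention everywhere
removes the most common silent-bug class in interval analytics.

Pileups enter as a 6-column TSV — seqid, 1-based position, depth, reads
matching the reference base, reads supporting a substitution allele,
reads supporting an insertion/deletion allele — producible per site from
`samtools mpileup` output by counting read bases per category. The TSV
contract keeps the estimator testable without an aligner; quality
filtering is the pileup producer's responsibility. Each support count
must not exceed depth; the three counts need not sum to depth
(multi-allelic remainders are allowed).

## Depth-conditioned heterozygosity

Model: in a composite diploid assembly, reads from both haplotypes map to
properly collapsed sites, so those sites sit at the modal depth D\* of
the genome-wide depth histogram; erroneously duplicated (haplotig) sites
sit near D\*/2 with reads from a single haplotype. Conditioning on depth
= D\* therefore selects exactly the sites where a heterozygous position
shows a ~50/50 allele split.

- **Allele-balance band** `[lower, upper]`, default `[0.30, 0.70]`: a
  site is heterozygous when f = ref/depth lies in the band; f ≥ upper is
  homozygous-reference, f ≤ 1−upper homozygous-alternate. Exact halves
  are impossible at odd depths, so "half the reads" must be a band; 0.30
  / 0.70 is wide enough that a Binomial(178, ½) fraction essentially
  never escapes it (sd ≈ 0.037) yet narrow enough that sequencing errors
  at 0.2%/base never enter it. With an asymmetric band (lower > 1−upper)
  a gap zone appears; such "other" sites stay in the denominator — the
  estimate divides by **all** sites at D\*.
- **Depth window** default 0 (exactly D\*); a ±window exists for sparse
  data.
- Het subtype: indel if indel-supporting reads outnumber
  substitution-supporting reads, SNP otherwise (ties → SNP, since
  substitutions dominate). Modal-depth ties → lowest depth. Both
  tie-breaks are deterministic.
- Region classes use precedence exonic > intronic > intergenic: a base
  exonic in any transcript of any gene is exonic; inside a gene span but
  not exonic is intronic. Per-site assignment is unique, so stratum site
  counts at D\* sum exactly to the depth-histogram count at D\*.

Known limitation: short reads from a divergent allele may fail to map in
regions of very high combined SNP+indel heterozygosity, capping the
measurable rate; the estimator inherits whatever mapping bias the pileup
carries.

## Nested intronic genes

Introns are per-transcript exon gaps, deduplicated by coordinates within
each gene. The longest ⌈0.005·N⌉ introns genome-wide are excluded before
detection — leader-sharing first exons create artifactual mega-introns
that would otherwise swallow whole gene neighborhoods (ties in length are
broken by position so the excluded set is deterministic).

Nesting definition (shared verbatim by the detector and the brute-force
test oracle): transcript T of gene G (G ≠ H) nests in intron I of a
transcript of host H iff the bp of T extending beyond I on each side is
(a) at most `tolerance` × T's genomic span (default 0.15), and (b) no
larger than the host exon flanking that side — overlap must be *with the
host's exons*, not past them. The allowance is an integer floor with a
1e-9 epsilon so that a decimal tolerance like 0.15 allows exactly 150 bp
on a 1000-bp transcript. One qualifying transcript suffices; both
orientations count (orientation is recorded, never filtered). Each NI
gene is reported once with its minimal-span qualifying intron; nesting
depth is 2 when that intron belongs to a gene that is itself NI (capped
at 2 in reporting). The tolerance denominator is the nested transcript's
genomic span — the natural reading of end-overlap "at the 5′ and 3′ ends
of the nested transcript".

The exonic-bp census uses strand-collapsed exon unions (genome-wide, and
over NI genes), making the percentage invariant under transcript
duplication. TE flanks are the segments between the host intron
boundaries and the nested gene's span; a side is flanked when ≥ 1 bp of a
TE interval overlaps the segment, with no extra distance window — the
host intron itself bounds the search.

## Microsynteny

Reciprocal best hits: best hit per query by bitscore, ties by lower
e-value then lexicographic subject id; duplicate (query, subject) rows
keep the highest bitscore. A pair survives iff each member is the other's
best.

Chaining: genes get per-sequence ordinal indices by start coordinate
(ties by end then id). A chain is a subsequence of pairs strictly
increasing in A-order and strictly monotone in B-order — orientation
(forward/reverse) is fixed by the first step — where every consecutive
step has ≤ `max_intervening` (default 5) intervening genes *on both
genomes* (all annotated genes count, matched or not) and ≤ `max_gap`
(default 30 kb) start-to-start distance *on both genomes*. Symmetric
enforcement is the stricter, order-independent reading and makes
genome-swap give identical blocks. Blocks require ≥ `min_block` genes
(default 3) and are extracted longest-first (dynamic program over chain
edges); ties go to the lexicographically smallest A-ordinal sequence,
then forward orientation. Pairs belong to at most one block. Reverse
chains are allowed — inversions preserve collinearity — and individual
gene strands are ignored.

Macrosynteny: each A-sequence is assigned the B-sequence receiving the
plurality of its ortholog pairs (ties → lexicographically smallest,
flagged ambiguous), with Oxford dot-plot coordinates emitted as gene
start positions.

## Trans-spliced leader

The scan aligns the 44-bp leader motif semi-globally (free end gaps on
the genome side) against both strands. Identity is matching columns over
**all** alignment columns — gaps count against identity — the stricter
convention, configurable. A match requires identity ≥ 0.90 and an
aligned genomic span within [35, 48] bp. Implementation: iterative
best-hit extraction with edlib's infix search — every location at the
current optimal edit distance is scored exactly from its global
alignment cigar, masked, and the search repeats until the optimal
distance exceeds ⌊(1−min_identity)·max_len⌋. Overlapping candidates
reduce to the highest-identity non-overlapping set, ties leftmost.

A consequence of windowed scanning worth knowing: a copy carrying
substitutions at the motif's extreme ends can match over a trimmed,
shorter window at ≥ 90% identity. That is correct behavior under the
definition (the trimmed window genuinely is ≥ 90% identical and within
the length range); threshold-sharpness experiments therefore plant
interior substitutions, where 4 substitutions (40/44 = 0.909) match and
5 (39/44 = 0.886) cannot be rescued by trimming.

Read-prefix detection: a read carries the leader when some motif suffix
of length ≥ `min_suffix` (default 15) matches the read's 5′ start
ungapped with mismatch fraction ≤ 1−min_identity; reads are also tested
reverse-complemented. Fifteen bases make random hits rare (4⁻¹⁵ per
position before mismatch allowance) while tolerating the 5′ shearing
common in full-length cDNA reads — so measured fractions are lower
bounds. First exons are taken in transcript orientation (genomic last
exon on minus-strand transcripts); genes cluster by the exact genomic
interval of their first exon's motif match.

## TAD boundary permutation test

Observed statistic: the median, over deduplicated TAD boundary points, of
the distance to the nearest gene — 0 for points inside any gene span,
otherwise bp to the nearest gene start/end on that chromosome (a
TSS-only distance is available behind a flag). Chromosomes without genes
contribute their length and are flagged.

Null: each of n permutations (default 1000) re-places every TAD with its
observed length — chromosome drawn with probability proportional to
length among chromosomes it fits, start uniform — and recomputes the
same median. Placed TADs may overlap: no exclusion constraint is
imposed, because overlap-free packing changes the null subtly and is not
part of the question being asked. One-sided p with add-one correction,
p = (#{null ≤ observed} + 1)/(n + 1) ∈ [1/(n+1), 1]; at n = 999 the
attainable minimum is 0.001.

## Synthetic data

All draws in one generator call flow from a single `numpy` Generator
seeded by the caller; identical seed and configuration give identical
output. Defaults are the operating points the estimators were designed
for: mean depth 178×, SNP rate 0.02, indel rate 0.012, per-read-base
error 0.002, 44-bp leader at ≥ 90% identity, 60-kb TADs.

- **Diploid pileup.** Depth is Poisson around the mean (the observed
  depth peak is unimodal and near-symmetric; a negative-binomial switch
  exists for overdispersed data). At a heterozygous site each read comes
  from either haplotype with probability ½; an error flips a read's
  support to one of the two wrong categories uniformly. Indels are
  planted as single-position pileup signals, not realized in sequence
  space — the estimator consumes pileups only.
- **Nested annotations.** Two-exon hosts around one large intron
  (default 30 kb); singly nested genes placed inside, optionally
  extended into the host's flanking exon by a requested fraction of
  their own length; doubly nested genes inside a carrier NI gene's
  intron. The truth table records (host, nested, depth, overlap
  fraction).
- **Ortholog tables.** Genome B is genome A's gene order transformed by
  inversions (segment reversed in place) and relocations (each gene
  moved to its own separate sequence). The default 16-kb start-to-start
  spacing is deliberate: under the 30-kb gap rule a chain can never skip
  a gene, so the construction segments are exactly the detectable
  blocks and planted truth is unambiguous. Decoy hits at lower bitscore
  exercise the RBH filter.
- **Leader sequences.** Uniform random background; copies mutated at
  ⌈divergence·44⌉ distinct positions, placed non-overlapping on random
  strands. `interior_margin` keeps mutations away from motif ends for
  threshold experiments (see above).
- **TAD landscape.** Genes tile chromosomes (2 kb gene / 10 kb period);
  each TAD's start boundary is planted at a controlled offset from a
  gene end. The truth median refers to the planted offsets.

What the generators do **not** emulate: real base composition, repeats,
mapping bias, linked variants, read-length effects, Hi-C contact noise,
or annotation error. Background sequence is i.i.d. uniform ACGT — the
consuming algorithms are interval and counting procedures, and the one
sequence-sensitive stage (leader scanning) controls false positives by
its identity threshold, which the simulations verify directly. Passing
tests therefore demonstrate algorithmic correctness and calibration
under the stated models, not robustness to every artifact of real
sequencing data.

## Utilities

Physical coverage is Σ(total bases)/genome size over libraries sharing a
genome size, reported to one decimal. Global percent identity uses
Needleman–Wunsch with affine gaps (match +1, mismatch −1, gap open −2,
gap extend −0.5 — configurable, and stated because published identity
figures rarely name their scoring); identity is identical columns over
all alignment columns, rounded to one decimal.

## Problem sizes

Tests and the acceptance script run at desk scale: 1-Mb pileups (≈ 30,000
sites at the depth mode each), annotations of ≤ 50 genes for oracle
comparisons (100 random instances), ortholog sets of ≤ 30 genes, 1-Mb
leader scans with 25–50 planted copies, 30–200 TADs with permutation
n = 200–999. These sizes give binomial standard errors comfortably
inside the tolerances tested while keeping the whole suite fast; the
algorithms themselves stream or vectorize and run unchanged on
chromosome-scale inputs.
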