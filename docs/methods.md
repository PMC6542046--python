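# Methods

## The problem

When the same retrotransposon family (an RTE-clade non-LTR element, e.g.
BovB, AviRTE, RTE1_Sar) turns up in a parasite genome and in its host's
genome, two histories can explain it: horizontal transposon transfer (HTT)
or plain sequence contamination during library preparation. Assemblies are
unreliable witnesses — repetitive regions misassemble, and contaminant
reads co-assemble into host-like scaffolds. Reads are better witnesses: a
read pair or a long read comes from one contiguous DNA molecule, so the
*non-repetitive* part of a read that carries the element tells you which
genome the molecule came from.

## The contamination test (`contest`)

Selection of element-bearing reads works in one of three modes:

* **long** — a long read is selected when its six-frame translation hits
  the element's ORF (E < 1e-10). Translated search tolerates the high
  nucleotide divergence of old copies.
* **ref** — read pairs are selected when exactly one mate maps inside an
  element interval annotated on the reference assembly (intervals from
  `repeatmask.reference_rte_bed`, copies under 20% divergence and at least
  200 bp). Pairs with both mates inside element intervals are discarded:
  they carry no informative flank. The in-element mate must additionally
  have the element as its best repeat-library hit (reciprocal check), so a
  mate that merely overlaps a mis-annotated interval does not count.
* **noref** — assembly-free: both mates are quality-masked (bases under
  Q20 to N, the seqtk convention); a pair is selected when one mate's best
  repeat-library hit is the element (E < 1e-10) and the other mate has no
  element hit at all. Mates with more than 50% masked bases are dropped at
  this stage as unusable.

The informative read (the non-element mate, or the whole long read) is
hard-masked against the complete repeat library, then searched against two
databases: **self** (genomes of the focal species' own taxon) and
**non-self** (genomes of the candidate donor/contaminant taxon). Both
searches use one shared effective database size — the larger of the two
databases — so E-values and the bitscore ranking are comparable across
databases. Hits to the focal species' own genome are discarded (assemblies
contain their own reads, so such hits are uninformative); the database
label of the best surviving hit, ranked by bitscore with deterministic
tie-breaking (E-value, then subject id), is the read's verdict. Equal top
bitscores in both databases give `ambiguous`; an empty pool `unassigned`;
fewer than 30 unmasked bases `low-quality`. The 30 nt floor exists because
below the seed size a database search is meaningless; it was chosen once
and is configurable.

Dataset-level fractions are computed over assigned (self + non-self) reads
only. A fraction of at least `call_threshold` (default 0.80) non-self
yields the call `contamination`; at least that fraction self yields
`endogenous/HTT-consistent`; anything else `inconclusive`. Real datasets
report 85–97% majorities, so any threshold in the majority range
reproduces the same calls; 0.80 keeps a margin against sampling noise in
small read sets.

A known, expected failure mode (visible in the synthetic HTT scenario as a
few percent non-self reads): an informative read carrying an old,
fragmented element remnant the masker missed keeps enough element sequence
to hit element copies in the other taxon's genomes, while its genuine
flank hits in its own genome are discarded as own-species hits. The
majority rule absorbs this.

## The search engine (`alignkit`)

Pairwise alignment (local and global, affine gaps) delegates to
Bio.Align.PairwiseAligner. Database search is k-mer seed-and-extend:
exact seeds (k = 11 nucleotide, k = 5 amino acid) are chained into
candidate boxes when they are close along the subject (≤ 500 bp) and on a
nearby diagonal (±120, tolerating indel drift); each box, padded by
120 bp, is extended. Boxes up to 10^6 DP cells are extended by exact
affine Smith–Waterman; larger boxes use an edlib edit-distance path that
is rescored per column under the scoring scheme and trimmed to its
best-scoring contiguous segment (a Kadane pass), which recovers the local
alignment score to excellent approximation at the divergences that matter
here while keeping long-read work near-linear. Protein extension is always
exact SW (BLOSUM62).

Scores become bitscores via the Karlin–Altschul form
`bits = (λ·S − ln K)/ln 2` with the widely published gapped constants for
the default schemes (nucleotide +2/−3, open 5, extend 2: λ = 0.625,
K = 0.41; BLOSUM62 open 11 extend 1: λ = 0.267, K = 0.041), and
`E = m·n·2^(−bits)` with the query length and the configured effective
database size. The engine reads and writes BLAST-style 12-column tabular,
so an external blastn/DIAMOND run can replace it in any downstream step.

Limitations: no low-complexity filter (repeat masking plays that role in
this pipeline), no edge-effect corrections, no composition-based
statistics. A planted subject region needs at least one exact k-mer match
to be found; at 20% divergence an 11-mer match occurs every ~12 bp in
expectation, so misses only matter for very short (<~30 bp) homologies —
below the informative-length floor anyway.

## Repeat annotation (`repeatmask`)

Each library consensus is searched against the target; hits become
annotations carrying a raw divergence (mismatches + indels over aligned
columns, gap columns included — the RepeatMasker-like convention) and the
matched consensus span. Same-family, same-strand overlaps are merged
(union; length-weighted divergence) before the length (keep ≥ threshold)
and divergence (keep strictly under threshold, matching the "under 20%"
phrasing) filters. Hard masking writes N, soft masking lowercases; both
conserve length. The divergence used here is deliberately the raw one; the
CpG-corrected K2P lives in `kimura` and is used for ages, not filtering.

## Screening (`httscreen`)

An element × genome hit (E < 1e-10) with alignment length ≥ 100 bp is
extracted, de-duplicated by exact coordinates (seq, start, end, strand),
and searched back against the whole element library; the locus counts only
if its best reciprocal hit is the originating element. At least 10
surviving loci per (element, species) are required to nominate a
candidate — a floor against spurious single-hit calls. Both boundaries are
inclusive on the keep side. The read-level translated screen reports ORF
hits passing E < 1e-10 and amino-acid identity strictly above 75%; note
that ~10% nucleotide divergence already drops amino-acid identity to
~65–75% for non-coding-constrained sequence, so this screen targets
*recent* element activity.

## Consensus and trees (`consensus_evo`)

Per-species consensus: each genomic fragment is locally aligned to a
family seed sequence (better strand kept); per seed column the plurality
base over fragments wins where coverage ≥ 3, otherwise the seed base is
retained; insertions relative to the seed are discarded. This
reference-anchored star alignment plus majority rule replaces a multiple
aligner + profile-HMM consensus; the property the downstream analysis
needs — recovery of the family ancestor from diverged copies — is tested
directly (≥99% identity from 30 copies at 10% divergence).

Pairwise consensus identity: global alignment with free terminal gaps;
identity = matches over alignment columns.

Defragmentation merges same-family, same-strand annotations on one
sequence into copies when the genomic gap is ≤ 5000 bp and consensus
coordinates progress collinearly (next start ≥ previous end − 20, mirrored
on the minus strand); an intervening annotation of another family breaks
the chain (strict mode). The 5000/20 defaults are configurable; fragment
counts are conserved by construction. Top copies are selected by merged
length (descending) then mean divergence (ascending), a literal composite
sort.

Trees: neighbor joining (scikit-bio) on CpG-excluded K2P distances between
consensuses, negative NJ branches clamped to zero, midpoint rooting
available. For consensus-vs-consensus distances, CpG columns of *either*
sequence are excluded so the matrix stays symmetric. `star_score`
(internal branch length over total branch length; 0 for a perfect star)
quantifies how star-like an intra-species copy phylogeny is — the neutral
post-insertion expectation. `is_cherry` tests the transfer topology: on
the unrooted tree, recipient and donor lineage joined by a single internal
node.

## Divergence and landscapes (`kimura`)

Copy age is the Kimura 2-parameter distance to the species consensus,
`K = −½ ln((1−2p−q)√(1−2q))`, with transitions p and transversions q
counted over columns where both sequences have A/C/G/T. CpG exclusion
removes both positions of every CpG dinucleotide of the ungapped consensus
(mapped through the alignment) before counting, because methylated CpGs
hypermutate and would inflate apparent ages. Exclusion of whole positions
was chosen over RepeatMasker's alternative of down-weighting CpG
transitions; the behaviour is a flag on `count_changes`. Saturated pairs
(either log argument ≤ 0) are flagged rather than given a number. The
landscape bins each copy's length by its distance (percent scale, 1%
bins) and reports min / length-weighted mean / max, on both percent and
proportion scales.

## The generator (`simfixtures`)

The generator emulates the study's data regime: one element family with a
full-length ORF (so both nucleotide and translated selection work), a
recipient and a donor genome of 100 kb background each, 2×150 bp FR pairs
at 20× with Normal(500, 50) inserts, exponential long reads (mean 8 kb) at
5×, 0.5% substitution errors. Substitution evolution is a genuine K2P
process: `divergence` is the K2P evolutionary distance and per-site change
probabilities are the K2P transition-matrix closed forms at that distance
(transition:transversion ratio κ = 2), so downstream K2P estimates are
directly comparable to the generating parameter — single-hit mutation
schemes would make the multiple-hit correction overshoot badly beyond
~15% divergence. Indels (1–5 bp, rate 5×10⁻⁴/site) are added on top.

Scenarios: **HTT** plants copies in both genomes, the recipient's seeded
from a donor-lineage copy (transfer divergence 0.03), and emits recipient
reads only; **contamination** plants the element only in the donor and
mixes donor reads in at 5% — and its "assembly" includes the donor genome
as extra contigs, because a real assembly built from contaminated reads
contains contaminant scaffolds (that is precisely what the reference mode
exploits); **negative** has no element at all. Databases contain the focal
genome itself (tagged with the focal species, exercising the own-genome
discard) plus background-derived sister genomes at 20% divergence —
deep host–parasite-scale divergence, so self/non-self assignment is
learnable but not trivial. Qualities are Q40 except Q11 at error
positions, which keeps quality masking exercisable.

What the generator does **not** emulate: platform-specific error profiles
(PacBio homopolymer indels), diploidy, nested repeat structure, taxonomic
breadth beyond one sister per taxon, GC heterogeneity. Passing tests
therefore demonstrate the method's logic and its behaviour under realistic
divergences and coverages, not its performance on any particular real
library.

## Numerical and reproducibility choices

All randomness flows through one `numpy.random.Generator`; a fixed seed
gives byte-identical FASTA/FASTQ/SAM/TSV outputs. Hit ordering, consensus
tie-breaks (base order), and top-copy sorting are all deterministic.
Internal coordinates are 0-based half-open everywhere; SAM/BLAST tabular
conversions happen only at I/O boundaries. The acceptance script runs the
three-scenario sweep at half scale (50 kb backgrounds, 15+15 copies, 10×
pairs, 3× long reads, 20 topology replicates) — sizes chosen to keep a
full from-scratch rerun quick while leaving hundreds of informative reads
per call; the test suite exercises the full-scale conditions.
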