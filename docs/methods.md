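# Methods

This note records the models, conventions and design choices behind
`breakins`, in the order data flows through the pipeline.

## Coordinates and conventions

All sequence is uppercase `{A,C,G,T,N}`; coordinates are 0-based
half-open internally and 1-based inclusive in emitted TSV. "x bp from the
DSB end" counts the bases strictly between the break end and the first
base of a feature, so 10-bp arms at offsets 2 and 53 enclose a 41-bp
spacer. Reported percentages are percentages; microhomologies, arm, loop
and copy lengths are in nucleotides.

## Locus model

`LocusModel` describes the cut locus: cut position, 3' overhang length
(default 4 nt), primer offsets (11 bp upstream, 18 bp downstream of the
cut), and a pair of inverted microhomology arms downstream of the cut
(default 10 bp at offsets 2/53 with one tolerated internal mismatch).
`build_locus` synthesizes a random background and plants the arm pair and
the first copy-template bases deterministically. With default geometry
the planted bases reproduce the canonical arm-context pair
(`CAGTATA`/`CAGCATA`) and copy start (`TACTT` in product orientation), so
seed construction yields the canonical seed strings.

Foldback bookkeeping, derived from strand polarity: resection of the
break's distal end exposes 3' ssDNA; the arm nearest the break anneals to
the far arm (a hairpin whose loop is the spacer); synthesis primed at the
annealed arm copies template immediately distal of the far arm; the
extended strand is captured by the other break end. In product
orientation the read is `left flank + revcomp(copied segment) + right
flank starting at the near arm` — the `arm1_offset` bases nearest the
break are trimmed during hairpin formation. The annealed arm heteroduplex
can resolve to either strand's variant, so products carry either arm
context; the simulator draws the variant uniformly.

### Identifiability guards

A copy of length *c* is letter-for-letter identical at the junction to a
copy of length *c+1* whenever the base left of the cut complements
template base *c*. Truth tables therefore record the canonical
(maximal-extension) copy length, and the detector is tested against that
canonical value. To keep short copies — the regime the assay's
exact-length signature counter addresses — fully identifiable, the
default locus additionally fixes the base left of the cut to `G` and
keeps template positions 5–12 past the copy origin C-free, making copy
lengths up to 12 unambiguous; and the first trimmed base right of the cut
is kept different from `T` (the invariable terminal base of every
inverted copy) so flank anchoring can never absorb a copy's terminal
base. These constraints slightly deplete left-junction microhomology for
short foldbacks relative to a fully random locus; they trade a small
amount of junction-statistics realism for exact recoverability, which is
what the test suite relies on.

## Synthetic donor genome

Four contigs stand in for the donor categories (nuclear, rDNA, Ty LTR,
mitochondrial), with a masked window on the nuclear contig emulating
homology-donor masking, feature tracks (telomere, R-loop, tandem repeat,
ARS, tRNA) for the enrichment stage, and planted **cassettes**: fixed
same-locus donor pairs that complex-insertion events are drawn from,
mimicking the hotspot structure of real inverted-insertion donors. Each
inverted cassette draws fragment lengths (fragment 1: 100–140 bp,
fragment 2: 40–70 bp, keeping fragment 1 dominant so greedy tiling is
deterministic), an inter-fragment microhomology *m* from a distribution
peaked at 6 (range 2–11, matching the observed inter-fragment
microhomology range), and a junction distance *d ≥ 2m+2* (even), the
smallest spacing at which the microhomology constraint
`g[e1-m:e1] == revcomp(g[e2:e2+m])` can be planted without
self-referential base pairings. Direct cassettes use *d ≥ m+6*. One-base
boundary mutations pin the planted microhomology to exactly *m*, and
three forced mismatches after fragment 1's end prevent its local
alignment from creeping across the junction — making detection
coordinate-exact on error-free reads. Cross-locus pairs are drawn by
rejection sampling under the same junction guards.

## Read simulation

Each read is the amplicon of one repair product: intact end joining
(reference amplicon), foldback inversion (copy length from a truncated
geometric distribution starting at 2, p = 0.12, cap 150 — majority under
14 bp), simple templated insertion (donor segment, log-normal size with
median 88 bp and σ = 0.45, clipped to 12–240 bp, category-weighted across
contigs), complex insertion (cassette or cross-locus pair), or capture of
the 69-nt barcoded oligo (single-molecule foldback vs two-molecule
pairing, default 16% single). Substitution errors are applied per base
(default 0.1%, a free parameter of the assay, not a measured value) at
the product level before mate generation, so R1/R2 stay consistent;
per-mate independent errors are not modelled. Indel errors are off by
default and available behind a flag. PCR duplicates are exact copies of
already-errored reads, appended after the unique draws so a run with
duplicates extends a run without them. Mates are the first/last
`read_len` bases of the product (R2 reverse complemented). The truth
table has one row per emitted read, duplicates flagged with their source.

What the generator does **not** emulate: platform-specific error
profiles, quality-score structure (all bases Q37), library-prep bias,
chimeric PCR artifacts, or colony pooling. Passing tests demonstrate the
correctness of the junction arithmetic and bookkeeping under the modelled
noise, not robustness to real MiSeq artifacts.

## Read merging and QC

Merging is ungapped: the best overlap placement of R1 against
revcomp(R2) maximizes matches − mismatches (ties: longer overlap, then
smaller shift), subject to `min_overlap` (default 10) and
`max_mismatch_frac` (default 0.1); the consensus takes the
higher-quality base at disagreements, R1 at quality ties. This is a
contract re-implementation of overlap merging, oracle-tested against an
exhaustive shift scan; it is not a bit-level match of any external tool.
QC drops reads below a mean-quality floor or sharing a k-mer (default
k=21) with a contaminant sequence.

## Insertion detection

`locate_insert` anchors the 11-bp upstream flank at the read start and
the 18-bp downstream flank at the read end (semi-global, edit distance ≤
4 by default, both orientations tried). Junction-trimmed reference bases
are read off trailing insertion ops of the flank CIGAR. Because edit
distance ties allow junction mismatches and indels to trade against each
other, each co-optimal anchoring is normalized — trailing non-match
blocks count as trimmed reference, never as claimed insert bases — and
the anchoring with fewest flank-internal edits, then largest read
consumption, wins. The unanchored middle is the insert; events are kept
when it exceeds 10 bp (strictly; shorter local inversions are the
foldback module's domain).

Deduplication keys are the insert plus 5 bp of read sequence on each
side. Single-base indels within 3 nt (configurable) of either junction
are treated as sequencing error: the observed flank is replaced by the
reference flank when a global alignment shows exactly one 1-bp indel
inside the window and nothing else. Read support is recorded but never
multiplies event counts.

Donor mapping tiles each insert greedily: the best local alignment
(match +1, mismatch −2, gaps −10 so a 1-bp indel is tolerable but the
aligner never bridges the genomic gap between two donor fragments) over
all contigs and both strands is accepted at ≥ 10 insert bases and ≥ 90%
identity, and the uncovered flanking segments are recursed on — so hits
never overlap on the insert. Masked donor bases are lowercased and
unmatchable. The cut locus itself is searchable as an extra contig, which
classifies long foldbacks as locus-local. Ties break deterministically by
score, identity, contig order, leftmost coordinate, plus strand.
Categories follow annotation overlap with priority
mtDNA > Ty_LTR > rDNA > nuclear. Per-sample frequencies are compared by
2×2 chi-square without continuity correction.

## Foldback scan

Seeds require exact matches (sequencing errors cost sensitivity, not
specificity — an accepted, documented bias). Copy length is measured by
maximal extension of the inverted duplication against the template
(0 mismatches by default); the left-junction microhomology uses the
standard terminal-identity convention; dedup follows the same
5-bp-flank rule, one event per unique sequence. The exact-length
signature counter accepts reads matching the *m*-length signature and
rejects any read also matching the (*m*+1)-length signature, reporting a
read count (not deduplicated events). Unmerged-read scanning works on
whatever reads are supplied; the pipeline feeds merged reads only.

## Inverted pairs

`same_locus_window` defaults to 1000 bp: observed junction distances span
roughly 2–119 bp, so 1000 gives margin while excluding cross-locus
pairs; it is configurable and documents an operational gap (no published
threshold exists). Overlap and gap are separate non-negative fields.
Orientation fractions among complex events exclude rDNA and Ty donors by
default.

## Barcode analysis

Recognition seeds are all tiled 10-mers of the oligo's N-free segments
plus reverse complements — a superset of any hand-picked seed list,
raising sensitivity without changing exact-match specificity. Barcodes
are defined between exact 5-bp flanks, extracted in both orientations and
reverse complemented into design orientation before comparison: a
foldback copies the barcode as its reverse complement, so "identical
barcodes" is only meaningful after orientation. Occurrences with a wrong
enclosed length are counted as malformed. The chance expectation is
4^−barcode_len in closed form and a seeded Monte Carlo (default 10,000
resamples) with a 95% percentile interval.

## Feature enrichment

Shuffled controls preserve the interval-length multiset and count,
placing each interval uniformly over unmasked positions genome-wide
(per-chromosome placement behind a flag). Proximity is within-distance
(closest-edge, overlap = 0) or ≥ 1-bp overlap per track; defaults follow
the assay's rules (0.2 kb for R-loops, 1 kb for telomeres, overlap for
tandem repeats). P-values use the one-sided add-one permutation
estimator, (1 + #{null ≥ observed}) / (1 + n), which never returns 0;
the default 1000 iterations is a convention (no published count exists).

## Problem sizes and numerical choices

The bundled tests run the full pipeline at 250–2000 reads and the
uniformity/calibration checks at 10⁴ draws — sizes chosen so the whole
suite completes in well under a minute of alignment-dominated compute
while keeping binomial checks at 3-SD resolution. Random number use is
`numpy.random.default_rng` throughout; every stochastic entry point
takes an explicit seed, and identical configuration reproduces
byte-identical outputs.

## Known limitations

* The locus and genome are synthetic; no claim is made about recovering
  published biological effect sizes from real reads.
* Gapped read merging, adapter trimming and quality recalibration are out
  of scope; foldback seeds tolerate no mismatches.
* Donor tiling recursion reports at most 4 fragments per insert and can,
  on repetitive donors, prefer a contig earlier in sort order among
  exactly tied alignments.
* The junction-indel forgiveness rule handles single 1-bp indels per
  flank, matching its stated contract, not arbitrary indel clusters.
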