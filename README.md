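# breakins

Detection and simulation of templated and inverted insertions at DNA
double-strand breaks (DSBs), for amplicon sequencing of repair products at
an endonuclease-cut locus.

## The problem

When a single chromosomal DSB is repaired by end joining, the junction
occasionally captures extra DNA: short **local foldback inversions**
templated by microhomologies right next to the break, **templated
insertions** copied from elsewhere in the genome (often fragile or
repetitive regions), **complex insertions** tiled by two donor fragments —
frequently two fragments of one locus in inverted orientation — and
captures of **extrachromosomal ssDNA**. Deep amplicon sequencing across
the repaired locus reads out these rare products at scale, but turning
reads into events requires careful junction arithmetic: anchoring each
read to the reference amplicon, calling the inserted middle segment,
measuring junctional microhomology, tiling inserts with donor alignments,
and collapsing PCR duplicates without merging distinct events.

`breakins` implements that analysis as a tested, reusable library plus a
CLI, together with a synthetic-data generator that emulates the assay
geometry — a cut with a 4-nt 3' overhang, primers 11 bp upstream and 18 bp
downstream of the cut, and a pair of imperfect 10-bp inverted
microhomology arms beginning 2 and 53 bp from the break (a 41-bp hairpin
loop) — so every stage is verifiable against generative ground truth
without any external data.

## Core definitions

* **Junctional microhomology** between a flank *F* and an insert *I* is the
  maximal terminal identity: on the left, the largest *k* with
  `F[-k:] == I[:k]` (mirrored on the right).
* A **foldback inversion** of copy length *c* appears in product
  orientation as `revcomp(T[0:c])` immediately left of the proximal arm,
  where *T* is the template just distal of the far arm. The scan seed is
  `revcomp(T[0:min_copy])` + the arm context — one seed per variant of the
  imperfect arm pair (for the default locus, `TACTTCAGTATA` and
  `TACTTCAGCATA`), which guarantees every reported inversion copied at
  least `min_copy` bases.
* An **inverted pair** is a two-donor insertion whose fragments map to one
  locus on opposite strands; its metrics are the donor-interval overlap,
  the distance between the fragment junction points on the donor, and the
  inter-fragment microhomology measured against the donor extension of the
  second fragment.
* For the **barcoded 69-nt capture oligo** (4-nt N barcode, 8-nt inverted
  repeats with an 18-nt spacer at the 3' end), a single-molecule foldback
  yields two identical oriented barcodes; two-molecule pairing yields
  independent barcodes, identical by chance with probability
  `4^-barcode_len = 1/256`.

## Worked example

```python
import breakins as b
from breakins.simulate import SimConfig, simulate_reads

locus = b.build_locus()                    # plants the published geometry
print(locus.spacer)                        # 41
print([s.sequence for s in b.build_seeds(locus, min_copy=5)])
# ['TACTTCAGTATA', 'TACTTCAGCATA']

genome = b.default_genome()
cfg = SimConfig(n_reads=1000, error_rate=0.0, duplicate_rate=0.3, rng_seed=42)
reads, truth = simulate_reads(locus, genome, cfg)

events, counts = b.detect_insertions(reads, locus, genome)
print(counts)
# {'reads': 1000, 'unalignable': 0, 'no_insert': 690, 'insert_reads': 310,
#  'events': 166}

fb = b.scan_for_foldbacks(reads, b.build_seeds(locus, 5), locus)
print(len(fb), b.count_short_signature(reads, locus, 2))
# 35 29
```

1000 reads at 30% PCR duplication collapse to 166 unique insertion events
(`insert_reads` counts every read carrying a >10-bp insert, duplicates
included); the foldback scan finds 35 unique inversions of 5 bp or longer,
and 29 reads carry the exact 2-bp inversion signature. On error-free input
the 166 events match the truth table's unique inserts exactly — that
round trip is one of the acceptance tests.

The same stages run from a shell:

```sh
breakins simulate --out sim/ --seed 3 --n-reads 2000
breakins run --config cfg.yaml        # full pipeline with a run report
```

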