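"""Analysis of insertions of a transformed barcoded ssDNA oligo.

The assay transforms a 69-nt single-stranded oligo carrying a random
4-nt barcode in its middle and an 8-nt inverted repeat (18-nt spacer) at
its 3' end.  A foldback within one molecule duplicates the barcode as its
reverse complement (two identical barcodes after orientation); pairing
between two molecules yields two independent barcodes.  The observed
identical fraction is compared against the chance collision probability
4^-barcode_len, estimated both in closed form and by Monte Carlo.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np

from .dna import revcomp

#: the printed 69-mer capture oligo: 4-nt N barcode in the middle, 8-nt
#: inverted repeats at the 3' terminus separated by an 18-nt spacer
CAPTURE_OLIGO = (
    "CATTGAACAACATGTTGCTGTAAG" "NNNN" "ACTCATAGTACAGACGGCGTGTATCTGGTATTGGTCTGTAC"
)

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class InvertedRepeat:
    arm_len: int
    spacer: int
    pos1: int
    pos2: int


def find_inverted_repeats(
    seq: str, min_arm: int = 1, max_spacer: int | None = None
) -> list[InvertedRepeat]:
    """All maximal inverted-repeat pairs with non-overlapping arms.

    An arm pair (pos1, pos2, arm_len) satisfies
    ``seq[pos1:pos1+arm_len] == revcomp(seq[pos2:pos2+arm_len])``.
    N never matches.  Pairs lie on anti-diagonals of the complementarity
    matrix; each maximal run on a diagonal yields one maximal pair,
    clipped at the centre so the arms do not overlap.  Sorted by arm
    length descending, then leftmost pos1.
    """
    n = len(seq)
    out: list[InvertedRepeat] = []
    for s in range(1, 2 * n - 2):
        # positions p pair with q = s - p; only p < q matters
        run_start: int | None = None
        lo = max(0, s - n + 1)
        hi = min(n - 1, s - 1)  # ensure q = s-p >= 0 ... handled by lo
        inner = (s - 1) // 2  # last p with p < s - p
        for p in range(lo, min(hi, inner) + 2):
            q = s - p
            ok = (
                p <= inner
                and 0 <= q < n
                and seq[p] in _PAIR
                and seq[q] == _PAIR[seq[p]]
            )
            if ok:
                if run_start is None:
                    run_start = p
            else:
                if run_start is not None:
                    a, b = run_start, p - 1
                    arm = b - a + 1
                    spacer = s - 2 * b - 1
                    if arm >= min_arm and (max_spacer is None or spacer <= max_spacer):
                        out.append(InvertedRepeat(arm, spacer, a, s - b))
                    run_start = None
    out.sort(key=lambda r: (-r.arm_len, r.pos1, r.spacer))
    return out


@dataclass(frozen=True)
class OligoDesign:
    """Parsed barcoded-oligo design.

    ``sequence`` contains exactly one contiguous run of N (the barcode).
    ``arm1_pos``/``arm2_pos`` locate the inverted-repeat arms in the 3'
    region; foldback synthesis primed at the 3' terminal arm copies the
    molecule back from ``arm1_pos`` toward the 5' end.
    """

    sequence: str
    barcode_start: int
    barcode_len: int
    arm_len: int
    spacer_len: int
    arm1_pos: int
    arm2_pos: int
    seed_substrings: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def barcode_end(self) -> int:
        return self.barcode_start + self.barcode_len

    def up_flank(self, flank: int = 5) -> str:
        return self.sequence[self.barcode_start - flank : self.barcode_start]

    def down_flank(self, flank: int = 5) -> str:
        return self.sequence[self.barcode_end : self.barcode_end + flank]

    def with_barcode(self, barcode: str) -> str:
        """Concrete molecule with the N run replaced by ``barcode``."""
        if len(barcode) != self.barcode_len:
            raise ValueError("barcode length does not match design")
        return (
            self.sequence[: self.barcode_start]
            + barcode
            + self.sequence[self.barcode_end :]
        )

    @classmethod
    def from_sequence(
        cls,
        seq: str,
        seed_k: int = 10,
        min_arm: int = 6,
        max_spacer: int | None = None,
    ) -> "OligoDesign":
        seq = seq.upper()
        runs = [m.span() for m in re.finditer("N+", seq)]
        if len(runs) != 1:
            raise ValueError("oligo must contain exactly one contiguous N run (the barcode)")
        (bstart, bend) = runs[0]
        reps = find_inverted_repeats(seq, min_arm=min_arm, max_spacer=max_spacer)
        if not reps:
            raise ValueError("no inverted-repeat pair found in the oligo")
        top = reps[0]
        # seeds: tiled k-mers over the N-free segments, plus reverse complements
        seeds: list[str] = []
        for a, b in [(0, bstart), (bend, len(seq))]:
            segment = seq[a:b]
            for i in range(0, len(segment) - seed_k + 1):
                kmer = segment[i : i + seed_k]
                for s in (kmer, revcomp(kmer)):
                    if s not in seeds:
                        seeds.append(s)
        return cls(
            sequence=seq,
            barcode_start=bstart,
            barcode_len=bend - bstart,
            arm_len=top.arm_len,
            spacer_len=top.spacer,
            arm1_pos=top.pos1,
            arm2_pos=top.pos2,
            seed_substrings=tuple(seeds),
        )


def default_design() -> OligoDesign:
    return OligoDesign.from_sequence(CAPTURE_OLIGO)


def enumerate_barcodes(barcode_len: int):
    """Yield every possible barcode of the given length."""
    for tup in itertools.product("ACGT", repeat=barcode_len):
        yield "".join(tup)


def recognize_oligo_read(seq: str, design: OligoDesign) -> bool:
    """True when any design seed occurs exactly in the read."""
    return any(s in seq for s in design.seed_substrings)


def recognize_oligo_reads(reads, design: OligoDesign):
    """Flag reads containing any oligo-derived seed (exact match).

    ``reads`` is an iterable of (read_id, sequence) pairs.  Returns
    (flagged read ids, per-seed hit counts).  The seed set already
    contains reverse complements, so orientation is covered.
    """
    flagged: list[str] = []
    counts = {s: 0 for s in design.seed_substrings}
    for read_id, seq in reads:
        hit = False
        for s in design.seed_substrings:
            if s in seq:
                counts[s] += 1
                hit = True
        if hit:
            flagged.append(read_id)
    return flagged, counts


def extract_barcodes(
    seq: str, design: OligoDesign, flank: int = 5
) -> tuple[list[str], int]:
    """Barcodes enclosed between the design's 5-bp flanks, both strands.

    Each occurrence of (upstream flank, downstream flank) with exactly
    ``barcode_len`` enclosed bases yields one barcode, reverse
    complemented into design orientation when found on the minus strand.
    Occurrences whose enclosed length differs are counted as malformed.
    Returns (barcodes in read order, number of malformed occurrences).
    """
    up, down = design.up_flank(flank), design.down_flank(flank)
    blen = design.barcode_len
    slack = 4
    found: list[tuple[int, str]] = []
    malformed = 0
    for left, right, rc_out in (
        (up, down, False),
        (revcomp(down), revcomp(up), True),
    ):
        start = 0
        while True:
            i = seq.find(left, start)
            if i < 0:
                break
            start = i + 1
            inner = i + len(left)
            if seq[inner + blen : inner + blen + len(right)] == right:
                bc = seq[inner : inner + blen]
                found.append((i, revcomp(bc) if rc_out else bc))
                continue
            # flanks present at a different gap: malformed occurrence
            j = seq.find(right, inner, inner + blen + slack + len(right))
            if j >= 0 and j - inner != blen:
                malformed += 1
    found.sort(key=lambda t: t[0])
    return [bc for _, bc in found], malformed


@dataclass(frozen=True)
class BarcodeSummary:
    n_events: int
    n_excluded: int
    observed_identical_fraction: float
    analytic_expectation: float
    mc_mean: float
    mc_ci: tuple[float, float]
    exceeds_chance: bool


def monte_carlo_identical_fraction(
    barcode_len: int, n_events: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-replicate identical fraction for independent barcode pairs."""
    space = 4**barcode_len
    a = rng.integers(0, space, size=(reps, n_events))
    b = rng.integers(0, space, size=(reps, n_events))
    return (a == b).mean(axis=1)


def classify_and_expect(
    barcode_pairs,
    barcode_len: int,
    n_events: int | None = None,
    reps: int = 10_000,
    rng_seed: int = 0,
) -> BarcodeSummary:
    """Observed identical-barcode fraction vs the chance expectation.

    ``barcode_pairs`` is a list of per-event barcode lists; events with
    a number of barcodes other than two are excluded (and counted).
    The chance expectation is 4^-barcode_len in closed form and a Monte
    Carlo resample of ``n_events`` independent pairs, ``reps`` times.
    """
    valid = [p for p in barcode_pairs if len(p) == 2]
    excluded = len(barcode_pairs) - len(valid)
    observed = (
        float(np.mean([p[0] == p[1] for p in valid])) if valid else float("nan")
    )
    if n_events is None:
        n_events = len(valid)
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    rng = np.random.default_rng(rng_seed)
    fractions = monte_carlo_identical_fraction(barcode_len, n_events, reps, rng)
    lo, hi = np.percentile(fractions, [2.5, 97.5])
    return BarcodeSummary(
        n_events=len(valid),
        n_excluded=excluded,
        observed_identical_fraction=observed,
        analytic_expectation=4.0**-barcode_len,
        mc_mean=float(fractions.mean()),
        mc_ci=(float(lo), float(hi)),
        exceeds_chance=bool(valid and observed > hi),
    )
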