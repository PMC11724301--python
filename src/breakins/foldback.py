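"""Seed-scan detection of local foldback inversions at the cut locus.

A foldback inversion arises when the resected break end anneals to a
nearby inverted microhomology, forming a hairpin whose extension copies
adjacent template in inverted orientation.  In product orientation the
junction therefore reads: reverse complement of the copied segment, then
the proximal arm.  The scan seed is the reverse complement of the first
``min_copy`` copied template bases followed by the arm context (one seed
per arm variant of the imperfect inverted repeat); requiring the seed
guarantees every reported inversion copied at least ``min_copy`` bases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .dna import comp, revcomp
from .locus import LocusModel


@dataclass(frozen=True)
class Seed:
    sequence: str
    variant: int  # index into the locus arm variants
    context: str
    min_copy: int


@dataclass(frozen=True)
class FoldbackEvent:
    event_id: str
    copy_len: int
    mh_left: int
    loop_len: int
    seed_variant: int
    read_ids: tuple[str, ...]
    dedup_key: str

    @property
    def read_support(self) -> int:
        return len(self.read_ids)


def build_seeds(locus: LocusModel, min_copy: int = 5, context_len: int = 7) -> list[Seed]:
    """One scan seed per arm variant of the locus.

    For the default locus geometry and ``min_copy=5`` this reproduces the
    canonical seed pair TACTTCAGTATA / TACTTCAGCATA.
    """
    if min_copy < 1:
        raise ValueError("min_copy must be >= 1")
    if min_copy > locus.max_copy_len:
        raise ValueError("min_copy exceeds the available copy template")
    inv = revcomp(locus.copy_template(min_copy))
    return [
        Seed(sequence=inv + ctx, variant=i, context=ctx, min_copy=min_copy)
        for i, ctx in enumerate(locus.arm_variants(context_len))
    ]


def _measure(target: str, p: int, seed: Seed, locus: LocusModel, max_mismatch: int = 0):
    """Copy length by maximal extension of the inverted duplication.

    ``p`` is the seed match position in ``target``.  The inverted copy
    occupies target[p + min_copy - k : p + min_copy]; extension walks
    left through the read while the template match continues.
    """
    s = locus.sequence
    co = locus.copy_origin
    k = seed.min_copy
    mismatches = 0
    while True:
        idx = p + seed.min_copy - 1 - k
        if idx < 0 or co + k >= len(s):
            break
        if target[idx] == comp(s[co + k]):
            k += 1
        elif mismatches < max_mismatch:
            mismatches += 1
            k += 1
        else:
            break
    return k


def scan_for_foldbacks(
    reads,
    seeds: list[Seed],
    locus: LocusModel,
    max_copy_mismatch: int = 0,
    flank: int = 5,
) -> list[FoldbackEvent]:
    """Scan reads for foldback seeds and measure each inversion.

    Reads are checked in both orientations (exact seed match).  Events
    are deduplicated on the inverted copy plus ``flank`` bases of read
    sequence on each side; each unique sequence counts once regardless
    of read support.
    """
    found: dict[str, FoldbackEvent] = {}
    order: list[str] = []
    left_flank_seq = locus.sequence[: locus.cut_pos]
    for r in reads:
        rid, seq = (r.read_id, r.sequence) if hasattr(r, "sequence") else r
        hit = None
        for target in (seq.upper(), revcomp(seq.upper())):
            for seed in seeds:
                p = target.find(seed.sequence)
                if p >= 0:
                    hit = (target, p, seed)
                    break
            if hit:
                break
        if not hit:
            continue
        target, p, seed = hit
        k = _measure(target, p, seed, locus, max_copy_mismatch)
        ins_start = p + seed.min_copy - k
        insert = target[ins_start : p + seed.min_copy]
        key = target[max(0, ins_start - flank) : p + seed.min_copy + flank]
        if key in found:
            prev = found[key]
            found[key] = replace(prev, read_ids=prev.read_ids + (rid,))
            continue
        mh_left = _mh(left_flank_seq, insert)
        found[key] = FoldbackEvent(
            event_id="",
            copy_len=k,
            mh_left=mh_left,
            loop_len=locus.spacer,
            seed_variant=seed.variant,
            read_ids=(rid,),
            dedup_key=key,
        )
        order.append(key)
    return [
        replace(found[key], event_id=f"fb{i:05d}") for i, key in enumerate(order)
    ]


def _mh(flank: str, insert: str) -> int:
    k = min(len(flank), len(insert))
    while k > 0 and flank[-k:] != insert[:k]:
        k -= 1
    return k


def count_short_signature(
    reads, locus: LocusModel, exact_len: int, context_len: int = 7
) -> int:
    """Reads carrying the inversion signature of exactly ``exact_len``
    copied bases.

    A read matching the (exact_len + 1)-base signature is rejected, so
    only inversions of exactly the requested length are counted; the
    result is a read count, not a deduplicated event count.
    """
    if exact_len < 1:
        raise ValueError("exact_len must be >= 1")
    contexts = locus.arm_variants(context_len)
    sig = [revcomp(locus.copy_template(exact_len)) + c for c in contexts]
    longer = (
        [revcomp(locus.copy_template(exact_len + 1)) + c for c in contexts]
        if exact_len + 1 <= locus.max_copy_len
        else []
    )
    n = 0
    for r in reads:
        seq = (r.sequence if hasattr(r, "sequence") else r[1]).upper()
        both = (seq, revcomp(seq))
        if any(s in t for s in sig for t in both) and not any(
            s in t for s in longer for t in both
        ):
            n += 1
    return n
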