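"""Read quality filtering and paired-read overlap merging.

Downstream detection consumes merged reads only.  Merging is ungapped:
the best overlap between R1 and the reverse complement of R2 is found by
scanning all relative offsets, and a consensus is called with
disagreements resolved toward the higher base quality (ties toward R1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dna import revcomp


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str
    quality: str  # Phred+33

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence and quality lengths differ")

    @property
    def mean_q(self) -> float:
        return float(np.mean([ord(c) - 33 for c in self.quality])) if self.quality else 0.0


@dataclass(frozen=True)
class MergedRead:
    read_id: str
    sequence: str
    qualities: str
    merged_flag: bool


def _best_overlap(s1: str, s2: str, min_overlap: int, max_mismatch_frac: float):
    """Best ungapped overlap placement of s2 (already reverse complemented)
    relative to s1.

    Offset o is the position of s2's first base relative to s1's first
    base (negative: s2 starts left of s1).  Returns (offset, overlap,
    mismatches) maximizing matches - mismatches, ties toward longer
    overlap, then smaller |offset|, or None when no placement satisfies
    the thresholds.
    """
    a = np.frombuffer(s1.encode(), dtype=np.uint8)
    b = np.frombuffer(s2.encode(), dtype=np.uint8)
    n1, n2 = len(a), len(b)
    best = None
    for o in range(-(n2 - min_overlap), n1 - min_overlap + 1):
        lo1, hi1 = max(0, o), min(n1, o + n2)
        ov = hi1 - lo1
        if ov < min_overlap:
            continue
        seg1 = a[lo1:hi1]
        seg2 = b[lo1 - o : hi1 - o]
        mm = int((seg1 != seg2).sum())
        if mm > max_mismatch_frac * ov:
            continue
        score = (ov - mm) - mm
        key = (score, ov, -abs(o))
        if best is None or key > best[0]:
            best = (key, o, ov, mm)
    if best is None:
        return None
    return best[1], best[2], best[3]


def merge_pair(
    r1: FastqRead,
    r2: FastqRead,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> MergedRead:
    """Merge a read pair by its best ungapped overlap.

    R2 is reverse complemented, the best overlap is located, and the
    consensus over the union of both mates is returned.  When no offset
    reaches ``min_overlap`` bases at ``max_mismatch_frac`` or less, an
    unmerged marker (``merged_flag=False``, R1 passed through) is
    returned.
    """
    if not r1.sequence or not r2.sequence:
        raise ValueError("cannot merge an empty read")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    s2 = revcomp(r2.sequence)
    q2 = r2.quality[::-1]
    hit = _best_overlap(r1.sequence, s2, min_overlap, max_mismatch_frac)
    if hit is None:
        return MergedRead(r1.read_id, r1.sequence, r1.quality, False)
    o, _, _ = hit
    lo = min(0, o)
    hi = max(len(r1.sequence), o + len(s2))
    seq, qual = [], []
    for p in range(lo, hi):
        c1 = r1.sequence[p] if 0 <= p < len(r1.sequence) else None
        c2 = s2[p - o] if 0 <= p - o < len(s2) else None
        if c1 is not None and c2 is not None:
            p1, p2 = r1.quality[p], q2[p - o]
            if c1 == c2:
                seq.append(c1)
                qual.append(max(p1, p2))
            elif p2 > p1:
                seq.append(c2)
                qual.append(p2)
            else:
                seq.append(c1)
                qual.append(p1)
        elif c1 is not None:
            seq.append(c1)
            qual.append(r1.quality[p])
        else:
            seq.append(c2)
            qual.append(q2[p - o])
    return MergedRead(r1.read_id, "".join(seq), "".join(qual), True)


def quality_filter(
    reads,
    min_mean_q: float = 20.0,
    contaminant_seqs=(),
    k: int = 21,
):
    """Drop low-quality reads and reads sharing a k-mer with a contaminant.

    Returns (kept reads, report dict with per-reason drop counts).
    """
    kmers: set[str] = set()
    for c in contaminant_seqs:
        c = c.upper()
        for i in range(0, max(0, len(c) - k + 1)):
            kmers.add(c[i : i + k])
    kept = []
    report = {"input": 0, "low_quality": 0, "contaminant": 0, "kept": 0}
    for r in reads:
        report["input"] += 1
        if _mean_q(r) < min_mean_q:
            report["low_quality"] += 1
            continue
        seq = r.sequence
        if kmers and any(seq[i : i + k] in kmers for i in range(0, max(0, len(seq) - k + 1))):
            report["contaminant"] += 1
            continue
        kept.append(r)
        report["kept"] += 1
    return kept, report


def _mean_q(r) -> float:
    q = getattr(r, "quality", "") or getattr(r, "qualities", "")
    return float(np.mean([ord(c) - 33 for c in q])) if q else 0.0
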