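"""Classification and metrics for complex (two-donor) insertions.

Two donor fragments from one locus in opposite orientation form an
inverted pair — the signature of microhomology-mediated template
switching — while same-orientation fragments form a direct pair.  The
metrics mirror the assay's readouts: donor-interval overlap, distance
between the fragment-fragment junction points on the donor, and the
inter-fragment junction microhomology measured against the donor
extension of the second fragment.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .detect import DonorHit, InsertionEvent, call_microhomology
from .dna import revcomp
from .genome import DonorGenome
from .locus import LocusModel

RELATIONS = ("inverted", "direct", "different_locus")


def _interval_distance(s1: int, e1: int, s2: int, e2: int) -> int:
    if s1 < e2 and s2 < e1:
        return 0
    return max(s2 - e1, s1 - e2)


def classify_pair(hit1: DonorHit, hit2: DonorHit, same_locus_window: int = 1000) -> str:
    """Relation of two donor alignments: inverted, direct or different_locus."""
    if hit1 is None or hit2 is None:
        raise ValueError("both donor hits must be mapped")
    if hit1.contig != hit2.contig:
        return "different_locus"
    if _interval_distance(hit1.start, hit1.end, hit2.start, hit2.end) > same_locus_window:
        return "different_locus"
    return "inverted" if hit1.strand != hit2.strand else "direct"


@dataclass(frozen=True)
class DonorPair:
    hit1: DonorHit
    hit2: DonorHit
    relation: str
    overlap_bp: int
    gap_bp: int
    junction_distance: int
    mh_between: int
    mh_outer_left: int
    mh_outer_right: int


def _junction_point(hit: DonorHit, side: str) -> int:
    """Donor coordinate of a fragment's junction-facing end.

    ``side`` is which end of the fragment faces the inter-fragment
    junction in insert orientation: "right" for fragment 1, "left" for
    fragment 2.
    """
    if side == "right":
        return hit.end if hit.strand == "+" else hit.start
    return hit.start if hit.strand == "+" else hit.end


def _fragment_seq(hit: DonorHit, genome: DonorGenome) -> str:
    seq = genome.contigs[hit.contig][hit.start : hit.end]
    return seq if hit.strand == "+" else revcomp(seq)


def donor_extension_mh(
    f1_seq: str, hit2: DonorHit, genome: DonorGenome, max_k: int = 30
) -> int:
    """Microhomology between fragment 1's end and fragment 2's
    donor-extended start (suffix/prefix convention)."""
    g = genome.contigs[hit2.contig]
    best = 0
    for k in range(1, min(max_k, len(f1_seq)) + 1):
        if hit2.strand == "+":
            ext = g[max(0, hit2.start - k) : hit2.start]
        else:
            ext = revcomp(g[hit2.end : hit2.end + k])
        if len(ext) == k and f1_seq[-k:] == ext:
            best = k
    return best


def pair_metrics(
    hit1: DonorHit,
    hit2: DonorHit,
    insert_seq: str,
    genome: DonorGenome,
    locus: LocusModel | None = None,
    same_locus_window: int = 1000,
) -> DonorPair:
    """Fill all pair metrics for a two-donor insertion.

    ``hit1`` is the fragment occurring first on the insert.  Overlap and
    gap are reported as separate non-negative fields.
    """
    relation = classify_pair(hit1, hit2, same_locus_window)
    if hit1.contig == hit2.contig:
        overlap = max(
            0, min(hit1.end, hit2.end) - max(hit1.start, hit2.start)
        )
        gap = _interval_distance(hit1.start, hit1.end, hit2.start, hit2.end)
        jd = abs(_junction_point(hit2, "left") - _junction_point(hit1, "right"))
    else:
        overlap, gap, jd = 0, -1, -1
    f1 = _fragment_seq(hit1, genome)
    mh_between = donor_extension_mh(f1, hit2, genome)
    mh_l = mh_r = 0
    if locus is not None and insert_seq:
        mh_l = call_microhomology(locus.sequence[: locus.cut_pos], insert_seq, "left")
        mh_r = call_microhomology(locus.sequence[locus.cut_pos :], insert_seq, "right")
    return DonorPair(
        hit1=hit1,
        hit2=hit2,
        relation=relation,
        overlap_bp=overlap,
        gap_bp=gap,
        junction_distance=jd,
        mh_between=mh_between,
        mh_outer_left=mh_l,
        mh_outer_right=mh_r,
    )


def summarize_complex(
    events: list[InsertionEvent],
    genome: DonorGenome,
    exclude_categories: tuple[str, ...] = ("rDNA", "Ty_LTR"),
    same_locus_window: int = 1000,
) -> dict:
    """Fractions of complex insertions and of inverted vs direct pairs.

    Complex = donor_count >= 2 among all insertion events.  Orientation
    fractions are computed among complex events whose two donors are
    both outside the excluded categories (repetitive classes excluded by
    default); reported as percentages, NA (None) when undefined.
    """
    n_events = len(events)
    complex_events = [ev for ev in events if ev.donor_count >= 2]
    n_complex = len(complex_events)
    n_inverted = n_direct = n_eligible = 0
    for ev in complex_events:
        if ev.donor_count != 2:
            continue
        h1, h2 = sorted(ev.donor_hits, key=lambda h: h.q_start)
        cats = {genome.category_of(h.contig, h.start, h.end) for h in (h1, h2)}
        if cats & set(exclude_categories):
            continue
        n_eligible += 1
        rel = classify_pair(h1, h2, same_locus_window)
        if rel == "inverted":
            n_inverted += 1
        elif rel == "direct":
            n_direct += 1
    return {
        "n_events": n_events,
        "n_complex": n_complex,
        "pct_complex": 100.0 * n_complex / n_events if n_events else None,
        "n_two_donor_eligible": n_eligible,
        "n_inverted": n_inverted,
        "n_direct": n_direct,
        "pct_inverted_of_complex": 100.0 * n_inverted / n_complex if n_complex else None,
        "pct_direct_of_complex": 100.0 * n_direct / n_complex if n_complex else None,
    }


def pairs_table(
    events: list[InsertionEvent],
    genome: DonorGenome,
    locus: LocusModel | None = None,
    same_locus_window: int = 1000,
) -> pd.DataFrame:
    """Per-event pair metrics for all two-donor insertions."""
    rows = []
    for ev in events:
        if ev.donor_count != 2:
            continue
        h1, h2 = sorted(ev.donor_hits, key=lambda h: h.q_start)
        pair = pair_metrics(h1, h2, ev.insert_seq, genome, locus, same_locus_window)
        rows.append(
            {
                "event_id": ev.event_id,
                "contig1": h1.contig,
                "start1": h1.start + 1,
                "end1": h1.end,
                "strand1": h1.strand,
                "contig2": h2.contig,
                "start2": h2.start + 1,
                "end2": h2.end,
                "strand2": h2.strand,
                "relation": pair.relation,
                "overlap_bp": pair.overlap_bp,
                "gap_bp": pair.gap_bp,
                "junction_distance": pair.junction_distance,
                "mh_between": pair.mh_between,
                "mh_outer_left": pair.mh_outer_left,
                "mh_outer_right": pair.mh_outer_right,
            }
        )
    return pd.DataFrame(rows)
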