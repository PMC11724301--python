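"""Detection of >10-bp insertions at the cut site.

A merged read is anchored to the reference amplicon by aligning the
upstream primer flank at the read start and the downstream flank at the
read end (semi-global, bounded edit distance).  The unanchored middle is
the insert.  Events are deduplicated on the insert plus 5 bp of read
sequence on each side, insert fragments are tiled against the donor
genome by local alignment with recursive segmentation, junction
microhomologies are called as maximal terminal suffix/prefix identity,
and per-sample frequencies are compared by chi-square.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .dna import revcomp
from .genome import DonorGenome
from .locus import LocusModel

# ---------------------------------------------------------------------------
# insert location


@dataclass(frozen=True)
class LocateResult:
    """Outcome of anchoring one read to the reference amplicon.

    ``status`` is "insert", "none" (no or <=10 bp middle segment) or
    "unalignable" (a primer flank could not be placed in either read
    orientation).  ``target`` is the read in the orientation that
    anchored; insert coordinates index into it.  ``left_flank_end`` /
    ``right_flank_start`` are locus coordinates relative to the cut
    (negative = upstream), accounting for junction-trimmed flank bases.
    """

    status: str
    target: str = ""
    orientation: str = "+"
    insert_start: int = 0
    insert_end: int = 0
    left_flank_end: int = 0
    right_flank_start: int = 0

    @property
    def insert_seq(self) -> str:
        return self.target[self.insert_start : self.insert_end]


def _cigar_trailing(cigar: str, op: str) -> int:
    m = re.search(rf"(\d+){op}$", cigar or "")
    return int(m.group(1)) if m else 0


def _anchor_flank(query: str, target: str, max_edit: int):
    """Anchor a flank at the start of ``target``; junction at the far end.

    Edit-distance ties allow junction-proximal mismatches and indels to be
    traded against each other, moving the apparent junction.  Each
    co-optimal anchoring is normalized by stripping its trailing non-match
    block (junction-adjacent mismatches count as trimmed reference, never
    as claimed insert bases), and the normalized anchoring consuming the
    most read bases wins.  Returns (inclusive end in target,
    junction-trimmed reference bases) or None when the flank does not
    align within ``max_edit``.
    """
    res = edlib.align(query, target, mode="SHW", task="path", k=max_edit)
    if res["editDistance"] < 0:
        return None
    best = None
    for _, end in dict.fromkeys(res["locations"]):
        cigar = edlib.align(query, target[: end + 1], mode="NW", task="path")["cigar"]
        ops = [(int(n), op) for n, op in re.findall(r"(\d+)([=XIDM])", cigar or "")]
        trimmed = 0
        while ops and ops[-1][1] != "=":
            n, op = ops.pop()
            if op in ("X", "M"):
                trimmed += n
                end -= n
            elif op == "I":  # query-only: reference missing from the read
                trimmed += n
            elif op == "D":  # target-only: give the base back to the insert
                end -= n
        kept_edits = sum(n for n, op in ops if op != "=")
        # fewest flank-internal edits first: a co-optimal anchoring must
        # not burn its edit budget to grab coincidental matches deeper in
        # the read; then prefer consuming the most read bases
        cand = (-kept_edits, end, -trimmed)
        if best is None or cand > best:
            best = cand
    return best[1], -best[2]


def locate_insert(
    read: str, locus: LocusModel, max_edit: int = 4, min_insert: int = 10
) -> LocateResult:
    """Locate the inserted middle segment of a read, if any.

    The upstream flank is aligned anchored at the read start, the
    downstream flank anchored at the read end; trailing insertions in
    either alignment's CIGAR are junction-trimmed reference bases and
    shift the reported junction coordinates.  Middle segments of
    ``min_insert`` or fewer bases return status "none".
    """
    left = locus.left_flank
    right = locus.right_flank
    read = read.upper()
    for orientation, target in (("+", read), ("-", revcomp(read))):
        anchor_l = _anchor_flank(left, target, max_edit)
        if anchor_l is None:
            continue
        anchor_r = _anchor_flank(right[::-1], target[::-1], max_edit)
        if anchor_r is None:
            continue
        end_l, del_l = anchor_l  # inclusive end in target
        end_r_rev, del_r = anchor_r
        start_r = len(target) - 1 - end_r_rev
        ins_start, ins_end = end_l + 1, start_r
        if ins_end < ins_start:
            ins_start = ins_end = end_l + 1
        res = LocateResult(
            status="insert" if ins_end - ins_start > min_insert else "none",
            target=target,
            orientation=orientation,
            insert_start=ins_start,
            insert_end=ins_end,
            left_flank_end=-del_l,
            right_flank_start=del_r,
        )
        return res
    return LocateResult(status="unalignable", target=read)


# ---------------------------------------------------------------------------
# junction microhomology


def call_microhomology(flank: str, insert: str, side: str) -> int:
    """Junctional microhomology as maximal terminal suffix/prefix identity.

    left: largest k with flank[-k:] == insert[:k].
    right: largest k with insert[-k:] == flank[:k].
    """
    if not flank or not insert:
        raise ValueError("flank and insert must be non-empty")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    k = min(len(flank), len(insert))
    if side == "left":
        while k > 0 and flank[-k:] != insert[:k]:
            k -= 1
    else:
        while k > 0 and insert[-k:] != flank[:k]:
            k -= 1
    return k


# ---------------------------------------------------------------------------
# donor mapping


@dataclass(frozen=True)
class DonorHit:
    contig: str
    start: int
    end: int
    strand: str
    identity: float
    q_start: int  # span on the insert
    q_end: int


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1.0
    a.mismatch_score = -2.0
    # gaps priced so a single 1-bp sequencing indel is tolerable but the
    # aligner never bridges the genomic gap between two donor fragments
    a.open_gap_score = -10.0
    a.extend_gap_score = -10.0
    return a


def map_donors(
    insert_seq: str,
    genome: DonorGenome,
    locus: LocusModel | None = None,
    min_seg: int = 10,
    min_identity: float = 0.9,
    max_hits: int = 4,
) -> list[DonorHit]:
    """Tile the insert with its highest-scoring donor alignments.

    Fragments are found greedily: the best local alignment of the
    still-uncovered insert segment over all contigs and strands is
    accepted when it covers at least ``min_seg`` insert bases at
    ``min_identity`` or better, and the flanking uncovered segments are
    recursed on.  Masked donor bases are lowercased and can never match.
    The cut locus itself is searchable as an extra contig when given.
    Hits are returned ordered along the insert.
    """
    if not genome.contigs and locus is None:
        raise ValueError("donor genome is empty")
    targets = {name: genome.mapping_sequence(name) for name in sorted(genome.contigs)}
    if locus is not None:
        targets[locus.locus_id] = locus.sequence
    aligner = _aligner()
    insert_seq = insert_seq.upper()
    hits: list[DonorHit] = []
    segments = [(0, len(insert_seq))]
    while segments and len(hits) < max_hits:
        seg_start, seg_end = segments.pop(0)
        seg = insert_seq[seg_start:seg_end]
        if len(seg) < min_seg:
            continue
        best = None
        for contig, tseq in targets.items():
            for strand in ("+", "-"):
                query = seg if strand == "+" else revcomp(seg)
                alns = aligner.align(tseq, query)
                if alns.score <= 0:
                    continue
                aln = alns[0]
                counts = aln.counts()
                length = counts.identities + counts.mismatches + counts.gaps
                identity = counts.identities / length if length else 0.0
                t_blocks, q_blocks = aln.aligned
                t0, t1 = int(t_blocks[0][0]), int(t_blocks[-1][1])
                q0, q1 = int(q_blocks[0][0]), int(q_blocks[-1][1])
                key = (alns.score, identity, -_contig_rank(contig, targets), -t0, strand == "+")
                if best is None or key > best[0]:
                    best = (key, contig, strand, t0, t1, q0, q1, identity)
        if best is None:
            continue
        _, contig, strand, t0, t1, q0, q1, identity = best
        if strand == "-":
            q0, q1 = len(seg) - q1, len(seg) - q0
        q_cov = q1 - q0
        if q_cov < min_seg or identity < min_identity:
            continue
        if genome.is_masked(contig, t0, t1):
            continue
        hits.append(
            DonorHit(contig, t0, t1, strand, identity, seg_start + q0, seg_start + q1)
        )
        if q0 >= min_seg:
            segments.append((seg_start, seg_start + q0))
        if len(seg) - q1 >= min_seg:
            segments.append((seg_start + q1, seg_end))
    hits.sort(key=lambda h: h.q_start)
    return hits


def _contig_rank(contig: str, targets: dict) -> int:
    return list(targets).index(contig)


# ---------------------------------------------------------------------------
# events and deduplication


@dataclass(frozen=True)
class InsertionEvent:
    event_id: str
    read_ids: tuple[str, ...]
    insert_seq: str
    left_flank_end: int
    right_flank_start: int
    dedup_key: str
    donor_hits: tuple[DonorHit, ...] = ()
    mh_left: int = 0
    mh_right: int = 0
    category: str = ""

    @property
    def donor_count(self) -> int:
        return len(self.donor_hits)

    @property
    def read_support(self) -> int:
        return len(self.read_ids)


def _normalize_flank(observed: str, reference: str, window: int) -> str:
    """Undo a single-base junction indel inside ``window`` of the junction.

    ``observed``/``reference`` are flank strings whose junction-proximal
    end is the string end.  When a global alignment shows exactly one
    1-bp indel within ``window`` bases of the junction and no other
    differences, the reference flank is substituted; otherwise the
    observed flank is kept.
    """
    if window <= 0 or observed == reference:
        return observed
    res = edlib.align(observed, reference, mode="NW", task="path", k=2)
    if res["editDistance"] != 1:
        return observed
    ops = re.findall(r"(\d+)([=XIDM])", res["cigar"])
    pos = 0  # position in reference
    indel = None
    for n, op in ops:
        n = int(n)
        if op in ("X",):
            return observed
        if op == "D":  # base in reference missing from observed
            if n == 1:
                indel = pos
            else:
                return observed
        elif op == "I":  # extra base in observed
            if n == 1:
                indel = pos
            else:
                return observed
        if op in ("=", "X", "D", "M"):
            pos += n
        if op == "M":
            return observed
    if indel is None:
        return observed
    if len(reference) - indel <= window:
        return reference
    return observed


def build_event(
    read_id: str,
    loc: LocateResult,
    locus: LocusModel,
    flank: int = 5,
    indel_window: int = 3,
) -> InsertionEvent:
    """Raw (pre-deduplication) event for a located insert."""
    t = loc.target
    cut = locus.cut_pos
    # compare the whole observed flank (read prefix/suffix) against the
    # whole reference flank: a 1-bp junction indel then shows up as exactly
    # one indel instead of a shifted window
    left_obs = t[: loc.insert_start]
    left_norm = _normalize_flank(left_obs, locus.left_flank, indel_window)
    right_obs = t[loc.insert_end :][::-1]
    right_ref = locus.sequence[
        cut + loc.right_flank_start : cut + locus.primer_down_offset
    ][::-1]
    right_norm = _normalize_flank(right_obs, right_ref, indel_window)
    left_key = left_norm[-flank:]
    right_key = right_norm[::-1][:flank]
    insert = loc.insert_seq
    mh_l = call_microhomology(locus.sequence[:cut], insert, "left") if insert else 0
    mh_r = (
        call_microhomology(locus.sequence[cut + loc.right_flank_start :], insert, "right")
        if insert
        else 0
    )
    return InsertionEvent(
        event_id="",
        read_ids=(read_id,),
        insert_seq=insert,
        left_flank_end=loc.left_flank_end,
        right_flank_start=loc.right_flank_start,
        dedup_key=left_key + "|" + insert + "|" + right_key,
        mh_left=mh_l,
        mh_right=mh_r,
    )


def disregard_junction_indels(
    event: InsertionEvent, locus: LocusModel, window: int = 3, flank: int = 5
) -> InsertionEvent:
    """Recompute the dedup key forgiving 1-bp junction indels in ``window``.

    With ``window=0`` the key is left untouched (identity behaviour).
    """
    left_key, insert, right_key = event.dedup_key.split("|")
    left_ref = locus.left_flank[-flank:]
    cut = locus.cut_pos
    right_ref = locus.sequence[
        cut + event.right_flank_start : cut + event.right_flank_start + flank
    ]
    new_left = _normalize_flank(left_key, left_ref, window)
    new_right = _normalize_flank(right_key[::-1], right_ref[::-1], window)[::-1]
    return replace(event, dedup_key=new_left + "|" + insert + "|" + new_right)


def deduplicate(events: list[InsertionEvent]) -> list[InsertionEvent]:
    """Collapse events sharing a dedup key; read support never multiplies counts."""
    by_key: dict[str, InsertionEvent] = {}
    order: list[str] = []
    for ev in events:
        if ev.dedup_key in by_key:
            prev = by_key[ev.dedup_key]
            by_key[ev.dedup_key] = replace(prev, read_ids=prev.read_ids + ev.read_ids)
        else:
            by_key[ev.dedup_key] = ev
            order.append(ev.dedup_key)
    out = []
    for i, key in enumerate(order):
        out.append(replace(by_key[key], event_id=f"event{i:05d}"))
    return out


def event_category(event: InsertionEvent, genome: DonorGenome, locus: LocusModel) -> str:
    if not event.donor_hits:
        return "unmapped"
    if any(h.contig == locus.locus_id for h in event.donor_hits):
        return "locus_local"
    cats = {genome.category_of(h.contig, h.start, h.end) for h in event.donor_hits}
    for cat in ("mtDNA", "Ty_LTR", "rDNA", "nuclear"):
        if cat in cats:
            return cat
    return "nuclear"


def detect_insertions(
    reads,
    locus: LocusModel,
    genome: DonorGenome,
    max_edit: int = 4,
    min_insert: int = 10,
    indel_window: int = 3,
    min_seg: int = 10,
    min_identity: float = 0.9,
):
    """Full detection pass: locate, deduplicate, map donors, annotate.

    ``reads`` is an iterable of (read_id, sequence) pairs or objects with
    ``read_id``/``sequence`` attributes.  Returns (events, counts dict).
    """
    raw: list[InsertionEvent] = []
    counts = {"reads": 0, "unalignable": 0, "no_insert": 0, "insert_reads": 0}
    for r in reads:
        rid, seq = (r.read_id, r.sequence) if hasattr(r, "sequence") else r
        counts["reads"] += 1
        loc = locate_insert(seq, locus, max_edit=max_edit, min_insert=min_insert)
        if loc.status == "unalignable":
            counts["unalignable"] += 1
        elif loc.status == "none":
            counts["no_insert"] += 1
        else:
            counts["insert_reads"] += 1
            raw.append(build_event(rid, loc, locus, indel_window=indel_window))
    events = deduplicate(raw)
    annotated = []
    for ev in events:
        hits = map_donors(
            ev.insert_seq, genome, locus=locus, min_seg=min_seg, min_identity=min_identity
        )
        ev = replace(ev, donor_hits=tuple(hits))
        ev = replace(ev, category=event_category(ev, genome, locus))
        annotated.append(ev)
    counts["events"] = len(annotated)
    return annotated, counts


# ---------------------------------------------------------------------------
# summaries


def annotate_and_summarize(
    samples: dict[str, tuple[list[InsertionEvent], int]],
    genome: DonorGenome,
    reference: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample insertion frequencies and distributions.

    ``samples`` maps sample name to (events, total repair products).
    Returns (frequency table, per-sample distribution table).  Fold
    change and the 2x2 chi-square p-value (no continuity correction) are
    computed against the named reference sample.
    """
    if reference not in samples:
        raise ValueError(f"unknown reference sample {reference!r}")
    for name, (_, total) in samples.items():
        if total <= 0:
            raise ValueError(f"sample {name!r} has non-positive product total")
    ref_events, ref_total = samples[reference]
    ref_n = len(ref_events)
    freq_rows, dist_rows = [], []
    for name, (events, total) in samples.items():
        n = len(events)
        freq = n / total
        ref_freq = ref_n / ref_total
        fold = freq / ref_freq if ref_freq > 0 else float("nan")
        if name == reference:
            p = 1.0
        else:
            table = np.array([[n, total - n], [ref_n, ref_total - ref_n]])
            if table[:, 0].sum() == 0:
                p = 1.0
            else:
                p = float(stats.chi2_contingency(table, correction=False)[1])
        freq_rows.append(
            {
                "sample": name,
                "n_products": total,
                "n_insertions": n,
                "frequency": freq,
                "fold_change": fold,
                "chi2_p": p,
            }
        )
        sizes = np.array([len(ev.insert_seq) for ev in events]) if events else np.array([])
        cats = pd.Series([ev.category for ev in events], dtype=object)
        dist_rows.append(
            {
                "sample": name,
                "median_size": float(np.median(sizes)) if sizes.size else float("nan"),
                "frac_lt_50": float((sizes < 50).mean()) if sizes.size else float("nan"),
                "frac_gt_100": float((sizes > 100).mean()) if sizes.size else float("nan"),
                **{
                    f"frac_{c}": float((cats == c).mean()) if len(cats) else float("nan")
                    for c in ("nuclear", "rDNA", "Ty_LTR", "mtDNA", "locus_local", "unmapped")
                },
            }
        )
    return pd.DataFrame(freq_rows), pd.DataFrame(dist_rows)
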