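"""Amplicon read simulator with ground truth for every repair-product class.

Each simulated read is the amplicon of one DSB repair product at the cut
locus: intact end joining, local foldback inversion, simple templated
insertion from the donor genome, complex (two-donor) insertion, or
capture of the transformed barcoded oligo.  Substitution errors and PCR
duplicates are applied on top.  The truth table carries one row per
emitted read (duplicates included, flagged) so every detection stage can
be validated against the generative record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .barcode import OligoDesign, default_design, enumerate_barcodes
from .dna import apply_substitution_errors, comp, random_dna, revcomp
from .genome import Cassette, DonorGenome
from .locus import LocusModel

EVENT_CLASSES = (
    "intact_nhej",
    "foldback",
    "simple_insertion",
    "complex_insertion",
    "oligo_capture",
)


@dataclass(frozen=True)
class SimConfig:
    """Generative conditions of a simulated sequencing run.

    The event mix, copy-length distribution, insert-size distribution and
    duplicate handling emulate the repair-product classes the assay
    sequences; the per-base substitution rate is a free parameter of the
    assay (default 0.1%).
    """

    n_reads: int = 2000
    event_mix: dict = field(
        default_factory=lambda: {
            "intact_nhej": 0.55,
            "foldback": 0.20,
            "simple_insertion": 0.15,
            "complex_insertion": 0.06,
            "oligo_capture": 0.04,
        }
    )
    complex_mix: dict = field(
        default_factory=lambda: {"inverted": 0.6, "direct": 0.2, "different_locus": 0.2}
    )
    oligo_single_fraction: float = 0.16
    foldback_copy_p: float = 0.12
    foldback_copy_min: int = 2
    foldback_copy_max: int = 150
    simple_size_median: float = 88.0
    simple_size_sigma: float = 0.45
    simple_size_min: int = 12
    simple_size_max: int = 240
    category_weights: dict = field(
        default_factory=lambda: {
            "nuclear": 0.55,
            "rDNA": 0.10,
            "Ty_LTR": 0.15,
            "mtDNA": 0.20,
        }
    )
    error_rate: float = 0.001
    indel_error_rate: float = 0.0
    duplicate_rate: float = 0.0
    read_len: int = 150
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name, mix in (("event_mix", self.event_mix), ("complex_mix", self.complex_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} proportions must be non-negative")
        unknown = set(self.event_mix) - set(EVENT_CLASSES)
        if unknown:
            raise ValueError(f"unknown event classes: {sorted(unknown)}")
        for rate in (self.error_rate, self.indel_error_rate, self.duplicate_rate,
                     self.oligo_single_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    quality: str


def _mh_left(flank: str, insert: str) -> int:
    k = min(len(flank), len(insert))
    while k > 0 and flank[-k:] != insert[:k]:
        k -= 1
    return k


def canonical_copy_len(locus: LocusModel, generative_len: int) -> int:
    """Maximal-extension copy length a given generative length presents as.

    When the base left of the cut complements the next template base, a
    copy of length c is letter-for-letter identical to one of length c+1
    in the repair product, so the canonical (reported) length extends as
    far as the match runs.
    """
    s = locus.sequence
    cut, co = locus.cut_pos, locus.copy_origin
    k = generative_len
    while (
        co + k < len(s)
        and cut - 1 - (k - generative_len) >= cut - locus.primer_up_offset
        and s[cut - 1 - (k - generative_len)] == comp(s[co + k])
    ):
        k += 1
    return k


def make_foldback_product(
    locus: LocusModel, copy_len: int, variant_idx: int = 0, context_len: int = 7
) -> str:
    """Amplicon of a local foldback-inversion repair product.

    The product is left flank + reverse complement of the copied template
    segment + right flank starting at the first arm (the ``arm1_offset``
    bases nearest the break are trimmed during hairpin formation).  The
    heteroduplex arm can resolve to either arm variant.
    """
    if copy_len < 1 or copy_len > locus.max_copy_len:
        raise ValueError("copy_len outside the available template")
    insert = revcomp(locus.copy_template(copy_len))
    right = locus.sequence[
        locus.cut_pos + locus.arm1_offset : locus.cut_pos + locus.primer_down_offset
    ]
    variants = locus.arm_variants(context_len=locus.arm_len)
    arm = variants[min(variant_idx, len(variants) - 1)]
    right = arm[: len(right)] + right[min(len(arm), len(right)) :]
    return locus.left_flank + insert + right


def make_simple_product(locus: LocusModel, insert: str) -> str:
    return locus.left_flank + insert + locus.right_flank


def simulate_oligo_capture(
    oligo,
    mode: str,
    rng: np.random.Generator,
    locus: LocusModel | None = None,
    flank: int = 5,
):
    """One oligo-capture insert (or full amplicon) with truth barcodes.

    ``single``: foldback within one molecule — the 3' terminal arm primes
    copying back from the internal arm toward the 5' end, duplicating the
    barcode as its reverse complement (truth barcodes identical).
    ``two_molecule``: the terminal arm of one molecule primes copying of a
    second, independently barcoded molecule.
    Returns (sequence, (barcode1, barcode2)) with barcodes in design
    orientation.
    """
    if mode not in ("single", "two_molecule"):
        raise ValueError("mode must be 'single' or 'two_molecule'")
    design = oligo if isinstance(oligo, OligoDesign) else OligoDesign.from_sequence(oligo)
    space = 4**design.barcode_len

    def draw_barcode() -> str:
        idx = int(rng.integers(0, space))
        out = []
        for _ in range(design.barcode_len):
            out.append("ACGT"[idx % 4])
            idx //= 4
        return "".join(out)

    b1 = draw_barcode()
    b2 = b1 if mode == "single" else draw_barcode()
    mol1 = design.with_barcode(b1)
    mol2 = design.with_barcode(b2)
    # copy extends from the internal arm toward the 5' end; it must at
    # least cover the barcode plus its upstream flank to be extractable
    min_copy = design.arm1_pos - (design.barcode_start - flank)
    copy_extent = int(rng.integers(min_copy, design.arm1_pos + 1))
    insert = mol1 + revcomp(mol2[design.arm1_pos - copy_extent : design.arm1_pos])
    seq = make_simple_product(locus, insert) if locus is not None else insert
    return seq, (b1, b2)


def _draw_foldback_len(cfg: SimConfig, rng: np.random.Generator, locus: LocusModel) -> int:
    hi = min(cfg.foldback_copy_max, locus.max_copy_len)
    while True:
        k = cfg.foldback_copy_min + int(rng.geometric(cfg.foldback_copy_p)) - 1
        if k <= hi:
            return k


def _draw_simple_insert(
    cfg: SimConfig, rng: np.random.Generator, genome: DonorGenome
) -> tuple[str, str, int, int, str, str]:
    cats = list(cfg.category_weights)
    probs = np.array([cfg.category_weights[c] for c in cats], dtype=float)
    probs /= probs.sum()
    category = cats[int(rng.choice(len(cats), p=probs))]
    by_cat = {}
    for contig, s, e, cat in genome.annotations:
        by_cat.setdefault(cat, []).append(contig)
    contig = str(rng.choice(by_cat[category]))
    g = genome.contigs[contig]
    size = int(
        np.clip(
            np.exp(np.log(cfg.simple_size_median) + cfg.simple_size_sigma * rng.normal()),
            cfg.simple_size_min,
            cfg.simple_size_max,
        )
    )
    for _ in range(200):
        start = int(rng.integers(0, len(g) - size + 1))
        if not genome.is_masked(contig, start, start + size):
            break
    else:
        raise ValueError("could not place donor segment outside masked intervals")
    strand = "+" if rng.random() < 0.5 else "-"
    seg = g[start : start + size]
    insert = seg if strand == "+" else revcomp(seg)
    return insert, contig, start, start + size, strand, category

def _donor_extension_mh(genome: DonorGenome, f1_seq: str, hit2, max_k: int = 30) -> int:
    """Microhomology between fragment 1's end and fragment 2's donor-extended start."""
    contig, s2, e2, strand2 = hit2
    g = genome.contigs[contig]
    best = 0
    for k in range(1, min(max_k, len(f1_seq)) + 1):
        ext = g[s2 - k : s2] if strand2 == "+" else revcomp(g[e2 : e2 + k])
        if len(ext) == k and f1_seq[-k:] == ext:
            best = k
    return best


def _draw_different_locus(
    cfg: SimConfig, rng: np.random.Generator, genome: DonorGenome
) -> tuple[str, tuple, tuple, int]:
    g1 = genome.contigs["chrII"]
    g2 = genome.contigs["chrM"]
    for _ in range(200):
        len1 = int(rng.integers(80, 121))
        s1 = int(rng.integers(6600, 8500 - len1))
        e1 = s1 + len1
        len2 = int(rng.integers(40, 65))
        s2 = int(rng.integers(0, len(g2) - len2 - 5))
        e2 = s2 + len2
        strand2 = "+" if rng.random() < 0.5 else "-"
        f1 = g1[s1:e1]
        f2 = g2[s2:e2] if strand2 == "+" else revcomp(g2[s2:e2])
        # three forced mismatches past fragment 1 keep its alignment from
        # creeping across the junction, so detection is coordinate-exact
        if all(g1[e1 + t] != f2[t] for t in range(3)):
            mh = _donor_extension_mh(genome, f1, ("chrM", s2, e2, strand2))
            return f1 + f2, ("chrII", s1, e1, "+"), ("chrM", s2, e2, strand2), mh
    raise ValueError("could not draw a clean cross-locus donor pair")


def simulate_reads(
    locus: LocusModel,
    genome: DonorGenome,
    cfg: SimConfig,
    oligo: OligoDesign | None = None,
) -> tuple[list[SimRead], pd.DataFrame]:
    """Simulate amplicon reads and the matching truth table.

    Deterministic for a fixed config: identical ``cfg`` (including
    ``rng_seed``) reproduces byte-identical reads and truth rows.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    needs_donor = (
        cfg.event_mix.get("simple_insertion", 0) > 0
        or cfg.event_mix.get("complex_insertion", 0) > 0
    )
    if needs_donor and not genome.contigs:
        raise ValueError("event mix requires donor sequence but the genome is empty")
    if oligo is None:
        oligo = default_design()

    classes = [c for c in EVENT_CLASSES if cfg.event_mix.get(c, 0) > 0]
    probs = np.array([cfg.event_mix[c] for c in classes], dtype=float)
    probs /= probs.sum()
    inverted_cassettes = [c for c in genome.cassettes if c.strand2 == "-"]
    direct_cassettes = [c for c in genome.cassettes if c.strand2 == "+"]

    n_dup = int(round(cfg.n_reads * cfg.duplicate_rate))
    n_unique = cfg.n_reads - n_dup
    reads: list[SimRead] = []
    rows: list[dict] = []

    for i in range(n_unique):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        row: dict = {
            "read_id": f"read{i:06d}",
            "event_class": cls,
            "subclass": "",
            "insert_seq": "",
            "insert_len": 0,
            "donor1_contig": "",
            "donor1_start": -1,
            "donor1_end": -1,
            "donor1_strand": "",
            "donor2_contig": "",
            "donor2_start": -1,
            "donor2_end": -1,
            "donor2_strand": "",
            "relation": "",
            "mh_between": -1,
            "junction_distance": -1,
            "overlap_bp": -1,
            "copy_len": 0,
            "seed_variant": -1,
            "barcode1": "",
            "barcode2": "",
            "category": "",
            "is_duplicate": False,
            "dup_of": "",
        }
        if cls == "intact_nhej":
            product = locus.amplicon
        elif cls == "foldback":
            gen_len = _draw_foldback_len(cfg, rng, locus)
            n_var = len(locus.arm_variants(context_len=locus.arm_len))
            variant = int(rng.integers(0, n_var))
            product = make_foldback_product(locus, gen_len, variant)
            insert = revcomp(locus.copy_template(gen_len))
            row.update(
                insert_seq=insert,
                insert_len=gen_len,
                copy_len=canonical_copy_len(locus, gen_len),
                seed_variant=variant,
                category="locus_local",
                donor1_contig=locus.locus_id,
                donor1_start=locus.copy_origin,
                donor1_end=locus.copy_origin + gen_len,
                donor1_strand="-",
            )
            row["mh_left"] = _mh_left(locus.sequence[: locus.cut_pos], insert)
        elif cls == "simple_insertion":
            insert, contig, s, e, strand, category = _draw_simple_insert(cfg, rng, genome)
            product = make_simple_product(locus, insert)
            row.update(
                insert_seq=insert,
                insert_len=len(insert),
                donor1_contig=contig,
                donor1_start=s,
                donor1_end=e,
                donor1_strand=strand,
                category=category,
            )
        elif cls == "complex_insertion":
            subs = list(cfg.complex_mix)
            sprobs = np.array([cfg.complex_mix[s] for s in subs], dtype=float)
            sprobs /= sprobs.sum()
            sub = subs[int(rng.choice(len(subs), p=sprobs))]
            if sub in ("inverted", "direct"):
                pool = inverted_cassettes if sub == "inverted" else direct_cassettes
                if not pool:
                    raise ValueError(f"genome carries no {sub} cassettes")
                cas: Cassette = pool[int(rng.integers(0, len(pool)))]
                insert = cas.insert_seq(genome.contigs)
                row.update(
                    subclass=sub,
                    insert_seq=insert,
                    insert_len=len(insert),
                    donor1_contig=cas.contig,
                    donor1_start=cas.s1,
                    donor1_end=cas.e1,
                    donor1_strand="+",
                    donor2_contig=cas.contig,
                    donor2_start=cas.s2,
                    donor2_end=cas.e2,
                    donor2_strand=cas.strand2,
                    relation=cas.relation,
                    mh_between=cas.mh,
                    junction_distance=cas.junction_distance,
                    overlap_bp=cas.overlap_bp,
                    category="nuclear",
                )
            else:
                insert, hit1, hit2, mh = _draw_different_locus(cfg, rng, genome)
                row.update(
                    subclass="different_locus",
                    insert_seq=insert,
                    insert_len=len(insert),
                    donor1_contig=hit1[0],
                    donor1_start=hit1[1],
                    donor1_end=hit1[2],
                    donor1_strand=hit1[3],
                    donor2_contig=hit2[0],
                    donor2_start=hit2[1],
                    donor2_end=hit2[2],
                    donor2_strand=hit2[3],
                    relation="different_locus",
                    mh_between=mh,
                    category="nuclear",
                )
            product = make_simple_product(locus, row["insert_seq"])
        else:  # oligo_capture
            mode = "single" if rng.random() < cfg.oligo_single_fraction else "two_molecule"
            product, (b1, b2) = simulate_oligo_capture(oligo, mode, rng, locus=locus)
            insert_len = len(product) - locus.primer_up_offset - locus.primer_down_offset
            row.update(
                subclass=mode,
                insert_seq=product[
                    locus.primer_up_offset : locus.primer_up_offset + insert_len
                ],
                insert_len=insert_len,
                barcode1=b1,
                barcode2=b2,
                category="oligo",
            )
        if cfg.error_rate > 0:
            product = apply_substitution_errors(rng, product, cfg.error_rate)
        if cfg.indel_error_rate > 0:
            product = _apply_indel_errors(rng, product, cfg.indel_error_rate)
        row["product_seq"] = product
        reads.append(SimRead(row["read_id"], product, "F" * len(product)))
        rows.append(row)

    for j in range(n_dup):
        src = int(rng.integers(0, n_unique))
        rid = f"read{n_unique + j:06d}"
        reads.append(replace(reads[src], read_id=rid))
        dup_row = dict(rows[src])
        dup_row.update(read_id=rid, is_duplicate=True, dup_of=rows[src]["read_id"])
        rows.append(dup_row)

    truth = pd.DataFrame(rows)
    return reads, truth


def _apply_indel_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(ch)
            out.append("ACGT"[int(rng.integers(0, 4))])
        else:
            out.append(ch)
    return "".join(out)


def make_pairs(
    reads: list[SimRead], read_len: int
) -> tuple[list[SimRead], list[SimRead]]:
    """Split products into R1/R2 mates of at most ``read_len`` bases."""
    r1, r2 = [], []
    for r in reads:
        n = min(read_len, len(r.sequence)) if read_len > 0 else len(r.sequence)
        r1.append(SimRead(r.read_id, r.sequence[:n], r.quality[:n]))
        rc = revcomp(r.sequence)
        r2.append(SimRead(r.read_id, rc[:n], r.quality[-n:]))
    return r1, r2
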