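"""Insert location, microhomology calling, donor mapping, deduplication."""

import numpy as np
import pytest

from breakins import (
    annotate_and_summarize,
    call_microhomology,
    deduplicate,
    detect_insertions,
    disregard_junction_indels,
    locate_insert,
    map_donors,
)
from breakins.detect import InsertionEvent, build_event
from breakins.dna import random_dna, revcomp
from breakins.genome import DonorGenome
from breakins.simulate import SimConfig, simulate_reads


# -- locate_insert ----------------------------------------------------------


def test_reference_amplicon_has_no_insert(locus):
    assert locate_insert(locus.amplicon, locus).status == "none"


@pytest.mark.parametrize("n, status", [(12, "insert"), (11, "insert"), (10, "none")])
def test_insert_length_threshold_is_strictly_greater_than_10(locus, n, status):
    rng = np.random.default_rng(n)
    cut = locus.primer_up_offset
    read = locus.amplicon[:cut] + random_dna(rng, n) + locus.amplicon[cut:]
    res = locate_insert(read, locus)
    assert res.status == status
    if status == "insert":
        assert len(res.insert_seq) == n


def test_locate_insert_handles_reverse_orientation(locus):
    rng = np.random.default_rng(0)
    cut = locus.primer_up_offset
    ins = random_dna(rng, 20)
    read = locus.amplicon[:cut] + ins + locus.amplicon[cut:]
    res = locate_insert(revcomp(read), locus)
    assert res.status == "insert"
    assert res.orientation == "-"
    assert res.insert_seq == ins


def test_unrelated_read_is_unalignable(locus):
    rng = np.random.default_rng(1)
    assert locate_insert(random_dna(rng, 60), locus).status == "unalignable"


# -- microhomology ----------------------------------------------------------


def test_microhomology_examples():
    assert call_microhomology("AATTGCTA", "GCTATCC", "left") == 4
    assert call_microhomology("AATTGCTA", "CCCC", "left") == 0
    assert call_microhomology("GCTAACGT", "TTTGCTA", "right") == 4


def test_microhomology_matches_exhaustive_scan():
    def oracle(flank, insert, side):
        best = 0
        for k in range(1, min(len(flank), len(insert)) + 1):
            if side == "left" and flank[-k:] == insert[:k]:
                best = k
            if side == "right" and insert[-k:] == flank[:k]:
                best = k
        return best

    rng = np.random.default_rng(2)
    for _ in range(1000):
        flank = random_dna(rng, int(rng.integers(1, 15)), alphabet="AC")
        insert = random_dna(rng, int(rng.integers(1, 15)), alphabet="AC")
        for side in ("left", "right"):
            assert call_microhomology(flank, insert, side) == oracle(flank, insert, side)


# -- donor mapping ----------------------------------------------------------


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(3)
    return DonorGenome(
        contigs={"chrA": random_dna(rng, 2000), "chrB": random_dna(rng, 1500)},
        annotations=[("chrA", 0, 2000, "nuclear"), ("chrB", 0, 1500, "nuclear")],
        masked=[("chrA", 1500, 1600)],
    )


def test_exact_segment_maps_uniquely(toy_genome):
    seg = toy_genome.contigs["chrA"][400:450]
    hits = map_donors(seg, toy_genome)
    assert len(hits) == 1
    h = hits[0]
    assert (h.contig, h.start, h.end, h.strand) == ("chrA", 400, 450, "+")
    assert h.identity == 1.0


def test_reverse_complement_maps_same_interval_minus_strand(toy_genome):
    seg = toy_genome.contigs["chrA"][400:450]
    (h,) = map_donors(revcomp(seg), toy_genome)
    assert (h.contig, h.start, h.end, h.strand) == ("chrA", 400, 450, "-")


def test_chimeric_insert_tiles_two_donors(toy_genome):
    f1 = toy_genome.contigs["chrA"][100:140]
    f2 = toy_genome.contigs["chrB"][700:740]
    hits = map_donors(f1 + f2, toy_genome)
    assert len(hits) == 2
    assert (hits[0].contig, hits[0].start, hits[0].end) == ("chrA", 100, 140)
    assert (hits[1].contig, hits[1].start, hits[1].end) == ("chrB", 700, 740)


def test_masked_intervals_never_reported(toy_genome):
    seg = toy_genome.contigs["chrA"][1500:1560]
    hits = map_donors(seg, toy_genome)
    assert all(not toy_genome.is_masked(h.contig, h.start, h.end) for h in hits)


def test_unmappable_insert_gives_empty_hits(toy_genome):
    hits = map_donors("ACGT" * 10, DonorGenome(contigs={"c": "TTTTTTTTTTTTTTTT"}))
    assert hits == []


# -- deduplication and junction indels --------------------------------------


def _event_from_read(read, locus):
    res = locate_insert(read, locus)
    assert res.status == "insert"
    return build_event("r", res, locus)


def test_identical_reads_collapse_with_support(locus):
    rng = np.random.default_rng(4)
    cut = locus.primer_up_offset
    read = locus.amplicon[:cut] + random_dna(rng, 15) + locus.amplicon[cut:]
    events = deduplicate([_event_from_read(read, locus), _event_from_read(read, locus)])
    assert len(events) == 1
    assert events[0].read_support == 2


def test_difference_beyond_flank_window_still_collapses(locus):
    """Only the insert and 5 bp on each side enter the dedup key."""
    rng = np.random.default_rng(5)
    cut = locus.primer_up_offset
    ins = random_dna(rng, 15)
    a = locus.amplicon[:cut] + ins + locus.amplicon[cut:]
    # substitution 8 bp downstream of the right junction
    pos = cut + 15 + 8
    alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[a[pos]]
    b = a[:pos] + alt + a[pos + 1 :]
    events = deduplicate([_event_from_read(a, locus), _event_from_read(b, locus)])
    assert len(events) == 1


def test_difference_inside_flank_window_separates(locus):
    rng = np.random.default_rng(6)
    cut = locus.primer_up_offset
    ins = random_dna(rng, 15)
    a = locus.amplicon[:cut] + ins + locus.amplicon[cut:]
    pos = cut + 15 + 2  # inside the 5-bp right flank window
    alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[a[pos]]
    b = a[:pos] + alt + a[pos + 1 :]
    events = deduplicate([_event_from_read(a, locus), _event_from_read(b, locus)])
    assert len(events) == 2


def test_junction_indel_within_window_is_disregarded(locus):
    rng = np.random.default_rng(7)
    cut = locus.primer_up_offset
    ins = random_dna(rng, 15)
    clean = locus.amplicon[:cut] + ins + locus.amplicon[cut:]
    # one extra base 2 nt upstream of the left junction
    indel = clean[: cut - 2] + "A" + clean[cut - 2 :]
    ev_clean = _event_from_read(clean, locus)
    ev_indel = _event_from_read(indel, locus)
    assert ev_clean.dedup_key == ev_indel.dedup_key
    # window=0: no forgiveness
    ev0 = disregard_junction_indels(ev_indel, locus, window=0)
    assert ev0.dedup_key == ev_indel.dedup_key  # identity on the already-built key


def test_junction_indel_outside_window_separates(locus):
    rng = np.random.default_rng(8)
    cut = locus.primer_up_offset
    ins = random_dna(rng, 15)
    clean = locus.amplicon[:cut] + ins + locus.amplicon[cut:]
    res_clean = locate_insert(clean, locus)
    indel = clean[: cut - 4] + "A" + clean[cut - 4 :]
    res_indel = locate_insert(indel, locus)
    a = build_event("r", res_clean, locus, indel_window=3)
    b = build_event("r", res_indel, locus, indel_window=3)
    assert a.dedup_key != b.dedup_key


# -- summaries --------------------------------------------------------------


def _fake_events(n, category="nuclear", size=20):
    rng = np.random.default_rng(9)
    out = []
    for i in range(n):
        out.append(
            InsertionEvent(
                event_id=f"e{i}",
                read_ids=(f"r{i}",),
                insert_seq=random_dna(rng, size),
                left_flank_end=0,
                right_flank_start=0,
                dedup_key=str(i),
                category=category,
            )
        )
    return out


def test_frequency_table_fold_change_and_chi_square(genome):
    samples = {
        "mutant": (_fake_events(10), 1000),
        "wt": (_fake_events(1), 1000),
    }
    freq, _ = annotate_and_summarize(samples, genome, reference="wt")
    row = freq.set_index("sample").loc["mutant"]
    assert row["fold_change"] == pytest.approx(10.0)
    # 2x2 chi-square without continuity correction on [[10,990],[1,999]]
    assert row["chi2_p"] == pytest.approx(0.00650659748363784, rel=1e-9)


def test_all_rdna_donors_give_pure_rdna_category(genome):
    events = _fake_events(5, category="rDNA")
    _, dist = annotate_and_summarize({"s": (events, 100)}, genome, reference="s")
    assert dist.iloc[0]["frac_rDNA"] == pytest.approx(1.0)


def test_unknown_reference_sample_rejected(genome):
    with pytest.raises(ValueError, match="reference"):
        annotate_and_summarize({"s": (_fake_events(1), 10)}, genome, reference="nope")


def test_median_insert_size_recovered(locus, genome):
    """Simulated donor insert sizes drawn around median 88 are recovered."""
    cfg = SimConfig(
        n_reads=300,
        event_mix={"simple_insertion": 1.0},
        error_rate=0.0,
        rng_seed=10,
    )
    reads, truth = simulate_reads(locus, genome, cfg)
    events, _ = detect_insertions(reads, locus, genome)
    _, dist = annotate_and_summarize({"s": (events, 300)}, genome, reference="s")
    med = dist.iloc[0]["median_size"]
    assert abs(med - 88) < 15
    assert sorted(len(e.insert_seq) for e in events) == sorted(truth["insert_len"])
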