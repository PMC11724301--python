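"""Oligo design parsing, inverted-repeat finding, barcode extraction and
the identical-barcode chance expectation."""

import numpy as np
import pytest

from breakins import (
    CAPTURE_OLIGO,
    classify_and_expect,
    default_design,
    enumerate_barcodes,
    extract_barcodes,
    find_inverted_repeats,
    recognize_oligo_reads,
)
from breakins.barcode import OligoDesign, recognize_oligo_read
from breakins.dna import random_dna, revcomp
from breakins.simulate import simulate_oligo_capture


def test_printed_oligo_parses_to_69_nt():
    assert default_design().length == 69


def test_printed_oligo_top_inverted_repeat_arm8_spacer18():
    reps = find_inverted_repeats(CAPTURE_OLIGO, min_arm=6)
    top = reps[0]
    assert top.arm_len == 8
    assert top.spacer == 18
    arm1 = CAPTURE_OLIGO[top.pos1 : top.pos1 + 8]
    arm2 = CAPTURE_OLIGO[top.pos2 : top.pos2 + 8]
    assert (arm1, arm2) == ("GTACAGAC", "GTCTGTAC")
    assert revcomp(arm2) == arm1


def test_direct_repeat_is_not_inverted():
    s = "GATTACAA" + "CCATTCTGGA" + "GATTACAA"
    assert find_inverted_repeats(s, min_arm=6) == []


def test_concatenated_reverse_complement_is_full_palindrome():
    s = "ACGGTCAATT"
    reps = find_inverted_repeats(s + revcomp(s), min_arm=4)
    top = reps[0]
    assert top.arm_len == len(s)
    assert top.spacer == 0


def test_exhaustive_pair_scan_confirms_finder_on_oligo():
    """Independent all-pairs scan agrees with the diagonal-run finder."""
    seq = CAPTURE_OLIGO
    n = len(seq)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    found = []
    # anchor arm1 start i and arm2 end e; pairing is seq[i+t] ~ seq[e-1-t]
    for i in range(n):
        for e in range(i + 2, n + 1):
            m = 0
            while (
                i + m < e - m - 1
                and seq[i + m] in comp
                and seq[e - 1 - m] == comp[seq[i + m]]
            ):
                m += 1
            if m >= 6:
                found.append((m, (e - m) - (i + m), i, e - m))
    top = max(found)
    assert (top[0], top[1]) == (8, 18)
    assert seq[top[2] : top[2] + 8] == revcomp(seq[top[3] : top[3] + 8])


def test_recognition_by_printed_seed():
    design = default_design()
    rng = np.random.default_rng(0)
    bg = random_dna(rng, 40)
    flagged, counts = recognize_oligo_reads(
        [("a", bg + "CATTGAACAA" + bg), ("b", bg)], design
    )
    assert flagged == ["a"]
    assert counts["CATTGAACAA"] >= 1


def test_one_mismatch_seed_not_recognized():
    design = default_design()
    seed = "CATTGAACAA"
    near = "CATTGTACAA"  # one substitution
    assert near not in design.seed_substrings
    assert not recognize_oligo_read("GGGG" + near + "GGGG", design)


def test_reference_only_read_not_recognized(locus):
    design = default_design()
    assert not recognize_oligo_read(locus.amplicon, design)


def test_extract_two_identical_barcodes_from_single_molecule():
    rng = np.random.default_rng(1)
    design = default_design()
    seq, (b1, b2) = simulate_oligo_capture(design, "single", rng)
    codes, malformed = extract_barcodes(seq, design)
    assert codes == [b1, b1] and malformed == 0


def test_extract_two_independent_barcodes_from_two_molecules():
    rng = np.random.default_rng(2)
    design = default_design()
    seq, (b1, b2) = simulate_oligo_capture(design, "two_molecule", rng)
    codes, _ = extract_barcodes(seq, design)
    assert sorted(codes) == sorted([b1, b2])


def test_single_oligo_copy_yields_one_barcode():
    design = default_design()
    mol = design.with_barcode("ACGT")
    codes, _ = extract_barcodes(mol, design)
    assert codes == ["ACGT"]


def test_extraction_is_strand_invariant():
    rng = np.random.default_rng(3)
    design = default_design()
    for mode in ("single", "two_molecule"):
        seq, _ = simulate_oligo_capture(design, mode, rng)
        a, _ = extract_barcodes(seq, design)
        b, _ = extract_barcodes(revcomp(seq), design)
        assert sorted(a) == sorted(b)


def test_malformed_gap_counted_not_extracted():
    design = default_design()
    bad = design.up_flank() + "ACG" + design.down_flank()  # 3-base barcode slot
    codes, malformed = extract_barcodes("TTTT" + bad + "TTTT", design)
    assert codes == [] and malformed == 1


def test_barcode_space_of_4mers_is_256():
    assert sum(1 for _ in enumerate_barcodes(4)) == 256


def test_chance_expectation_below_one_percent():
    s = classify_and_expect([["AAAA", "CCCC"]] * 10, barcode_len=4, n_events=342, rng_seed=1)
    assert s.analytic_expectation == pytest.approx(1 / 256)
    assert s.analytic_expectation < 0.01
    assert s.mc_mean < 0.01


def test_all_identical_pairs_report_100_percent():
    s = classify_and_expect([["ACGT", "ACGT"]] * 5, barcode_len=4, rng_seed=0)
    assert s.observed_identical_fraction == pytest.approx(1.0)


def test_events_without_two_barcodes_excluded():
    pairs = [["AAAA", "AAAA"], ["CCCC"], ["AAAA", "CCCC", "GGGG"]]
    s = classify_and_expect(pairs, barcode_len=4, rng_seed=0)
    assert s.n_events == 1 and s.n_excluded == 2


def test_mixture_observed_fraction_matches_binomial_propagation():
    """16% single-molecule + 84% two-molecule at n=342: observed identical
    fraction lands within 3 binomial SD of 0.16 + chance * 0.84."""
    rng = np.random.default_rng(7)
    design = default_design()
    n = 342
    pairs = []
    for _ in range(n):
        mode = "single" if rng.random() < 0.16 else "two_molecule"
        seq, _ = simulate_oligo_capture(design, mode, rng)
        codes, _ = extract_barcodes(seq, design)
        pairs.append(codes)
    s = classify_and_expect(pairs, design.barcode_len, rng_seed=11)
    p = 0.16 + (1 / 256) * 0.84
    sd = np.sqrt(p * (1 - p) / n)
    assert abs(s.observed_identical_fraction - p) <= 3 * sd
    assert s.exceeds_chance
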