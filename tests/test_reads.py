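"""Pair merging against a brute-force overlap oracle, and read QC."""

import numpy as np
import pytest

from breakins.dna import random_dna, revcomp
from breakins.reads import FastqRead, merge_pair, quality_filter


def oracle_best_overlap(s1, s2, min_overlap, max_mismatch_frac):
    """Reference implementation: plain-python scan over all shifts."""
    best = None
    for o in range(-(len(s2) - min_overlap), len(s1) - min_overlap + 1):
        lo, hi = max(0, o), min(len(s1), o + len(s2))
        ov = hi - lo
        if ov < min_overlap:
            continue
        mm = sum(s1[p] != s2[p - o] for p in range(lo, hi))
        if mm > max_mismatch_frac * ov:
            continue
        key = (ov - 2 * mm, ov, -abs(o))
        if best is None or key > best[0]:
            best = (key, o, ov, mm)
    return None if best is None else best[1:]


def _pair_from_product(product, rng=None, read_len=None):
    n = read_len or len(product)
    r1 = FastqRead("r", product[:n], "F" * min(n, len(product)))
    rc = revcomp(product)
    r2 = FastqRead("r", rc[:n], "F" * min(n, len(product)))
    return r1, r2


def test_full_overlap_identity():
    rng = np.random.default_rng(0)
    product = random_dna(rng, 80)
    r1, r2 = _pair_from_product(product)
    m = merge_pair(r1, r2)
    assert m.merged_flag and m.sequence == product


def test_disagreement_resolved_toward_higher_quality():
    rng = np.random.default_rng(1)
    s = random_dna(rng, 40)
    # R2 disagrees at one overlap position but carries higher quality
    pos = 20
    alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[pos]]
    s2 = s[:pos] + alt + s[pos + 1 :]
    r1 = FastqRead("r", s, "5" * 40)  # Q20
    r2 = FastqRead("r", revcomp(s2), "I" * 40)  # Q40
    m = merge_pair(r1, r2)
    assert m.merged_flag
    assert m.sequence[pos] == alt
    # ties go to R1
    r2_tie = FastqRead("r", revcomp(s2), "5" * 40)
    assert merge_pair(r1, r2_tie).sequence[pos] == s[pos]


def test_no_sufficient_overlap_returns_unmerged():
    rng = np.random.default_rng(2)
    r1 = FastqRead("r", random_dna(rng, 30), "F" * 30)
    r2 = FastqRead("r", random_dna(rng, 30), "F" * 30)
    m = merge_pair(r1, r2, min_overlap=25)
    assert not m.merged_flag


def test_merge_decision_matches_bruteforce_oracle():
    rng = np.random.default_rng(3)
    for _ in range(300):
        product = random_dna(rng, int(rng.integers(30, 90)))
        n = int(rng.integers(20, min(60, len(product)) + 1))
        r1s = product[:n]
        r2s = revcomp(product)[:n]
        got = merge_pair(
            FastqRead("r", r1s, "F" * n), FastqRead("r", r2s, "F" * n), min_overlap=10
        )
        exp = oracle_best_overlap(r1s, revcomp(r2s), 10, 0.1)
        assert got.merged_flag == (exp is not None)
        if exp is not None:
            o, ov, mm = exp
            lo = min(0, o)
            hi = max(len(r1s), o + n)
            assert len(got.sequence) == hi - lo


def test_mate_swap_symmetry():
    """Merging (r2, r1) yields the reverse complement of merging (r1, r2)."""
    rng = np.random.default_rng(4)
    for _ in range(50):
        product = random_dna(rng, 60)
        r1, r2 = _pair_from_product(product, read_len=45)
        a = merge_pair(r1, r2)
        b = merge_pair(r2, r1)
        assert a.merged_flag == b.merged_flag
        if a.merged_flag:
            assert b.sequence == revcomp(a.sequence)


def test_empty_read_rejected():
    with pytest.raises(ValueError):
        merge_pair(FastqRead("r", "", ""), FastqRead("r", "ACGT", "FFFF"))


def test_quality_filter_rules():
    rng = np.random.default_rng(5)
    good = FastqRead("good", random_dna(rng, 50), "I" * 50)
    low = FastqRead("low", random_dna(rng, 50), "#" * 50)  # Q2
    contaminant = random_dna(rng, 31)
    hit = FastqRead("hit", random_dna(rng, 20) + contaminant + random_dna(rng, 10), "I" * 61)
    kept, report = quality_filter([good, low, hit], min_mean_q=20, contaminant_seqs=[contaminant])
    assert [r.read_id for r in kept] == ["good"]
    assert report["low_quality"] == 1 and report["contaminant"] == 1


def test_quality_filter_counts_spiked_contaminants():
    rng = np.random.default_rng(6)
    contaminant = random_dna(rng, 60)
    clean = [FastqRead(f"c{i}", random_dna(rng, 80), "I" * 80) for i in range(990)]
    spiked = [
        FastqRead(f"s{i}", contaminant[:40] + random_dna(rng, 40), "I" * 80)
        for i in range(10)
    ]
    kept, report = quality_filter(clean + spiked, contaminant_seqs=[contaminant])
    assert report["contaminant"] == 10
    assert len(kept) == 990
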