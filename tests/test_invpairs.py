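"""Two-donor insertion classification and pair metrics."""

import numpy as np
import pytest

from breakins import classify_pair, pair_metrics, summarize_complex
from breakins.detect import DonorHit, InsertionEvent
from breakins.dna import comp, random_dna, revcomp
from breakins.genome import DonorGenome
from breakins.invpairs import donor_extension_mh


def _hit(contig, start, end, strand, q_start=0):
    return DonorHit(contig, start, end, strand, 1.0, q_start, q_start + end - start)


def test_classify_same_locus_opposite_strands_inverted():
    assert classify_pair(_hit("chrV", 1000, 1100, "+"), _hit("chrV", 1050, 1150, "-")) == "inverted"


def test_classify_same_locus_same_strand_direct():
    assert classify_pair(_hit("chrV", 1000, 1100, "+"), _hit("chrV", 1200, 1300, "+")) == "direct"


def test_classify_other_contig_or_far_apart_different_locus():
    assert classify_pair(_hit("chrV", 1000, 1100, "+"), _hit("chrX", 1000, 1100, "-")) == "different_locus"
    assert (
        classify_pair(
            _hit("chrV", 1000, 1100, "+"), _hit("chrV", 5000, 5100, "-"), same_locus_window=1000
        )
        == "different_locus"
    )


def test_classify_is_symmetric_in_hit_order():
    rng = np.random.default_rng(0)
    for _ in range(100):
        h1 = _hit("c", int(rng.integers(0, 500)), int(rng.integers(500, 900)), "+")
        h2 = _hit("c", int(rng.integers(0, 500)), int(rng.integers(500, 900)), "-")
        assert classify_pair(h1, h2) == classify_pair(h2, h1)


def test_unmapped_hit_rejected():
    with pytest.raises(ValueError, match="mapped"):
        classify_pair(None, _hit("c", 0, 10, "+"))


@pytest.fixture()
def planted_genome():
    """One contig with an inverted pair planted to share a 6-bp junction
    microhomology: g[e1-6:e1] == revcomp(g[e2:e2+6])."""
    rng = np.random.default_rng(1)
    g = list(random_dna(rng, 400))
    s1, e1 = 20, 140
    d = 14
    e2 = e1 - d
    s2 = e2 - 60
    for j in range(6):
        g[e2 + j] = comp(g[e1 - 1 - j])
    if g[e2 + 6] == comp(g[e1 - 7]):
        g[e2 + 6] = "A" if comp(g[e1 - 7]) != "A" else "C"
    genome = DonorGenome(contigs={"c": "".join(g)}, annotations=[("c", 0, 400, "nuclear")])
    return genome, (s1, e1, s2, e2, d)


def test_inverted_pair_metrics_recover_planted_values(planted_genome):
    genome, (s1, e1, s2, e2, d) = planted_genome
    g = genome.contigs["c"]
    insert = g[s1:e1] + revcomp(g[s2:e2])
    h1 = _hit("c", s1, e1, "+", q_start=0)
    h2 = _hit("c", s2, e2, "-", q_start=e1 - s1)
    pm = pair_metrics(h1, h2, insert, genome)
    assert pm.relation == "inverted"
    assert pm.mh_between == 6
    assert pm.overlap_bp == e2 - max(s1, s2)
    assert pm.junction_distance == d


def test_adjacent_fragments_have_zero_overlap_and_gap_distance():
    rng = np.random.default_rng(2)
    genome = DonorGenome(contigs={"c": random_dna(rng, 300)})
    h1 = _hit("c", 50, 100, "+", q_start=0)
    h2 = _hit("c", 120, 170, "+", q_start=50)
    g = genome.contigs["c"]
    insert = g[50:100] + g[120:170]
    pm = pair_metrics(h1, h2, insert, genome)
    assert pm.overlap_bp == 0
    assert pm.gap_bp == 20
    assert pm.junction_distance == 20


def test_identical_intervals_opposite_strands_fully_overlap():
    rng = np.random.default_rng(3)
    genome = DonorGenome(contigs={"c": random_dna(rng, 300)})
    h1 = _hit("c", 50, 120, "+", q_start=0)
    h2 = _hit("c", 50, 120, "-", q_start=70)
    g = genome.contigs["c"]
    insert = g[50:120] + revcomp(g[50:120])
    pm = pair_metrics(h1, h2, insert, genome)
    assert pm.overlap_bp == 70
    assert pm.relation == "inverted"


def test_mh_between_matches_bruteforce_oracle():
    rng = np.random.default_rng(4)
    for _ in range(200):
        genome = DonorGenome(contigs={"c": random_dna(rng, 120, alphabet="AC")})
        g = genome.contigs["c"]
        s2, e2 = 40, 80
        strand = "+" if rng.random() < 0.5 else "-"
        f1 = random_dna(rng, 30, alphabet="AC")
        h2 = _hit("c", s2, e2, strand)
        got = donor_extension_mh(f1, h2, genome)
        best = 0
        for k in range(1, 31):
            ext = g[s2 - k : s2] if strand == "+" else revcomp(g[e2 : e2 + k])
            if len(ext) == k and f1[-k:] == ext:
                best = k
        assert got == best


def _event(i, hits, category="nuclear"):
    return InsertionEvent(
        event_id=f"e{i}",
        read_ids=(f"r{i}",),
        insert_seq="A" * 30,
        left_flank_end=0,
        right_flank_start=0,
        dedup_key=str(i),
        donor_hits=tuple(hits),
        category=category,
    )


def test_summarize_complex_fixture_fractions(genome):
    """15 of 23 inverted complex events report as 65.2%."""
    events = []
    i = 0
    for _ in range(15):  # inverted same-locus pairs on the nuclear contig
        events.append(_event(i, [_hit("chrII", 7000, 7100, "+", 0), _hit("chrII", 7050, 7150, "-", 100)]))
        i += 1
    for _ in range(8):  # direct pairs
        events.append(_event(i, [_hit("chrII", 7000, 7100, "+", 0), _hit("chrII", 7150, 7250, "+", 100)]))
        i += 1
    for _ in range(77):  # simple events
        events.append(_event(i, [_hit("chrII", 7000, 7100, "+", 0)]))
        i += 1
    s = summarize_complex(events, genome)
    assert s["n_complex"] == 23
    assert s["pct_inverted_of_complex"] == pytest.approx(65.2, abs=0.05)
    assert s["pct_complex"] == pytest.approx(23.0, abs=1e-9)


def test_summarize_complex_empty_is_na(genome):
    s = summarize_complex([_event(0, [_hit("chrII", 0, 50, "+")])], genome)
    assert s["n_complex"] == 0
    assert s["pct_inverted_of_complex"] is None


def test_summarize_all_inverted_is_100(genome):
    events = [
        _event(i, [_hit("chrII", 7000, 7100, "+", 0), _hit("chrII", 7020, 7120, "-", 100)])
        for i in range(4)
    ]
    s = summarize_complex(events, genome)
    assert s["pct_inverted_of_complex"] == pytest.approx(100.0)


def test_summarize_excludes_repetitive_categories(genome):
    events = [
        _event(0, [_hit("rDNA", 100, 200, "+", 0), _hit("rDNA", 150, 250, "-", 100)]),
        _event(1, [_hit("chrII", 7000, 7100, "+", 0), _hit("chrII", 7050, 7150, "-", 100)]),
    ]
    s = summarize_complex(events, genome)
    assert s["n_two_donor_eligible"] == 1
    assert s["n_inverted"] == 1
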