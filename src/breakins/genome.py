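"""Synthetic donor genome: contigs, annotations, masking and planted
same-locus donor-pair cassettes.

The genome stands in for the yeast genome the assay maps insertion donors
against.  Contigs carry category annotations (nuclear, rDNA, Ty_LTR,
mtDNA), a masked interval emulating homology-donor masking, feature tracks
for enrichment analysis, and a small number of "cassettes": fixed
same-locus donor pairs with a planted inter-fragment microhomology that
complex (two-donor) insertion events are drawn from, mimicking the
hotspot structure of real inverted-insertion donors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dna import comp, mutate_base, random_dna, revcomp

Interval = tuple[str, int, int]


@dataclass(frozen=True)
class Cassette:
    """A same-locus donor pair planted in the genome.

    fragment 1 is ``contig[s1:e1]`` on the plus strand; fragment 2 is
    ``contig[s2:e2]`` on ``strand2``.  ``mh`` is the inter-fragment
    junction microhomology planted at genome-build time.
    """

    contig: str
    s1: int
    e1: int
    s2: int
    e2: int
    strand2: str  # "-" => inverted pair, "+" => direct pair
    mh: int
    junction_distance: int
    overlap_bp: int

    @property
    def relation(self) -> str:
        return "inverted" if self.strand2 == "-" else "direct"

    def insert_seq(self, contigs: dict[str, str]) -> str:
        g = contigs[self.contig]
        f1 = g[self.s1 : self.e1]
        f2 = g[self.s2 : self.e2]
        if self.strand2 == "-":
            f2 = revcomp(f2)
        return f1 + f2


@dataclass
class DonorGenome:
    """Named contigs with category annotations and masked intervals."""

    contigs: dict[str, str]
    annotations: list[tuple[str, int, int, str]] = field(default_factory=list)
    masked: list[Interval] = field(default_factory=list)
    features: dict[str, list[Interval]] = field(default_factory=dict)
    cassettes: list[Cassette] = field(default_factory=list)

    def __post_init__(self) -> None:
        for contig, start, end, _ in self.annotations:
            if contig not in self.contigs:
                raise ValueError(f"annotation on unknown contig {contig!r}")
            if not (0 <= start < end <= len(self.contigs[contig])):
                raise ValueError(f"annotation interval out of bounds on {contig!r}")
        for contig, start, end in self.masked:
            if not (0 <= start < end <= len(self.contigs[contig])):
                raise ValueError(f"masked interval out of bounds on {contig!r}")

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def mapping_sequence(self, contig: str) -> str:
        """Contig sequence with masked intervals lowercased.

        Donor alignment scoring is case sensitive, so lowercase (masked)
        bases never match an uppercase insert base: masked intervals are
        effectively excluded from donor mapping.
        """
        seq = self.contigs[contig]
        spans = [(s, e) for c, s, e in self.masked if c == contig]
        if not spans:
            return seq
        out = list(seq)
        for s, e in spans:
            out[s:e] = seq[s:e].lower()
        return "".join(out)

    def is_masked(self, contig: str, start: int, end: int) -> bool:
        return any(c == contig and start < me and ms < end for c, ms, me in self.masked)

    def category_of(self, contig: str, start: int, end: int) -> str:
        """Donor category by annotation overlap, priority mtDNA > Ty_LTR > rDNA > nuclear."""
        cats = {
            cat
            for c, s, e, cat in self.annotations
            if c == contig and start < e and s < end
        }
        for cat in ("mtDNA", "Ty_LTR", "rDNA", "nuclear"):
            if cat in cats:
                return cat
        return "nuclear"


def _plant_inverted_cassette(
    g: list[str], contig: str, block: int, rng: np.random.Generator, mh_choices, mh_weights
) -> Cassette:
    s1 = block + 20
    len1 = int(rng.integers(100, 141))
    e1 = s1 + len1
    m = int(rng.choice(mh_choices, p=mh_weights))
    d = 2 * m + 2 + 2 * int(rng.integers(0, 5))  # even, >= 2m+2: constraints stay disjoint
    e2 = e1 - d
    len2 = int(rng.integers(40, 71))
    s2 = e2 - len2
    # plant the inter-fragment microhomology: f1 suffix == revcomp(donor
    # extension of f2), i.e. g[e1-m:e1] == revcomp(g[e2:e2+m])
    for j in range(m):
        g[e2 + j] = comp(g[e1 - 1 - j])
    # boundary: exactly m, not more
    if g[e2 + m] == comp(g[e1 - m - 1]):
        g[e2 + m] = mutate_base(rng, g[e2 + m], forbidden=comp(g[e1 - m - 1]))
    # guards: three forced mismatches after fragment 1 so its local
    # alignment cannot creep past the junction
    for t in range(3):
        bad = comp(g[e2 - 1 - t])
        if g[e1 + t] == bad:
            g[e1 + t] = mutate_base(rng, g[e1 + t], forbidden=bad)
    frag1 = "".join(g[s1:e1])
    ext = revcomp("".join(g[e2 : e2 + m + 1]))
    assert frag1[-m:] == ext[1:], "planted microhomology failed self-check"
    return Cassette(
        contig=contig,
        s1=s1,
        e1=e1,
        s2=s2,
        e2=e2,
        strand2="-",
        mh=m,
        junction_distance=d,
        overlap_bp=max(0, e2 - max(s1, s2)),
    )


def _plant_direct_cassette(
    g: list[str], contig: str, block: int, rng: np.random.Generator, mh_choices, mh_weights
) -> Cassette:
    s1 = block + 20
    len1 = int(rng.integers(100, 141))
    e1 = s1 + len1
    m = int(rng.choice(mh_choices, p=mh_weights))
    d = m + 6 + int(rng.integers(0, 15))
    s2 = e1 + d
    len2 = int(rng.integers(40, 71))
    e2 = s2 + len2
    g[s2 - m : s2] = g[e1 - m : e1]
    if g[s2 - m - 1] == g[e1 - m - 1]:
        g[s2 - m - 1] = mutate_base(rng, g[s2 - m - 1], forbidden=g[e1 - m - 1])
    for t in range(3):
        if g[e1 + t] == g[s2 + t]:
            g[e1 + t] = mutate_base(rng, g[e1 + t], forbidden=g[s2 + t])
    return Cassette(
        contig=contig,
        s1=s1,
        e1=e1,
        s2=s2,
        e2=e2,
        strand2="+",
        mh=m,
        junction_distance=d,
        overlap_bp=0,
    )


def default_genome(
    rng_seed: int = 11,
    n_inverted_cassettes: int = 4,
    n_direct_cassettes: int = 2,
) -> DonorGenome:
    """Build the default synthetic donor genome.

    Four contigs, one per donor category, a masked window on the nuclear
    contig, feature tracks used by the enrichment stage, and planted
    same-locus donor-pair cassettes on the nuclear contig.
    """
    rng = np.random.default_rng(rng_seed)
    sizes = {"chrII": 9000, "rDNA": 2500, "Ty1": 1500, "chrM": 3000}
    contigs = {name: random_dna(rng, n) for name, n in sizes.items()}

    g = list(contigs["chrII"])
    # tandem repeats planted into the nuclear contig
    g[5000:5050] = "AC" * 25
    g[5200:5250] = "TTAGG" * 10

    mh_choices = np.arange(2, 12)
    mh_weights = np.array([4, 7, 10, 13, 16, 16, 13, 10, 7, 4], dtype=float)
    mh_weights /= mh_weights.sum()
    cassettes: list[Cassette] = []
    block = 1200
    for _ in range(n_inverted_cassettes):
        cassettes.append(_plant_inverted_cassette(g, "chrII", block, rng, mh_choices, mh_weights))
        block += 420
    for _ in range(n_direct_cassettes):
        cassettes.append(_plant_direct_cassette(g, "chrII", block, rng, mh_choices, mh_weights))
        block += 420
    contigs["chrII"] = "".join(g)

    annotations = [
        ("chrII", 0, sizes["chrII"], "nuclear"),
        ("rDNA", 0, sizes["rDNA"], "rDNA"),
        ("Ty1", 0, sizes["Ty1"], "Ty_LTR"),
        ("chrM", 0, sizes["chrM"], "mtDNA"),
    ]
    masked = [("chrII", 6000, 6500)]
    features = {
        "telomere": [("chrII", 0, 300), ("chrII", 8700, 9000)],
        "R_loop": [("chrII", 4300, 4450), ("chrII", 7000, 7150)],
        "tandem_repeat": [("chrII", 5000, 5050), ("chrII", 5200, 5250)],
        "ARS": [("chrII", 7600, 7700)],
        "tRNA": [("chrII", 4800, 4870)],
    }
    return DonorGenome(
        contigs=contigs,
        annotations=annotations,
        masked=masked,
        features=features,
        cassettes=cassettes,
    )
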