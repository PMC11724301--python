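"""Geometry and construction of the cut-locus model.

The locus emulates an HO-endonuclease-cut MATa-like amplicon: a cut site
with a short 3' overhang, PCR primers a few bases up- and downstream, and a
pair of imperfect inverted microhomology "arms" downstream of the cut whose
annealing drives local foldback inversions.  Offsets follow the convention
that "x bp from the DSB end" counts the bases strictly between the break
end and the arm's first base, which makes the published 10-bp arms at 2 and
53 bp sit around a 41-bp spacer (the hairpin loop).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dna import BASES, comp, hamming, mutate_base, random_dna, revcomp

#: canonical arm for the default geometry; its first 7 bases are the
#: junction context of the first published seed variant
_CANONICAL_ARM = "CAGTATACGG"
#: canonical first 5 bases at the copy origin; their reverse complement
#: (TACTT) is the start of the inverted copy as it appears in products
_CANONICAL_ORIGIN = "AAGTA"


@dataclass(frozen=True)
class LocusModel:
    """Amplicon geometry of an endonuclease-cut locus.

    Attributes
    ----------
    sequence:
        Top-strand sequence of the chromosomal region around the cut.  It
        must extend far enough right of the cut to serve as the template
        for foldback copies.
    cut_pos:
        0-based offset of the break point on the top strand.
    arm1_offset, arm2_offset:
        Bases strictly between the break end and the first base of each
        inverted-microhomology arm (downstream of the cut).
    """

    locus_id: str
    sequence: str
    cut_pos: int
    overhang_len: int = 4
    primer_up_offset: int = 11
    primer_down_offset: int = 18
    arm_len: int = 10
    arm1_offset: int = 2
    arm2_offset: int = 53
    arm_mismatches: int = 1

    def __post_init__(self) -> None:
        if self.arm2_offset < self.arm1_offset + self.arm_len:
            raise ValueError(
                "arm2_offset must be at least arm1_offset + arm_len "
                "(arms must not overlap)"
            )
        if self.spacer < 0:
            raise ValueError("spacer = arm2_offset - arm1_offset - arm_len must be >= 0")
        if len(self.sequence) < self.primer_up_offset + self.primer_down_offset:
            raise ValueError("sequence shorter than primer_up_offset + primer_down_offset")
        if self.cut_pos < self.primer_up_offset:
            raise ValueError("cut_pos leaves no room for the upstream primer offset")
        if self.cut_pos + self.primer_down_offset > len(self.sequence):
            raise ValueError("cut_pos leaves no room for the downstream primer offset")
        if self.cut_pos + self.arm2_offset + self.arm_len > len(self.sequence):
            raise ValueError("sequence too short to contain the distal arm")
        mism = hamming(self.arm1, revcomp(self.arm2))
        if mism > self.arm_mismatches:
            raise ValueError(
                f"reverse complement of arm2 differs from arm1 at {mism} positions, "
                f"more than the tolerated {self.arm_mismatches}"
            )

    # -- geometry ---------------------------------------------------------

    @property
    def spacer(self) -> int:
        """Bases between the arms: the hairpin loop length."""
        return self.arm2_offset - self.arm1_offset - self.arm_len

    @property
    def arm1(self) -> str:
        s = self.cut_pos + self.arm1_offset
        return self.sequence[s : s + self.arm_len]

    @property
    def arm2(self) -> str:
        s = self.cut_pos + self.arm2_offset
        return self.sequence[s : s + self.arm_len]

    @property
    def copy_origin(self) -> int:
        """First template position copied by foldback synthesis (abs coord)."""
        return self.cut_pos + self.arm2_offset + self.arm_len

    @property
    def max_copy_len(self) -> int:
        return len(self.sequence) - self.copy_origin

    def copy_template(self, length: int) -> str:
        """Template segment copied by a foldback of the given length."""
        if length > self.max_copy_len:
            raise ValueError("requested copy length exceeds available template")
        return self.sequence[self.copy_origin : self.copy_origin + length]

    def arm_variants(self, context_len: int = 7) -> list[str]:
        """Junction contexts a foldback product can carry at the right arm.

        The annealed arm heteroduplex can resolve to either strand's
        version, so both arm1 and revcomp(arm2) (identical when the arms
        are a perfect inverted repeat) are possible in products.
        """
        v1 = self.arm1[:context_len]
        v2 = revcomp(self.arm2)[:context_len]
        return [v1] if v1 == v2 else [v1, v2]

    # -- amplicon views ---------------------------------------------------

    @property
    def amplicon(self) -> str:
        """Reference amplicon: primer-to-primer window around the cut."""
        return self.sequence[
            self.cut_pos - self.primer_up_offset : self.cut_pos + self.primer_down_offset
        ]

    @property
    def left_flank(self) -> str:
        """Amplicon sequence upstream of the cut."""
        return self.sequence[self.cut_pos - self.primer_up_offset : self.cut_pos]

    @property
    def right_flank(self) -> str:
        """Amplicon sequence downstream of the cut."""
        return self.sequence[self.cut_pos : self.cut_pos + self.primer_down_offset]


def build_locus(
    arm_len: int = 10,
    arm1_offset: int = 2,
    arm2_offset: int = 53,
    arm_mismatches: int = 1,
    overhang_len: int = 4,
    primer_up_offset: int = 11,
    primer_down_offset: int = 18,
    template_extra: int = 160,
    locus_id: str = "locus",
    rng_seed: int = 7,
) -> LocusModel:
    """Synthesize a locus embedding the requested cut geometry.

    The background sequence is random but the arm pair (with exactly
    ``arm_mismatches`` mismatching positions between arm1 and the reverse
    complement of arm2) and the first bases of the foldback copy template
    are planted deterministically.  With the default geometry this
    reproduces the canonical CAGTATA/CAGCATA arm-context pair and the
    TACTT copy start, so seed construction yields the published seed
    strings.  Two single-base guards around the copy origin keep copy
    lengths 4/5 unambiguous at the junction.
    """
    if arm_len < 1:
        raise ValueError("arm_len must be >= 1")
    if arm_mismatches < 0 or arm_mismatches > arm_len:
        raise ValueError("arm_mismatches must lie in [0, arm_len]")
    if arm2_offset < arm1_offset + arm_len:
        raise ValueError("arm2_offset must be at least arm1_offset + arm_len (arms must not overlap)")
    if arm1_offset < 0:
        raise ValueError("arm1_offset must be >= 0")

    rng = np.random.default_rng(rng_seed)
    cut_pos = max(primer_up_offset + 10, 120)
    total = cut_pos + arm2_offset + arm_len + max(template_extra, primer_down_offset)
    seq = list(random_dna(rng, total))

    # arm pair: arm1, and arm2 = revcomp(arm1 with planted mismatches)
    if arm_len == len(_CANONICAL_ARM):
        arm1 = _CANONICAL_ARM
    else:
        arm1 = random_dna(rng, arm_len)
    positions = [p for p in [3] if p < arm_len] + [p for p in range(arm_len) if p != 3]
    variant = list(arm1)
    for p in positions[:arm_mismatches]:
        variant[p] = mutate_base(rng, variant[p])
    arm2 = revcomp("".join(variant))
    a1 = cut_pos + arm1_offset
    a2 = cut_pos + arm2_offset
    seq[a1 : a1 + arm_len] = arm1
    seq[a2 : a2 + arm_len] = arm2

    # copy origin: plant canonical first bases when there is room
    co = cut_pos + arm2_offset + arm_len
    if total - co >= len(_CANONICAL_ORIGIN):
        seq[co : co + len(_CANONICAL_ORIGIN)] = _CANONICAL_ORIGIN
        # identifiability guard: a copy of length k is indistinguishable
        # from k+1 when the base left of the cut complements template base
        # k.  Fixing that flank base to G (no complement in AAGTA) and
        # keeping the next template bases C-free makes copy lengths up to
        # 12 unambiguous at the junction.
        seq[cut_pos - 1] = "G"
        for pos in range(co + 5, min(co + 13, total)):
            if seq[pos] == "C":
                seq[pos] = mutate_base(rng, "C", forbidden="C")
        # the inverted copy always ends in T (complement of the A at the
        # copy origin); the first trimmed base right of the cut must differ
        # so flank anchoring cannot absorb the copy's terminal base
        if arm1_offset > 0 and seq[cut_pos] == "T":
            seq[cut_pos] = mutate_base(rng, "T", forbidden="T")

    return LocusModel(
        locus_id=locus_id,
        sequence="".join(seq),
        cut_pos=cut_pos,
        overhang_len=overhang_len,
        primer_up_offset=primer_up_offset,
        primer_down_offset=primer_down_offset,
        arm_len=arm_len,
        arm1_offset=arm1_offset,
        arm2_offset=arm2_offset,
        arm_mismatches=arm_mismatches,
    )
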