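"""Small DNA utilities shared across the package.

Sequences are plain uppercase strings over {A,C,G,T,N}; coordinates are
0-based half-open internally and 1-based inclusive in emitted tables.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def comp(base: str) -> str:
    """Complement of a single base (case preserved, N -> N)."""
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, length: int, alphabet: str = BASES) -> str:
    """Uniform random DNA string of the given length."""
    idx = rng.integers(0, len(alphabet), size=length)
    return "".join(alphabet[i] for i in idx)


def mutate_base(rng: np.random.Generator, base: str, forbidden: str = "") -> str:
    """A base different from `base` and any base in `forbidden`."""
    choices = [b for b in BASES if b != base and b not in forbidden]
    return choices[int(rng.integers(0, len(choices)))]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def apply_substitution_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Independent per-base substitutions at the given rate."""
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        cur = chr(arr[i])
        if cur not in BASES:
            continue
        arr[i] = ord(mutate_base(rng, cur))
    return arr.tobytes().decode()
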