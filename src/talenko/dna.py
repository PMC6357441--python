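"""Small DNA helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (upper-case ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string of the given length."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def mutate_base(rng: np.random.Generator, base: str) -> str:
    """Substitute a base with one of the three alternatives, uniformly."""
    choices = [b for b in BASES if b != base]
    return choices[int(rng.integers(0, 3))]


def hamming(a: str, b: str) -> int:
    """Hamming distance; sequences must have equal length. N never matches."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")
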