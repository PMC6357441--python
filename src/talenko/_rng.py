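"""Labeled child random streams.

All randomness in talenko flows from a single integer seed. Independent
simulation steps draw from child generators keyed by a string label, so adding
one step never shifts the stream consumed by another (reproducibility across
versions of the pipeline).
"""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for (seed, label), stable across processes."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
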