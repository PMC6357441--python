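"""Synthetic paralog-family genomes.

The simulated system is an X-linked family of highly similar gene copies
(three coding paralogs plus an optional pseudogene) embedded in random flank
sequence on one toy chromosome. Copies are derived from a common ancestral
sequence by planting disjoint substitution sites, which bounds every pairwise
identity from below: two copies with ``d`` private substitutions each differ
at no more than ``2 d`` positions.

A central window of each copy is kept free of divergence so that at least one
conserved TALEN target site exists in every copy — the property that makes a
single nuclease pair able to hit the whole family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._rng import child_rng
from .dna import mutate_base, random_dna
from .errors import ContradictionError, ParameterError


@dataclass(frozen=True)
class GeneCopy:
    """One gene copy on the toy chromosome (0-based half-open coordinates)."""

    label: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start:
            raise ParameterError(f"empty interval for {self.label}")
        if self.strand not in "+-":
            raise ParameterError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ParalogFamily:
    """A toy chromosome carrying n homologous gene copies.

    identity_matrix holds realized pairwise fraction-identical values for all
    copies (pseudogene included for reference); the identity floor applies to
    coding copies only.
    """

    chromosome_name: str
    sequence: str
    copies: list[GeneCopy]
    pseudogene_label: Optional[str] = None
    identity_matrix: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        n = len(self.sequence)
        prev_end = -1
        for c in sorted(self.copies, key=lambda c: c.start):
            if c.start < 0 or c.end > n:
                raise ParameterError(f"copy {c.label} outside chromosome bounds")
            if c.start < prev_end:
                raise ParameterError(f"copy {c.label} overlaps a previous copy")
            prev_end = c.end
        labels = [c.label for c in self.copies]
        if len(set(labels)) != len(labels):
            raise ParameterError("duplicate gene labels")
        if self.pseudogene_label is not None and self.pseudogene_label not in labels:
            raise ParameterError("pseudogene label not among copies")

    def copy(self, label: str) -> GeneCopy:
        for c in self.copies:
            if c.label == label:
                return c
        raise KeyError(label)

    def copy_seq(self, label: str) -> str:
        c = self.copy(label)
        return self.sequence[c.start:c.end]

    def coding_copies(self) -> list[GeneCopy]:
        """Copies that count for family-wide specificity (pseudogene excluded)."""
        return [c for c in self.copies if c.label != self.pseudogene_label]

    def to_fasta(self) -> str:
        rec = SeqRecord(Seq(self.sequence), id=self.chromosome_name, description="")
        buf = StringIO()
        SeqIO.write([rec], buf, "fasta")
        return buf.getvalue()


def _pairwise_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 1.0
    return sum(1 for x, y in zip(a, b) if x == y) / n


def make_paralog_family(
    seed: int,
    n_copies: int = 3,
    copy_len: int = 500,
    min_identity: float = 0.92,
    flank_len: int = 500,
    with_pseudogene: bool = True,
    divergent_sites: Optional[int] = None,
    pseudogene_extra_sites: int = 20,
    conserved_window_len: int = 60,
    chromosome_name: str = "chrX_sim",
) -> ParalogFamily:
    """Generate a paralog family whose pairwise identities respect a floor.

    Each copy receives ``divergent_sites`` private substitutions relative to a
    common ancestral sequence; sites are disjoint across copies, so realized
    pairwise identity is at least ``1 - 2*divergent_sites/copy_len`` and never
    below ``min_identity``. When ``divergent_sites`` is None a value filling
    ~80% of the allowed budget is used. A central conserved window receives no
    substitutions in any copy.

    Deterministic for a fixed seed.
    """
    if n_copies < 1:
        raise ParameterError("n_copies must be >= 1")
    if not (0 < min_identity <= 1):
        raise ParameterError("min_identity must be in (0, 1]")
    if copy_len < 60:
        raise ParameterError("copy_len must be >= 60")

    if min_identity == 1.0 and divergent_sites is not None and divergent_sites > 0:
        raise ContradictionError("min_identity=1 is incompatible with divergence sites > 0")
    budget = int(np.floor(copy_len * (1.0 - min_identity) / 2.0))
    if divergent_sites is None:
        d = int(budget * 0.8)
    else:
        d = int(divergent_sites)
        if d > budget:
            raise ParameterError(
                f"divergent_sites={d} violates the identity floor (budget {budget})"
            )

    rng = child_rng(seed, "family")
    ancestral = random_dna(rng, copy_len)

    # Positions eligible for divergence: outside the conserved central window.
    win_lo = max(0, copy_len // 2 - conserved_window_len // 2)
    win_hi = min(copy_len, win_lo + conserved_window_len)
    eligible = np.array([i for i in range(copy_len) if not (win_lo <= i < win_hi)])
    total_labels = n_copies + (1 if with_pseudogene else 0)
    need = d * n_copies + (d + pseudogene_extra_sites if with_pseudogene else 0)
    if need > len(eligible):
        raise ParameterError("copy too short for the requested divergence")
    picked = rng.choice(eligible, size=need, replace=False)

    labels = [f"gene{i + 1}" for i in range(n_copies)]
    pseudo_label = None
    seqs: dict[str, str] = {}
    cursor = 0
    for i, lab in enumerate(labels):
        sites = picked[cursor:cursor + d]
        cursor += d
        s = list(ancestral)
        for p in sites:
            s[p] = mutate_base(rng, s[p])
        seqs[lab] = "".join(s)
    if with_pseudogene:
        pseudo_label = "pseudogene"
        sites = picked[cursor:cursor + d + pseudogene_extra_sites]
        s = list(ancestral)
        for p in sites:
            s[p] = mutate_base(rng, s[p])
        seqs[pseudo_label] = "".join(s)
        labels = labels + [pseudo_label]

    parts = [random_dna(rng, flank_len)]
    copies: list[GeneCopy] = []
    pos = flank_len
    for lab in labels:
        copies.append(GeneCopy(lab, pos, pos + copy_len))
        parts.append(seqs[lab])
        pos += copy_len
        parts.append(random_dna(rng, flank_len))
        pos += flank_len
    sequence = "".join(parts)

    ident = pd.DataFrame(np.ones((total_labels, total_labels)), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                v = _pairwise_identity(seqs[a], seqs[b])
                ident.loc[a, b] = ident.loc[b, a] = v

    fam = ParalogFamily(chromosome_name, sequence, copies, pseudo_label, ident)
    coding = [c.label for c in fam.coding_copies()]
    for i, a in enumerate(coding):
        for j, b in enumerate(coding):
            if i < j and fam.identity_matrix.loc[a, b] < min_identity:
                raise ContradictionError("realized identity below floor (internal)")
    return fam
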