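"""TAL-effector nuclease design over a paralog family.

A TALEN arm is a TAL repeat array read 5'->3' along its bound strand, one
repeat variable di-residue (RVD) per base: NI=A, HD=C, NN=G, NG=T, with NK as
an optional alternative for a 3' half-repeat T. A working nuclease needs two
arms bound on opposite strands across a spacer, so candidate pairs are
enumerated as (plus-strand arm, minus-strand arm, spacer) triples inside gene
copies, optionally requiring the canonical T immediately 5' of each bound
site.

Specificity against the family is classified by Hamming matching of both arms
(no indels inside binding sites): a copy is "hit" when both arms match within
a mismatch allowance at some placement with an admissible spacer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .dna import hamming, revcomp
from .errors import EncodingError, ParameterError
from .family import ParalogFamily

RVD_FOR_BASE = {"A": "NI", "C": "HD", "G": "NN", "T": "NG"}
BASE_FOR_RVD = {"NI": "A", "HD": "C", "NN": "G", "NG": "T", "NK": "T"}


@dataclass(frozen=True)
class RvdArray:
    """Ordered RVD list plus the strand the arm binds."""

    rvds: tuple[str, ...]
    target_strand: str = "plus"

    def __post_init__(self):
        if len(self.rvds) < 1:
            raise EncodingError("empty RVD array")
        for i, r in enumerate(self.rvds):
            if r not in BASE_FOR_RVD:
                raise EncodingError(f"unknown RVD {r!r}")
            if r == "NK" and i != len(self.rvds) - 1:
                raise EncodingError("NK is only valid at the 3' half-repeat position")
        if self.target_strand not in ("plus", "minus"):
            raise EncodingError("target_strand must be plus or minus")


def encode_rvd(dna: str, nk_for_3prime_T: bool = False, target_strand: str = "plus") -> RvdArray:
    """Encode a recognition sequence into RVDs (A->NI, C->HD, G->NN, T->NG).

    With ``nk_for_3prime_T`` set, a terminal T is encoded as NK instead.
    """
    if not dna:
        raise EncodingError("empty recognition sequence")
    rvds = []
    for b in dna.upper():
        if b not in RVD_FOR_BASE:
            raise EncodingError(f"cannot encode base {b!r}")
        rvds.append(RVD_FOR_BASE[b])
    if nk_for_3prime_T and dna[-1].upper() == "T":
        rvds[-1] = "NK"
    return RvdArray(tuple(rvds), target_strand)


def decode_rvd(rvds: RvdArray | tuple[str, ...] | list[str]) -> str:
    """Inverse cipher; NK decodes to T."""
    if isinstance(rvds, RvdArray):
        seq = rvds.rvds
    else:
        seq = tuple(rvds)
        RvdArray(seq)  # validates
    return "".join(BASE_FOR_RVD[r] for r in seq)


@dataclass(frozen=True)
class TalenPair:
    """Two recognition arms with spacer constraints.

    left_seq is the plus-strand recognition sequence; right_seq is given
    5'->3' on the minus strand (i.e. the reverse complement of the plus-strand
    segment it covers). Optional placement metadata records where the pair was
    enumerated.
    """

    left_seq: str
    right_seq: str
    spacer_min: int
    spacer_max: int
    arm_len: int = 15
    left_rvds: RvdArray = field(default=None)  # type: ignore[assignment]
    right_rvds: RvdArray = field(default=None)  # type: ignore[assignment]
    gene_label: Optional[str] = None
    left_start: Optional[int] = None  # chromosome coordinate, 0-based
    spacer: Optional[int] = None

    def __post_init__(self):
        if len(self.left_seq) != self.arm_len or len(self.right_seq) != self.arm_len:
            raise ParameterError("arm lengths must equal arm_len")
        if self.spacer_min > self.spacer_max:
            raise ParameterError("spacer_min > spacer_max")
        if self.left_rvds is None:
            object.__setattr__(self, "left_rvds", encode_rvd(self.left_seq, target_strand="plus"))
        if self.right_rvds is None:
            object.__setattr__(self, "right_rvds", encode_rvd(self.right_seq, target_strand="minus"))

    @property
    def site_len(self) -> int:
        """Plus-strand footprint length at a given spacer (minimum)."""
        return 2 * self.arm_len + self.spacer_min


@dataclass
class SpecificityReport:
    """Per-copy hit table and the family-level class of a pair."""

    hits: dict[str, bool]
    mismatches: dict[str, tuple[int, int]]  # best (left, right) mismatch counts
    pseudogene_hit: Optional[bool]
    klass: str  # family_wide | single_copy | partial | none


def enumerate_pairs(
    family: ParalogFamily,
    arm_len: int = 15,
    spacer_range: tuple[int, int] = (12, 20),
    require_5prime_T: bool = True,
) -> list[TalenPair]:
    """Enumerate all candidate pairs inside gene copies.

    The left arm matches the plus strand; the right arm is the reverse
    complement of the plus-strand window beyond the spacer. With
    ``require_5prime_T`` the base immediately 5' of each bound site must be T
    (on the respective strand). Output is sorted by (position, spacer, arms).
    """
    if arm_len < 8:
        raise ParameterError("arm_len must be >= 8")
    smin, smax = spacer_range
    if smin > smax:
        raise ParameterError("inverted spacer_range")
    seq = family.sequence
    out: list[TalenPair] = []
    for c in family.copies:
        for i in range(c.start, c.end - arm_len + 1):
            if require_5prime_T and (i == 0 or seq[i - 1] != "T"):
                continue
            left = seq[i:i + arm_len]
            for s in range(smin, smax + 1):
                j = i + arm_len + s  # right-arm plus-strand window start
                j_end = j + arm_len
                if j_end > c.end:
                    break
                # 5' of the minus-strand arm is plus position j_end (must be A on plus).
                if require_5prime_T and (j_end >= len(seq) or seq[j_end] != "A"):
                    continue
                right = revcomp(seq[j:j_end])
                out.append(
                    TalenPair(
                        left_seq=left,
                        right_seq=right,
                        spacer_min=smin,
                        spacer_max=smax,
                        arm_len=arm_len,
                        gene_label=c.label,
                        left_start=i,
                        spacer=s,
                    )
                )
    out.sort(key=lambda p: (p.left_start, p.spacer, p.left_seq, p.right_seq))
    return out


def find_pair_sites(
    pair: TalenPair,
    family: ParalogFamily,
    max_mismatch_per_arm: int = 0,
) -> dict[str, list[tuple[int, int, int, int]]]:
    """All placements of a pair inside each copy, by Hamming matching.

    Returns, per gene label, a list of (left_start, spacer, left_mm, right_mm)
    with both arms within the mismatch allowance and the spacer within the
    pair's constraint. Coordinates are chromosome 0-based.
    """
    if max_mismatch_per_arm < 0:
        raise ParameterError("max_mismatch_per_arm must be >= 0")
    L = pair.arm_len
    seq = family.sequence
    right_plus = revcomp(pair.right_seq)
    sites: dict[str, list[tuple[int, int, int, int]]] = {}
    for c in family.copies:
        found = []
        for i in range(c.start, c.end - L + 1):
            lm = hamming(seq[i:i + L], pair.left_seq)
            if lm > max_mismatch_per_arm:
                continue
            for s in range(pair.spacer_min, pair.spacer_max + 1):
                j = i + L + s
                if j + L > c.end:
                    break
                rm = hamming(seq[j:j + L], right_plus)
                if rm <= max_mismatch_per_arm:
                    found.append((i, s, lm, rm))
        sites[c.label] = found
    return sites


def classify_specificity(
    pair: TalenPair,
    family: ParalogFamily,
    max_mismatch_per_arm: int = 0,
) -> SpecificityReport:
    """Classify a pair against the family.

    family_wide: all coding copies hit; single_copy: exactly one; none: zero;
    partial otherwise. The pseudogene is scanned but excluded from the class.
    """
    sites = find_pair_sites(pair, family, max_mismatch_per_arm)
    hits: dict[str, bool] = {}
    mms: dict[str, tuple[int, int]] = {}
    for c in family.copies:
        placements = sites[c.label]
        hits[c.label] = bool(placements)
        if placements:
            best = min(placements, key=lambda t: t[2] + t[3])
            mms[c.label] = (best[2], best[3])
        else:
            mms[c.label] = (pair.arm_len + 1, pair.arm_len + 1)
    coding = [c.label for c in family.coding_copies()]
    n_hit = sum(hits[g] for g in coding)
    if n_hit == len(coding):
        klass = "family_wide"
    elif n_hit == 1:
        klass = "single_copy"
    elif n_hit == 0:
        klass = "none"
    else:
        klass = "partial"
    pseudo_hit = hits.get(family.pseudogene_label) if family.pseudogene_label else None
    return SpecificityReport(
        hits={g: hits[g] for g in coding},
        mismatches=mms,
        pseudogene_hit=pseudo_hit,
        klass=klass,
    )


def pair_report_tsv(pairs: list[TalenPair], reports: list[SpecificityReport]) -> str:
    """TSV report: gene, start, arms, RVD strings, spacer, class."""
    lines = ["gene\tleft_start\tspacer\tleft_arm\tright_arm\tleft_rvds\tright_rvds\tclass"]
    for p, r in zip(pairs, reports):
        lines.append(
            "\t".join(
                [
                    str(p.gene_label),
                    str(p.left_start),
                    str(p.spacer),
                    p.left_seq,
                    p.right_seq,
                    "-".join(p.left_rvds.rvds),
                    "-".join(p.right_rvds.rvds),
                    r.klass,
                ]
            )
        )
    return "\n".join(lines) + "\n"
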