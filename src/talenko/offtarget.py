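"""Paired binding-site scanning with in-silico-PCR semantics.

The off-target question for a TALEN pair is whether the genome contains two
binding sites in productive orientation (left arm on the plus strand, right
arm on the minus strand, left before right) close enough for FokI
dimerization. The scan treats the two recognition sequences like PCR primers:
a site counts when the 3'-terminal ``min_perfect_match`` bases of the primer
match the genome exactly (mismatches further 5' are ignored), and a pair of
sites counts when the implied product size does not exceed ``max_product``.

Defaults follow the standard relaxed search: minimum perfect match 8 nt and
maximum product 100 bp. N in the genome never matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .dna import revcomp
from .errors import ParameterError
from .design import TalenPair


@dataclass(frozen=True)
class PairedHit:
    """One productive left/right site pair (0-based half-open, plus axis)."""

    chrom: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    product_size: int
    left_perfect_match: int
    right_perfect_match: int


def _check_genome(seq: str) -> None:
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ParameterError(f"genome contains non-ACGTN symbols: {sorted(bad)!r}")


def _anchor_positions(seq: str, anchor: str) -> list[int]:
    """All start positions of exact occurrences of ``anchor`` in ``seq``."""
    if "N" in anchor:
        return []
    pos, out = seq.find(anchor), []
    while pos != -1:
        out.append(pos)
        pos = seq.find(anchor, pos + 1)
    return out


def _extend_left(seq: str, primer: str, anchor_start: int, k: int) -> int:
    """Length of the maximal 3'-terminal perfect match at this site."""
    m = k
    i = anchor_start - 1
    j = len(primer) - k - 1
    while i >= 0 and j >= 0 and seq[i] == primer[j] and seq[i] != "N":
        m += 1
        i -= 1
        j -= 1
    return m


def scan_paired_sites(
    genome: str | Mapping[str, str],
    left_seq: str,
    right_seq: str,
    min_perfect_match: int = 8,
    max_product: int = 100,
    chrom: str = "genome",
) -> list[PairedHit]:
    """Find all productive paired sites of (left_seq, right_seq).

    left_seq binds the plus strand; right_seq (given 5'->3' on the minus
    strand) binds the minus strand, downstream of the left site. The binding
    site of each primer spans the full primer length positionally, anchored at
    its 3' end; the product runs from the 5' end of the left site to the 5'
    end of the right site on the plus axis (right_end), inclusive amplicon
    convention: product_size = right_end - left_start.

    Hits are sorted by (chrom, left_start, right_end).
    """
    if isinstance(genome, str):
        contigs: Iterable[tuple[str, str]] = [(chrom, genome)]
    else:
        contigs = sorted(genome.items())
    if min_perfect_match > min(len(left_seq), len(right_seq)):
        raise ParameterError("min_perfect_match exceeds arm length")
    if min_perfect_match < 1:
        raise ParameterError("min_perfect_match must be >= 1")
    k = min_perfect_match
    hits: list[PairedHit] = []
    left_anchor = left_seq[-k:]
    # The right primer's 3' end points 5'-ward on the plus axis; its anchor on
    # the plus strand is revcomp(right 3'-terminal k-mer), at the left edge of
    # the right binding site.
    right_anchor_plus = revcomp(right_seq[-k:])
    for cname, seq in contigs:
        _check_genome(seq)
        lefts = []
        for p in _anchor_positions(seq, left_anchor):
            # 3' end of left primer at p+k; full site spans [site_start, p+k).
            site_end = p + k
            site_start = site_end - len(left_seq)
            if site_start < 0:  # binding site runs off the contig
                continue
            pm = _extend_left(seq, left_seq, p, k)
            lefts.append((site_start, site_end, pm))
        rights = []
        for p in _anchor_positions(seq, right_anchor_plus):
            # Minus-strand primer: its 3' end sits at plus position p; the
            # full site spans [p, p + len(right_seq)) on the plus axis.
            site_start = p
            site_end = p + len(right_seq)
            if site_end > len(seq):  # binding site runs off the contig
                continue
            # extend the perfect match 3'->5' along the minus strand, i.e.
            # rightward on the plus axis past the anchor.
            m = k
            i = p + k
            j = len(right_seq) - k - 1
            while i < len(seq) and j >= 0 and seq[i] == revcomp(right_seq[j]) and seq[i] != "N":
                m += 1
                i += 1
                j -= 1
            rights.append((site_start, site_end, m))
        for ls, le, lpm in lefts:
            for rs, re, rpm in rights:
                if le > rs:  # left site must be fully before the right site
                    continue
                product = re - ls
                if product <= max_product:
                    hits.append(PairedHit(cname, ls, le, rs, re, product, lpm, rpm))
    hits.sort(key=lambda h: (h.chrom, h.left_start, h.right_end))
    return hits


def scan_for_pair(
    genome: str | Mapping[str, str],
    pair: TalenPair,
    min_perfect_match: int = 8,
    max_product: int = 100,
    chrom: str = "genome",
) -> list[PairedHit]:
    """Scan both FokI-compatible orientations of a TalenPair.

    FokI dimerization is orientation-symmetric, so the swapped arrangement
    (right arm binding the plus strand, left arm the minus strand) is also
    scanned and the union returned (deduplicated, sorted).
    """
    a = scan_paired_sites(genome, pair.left_seq, pair.right_seq, min_perfect_match, max_product, chrom)
    b = scan_paired_sites(genome, pair.right_seq, pair.left_seq, min_perfect_match, max_product, chrom)
    seen = set()
    out = []
    for h in a + b:
        key = (h.chrom, h.left_start, h.left_end, h.right_start, h.right_end)
        if key not in seen:
            seen.add(key)
            out.append(h)
    out.sort(key=lambda h: (h.chrom, h.left_start, h.right_end))
    return out


def hits_to_bed(hits: list[PairedHit], name_prefix: str = "pairhit") -> str:
    """BED6 over the full product interval, score = min perfect-match length."""
    lines = []
    for i, h in enumerate(hits):
        score = min(h.left_perfect_match, h.right_perfect_match)
        lines.append(
            f"{h.chrom}\t{h.left_start}\t{h.right_end}\t{name_prefix}{i}\t{score}\t+"
        )
    return "\n".join(lines) + ("\n" if lines else "")
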