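"""Founder genotype tables, all-or-nothing summaries and chimera detection.

Founder genotypes from Sanger screening are written in a compact dialect:
``XX (wt)`` / ``XY (wt)`` for unmodified animals, ``X^Δn`` for a deletion of
n nucleotides on one X allele, ``+n`` for an insertion, ``Δn+m`` for a
deletion with insertion, base substitutions like ``C/T,A/G``, an optional
``Chimera of ...`` annotation (segment tags kept verbatim), and ``No
successful PCR amplification`` where a fusion destroyed a primer site. Both
delta glyphs (U+2206 and U+0394) are accepted.

Paralog fusions (chimeras) are inferred from amplification patterns — both
partner genes fail their gene-specific primers while the mixed cross-gene
pair amplifies — and their junctions are located exactly from amplicon
sequence by maximal prefix/suffix decomposition against the two parent
genes.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from .errors import GenotypeParseError, NoJunctionError, ParameterError
from .simulate import junction_microhomology

_DELTA = "[∆Δ]"  # ∆ or Δ


# ------------------------------------------------------------------ allele model


@dataclass(frozen=True)
class AlleleDescriptor:
    """One X allele of one gene: wt, Δn, +n, Δn+m or substitutions."""

    kind: str  # wt | del | ins | delins | subst
    del_len: int = 0
    ins_len: int = 0
    substitutions: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("wt", "del", "ins", "delins", "subst"):
            raise GenotypeParseError(f"bad allele kind {self.kind}")
        if self.kind in ("del", "delins") and self.del_len < 1:
            raise GenotypeParseError("deletion length must be >= 1")

    @property
    def is_modified(self) -> bool:
        return self.kind != "wt"

    def format(self) -> str:
        if self.kind == "wt":
            return "wt"
        if self.kind == "del":
            return f"Δ{self.del_len}"
        if self.kind == "ins":
            return f"+{self.ins_len}"
        if self.kind == "delins":
            return f"Δ{self.del_len}+{self.ins_len}"
        return ",".join(self.substitutions)


@dataclass
class GeneResult:
    """One gene's cell in the founder table."""

    alleles: list[AlleleDescriptor] = field(default_factory=list)
    failed_amplification: bool = False
    chimera_tag: Optional[str] = None

    @property
    def informative(self) -> bool:
        return bool(self.alleles) or self.failed_amplification

    @property
    def modified(self) -> bool:
        """failed amplification counts as modified: in practice those samples
        turned out to be fusions that destroyed a primer site."""
        if self.failed_amplification:
            return True
        return any(a.is_modified for a in self.alleles)

    @property
    def all_wt(self) -> bool:
        return not self.failed_amplification and bool(self.alleles) and not any(
            a.is_modified for a in self.alleles
        )


@dataclass
class GenotypeRecord:
    pup_id: str
    sex: str
    genes: dict[str, GeneResult]


# ----------------------------------------------------------------------- parsing

_WT_RE = re.compile(r"^X[XY]\s*\(wt\)$")
_FAILED_RE = re.compile(r"^No successful PCR amplification\.?$", re.IGNORECASE)
_DESC_RE = re.compile(
    rf"^(?:{_DELTA}(?P<del>\d+)(?:\+(?P<ins>\d+))?|\+(?P<ins_only>\d+)|"
    rf"(?P<subst>[ACGT]/[ACGT](?:\s*,\s*[ACGT]/[ACGT])*))$"
)
_CHIMERA_RE = re.compile(r"\bChimera(?:\s+of)?\s+(?P<tag>\S+)\s*\)?\s*$", re.IGNORECASE)


def _parse_descriptor(token: str) -> AlleleDescriptor:
    m = _DESC_RE.match(token.strip())
    if not m:
        raise GenotypeParseError(f"malformed allele token {token!r}")
    if m.group("subst"):
        subs = tuple(s.strip() for s in m.group("subst").split(","))
        return AlleleDescriptor("subst", substitutions=subs)
    if m.group("ins_only"):
        return AlleleDescriptor("ins", ins_len=int(m.group("ins_only")))
    d = int(m.group("del"))
    if m.group("ins"):
        return AlleleDescriptor("delins", del_len=d, ins_len=int(m.group("ins")))
    return AlleleDescriptor("del", del_len=d)


def parse_gene_cell(text: str, sex: str) -> GeneResult:
    """Parse one gene cell of a founder genotype row."""
    text = text.strip()
    if _FAILED_RE.match(text):
        return GeneResult(failed_amplification=True)
    chim = _CHIMERA_RE.search(text)
    tag = None
    if chim:
        tag = chim.group("tag").rstrip(")")
        text = text[:chim.start()].strip()
    if _WT_RE.match(text):
        n = 1 if sex == "male" else 2
        return GeneResult(alleles=[AlleleDescriptor("wt")] * n, chimera_tag=tag)
    # allele tokens: male "X^<desc> Y", female "X^<desc> X^<desc>"
    tokens = text.split()
    alleles: list[AlleleDescriptor] = []
    for tok in tokens:
        if tok == "Y":
            continue
        if tok.startswith("X^"):
            alleles.append(_parse_descriptor(tok[2:]))
        elif tok == "X":
            alleles.append(AlleleDescriptor("wt"))
        else:
            raise GenotypeParseError(f"malformed token {tok!r} in {text!r}")
    expected = 1 if sex == "male" else 2
    if len(alleles) != expected:
        raise GenotypeParseError(
            f"{sex} must have {expected} X allele(s), found {len(alleles)} in {text!r}"
        )
    return GeneResult(alleles=alleles, chimera_tag=tag)


def format_gene_cell(result: GeneResult, sex: str) -> str:
    """Inverse of parse_gene_cell on its canonical output."""
    if result.failed_amplification:
        return "No successful PCR amplification"
    if result.all_wt:
        base = "XX (wt)" if sex == "female" else "XY (wt)"
    else:
        parts = []
        for a in result.alleles:
            parts.append("X" if a.kind == "wt" else f"X^{a.format()}")
        if sex == "male":
            parts.append("Y")
        base = " ".join(parts)
    if result.chimera_tag:
        base += f" Chimera of {result.chimera_tag}"
    return base


def parse_genotype(row: dict[str, str], gene_columns: Sequence[str]) -> GenotypeRecord:
    """Parse one founder-table row ({pup_id, sex, <gene cells>})."""
    sex = row["sex"].strip().lower()
    if sex not in ("male", "female"):
        raise GenotypeParseError(f"bad sex {row['sex']!r}")
    genes = {g: parse_gene_cell(row[g], sex) for g in gene_columns}
    return GenotypeRecord(pup_id=row["pup_id"].strip(), sex=sex, genes=genes)


def load_founder_table(path: Optional[str] = None) -> list[GenotypeRecord]:
    """Load the packaged founder genotype fixture (or a user TSV in the same
    dialect: columns pup_id, sex, then one column per gene)."""
    if path is None:
        src = resources.files("talenko").joinpath("data/founder_genotypes.tsv")
        text = src.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    if not rows:
        raise GenotypeParseError("empty founder table")
    gene_cols = [c for c in rows[0].keys() if c not in ("pup_id", "sex")]
    return [parse_genotype(r, gene_cols) for r in rows]


# ----------------------------------------------------------------------- summary


def founder_summary(records: Sequence[GenotypeRecord],
                    failed_amp_policy: str = "modified") -> dict[str, int]:
    """All-or-nothing bookkeeping over founder pups.

    A pup is modified_all_genes when every informative gene carries at least
    one non-wt allele; unmodified when every gene is wt on all alleles;
    partial otherwise. With failed_amp_policy='modified' (default) a failed
    amplification counts as informative-and-modified; with 'missing' it is
    excluded from the informative set.
    """
    if not records:
        raise ParameterError("founder_summary needs at least one record")
    if failed_amp_policy not in ("modified", "missing"):
        raise ParameterError("failed_amp_policy must be 'modified' or 'missing'")
    n_mod = n_unmod = n_partial = n_failed = 0
    for rec in records:
        results = list(rec.genes.values())
        if any(r.failed_amplification for r in results):
            n_failed += 1
        if failed_amp_policy == "missing":
            informative = [r for r in results if r.informative and not r.failed_amplification]
        else:
            informative = [r for r in results if r.informative]
        if informative and all(r.modified for r in informative):
            n_mod += 1
        elif informative and all(r.all_wt for r in informative):
            n_unmod += 1
        else:
            n_partial += 1
    return {
        "n_total": len(records),
        "n_modified_all_genes": n_mod,
        "n_unmodified": n_unmod,
        "n_partial": n_partial,
        "n_with_failed_amp": n_failed,
    }


# ---------------------------------------------------------------------- chimeras


@dataclass
class AmplificationMatrix:
    """Binary PCR outcomes per pup: gene-specific and mixed cross-gene pairs."""

    gene_specific: dict[str, bool]
    mixed: dict[tuple[str, str], bool]  # (forward gene, reverse gene) -> success

    def __post_init__(self):
        if not self.gene_specific:
            raise ParameterError("need at least one gene-specific primer pair")


@dataclass(frozen=True)
class ChimeraEvent:
    gene_5prime: str
    gene_3prime: str
    junction_position_5prime: int  # breakpoint offset within the 5' gene
    junction_position_3prime: int  # breakpoint offset within the 3' gene
    junction_deletion_len: int
    microhomology_len: int

    def __post_init__(self):
        if self.gene_5prime == self.gene_3prime:
            raise ParameterError("chimera genes must be distinct")
        if self.microhomology_len < 0:
            raise ParameterError("microhomology_len must be >= 0")


def infer_chimera_from_amplification(matrix: AmplificationMatrix) -> list[tuple[str, str]]:
    """Fusion candidates (A -> B) from a pup's amplification pattern.

    A->B is emitted iff both A's and B's gene-specific pairs fail and the
    A-forward / B-reverse mixed pair succeeds. A gene whose specific pair
    still amplifies is not called (a mosaic carrier retains an intact copy
    and is handled upstream).
    """
    out = []
    for (fw, rev), success in sorted(matrix.mixed.items()):
        if not success or fw == rev:
            continue
        if matrix.gene_specific.get(fw, True) or matrix.gene_specific.get(rev, True):
            continue
        out.append((fw, rev))
    return out


def locate_fusion_junction(
    amplicon: str,
    gene_a_seq: str,
    gene_b_seq: str,
    gene_a: str = "geneA",
    gene_b: str = "geneB",
    min_anchor: int = 15,
) -> ChimeraEvent:
    """Decompose a chimeric amplicon into an A-prefix + B-suffix.

    Takes the maximal prefix of the amplicon matching gene A, backs off until
    the remainder is a suffix of gene B, and reports the junction. The
    junction deletion (bases of A+B lost relative to an A-then-B reference)
    is invariant across equivalent decompositions; microhomology is the
    longest exact repeat of A and B spanning the junction, which makes the
    breakpoint ambiguous by exactly that many bases. Among equal
    decompositions the maximal-microhomology (leftmost) placement is
    reported.
    """
    # maximal exact prefix shared with A
    p_max = 0
    for i in range(min(len(amplicon), len(gene_a_seq))):
        if amplicon[i] != gene_a_seq[i]:
            break
        p_max = i + 1
    if p_max < min_anchor:
        raise NoJunctionError(f"A-prefix anchor shorter than {min_anchor}")
    for p in range(p_max, min_anchor - 1, -1):
        cb = len(gene_b_seq) - (len(amplicon) - p)
        if cb < 0 or len(amplicon) - p < min_anchor:
            continue
        if amplicon[p:] == gene_b_seq[cb:]:
            # slide left across the microhomology to the leftmost placement
            mh = junction_microhomology(gene_a_seq, gene_b_seq, p, cb)
            ml = 0
            while ml < p and ml < cb and gene_a_seq[p - 1 - ml] == gene_b_seq[cb - 1 - ml]:
                ml += 1
            ca, cb_left = p - ml, cb - ml
            deletion = (len(gene_a_seq) - ca) + cb_left
            return ChimeraEvent(
                gene_5prime=gene_a, gene_3prime=gene_b,
                junction_position_5prime=ca, junction_position_3prime=cb_left,
                junction_deletion_len=deletion, microhomology_len=mh,
            )
    raise NoJunctionError("no A-prefix/B-suffix decomposition with the required anchors")
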