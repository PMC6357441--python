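"""Pedigree-based separation of induced indels from strain background.

The core idea: a nuclease-induced off-target lesion in a founder is
heterozygous and, under repeated backcrossing of carrier females to wild-type
males, is transmitted with probability 0.5 per generation — its prevalence is
"diluted" by half each generation and, once lost from the line, it cannot
reappear. A fixed strain difference against the reference genome is
homozygous in every animal and never dilutes. The classifier formalizes this
as an absorbing Markov chain per variant: the likelihood of a
presence/absence pattern under the founder-heterozygous model is a product of
per-generation retention terms with absorbing absence, while the strain model
assigns probability one to all-present patterns and zero otherwise.

A variant present in every generation but absent from the strain panel cannot
be cleared computationally (a segregating strain polymorphism mimics it); it
is classed needs_validation, mirroring wet-lab confirmation by amplicon size
comparison, for which region design and gel-resolution helpers are provided.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import CoordinateSystemError, ParameterError
from .variants import GENOTYPE_CODES, VariantCall

HET_CODES = ("0/1", "0/2", "1/2")


# ----------------------------------------------------------------- strain filter


@dataclass
class StrainPanel:
    """Known strain-vs-reference differences keyed by (chrom, pos, ref, alt).

    Deletion entries additionally match calls at +-1 bp with identical size
    (left-alignment slack). The coordinate system is declared so that a panel
    in a different system is rejected rather than silently misapplied.
    """

    entries: set[tuple[str, int, str, str]] = field(default_factory=set)
    deletions: set[tuple[str, int, int]] = field(default_factory=set)  # (chrom, pos, size)
    coordinate_system: str = "simulated_v1"

    @classmethod
    def from_variant_defs(cls, defs: Iterable, coordinate_system: str = "simulated_v1") -> "StrainPanel":
        panel = cls(coordinate_system=coordinate_system)
        for v in defs:
            panel.add(v.chrom, v.pos, v.ref, v.alt, v.vtype, v.size)
        return panel

    def add(self, chrom: str, pos: int, ref: str, alt: str, vtype: str = "SNV", size: int = 0):
        self.entries.add((chrom, pos, ref, alt))
        if vtype == "DEL":
            self.deletions.add((chrom, pos, size))

    def __contains__(self, call: VariantCall) -> bool:
        if (call.chrom, call.pos, call.ref, call.alt) in self.entries:
            return True
        if call.vtype == "DEL":
            for dp in (call.pos - 1, call.pos, call.pos + 1):
                if (call.chrom, dp, call.size) in self.deletions:
                    return True
        return False


def strain_filter(
    calls: Sequence[VariantCall],
    panel: StrainPanel,
    calls_coordinate_system: str = "simulated_v1",
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition calls into (retained, removed-by-panel).

    removed holds calls matching the panel exactly on (chrom, pos, ref, alt),
    or for deletions within +-1 bp at identical size. retained + removed is
    the input. A panel declared in a different coordinate system raises.
    """
    if panel.coordinate_system != calls_coordinate_system:
        raise CoordinateSystemError(
            f"panel is in {panel.coordinate_system!r}, calls in {calls_coordinate_system!r}"
        )
    retained, removed = [], []
    for c in calls:
        (removed if c in panel else retained).append(c)
    return retained, removed


# ------------------------------------------------------------ zygosity partition


def zygosity_partition(calls: Sequence[VariantCall]) -> dict[str, int]:
    """Counts per genotype code; includes a 'het_total' = 0/1 + 0/2 + 1/2."""
    counts = Counter(c.genotype_code for c in calls)
    out = {code: counts.get(code, 0) for code in GENOTYPE_CODES}
    out["het_total"] = sum(out[c] for c in HET_CODES)
    return out


# --------------------------------------------------------- generation intersect


def _match(a: VariantCall, b: VariantCall) -> bool:
    """Same variant across samples: chrom, type, size; pos exact for SNVs,
    +-1 for indels (left-alignment ambiguity)."""
    if a.chrom != b.chrom or a.vtype != b.vtype or a.size != b.size:
        return False
    tol = 0 if a.vtype == "SNV" else 1
    return abs(a.pos - b.pos) <= tol


def intersect_generations(
    calls_by_generation: Mapping[int, Sequence[VariantCall]],
) -> list[VariantCall]:
    """Variants present in every generation (anchored on the earliest one).

    Requires >= 2 generations. The returned list is the earliest generation's
    calls that find a match in every other generation; its size is
    non-increasing as generations are added.
    """
    if len(calls_by_generation) < 2:
        raise ParameterError("intersection needs calls from at least two generations")
    gens = sorted(calls_by_generation)
    anchors = list(calls_by_generation[gens[0]])
    common = []
    for a in anchors:
        if all(any(_match(a, b) for b in calls_by_generation[g]) for g in gens[1:]):
            common.append(a)
    return common


# ----------------------------------------------------------------- dilution test


@dataclass
class DilutionReport:
    """Per-variant persistence pattern with model likelihoods and a class."""

    variant_id: str
    presence: list[str]  # per generation: present | absent | missing
    zygosity: list[str]
    in_strain_panel: bool
    lik_induced: float
    lik_strain: float
    classification: str  # strain_variant | induced_candidate | inconsistent | needs_validation


def dilution_test(
    variant_id: str,
    presence: Sequence[str],
    zygosity: Optional[Sequence[str]] = None,
    in_strain_panel: bool = False,
    retention: float = 0.5,
) -> DilutionReport:
    """Score a presence pattern under the induced vs strain models.

    lik_induced multiplies ``retention`` for each generation the variant is
    still present, (1 - retention) at the first absence, and 1 thereafter
    (absence is absorbing: a present-after-absent pattern is impossible under
    the model, lik_induced = 0, class inconsistent). 'missing' observations
    contribute no factor. lik_strain is 1 iff the variant is present in every
    observed generation.
    """
    if not presence:
        raise ParameterError("empty presence pattern")
    if not (0.0 < retention < 1.0):
        raise ParameterError("retention must be in (0, 1)")
    for p in presence:
        if p not in ("present", "absent", "missing"):
            raise ParameterError(f"bad presence state {p!r}")
    lik = 1.0
    absorbed = False
    inconsistent = False
    for p in presence:
        if p == "missing":
            continue
        if p == "present":
            if absorbed:
                inconsistent = True
                break
            lik *= retention
        else:
            if not absorbed:
                lik *= 1.0 - retention
                absorbed = True
    observed = [p for p in presence if p != "missing"]
    all_present = bool(observed) and all(p == "present" for p in observed)
    lik_strain = 1.0 if all_present else 0.0
    if inconsistent:
        lik_induced = 0.0
        klass = "inconsistent"
    else:
        lik_induced = lik
        if all_present:
            klass = "strain_variant" if in_strain_panel else "needs_validation"
        else:
            klass = "induced_candidate" if lik_induced > 0 else "inconsistent"
    return DilutionReport(
        variant_id=variant_id,
        presence=list(presence),
        zygosity=list(zygosity) if zygosity is not None else [],
        in_strain_panel=in_strain_panel,
        lik_induced=lik_induced,
        lik_strain=lik_strain,
        classification=klass,
    )


def dilution_report_tsv(reports: Sequence[DilutionReport]) -> str:
    lines = ["variant_id\tpresence\tin_strain_panel\tlik_induced\tlik_strain\tclassification"]
    for r in reports:
        lines.append(
            f"{r.variant_id}\t{','.join(r.presence)}\t{int(r.in_strain_panel)}"
            f"\t{r.lik_induced:.6g}\t{r.lik_strain:.6g}\t{r.classification}"
        )
    return "\n".join(lines) + "\n"


# ------------------------------------------------------------- validation design


@dataclass
class ValidationRegion:
    """An amplicon spanning a candidate indel for wet confirmation."""

    variant_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    wt_size: int
    mut_size: int
    clipped: bool = False
    oversized: bool = False


def design_validation_regions(
    variants: Sequence[VariantCall],
    contig_length: int,
    target_len: int = 350,
    target_len_range: tuple[int, int] = (300, 450),
) -> list[ValidationRegion]:
    """Center a ~300-450 bp amplicon on each variant.

    The wild-type amplicon defaults to ``target_len``; the mutant amplicon is
    wt - del + ins. Regions hitting a contig end are clipped and flagged; a
    variant larger than the maximum range is flagged oversized, never
    dropped.
    """
    lo, hi = target_len_range
    if not (lo <= target_len <= hi):
        raise ParameterError("target_len outside target_len_range")
    out = []
    for v in variants:
        span = v.size if v.vtype == "DEL" else 1
        length = max(target_len, span + 2) if span + 2 > target_len else target_len
        oversized = length > hi
        center = v.pos - 1 + span // 2
        ideal_start = center - length // 2
        clipped = ideal_start < 0 or ideal_start + length > contig_length
        start = max(0, min(ideal_start, contig_length - length))
        start = max(0, start)
        end = min(contig_length, start + length)
        wt = end - start
        if v.vtype == "DEL":
            mut = wt - v.size
        elif v.vtype == "INS":
            mut = wt + v.size
        else:
            mut = wt
        out.append(
            ValidationRegion(
                variant_id=v.truth_id or f"{v.chrom}:{v.pos}:{v.vtype}{v.size}",
                chrom=v.chrom, start=start, end=end,
                wt_size=wt, mut_size=mut, clipped=clipped, oversized=oversized,
            )
        )
    return out


def regions_to_bed(regions: Sequence[ValidationRegion]) -> str:
    lines = []
    for r in regions:
        flags = []
        if r.clipped:
            flags.append("clipped")
        if r.oversized:
            flags.append("oversized")
        name = r.variant_id + ("|" + ",".join(flags) if flags else "")
        lines.append(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t+")
    return "\n".join(lines) + ("\n" if lines else "")


def compare_amplicons(wt_size: int, mut_size: int, resolution: int = 5) -> str:
    """Whether two amplicons can be told apart on a gel that resolves
    ``resolution`` nt differences (deletions >= 5 nt are resolvable on 7%
    polyacrylamide)."""
    if wt_size <= 0 or mut_size <= 0:
        raise ParameterError("amplicon sizes must be positive")
    return "distinguishable" if abs(wt_size - mut_size) >= resolution else "indistinguishable"
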