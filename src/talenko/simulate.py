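"""Synthetic data for the multi-copy knockout pipeline.

This module generates everything the analysis consumes, with full truth
records: TALEN-edited founder genotypes over a paralog family (all-or-nothing
editing with optional mosaicism and paralog fusions showing junction
microhomology), backcross pedigrees with Mendelian X-linked and autosomal
transmission, a panel of fixed strain-difference variants plus optional
induced off-target candidates, noisy variant calls (false positives and
size errors), and gapped short-read alignments against the unedited
reference.

Conventions: coordinates are 0-based half-open internally and 1-based in
VCF/SAM-subset output; all randomness flows from a single seed through
labeled child streams.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._rng import child_rng
from .design import TalenPair, find_pair_sites
from .dna import random_dna
from .errors import NoCutSiteError, ParameterError, PedigreeError
from .family import ParalogFamily
from .variants import AlignmentRecord, VariantCall

# --------------------------------------------------------------------------- types


@dataclass(frozen=True)
class EditEvent:
    """One nuclease-induced lesion in one gene copy.

    position is a 0-based offset within the gene copy. A fusion event joins
    the 5' part of ``gene_label`` (up to ``position``) to the 3' part of
    ``partner_gene`` (from ``partner_position``); its del_len is the junction
    loss relative to an A-then-B reference.
    """

    gene_label: str
    kind: str  # deletion | insertion | delins | fusion
    position: int
    del_len: int = 0
    ins_len: int = 0
    ins_seq: str = ""
    partner_gene: Optional[str] = None
    partner_position: Optional[int] = None
    microhomology_len: int = 0
    edit_id: str = ""

    def __post_init__(self):
        if self.kind not in ("deletion", "insertion", "delins", "fusion"):
            raise ParameterError(f"bad edit kind {self.kind}")
        if self.kind == "deletion" and not (self.del_len > 0 and self.ins_len == 0):
            raise ParameterError("deletion requires del_len > 0 and ins_len == 0")
        if self.kind == "insertion" and not (self.ins_len > 0 and self.del_len == 0):
            raise ParameterError("insertion requires ins_len > 0 and del_len == 0")
        if self.kind == "delins" and not (self.del_len > 0 and self.ins_len > 0):
            raise ParameterError("delins requires del_len > 0 and ins_len > 0")
        if self.kind == "fusion":
            if self.partner_gene is None or self.partner_gene == self.gene_label:
                raise ParameterError("fusion requires a distinct partner gene")
            if self.del_len <= 0:
                raise ParameterError("fusion junction always loses sequence")


Haplotype = dict[str, tuple[EditEvent, ...]]  # gene label -> events (empty tuple = wt)


@dataclass
class Individual:
    """A sexed, generation-tagged member of the pedigree."""

    id: str
    sex: str  # male | female
    generation: int
    x_haplotypes: list[Haplotype]
    background_het_variants: set[str] = field(default_factory=set)
    strain_variants: set[str] = field(default_factory=set)
    mosaic_fraction: dict[str, float] = field(default_factory=dict)
    sire: Optional[str] = None
    dam: Optional[str] = None

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ParameterError(f"bad sex {self.sex}")
        expected = 1 if self.sex == "male" else 2
        if len(self.x_haplotypes) != expected:
            raise PedigreeError(
                f"{self.sex} must carry exactly {expected} X haplotype(s), got {len(self.x_haplotypes)}"
            )

    def edited_genes(self) -> set[str]:
        return {g for hap in self.x_haplotypes for g, evs in hap.items() if evs}

    def is_carrier(self) -> bool:
        return bool(self.edited_genes())


@dataclass
class SimParams:
    """Simulation conditions. The seed is mandatory: no implicit entropy."""

    seed: int
    founder_edit_prob: float = 0.47  # ~9 modified founders of 19 pups
    all_or_nothing: bool = True
    del_len_mean: float = 15.0
    ins_prob: float = 0.1
    ins_len_mean: float = 8.0
    long_ins_len: int = 286
    long_ins_prob: float = 0.02
    fusion_prob: float = 0.2
    microhomology_range: tuple[int, int] = (2, 6)
    mosaic_fraction: float = 1.0  # carrier fraction of founder background edits
    n_strain_variants: int = 200
    n_induced_offtargets: int = 0
    autosome_len: int = 200_000
    read_len: int = 100
    coverage: float = 30.0
    base_error_rate: float = 0.0
    fp_indel_rate: float = 0.0  # spurious indel calls per Mb
    size_error_sd: float = 0.0

    def __post_init__(self):
        for name in ("founder_edit_prob", "ins_prob", "fusion_prob", "long_ins_prob",
                     "mosaic_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.coverage <= 0:
            raise ParameterError("coverage must be > 0")
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        lo, hi = self.microhomology_range
        if not (0 <= lo <= hi):
            raise ParameterError("bad microhomology_range")


# ------------------------------------------------------------------- TALEN editing


def junction_microhomology(a_seq: str, b_seq: str, ca: int, cb: int) -> int:
    """Microhomology spanning a fusion junction at (ca in A, cb in B).

    Defined as m_left + m_right where A[ca-m_left:ca] == B[cb-m_left:cb] and
    A[ca:ca+m_right] == B[cb:cb+m_right]; this value is invariant across all
    breakpoint placements that yield the same fusion sequence.
    """
    ml = 0
    while ml < ca and ml < cb and a_seq[ca - 1 - ml] == b_seq[cb - 1 - ml]:
        ml += 1
    mr = 0
    while ca + mr < len(a_seq) and cb + mr < len(b_seq) and a_seq[ca + mr] == b_seq[cb + mr]:
        mr += 1
    return ml + mr


def _choose_fusion_cut(
    a_seq: str,
    b_seq: str,
    ca: int,
    cb_center: int,
    mh_range: tuple[int, int],
    rng: np.random.Generator,
    window: int = 40,
) -> tuple[int, int]:
    """Pick the partner cut so the junction shows microhomology in range.

    Scans candidate B breakpoints around the nominal cut; among candidates
    with microhomology inside the configured range the longest wins, ties to
    the leftmost. Falls back to the candidate closest to the range.
    """
    lo, hi = mh_range
    best: Optional[tuple[int, int]] = None  # (mh, cb)
    fallback: Optional[tuple[int, int]] = None
    start = max(1, cb_center - window)
    stop = min(len(b_seq) - 1, cb_center + window)
    for cb in range(start, stop + 1):
        mh = junction_microhomology(a_seq, b_seq, ca, cb)
        if lo <= mh <= hi:
            if best is None or mh > best[0]:
                best = (mh, cb)
        dist = min(abs(mh - lo), abs(mh - hi))
        if fallback is None or dist < min(abs(fallback[0] - lo), abs(fallback[0] - hi)):
            fallback = (mh, cb)
    mh, cb = best if best is not None else fallback  # type: ignore[misc]
    return cb, mh


def _cut_offsets(family: ParalogFamily, pair: TalenPair) -> dict[str, int]:
    """Gene-relative cut offsets (spacer midpoint) for every copy with a site."""
    sites = find_pair_sites(pair, family, max_mismatch_per_arm=0)
    cuts: dict[str, int] = {}
    for c in family.copies:
        placements = sites[c.label]
        if placements:
            left_start, spacer, _, _ = placements[0]
            cut = left_start + pair.arm_len + spacer // 2
            cuts[c.label] = cut - c.start
    return cuts


def _small_edit(
    gene: str, cut: int, gene_len: int, params: SimParams, rng: np.random.Generator, edit_id: str
) -> EditEvent:
    del_len = int(rng.geometric(1.0 / params.del_len_mean))
    start = max(0, min(cut - del_len // 2, gene_len - del_len))
    if rng.random() < params.ins_prob:
        if rng.random() < params.long_ins_prob:
            ins_len = params.long_ins_len
        else:
            ins_len = int(rng.geometric(1.0 / params.ins_len_mean))
        return EditEvent(
            gene, "delins", start, del_len=del_len, ins_len=ins_len,
            ins_seq=random_dna(rng, ins_len), edit_id=edit_id,
        )
    return EditEvent(gene, "deletion", start, del_len=del_len, edit_id=edit_id)


def edit_haplotype(
    family: ParalogFamily,
    pair: TalenPair,
    params: SimParams,
    rng: np.random.Generator,
    id_prefix: str = "edit",
) -> Haplotype:
    """Apply nuclease outcomes to one X haplotype: every coding copy with a
    cut site receives one lesion; with probability fusion_prob two adjacent
    cut copies are replaced by a single fusion allele."""
    cuts = _cut_offsets(family, pair)
    coding = [c for c in family.coding_copies() if c.label in cuts]
    if not coding:
        raise NoCutSiteError("TALEN pair has no cut site in any coding copy")
    hap: Haplotype = {c.label: () for c in family.copies}
    counter = itertools.count()
    fusion_members: set[str] = set()
    if len(coding) >= 2 and rng.random() < params.fusion_prob:
        i = int(rng.integers(0, len(coding) - 1))
        a, b = coding[i], coding[i + 1]
        a_seq, b_seq = family.copy_seq(a.label), family.copy_seq(b.label)
        ca = cuts[a.label]
        cb, mh = _choose_fusion_cut(a_seq, b_seq, ca, cuts[b.label], params.microhomology_range, rng)
        del_len = (len(a_seq) - ca) + cb
        hap[a.label] = (
            EditEvent(
                a.label, "fusion", ca, del_len=del_len,
                partner_gene=b.label, partner_position=cb, microhomology_len=mh,
                edit_id=f"{id_prefix}_fusion_{a.label}_{b.label}",
            ),
        )
        fusion_members = {a.label, b.label}
    for c in coding:
        if c.label in fusion_members:
            continue
        hap[c.label] = (
            _small_edit(c.label, cuts[c.label], c.length, params, rng,
                        f"{id_prefix}_{c.label}_{next(counter)}"),
        )
    return hap


def apply_talen_edits(
    family: ParalogFamily,
    pair: TalenPair,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> Haplotype:
    """One founder draw: either every coding copy is edited or none is.

    Under the all-or-nothing model the founder-level Bernoulli draw
    (founder_edit_prob) decides between a fully edited haplotype and an
    entirely wild-type one. With the flag off, each copy is edited
    independently with the same probability.
    """
    if rng is None:
        rng = child_rng(params.seed, "talen_edits")
    if params.all_or_nothing:
        if rng.random() < params.founder_edit_prob:
            return edit_haplotype(family, pair, params, rng)
        return {c.label: () for c in family.copies}
    cuts = _cut_offsets(family, pair)
    if not any(c.label in cuts for c in family.coding_copies()):
        raise NoCutSiteError("TALEN pair has no cut site in any coding copy")
    hap: Haplotype = {c.label: () for c in family.copies}
    for c in family.coding_copies():
        if c.label in cuts and rng.random() < params.founder_edit_prob:
            hap[c.label] = (_small_edit(c.label, cuts[c.label], c.length, params, rng,
                                        f"ind_{c.label}"),)
    return hap


# ----------------------------------------------------------------- variant panels


@dataclass(frozen=True)
class VariantDef:
    """Truth definition of a background variant on the synthetic autosome."""

    variant_id: str
    chrom: str
    pos: int  # 1-based, VCF anchored
    ref: str
    alt: str
    vtype: str
    size: int
    origin: str  # strain | induced


@dataclass
class VariantPanel:
    """Strain-difference panel plus optional induced off-target candidates."""

    autosome_name: str
    autosome_seq: str
    strain: list[VariantDef]
    induced: list[VariantDef]

    def by_id(self) -> dict[str, VariantDef]:
        return {v.variant_id: v for v in self.strain + self.induced}


def make_variant_panel(params: SimParams, autosome_name: str = "chrA_sim") -> VariantPanel:
    """Draw non-overlapping strain and induced variants on a random autosome.

    Strain variants model fixed differences versus the reference (half SNVs,
    half small deletions); induced candidates are heterozygous deletions, the
    lesion type a nuclease leaves behind.
    """
    rng = child_rng(params.seed, "variant_panel")
    seq = random_dna(rng, params.autosome_len)
    n_total = params.n_strain_variants + params.n_induced_offtargets
    if n_total == 0:
        return VariantPanel(autosome_name, seq, [], [])
    # spaced, non-overlapping 1-based anchor positions (keep 50 bp apart)
    positions = rng.choice(
        np.arange(100, params.autosome_len - 400, 50), size=n_total, replace=False
    )
    positions.sort()
    idx = rng.permutation(n_total)
    strain, induced = [], []
    for k, pos in enumerate(positions):
        pos = int(pos)
        is_strain = idx[k] < params.n_strain_variants
        anchor = seq[pos - 1]
        if is_strain and k % 2 == 0:
            # SNV
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[seq[pos]]
            v = VariantDef(f"strain_snv_{k}", autosome_name, pos + 1, seq[pos], alt, "SNV", 0, "strain")
            strain.append(v)
            continue
        size = int(rng.integers(1, 21))
        ref = anchor + seq[pos:pos + size]
        v = VariantDef(
            f"{'strain' if is_strain else 'induced'}_del_{k}", autosome_name, pos, ref, anchor,
            "DEL", size, "strain" if is_strain else "induced",
        )
        (strain if is_strain else induced).append(v)
    return VariantPanel(autosome_name, seq, strain, induced)


# ----------------------------------------------------------------------- pedigree


def make_founder(
    family: ParalogFamily,
    pair: TalenPair,
    params: SimParams,
    panel: VariantPanel,
    rng: np.random.Generator,
    founder_id: str = "G0_founder",
    sex: str = "female",
    force_edited: bool = False,
) -> Individual:
    """Draw a G0 founder under the all-or-nothing editing model.

    An edited founder has every coding copy mutated on every X haplotype
    (each haplotype drawing its own unique lesions, as observed in modified
    female founders) and carries all induced off-target candidates as
    heterozygous background variants at the configured mosaic fraction.
    """
    edited = force_edited or (rng.random() < params.founder_edit_prob)
    n_hap = 1 if sex == "male" else 2
    if edited:
        haps = [edit_haplotype(family, pair, params, rng, id_prefix=f"{founder_id}_h{i}")
                for i in range(n_hap)]
        background = {v.variant_id for v in panel.induced}
    else:
        haps = [{c.label: () for c in family.copies} for _ in range(n_hap)]
        background = set()
    mosaic = {vid: params.mosaic_fraction for vid in background if params.mosaic_fraction < 1.0}
    return Individual(
        id=founder_id, sex=sex, generation=0, x_haplotypes=haps,
        background_het_variants=background,
        strain_variants={v.variant_id for v in panel.strain},
        mosaic_fraction=mosaic,
    )


def wildtype_individual(
    family: ParalogFamily, panel: VariantPanel, id: str, sex: str, generation: int
) -> Individual:
    wt_hap: Haplotype = {c.label: () for c in family.copies}
    n_hap = 1 if sex == "male" else 2
    return Individual(
        id=id, sex=sex, generation=generation,
        x_haplotypes=[dict(wt_hap) for _ in range(n_hap)],
        strain_variants={v.variant_id for v in panel.strain},
    )


def mate(
    mother: Individual,
    father: Individual,
    n_offspring: int,
    rng: np.random.Generator,
    generation: Optional[int] = None,
    id_prefix: str = "ind",
    force_sex: Optional[str] = None,
) -> list[Individual]:
    """Mendelian cross.

    The mother transmits one of her two X haplotypes uniformly (the whole
    gene family travels as one linked block); the father transmits his X to
    daughters and Y to sons. Each autosomal heterozygous variant passes with
    probability 0.5 per meiosis (scaled by its mosaic carrier fraction, which
    resets to 1 in carriers); fixed strain variants pass to every offspring.
    """
    if mother.sex != "female":
        raise PedigreeError("mother must be female")
    if father.sex != "male":
        raise PedigreeError("father must be male")
    if generation is None:
        generation = max(mother.generation, father.generation) + 1
    offspring = []
    for i in range(n_offspring):
        sex = force_sex or ("female" if rng.random() < 0.5 else "male")
        maternal_x = mother.x_haplotypes[int(rng.integers(0, 2))]
        haps = [dict(maternal_x)]
        if sex == "female":
            haps.append(dict(father.x_haplotypes[0]))
        background: set[str] = set()
        mosaic: dict[str, float] = {}
        for parent in (mother, father):
            for vid in parent.background_het_variants:
                p = 0.5 * parent.mosaic_fraction.get(vid, 1.0)
                if rng.random() < p:
                    background.add(vid)  # transmitted edits become constitutive
        offspring.append(
            Individual(
                id=f"{id_prefix}_{generation}_{i}", sex=sex, generation=generation,
                x_haplotypes=haps, background_het_variants=background,
                strain_variants=mother.strain_variants | father.strain_variants,
                mosaic_fraction=mosaic, sire=father.id, dam=mother.id,
            )
        )
    return offspring


def simulate_pedigree(
    founders: Sequence[Individual],
    scheme: str,
    n_generations: int,
    params: SimParams,
    family: ParalogFamily,
    panel: VariantPanel,
    rng: Optional[np.random.Generator] = None,
    litter_size: int = 8,
    max_attempts: int = 200,
) -> list[Individual]:
    """Backcross line: carrier females crossed to wild-type males.

    Each generation produces a litter; a carrier female continues the line
    and a carrier male is retained as that generation's sequenced animal.
    Returns all individuals, founders first, generation-ordered.
    """
    if scheme not in ("backcross_female_mut", "founder_cross_then_backcross"):
        raise PedigreeError(f"unknown scheme {scheme!r}")
    if n_generations < 1:
        raise PedigreeError("n_generations must be >= 1")
    if rng is None:
        rng = child_rng(params.seed, "pedigree")
    if scheme == "founder_cross_then_backcross":
        mothers = [f for f in founders if f.sex == "female"]
        fathers = [f for f in founders if f.sex == "male"]
        if not mothers or not fathers:
            raise PedigreeError("founder cross needs one female and one male founder")
        mother, father = mothers[0], fathers[0]
    else:
        mothers = [f for f in founders if f.sex == "female"]
        if not mothers:
            raise PedigreeError("backcross from a female line needs a female founder")
        mother = mothers[0]
        father = wildtype_individual(family, panel, "wt_sire_0", "male", mother.generation)
    if not mother.is_carrier():
        raise PedigreeError("line founder carries no edit")

    everyone: list[Individual] = list(founders)
    for g in range(1, n_generations + 1):
        next_mother = None
        litter: list[Individual] = []
        for _ in range(max_attempts):
            litter = mate(mother, father, litter_size, rng, generation=g, id_prefix=f"line_g{g}")
            carrier_females = [o for o in litter if o.sex == "female" and o.is_carrier()]
            carrier_males = [o for o in litter if o.sex == "male" and o.is_carrier()]
            if carrier_females and carrier_males:
                next_mother = carrier_females[0]
                break
        if next_mother is None:
            raise PedigreeError(f"no carrier offspring after {max_attempts} litters at G{g}")
        everyone.extend(litter)
        mother = next_mother
        father = wildtype_individual(family, panel, f"wt_sire_{g}", "male", g)
    return everyone


def sequenced_male(individuals: Sequence[Individual], generation: int) -> Individual:
    """The generation's exome-sequenced animal: first carrier male."""
    for ind in individuals:
        if ind.generation == generation and ind.sex == "male" and ind.is_carrier():
            return ind
    raise PedigreeError(f"no carrier male in generation {generation}")


# ------------------------------------------------------------------ variant calls


def _edit_to_call(
    family: ParalogFamily, event: EditEvent, genotype: str, sample: str,
    generation: Optional[int], params: SimParams, rng: np.random.Generator,
) -> Optional[VariantCall]:
    """Render one X-linked edit as a (possibly size-perturbed) variant call."""
    gene = family.copy(event.gene_label)
    seq = family.sequence
    if event.kind == "fusion":
        partner = family.copy(event.partner_gene)
        start = gene.start + event.position  # first lost base, 0-based
        end = partner.start + event.partner_position
        size = end - start
        pos = start  # anchored base before the loss, 1-based == start 0-based + 1 - 1
        ref = seq[start - 1:end]
        alt = seq[start - 1]
        vtype, true_size = "DEL", size
    elif event.kind in ("deletion", "delins"):
        start = gene.start + event.position
        true_size = event.del_len
        pos = start
        ref = seq[start - 1:start + true_size]
        alt = seq[start - 1] + event.ins_seq
        vtype = "DEL" if event.del_len >= event.ins_len else "INS"
        if event.kind == "delins":
            # report as the net size change, the way a small-indel caller sees it
            net = event.del_len - event.ins_len
            if net == 0:
                return None
            vtype = "DEL" if net > 0 else "INS"
            true_size = abs(net)
            ref, alt = "N", "N"  # replaced sequence is not a literal ref/alt pair
    else:  # insertion
        start = gene.start + event.position
        true_size = event.ins_len
        pos = start
        ref = seq[start - 1]
        alt = seq[start - 1] + event.ins_seq
        vtype = "INS"
    reported = _perturb_size(true_size, params, rng)
    if reported != true_size:
        ref, alt = "N", "N"  # sequence no longer literal once size is mispredicted
    return VariantCall(
        chrom=family.chromosome_name, pos=pos, ref=ref, alt=alt, vtype=vtype,
        size=reported, support=int(params.coverage),
        quality=min(10.0 * params.coverage, 250.0),
        sample=sample, generation=generation, genotype_code=genotype,
        truth_id=event.edit_id or f"{event.gene_label}@{event.position}",
    )


def _perturb_size(true_size: int, params: SimParams, rng: np.random.Generator) -> int:
    """Symmetric rounded-normal size error, truncated so the sign survives."""
    if params.size_error_sd <= 0 or true_size <= 1:
        return true_size
    err = int(np.rint(rng.normal(0.0, params.size_error_sd)))
    err = max(-(true_size - 1), min(true_size - 1, err))
    return true_size + err


def simulate_variant_calls(
    individual: Individual,
    family: ParalogFamily,
    panel: VariantPanel,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> list[VariantCall]:
    """Emulated caller output for one individual.

    True X-linked edits genotype as 1/1 (hemizygous male or homozygous
    female), 0/1 (one of two haplotypes) or 1/2 (two distinct lesions in one
    gene); background heterozygous variants as 0/1; fixed strain variants as
    1/1. Sizes are perturbed by the configured error model and spurious indel
    calls are injected at fp_indel_rate per Mb with random zygosity. Every
    call carries a quality score and true calls keep their truth id.
    """
    if rng is None:
        rng = child_rng(params.seed, f"calls_{individual.id}")
    calls: list[VariantCall] = []
    defs = panel.by_id()
    # X-linked edits
    for gene in family.copies:
        alleles = [hap.get(gene.label, ()) for hap in individual.x_haplotypes]
        distinct = [evs for evs in {tuple(e) for e in alleles} if evs]
        if not distinct:
            continue
        if len(individual.x_haplotypes) == 1:
            genotype = "1/1"  # hemizygous
            for evs in distinct:
                for e in evs:
                    c = _edit_to_call(family, e, genotype, individual.id,
                                      individual.generation, params, rng)
                    if c:
                        calls.append(c)
        else:
            if len(distinct) == 2:
                genotype = "1/2"
            elif alleles[0] == alleles[1]:
                genotype = "1/1"
            else:
                genotype = "0/1"
            for evs in distinct:
                for e in evs:
                    c = _edit_to_call(family, e, genotype, individual.id,
                                      individual.generation, params, rng)
                    if c:
                        calls.append(c)
    # autosomal background + strain variants
    for vid in sorted(individual.background_het_variants):
        v = defs[vid]
        size = _perturb_size(v.size, params, rng) if v.vtype != "SNV" else 0
        ref, alt = (v.ref, v.alt) if size == v.size else ("N", "N")
        calls.append(VariantCall(
            chrom=v.chrom, pos=v.pos, ref=ref, alt=alt, vtype=v.vtype, size=size,
            support=int(params.coverage / 2), quality=min(10.0 * params.coverage, 250.0),
            sample=individual.id, generation=individual.generation,
            genotype_code="0/1", truth_id=vid,
        ))
    for vid in sorted(individual.strain_variants):
        v = defs[vid]
        size = _perturb_size(v.size, params, rng) if v.vtype != "SNV" else 0
        ref, alt = (v.ref, v.alt) if size == v.size else ("N", "N")
        calls.append(VariantCall(
            chrom=v.chrom, pos=v.pos, ref=ref, alt=alt, vtype=v.vtype, size=size,
            support=int(params.coverage), quality=min(10.0 * params.coverage, 250.0),
            sample=individual.id, generation=individual.generation,
            genotype_code="1/1", truth_id=vid,
        ))
    # spurious calls
    genome_mb = (len(family.sequence) + len(panel.autosome_seq)) / 1e6
    n_fp = int(rng.poisson(params.fp_indel_rate * genome_mb))
    for i in range(n_fp):
        on_autosome = rng.random() < len(panel.autosome_seq) / (
            len(panel.autosome_seq) + len(family.sequence)
        )
        chrom = panel.autosome_name if on_autosome else family.chromosome_name
        limit = len(panel.autosome_seq) if on_autosome else len(family.sequence)
        pos = int(rng.integers(100, max(101, limit - 100)))
        size = int(rng.geometric(0.2))
        calls.append(VariantCall(
            chrom=chrom, pos=pos, ref="N", alt="N", vtype="DEL", size=size,
            support=int(rng.integers(1, 6)), quality=float(rng.uniform(0, 250)),
            sample=individual.id, generation=individual.generation,
            genotype_code="0/1" if rng.random() < 0.5 else "1/1", truth_id=None,
        ))
    calls.sort(key=lambda c: (c.chrom, c.pos, c.vtype, c.size))
    return calls


# -------------------------------------------------------------------------- reads


def haplotype_edit_layout(family: ParalogFamily, hap: Haplotype) -> list[tuple[int, int, str]]:
    """Absolute-coordinate lesion list (ref_start 0-based, del_len, ins_seq)."""
    out = []
    for gene in family.copies:
        for e in hap.get(gene.label, ()):
            if e.kind == "fusion":
                start = family.copy(e.gene_label).start + e.position
                end = family.copy(e.partner_gene).start + e.partner_position
                out.append((start, end - start, ""))
            else:
                start = family.copy(e.gene_label).start + e.position
                out.append((start, e.del_len, e.ins_seq))
    out.sort()
    return out


def simulate_reads(
    reference: str,
    edits: Sequence[tuple[int, int, str]],
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
    chrom: str = "chrX_sim",
    min_anchor: int = 5,
) -> list[AlignmentRecord]:
    """Uniform-coverage gapped reads from an edited haplotype.

    ``edits`` are (ref_start 0-based, del_len, ins_seq) lesions, sorted and
    non-overlapping. Reads are drawn uniformly from the edited sequence and
    reported against the UNEDITED reference: deletions inside a read appear
    as D ops, insertions as I ops; lesion overhang with less than
    ``min_anchor`` aligned bases at a read edge is soft-clipped. Substitution
    errors occur per base at base_error_rate. Deterministic per seed; records
    are sorted by reference position.
    """
    if params.read_len <= 0:
        raise ParameterError("read_len must be > 0")
    if rng is None:
        rng = child_rng(params.seed, "reads")
    # build block map: list of (hap_start, length, ref_start or None-for-insert)
    blocks: list[tuple[int, int, Optional[int]]] = []
    hap_parts: list[str] = []
    hap_pos = 0
    ref_pos = 0
    for start, dlen, ins in sorted(edits):
        if start < ref_pos:
            raise ParameterError("edits overlap or are unsorted")
        seg = reference[ref_pos:start]
        if seg:
            blocks.append((hap_pos, len(seg), ref_pos))
            hap_parts.append(seg)
            hap_pos += len(seg)
        ref_pos = start + dlen
        if ins:
            blocks.append((hap_pos, len(ins), None))
            hap_parts.append(ins)
            hap_pos += len(ins)
    seg = reference[ref_pos:]
    if seg:
        blocks.append((hap_pos, len(seg), ref_pos))
        hap_parts.append(seg)
        hap_pos += len(seg)
    haplotype = "".join(hap_parts)
    if params.read_len >= len(haplotype):
        raise ParameterError("read_len must be smaller than the haplotype")

    n_reads = int(round(params.coverage * len(haplotype) / params.read_len))
    starts = np.sort(rng.integers(0, len(haplotype) - params.read_len + 1, size=n_reads))
    records: list[AlignmentRecord] = []
    for i, s in enumerate(starts):
        s = int(s)
        e = s + params.read_len
        seq = haplotype[s:e]
        if params.base_error_rate > 0:
            seq = _add_errors(seq, params.base_error_rate, rng)
        # per-read alignment pieces: ("M", take, ref_start) | ("I", take) | ("D", gap)
        pieces: list[tuple] = []
        prev_ref_end = None
        for b_start, b_len, b_ref in blocks:
            b_end = b_start + b_len
            if b_end <= s or b_start >= e:
                continue
            lo, hi = max(s, b_start), min(e, b_end)
            take = hi - lo
            if b_ref is None:
                pieces.append(("I", take))
            else:
                seg_ref_start = b_ref + (lo - b_start)
                if prev_ref_end is not None and seg_ref_start > prev_ref_end:
                    pieces.append(("D", seg_ref_start - prev_ref_end))
                pieces.append(("M", take, seg_ref_start))
                prev_ref_end = seg_ref_start + take
        rec = _pieces_to_record(pieces, seq, min_anchor, chrom, f"r{i:06d}",
                                0 if rng.random() < 0.5 else 16)
        if rec is not None:
            records.append(rec)
    records.sort(key=lambda r: r.pos)
    return records


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = list(seq)
    for j in np.nonzero(rng.random(len(arr)) < rate)[0]:
        b = arr[j]
        alts = [x for x in "ACGT" if x != b]
        arr[j] = alts[int(rng.integers(0, 3))]
    return "".join(arr)


def _pieces_to_record(
    pieces: list[tuple], seq: str, min_anchor: int, chrom: str, qname: str, flag: int
) -> Optional[AlignmentRecord]:
    """Turn alignment pieces into a SAM-subset record.

    Edge M blocks shorter than ``min_anchor`` (and any I pieces outside the
    aligned core) are soft-clipped; D pieces at the edges are dropped. Reads
    with no aligned core are discarded.
    """
    m_lens = [(idx, p[1]) for idx, p in enumerate(pieces) if p[0] == "M"]
    if not m_lens:
        return None
    # choose the aligned core: first/last M blocks that satisfy the anchor, or
    # the largest M block if none does
    good = [idx for idx, ln in m_lens if ln >= min_anchor]
    if good:
        first, last = good[0], good[-1]
    else:
        first = last = max(m_lens, key=lambda t: t[1])[0]
    lead_clip = sum(p[1] for p in pieces[:first] if p[0] in ("M", "I"))
    tail_clip = sum(p[1] for p in pieces[last + 1:] if p[0] in ("M", "I"))
    core = pieces[first:last + 1]
    pos1 = core[0][2] + 1  # 1-based
    ops: list[tuple[int, str]] = []
    if lead_clip:
        ops.append((lead_clip, "S"))
    for p in core:
        if p[0] == "M":
            ops.append((p[1], "M"))
        elif p[0] == "I":
            ops.append((p[1], "I"))
        else:
            ops.append((p[1], "D"))
    if tail_clip:
        ops.append((tail_clip, "S"))
    merged: list[tuple[int, str]] = []
    for n, op in ops:
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    cigar = "".join(f"{n}{op}" for n, op in merged)
    return AlignmentRecord(qname, flag, chrom, pos1, cigar, seq)


# --------------------------------------------------------------------- NM4 helper


def nm4_genotype(family: ParalogFamily, sizes: Sequence[int] = (5, 10, 64)) -> Haplotype:
    """The sequenced knockout line's X haplotype: one engineered deletion per
    coding copy (5, 10 and 64 bp by default), centered in each copy."""
    coding = family.coding_copies()
    if len(sizes) != len(coding):
        raise ParameterError("one deletion size per coding copy required")
    hap: Haplotype = {c.label: () for c in family.copies}
    for c, size in zip(coding, sizes):
        pos = c.length // 2 - int(size) // 2
        hap[c.label] = (EditEvent(c.label, "deletion", pos, del_len=int(size),
                                  edit_id=f"nm4_{c.label}_del{size}"),)
    return hap
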