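"""End-to-end orchestration: simulate -> design -> scan -> call -> dilute.

A single validated configuration drives every stage; all randomness flows
from its seed through labeled child streams, and a manifest records the
config hash so reruns are byte-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from ._rng import child_rng
from .design import classify_specificity, enumerate_pairs, pair_report_tsv
from .dilution import (
    StrainPanel,
    design_validation_regions,
    dilution_report_tsv,
    dilution_test,
    intersect_generations,
    regions_to_bed,
    strain_filter,
    zygosity_partition,
)
from .errors import ConfigError, PedigreeError, StageError
from .family import make_paralog_family
from .io import write_fasta, write_pedigree_tsv, write_sam_subset, write_vcf
from .offtarget import hits_to_bed, scan_for_pair
from .simulate import (
    SimParams,
    VariantPanel,
    haplotype_edit_layout,
    make_founder,
    make_variant_panel,
    sequenced_male,
    simulate_pedigree,
    simulate_reads,
    simulate_variant_calls,
)
from .variants import VariantCall, assign_genotype, call_indels, quality_filter

# ------------------------------------------------------------------------ config


def _check_keys(block: dict, allowed: set[str], name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {name}: {sorted(unknown)}")


@dataclass
class DesignConfig:
    arm_len: int = 15
    spacer_min: int = 12
    spacer_max: int = 20
    require_5prime_T: bool = True
    max_mismatch_per_arm: int = 3


@dataclass
class ScanConfig:
    min_perfect_match: int = 8
    max_product: int = 100


@dataclass
class CallConfig:
    min_support: int = 3
    merge_tolerance: int = 3
    min_quality: float = 100.0


@dataclass
class DilutionConfig:
    retention: float = 0.5
    generations: int = 3


@dataclass
class FamilyConfig:
    n_copies: int = 3
    copy_len: int = 500
    min_identity: float = 0.92
    flank_len: int = 500
    with_pseudogene: bool = True


@dataclass
class RunConfig:
    seed: int
    out_dir: str = "talenko_out"
    family: FamilyConfig = field(default_factory=FamilyConfig)
    sim: SimParams = None  # type: ignore[assignment]
    design: DesignConfig = field(default_factory=DesignConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    call: CallConfig = field(default_factory=CallConfig)
    dilution: DilutionConfig = field(default_factory=DilutionConfig)

    def __post_init__(self):
        if self.sim is None:
            self.sim = SimParams(seed=self.seed)
        if self.dilution.generations < 2:
            raise ConfigError("dilution needs at least 2 generations")
        if self.design.spacer_min > self.design.spacer_max:
            raise ConfigError("spacer_min > spacer_max")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        _check_keys(d, {"seed", "out_dir", "family", "sim", "design", "scan", "call", "dilution"},
                    "config")
        if "seed" not in d:
            raise ConfigError("config requires a seed")
        kwargs: dict[str, Any] = {"seed": int(d["seed"])}
        if "out_dir" in d:
            kwargs["out_dir"] = str(d["out_dir"])
        specs = {
            "family": FamilyConfig, "design": DesignConfig, "scan": ScanConfig,
            "call": CallConfig, "dilution": DilutionConfig,
        }
        for key, klass in specs.items():
            block = d.get(key, {})
            allowed = {f.name for f in dataclasses.fields(klass)}
            _check_keys(block, allowed, key)
            try:
                kwargs[key] = klass(**block)
            except TypeError as e:
                raise ConfigError(f"bad {key} block: {e}") from e
        sim_block = dict(d.get("sim", {}))
        allowed = {f.name for f in dataclasses.fields(SimParams)}
        _check_keys(sim_block, allowed, "sim")
        sim_block.setdefault("seed", kwargs["seed"])
        if "microhomology_range" in sim_block:
            sim_block["microhomology_range"] = tuple(sim_block["microhomology_range"])
        kwargs["sim"] = SimParams(**sim_block)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(d)

    def to_canonical_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return o

        return json.dumps(enc_config(self), sort_keys=True, default=enc)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()


def enc_config(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d.pop("out_dir", None)  # paths are not part of the scientific configuration
    return d


# --------------------------------------------------------------------- pipeline


@dataclass
class RunReport:
    config_hash: str
    seed: int
    out_dir: str
    stage_summaries: dict[str, Any]
    candidate_variants: list[VariantCall]
    evaluation: dict[str, Any]


def run_end_to_end(config: RunConfig) -> RunReport:
    """Execute every stage and write machine-readable artifacts.

    Raises StageError (carrying the stage name) on any stage failure. Rerun
    with the same config reproduces byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries: dict[str, Any] = {}
    params = config.sim

    # ---- simulate: genomes ----
    stage = "simulate"
    try:
        fam = make_paralog_family(
            seed=params.seed,
            n_copies=config.family.n_copies,
            copy_len=config.family.copy_len,
            min_identity=config.family.min_identity,
            flank_len=config.family.flank_len,
            with_pseudogene=config.family.with_pseudogene,
        )
        panel = make_variant_panel(params)
        (out / "genome.fasta").write_text(
            write_fasta({fam.chromosome_name: fam.sequence, panel.autosome_name: panel.autosome_seq})
        )
        summaries[stage] = {
            "chromosome_len": len(fam.sequence),
            "autosome_len": len(panel.autosome_seq),
            "n_strain_variants": len(panel.strain),
            "n_induced_offtargets": len(panel.induced),
            "min_pairwise_identity_coding": float(
                min(
                    fam.identity_matrix.loc[a.label, b.label]
                    for i, a in enumerate(fam.coding_copies())
                    for j, b in enumerate(fam.coding_copies())
                    if i < j
                )
            ) if config.family.n_copies > 1 else 1.0,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ---- design ----
    stage = "design"
    try:
        pairs = enumerate_pairs(
            fam, arm_len=config.design.arm_len,
            spacer_range=(config.design.spacer_min, config.design.spacer_max),
            require_5prime_T=config.design.require_5prime_T,
        )
        chosen = None
        chosen_report = None
        reports = []
        for p in pairs:
            rep = classify_specificity(p, fam, max_mismatch_per_arm=0)
            reports.append(rep)
            if chosen is None and rep.klass == "family_wide":
                chosen, chosen_report = p, rep
        if chosen is None:
            for p, rep0 in zip(pairs, reports):
                rep = classify_specificity(p, fam, config.design.max_mismatch_per_arm)
                if rep.klass == "family_wide":
                    chosen, chosen_report = p, rep
                    break
        if chosen is None:
            raise StageError(stage, "no family-wide TALEN pair found")
        (out / "talen_pairs.tsv").write_text(pair_report_tsv(pairs, reports))
        summaries[stage] = {
            "n_candidate_pairs": len(pairs),
            "n_family_wide": sum(r.klass == "family_wide" for r in reports),
            "chosen_left": chosen.left_seq,
            "chosen_right": chosen.right_seq,
            "chosen_class": chosen_report.klass,
        }
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ---- scan ----
    stage = "scan"
    try:
        genome = {fam.chromosome_name: fam.sequence, panel.autosome_name: panel.autosome_seq}
        hits = scan_for_pair(
            genome, chosen,
            min_perfect_match=config.scan.min_perfect_match,
            max_product=config.scan.max_product,
        )
        on_target = [
            h for h in hits
            if h.chrom == fam.chromosome_name
            and any(c.start <= h.left_start < c.end for c in fam.copies)
        ]
        (out / "paired_hits.bed").write_text(hits_to_bed(hits))
        summaries[stage] = {
            "n_hits": len(hits),
            "n_on_target": len(on_target),
            "n_off_target": len(hits) - len(on_target),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ---- simulate: founders, pedigree, reads, calls ----
    stage = "pedigree"
    try:
        rng = child_rng(params.seed, "pipeline_founder")
        founder = None
        for _ in range(1000):
            cand = make_founder(fam, chosen, params, panel, rng, founder_id="G0_founder",
                                sex="female")
            if cand.is_carrier():
                founder = cand
                break
        if founder is None:
            raise StageError(stage, "no edited founder in 1000 draws")
        individuals = simulate_pedigree(
            [founder], "backcross_female_mut", config.dilution.generations, params, fam, panel,
        )
        (out / "pedigree.tsv").write_text(write_pedigree_tsv(individuals))
        summaries[stage] = {
            "n_individuals": len(individuals),
            "generations": config.dilution.generations,
        }
    except (StageError, PedigreeError) as e:
        if isinstance(e, StageError):
            raise
        raise StageError(stage, str(e)) from e
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    stage = "call"
    try:
        calls_by_gen: dict[int, list[VariantCall]] = {}
        for g in range(1, config.dilution.generations + 1):
            male = sequenced_male(individuals, g)
            edits = haplotype_edit_layout(fam, male.x_haplotypes[0])
            reads = simulate_reads(
                fam.sequence, edits, params,
                rng=child_rng(params.seed, f"reads_g{g}"), chrom=fam.chromosome_name,
            )
            (out / f"alignments_g{g}.tsv").write_text(write_sam_subset(reads))
            x_calls = call_indels(
                reads, min_support=config.call.min_support,
                merge_tolerance=config.call.merge_tolerance,
                reference=fam.sequence, chrom=fam.chromosome_name,
                sample=male.id, generation=g,
            )
            x_calls = assign_genotype(x_calls)
            auto_calls = [
                c for c in simulate_variant_calls(
                    male, fam, panel, params, rng=child_rng(params.seed, f"calls_g{g}")
                )
                if c.chrom == panel.autosome_name
            ]
            merged = quality_filter(x_calls + auto_calls, config.call.min_quality)
            merged.sort(key=lambda c: (c.chrom, c.pos, c.vtype, c.size))
            calls_by_gen[g] = merged
            (out / f"calls_g{g}.vcf").write_text(
                write_vcf(merged, male.id,
                          contigs={fam.chromosome_name: len(fam.sequence),
                                   panel.autosome_name: len(panel.autosome_seq)})
            )
        summaries[stage] = {f"G{g}": len(v) for g, v in calls_by_gen.items()}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ---- dilute ----
    stage = "dilute"
    try:
        strain_panel = StrainPanel.from_variant_defs(panel.strain)
        retained_by_gen: dict[int, list[VariantCall]] = {}
        removed_counts = {}
        for g, calls in calls_by_gen.items():
            retained, removed = strain_filter(calls, strain_panel)
            retained_by_gen[g] = retained
            removed_counts[g] = len(removed)
        zyg = {g: zygosity_partition(v) for g, v in retained_by_gen.items()}
        common = intersect_generations(retained_by_gen)
        gens = sorted(retained_by_gen)
        reports = []
        candidates: list[VariantCall] = []
        for anchor in common:
            presence = ["present"] * len(gens)
            rep = dilution_test(
                anchor.truth_id or f"{anchor.chrom}:{anchor.pos}:{anchor.vtype}{anchor.size}",
                presence, in_strain_panel=anchor in strain_panel,
                retention=config.dilution.retention,
            )
            reports.append(rep)
            if rep.classification in ("needs_validation", "induced_candidate"):
                candidates.append(anchor)
        # exclude the engineered on-target lesions from the off-target candidate list
        candidates = [c for c in candidates if c.chrom != fam.chromosome_name or not any(
            g.start <= c.pos - 1 < g.end for g in fam.copies
        )]
        (out / "dilution_report.tsv").write_text(dilution_report_tsv(reports))
        regions = design_validation_regions(
            candidates, contig_length=len(panel.autosome_seq)
        )
        (out / "validation_regions.bed").write_text(regions_to_bed(regions))
        summaries[stage] = {
            "removed_by_strain_filter": removed_counts,
            "het_totals": {g: zyg[g]["het_total"] for g in gens},
            "n_common": len(common),
            "n_candidates": len(candidates),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ---- evaluate ----
    stage = "evaluate"
    try:
        truth_ids = {v.variant_id for v in panel.induced}
        induced_in_candidates = [
            c.truth_id for c in candidates if c.truth_id and c.truth_id in truth_ids
        ]
        evaluation = {
            "n_truth_induced": len(truth_ids),
            "n_candidates": len(candidates),
            "induced_truth_in_candidates": induced_in_candidates,
            "candidate_origins": {
                "strain_panel_omission_or_strain": sum(
                    1 for c in candidates if c.truth_id and c.truth_id not in truth_ids
                ),
                "caller_artifact": sum(1 for c in candidates if not c.truth_id),
                "induced": len(induced_in_candidates),
            },
        }
        summaries[stage] = evaluation
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": summaries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return RunReport(
        config_hash=manifest["config_hash"], seed=config.seed, out_dir=str(out),
        stage_summaries=summaries, candidate_variants=candidates, evaluation=evaluation,
    )


# ------------------------------------------------------------------- evaluation


def evaluate_against_truth(
    called: list[VariantCall], truth: list[dict], pos_tolerance: int = 1
) -> dict[str, Any]:
    """Match calls to truth records {chrom, pos, vtype, size} by position.

    Returns TP/FP/FN counts and per-TP absolute size errors.
    """
    if truth is None:
        raise ConfigError("missing truth records")
    unmatched = list(called)
    tp = 0
    size_errors: list[int] = []
    fn = 0
    for t in truth:
        hit = None
        for c in unmatched:
            if c.chrom == t["chrom"] and c.vtype == t["vtype"] and abs(c.pos - t["pos"]) <= pos_tolerance:
                hit = c
                break
        if hit is None:
            fn += 1
        else:
            tp += 1
            size_errors.append(abs(hit.size - t["size"]))
            unmatched.remove(hit)
    return {"TP": tp, "FP": len(unmatched), "FN": fn, "size_errors": size_errors}
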