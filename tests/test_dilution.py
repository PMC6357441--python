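"""Strain filtering, zygosity partition, generation intersection, dilution."""

import itertools

import pytest

from talenko import (
    StrainPanel,
    compare_amplicons,
    design_validation_regions,
    dilution_test,
    intersect_generations,
    strain_filter,
    zygosity_partition,
)
from talenko.errors import CoordinateSystemError, ParameterError
from talenko.variants import VariantCall


def vc(chrom="chr1", pos=100, ref="AT", alt="A", vtype="DEL", size=1, gt="0/1", tid=None):
    return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt, vtype=vtype, size=size,
                       genotype_code=gt, truth_id=tid)


class TestStrainFilter:
    def test_empty_panel_retains_everything(self):
        calls = [vc(pos=p) for p in (10, 20, 30)]
        retained, removed = strain_filter(calls, StrainPanel())
        assert retained == calls and removed == []

    def test_full_panel_removes_everything(self):
        calls = [vc(pos=p) for p in (10, 20, 30)]
        panel = StrainPanel()
        for c in calls:
            panel.add(c.chrom, c.pos, c.ref, c.alt, c.vtype, c.size)
        retained, removed = strain_filter(calls, panel)
        assert retained == [] and removed == calls

    def test_deletion_position_slack(self):
        panel = StrainPanel()
        panel.add("chr1", 100, "AT", "A", "DEL", 1)
        near = vc(pos=101, ref="TA", alt="T")  # +-1, same size
        far = vc(pos=103)
        other_size = vc(pos=100, ref="ATT", alt="A", size=2)
        retained, removed = strain_filter([near, far, other_size], panel)
        assert removed == [near]
        assert retained == [far, other_size]

    def test_partition_is_exact(self):
        calls = [vc(pos=p, tid=f"v{p}") for p in range(0, 200, 10)]
        panel = StrainPanel()
        for c in calls[::2]:
            panel.add(c.chrom, c.pos, c.ref, c.alt, c.vtype, c.size)
        retained, removed = strain_filter(calls, panel)
        assert sorted(c.pos for c in retained + removed) == sorted(c.pos for c in calls)
        assert {c.truth_id for c in removed} == {c.truth_id for c in calls[::2]}

    def test_coordinate_system_mismatch_raises(self):
        panel = StrainPanel(coordinate_system="other_assembly")
        with pytest.raises(CoordinateSystemError):
            strain_filter([vc()], panel)


class TestZygosity:
    def test_all_het(self):
        assert zygosity_partition([vc(gt="0/1")] * 10)["het_total"] == 10

    def test_het_total_sums_three_codes(self):
        calls = ([vc(gt="0/1")] * 2 + [vc(gt="1/2")] * 1 + [vc(gt="1/1")] * 5)
        part = zygosity_partition(calls)
        assert part["het_total"] == 3
        assert part["1/1"] == 5
        assert sum(part[k] for k in ("0/0", "0/1", "0/2", "1/1", "1/2", "2/2", "no_call")) == 8

    def test_empty(self):
        part = zygosity_partition([])
        assert all(v == 0 for v in part.values())


class TestIntersect:
    def test_identical_sets(self):
        calls = [vc(pos=p) for p in (10, 20)]
        out = intersect_generations({1: calls, 2: calls, 3: calls})
        assert out == calls

    def test_disjoint_sets_empty(self):
        assert intersect_generations({1: [vc(pos=10)], 2: [vc(pos=500)]}) == []

    def test_single_generation_rejected(self):
        with pytest.raises(ParameterError):
            intersect_generations({1: [vc()]})

    def test_position_slack_for_indels_only(self):
        g1 = [vc(pos=100)]
        g2 = [vc(pos=101)]
        assert len(intersect_generations({1: g1, 2: g2})) == 1
        s1 = [vc(pos=100, ref="A", alt="G", vtype="SNV", size=0)]
        s2 = [vc(pos=101, ref="A", alt="G", vtype="SNV", size=0)]
        assert intersect_generations({1: s1, 2: s2}) == []

    def test_nonincreasing_in_generations(self):
        gens = {g: [vc(pos=p) for p in range(0, 300, 10) if (p * (g + 3)) % 7 != 0]
                for g in range(1, 5)}
        sizes = []
        for k in range(2, 5):
            sizes.append(len(intersect_generations({g: gens[g] for g in range(1, k + 1)})))
        assert sizes == sorted(sizes, reverse=True)

    def test_order_independent(self):
        gens = {1: [vc(pos=10), vc(pos=20)], 2: [vc(pos=10)], 3: [vc(pos=10), vc(pos=20)]}
        base = {c.pos for c in intersect_generations(gens)}
        for perm in itertools.permutations([1, 2, 3]):
            relabeled = {i + 1: gens[g] for i, g in enumerate(perm)}
            assert {c.pos for c in intersect_generations(relabeled)} == base


class TestDilutionModel:
    def test_all_present_three_generations(self):
        r = dilution_test("v", ["present"] * 3)
        assert r.lik_induced == pytest.approx(0.125)
        assert r.lik_strain == 1.0
        assert r.classification == "needs_validation"

    def test_all_present_in_panel_is_strain(self):
        r = dilution_test("v", ["present"] * 3, in_strain_panel=True)
        assert r.classification == "strain_variant"

    def test_reappearance_is_inconsistent(self):
        r = dilution_test("v", ["present", "absent", "present"])
        assert r.lik_induced == 0.0
        assert r.classification == "inconsistent"

    def test_absorbing_loss(self):
        r = dilution_test("v", ["present", "absent", "absent"])
        assert r.lik_induced == pytest.approx(0.25)  # 0.5 * 0.5 * 1
        assert r.lik_strain == 0.0
        assert r.classification == "induced_candidate"

    def test_missing_observations_skip_factors(self):
        r = dilution_test("v", ["present", "missing", "present"])
        assert r.lik_induced == pytest.approx(0.25)
        assert r.classification == "needs_validation"

    def test_custom_retention(self):
        r = dilution_test("v", ["present", "present"], retention=0.3)
        assert r.lik_induced == pytest.approx(0.09)

    def test_empty_pattern_rejected(self):
        with pytest.raises(ParameterError):
            dilution_test("v", [])


class TestValidationRegions:
    def test_centered_amplicon_arithmetic(self):
        [r] = design_validation_regions([vc(pos=5000, ref="A" * 11, alt="A", size=10)],
                                        contig_length=100_000)
        assert r.wt_size == 350
        assert r.mut_size == 340
        assert not r.clipped and not r.oversized
        assert r.start <= 4999 < r.end  # contains the variant

    def test_clipped_at_contig_start(self):
        [r] = design_validation_regions([vc(pos=10)], contig_length=100_000)
        assert r.clipped
        assert r.start == 0

    def test_snv_sizes_equal(self):
        [r] = design_validation_regions(
            [vc(pos=5000, ref="A", alt="G", vtype="SNV", size=0)], contig_length=100_000)
        assert r.wt_size == r.mut_size

    def test_oversized_variant_flagged_not_dropped(self):
        big = vc(pos=5000, ref="A" * 501, alt="A", size=500)
        [r] = design_validation_regions([big], contig_length=100_000)
        assert r.oversized


class TestAmpliconComparison:
    @pytest.mark.parametrize("wt,mut,expected", [
        (350, 345, "distinguishable"),   # 5 nt resolvable on the gel
        (350, 340, "distinguishable"),
        (350, 350, "indistinguishable"),
        (350, 346, "indistinguishable"),  # 4 nt below resolution
    ])
    def test_resolution_boundary(self, wt, mut, expected):
        assert compare_amplicons(wt, mut) == expected

    def test_positive_sizes_required(self):
        with pytest.raises(ParameterError):
            compare_amplicons(0, 10)
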