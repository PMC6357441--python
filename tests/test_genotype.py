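"""Founder genotype parsing, all-or-nothing summary, chimera detection."""

import pytest

from talenko import (
    AmplificationMatrix,
    SimParams,
    founder_summary,
    infer_chimera_from_amplification,
    load_founder_table,
    locate_fusion_junction,
)
from talenko._rng import child_rng
from talenko.errors import GenotypeParseError, NoJunctionError
from talenko.genotype import format_gene_cell, parse_gene_cell
from talenko.simulate import edit_haplotype


class TestParser:
    def test_male_deletion_with_insertion(self):
        r = parse_gene_cell("X^Δ5+286 Y", "male")
        assert len(r.alleles) == 1
        a = r.alleles[0]
        assert (a.kind, a.del_len, a.ins_len) == ("delins", 5, 286)

    def test_female_two_distinct_deletions(self):
        r = parse_gene_cell("X^Δ22 X^Δ160", "female")
        assert [a.del_len for a in r.alleles] == [22, 160]
        assert all(a.kind == "del" for a in r.alleles)

    def test_wildtype_female(self):
        r = parse_gene_cell("XX (wt)", "female")
        assert len(r.alleles) == 2 and r.all_wt

    def test_both_delta_glyphs_accepted(self):
        for glyph in ("∆", "Δ"):
            r = parse_gene_cell(f"X^{glyph}17 Y", "male")
            assert r.alleles[0].del_len == 17

    def test_failed_amplification(self):
        r = parse_gene_cell("No successful PCR amplification.", "female")
        assert r.failed_amplification and r.modified

    def test_substitution_alleles(self):
        r = parse_gene_cell("X^C/T,A/G Y", "male")
        assert r.alleles[0].kind == "subst"
        assert r.alleles[0].substitutions == ("C/T", "A/G")

    def test_chimera_tag_preserved_verbatim(self):
        r = parse_gene_cell("X^Δ12 X^Δ12 Chimera of b/Δ/c", "female")
        assert r.chimera_tag == "b/Δ/c"
        assert [a.del_len for a in r.alleles] == [12, 12]

    def test_malformed_token_names_the_token(self):
        with pytest.raises(GenotypeParseError, match="Q17"):
            parse_gene_cell("X^Q17 Y", "male")

    def test_wrong_allele_count_rejected(self):
        with pytest.raises(GenotypeParseError):
            parse_gene_cell("X^Δ5 X^Δ5", "male")

    def test_roundtrip_on_packaged_table(self):
        """parse(format(parse(x))) == parse(x) for every cell of the fixture."""
        records = load_founder_table()
        for rec in records:
            for gene, result in rec.genes.items():
                text = format_gene_cell(result, rec.sex)
                again = parse_gene_cell(text, rec.sex)
                assert again == result, (rec.pup_id, gene)


class TestFounderSummary:
    def test_packaged_table_all_or_nothing(self):
        records = load_founder_table()
        s = founder_summary(records)
        assert s["n_total"] == 19
        assert s["n_modified_all_genes"] == 9
        assert s["n_unmodified"] == 10
        assert s["n_partial"] == 0
        assert s["n_with_failed_amp"] == 2

    def test_counts_are_a_partition(self):
        s = founder_summary(load_founder_table())
        assert s["n_modified_all_genes"] + s["n_unmodified"] + s["n_partial"] == s["n_total"]

    def test_single_wt_pup(self):
        recs = load_founder_table()
        wt = [r for r in recs if r.pup_id == "L74-1"]
        assert founder_summary(wt)["n_unmodified"] == 1

    def test_constructed_partial(self):
        from talenko.genotype import GenotypeRecord

        rec = GenotypeRecord("p", "male", {
            "g1": parse_gene_cell("XY (wt)", "male"),
            "g2": parse_gene_cell("X^Δ5 Y", "male"),
        })
        assert founder_summary([rec])["n_partial"] == 1

    def test_failed_amp_policy_missing(self):
        recs = load_founder_table()
        s = founder_summary(recs, failed_amp_policy="missing")
        # the two fusion pups remain all-modified on their amplifiable genes
        assert s["n_modified_all_genes"] == 9


class TestChimeraInference:
    def test_fusion_pattern_yields_candidate(self):
        m = AmplificationMatrix(
            gene_specific={"gene1": True, "gene2": False, "gene3": False},
            mixed={("gene2", "gene3"): True},
        )
        assert infer_chimera_from_amplification(m) == [("gene2", "gene3")]

    def test_all_specific_succeed_means_no_candidates(self):
        m = AmplificationMatrix(
            gene_specific={"gene1": True, "gene2": True, "gene3": True},
            mixed={("gene2", "gene3"): True},
        )
        assert infer_chimera_from_amplification(m) == []

    def test_truth_table_of_inference_rule(self):
        """Exhaustive enumeration: candidate iff (not A, not B, mixed)."""
        for a_ok in (True, False):
            for b_ok in (True, False):
                for mixed_ok in (True, False):
                    m = AmplificationMatrix(
                        gene_specific={"A": a_ok, "B": b_ok},
                        mixed={("A", "B"): mixed_ok},
                    )
                    got = infer_chimera_from_amplification(m)
                    expect = [("A", "B")] if (not a_ok and not b_ok and mixed_ok) else []
                    assert got == expect


class TestJunctionFinder:
    A = "ACGTACGTGGATCCTTAGCAAGCTTGCATGCCTGCAGGTCGAC"  # 43 nt
    B = "TTGACCATGATTACGCCAAGCTTGGGCTGCAGGTCGACTCTAG"  # 43 nt

    def test_hand_built_junction_with_known_microhomology(self):
        """A[:28] + B[31:]; the junction flanks share the 4-mer TGCA."""
        a, b = self.A, self.B
        ca, cb = 28, 31
        amplicon = a[:ca] + b[cb:]
        ev = locate_fusion_junction(amplicon, a, b, "A", "B", min_anchor=8)
        # independent exhaustive oracle over every decomposition of the amplicon
        best = None
        for p in range(8, len(amplicon) - 8 + 1):
            cb2 = len(b) - (len(amplicon) - p)
            if cb2 < 0 or amplicon[:p] != a[:p] or amplicon[p:] != b[cb2:]:
                continue
            ml = 0
            while ml < p and ml < cb2 and a[p - 1 - ml] == b[cb2 - 1 - ml]:
                ml += 1
            mr = 0
            while p + mr < len(a) and cb2 + mr < len(b) and a[p + mr] == b[cb2 + mr]:
                mr += 1
            best = (ml + mr, (len(a) - p) + cb2)
        assert best is not None
        assert (ev.microhomology_len, ev.junction_deletion_len) == best
        assert ev.microhomology_len == 4

    def test_pure_gene_a_has_no_junction(self):
        with pytest.raises(NoJunctionError):
            locate_fusion_junction(self.A, self.A, self.B, min_anchor=8)

    def test_short_anchor_rejected(self):
        amplicon = self.A[:5] + self.B[20:]
        with pytest.raises(NoJunctionError):
            locate_fusion_junction(amplicon, self.A, self.B, min_anchor=15)

    def test_simulated_fusions_recovered_exactly(self, family, family_wide_pair):
        params = SimParams(seed=61, fusion_prob=1.0)
        rng = child_rng(61, "fus")
        n = 0
        for _ in range(100):
            hap = edit_haplotype(family, family_wide_pair, params, rng)
            for g, evs in hap.items():
                for e in evs:
                    if e.kind != "fusion":
                        continue
                    n += 1
                    a = family.copy_seq(e.gene_label)
                    b = family.copy_seq(e.partner_gene)
                    amplicon = a[:e.position] + b[e.partner_position:]
                    ev = locate_fusion_junction(amplicon, a, b, e.gene_label, e.partner_gene)
                    assert ev.gene_5prime == e.gene_label
                    assert ev.gene_3prime == e.partner_gene
                    assert ev.junction_deletion_len == e.del_len
                    assert ev.microhomology_len == e.microhomology_len
                    # breakpoint placement agrees within the microhomology span
                    assert abs(ev.junction_position_5prime - e.position) <= e.microhomology_len
        assert n >= 90
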