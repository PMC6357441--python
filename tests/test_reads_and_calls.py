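"""Read simulation against the unedited reference, and indel calling."""

import numpy as np
import pysam
import pytest

from talenko import SimParams, assign_genotype, call_indels, quality_filter
from talenko._rng import child_rng
from talenko.dna import random_dna
from talenko.errors import ParameterError
from talenko.io import to_sam
from talenko.simulate import simulate_reads
from talenko.variants import AlignmentRecord, genotype_from_fractions


@pytest.fixture(scope="module")
def reference():
    return random_dna(np.random.default_rng(77), 10_000)


def _params(seed=41, coverage=30.0, read_len=100, **kw):
    return SimParams(seed=seed, coverage=coverage, read_len=read_len, **kw)


class TestReadSimulator:
    def test_unedited_region_single_m_op(self, reference):
        reads = simulate_reads(reference, [], _params(), chrom="chrT")
        assert reads
        assert all(r.cigar == "100M" for r in reads)
        # sequences really come from the reference at the stated position
        for r in reads[:50]:
            assert reference[r.pos - 1:r.pos - 1 + 100] == r.seq

    def test_read_spanning_deletion_contains_d_op(self, reference):
        """Constructed alignment oracle: a 64 bp deletion with >=20 nt anchors
        must appear as a 64D op between two M blocks."""
        edits = [(5000, 64, "")]
        reads = simulate_reads(reference, edits, _params(), chrom="chrT")
        spanning = [
            r for r in reads
            if r.pos <= 5000 - 20 + 1 and r.reference_end() >= 5064 + 20
        ]
        assert spanning
        assert all("64D" in r.cigar for r in spanning)

    def test_insertion_appears_as_i_op(self, reference):
        edits = [(5000, 0, "ACGTACGTAC")]
        reads = simulate_reads(reference, edits, _params(), chrom="chrT")
        assert any("10I" in r.cigar for r in reads)

    def test_mean_depth_tracks_coverage(self, reference):
        reads = simulate_reads(reference, [], _params(coverage=50.0), chrom="chrT")
        depth = np.zeros(len(reference))
        for r in reads:
            depth[r.pos - 1:r.pos - 1 + 100] += 1
        mid = depth[1000:9000]
        assert abs(mid.mean() - 50.0) < 5.0  # within 10%

    def test_deterministic_per_seed(self, reference):
        a = simulate_reads(reference, [(3000, 5, "")], _params(seed=9), chrom="chrT")
        b = simulate_reads(reference, [(3000, 5, "")], _params(seed=9), chrom="chrT")
        assert a == b

    def test_parameter_errors(self, reference):
        with pytest.raises(ParameterError):
            simulate_reads(reference, [], _params(read_len=0))
        with pytest.raises(ParameterError):
            simulate_reads("ACGT" * 10, [], _params(read_len=100))

    def test_output_parses_as_sam(self, reference, tmp_path):
        """External format oracle: pysam parses the emitted alignments."""
        reads = simulate_reads(reference, [(5000, 64, "")], _params(), chrom="chrT")
        sam_path = tmp_path / "sim.sam"
        sam_path.write_text(to_sam(reads, {"chrT": len(reference)}))
        with pysam.AlignmentFile(str(sam_path), "r") as fh:
            parsed = list(fh)
        assert len(parsed) == len(reads)
        for ours, theirs in zip(reads, parsed):
            assert theirs.reference_start + 1 == ours.pos
            assert theirs.cigarstring == ours.cigar


class TestCaller:
    def test_planted_deletion_called_exactly(self, reference):
        reads = simulate_reads(reference, [(4000, 10, "")], _params(), chrom="chrT")
        calls = call_indels(reads, min_support=3, reference=reference, chrom="chrT")
        assert len(calls) == 1
        c = calls[0]
        assert (c.vtype, c.size) == ("DEL", 10)
        assert c.pos == 4000  # VCF anchor base before the deleted run
        assert len(c.ref) - len(c.alt) == 10

    def test_no_gaps_no_calls(self, reference):
        reads = simulate_reads(reference, [], _params(), chrom="chrT")
        assert call_indels(reads, reference=reference) == []

    def test_nearby_deletions_not_merged(self, reference):
        """Two deletions 5 bp apart with merge_tolerance=2 stay distinct."""
        reads = simulate_reads(reference, [(4000, 3, ""), (4008, 3, "")],
                               _params(), chrom="chrT")
        calls = call_indels(reads, min_support=3, merge_tolerance=2,
                            reference=reference, chrom="chrT")
        assert len(calls) == 2
        assert sorted(c.pos for c in calls) == [4000, 4008]

    def test_unsorted_input_rejected(self, reference):
        reads = simulate_reads(reference, [], _params(), chrom="chrT")
        with pytest.raises(ParameterError):
            call_indels(list(reversed(reads)), reference=reference)

    def test_empty_input(self):
        assert call_indels([]) == []

    def test_hemizygous_and_het_genotypes(self, reference):
        # hemizygous: every spanning read carries the deletion
        reads = simulate_reads(reference, [(4000, 10, "")], _params(), chrom="chrT")
        calls = assign_genotype(call_indels(reads, reference=reference, chrom="chrT"))
        assert calls[0].genotype_code == "1/1"
        # heterozygous: mix reads from edited and wild-type haplotypes
        p = _params(coverage=15.0)
        mut = simulate_reads(reference, [(4000, 10, "")], p, rng=child_rng(1, "a"), chrom="chrT")
        wt = simulate_reads(reference, [], p, rng=child_rng(1, "b"), chrom="chrT")
        both = sorted(mut + wt, key=lambda r: r.pos)
        calls = assign_genotype(call_indels(both, reference=reference, chrom="chrT"))
        assert calls[0].genotype_code == "0/1"

    def test_multiallelic_site_genotyped_1_2(self, reference):
        """Two distinct deletion sizes at one site at ~50/50 fractions."""
        p = _params(coverage=15.0)
        a = simulate_reads(reference, [(4000, 10, "")], p, rng=child_rng(2, "a"), chrom="chrT")
        b = simulate_reads(reference, [(4000, 16, "")], p, rng=child_rng(2, "b"), chrom="chrT")
        both = sorted(a + b, key=lambda r: r.pos)
        calls = assign_genotype(call_indels(both, reference=reference, chrom="chrT"))
        assert {c.size for c in calls} == {10, 16}
        assert all(c.genotype_code == "1/2" for c in calls)

    def test_genotype_fraction_thresholds(self):
        assert genotype_from_fractions(1.0) == "1/1"
        assert genotype_from_fractions(0.5) == "0/1"
        assert genotype_from_fractions(0.8) == "1/1"
        assert genotype_from_fractions(0.19) == "no_call"
        assert genotype_from_fractions(0.5, 0.5) == "1/2"

    def test_quality_filter_monotone_sweep(self, reference):
        reads = simulate_reads(reference, [(4000, 10, ""), (7000, 7, "")],
                               _params(), chrom="chrT")
        calls = call_indels(reads, reference=reference, chrom="chrT")
        assert quality_filter(calls, 0) == calls
        prev = len(calls)
        for cut in (0, 50, 100, 200, 251, 1e9):
            n = len(quality_filter(calls, cut))
            assert n <= prev
            prev = n
        assert prev == 0

    def test_mixed_quality_cutoff(self):
        from dataclasses import replace

        from talenko.variants import VariantCall

        lo = VariantCall("c", 10, "N", "N", "DEL", 5, quality=50.0)
        hi = replace(lo, pos=100, quality=150.0)
        kept = quality_filter([lo, hi], 100.0)
        assert kept == [hi]
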