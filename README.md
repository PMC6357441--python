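# talenko

Tools for the computational side of a multi-copy gene-family knockout:
designing one TALEN pair that cuts every member of a highly similar X-linked
paralog family, scanning a genome for paired off-target binding sites, calling
the engineered indels from gapped alignments, and separating true
nuclease-induced off-target variants from strain background by a
pedigree-dilution analysis. Everything runs on synthetic genomes and pedigrees
generated by the package itself, with full truth records, so every claim the
pipeline makes can be checked against what was actually simulated.

The motivating system is the mouse H2A.B.3 histone-variant family: three
X-linked genes (H2Afb3, Gm14920, H2Afb2, > 92% identical) plus a pseudogene,
knocked out simultaneously with a single TALEN pair.

## Who this is for

Genome-editing groups who need to argue, quantitatively, that an editing
experiment produced no off-target mutations — and anyone building or testing
off-target verification pipelines who needs realistic positive and negative
controls with known ground truth.

## The core ideas

**RVD cipher.** A TAL effector reads DNA one base per repeat through its
repeat variable di-residue: NI→A, HD→C, NN→G, NG→T, with NK as an alternative
for a 3′ half-repeat T. A nuclease pair is two 15-mer arms bound on opposite
strands across a 12–20 bp spacer; FokI cleaves only as a dimer.

**Paired off-target scan.** Candidate off-target loci are sought with
in-silico PCR semantics: each arm acts as a primer whose 3′-terminal
`min_perfect_match` bases (default 8 of 15) must match exactly, and a locus
counts only if both sites occur in productive orientation within a maximum
product size (default 100 bp). Correctness is defined by exact agreement with
a brute-force scanner.

**Backcross dilution.** A founder's heterozygous variant is transmitted with
probability 1/2 per meiosis, so crossing carrier females to wild-type males
halves its prevalence each generation: P(still present at generation g) =
0.5^g, and absence is absorbing. Fixed strain differences are homozygous and
never dilute. Per variant the package computes

    lik_induced = ∏_g (0.5 if present at g else 0.5 at first absence, 1 after)
    lik_strain  = 1 if present in every generation else 0

and classifies each variant as `strain_variant`, `induced_candidate`,
`inconsistent`, or `needs_validation` (present everywhere but not in the
strain panel — resolvable only by wet validation, for which 300–450 bp
amplicon designs and a 5-nt gel-resolution check are provided).

**All-or-nothing editing and chimeras.** Founder editing is modeled as a
single Bernoulli event per animal: either every family member is cut or none
is. Repair can fuse the 5′ part of one paralog to the 3′ part of its neighbor
(a chimera) with sequence lost at the junction and terminal microhomology, as
NHEJ predicts. Chimeras are detected from PCR amplification logic (both
gene-specific primer pairs fail, the mixed cross-gene pair succeeds) and their
junctions located exactly from amplicon sequence.

## Worked example

```python
from talenko import (make_paralog_family, nm4_genotype, quality_filter)
from talenko.simulate import SimParams, haplotype_edit_layout, simulate_reads
from talenko.variants import call_indels

fam = make_paralog_family(seed=1)          # 3 copies + pseudogene, >= 92% identical
hap = nm4_genotype(fam, sizes=(5, 10, 64)) # the knockout male's X haplotype
params = SimParams(seed=1, coverage=30.0)
reads = simulate_reads(fam.sequence, haplotype_edit_layout(fam, hap), params,
                       chrom=fam.chromosome_name)
calls = quality_filter(call_indels(reads, reference=fam.sequence,
                                   chrom=fam.chromosome_name), 100.0)
print([(c.pos, c.vtype, c.size, c.genotype_code) for c in calls])
```

prints

```
[(748, 'DEL', 5, 'no_call'), (1745, 'DEL', 10, 'no_call'), (2718, 'DEL', 64, 'no_call')]
```

three deletion calls, one per gene copy, each at its exact engineered size
(run `assign_genotype` on the calls to add hemizygous `1/1` codes). The
founder screening table ships with the package:

```
$ talenko genotype
{
  "n_modified_all_genes": 9,
  "n_partial": 0,
  "n_total": 19,
  "n_unmodified": 10,
  "n_with_failed_amp": 2
}
```

19 pups, 9 with every family member mutated, 10 untouched, none in between —
the all-or-nothing pattern. The full pipeline (`talenko run --config
run.yaml`) chains simulate → design → scan → call → dilute and writes FASTA,
VCF, BED, TSV and a manifest whose hash reproduces byte-identically for a
fixed seed.

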