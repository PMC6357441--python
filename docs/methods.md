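# Methods

This note documents the models behind talenko, the parameters that matter,
the numerical conventions, and what the synthetic data can and cannot show.

## Synthetic paralog family

A toy X chromosome carries `n_copies` gene copies (default 3, 500 nt each,
separated by 500 nt random flanks) plus an optional pseudogene. All copies
derive from one ancestral sequence; each receives `d` private substitutions
at positions disjoint across copies, so any two copies differ at ≤ 2d sites
and pairwise identity is bounded below by `1 − 2d/copy_len`. By default `d`
fills 80% of the budget allowed by `min_identity` (default 0.92, matching a
family whose members are > 92% identical); the realized identity matrix is
recorded and checked. The pseudogene receives 20 extra substitutions and is
excluded from family-wide specificity counts and from editing.

A central 60-nt window of every copy receives no substitutions. Real gene
families targetable by a single nuclease pair necessarily contain a conserved
target site; reserving the window makes the simulated design problem
well-posed under every seed rather than probabilistically so.

All randomness flows from one integer seed through labeled child streams
(`crc32(label)` as a spawn key), so adding a simulation step never shifts the
draws of another. Identical seeds give byte-identical FASTA/VCF/TSV outputs.

## TALEN design

The RVD cipher is positional (NI/HD/NN/NG for A/C/G/T; NK optionally encodes
a terminal T) and bijective with the flag off. Arms are 15-mers counted as
recognition bases only — whether the canonical 5′ T is included in an arm
length is convention-dependent, so here it is a separate, optional constraint
(default on, as is standard for TAL effectors). The spacer is the plus-strand
gap strictly between the two arm footprints, admissible in 12–20 bp.
Specificity against the family uses Hamming matching only (TAL repeats read
contiguous bases; indels inside a binding site are not modeled). The class is
`family_wide` when all coding copies are hit, `single_copy` when exactly one
is, with `partial`/`none` otherwise; the hit set is non-decreasing in the
mismatch allowance. Candidate ranking is positional; activity scoring is out
of scope.

## Paired off-target scan

"Minimum perfect match" follows in-silico-PCR primer semantics: a site
counts when the 3′-terminal `min_perfect_match` bases (default 8) of the arm
match the genome exactly, with arbitrary mismatches further 5′; the binding
site spans the full arm length positionally, anchored at the 3′ end, and N
never matches. A paired hit needs the left arm on the plus strand strictly
before the right arm's minus-strand site, with product size (5′ end of the
left site to the 5′ end of the right site, inclusive amplicon convention) at
most `max_product` (default 100 bp). `scan_for_pair` also scans the swapped
orientation, since FokI dimerization is orientation-symmetric. The
implementation indexes the 3′ anchor with exact string search; its contract
is exact agreement with a brute-force scan over every position, which the
test suite enforces across random genomes and the full parameter grid, along
with monotonicity in both parameters.

## Editing model

Founder editing is all-or-nothing: one Bernoulli draw per founder
(`founder_edit_prob`, default 0.47 ≈ 9 modified of 19 screened pups) decides
whether every coding copy with a cut site is lesioned or none is. Deletion
lengths are shifted-geometric with mean `del_len_mean` = 15 nt (the observed
lesions are mostly small deletions; no distribution is reported, so a
maximum-entropy-style single-parameter choice is used). Insertions accompany
a deletion with probability 0.1; their length is geometric (mean 8) except
for a rare long insertion (286 nt with probability 0.02 given an insertion),
mimicking a Δ5+286-type allele. Cut position is the spacer midpoint.

With probability `fusion_prob` (default 0.2) two adjacent cut copies are
replaced by a single fusion allele. The partner breakpoint is chosen by
scanning ±40 nt around the nominal cut for junction microhomology within
`microhomology_range` (2–6 nt); the longest wins, ties to the leftmost.
Microhomology is defined junction-invariantly as m_left + m_right, the exact
repeat shared by the two parents across the breakpoint — the same quantity
the junction finder recomputes from sequence, and the size of the breakpoint
ambiguity. The junction deletion length, len(A) + len(B) − len(fusion), is
invariant under breakpoint placement, which is why recovery can be exact.

Mosaicism is a per-variant carrier fraction f in the founder
(`mosaic_fraction`, default 1 = constitutive); a mosaic variant transmits
with probability f/2 and becomes constitutive (f = 1) in carriers, so
founder-restricted mosaicism decays out of the line within a couple of
generations, as observed in real colonies.

## Pedigree

The three gene copies sit on one X chromosome and travel as one linked
haplotype (no recombination inside the family). Mothers transmit one of two
X haplotypes uniformly; fathers give X to daughters and Y to sons. Autosomal
heterozygous variants transmit with probability 1/2 per meiosis; strain
variants (fixed differences) go to every offspring. The backcross scheme
crosses a carrier female to a wild-type male each generation, keeping a
carrier female to continue the line and a carrier male as that generation's
sequenced animal (litter size 8, redrawn until both exist).

## Reads and calling

Reads (default 100 bp, 30×) are drawn uniformly from the edited haplotype
and reported against the unedited reference: deletions inside a read appear
as D ops, insertions as I; an edge anchor shorter than 5 aligned bases is
soft-clipped. Query sequences are stored plus-strand oriented (SAM
convention); the sampled strand flag carries no extra information in this
uniform-coverage model. Substitution errors are i.i.d. per base.

The caller collects I/D evidence, re-anchors soft-clip breakpoints by an
exact 15-mer seed search within 500 bp, merges evidence of the same type
within 3 bp and size ±1, and calls clusters with support ≥ 3 at the modal
position and size. Quality is 10 × support capped at 250 — deliberately
simple and monotone in evidence, so the meaningful statement is the cut-off
semantics (survivors non-increasing in the threshold; default cut-off 100),
not the score's absolute scale. Genotypes come from allele fractions with a
conventional heterozygous band [0.2, 0.8): hemizygous/homozygous 1/1,
heterozygous 0/1, two distinct alts both in the band 1/2; zero spanning
reads gives no_call. Codes 0/2 and 2/2 are accepted throughout (they arise
when allele numbering is imposed externally, e.g. across samples) but a
single-sample run emits only 0/1, 1/1, 1/2 and no_call.

The emulated exome-scale caller (`simulate_variant_calls`) bypasses reads:
it renders true genotypes directly as calls, perturbs indel sizes by a
rounded Normal(0, `size_error_sd`) truncated to preserve sign and existence
(symmetric, hence unbiased), and injects spurious indel calls at
`fp_indel_rate` per Mb with random zygosity and quality. Truth ids ride on a
hidden field and are never serialized to VCF.

## Dilution analysis

Strain filtering removes calls matching the panel exactly on
(chrom, pos, ref, alt), with ±1 bp slack at identical size for deletions
(left-alignment ambiguity); a panel declared in a different coordinate
system is rejected outright rather than lifted over. The cross-generation
intersection matches on (chrom, type, size) with the same ±1 indel slack and
is associative and order-independent. The dilution model is the absorbing
Markov chain described in the README with `retention` a parameter (default
0.5 — the Mendelian value; other values model transmission distortion).
No multiple-testing control is applied: the procedure is a deterministic
filter cascade, not a p-value screen. The classifier never auto-clears an
all-present variant that is absent from the panel — a segregating strain
polymorphism is indistinguishable from an induced lesion by pattern alone —
so such variants are classed `needs_validation`, and validation amplicons
(350 nt by default, 300–450 admissible, flagged when clipped or oversized)
with a 5-nt gel-resolution comparison stand in for the wet step.

## Pipeline

One YAML config (unknown keys rejected) drives all stages; the manifest
records a SHA-256 over the canonical scientific configuration (output paths
excluded), and reruns are byte-identical. The line founder is redrawn until
edited (capped at 1000 draws) because an end-to-end run requires a carrier
line; raw founder statistics remain available through `make_founder`.
Exit codes: 0 success, 2 configuration error, 3 stage error.

## Problem sizes

Defaults used by the tests and the acceptance script: 500-nt copies with
500-nt flanks (≈ 4.5 kb X chromosome), a 200 kb autosome, 30× coverage,
10,000 offspring and 10,000 replicate lines for the Mendelian checks, 20
seeds for deletion recovery, 100 random genomes of 5–100 kb for the scan
oracle sweep, and 1,000 simulated fusions for junction recovery.

## What passing tests do and do not show

The generator produces uniform coverage, i.i.d. substitution errors, exact
Mendelian transmission and a clean, non-segregating strain panel. Passing
tests therefore demonstrate the correctness of the algorithms under their
stated models — exact deletion recovery, exact scan semantics, the 0.5^g
dilution law, all-or-nothing bookkeeping — not robustness to capture bias,
mapping artifacts, segregating strain polymorphism, or caller-specific error
modes of real exome data. The false-prediction phenomenology of real
pipelines is represented only through the configurable size-error and
false-positive rates. Recombination within the family, instrument error
profiles and activity scoring of nuclease pairs are out of scope.
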