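"""Plain-text serialization: FASTA, VCF subset, SAM-subset TSV, pedigree TSV.

All output is deterministic given identical inputs (stable ordering, no
timestamps), so reruns with the same seed produce byte-identical files.
"""

from __future__ import annotations

from io import StringIO
from typing import Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import Individual
from .variants import AlignmentRecord, VariantCall

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type">\n'
    '##INFO=<ID=SIZE,Number=1,Type=Integer,Description="Indel size in bp">\n'
    '##INFO=<ID=GEN,Number=1,Type=Integer,Description="Pedigree generation">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_fasta(contigs: Mapping[str, str]) -> str:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    buf = StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_vcf(calls: Sequence[VariantCall], sample: str, contigs: Optional[Mapping[str, int]] = None) -> str:
    """VCF v4.2 subset with a single sample GT column.

    no_call genotypes are written as './.'; truth ids stay internal and are
    never serialized.
    """
    out = [VCF_HEADER]
    if contigs:
        for name, length in contigs.items():
            out.append(f"##contig=<ID={name},length={length}>\n")
    out.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
    for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.vtype, c.size)):
        gt = "./." if c.genotype_code == "no_call" else c.genotype_code
        info = f"TYPE={c.vtype};SIZE={c.size}"
        if c.generation is not None:
            info += f";GEN={c.generation}"
        out.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{c.quality:.0f}\tPASS\t{info}\tGT\t{gt}\n"
        )
    return "".join(out)


def parse_vcf(text: str) -> list[VariantCall]:
    """Read the subset written by write_vcf back into VariantCall objects."""
    calls = []
    sample = ""
    generation = None
    for line in text.splitlines():
        if line.startswith("##"):
            continue
        if line.startswith("#CHROM"):
            sample = line.split("\t")[-1]
            continue
        if not line.strip():
            continue
        f = line.split("\t")
        info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
        gt = f[9]
        calls.append(
            VariantCall(
                chrom=f[0], pos=int(f[1]), ref=f[3], alt=f[4],
                vtype=info.get("TYPE", "SNV"), size=int(info.get("SIZE", 0)),
                quality=float(f[5]), sample=sample,
                generation=int(info["GEN"]) if "GEN" in info else None,
                genotype_code="no_call" if gt in (".", "./.") else gt,
            )
        )
    return calls


def write_sam_subset(records: Sequence[AlignmentRecord]) -> str:
    """TSV: qname, flag, rname, pos (1-based), cigar, seq."""
    lines = ["qname\tflag\trname\tpos\tcigar\tseq"]
    for r in records:
        lines.append(f"{r.qname}\t{r.flag}\t{r.rname}\t{r.pos}\t{r.cigar}\t{r.seq}")
    return "\n".join(lines) + "\n"


def to_sam(records: Sequence[AlignmentRecord], contigs: Mapping[str, int]) -> str:
    """Full SAM text (for interoperability checks with standard parsers)."""
    out = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in contigs.items():
        out.append(f"@SQ\tSN:{name}\tLN:{length}")
    for r in records:
        out.append(
            f"{r.qname}\t{r.flag}\t{r.rname}\t{r.pos}\t60\t{r.cigar}\t*\t0\t0\t{r.seq}\t*"
        )
    return "\n".join(out) + "\n"


def write_pedigree_tsv(individuals: Sequence[Individual]) -> str:
    lines = ["id\tsex\tgeneration\tsire\tdam"]
    for ind in individuals:
        lines.append(
            f"{ind.id}\t{ind.sex}\t{ind.generation}\t{ind.sire or '.'}\t{ind.dam or '.'}"
        )
    return "\n".join(lines) + "\n"
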