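"""VCF v4.2 emission with indel normalization.

Records carry CHROM/POS/REF/ALT/QUAL, GT and GQ, and an AP INFO field
with the network's per-allele probabilities.  Indel alleles are
left-aligned and parsimony-trimmed against the reference before
writing so output is interoperable with standard truth-comparison
tools.  Internal coordinates are 0-based; conversion to VCF's 1-based
convention happens here only.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

from .genotyping import VariantCall
from .pileup import ReferenceView


def normalize_alleles(
    reference: ReferenceView, contig: str, position: int, alleles: Sequence[str]
) -> Tuple[int, List[str]]:
    """Left-align and trim an allele tuple (REF first) at ``position``."""
    alleles = [a.upper() for a in alleles]
    changed = True
    while changed:
        changed = False
        if len(set(a[-1] if a else "" for a in alleles)) == 1 and alleles[0]:
            if all(len(a) >= 2 for a in alleles):
                alleles = [a[:-1] for a in alleles]
                changed = True
            elif position > 0:
                prev = reference.base(contig, position - 1)
                alleles = [prev + a[:-1] for a in alleles]
                position -= 1
                changed = True
    while all(len(a) >= 2 for a in alleles) and len(set(a[0] for a in alleles)) == 1:
        alleles = [a[1:] for a in alleles]
        position += 1
    return position, alleles


def write_vcf(
    calls: Sequence[VariantCall],
    reference: ReferenceView,
    contig_lengths: Dict[str, int],
    path: str,
    sample: str = "SAMPLE",
) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##source=allelecall")
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality (phred)")
    header.info.add("AP", ".", "Float", "Per-allele truth probabilities (REF first)")
    header.add_sample(sample)

    normalized = []
    for call in calls:
        position, alleles = normalize_alleles(
            reference, call.contig, call.position, [call.ref_allele] + call.alt_alleles
        )
        normalized.append((call.contig, position, alleles, call))
    normalized.sort(key=lambda t: (t[0], t[1]))

    with pysam.VariantFile(path, "w", header=header) as vcf:
        for contig, position, alleles, call in normalized:
            rec = vcf.new_record(
                contig=contig,
                start=position,
                stop=position + len(alleles[0]),
                alleles=tuple(alleles),
                qual=call.genotype_quality,
            )
            probs = list(call.allele_probabilities.values())
            if probs:
                rec.info["AP"] = tuple(round(p, 4) for p in probs)
            rec.samples[sample]["GT"] = tuple(call.genotype)
            rec.samples[sample]["GQ"] = int(round(call.genotype_quality))
            vcf.write(rec)


def read_calls(path: str) -> List[Tuple[str, int, str, Tuple[str, ...], Tuple[int, ...]]]:
    """(contig, 0-based pos, ref, alts, sorted genotype) per record."""
    import pysam

    out = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            gt = ()
            if rec.samples:
                raw = rec.samples[0]["GT"]
                gt = tuple(sorted(0 if g is None else int(g) for g in raw))
            out.append((rec.contig, rec.start, rec.ref, tuple(rec.alts or ()), gt))
    return out
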