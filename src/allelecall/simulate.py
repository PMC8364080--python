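"""Synthetic diploid genomes and platform-flavored aligned reads.

The simulator provides desk-scale, fully self-contained inputs for
every pipeline stage: a random reference contig, planted heterozygous
and homozygous SNVs and 1-50 bp indels with a truth VCF and a
confident-region BED, and reads drawn from the two truth haplotypes.

Two error profiles are modeled.  The short-read profile emits paired
150 bp reads whose errors are substitution-dominated.  The long-read
profile emits multi-kilobase reads with low-rate indel errors whose
probability is multiplied inside homopolymer runs, mimicking the
context-specific indel errors of circular consensus sequencing; these
reads optionally carry an HP tag naming their haplotype of origin.

Reads are emitted pre-aligned at their known simulation coordinates
(CIGAR built during the haplotype walk), so no external aligner is
needed and coordinates are exact by construction.  Identical config and
seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

BASES = "ACGT"


@dataclass
class PlatformProfile:
    """Error and geometry model for one sequencing platform."""

    name: str = "short"
    read_length: int = 150
    coverage: float = 30.0
    paired: bool = True
    fragment_length: int = 400
    substitution_rate: float = 0.001
    insertion_rate: float = 1e-5
    deletion_rate: float = 1e-5
    homopolymer_multiplier: float = 0.0  # extra indel rate per run base beyond 1
    base_quality: int = 35
    mapping_quality: int = 60
    haplotag: bool = False

    @classmethod
    def short_read(cls, **overrides) -> "PlatformProfile":
        return dataclasses.replace(cls(), **overrides)

    @classmethod
    def long_read(cls, **overrides) -> "PlatformProfile":
        base = cls(
            name="ccs",
            read_length=5000,
            coverage=30.0,
            paired=False,
            substitution_rate=0.0005,
            insertion_rate=0.002,
            deletion_rate=0.002,
            homopolymer_multiplier=1.0,
            base_quality=30,
            mapping_quality=60,
            haplotag=True,
        )
        return dataclasses.replace(base, **overrides)


@dataclass
class SimulationConfig:
    """Genome-level simulation parameters."""

    seed: int = 0
    contig: str = "sim1"
    length: int = 100_000
    snv_rate: float = 1e-3
    indel_rate: float = 2e-4
    max_indel: int = 50
    indel_length_p: float = 0.35  # truncated geometric over 1..max_indel
    het_fraction: float = 2 / 3  # human-typical het:hom of about 2:1
    edge_margin: int = 300  # confident regions exclude contig edges
    min_variant_gap: int = 3


@dataclass
class PlantedVariant:
    """One truth variant with a phased diploid genotype."""

    position: int  # 0-based
    ref: str
    alt: str
    genotype: Tuple[int, int]  # per-haplotype allele index (0 ref / 1 alt)

    @property
    def end(self) -> int:
        return self.position + len(self.ref)

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]


def _draw_indel_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    while True:
        n = int(rng.geometric(cfg.indel_length_p))
        if 1 <= n <= cfg.max_indel:
            return n


def simulate_genome(
    config: SimulationConfig,
) -> Tuple[str, List[PlantedVariant], List[Tuple[int, int]]]:
    """Reference sequence, planted variants, and confident regions.

    Variants never overlap (draws landing inside an existing variant's
    span plus ``min_variant_gap`` are re-drawn elsewhere implicitly by
    the left-to-right scan).
    """
    rng = np.random.default_rng(config.seed)
    reference = "".join(rng.choice(list(BASES), size=config.length))
    variants: List[PlantedVariant] = []
    blocked_until = -1
    position = config.edge_margin
    while position < config.length - config.edge_margin - config.max_indel - 1:
        r = rng.random()
        if r >= config.snv_rate + config.indel_rate or position <= blocked_until:
            position += 1
            continue
        het = rng.random() < config.het_fraction
        if het:
            genotype = (0, 1) if rng.random() < 0.5 else (1, 0)
        else:
            genotype = (1, 1)
        if r < config.snv_rate:
            ref = reference[position]
            alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
            variants.append(PlantedVariant(position, ref, alt, genotype))
            blocked_until = position + config.min_variant_gap
        else:
            size = _draw_indel_length(rng, config)
            anchor = reference[position]
            if rng.random() < 0.5:  # insertion
                ins = "".join(rng.choice(list(BASES), size=size))
                variants.append(PlantedVariant(position, anchor, anchor + ins, genotype))
                blocked_until = position + config.min_variant_gap
            else:  # deletion
                ref = reference[position : position + 1 + size]
                variants.append(PlantedVariant(position, ref, anchor, genotype))
                blocked_until = position + size + config.min_variant_gap
        position += 1
    regions = [(config.edge_margin, config.length - config.edge_margin)]
    return reference, variants, regions


# ---- read generation -------------------------------------------------------


@dataclass
class SimRead:
    name: str
    start: int
    sequence: str
    qualities: List[int]
    cigar: List[Tuple[int, int]]  # pysam ops: 0=M, 1=I, 2=D
    reverse: bool
    haplotag: Optional[int]
    paired: bool = False
    first_in_pair: bool = True
    mate_start: int = 0


def _hap_variants(variants: Sequence[PlantedVariant], hap: int) -> List[PlantedVariant]:
    return [v for v in variants if v.genotype[hap] == 1]


def homopolymer_runs(reference: str) -> np.ndarray:
    """runs[i] = length of the homopolymer run containing position i."""
    arr = np.frombuffer(reference.encode(), dtype=np.uint8)
    runs = np.empty(len(arr), dtype=np.int32)
    start = 0
    for i in range(1, len(arr) + 1):
        if i == len(arr) or arr[i] != arr[start]:
            runs[start:i] = i - start
            start = i
    return runs


def _walk_read(
    reference: str,
    hap_vars: List[PlantedVariant],
    var_positions: np.ndarray,
    ref_start: int,
    length: int,
    profile: PlatformProfile,
    rng: np.random.Generator,
    runs: Optional[np.ndarray] = None,
) -> Optional[Tuple[int, str, List[int], List[Tuple[int, int]]]]:
    """Emit up to ``length`` read bases walking one haplotype from ref_start."""
    seq: List[str] = []
    quals: List[int] = []
    cigar: List[Tuple[int, int]] = []

    def push(op: int, n: int = 1) -> None:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    vi = int(np.searchsorted(var_positions, ref_start))
    # never start inside a deletion span or at a non-clean position
    if vi > 0 and hap_vars[vi - 1].end > ref_start:
        ref_start = hap_vars[vi - 1].end
    cursor = ref_start
    L = len(reference)
    hp = profile.homopolymer_multiplier

    while len(seq) < length and cursor < L:
        if vi < len(hap_vars) and hap_vars[vi].position == cursor:
            v = hap_vars[vi]
            vi += 1
            if len(v.ref) == 1 and len(v.alt) == 1:  # SNV
                seq.append(v.alt)
                quals.append(profile.base_quality)
                push(0)
                cursor += 1
            elif len(v.alt) > len(v.ref):  # insertion
                seq.append(v.ref)
                quals.append(profile.base_quality)
                push(0)
                inserted = v.alt[1:]
                take = min(len(inserted), length - len(seq))
                if take > 0:
                    seq.extend(inserted[:take])
                    quals.extend([profile.base_quality] * take)
                    push(1, take)
                cursor += 1
            else:  # deletion
                seq.append(v.alt)
                quals.append(profile.base_quality)
                push(0)
                push(2, len(v.ref) - 1)
                cursor = v.end
            continue
        # plain reference base, subject to sequencing error
        base = reference[cursor]
        mult = 1.0
        if hp > 0.0 and runs is not None:
            mult = 1.0 + hp * (min(int(runs[cursor]), 8) - 1)
        if rng.random() < profile.substitution_rate:
            base = BASES[(BASES.index(base) + 1 + int(rng.integers(3))) % 4]
        seq.append(base)
        quals.append(profile.base_quality)
        push(0)
        cursor += 1
        if rng.random() < profile.insertion_rate * mult and len(seq) < length:
            seq.append(BASES[int(rng.integers(4))])
            quals.append(profile.base_quality)
            push(1)
        elif rng.random() < profile.deletion_rate * mult:
            # error deletion of the next base, unless a variant sits there
            if cursor < L and (vi >= len(hap_vars) or hap_vars[vi].position > cursor):
                push(2)
                cursor += 1
    if not seq or cigar[0][0] != 0:
        return None
    while cigar and cigar[-1][0] != 0:  # alignments must end on aligned bases
        op, n = cigar.pop()
        if op == 1:
            seq = seq[:-n]
            quals = quals[:-n]
    if not seq:
        return None
    return ref_start, "".join(seq), quals, cigar


def simulate_reads(
    reference: str,
    variants: Sequence[PlantedVariant],
    profile: PlatformProfile,
    seed: int = 0,
    contig: str = "sim1",
) -> List[SimRead]:
    """Draw reads from the two truth haplotypes under the error profile."""
    rng = np.random.default_rng(seed)
    L = len(reference)
    hap_vars = [_hap_variants(variants, 0), _hap_variants(variants, 1)]
    var_positions = [np.array([v.position for v in hv]) for hv in hap_vars]
    runs = homopolymer_runs(reference) if profile.homopolymer_multiplier > 0 else None

    reads: List[SimRead] = []
    if profile.paired:
        n_fragments = int(round(profile.coverage * L / (2 * profile.read_length)))
        for i in range(n_fragments):
            hap = int(rng.integers(2))
            frag = max(profile.fragment_length + int(rng.normal(0, 30)), 2 * profile.read_length)
            start = int(rng.integers(0, max(L - frag, 1)))
            for mate, (s, reverse) in enumerate(
                [(start, False), (start + frag - profile.read_length, True)]
            ):
                walked = _walk_read(
                    reference, hap_vars[hap], var_positions[hap], s,
                    profile.read_length, profile, rng, runs,
                )
                if walked is None:
                    continue
                ref_start, seq, quals, cigar = walked
                reads.append(
                    SimRead(
                        name=f"{profile.name}_frag{i}",
                        start=ref_start,
                        sequence=seq,
                        qualities=quals,
                        cigar=cigar,
                        reverse=reverse,
                        haplotag=(hap + 1) if profile.haplotag else None,
                        paired=True,
                        first_in_pair=(mate == 0),
                        mate_start=start if mate == 1 else start + frag - profile.read_length,
                    )
                )
    else:
        n_reads = int(round(profile.coverage * L / profile.read_length))
        for i in range(n_reads):
            hap = int(rng.integers(2))
            length = profile.read_length
            start = int(rng.integers(-length // 2, L - length // 2))
            start = max(start, 0)
            walked = _walk_read(
                reference, hap_vars[hap], var_positions[hap], start, length, profile, rng, runs
            )
            if walked is None:
                continue
            ref_start, seq, quals, cigar = walked
            reads.append(
                SimRead(
                    name=f"{profile.name}_read{i}",
                    start=ref_start,
                    sequence=seq,
                    qualities=quals,
                    cigar=cigar,
                    reverse=bool(rng.integers(2)),
                    haplotag=(hap + 1) if profile.haplotag else None,
                )
            )
    reads.sort(key=lambda r: (r.start, r.name))
    return reads


# ---- file emission ---------------------------------------------------------


def write_reference(reference: str, contig: str, path: str) -> None:
    import pysam

    with open(path, "w") as fa:
        fa.write(f">{contig}\n")
        for i in range(0, len(reference), 60):
            fa.write(reference[i : i + 60] + "\n")
    pysam.faidx(path)


def write_truth_vcf(
    variants: Sequence[PlantedVariant], contig: str, length: int, path: str
) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##source=allelecall-simulate")
    header.contigs.add(contig, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample("SIM")
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for v in sorted(variants, key=lambda x: x.position):
            rec = vcf.new_record(
                contig=contig,
                start=v.position,
                stop=v.end,
                alleles=(v.ref, v.alt),
            )
            rec.samples["SIM"]["GT"] = v.genotype
            rec.samples["SIM"].phased = True
            vcf.write(rec)


def write_bed(regions: Sequence[Tuple[int, int]], contig: str, path: str) -> None:
    with open(path, "w") as bed:
        for start, end in regions:
            bed.write(f"{contig}\t{start}\t{end}\n")


def write_bam(
    reads: Sequence[SimRead], contig: str, length: int, path: str, sample: str = "SIM"
) -> None:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": contig, "LN": length}],
        "RG": [{"ID": sample, "SM": sample}],
    }
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for read in reads:
            rec = pysam.AlignedSegment(bam.header)
            rec.query_name = read.name
            rec.query_sequence = read.sequence
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.qualities)
            )
            rec.reference_id = 0
            rec.reference_start = read.start
            rec.mapping_quality = 60
            rec.cigartuples = read.cigar
            flag = 0
            if read.reverse:
                flag |= 0x10
            if read.paired:
                flag |= 0x1 | 0x2
                flag |= 0x40 if read.first_in_pair else 0x80
                flag |= 0x20 if not read.reverse else 0
                rec.next_reference_id = 0
                rec.next_reference_start = read.mate_start
            rec.flag = flag
            rec.set_tag("RG", sample)
            if read.haplotag is not None:
                rec.set_tag("HP", read.haplotag)
            bam.write(rec)
    pysam.index(path)
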