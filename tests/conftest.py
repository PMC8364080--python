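"""Shared fixtures: hand-built pileups and a small simulated dataset."""

from __future__ import annotations

import numpy as np
import pytest

from allelecall.datatypes import CandidateAllele, ReadAlignment, SiteData
from allelecall.pileup import ReferenceView


def make_read(
    read_id: str,
    start: int,
    sequence: str,
    contig: str = "chr1",
    quality: int = 30,
    mapping_quality: int = 60,
    strand: str = "+",
    haplotag=None,
    events: dict | None = None,
):
    """Build a ReadAlignment from a reference-matching walk plus edits.

    ``sequence`` is the reference-aligned base string; ``events`` maps a
    reference position to ("ins", bases) or ("del", length) applied
    immediately after that position's base.
    """
    events = events or {}
    pairs = []
    refpos = start
    i = 0
    while i < len(sequence):
        base = sequence[i]
        pairs.append((refpos, base, quality))
        if refpos in events:
            kind, arg = events[refpos]
            if kind == "ins":
                for b in arg:
                    pairs.append((None, b, quality))
            elif kind == "del":
                for d in range(arg):
                    refpos += 1
                    pairs.append((refpos, None, quality))
                    i += 1  # consumed reference positions, not read bases
        refpos += 1
        i += 1
    return ReadAlignment(
        read_id=read_id,
        contig=contig,
        start=start,
        aligned_pairs=pairs,
        mapping_quality=mapping_quality,
        strand=strand,
        haplotag=haplotag,
    )


@pytest.fixture
def reference_50bp():
    #           0         1         2         3         4
    #           0123456789012345678901234567890123456789012345678
    seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC"
    return ReferenceView({"chr1": seq}), seq


@pytest.fixture
def simple_site(reference_50bp):
    """A site at position 20 with a reference allele and a C substitution."""
    ref, seq = reference_50bp
    reads = {}
    for i in range(6):
        reads[f"ref{i}"] = make_read(f"ref{i}", 5, seq[5:40])
    for i in range(4):
        alt_seq = seq[5:20] + "C" + seq[21:40]
        reads[f"alt{i}"] = make_read(f"alt{i}", 5, alt_seq)
    candidates = [
        CandidateAllele(seq[20], 1, True, {f"ref{i}" for i in range(6)}),
        CandidateAllele("C", 1, False, {f"alt{i}" for i in range(4)}),
    ]
    site = SiteData(
        contig="chr1",
        position=20,
        reference_context=seq,
        context_start=0,
        candidates=candidates,
        reads=reads,
    )
    site.validate()
    return site


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A 20 kb error-free short-read dataset with all files on disk."""
    from allelecall.simulate import (
        PlatformProfile,
        SimulationConfig,
        simulate_genome,
        simulate_reads,
        write_bam,
        write_bed,
        write_reference,
        write_truth_vcf,
    )

    out = tmp_path_factory.mktemp("sim")
    config = SimulationConfig(seed=7, length=20_000)
    reference, variants, regions = simulate_genome(config)
    profile = PlatformProfile.short_read(
        coverage=30, substitution_rate=0.0, insertion_rate=0.0, deletion_rate=0.0
    )
    reads = simulate_reads(reference, variants, profile, seed=8)
    paths = {
        "reference": str(out / "ref.fa"),
        "truth_vcf": str(out / "truth.vcf"),
        "confident_bed": str(out / "conf.bed"),
        "bam": str(out / "short.bam"),
    }
    write_reference(reference, config.contig, paths["reference"])
    write_truth_vcf(variants, config.contig, config.length, paths["truth_vcf"])
    write_bed(regions, config.contig, paths["confident_bed"])
    write_bam(reads, config.contig, config.length, paths["bam"])
    return {
        "config": config,
        "reference": reference,
        "variants": variants,
        "regions": regions,
        "paths": paths,
    }
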