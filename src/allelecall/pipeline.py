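"""End-to-end orchestration: simulate, hotspots, training data, call.

Work is partitioned into genomic region chunks processed independently
and merged in coordinate order, so a parallel run is result-equivalent
to a serial one.  Every entry point logs its seed and configuration so
outputs are reproducible from the log alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import CandidateAllele, SiteData
from .genotyping import VariantCall, best_event, emit_variant
from .labeling import TruthSet, filter_confident, label_sites
from .model import HybridModel, load_checkpoint
from .pileup import (
    EmptySiteError,
    HotspotParams,
    ReferenceView,
    extract_site_data,
    find_hotspots,
    merge_hotspots,
    read_alignments,
)
from .shards import ShardSite, save_shard, site_to_shard

logger = logging.getLogger(__name__)

DEFAULT_CHUNK = 50_000


@dataclass
class CallConfig:
    reference: str
    bam_a: str
    bam_b: Optional[str] = None  # second platform enables hybrid calling
    checkpoint: str = ""
    contig: Optional[str] = None
    start: int = 0
    end: Optional[int] = None
    ploidy: int = 2
    haplotagged_a: bool = False
    haplotagged_b: bool = True
    hotspot: HotspotParams = field(default_factory=HotspotParams)
    chunk_size: int = DEFAULT_CHUNK
    workers: int = 1
    sample: str = "SAMPLE"


def _trimmed_site(site: SiteData, keys: Sequence[Tuple[str, int]]) -> SiteData:
    """Restrict a site to the candidates that survived encoding."""
    kept = [c for c in site.candidates if c.key() in set(keys)]
    return SiteData(
        contig=site.contig,
        position=site.position,
        reference_context=site.reference_context,
        context_start=site.context_start,
        candidates=kept,
        reads=site.reads,
        discarded=site.discarded,
    )


def _unified_candidates(
    site_a: Optional[SiteData], site_b: Optional[SiteData]
) -> List[CandidateAllele]:
    """Union of the two platforms' candidate lists, reference first."""
    merged: Dict[Tuple[str, int], CandidateAllele] = {}
    for site, prefix in ((site_a, "a:"), (site_b, "b:")):
        if site is None:
            continue
        for cand in site.candidates:
            entry = merged.setdefault(
                cand.key(),
                CandidateAllele(cand.allele_sequence, cand.ref_span, cand.is_reference, set()),
            )
            entry.support |= {prefix + rid for rid in cand.support}
    ordered = sorted(
        merged.values(), key=lambda c: (not c.is_reference, -len(c.support), c.key())
    )
    return ordered


def call_region(
    model,
    reference: ReferenceView,
    config: CallConfig,
    contig: str,
    start: int,
    end: int,
) -> List[VariantCall]:
    """Call variants in [start, end); hotspot scan pads by one chunk flank."""
    flank = 300
    reads_a = read_alignments(config.bam_a, contig, max(start - flank, 0), end + flank)
    hotspots = find_hotspots(reads_a, reference, config.hotspot)
    reads_b: List = []
    if config.bam_b:
        reads_b = read_alignments(config.bam_b, contig, max(start - flank, 0), end + flank)
        hotspots = merge_hotspots(hotspots, find_hotspots(reads_b, reference, config.hotspot))
    hotspots = [h for h in hotspots if start <= h.position < end]

    calls: List[VariantCall] = []
    for hotspot in hotspots:
        try:
            if config.bam_b:
                call = _call_hybrid_site(model, reference, config, hotspot, reads_a, reads_b)
            else:
                call = _call_single_site(model, reference, config, hotspot, reads_a)
        except EmptySiteError:
            continue
        if call is not None:
            calls.append(call)
    return calls


def _call_single_site(model, reference, config, hotspot, reads) -> Optional[VariantCall]:
    site = extract_site_data(hotspot, reads, reference, config.hotspot)
    shard = site_to_shard(site, haplotagged=config.haplotagged_a)
    if shard is None:
        return None
    p = model.site_forward(shard.encodings, shard.supports)
    trimmed = _trimmed_site(site, shard.candidate_keys)
    event, posterior = best_event(p, config.ploidy)
    return emit_variant(trimmed, event, posterior, probabilities=p, ploidy=config.ploidy)


def _call_hybrid_site(model, reference, config, hotspot, reads_a, reads_b) -> Optional[VariantCall]:
    site_a = site_b = None
    try:
        site_a = extract_site_data(hotspot, reads_a, reference, config.hotspot)
    except EmptySiteError:
        pass
    try:
        site_b = extract_site_data(hotspot, reads_b, reference, config.hotspot)
    except EmptySiteError:
        pass
    if site_a is None and site_b is None:
        raise EmptySiteError(f"no reads at {hotspot.contig}:{hotspot.position}")

    shard_a = site_to_shard(site_a, haplotagged=config.haplotagged_a) if site_a else None
    shard_b = site_to_shard(site_b, haplotagged=config.haplotagged_b) if site_b else None
    if shard_a is None and shard_b is None:
        return None

    unified = _unified_candidates(
        _trimmed_site(site_a, shard_a.candidate_keys) if shard_a else None,
        _trimmed_site(site_b, shard_b.candidate_keys) if shard_b else None,
    )
    keys = [c.key() for c in unified]

    def platform_inputs(shard, channels):
        if shard is None:
            enc = np.zeros((0, channels, model.spec_a.window), dtype=np.uint8)
            return enc, [[] for _ in keys]
        lookup = {k: s for k, s in zip(shard.candidate_keys, shard.supports)}
        return shard.encodings, [lookup.get(k, []) for k in keys]

    enc_a, sup_a = platform_inputs(shard_a, model.spec_a.in_channels)
    enc_b, sup_b = platform_inputs(shard_b, model.spec_b.in_channels)
    p = model.site_forward(enc_a, sup_a, enc_b, sup_b)

    base_site = site_a if site_a is not None else site_b
    synthetic = SiteData(
        contig=base_site.contig,
        position=base_site.position,
        reference_context=base_site.reference_context,
        context_start=base_site.context_start,
        candidates=unified,
        reads={},
        discarded=set(),
    )
    event, posterior = best_event(p, config.ploidy)
    return _emit_unchecked(synthetic, event, posterior, p, config.ploidy)


def _emit_unchecked(site, event, posterior, p, ploidy):
    # the unified hybrid site has no per-read registry; skip read validation
    return emit_variant(site, event, posterior, probabilities=p, ploidy=ploidy)


def _region_worker(args):
    (checkpoint, reference_path, config_doc, contig, start, end) = args
    import pysam

    model, _ = load_checkpoint(checkpoint)
    config = _config_from_doc(config_doc)
    reference = ReferenceView(pysam.FastaFile(reference_path))
    return call_region(model, reference, config, contig, start, end)


def _config_doc(config: CallConfig) -> dict:
    doc = dataclasses.asdict(config)
    return doc


def _config_from_doc(doc: dict) -> CallConfig:
    doc = dict(doc)
    doc["hotspot"] = HotspotParams(**doc["hotspot"])
    return CallConfig(**doc)


def run_call(config: CallConfig, out_vcf: str) -> int:
    """Full calling flow; returns the number of records written."""
    import pysam

    from .vcfio import write_vcf

    fasta = pysam.FastaFile(config.reference)
    reference = ReferenceView(fasta)
    contig_lengths = dict(zip(fasta.references, fasta.lengths))
    model, meta = load_checkpoint(config.checkpoint)
    hybrid = isinstance(model, HybridModel)
    if hybrid != bool(config.bam_b):
        kind = "hybrid" if hybrid else "single-platform"
        raise ValueError(
            f"checkpoint is a {kind} model but "
            f"{'one BAM was' if hybrid else 'two BAMs were'} provided"
        )
    if not hybrid and model.spec.in_channels != (7 if config.haplotagged_a else 6):
        raise ValueError(
            f"checkpoint expects {model.spec.in_channels} input channels but the "
            f"platform encoding provides {7 if config.haplotagged_a else 6}"
        )
    logger.info("call config: %s", json.dumps(_config_doc(config), default=str))

    contigs = [config.contig] if config.contig else list(fasta.references)
    tasks = []
    for contig in contigs:
        length = contig_lengths[contig]
        start = config.start
        end = min(config.end if config.end is not None else length, length)
        for chunk_start in range(start, end, config.chunk_size):
            tasks.append((contig, chunk_start, min(chunk_start + config.chunk_size, end)))

    calls: List[VariantCall] = []
    if config.workers > 1:
        args = [
            (config.checkpoint, config.reference, _config_doc(config), c, s, e)
            for c, s, e in tasks
        ]
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            for chunk_calls in pool.map(_region_worker, args):
                calls.extend(chunk_calls)
    else:
        for contig, s, e in tasks:
            calls.extend(call_region(model, reference, config, contig, s, e))

    calls.sort(key=lambda c: (c.contig, c.position))
    write_vcf(calls, reference, contig_lengths, out_vcf, sample=config.sample)
    logger.info("wrote %d records to %s", len(calls), out_vcf)
    return len(calls)


@dataclass
class TrainingDataConfig:
    reference: str
    bam: str
    truth_vcf: str
    confident_bed: str
    contig: str
    start: int = 0
    end: Optional[int] = None
    haplotagged: bool = False
    hotspot: HotspotParams = field(default_factory=HotspotParams)


def make_training_sites(config: TrainingDataConfig) -> List[ShardSite]:
    """Hotspots -> confident filter -> extraction -> labeling -> shard sites."""
    import pysam

    reference = ReferenceView(pysam.FastaFile(config.reference))
    truth = TruthSet.load(config.truth_vcf, config.confident_bed)
    reads = read_alignments(config.bam, config.contig, config.start, config.end)
    hotspots = find_hotspots(reads, reference, config.hotspot)
    if config.end is not None:
        hotspots = [h for h in hotspots if config.start <= h.position < config.end]
    n_total = len(hotspots)
    hotspots = filter_confident(hotspots, truth)
    logger.info(
        "hotspots: %d found, %d inside confident regions", n_total, len(hotspots)
    )
    sites = []
    for hotspot in hotspots:
        try:
            sites.append(extract_site_data(hotspot, reads, reference, config.hotspot))
        except EmptySiteError:
            continue
    labels = label_sites(sites, truth, reference)
    shard_sites = []
    for site in sites:
        shard = site_to_shard(
            site, haplotagged=config.haplotagged, labels=labels[(site.contig, site.position)]
        )
        if shard is not None:
            shard_sites.append(shard)
    logger.info("prepared %d labeled shard sites", len(shard_sites))
    return shard_sites


def run_make_training_data(config: TrainingDataConfig, out_shard: str) -> int:
    shard_sites = make_training_sites(config)
    save_shard(out_shard, shard_sites)
    return len(shard_sites)
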