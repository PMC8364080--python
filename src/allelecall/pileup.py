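"""Hotspot detection and per-site candidate extraction from alignments.

A *hotspot* is a reference position where some non-reference allele is
spelled by at least ``min_count`` reads making up at least
``min_fraction`` of the overlapping depth.  At a hotspot, each read
implies exactly one allele anchored at the position:

* matching base, next column a match      -> SNV / reference, ref_span 1
* base followed by inserted columns       -> insertion, ref_span 1
* base followed by d deletion columns     -> deletion, ref_span 1 + d

Reads whose alignment is ambiguous at the site (a deletion passing
through the anchor, or no aligned base there) go to a discard pool
rather than being forced onto an allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import CandidateAllele, Hotspot, ReadAlignment, SiteData

AlleleKey = Tuple[str, int]  # (replacement sequence, reference span)


@dataclass
class HotspotParams:
    """Thresholds for hotspot detection and site extraction."""

    min_fraction: float = 0.12
    min_count: int = 2
    max_candidates: int = 8  # non-reference candidates kept per site
    max_reads_per_candidate: int = 100
    seed: int = 0
    context_flank: int = 160  # reference context half-width around a site


class ReferenceView:
    """Uniform fetch() over a pysam FastaFile or a plain {contig: str} dict."""

    def __init__(self, source):
        self._source = source

    def fetch(self, contig: str, start: int, end: int) -> str:
        start = max(start, 0)
        if hasattr(self._source, "fetch"):
            return self._source.fetch(contig, start, end).upper()
        try:
            seq = self._source[contig]
        except KeyError as exc:
            raise KeyError(f"contig {contig!r} absent from reference") from exc
        return seq[start:end].upper()

    def base(self, contig: str, position: int) -> str:
        return self.fetch(contig, position, position + 1)


def read_alignments(
    bam_path: str, contig: str, start: int = 0, end: Optional[int] = None
) -> List[ReadAlignment]:
    """Load reads overlapping [start, end) from an indexed BAM/SAM."""
    import pysam

    reads: List[ReadAlignment] = []
    with pysam.AlignmentFile(bam_path) as bam:
        if contig not in bam.references:
            raise KeyError(f"contig {contig!r} absent from alignment file")
        for rec in bam.fetch(contig, start, end):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            quals = rec.query_qualities
            seq = rec.query_sequence
            pairs = []
            for qpos, rpos in rec.get_aligned_pairs():
                if qpos is None and rpos is None:
                    continue
                base = seq[qpos] if qpos is not None else None
                qual = int(quals[qpos]) if (qpos is not None and quals is not None) else 30
                pairs.append((rpos, base, qual))
            if not pairs:
                continue
            haplotag = None
            if rec.has_tag("HP"):
                haplotag = int(rec.get_tag("HP"))
            reads.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    contig=contig,
                    start=rec.reference_start,
                    aligned_pairs=pairs,
                    mapping_quality=min(rec.mapping_quality, 60),
                    strand="-" if rec.is_reverse else "+",
                    haplotag=haplotag,
                )
            )
    return reads


def allele_observations(read: ReadAlignment):
    """Single alignment walk yielding (position, allele-key-or-None).

    One item per covered reference position: the allele the read spells
    anchored there, or None where the alignment is ambiguous (a deletion
    passing through, or a deletion running off the alignment end).
    """
    columns = read.aligned_pairs
    n = len(columns)
    idx = 0
    while idx < n:
        refpos, base, _q = columns[idx]
        if refpos is None:  # leading / stray insertion columns
            idx += 1
            continue
        if base is None:  # inside a deletion: covered but ambiguous
            yield refpos, None
            idx += 1
            continue
        j = idx + 1
        inserted = []
        while j < n and columns[j][0] is None:
            inserted.append(columns[j][1])
            j += 1
        if inserted:
            yield refpos, (base + "".join(inserted), 1)
            idx = j
            continue
        deleted = 0
        while j < n and columns[j][1] is None and columns[j][0] is not None:
            deleted += 1
            j += 1
        if deleted and j >= n:
            yield refpos, None  # deletion length unknown at alignment end
        else:
            yield refpos, (base, 1 + deleted)
        idx += 1  # deletion columns re-visited to record covered depth


def implied_allele(read: ReadAlignment, position: int) -> Optional[AlleleKey]:
    """The allele this read spells at ``position``, or None if ambiguous."""
    for refpos, allele in allele_observations(read):
        if refpos == position:
            return allele
        if refpos > position:
            return None
    return None


def _allele_label(key: AlleleKey) -> str:
    seq, span = key
    return seq if span == 1 else f"{seq}/{span}"


def find_hotspots(
    alignments: Iterable[ReadAlignment],
    reference: ReferenceView,
    params: Optional[HotspotParams] = None,
) -> List[Hotspot]:
    """Scan a sorted pileup for sites with credible non-reference support."""
    params = params or HotspotParams()
    # one walk per read: non-reference observations + ambiguity + depth events
    nonref: Dict[str, Dict[int, Dict[AlleleKey, int]]] = {}
    ambiguous: Dict[str, Dict[int, int]] = {}
    events: Dict[str, List[Tuple[int, int]]] = {}
    last_start: Dict[str, int] = {}
    for read in alignments:
        contig = read.contig
        prev = last_start.get(contig, -1)
        if read.start < prev:
            raise ValueError("alignments must be sorted by coordinate")
        last_start[contig] = read.start
        events.setdefault(contig, []).append((read.start, +1))
        events[contig].append((read.end, -1))
        ctx = reference.fetch(contig, read.start, read.end)
        for position, allele in allele_observations(read):
            if allele is None:
                amb = ambiguous.setdefault(contig, {})
                amb[position] = amb.get(position, 0) + 1
                continue
            if allele[1] == 1 and allele[0] == ctx[position - read.start]:
                continue  # reference-matching observation
            site = nonref.setdefault(contig, {}).setdefault(position, {})
            site[allele] = site.get(allele, 0) + 1

    hotspots: List[Hotspot] = []
    for contig in sorted(nonref):
        positions = sorted(nonref[contig])
        # sweep depth only at positions that carry non-reference support
        evs = sorted(events[contig])
        depth_at: Dict[int, int] = {}
        depth = 0
        ei = 0
        for position in positions:
            while ei < len(evs) and evs[ei][0] <= position:
                depth += evs[ei][1]
                ei += 1
            depth_at[position] = depth
        for position in positions:
            counts = nonref[contig][position]
            total = depth_at[position]
            if not any(
                c >= params.min_count and c / total >= params.min_fraction
                for c in counts.values()
            ):
                continue
            ref_base = reference.base(contig, position)
            amb = ambiguous.get(contig, {}).get(position, 0)
            ref_count = total - sum(counts.values()) - amb
            allele_counts = {_allele_label(k): c for k, c in sorted(counts.items())}
            if ref_count > 0:
                allele_counts[ref_base] = allele_counts.get(ref_base, 0) + ref_count
            hotspots.append(
                Hotspot(
                    contig=contig,
                    position=position,
                    allele_counts=allele_counts,
                    depth=total,
                )
            )
    return hotspots


def merge_hotspots(
    hotspots_a: Sequence[Hotspot], hotspots_b: Sequence[Hotspot]
) -> List[Hotspot]:
    """Sorted union of two platforms' hotspot sets by (contig, position).

    The union is over *sites*: X ∪ X = X.  The merged hotspot carries
    the first platform's counts at its top level and retains each
    platform's original counts under ``sources`` ("a"/"b").
    """
    by_site: Dict[Tuple[str, int], Hotspot] = {}
    for label, hotspots in (("a", hotspots_a), ("b", hotspots_b)):
        for h in hotspots:
            key = h.sort_key()
            if key not in by_site:
                merged = Hotspot(h.contig, h.position, dict(h.allele_counts), h.depth)
                merged.sources = {}
                by_site[key] = merged
            by_site[key].sources[label] = h
    return [by_site[k] for k in sorted(by_site)]


class EmptySiteError(ValueError):
    """No overlapping reads at a hotspot."""


def extract_site_data(
    hotspot: Hotspot,
    alignments: Iterable[ReadAlignment],
    reference: ReferenceView,
    params: Optional[HotspotParams] = None,
) -> SiteData:
    """Enumerate candidate alleles at a hotspot and group reads by allele.

    Every overlapping read lands in exactly one candidate's support set
    or in the discard pool; the reference allele is included when
    supported.  Support sets exceeding ``max_reads_per_candidate`` are
    downsampled with a deterministic per-site RNG; the non-reference
    candidate list is capped at ``max_candidates`` by support size.
    """
    params = params or HotspotParams()
    position = hotspot.position
    overlapping = {
        r.read_id: r
        for r in alignments
        if r.contig == hotspot.contig and r.overlaps(position)
    }
    if not overlapping:
        raise EmptySiteError(f"no reads overlap {hotspot.contig}:{position}")

    flank = params.context_flank
    ctx_start = max(position - flank, 0)
    context = reference.fetch(hotspot.contig, ctx_start, position + flank)
    ref_base = context[position - ctx_start]

    support: Dict[AlleleKey, set] = {}
    discarded = set()
    for read_id, read in overlapping.items():
        allele = implied_allele(read, position)
        if allele is None:
            discarded.add(read_id)
        else:
            support.setdefault(allele, set()).add(read_id)

    ref_key = (ref_base, 1)
    alt_keys = [k for k in support if k != ref_key]
    # keep the highest-support non-reference candidates, ties by allele key
    alt_keys.sort(key=lambda k: (-len(support[k]), k))
    for dropped in alt_keys[params.max_candidates :]:
        discarded |= support.pop(dropped)
    alt_keys = alt_keys[: params.max_candidates]

    rng = np.random.default_rng([params.seed, position & 0x7FFFFFFF])
    candidates: List[CandidateAllele] = []
    ordered = ([ref_key] if ref_key in support else []) + alt_keys
    for key in ordered:
        ids = sorted(support[key])
        if len(ids) > params.max_reads_per_candidate:
            keep = rng.choice(len(ids), size=params.max_reads_per_candidate, replace=False)
            kept = {ids[i] for i in sorted(keep)}
            discarded |= set(ids) - kept
            ids = sorted(kept)
        candidates.append(
            CandidateAllele(
                allele_sequence=key[0],
                ref_span=key[1],
                is_reference=(key == ref_key),
                support=set(ids),
            )
        )

    site = SiteData(
        contig=hotspot.contig,
        position=position,
        reference_context=context,
        context_start=ctx_start,
        candidates=candidates,
        reads=overlapping,
        discarded=discarded,
    )
    site.validate()
    return site
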