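"""Truth labeling of candidate alleles for training-data generation.

Ground-truth VCFs and the caller's pileup can spell the same event
differently (left- vs right-aligned indels, composite representations),
so labels cannot come from naive record comparison.  Instead, hotspots
are clustered with nearby truth variants, the truth genotypes are
expanded into candidate haplotype-sequence pairs for the cluster
window, and each haplotype is searched for in the prefix tree induced
by the candidate alleles and the interleaved reference segments.  A
candidate is labeled true exactly when some truth haplotype is spelled
by a root-to-leaf path that selects that candidate at its hotspot.
"""

from __future__ import annotations

import bisect
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .datatypes import Hotspot, SiteData
from .pileup import ReferenceView

logger = logging.getLogger(__name__)

#: hotspots closer than this cluster together (bp)
DEFAULT_CLUSTER_DISTANCE = 20
#: cap on phase assignments expanded per cluster
MAX_PHASE_ASSIGNMENTS = 64
#: reference flank added around each cluster window (bp)
CLUSTER_FLANK = 10


@dataclass
class TruthVariant:
    """A normalized truth record, 0-based."""

    contig: str
    position: int
    ref: str
    alts: Tuple[str, ...]
    genotype: Tuple[int, ...]  # VCF allele indices, diploid

    @property
    def end(self) -> int:
        return self.position + len(self.ref)

    def allele(self, index: int) -> str:
        return self.ref if index == 0 else self.alts[index - 1]


@dataclass
class TruthSet:
    variants: List[TruthVariant]
    confident_regions: Dict[str, List[Tuple[int, int]]]

    @classmethod
    def load(cls, vcf_path: str, bed_path: str) -> "TruthSet":
        import pysam

        variants: List[TruthVariant] = []
        with pysam.VariantFile(vcf_path) as vcf:
            for rec in vcf:
                sample = rec.samples[0] if rec.samples else None
                gt = sample["GT"] if sample is not None else (1, 1)
                gt = tuple(0 if g is None else int(g) for g in gt)
                variants.append(
                    TruthVariant(
                        contig=rec.contig,
                        position=rec.start,
                        ref=rec.ref.upper(),
                        alts=tuple((a or "").upper() for a in rec.alts or ()),
                        genotype=gt,
                    )
                )
        variants.sort(key=lambda v: (v.contig, v.position))

        regions: Dict[str, List[Tuple[int, int]]] = {}
        with open(bed_path) as bed:
            for line in bed:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                regions.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
        merged: Dict[str, List[Tuple[int, int]]] = {}
        for contig, ivals in regions.items():
            ivals.sort()
            out = [list(ivals[0])]
            for start, end in ivals[1:]:
                if start <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], end)
                else:
                    out.append([start, end])
            merged[contig] = [(s, e) for s, e in out]
        return cls(variants=variants, confident_regions=merged)

    def contains(self, contig: str, position: int) -> bool:
        ivals = self.confident_regions.get(contig)
        if not ivals:
            return False
        idx = bisect.bisect_right([s for s, _ in ivals], position) - 1
        return idx >= 0 and ivals[idx][0] <= position < ivals[idx][1]


def filter_confident(hotspots: Sequence[Hotspot], truth: TruthSet) -> List[Hotspot]:
    """Keep only hotspots inside the high-confidence intervals."""
    kept = []
    for h in hotspots:
        if h.contig not in truth.confident_regions:
            warnings.warn(f"contig {h.contig!r} absent from confident regions; hotspot dropped")
            continue
        if truth.contains(h.contig, h.position):
            kept.append(h)
    return kept


@dataclass
class Cluster:
    """Nearby hotspot sites plus the truth variants at or near them."""

    contig: str
    sites: List[SiteData]
    variants: List[TruthVariant]
    window_start: int = 0
    window_end: int = 0


def cluster_sites(
    sites: Sequence[SiteData],
    truth: TruthSet,
    distance: int = DEFAULT_CLUSTER_DISTANCE,
) -> List[Cluster]:
    """Group hotspot sites within ``distance`` bp and attach truth variants."""
    clusters: List[Cluster] = []
    for site in sorted(sites, key=lambda s: (s.contig, s.position)):
        span = max(c.ref_span for c in site.candidates)
        if (
            clusters
            and clusters[-1].contig == site.contig
            and site.position <= clusters[-1].window_end + distance
        ):
            clusters[-1].sites.append(site)
            clusters[-1].window_end = max(clusters[-1].window_end, site.position + span)
        else:
            clusters.append(
                Cluster(
                    contig=site.contig,
                    sites=[site],
                    variants=[],
                    window_start=site.position,
                    window_end=site.position + span,
                )
            )
    for cluster in clusters:
        for v in truth.variants:
            if v.contig != cluster.contig:
                continue
            if v.end > cluster.window_start - distance and v.position < cluster.window_end + distance:
                cluster.variants.append(v)
                cluster.window_start = min(cluster.window_start, v.position)
                cluster.window_end = max(cluster.window_end, v.end)
        cluster.window_start -= CLUSTER_FLANK
        cluster.window_end += CLUSTER_FLANK
    return clusters


def _apply_variants(
    window: str, window_start: int, chosen: Sequence[Tuple[TruthVariant, int]]
) -> Optional[str]:
    """Apply (variant, allele-index) choices to the reference window.

    Returns None when two chosen non-reference alleles overlap (an
    inconsistent haplotype).
    """
    out = []
    cursor = window_start
    for variant, allele_idx in sorted(chosen, key=lambda t: t[0].position):
        if allele_idx == 0:
            continue
        if variant.position < cursor:
            return None
        out.append(window[cursor - window_start : variant.position - window_start])
        out.append(variant.allele(allele_idx))
        cursor = variant.end
    out.append(window[cursor - window_start :])
    return "".join(out)


def truth_haplotype_pairs(
    cluster: Cluster, reference: ReferenceView
) -> List[Tuple[str, str]]:
    """All phasing-consistent haplotype-sequence pairs for the cluster.

    Unphased genotypes expand over both phase assignments per
    heterozygous variant (capped); duplicate pairs are removed.  Returns
    an empty list when every assignment is internally inconsistent.
    """
    window = reference.fetch(cluster.contig, cluster.window_start, cluster.window_end)
    window_start = max(cluster.window_start, 0)
    variants = cluster.variants
    het = [v for v in variants if len(set(v.genotype)) > 1]
    if len(het) > 6 or 2 ** len(het) > MAX_PHASE_ASSIGNMENTS:
        warnings.warn(
            f"cluster {cluster.contig}:{cluster.window_start} has {len(het)} unphased "
            "heterozygous variants; skipped"
        )
        return []

    pairs: Set[Tuple[str, str]] = set()
    for mask in range(2 ** len(het)):
        hap1: List[Tuple[TruthVariant, int]] = []
        hap2: List[Tuple[TruthVariant, int]] = []
        hi = 0
        for v in variants:
            g = sorted(v.genotype)
            if len(set(g)) == 1:  # homozygous: both haplotypes
                hap1.append((v, g[0]))
                hap2.append((v, g[0]))
            else:
                a, b = g[0], g[-1]
                if (mask >> hi) & 1:
                    a, b = b, a
                hap1.append((v, a))
                hap2.append((v, b))
                hi += 1
        s1 = _apply_variants(window, window_start, hap1)
        s2 = _apply_variants(window, window_start, hap2)
        if s1 is None or s2 is None:
            continue
        pairs.add((s1, s2) if s1 <= s2 else (s2, s1))
    if not pairs and variants:
        warnings.warn(
            f"cluster {cluster.contig}:{cluster.window_start}: all truth phase "
            "assignments inconsistent; skipped"
        )
    return sorted(pairs)


def match_candidates(
    cluster: Cluster, haplotype_pairs: Sequence[Tuple[str, str]], reference: ReferenceView
) -> Dict[Tuple[int, Tuple[str, int]], bool]:
    """Label every candidate at every hotspot of the cluster.

    Performs a prefix-pruned depth-first search over the tree whose
    branches select one candidate (or the implicit reference) per
    hotspot, with fixed reference segments in between.  A candidate is
    true iff some truth haplotype sequence is spelled by a path through
    it.  With no matching path at all, every candidate is labeled false
    and the cluster is flagged (possible truth/representation gap).
    """
    window = reference.fetch(cluster.contig, cluster.window_start, cluster.window_end)
    window_start = max(cluster.window_start, 0)
    targets: Set[str] = set()
    for a, b in haplotype_pairs:
        targets.add(a)
        targets.add(b)

    labels: Dict[Tuple[int, Tuple[str, int]], bool] = {}
    for site in cluster.sites:
        for cand in site.candidates:
            labels[(site.position, cand.key())] = False
    if not targets:
        return labels

    sites = sorted(cluster.sites, key=lambda s: s.position)
    any_match = False

    def options(site: SiteData) -> List[Tuple[Optional[Tuple[str, int]], str, int]]:
        """(candidate key or None for implicit ref, replacement, ref span)."""
        opts: List[Tuple[Optional[Tuple[str, int]], str, int]] = []
        has_ref = False
        for cand in site.candidates:
            opts.append((cand.key(), cand.allele_sequence, cand.ref_span))
            has_ref = has_ref or cand.is_reference
        if not has_ref:
            base = window[site.position - window_start]
            opts.append((None, base, 1))
        return opts

    def dfs(site_idx: int, cursor: int, prefix: str, used: Tuple) -> None:
        nonlocal any_match
        if not any(t.startswith(prefix) for t in targets):
            return
        if site_idx == len(sites):
            full = prefix + window[cursor - window_start :]
            if full in targets:
                any_match = True
                for pos, key in used:
                    if key is not None:
                        labels[(pos, key)] = True
            return
        site = sites[site_idx]
        if site.position < cursor:
            # consumed by a previous allele's reference span: no choice here
            dfs(site_idx + 1, cursor, prefix, used)
            return
        gap = window[cursor - window_start : site.position - window_start]
        for key, replacement, span in options(site):
            dfs(
                site_idx + 1,
                site.position + span,
                prefix + gap + replacement,
                used + ((site.position, key),),
            )

    dfs(0, window_start, "", ())
    if not any_match:
        logger.warning(
            "cluster %s:%d: no candidate path matches any truth haplotype",
            cluster.contig,
            cluster.window_start,
        )
    return labels


def label_sites(
    sites: Sequence[SiteData],
    truth: TruthSet,
    reference: ReferenceView,
    distance: int = DEFAULT_CLUSTER_DISTANCE,
) -> Dict[Tuple[str, int], Dict[Tuple[str, int], bool]]:
    """Labels for all sites: (contig, position) -> candidate key -> bool."""
    out: Dict[Tuple[str, int], Dict[Tuple[str, int], bool]] = {}
    for cluster in cluster_sites(sites, truth, distance):
        pairs = truth_haplotype_pairs(cluster, reference)
        labels = match_candidates(cluster, pairs, reference)
        for site in cluster.sites:
            site_labels = {
                key: labels[(site.position, key)]
                for key in (c.key() for c in site.candidates)
            }
            out[(site.contig, site.position)] = site_labels
    return out
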