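"""Exact genotype inference from per-allele truth probabilities.

The network emits, for each candidate allele j at a site, an independent
probability p_j that the allele is truly present.  A genotype at ploidy
p corresponds to an allele-status tuple E = (e_1 .. e_n), e_j in
{True, False}, with between 1 and p alleles marked True (the event space
Omega_p).  Because the alleles are conditionally independent given the
data, the log-likelihood of E factorizes as

    log P(E|D) = sum_j log( p_j if e_j else 1 - p_j )

and the ploidy-conditioned posterior renormalizes over Omega_p only.
The best event maximizes the unnormalized log-likelihood (the
normalizer is constant over Omega_p and cannot change the argmax).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import SiteData

#: probabilities are clamped into this open interval before logarithms
PROB_FLOOR = 1e-6
#: genotype quality cap, VCF convention
MAX_GQ = 99.0


def _clamp(p: float) -> float:
    return min(max(p, PROB_FLOOR), 1.0 - PROB_FLOOR)


@dataclass
class GenotypeEvent:
    """An allele-status tuple with its (unnormalized) log-likelihood."""

    statuses: Tuple[bool, ...]
    log_likelihood: float

    @property
    def true_indices(self) -> Tuple[int, ...]:
        return tuple(i for i, e in enumerate(self.statuses) if e)


@dataclass
class VariantCall:
    """One VCF-ready record (position still 0-based here)."""

    contig: str
    position: int
    ref_allele: str
    alt_alleles: List[str]
    genotype: Tuple[int, ...]  # VCF allele indices, 0 = ref
    genotype_quality: float
    allele_probabilities: Dict[str, float]


def event_log_likelihood(p: Sequence[float], statuses: Sequence[bool]) -> float:
    """log P(E|D) for one allele-status tuple under independent Bernoullis."""
    if len(p) != len(statuses):
        raise ValueError(f"{len(p)} probabilities but {len(statuses)} statuses")
    total = 0.0
    for pj, ej in zip(p, statuses):
        pj = _clamp(float(pj))
        total += math.log(pj if ej else 1.0 - pj)
    return total


def enumerate_event_space(n: int, ploidy: int = 2) -> List[Tuple[bool, ...]]:
    """All status tuples with between 1 and ``ploidy`` True entries.

    |Omega_p| = sum_{k=1..min(p,n)} C(n, k).  Order is deterministic:
    fewer True statuses first, then lexicographic by True-index tuple,
    which is also the tie-break order used by :func:`best_event`.
    """
    if n < 1:
        raise ValueError("need at least one candidate allele")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    events: List[Tuple[bool, ...]] = []
    for k in range(1, min(ploidy, n) + 1):
        for trues in itertools.combinations(range(n), k):
            statuses = tuple(i in trues for i in range(n))
            events.append(statuses)
    return events


def best_event(
    p: Sequence[float], ploidy: int = 2
) -> Tuple[GenotypeEvent, Dict[Tuple[bool, ...], float]]:
    """Argmax over Omega_p plus the normalized posterior over the space.

    Ties in log-likelihood are broken by the enumeration order (fewer
    True statuses first, then lexicographic), so output is deterministic.
    """
    events = enumerate_event_space(len(p), ploidy)
    logls = np.array([event_log_likelihood(p, e) for e in events])
    # log-sum-exp normalizer for the ploidy-conditioned posterior
    shift = logls.max()
    weights = np.exp(logls - shift)
    posterior = weights / weights.sum()
    best_idx = int(np.argmax(logls))  # first maximum = tie-break order
    event = GenotypeEvent(events[best_idx], float(logls[best_idx]))
    return event, {e: float(q) for e, q in zip(events, posterior)}


def emit_variant(
    site: SiteData,
    event: GenotypeEvent,
    posterior: Dict[Tuple[bool, ...], float],
    probabilities: Optional[Sequence[float]] = None,
    ploidy: int = 2,
) -> Optional[VariantCall]:
    """Turn the best event into a variant record, or None for hom-ref.

    The true-allele set V = {j : e_j} determines the genotype: a
    singleton V is homozygous (the allele fills all ploidy slots), a
    larger V is heterozygous.  V = {reference} produces no record.
    """
    n = len(site.candidates)
    if len(event.statuses) != n:
        raise ValueError("event does not match the site's candidate list")
    true_idx = list(event.true_indices)
    if not true_idx:
        raise ValueError("event has no true allele")
    chosen = [site.candidates[i] for i in true_idx]
    if all(c.is_reference for c in chosen):
        return None

    # REF spans the longest ref_span among chosen alleles plus reference;
    # shorter alleles are padded with the trailing reference sequence.
    span = max(max(c.ref_span for c in chosen), 1)
    ctx_off = site.position - site.context_start
    ref_allele = site.reference_context[ctx_off : ctx_off + span]
    if len(ref_allele) < span:
        raise ValueError("reference context too short for deletion allele")

    alts: List[str] = []
    gt_indices: List[int] = []
    for cand in chosen:
        if cand.is_reference:
            gt_indices.append(0)
            continue
        alt = cand.allele_sequence + ref_allele[cand.ref_span :]
        if alt == ref_allele:
            gt_indices.append(0)
            continue
        if alt not in alts:
            alts.append(alt)
        gt_indices.append(1 + alts.index(alt))
    if not alts:
        return None

    # homozygous iff V is a singleton: replicate the allele across ploidy
    if len(gt_indices) == 1:
        genotype = tuple(gt_indices * ploidy)
    else:
        genotype = tuple(sorted(gt_indices))

    perr = 1.0 - posterior[event.statuses]
    gq = MAX_GQ if perr <= 0.0 else min(MAX_GQ, -10.0 * math.log10(max(perr, 1e-10)))

    probs: Dict[str, float] = {}
    if probabilities is not None:
        for cand, pj in zip(site.candidates, probabilities):
            label = "REF" if cand.is_reference else cand.allele_sequence
            probs[f"{label}:{cand.ref_span}"] = float(pj)

    return VariantCall(
        contig=site.contig,
        position=site.position,
        ref_allele=ref_allele,
        alt_alleles=alts,
        genotype=genotype,
        genotype_quality=float(gq),
        allele_probabilities=probs,
    )
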