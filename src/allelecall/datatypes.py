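"""Core value types shared across the calling pipeline.

Coordinates are 0-based half-open everywhere inside the package; the VCF
writer converts to 1-based on output.  A candidate allele is represented
as the replacement string for a reference span anchored at the site:

* SNV at ``pos``:          ref_span=1, allele_sequence = alternate base
* insertion after ``pos``: ref_span=1, allele_sequence = anchor base + inserted bases
* deletion after ``pos``:  ref_span=1+len, allele_sequence = anchor base

The reference allele itself is ref_span=1 with the reference base, so
every candidate at a site shares the anchor base convention used by VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

#: aligned pair: (reference position or None, read base or None, base quality)
AlignedColumn = Tuple[Optional[int], Optional[str], int]


@dataclass
class ReadAlignment:
    """One aligned read restricted to a scanned window.

    ``aligned_pairs`` walks the alignment column by column: matches and
    mismatches carry both a reference position and a read base,
    insertions carry a read base with reference position ``None``, and
    deletions carry a reference position with read base ``None``.
    """

    read_id: str
    contig: str
    start: int
    aligned_pairs: Sequence[AlignedColumn]
    mapping_quality: int
    strand: str  # "+" or "-"
    haplotag: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        last = -1
        for refpos, base, qual in self.aligned_pairs:
            if refpos is not None:
                if refpos <= last:
                    raise ValueError(
                        f"reference positions not strictly increasing in {self.read_id}"
                    )
                last = refpos
            if not (0 <= qual <= 93):
                raise ValueError(f"base quality {qual} out of range in {self.read_id}")

    @property
    def end(self) -> int:
        """One past the last aligned reference position."""
        last = self.start
        for refpos, _, _ in self.aligned_pairs:
            if refpos is not None:
                last = refpos
        return last + 1

    def overlaps(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass
class Hotspot:
    """A reference site where non-reference allele support crosses threshold."""

    contig: str
    position: int
    allele_counts: dict  # allele key -> supporting-read count
    depth: int
    sources: dict = field(default_factory=dict)  # per-platform originals after merge

    def sort_key(self) -> Tuple[str, int]:
        return (self.contig, self.position)


@dataclass
class CandidateAllele:
    """An allele hypothesis at a site with the read ids that spell it."""

    allele_sequence: str
    ref_span: int
    is_reference: bool
    support: set = field(default_factory=set)

    def key(self) -> Tuple[str, int]:
        return (self.allele_sequence, self.ref_span)


@dataclass
class SiteData:
    """Everything the model needs at one hotspot."""

    contig: str
    position: int
    reference_context: str  # window of reference sequence
    context_start: int  # reference coordinate of reference_context[0]
    candidates: list  # list[CandidateAllele], reference candidate first if present
    reads: dict  # read_id -> ReadAlignment
    discarded: set = field(default_factory=set)  # read ids with ambiguous alignment

    @property
    def reference_base(self) -> str:
        return self.reference_context[self.position - self.context_start]

    def validate(self) -> None:
        keys = [c.key() for c in self.candidates]
        if len(keys) != len(set(keys)):
            raise ValueError("candidate alleles are not pairwise distinct")
        seen: set = set()
        for cand in self.candidates:
            if not cand.support:
                raise ValueError("candidate with empty support")
            if cand.support & seen:
                raise ValueError("support sets are not disjoint")
            seen |= cand.support
            missing = cand.support - set(self.reads)
            if missing:
                raise ValueError(f"supporting reads absent from site: {missing}")
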