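"""Fixed-length 8-bit read encodings.

Each read supporting a candidate allele becomes a (C, L) uint8 matrix
with L = 150 alignment columns and C channels:

    0  read base        A/C/G/T/other -> 25/75/125/175/0
    1  reference base   same code; pad for inserted columns
    2  base quality     min(q, 40) * 254 / 40
    3  mapping quality  min(m, 60) * 254 / 60
    4  strand           forward 170 / reverse 85
    5  site flag        255 on the columns of the analyzed site, else 0
    6  haplotag         none 0 / tag 1 -> 120 / tag 2 -> 240   (optional)

The column carrying the analyzed site is forced to index L // 2 = 75;
alignment columns fill outward until the read ends or the window edge,
and the remainder is padded with 0 in every channel.  Insertions occupy
their own columns (reference channel padded); deletion columns keep the
reference base with the read-base channel padded.  The encoding is a
pure function of its inputs, and every channel value is an exact uint8
code, so storage round-trips losslessly.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from .datatypes import CandidateAllele, ReadAlignment, SiteData

WINDOW = 150
CENTER = WINDOW // 2

BASE_CODE = {"A": 25, "C": 75, "G": 125, "T": 175}
PAD = 0
STRAND_CODE = {"+": 170, "-": 85}
FLAG_ON = 255
HAPLOTAG_CODE = {None: 0, 1: 120, 2: 240}


class EncodingError(ValueError):
    """The read cannot spell an allele at the site (caller discards it)."""


def _base_code(base: Optional[str]) -> int:
    if base is None:
        return PAD
    return BASE_CODE.get(base.upper(), PAD)


def _qual_code(q: int) -> int:
    return int(round(min(q, 40) * 254 / 40))


def _mapq_code(m: int) -> int:
    return int(round(min(m, 60) * 254 / 60))


def _haplotag_code(tag: Optional[int]) -> int:
    if tag in HAPLOTAG_CODE:
        return HAPLOTAG_CODE[tag]
    return HAPLOTAG_CODE[2] if tag and tag >= 2 else HAPLOTAG_CODE[1]


def encode_read(
    read: ReadAlignment,
    site: SiteData,
    haplotagged: bool = False,
) -> np.ndarray:
    """Encode one read at the site, centered on the analyzed position.

    Returns a (C, 150) uint8 array, C = 7 when ``haplotagged``.
    Raises :class:`EncodingError` when the read has no base at the site
    (deletion through the site, or no overlap).
    """
    position = site.position
    columns = list(read.aligned_pairs)

    # locate the anchor column: the aligned base at the analyzed position
    anchor = None
    for idx, (refpos, base, _q) in enumerate(columns):
        if refpos == position:
            if base is None:
                raise EncodingError(
                    f"read {read.read_id} deletes through the site at {position}"
                )
            anchor = idx
            break
    if anchor is None:
        raise EncodingError(f"read {read.read_id} has no aligned base at {position}")

    # columns of the analyzed site: the anchor plus any insertion directly after
    site_cols = {anchor}
    j = anchor + 1
    while j < len(columns) and columns[j][0] is None:
        site_cols.add(j)
        j += 1

    n_channels = 7 if haplotagged else 6
    enc = np.zeros((n_channels, WINDOW), dtype=np.uint8)
    strand = STRAND_CODE[read.strand]
    mapq = _mapq_code(read.mapping_quality)
    hap = _haplotag_code(read.haplotag)

    ctx = site.reference_context
    ctx_start = site.context_start

    for col_idx in range(anchor - CENTER, anchor + (WINDOW - CENTER)):
        out = col_idx - anchor + CENTER
        if not (0 <= col_idx < len(columns)):
            continue  # beyond the read: stays padded
        refpos, base, qual = columns[col_idx]
        if refpos is not None and ctx_start <= refpos < ctx_start + len(ctx):
            ref_base = ctx[refpos - ctx_start]
        else:
            ref_base = None
        enc[0, out] = _base_code(base)
        enc[1, out] = _base_code(ref_base)
        enc[2, out] = _qual_code(qual) if base is not None else PAD
        enc[3, out] = mapq
        enc[4, out] = strand
        enc[5, out] = FLAG_ON if col_idx in site_cols else 0
        if haplotagged:
            enc[6, out] = hap
    return enc


def encode_site(
    site: SiteData, haplotagged: bool = False
) -> Dict[Tuple[str, int], np.ndarray]:
    """One encoding stack per candidate: key -> (n_support, C, 150) uint8.

    Per-read encoding failures route the read out of the support set;
    candidates left with no encodable read are dropped.
    """
    out: Dict[Tuple[str, int], np.ndarray] = {}
    for cand in site.candidates:
        stacks: List[np.ndarray] = []
        for read_id in sorted(cand.support):
            try:
                stacks.append(encode_read(site.reads[read_id], site, haplotagged))
            except EncodingError:
                site.discarded.add(read_id)
        if stacks:
            out[cand.key()] = np.stack(stacks)
    return out
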