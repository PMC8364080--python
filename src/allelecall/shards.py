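"""Self-describing training-shard containers.

A shard holds, per site: the stacked uint8 read encodings, the
per-candidate index lists into that stack, the candidate keys, and
(for training data) the per-candidate truth labels.  Serialization is
an .npz archive with a JSON manifest under ``__doc__`` carrying a
format version, so shards are portable across package versions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import SiteData
from .encoding import encode_site

FORMAT_VERSION = 1


@dataclass
class ShardSite:
    """One site's encodings for a single platform."""

    contig: str
    position: int
    encodings: np.ndarray  # (N, C, L) uint8
    supports: List[List[int]]  # per-candidate indices into the stack
    candidate_keys: List[Tuple[str, int]]
    reference_key: Optional[Tuple[str, int]]
    labels: Optional[List[bool]] = None


@dataclass
class HybridShardSite:
    """One site's encodings for two platforms over a unified candidate list."""

    contig: str
    position: int
    encodings_a: np.ndarray
    supports_a: List[List[int]]
    encodings_b: np.ndarray
    supports_b: List[List[int]]
    candidate_keys: List[Tuple[str, int]]
    reference_key: Optional[Tuple[str, int]]
    labels: Optional[List[bool]] = None


def site_to_shard(
    site: SiteData,
    haplotagged: bool = False,
    labels: Optional[Dict[Tuple[str, int], bool]] = None,
) -> Optional[ShardSite]:
    """Encode a site into shard form; None when nothing is encodable."""
    stacks = encode_site(site, haplotagged=haplotagged)
    if not stacks:
        return None
    keys: List[Tuple[str, int]] = []
    supports: List[List[int]] = []
    blocks: List[np.ndarray] = []
    offset = 0
    ref_key = None
    for cand in site.candidates:
        key = cand.key()
        if key not in stacks:
            continue
        block = stacks[key]
        keys.append(key)
        supports.append(list(range(offset, offset + block.shape[0])))
        blocks.append(block)
        offset += block.shape[0]
        if cand.is_reference:
            ref_key = key
    if not keys:
        return None
    shard = ShardSite(
        contig=site.contig,
        position=site.position,
        encodings=np.concatenate(blocks, axis=0),
        supports=supports,
        candidate_keys=keys,
        reference_key=ref_key,
        labels=[bool(labels[k]) for k in keys] if labels is not None else None,
    )
    return shard


def save_shard(path: str, sites: Sequence[ShardSite]) -> None:
    manifest = {
        "format_version": FORMAT_VERSION,
        "n_sites": len(sites),
        "sites": [
            {
                "contig": s.contig,
                "position": s.position,
                "supports": s.supports,
                "candidate_keys": [list(k) for k in s.candidate_keys],
                "reference_key": list(s.reference_key) if s.reference_key else None,
                "labels": s.labels,
            }
            for s in sites
        ],
    }
    arrays = {f"enc{i}": s.encodings for i, s in enumerate(sites)}
    np.savez_compressed(
        path, __doc__=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8), **arrays
    )


def load_shard(path: str) -> List[ShardSite]:
    out: List[ShardSite] = []
    with np.load(path) as data:
        manifest = json.loads(bytes(data["__doc__"]).decode())
        if manifest.get("format_version") != FORMAT_VERSION:
            raise ValueError("unsupported shard format version")
        for i, doc in enumerate(manifest["sites"]):
            out.append(
                ShardSite(
                    contig=doc["contig"],
                    position=doc["position"],
                    encodings=data[f"enc{i}"],
                    supports=[list(s) for s in doc["supports"]],
                    candidate_keys=[tuple(k) for k in doc["candidate_keys"]],
                    reference_key=tuple(doc["reference_key"]) if doc["reference_key"] else None,
                    labels=doc["labels"],
                )
            )
    return out
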