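"""The read/allele-structured variant-calling network.

Single-platform flow at one site, with reads i and candidate alleles j:

    f_i = CNN1(R_i)                       read-level features (superposable)
    A_j = CNN2( sum_{k in S_j} f_k )      allele-level features
    M   = sum_j A_j                       site-level feature
    p_j = sigmoid( CNN3( 2 A_j - M ) )    per-allele truth probability

Note 2A_j - M = A_j - sum_{k != j} A_k: each allele's evidence is judged
only relative to the pooled evidence of all other alleles, and the
comparison network runs once per candidate (n invocations, not O(n^2)).

The dual-platform model runs one CNN1/CNN2 tower per platform and fuses
allele and site features with small two-layer mixing networks before the
shared comparison head:

    A_j^hyb = CNN4( concat(A_j^a, A_j^b) )
    M^hyb   = CNN5( concat(M^a, M^b) )
    p_j     = sigmoid( CNN3( 2 A_j^hyb - M^hyb ) )

All layers are weight-normalized; there are no batch statistics, so
evaluation is deterministic and independent of batch composition.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .nnet import (
    GlobalAvgPool,
    Layer,
    Parameter,
    ReLU,
    ResidualPair,
    Sequential,
    WNConv1d,
    WNLinear,
    sigmoid,
)

WINDOW = 150  # encoding length; the analyzed site sits at column WINDOW // 2


class ConfigurationError(ValueError):
    """Model/input mismatch (e.g. 6-channel input into a 7-channel model)."""


@dataclass
class ModelSpec:
    """Architecture hyperparameters; parameter count is a pure function of this.

    ``entry_channels`` is the width of the very first convolution, so an
    extra input channel (the haplotag) costs exactly
    ``entry_channels * kernel`` additional weights and nothing else.
    """

    in_channels: int = 6
    entry_channels: int = 16
    width: int = 48
    kernel: int = 3
    stage1_pairs: int = 3
    stage2_pairs: int = 3
    stage3_pairs: int = 3
    head_hidden: int = 48
    window: int = WINDOW

    @classmethod
    def reduced(cls, in_channels: int = 6) -> "ModelSpec":
        """Desk-scale spec for miniature training runs."""
        return cls(
            in_channels=in_channels,
            entry_channels=16,
            width=16,
            kernel=3,
            stage1_pairs=1,
            stage2_pairs=1,
            stage3_pairs=1,
            head_hidden=16,
        )


def _tower(spec: ModelSpec, rng: np.random.Generator) -> Tuple[Sequential, Sequential]:
    """Stage-1 (reads) and stage-2 (alleles) networks for one platform."""
    stage1: List[Layer] = [
        WNConv1d(spec.in_channels, spec.entry_channels, spec.kernel, rng),
        ReLU(),
        WNConv1d(spec.entry_channels, spec.width, spec.kernel, rng),
        ReLU(),
    ]
    stage1 += [ResidualPair(spec.width, spec.kernel, rng) for _ in range(spec.stage1_pairs)]
    stage2 = [ResidualPair(spec.width, spec.kernel, rng) for _ in range(spec.stage2_pairs)]
    return Sequential(stage1), Sequential(stage2)


def _head(spec: ModelSpec, rng: np.random.Generator) -> Sequential:
    """Stage-3 comparison network: conv pairs, pooling, 2-layer classifier."""
    layers: List[Layer] = [ResidualPair(spec.width, spec.kernel, rng) for _ in range(spec.stage3_pairs)]
    layers += [
        GlobalAvgPool(),
        WNLinear(spec.width, spec.head_hidden, rng),
        ReLU(),
        WNLinear(spec.head_hidden, 1, rng),
    ]
    return Sequential(layers)


def _as_batch(x: np.ndarray) -> np.ndarray:
    if x.ndim == 2:
        return x[None]
    return x


def _normalize(enc: np.ndarray) -> np.ndarray:
    """8-bit encodings to floats in [0, 1]."""
    return enc.astype(np.float64) / 255.0


def superpose(features: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise sum of read-level features (permutation-invariant)."""
    feats = list(features)
    if not feats:
        raise ValueError("cannot superpose an empty feature list")
    out = np.array(feats[0], dtype=np.float64, copy=True)
    for f in feats[1:]:
        if f.shape != out.shape:
            raise ValueError("superposable features must share a shape")
        out += f
    return out


def site_feature(allele_features: Sequence[np.ndarray]) -> np.ndarray:
    """M = sum_j A_j, pooling the evidence from all candidates."""
    return superpose(allele_features)


class SinglePlatformModel:
    """CNN1/CNN2/CNN3 with the superposition wiring between them."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.cnn1, self.cnn2 = _tower(spec, rng)
        self.cnn3 = _head(spec, rng)
        self.stage3_invocations = 0
        self._cache: Optional[dict] = None

    # ---- parameter plumbing -------------------------------------------------
    def parameters(self) -> Dict[str, Parameter]:
        out: Dict[str, Parameter] = {}
        for prefix, net in (("cnn1", self.cnn1), ("cnn2", self.cnn2), ("cnn3", self.cnn3)):
            for name, p in net.parameters().items():
                out[f"{prefix}.{name}"] = p
        return out

    def count_parameters(self) -> int:
        return sum(int(p.value.size) for p in self.parameters().values())

    # ---- stage operations ---------------------------------------------------
    def _check_channels(self, enc: np.ndarray) -> None:
        if enc.shape[-2] != self.spec.in_channels:
            raise ConfigurationError(
                f"encoding has {enc.shape[-2]} channels, model expects {self.spec.in_channels}"
            )

    def read_cnn(self, encodings: np.ndarray) -> np.ndarray:
        """f_i = CNN1(R_i).  Accepts (C, L) or a batch (N, C, L)."""
        batch = _as_batch(np.asarray(encodings))
        self._check_channels(batch)
        out = self.cnn1.forward(_normalize(batch))
        return out[0] if np.asarray(encodings).ndim == 2 else out

    def allele_cnn(self, summed: np.ndarray) -> np.ndarray:
        """A_j = CNN2(sum of supporting read features)."""
        batch = _as_batch(np.asarray(summed, dtype=np.float64))
        out = self.cnn2.forward(batch)
        return out[0] if np.asarray(summed).ndim == 2 else out

    def compare_allele(self, allele_feature: np.ndarray, site_feat: np.ndarray) -> float:
        """p_j = sigmoid(CNN3(2 A_j - M)); one invocation per candidate."""
        if allele_feature.shape != site_feat.shape:
            raise ValueError("allele and site features must share a shape")
        logit = self.cnn3.forward((2.0 * allele_feature - site_feat)[None])
        self.stage3_invocations += 1
        return float(sigmoid(logit)[0, 0])

    # ---- full site pass (batched, with backward for training) --------------
    def site_forward(
        self, encodings: np.ndarray, supports: Sequence[Sequence[int]]
    ) -> np.ndarray:
        """Per-allele probabilities for one site.

        ``encodings``: (N_reads, C, L) uint8.  ``supports``: per-candidate
        index lists into the read axis.  Returns p of shape (n_candidates,).
        """
        enc = np.asarray(encodings)
        self._check_channels(enc)
        if not supports or any(len(s) == 0 for s in supports):
            raise ValueError("every candidate needs non-empty support")
        f = self.cnn1.forward(_normalize(enc))  # (N, W, L)
        summed = np.stack([f[list(s)].sum(axis=0) for s in supports])
        A = self.cnn2.forward(summed)  # (J, W, L)
        M = A.sum(axis=0)
        logits = self.cnn3.forward(2.0 * A - M[None])[:, 0]
        self.stage3_invocations += len(supports)
        self._cache = {"supports": [list(s) for s in supports], "n_reads": enc.shape[0]}
        return sigmoid(logits)

    def site_backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logit_j)."""
        if self._cache is None:
            raise RuntimeError("site_backward called before site_forward")
        supports = self._cache["supports"]
        dx = self.cnn3.backward(np.asarray(dlogits, dtype=np.float64)[:, None])
        # x_j = 2 A_j - sum_k A_k  =>  dA_k = 2 dx_k - sum_j dx_j
        dA = 2.0 * dx - dx.sum(axis=0, keepdims=True)
        ds = self.cnn2.backward(dA)
        df = np.zeros((self._cache["n_reads"],) + ds.shape[1:])
        for j, sup in enumerate(supports):
            for i in sup:
                df[i] += ds[j]
        self.cnn1.backward(df)


class HybridFusion:
    """A small two-layer mixing network: concat channels, return one width."""

    def __init__(self, width: int, kernel: int, rng: np.random.Generator):
        self.net = Sequential(
            [
                WNConv1d(2 * width, width, kernel, rng),
                ReLU(),
                WNConv1d(width, width, kernel, rng),
            ]
        )

    def parameters(self) -> Dict[str, Parameter]:
        return self.net.parameters()

    def forward(self, feat_a: np.ndarray, feat_b: np.ndarray) -> np.ndarray:
        a = _as_batch(np.asarray(feat_a, dtype=np.float64))
        b = _as_batch(np.asarray(feat_b, dtype=np.float64))
        if a.shape != b.shape:
            raise ValueError("fusion inputs must share a shape")
        out = self.net.forward(np.concatenate([a, b], axis=1))
        return out[0] if np.asarray(feat_a).ndim == 2 else out

    def backward(self, grad: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        g = self.net.backward(grad)
        half = g.shape[1] // 2
        return g[:, :half], g[:, half:]


class HybridModel:
    """Two platform towers, fusion networks, shared comparison head."""

    def __init__(self, spec_a: ModelSpec, spec_b: ModelSpec, seed: int = 0):
        if spec_a.width != spec_b.width or spec_a.kernel != spec_b.kernel:
            raise ConfigurationError("platform towers must agree on width and kernel")
        self.spec_a = spec_a
        self.spec_b = spec_b
        rng = np.random.default_rng(seed)
        self.cnn1_a, self.cnn2_a = _tower(spec_a, rng)
        self.cnn1_b, self.cnn2_b = _tower(spec_b, rng)
        self.fuse_allele_net = HybridFusion(spec_a.width, spec_a.kernel, rng)
        self.fuse_site_net = HybridFusion(spec_a.width, spec_a.kernel, rng)
        self.cnn3 = _head(spec_a, rng)
        self.stage3_invocations = 0
        self._cache: Optional[dict] = None

    def parameters(self) -> Dict[str, Parameter]:
        out: Dict[str, Parameter] = {}
        nets = [
            ("cnn1_a", self.cnn1_a),
            ("cnn2_a", self.cnn2_a),
            ("cnn1_b", self.cnn1_b),
            ("cnn2_b", self.cnn2_b),
            ("cnn4", self.fuse_allele_net.net),
            ("cnn5", self.fuse_site_net.net),
            ("cnn3", self.cnn3),
        ]
        for prefix, net in nets:
            for name, p in net.parameters().items():
                out[f"{prefix}.{name}"] = p
        return out

    def count_parameters(self) -> int:
        return sum(int(p.value.size) for p in self.parameters().values())

    def fuse_allele(self, feat_a: np.ndarray, feat_b: np.ndarray) -> np.ndarray:
        return self.fuse_allele_net.forward(feat_a, feat_b)

    def fuse_site(self, feat_a: np.ndarray, feat_b: np.ndarray) -> np.ndarray:
        return self.fuse_site_net.forward(feat_a, feat_b)

    @staticmethod
    def _platform_features(
        cnn1: Sequential,
        cnn2: Sequential,
        encodings: np.ndarray,
        supports: Sequence[Sequence[int]],
        width: int,
        window: int,
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Allele features with zero substituted for unsupported candidates."""
        n_cand = len(supports)
        have_reads = encodings.shape[0] > 0 and any(len(s) for s in supports)
        if not have_reads:
            A = np.zeros((n_cand, width, window))
            return A, A.copy(), np.zeros(0)
        f = cnn1.forward(_normalize(encodings))
        summed = np.stack(
            [
                f[list(s)].sum(axis=0) if len(s) else np.zeros(f.shape[1:])
                for s in supports
            ]
        )
        A = cnn2.forward(summed)
        mask = np.array([len(s) > 0 for s in supports], dtype=bool)
        A_masked = np.where(mask[:, None, None], A, 0.0)
        return A, A_masked, mask

    def site_forward(
        self,
        encodings_a: np.ndarray,
        supports_a: Sequence[Sequence[int]],
        encodings_b: np.ndarray,
        supports_b: Sequence[Sequence[int]],
    ) -> np.ndarray:
        """Per-allele probabilities over the unified candidate list.

        ``supports_a``/``supports_b`` must be aligned to the same unified
        candidate order; a candidate unseen on one platform carries an
        empty support list there and contributes a zero feature map.
        """
        if len(supports_a) != len(supports_b):
            raise ValueError("unified candidate lists must have equal length")
        if len(supports_a) == 0:
            raise ValueError("site has no candidates")
        if encodings_a.shape[0] == 0 and encodings_b.shape[0] == 0:
            raise ValueError("site has no reads on either platform")
        enc_a = np.asarray(encodings_a)
        enc_b = np.asarray(encodings_b)
        if enc_a.shape[0] and enc_a.shape[-2] != self.spec_a.in_channels:
            raise ConfigurationError("platform-A encoding channel mismatch")
        if enc_b.shape[0] and enc_b.shape[-2] != self.spec_b.in_channels:
            raise ConfigurationError("platform-B encoding channel mismatch")

        _, A_a, mask_a = self._platform_features(
            self.cnn1_a, self.cnn2_a, enc_a, supports_a, self.spec_a.width, self.spec_a.window
        )
        _, A_b, mask_b = self._platform_features(
            self.cnn1_b, self.cnn2_b, enc_b, supports_b, self.spec_b.width, self.spec_b.window
        )
        M_a = A_a.sum(axis=0)
        M_b = A_b.sum(axis=0)
        A_h = self.fuse_allele_net.forward(A_a, np.broadcast_to(A_b, A_a.shape).copy())
        M_h = self.fuse_site_net.forward(M_a, M_b)
        logits = self.cnn3.forward(2.0 * A_h - M_h[None])[:, 0]
        self.stage3_invocations += len(supports_a)
        self._cache = {
            "supports_a": [list(s) for s in supports_a],
            "supports_b": [list(s) for s in supports_b],
            "n_a": enc_a.shape[0],
            "n_b": enc_b.shape[0],
            "mask_a": mask_a,
            "mask_b": mask_b,
        }
        return sigmoid(logits)

    def site_backward(self, dlogits: np.ndarray) -> None:
        if self._cache is None:
            raise RuntimeError("site_backward called before site_forward")
        c = self._cache
        dx = self.cnn3.backward(np.asarray(dlogits, dtype=np.float64)[:, None])
        dA_h = 2.0 * dx
        dM_h = -dx.sum(axis=0)
        dM_a, dM_b = self.fuse_site_net.backward(dM_h[None])
        dA_a, dA_b = self.fuse_allele_net.backward(dA_h)
        dA_a = dA_a + dM_a  # M_a = sum_j A_j^a broadcasts into every allele
        dA_b = dA_b + dM_b
        for cnn1, cnn2, dA, mask, supports, n_reads in (
            (self.cnn1_a, self.cnn2_a, dA_a, c["mask_a"], c["supports_a"], c["n_a"]),
            (self.cnn1_b, self.cnn2_b, dA_b, c["mask_b"], c["supports_b"], c["n_b"]),
        ):
            if n_reads == 0 or not np.any(mask):
                continue
            dA = np.where(np.asarray(mask)[:, None, None], dA, 0.0)
            ds = cnn2.backward(dA)
            df = np.zeros((n_reads,) + ds.shape[1:])
            for j, sup in enumerate(supports):
                for i in sup:
                    df[i] += ds[j]
            cnn1.backward(df)


# ---- checkpoints -----------------------------------------------------------


def save_checkpoint(path: str, model, metadata: Optional[dict] = None) -> None:
    """Self-describing container: spec(s) + parameter tensors + metadata."""
    if isinstance(model, HybridModel):
        spec_doc = {"kind": "hybrid", "spec_a": asdict(model.spec_a), "spec_b": asdict(model.spec_b)}
    else:
        spec_doc = {"kind": "single", "spec": asdict(model.spec)}
    doc = {"format_version": 1, "model": spec_doc, "metadata": metadata or {}}
    arrays = {f"param:{k}": p.value for k, p in model.parameters().items()}
    np.savez(path, __doc__=np.frombuffer(json.dumps(doc).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str, seed: int = 0):
    with np.load(path) as data:
        doc = json.loads(bytes(data["__doc__"]).decode())
        spec_doc = doc["model"]
        if spec_doc["kind"] == "hybrid":
            model = HybridModel(
                ModelSpec(**spec_doc["spec_a"]), ModelSpec(**spec_doc["spec_b"]), seed=seed
            )
        else:
            model = SinglePlatformModel(ModelSpec(**spec_doc["spec"]), seed=seed)
        params = model.parameters()
        for key in data.files:
            if key.startswith("param:"):
                params[key[len("param:"):]].value[...] = data[key]
    return model, doc.get("metadata", {})
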