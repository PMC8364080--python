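"""Miniature training loop for the calling network.

The loss is per-allele binary cross-entropy on the clamped
probabilities — the network's output is exactly the Bernoulli
probability that a candidate allele is truly present, so cross-entropy
is the canonical objective.  A batch's loss is the support-weighted
mean of per-site losses (each site contributes one term per candidate
allele), which makes heterogeneous batches well defined.

Optimization uses Adam (default LR 1e-3, no schedule); one epoch is a
complete pass over the shard sites in a seeded shuffled order; the
best checkpoint is the epoch with the highest held-out per-allele
accuracy.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .genotyping import best_event
from .model import HybridModel, save_checkpoint
from .nnet import Adam

logger = logging.getLogger(__name__)

PROB_EPS = 1e-6


@dataclass
class TrainingConfig:
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_sites: int = 8
    seed: int = 0
    positive_weight: float = 1.0
    checkpoint_dir: Optional[str] = None


def _site_forward(model, site):
    if isinstance(model, HybridModel):
        return model.site_forward(
            site.encodings_a, site.supports_a, site.encodings_b, site.supports_b
        )
    return model.site_forward(site.encodings, site.supports)


def site_loss(p: np.ndarray, labels: Sequence[bool], positive_weight: float = 1.0) -> Tuple[float, np.ndarray]:
    """Mean per-allele BCE and d(loss)/d(logit) for one site."""
    y = np.asarray(labels, dtype=np.float64)
    p = np.clip(np.asarray(p), PROB_EPS, 1.0 - PROB_EPS)
    w = np.where(y > 0.5, positive_weight, 1.0)
    losses = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)) * w
    dlogit = (p - y) * w  # sigmoid + BCE composite gradient, per allele
    return float(losses.mean()), dlogit / len(y)


def batch_loss(model, sites: Sequence, positive_weight: float = 1.0) -> float:
    """Support-weighted mean of per-site losses (evaluation only)."""
    total = 0.0
    weight = 0.0
    for site in sites:
        p = _site_forward(model, site)
        loss, _ = site_loss(p, site.labels, positive_weight)
        n = len(site.labels)
        total += loss * n
        weight += n
    return total / max(weight, 1.0)


@dataclass
class EpochStats:
    epoch: int
    train_loss: float
    val_accuracy: float
    val_concordance: float


def evaluate(
    model, sites: Sequence, ploidy: int = 2
) -> Tuple[float, float]:
    """Per-allele accuracy and per-site genotype concordance.

    Concordance compares the set of alleles the likelihood maximizer
    selects against the labeled true-allele set, over sites whose label
    count is a feasible genotype (1..ploidy true alleles).
    """
    if not sites:
        raise ValueError("cannot evaluate on an empty shard")
    correct = 0
    total = 0
    site_hits = 0
    site_total = 0
    for site in sites:
        p = _site_forward(model, site)
        y = np.asarray(site.labels, dtype=bool)
        correct += int(((p >= 0.5) == y).sum())
        total += len(y)
        n_true = int(y.sum())
        if 1 <= n_true <= ploidy:
            event, _ = best_event(p, ploidy)
            site_total += 1
            if set(event.true_indices) == set(np.flatnonzero(y)):
                site_hits += 1
    accuracy = correct / total
    concordance = site_hits / site_total if site_total else float("nan")
    return accuracy, concordance


def train(
    model,
    train_sites: Sequence,
    config: TrainingConfig,
    val_sites: Optional[Sequence] = None,
) -> List[EpochStats]:
    """Train in place; returns per-epoch stats with the best epoch selected.

    Sites without labels are rejected.  When ``checkpoint_dir`` is set,
    one checkpoint per epoch plus a ``best.npz`` selection is written.
    """
    for site in train_sites:
        if site.labels is None:
            raise ValueError("training shards must carry labels")
    if not train_sites:
        raise ValueError("no training sites")
    val = list(val_sites) if val_sites else list(train_sites)

    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: List[EpochStats] = []
    best: Tuple[float, int] = (-1.0, -1)

    for epoch in range(config.epochs):
        order = rng.permutation(len(train_sites))
        epoch_loss = 0.0
        epoch_weight = 0.0
        for batch_start in range(0, len(order), config.batch_sites):
            batch = [train_sites[i] for i in order[batch_start : batch_start + config.batch_sites]]
            opt.zero_grad()
            weights = [len(s.labels) for s in batch]
            wsum = float(sum(weights))
            for site, w in zip(batch, weights):
                p = _site_forward(model, site)
                loss, dlogit = site_loss(p, site.labels, config.positive_weight)
                model.site_backward(dlogit * (w / wsum))
                epoch_loss += loss * w
                epoch_weight += w
            opt.step()
        acc, conc = evaluate(model, val)
        stats = EpochStats(epoch, epoch_loss / epoch_weight, acc, conc)
        history.append(stats)
        logger.info(
            "epoch %d: train_loss=%.4f val_acc=%.4f val_concordance=%.4f",
            epoch, stats.train_loss, acc, conc,
        )
        if config.checkpoint_dir:
            os.makedirs(config.checkpoint_dir, exist_ok=True)
            save_checkpoint(
                os.path.join(config.checkpoint_dir, f"epoch{epoch:03d}.npz"),
                model,
                metadata={"epoch": epoch, "seed": config.seed, "val_accuracy": acc},
            )
        if acc > best[0]:
            best = (acc, epoch)
            if config.checkpoint_dir:
                save_checkpoint(
                    os.path.join(config.checkpoint_dir, "best.npz"),
                    model,
                    metadata={"epoch": epoch, "seed": config.seed, "val_accuracy": acc},
                )
    logger.info("best epoch %d (val_acc=%.4f)", best[1], best[0])
    return history
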