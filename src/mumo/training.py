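"""Loss assembly, training loop, checkpoint selection and weight averaging.

Training minimises class-weighted cross-entropy on responder labels plus
``lambda_align`` times the contrastive alignment loss (computed over the
batch members with both modalities present). One checkpoint is recorded per
epoch with its validation AUC; the final model averages the weights of the
``top_k`` best-performing checkpoints (ties broken toward earlier epochs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .evaluation import auc
from .fusion import FusionConfig, MuMoNet, PatientFeatures, alignment_loss
from .nn import Adam, Tensor, stack

__all__ = ["TrainConfig", "Checkpoint", "total_loss", "train_model",
           "average_top_k", "risk_scores"]


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 16
    lr: float = 1e-3
    lambda_align: float = 0.1
    seed: int = 0
    top_k: int = 7
    val_metric: str = "auc"

    def validate(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.lambda_align < 0:
            raise ValueError("lambda_align must be >= 0")
        if self.val_metric != "auc":
            raise ValueError("only the AUC validation metric is supported")


@dataclass
class Checkpoint:
    """Full parameter snapshot with its validation metric."""

    state: dict[str, np.ndarray]
    epoch: int
    val_metric: float


def total_loss(probs: Sequence[Tensor], labels: Sequence[int],
               align: Tensor | float = 0.0, lambda_align: float = 0.0,
               class_weights: tuple[float, float] = (1.0, 1.0)) -> Tensor:
    """Weighted cross-entropy plus ``lambda_align`` times the alignment loss.

    ``probs`` are per-sample (non-response, response) probability pairs;
    labels are 1 for responders, 0 for non-responders. ``class_weights``
    is (weight of non-responders, weight of responders).
    """
    eps = 1e-12
    terms = []
    for pr, y in zip(probs, labels):
        w = class_weights[int(y)]
        terms.append((pr[int(y)] + eps).log() * (-w))
    ce = stack(terms).mean() if terms else Tensor(0.0)
    if isinstance(align, (int, float)):
        align = Tensor(float(align))
    return ce + align * lambda_align


def risk_scores(net: MuMoNet, samples: Sequence[PatientFeatures]) -> np.ndarray:
    """Non-response probability per sample (the model's risk score)."""
    return np.array([net.forward(s).risk_score for s in samples])


def _val_auc(net: MuMoNet, val: Sequence[PatientFeatures]) -> float:
    labeled = [s for s in val if s.label is not None]
    scores = risk_scores(net, labeled)
    y_nonresp = np.array([1 - s.label for s in labeled])
    return auc(scores, y_nonresp)


def train_model(train: Sequence[PatientFeatures],
                val: Sequence[PatientFeatures],
                fusion_config: FusionConfig,
                config: TrainConfig) -> tuple[MuMoNet, list[Checkpoint], list[dict]]:
    """Train a fusion network; returns (net, per-epoch checkpoints, history).

    Excluded (unlabelled) patients must already be removed from ``train``;
    both splits must contain both classes. The loss trajectory is
    reproducible for a fixed seed on fixed data (up to floating-point
    associativity of the underlying BLAS).
    """
    config.validate()
    train = [s for s in train if s.label is not None]
    for name, split in (("train", train), ("validation",
                                           [s for s in val if s.label is not None])):
        ys = {s.label for s in split}
        if ys != {0, 1}:
            raise ValueError(f"{name} split must contain both classes, has {ys}")

    labels = np.array([s.label for s in train])
    n_resp = labels.sum()
    n_non = len(labels) - n_resp
    # inverse-frequency class weights, normalised to mean 1
    w_non = len(labels) / (2.0 * n_non)
    w_resp = len(labels) / (2.0 * n_resp)
    class_weights = (w_non, w_resp)

    net = MuMoNet(fusion_config)
    opt = Adam(net.params, lr=config.lr)
    rng = np.random.default_rng(config.seed)
    checkpoints: list[Checkpoint] = []
    history: list[dict] = []

    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        ep_loss = ep_align = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [train[i] for i in idx]
            outs = [net.forward(s) for s in batch]
            pairs = [(o.path_agnostic, o.rad_agnostic) for o in outs
                     if o.eligible_for_alignment]
            align = alignment_loss(pairs, fusion_config.temperature) \
                if config.lambda_align > 0 else Tensor(0.0)
            loss = total_loss([o.probs for o in outs],
                              [s.label for s in batch],
                              align, config.lambda_align, class_weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.item()
            ep_align += float(align.item()) if hasattr(align, "item") else 0.0
            n_batches += 1
        val_auc = _val_auc(net, val)
        checkpoints.append(Checkpoint(state=net.state_dict(), epoch=epoch,
                                      val_metric=val_auc))
        history.append({"epoch": epoch, "loss": ep_loss / n_batches,
                        "align": ep_align / n_batches, "val_auc": val_auc})
    return net, checkpoints, history


def average_top_k(checkpoints: Sequence[Checkpoint], k: int
                  ) -> dict[str, np.ndarray]:
    """Parameter-wise mean of the k checkpoints with the best validation
    metric (ties toward the earlier epoch). Fewer than k checkpoints are
    averaged in full, with a warning."""
    if not checkpoints:
        raise ValueError("average_top_k: no checkpoints")
    ranked = sorted(checkpoints, key=lambda c: (-c.val_metric, c.epoch))
    if len(ranked) < k:
        warnings.warn(f"only {len(ranked)} checkpoints available; averaging all")
    chosen = ranked[:k]
    keys = chosen[0].state.keys()
    for c in chosen[1:]:
        if c.state.keys() != keys:
            raise ValueError("checkpoints have incompatible parameter sets")
    out = {}
    for key in keys:
        shapes = {c.state[key].shape for c in chosen}
        if len(shapes) > 1:
            raise ValueError(f"parameter {key!r} has incompatible shapes {shapes}")
        out[key] = np.mean([c.state[key] for c in chosen], axis=0)
    return out
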