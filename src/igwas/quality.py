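"""Image quality control.

A small convolutional classifier maps an RGB fundus image to a quality
score in [0, 1] (0 bad, 1 good). Images scoring above 0.5 count as
usable; the contrastive phenotyper trains only on the top-quality
subset (score > 0.95 by default), mirroring the common practice of
trading cohort size for image quality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .config import QualityConfig, substream
from .improc import prep_batch, random_rotate

__all__ = [
    "QualityModel", "QualityReport",
    "train_quality_scorer", "score_quality",
    "select_top_quality", "classification_metrics",
]


@dataclass
class QualityModel:
    net: nn.Sequential
    input_hw: int
    epochs_trained: int
    seed: int


@dataclass
class QualityReport:
    auroc: float
    ppv: float
    npv: float
    sensitivity: float
    specificity: float


def _build_net(cfg: QualityConfig, rng: np.random.Generator) -> nn.Sequential:
    hw = cfg.input_hw
    feat = (hw // 4) ** 2 * 16
    return nn.Sequential(
        nn.Conv3x3(3, 8, rng), nn.ReLU(), nn.AvgPool2(),
        nn.Conv3x3(8, 16, rng), nn.ReLU(), nn.AvgPool2(),
        nn.Flatten(),
        nn.Dense(feat, cfg.hidden, rng), nn.ReLU(),
        nn.Dense(cfg.hidden, 1, rng),
    )


def train_quality_scorer(corpus, epochs: int | None = None, seed: int | None = None,
                         cfg: QualityConfig | None = None) -> QualityModel:
    """Train the quality scorer with cross-entropy and early stopping.

    The corpus is split 80/20 (seeded) into train/validation; training
    stops when validation loss has not improved for ``cfg.patience``
    epochs and the best-validation parameters are retained.
    """
    cfg = cfg or QualityConfig()
    if epochs is not None:
        cfg.epochs = epochs
    if seed is not None:
        cfg.seed = seed

    labels = np.array([1.0 if im.quality_label == "good" else 0.0 for im in corpus])
    if len(np.unique(labels)) < 2 and cfg.epochs > 0:
        raise ValueError("quality corpus must contain both good and bad images")

    rng = substream(cfg.seed, "quality", "init")
    net = _build_net(cfg, rng)
    model = QualityModel(net=net, input_hw=cfg.input_hw,
                         epochs_trained=0, seed=cfg.seed)
    if cfg.epochs == 0:
        return model

    x = prep_batch(corpus, cfg.input_hw)
    split_rng = substream(cfg.seed, "quality", "split")
    order = split_rng.permutation(len(corpus))
    n_val = max(1, int(round(cfg.val_fraction * len(corpus))))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    xv, yv = x[val_idx], labels[val_idx]

    opt = nn.Adam(net.params, lr=cfg.lr)
    aug_rng = substream(cfg.seed, "quality", "augment")
    best_val, best_state, since_best = np.inf, net.get_state(), 0
    for epoch in range(cfg.epochs):
        perm = aug_rng.permutation(tr_idx)
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb = random_rotate(x[idx], 10.0, aug_rng)
            logits = net.forward(xb)[:, 0]
            _, dlogit = nn.binary_xent(logits, labels[idx])
            net.backward(dlogit[:, None])
            opt.step(net.grads)
        val_loss, _ = nn.binary_xent(net.forward(xv)[:, 0], yv)
        if val_loss < best_val - 1e-6:
            best_val, best_state, since_best = val_loss, net.get_state(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
        model.epochs_trained = epoch + 1
    net.set_state(best_state)
    return model


def score_quality(model: QualityModel, images) -> np.ndarray:
    """Score each image in [0, 1]; order-preserving."""
    for i, img in enumerate(images):
        px = np.asarray(img.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"malformed image at index {i}: shape {px.shape}")
    x = prep_batch(images, model.input_hw)
    return nn.sigmoid(model.net.forward(x)[:, 0])


def select_top_quality(images, scores, score_floor: float = 0.95,
                       max_n: int | None = None) -> list:
    """Images with score > score_floor, best first, truncated to max_n.

    Ties keep input order (stable sort), so the selection is invariant
    to permutations of the input up to that tie-break.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(images):
        raise ValueError("scores not aligned with images")
    keep = np.flatnonzero(scores > score_floor)
    order = keep[np.argsort(-scores[keep], kind="stable")]
    if max_n is not None:
        order = order[:max_n]
    return [images[i] for i in order]


def classification_metrics(scores, labels, threshold: float = 0.5) -> QualityReport:
    """AUROC (rank statistic, ties count half) and 2x2-table metrics.

    Positive class is good quality (label 1). PPV/NPV/sensitivity/
    specificity are computed from the confusion table at ``threshold``;
    empty denominators yield nan with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: only one class present")
    auroc = float(roc_auc_score(labels, scores))

    pred = scores > threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (empty denominator)")
            return float("nan")
        return num / den

    return QualityReport(
        auroc=auroc,
        ppv=_ratio(tp, tp + fp, "PPV"),
        npv=_ratio(tn, tn + fn, "NPV"),
        sensitivity=_ratio(tp, tp + fn, "sensitivity"),
        specificity=_ratio(tn, tn + fp, "specificity"),
    )
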