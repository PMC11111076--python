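"""Self-supervised contrastive phenotyper.

Both eyes of one subject are treated as two views of the same class: a
small convolutional encoder maps each image to a unit vector in R^d,
and an additive-angular-margin (ArcFace-style) softmax over per-subject
template vectors pulls a subject's images toward their template while
pushing them at least a margin ``m`` (radians) away from every other
subject's template. The scale ``s`` is an inverse temperature on the
cosine logits. The per-coordinate values of the embedding are the
learned endophenotypes used downstream as GWAS traits.

Loss, per sample i with target subject t(i):

    L_i = -log  exp(s cos(theta_i + m)) /
                [exp(s cos(theta_i + m)) + sum_{j != t(i)} exp(s cos theta_j)]

where theta_i is the angle between embedding i and its own template and
theta_j the angle to subject j's template. With m = 0 this is plain
softmax cross-entropy over cosine logits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from scipy.spatial.distance import jensenshannon

from . import nn
from .config import ArcFaceConfig, substream
from .improc import prep_batch, random_rotate

__all__ = [
    "TemplateBank", "EmbeddingMatrix", "PairStats", "PhenotyperModel",
    "arcface_loss", "train_phenotyper", "embed_images", "pair_similarity_stats",
]

N_GRADES = 5
JACCARD_BINS = 80


def _unit_rows(x: np.ndarray, what: str, warn: bool = True) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if warn and not np.allclose(norms, 1.0, atol=1e-6):
        warnings.warn(f"{what} not unit-normalized; normalizing internally")
    return x / np.maximum(norms, 1e-12)


@dataclass
class TemplateBank:
    """One unit-length template vector per training subject."""

    subject_ids: list
    vectors: np.ndarray     # (n_subjects, d), unit rows

    def __post_init__(self):
        self.vectors = _unit_rows(np.asarray(self.vectors, dtype=float),
                                  "templates", warn=False)
        self._index = {sid: k for k, sid in enumerate(self.subject_ids)}

    def target_indices(self, subject_ids) -> np.ndarray:
        try:
            return np.array([self._index[s] for s in subject_ids])
        except KeyError as exc:
            raise KeyError(f"unknown subject_id {exc.args[0]!r}") from None


@dataclass
class EmbeddingMatrix:
    """Images x d endophenotype matrix; every row has unit norm."""

    values: np.ndarray
    subject_ids: np.ndarray
    eyes: np.ndarray

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def for_eye(self, eye: str) -> "EmbeddingMatrix":
        mask = self.eyes == eye
        return EmbeddingMatrix(self.values[mask], self.subject_ids[mask],
                               self.eyes[mask])


@dataclass
class PairStats:
    matched: np.ndarray
    random: np.ndarray
    js_distance: float
    jaccard_index: float
    kde_grid: np.ndarray | None = None
    kde_matched: np.ndarray | None = None
    kde_random: np.ndarray | None = None

    @property
    def mean_random(self) -> float:
        return float(np.mean(self.random))


def _margin_logits(cos: np.ndarray, targets: np.ndarray,
                   s: float, m: float) -> np.ndarray:
    """Scaled cosine logits with the angular margin on the target column."""
    n = cos.shape[0]
    cos_t = np.clip(cos[np.arange(n), targets], -1.0 + 1e-12, 1.0 - 1e-12)
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    logits = s * cos
    logits[np.arange(n), targets] = s * (cos_t * np.cos(m) - sin_t * np.sin(m))
    return logits


def arcface_loss(embeddings: np.ndarray, subject_ids, templates: TemplateBank,
                 cfg: ArcFaceConfig) -> float:
    """Mean negative log margin-softmax probability of each own template."""
    cfg.validate()
    e = _unit_rows(np.asarray(embeddings, dtype=float), "embeddings")
    targets = templates.target_indices(subject_ids)
    cos = e @ templates.vectors.T
    logits = _margin_logits(cos, targets, cfg.s, cfg.m)
    loss, _ = nn.softmax_xent(logits, targets)
    return float(loss)


class _ArcFaceHead:
    """Learnable raw template weights; normalized rows at every use."""

    def __init__(self, n_classes: int, d: int, rng: np.random.Generator):
        self.W = rng.standard_normal((n_classes, d)) * 0.01
        self.params = [self.W]
        self.grads = [np.zeros_like(self.W)]

    def templates(self) -> np.ndarray:
        return self.W / np.maximum(np.linalg.norm(self.W, axis=1, keepdims=True), 1e-12)

    def loss_and_grads(self, e: np.ndarray, targets: np.ndarray,
                       s: float, m: float):
        """Returns (loss, d_loss/d_e); stores template gradient internally."""
        T = self.templates()
        n = e.shape[0]
        cos = e @ T.T
        cos_t = np.clip(cos[np.arange(n), targets], -1.0 + 1e-7, 1.0 - 1e-7)
        sin_t = np.sqrt(1.0 - cos_t ** 2)
        logits = s * cos
        logits[np.arange(n), targets] = s * (cos_t * np.cos(m) - sin_t * np.sin(m))
        loss, dlogits = nn.softmax_xent(logits, targets)
        # chain rule back to the raw cosines: target column gets the
        # derivative of cos(theta + m) wrt cos(theta)
        dcos = s * dlogits
        dtarget_scale = np.cos(m) + np.sin(m) * cos_t / np.maximum(sin_t, 1e-7)
        dcos[np.arange(n), targets] *= dtarget_scale
        de = dcos @ T
        dT = dcos.T @ e
        # backprop through the row normalization of W
        norms = np.maximum(np.linalg.norm(self.W, axis=1, keepdims=True), 1e-12)
        self.grads[0][...] = (dT - T * np.sum(dT * T, axis=1, keepdims=True)) / norms
        return loss, de


@dataclass
class PhenotyperModel:
    body: nn.Sequential
    head_embed: nn.Dense
    cfg: ArcFaceConfig
    loss_history: list = field(default_factory=list)

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Forward a prepped batch to unit-norm embeddings."""
        h = self.body.forward(x)
        z = self.head_embed.forward(h)
        return z / np.maximum(np.linalg.norm(z, axis=1, keepdims=True), 1e-12)


def _build_body(cfg: ArcFaceConfig, rng) -> tuple[nn.Sequential, nn.Dense]:
    feat = (cfg.input_hw // 4) ** 2 * 16
    body = nn.Sequential(
        nn.Conv3x3(3, 8, rng), nn.ReLU(), nn.AvgPool2(),
        nn.Conv3x3(8, 16, rng), nn.ReLU(), nn.AvgPool2(),
        nn.Flatten(),
        nn.Dense(feat, cfg.hidden, rng), nn.ReLU(),
    )
    return body, nn.Dense(cfg.hidden, cfg.d, rng)


def _holdout_pair_loss(model: PhenotyperModel, x_left, x_right,
                       cfg: ArcFaceConfig) -> float:
    """Contrastive loss on held-out subjects, template-free.

    Each held-out subject's left-eye embedding serves as their template
    and their right-eye embedding is scored against all of them — a
    genuine generalization measure for subjects the margin-softmax never
    saw (their learned templates do not exist).
    """
    e_left = model.embed(x_left)
    e_right = model.embed(x_right)
    ids = list(range(len(e_left)))
    bank = TemplateBank(subject_ids=ids, vectors=e_left)
    return arcface_loss(e_right, ids, bank, cfg)


def train_phenotyper(images, dr_grades=None,
                     cfg: ArcFaceConfig | None = None
                     ) -> tuple[PhenotyperModel, TemplateBank]:
    """Train the contrastive encoder on good-quality image pairs.

    Right-eye images are mirrored before encoding and random rotations
    are applied as augmentation. When per-subject diabetic-retinopathy
    grades are supplied, an auxiliary grade-classification head is
    trained jointly at a contrastive:classification weight ratio of
    ``cfg.aux_weight_ratio`` : 1. The parameters with the lowest
    held-out loss are retained. Deterministic given ``cfg.seed``.

    Parameters
    ----------
    images
        FundusImages tagged with subject_id and eye.
    dr_grades
        Optional mapping subject_id -> ordinal grade 0..4.
    """
    cfg = cfg or ArcFaceConfig()
    cfg.validate()
    subject_order = list(dict.fromkeys(img.subject_id for img in images))
    if len(subject_order) < 2:
        raise ValueError("contrastive training needs at least 2 subjects")

    split_rng = substream(cfg.seed, "phenotyper", "split")
    perm = split_rng.permutation(len(subject_order))
    n_val = max(1, int(round(cfg.val_fraction * len(subject_order))))
    val_subjects = {subject_order[i] for i in perm[:n_val]}
    train_subjects = [s for s in subject_order if s not in val_subjects]

    x_all = prep_batch(images, cfg.input_hw, flip_right=True)
    sid_arr = np.array([img.subject_id for img in images])
    eye_arr = np.array([img.eye for img in images])

    class_of = {s: k for k, s in enumerate(train_subjects)}
    train_idx = np.flatnonzero([s in class_of for s in sid_arr])
    targets_all = np.array([class_of.get(s, -1) for s in sid_arr])

    # held-out pairs for model selection
    val_left, val_right = [], []
    for s in val_subjects:
        li = np.flatnonzero((sid_arr == s) & (eye_arr == "left"))
        ri = np.flatnonzero((sid_arr == s) & (eye_arr == "right"))
        if len(li) and len(ri):
            val_left.append(li[0])
            val_right.append(ri[0])
    have_val = len(val_left) >= 2

    init_rng = substream(cfg.seed, "phenotyper", "init")
    body, head_embed = _build_body(cfg, init_rng)
    arc = _ArcFaceHead(len(train_subjects), cfg.d, init_rng)
    model = PhenotyperModel(body=body, head_embed=head_embed, cfg=cfg)

    use_aux = dr_grades is not None
    if use_aux:
        head_aux = nn.Dense(cfg.hidden, N_GRADES, init_rng)
        grades_all = np.array([int(dr_grades[s]) for s in sid_arr])
        params = body.params + head_embed.params + arc.params + head_aux.params
        grads = body.grads + head_embed.grads + arc.grads + head_aux.grads
    else:
        params = body.params + head_embed.params + arc.params
        grads = body.grads + head_embed.grads + arc.grads

    opt = nn.Adam(params, lr=cfg.lr)
    aug_rng = substream(cfg.seed, "phenotyper", "augment")

    if have_val:
        best_val = _holdout_pair_loss(model, x_all[val_left], x_all[val_right], cfg)
    else:
        best_val = np.inf
    model.loss_history.append(("epoch0_val", best_val))
    best_state = body.get_state() + [head_embed.W.copy(), head_embed.b.copy()]

    for epoch in range(cfg.epochs):
        order = aug_rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = random_rotate(x_all[idx], cfg.rotation_max_deg, aug_rng)
            h = body.forward(xb)
            z = head_embed.forward(h)
            znorm = np.maximum(np.linalg.norm(z, axis=1, keepdims=True), 1e-12)
            e = z / znorm
            loss, de = arc.loss_and_grads(e, targets_all[idx], cfg.s, cfg.m)
            dz = (de - e * np.sum(de * e, axis=1, keepdims=True)) / znorm
            dh = head_embed.backward(dz)
            if use_aux:
                aux_logits = head_aux.forward(h)
                aux_loss, daux = nn.softmax_xent(aux_logits, grades_all[idx])
                loss = loss + aux_loss / cfg.aux_weight_ratio
                dh = dh + head_aux.backward(daux / cfg.aux_weight_ratio)
            body.backward(dh)
            opt.step(grads)
            epoch_loss += loss * len(idx)
        model.loss_history.append(("train", epoch_loss / len(order)))
        if have_val:
            val = _holdout_pair_loss(model, x_all[val_left], x_all[val_right], cfg)
            model.loss_history.append(("val", val))
            if val < best_val:
                best_val = val
                best_state = body.get_state() + [head_embed.W.copy(),
                                                 head_embed.b.copy()]

    if have_val:
        body.set_state(best_state[:-2])
        head_embed.W[...] = best_state[-2]
        head_embed.b[...] = best_state[-1]

    bank = TemplateBank(subject_ids=train_subjects, vectors=arc.templates())
    return model, bank


def embed_images(model: PhenotyperModel, images,
                 batch_size: int = 256) -> EmbeddingMatrix:
    """Export unit-norm endophenotype vectors; no augmentation at inference."""
    x = prep_batch(images, model.cfg.input_hw, flip_right=True)
    chunks = [model.embed(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
    return EmbeddingMatrix(
        values=np.vstack(chunks),
        subject_ids=np.array([img.subject_id for img in images]),
        eyes=np.array([img.eye for img in images]),
    )


def pair_similarity_stats(emb: EmbeddingMatrix, n_random_pairs: int = 1000,
                          seed: int = 0) -> PairStats:
    """Matched- vs random-pair cosine-similarity separation diagnostics.

    Matched pairs are (left, right) of each subject; random pairs are
    sampled across subjects without replacement. The Jensen-Shannon
    distance (base 2, the square root of the divergence) and the Jaccard
    index (histogram intersection over union) are computed on fixed
    80-bin histograms over [-1, 1]; KDE curves (Scott bandwidth x 0.5)
    are attached for plotting.
    """
    values, sids, eyes = emb.values, emb.subject_ids, emb.eyes
    left = {s: i for i, s in enumerate(sids) if eyes[i] == "left"}
    right = {s: i for i, s in enumerate(sids) if eyes[i] == "right"}
    both = [s for s in left if s in right]
    if len(both) < 2:
        raise ValueError("need >= 2 subjects with both eyes")
    matched = np.array([float(values[left[s]] @ values[right[s]]) for s in both])

    rng = substream(seed, "pair_stats")
    n = len(values)
    all_pairs = n * (n - 1) // 2
    replace = n_random_pairs > all_pairs
    if replace:
        warnings.warn("more random pairs requested than available; "
                      "sampling with replacement")
    seen = set()
    random_sims = []
    max_tries = 50 * n_random_pairs
    tries = 0
    while len(random_sims) < n_random_pairs and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, n, size=2)
        if i == j or sids[i] == sids[j]:
            continue
        key = (min(i, j), max(i, j))
        if not replace and key in seen:
            continue
        seen.add(key)
        random_sims.append(float(values[i] @ values[j]))
    random_sims = np.array(random_sims)

    bins = np.linspace(-1.0, 1.0, JACCARD_BINS + 1)
    hm, _ = np.histogram(matched, bins=bins, density=False)
    hr, _ = np.histogram(random_sims, bins=bins, density=False)
    pm = hm / max(hm.sum(), 1)
    pr = hr / max(hr.sum(), 1)
    js = float(jensenshannon(pm, pr, base=2))
    if np.isnan(js):   # identical zero-mass corner
        js = 0.0
    jaccard = float(np.minimum(pm, pr).sum() / max(np.maximum(pm, pr).sum(), 1e-300))

    grid = np.linspace(-1.0, 1.0, 512)
    kde_m = kde_r = None
    try:
        km = sstats.gaussian_kde(matched)
        km.set_bandwidth(km.factor * 0.5)
        kr = sstats.gaussian_kde(random_sims)
        kr.set_bandwidth(kr.factor * 0.5)
        kde_m, kde_r = km(grid), kr(grid)
    except np.linalg.LinAlgError:   # degenerate (zero-variance) sample
        pass

    return PairStats(matched=matched, random=random_sims,
                     js_distance=js, jaccard_index=jaccard,
                     kde_grid=grid, kde_matched=kde_m, kde_random=kde_r)
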