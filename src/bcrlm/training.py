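"""Pretraining: masking, MLM + supervised contrastive losses, joint loop.

The objective is a convex combination

    L = (1 - w_cl) * L_mlm + w_cl * L_cl

where L_mlm is the masked-language-model loss (per-sequence sum of
negative log-probabilities at masked positions, averaged over the batch)
and L_cl is a supervised InfoNCE contrastive loss on [CLS] embeddings
with B-cell subtype labels defining the positive sets: same-subtype
sequences are pulled together, different subtypes pushed apart, with a
temperature-scaled cosine softmax.  The contrastive term embeds the
*unmasked* encoding via a second forward pass so that its signal is not
corrupted by masking noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad

from .model import (
    Model,
    ModelConfig,
    embed,
    encoder_forward,
    make_dropout_masks,
    mlm_head,
)
from .tokenization import EncodedSequence, MASK, Vocabulary, stack

IGNORE_INDEX = -100


# ---------------------------------------------------------------------------
# Masking


@dataclass
class MaskedBatch:
    corrupted_ids: np.ndarray  # (B, T)
    targets: np.ndarray  # (B, T), IGNORE_INDEX off the masked set
    masked: np.ndarray  # (B, T) bool, the masked set M
    seed: int


def apply_masking(
    batch: Sequence[EncodedSequence] | Tuple[np.ndarray, np.ndarray],
    vocab: Vocabulary,
    rate: float = 0.15,
    seed: int = 0,
) -> MaskedBatch:
    """BERT-style corruption of maskable (non-special, non-pad) positions.

    Each maskable position is independently selected with probability
    ``rate``; a selected position becomes [MASK] w.p. 0.8, a uniformly
    random amino-acid token w.p. 0.1, and stays unchanged w.p. 0.1.
    Original ids are kept as reconstruction targets on the masked set.
    """
    if not 0.0 < rate < 1.0:
        raise ValueError(f"masking rate must lie in (0, 1), got {rate}")
    if isinstance(batch, tuple):
        ids, maskable = batch
    else:
        ids, _, maskable = stack(batch)
    rng = np.random.default_rng(seed)
    selected = (rng.random(ids.shape) < rate) & maskable
    u = rng.random(ids.shape)
    aa_ids = vocab.amino_acid_ids
    random_tokens = rng.choice(aa_ids, size=ids.shape)

    corrupted = ids.copy()
    corrupted[selected & (u < 0.8)] = MASK
    swap = selected & (u >= 0.8) & (u < 0.9)
    corrupted[swap] = random_tokens[swap]
    targets = np.where(selected, ids, IGNORE_INDEX)
    return MaskedBatch(corrupted_ids=corrupted, targets=targets, masked=selected, seed=seed)


# ---------------------------------------------------------------------------
# Losses


def mlm_loss(mlm_logits, targets: np.ndarray):
    """Mean over sequences of summed negative log-probabilities at the
    masked positions (normalized by batch size |B|, not by |M|)."""
    targets = np.asarray(targets)
    mask = targets != IGNORE_INDEX
    if not mask.any():
        warnings.warn("mlm_loss: batch contains no masked positions, returning 0")
        return 0.0
    B, T, V = np.shape(mlm_logits)[0], np.shape(mlm_logits)[1], np.shape(mlm_logits)[2]
    safe = np.where(mask, targets, 0)
    onehot = np.eye(V)[safe]  # constant w.r.t. the logits
    m = anp.max(mlm_logits, axis=-1)
    logz = m + anp.log(anp.sum(anp.exp(mlm_logits - m[..., None]), axis=-1))
    picked = anp.sum(mlm_logits * onehot, axis=-1)
    logp = picked - logz
    return -anp.sum(logp * mask) / B


def cosine_similarity(h_i: np.ndarray, h_j: np.ndarray) -> float:
    h_i, h_j = np.asarray(h_i, float), np.asarray(h_j, float)
    ni, nj = np.linalg.norm(h_i), np.linalg.norm(h_j)
    if ni == 0 or nj == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(h_i @ h_j / (ni * nj))


def contrastive_loss(embeddings, subtype_labels: Sequence, tau: float):
    """Supervised InfoNCE on cosine similarities.

    For each anchor i with positive set P(i) (same label, j ≠ i):

        loss_i = -(1/|P(i)|) Σ_{p∈P(i)} log softmax_{a≠i}(sim(h_i,h_a)/τ)[p]

    averaged over anchors with at least one positive; anchors without a
    positive are skipped (0 with a warning if none remain).
    """
    if tau <= 0:
        raise ValueError(f"temperature tau must be > 0, got {tau}")
    labels = np.asarray(subtype_labels)
    n = labels.shape[0]
    pos = (labels[:, None] == labels[None, :]) & ~np.eye(n, dtype=bool)
    anchors = pos.any(axis=1)
    if not anchors.any():
        warnings.warn("contrastive_loss: no anchor has a positive pair, returning 0")
        return 0.0
    norms = anp.sqrt(anp.sum(embeddings * embeddings, axis=1, keepdims=True))
    z = embeddings / norms
    sim = (z @ z.T) / tau
    off = ~np.eye(n, dtype=bool)
    # log softmax over all a != i
    m = anp.max(anp.where(off, sim, -anp.inf), axis=1)
    logz = m + anp.log(anp.sum(anp.exp(sim - m[:, None]) * off, axis=1))
    logp = sim - logz[:, None]
    per_anchor = -anp.sum(logp * pos, axis=1) / anp.maximum(pos.sum(axis=1), 1)
    return anp.sum(per_anchor * anchors) / anchors.sum()


def total_loss(l_mlm, l_cl, w_cl: float):
    """Convex combination L = (1 − w_cl)·L_mlm + w_cl·L_cl."""
    if not 0.0 <= w_cl <= 1.0:
        raise ValueError(f"w_cl must lie in [0, 1], got {w_cl}")
    return (1.0 - w_cl) * l_mlm + w_cl * l_cl


# ---------------------------------------------------------------------------
# Sampling and learning-rate schedule


def balanced_sampler(
    subtype_labels: Sequence, batch_size: int, seed: int = 0
) -> Iterator[int]:
    """Infinite index stream with replacement, classes sampled uniformly
    (per-class probability ∝ 1/class frequency) so expected per-class
    counts per batch are equal.  Deterministic per seed."""
    labels = np.asarray(subtype_labels)
    if labels.size == 0:
        raise ValueError("balanced_sampler requires at least one label")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    classes = np.unique(labels)
    members = [np.flatnonzero(labels == c) for c in classes]
    rng = np.random.default_rng(seed)
    while True:
        cs = rng.integers(0, len(classes), size=batch_size)
        for c in cs:
            pool = members[c]
            yield int(pool[rng.integers(0, pool.size)])


@dataclass
class TrainingConfig:
    w_cl: float = 0.1
    tau: float = 0.07
    peak_lr: float = 1e-4
    warmup_fraction: float = 0.05
    plateau_patience: int = 3
    plateau_factor: float = 0.3
    batch_size: int = 32
    total_steps: int = 1000
    eval_interval: int = 100
    mask_rate: float = 0.15
    weight_decay: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_cl <= 1.0:
            raise ValueError("w_cl must lie in [0, 1]")
        for name in ("tau", "peak_lr", "warmup_fraction", "plateau_patience", "plateau_factor",
                     "batch_size", "total_steps", "eval_interval", "mask_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _plateau_decays(history: Sequence[float], patience: int) -> int:
    """Number of ×factor decays implied by a validation-loss history:
    after `patience` consecutive evaluations without improvement the rate
    decays and the counter resets (also resetting on improvement)."""
    best = np.inf
    streak = 0
    decays = 0
    for loss in history:
        if loss < best:
            best = loss
            streak = 0
        else:
            streak += 1
            if streak >= patience:
                decays += 1
                streak = 0
    return decays


def lr_schedule(
    step: int,
    total_steps: int,
    config: TrainingConfig,
    val_loss_history: Sequence[float] = (),
) -> float:
    """Linear warmup to the peak over the first ``warmup_fraction`` of
    steps (0 at step 0), then constant until the plateau rule fires."""
    if step < 0:
        raise ValueError("step must be >= 0")
    warmup_steps = max(1, int(round(config.warmup_fraction * total_steps)))
    if step < warmup_steps:
        return config.peak_lr * step / warmup_steps
    decays = _plateau_decays(val_loss_history, config.plateau_patience)
    return config.peak_lr * config.plateau_factor**decays


# ---------------------------------------------------------------------------
# Optimizer (decoupled weight decay Adam)


def _tree_map(f, *trees):
    t0 = trees[0]
    if isinstance(t0, dict):
        return {k: _tree_map(f, *[t[k] for t in trees]) for k in t0}
    if isinstance(t0, list):
        return [_tree_map(f, *[t[i] for t in trees]) for i in range(len(t0))]
    return f(*trees)


class AdamW:
    """Adam with decoupled weight decay; decay applies to matrices only
    (embeddings and projections), not biases or layer-norm parameters."""

    def __init__(self, params, config: TrainingConfig):
        self.cfg = config
        self.t = 0
        self.m = _tree_map(lambda p: np.zeros_like(p), params)
        self.v = _tree_map(lambda p: np.zeros_like(p), params)

    def step(self, params, grads, lr: float):
        self.t += 1
        b1, b2 = self.cfg.beta1, self.cfg.beta2
        c1 = 1 - b1**self.t
        c2 = 1 - b2**self.t
        wd = self.cfg.weight_decay

        def upd(p, g, m, v):
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            new = p - lr * (m / c1) / (np.sqrt(v / c2) + 1e-8)
            if p.ndim >= 2 and wd > 0:
                new = new - lr * wd * p
            return new

        return _tree_map(upd, params, grads, self.m, self.v)


# ---------------------------------------------------------------------------
# Joint training loop


def train(
    model: Model,
    train_set: Sequence[EncodedSequence],
    val_set: Sequence[EncodedSequence],
    config: TrainingConfig,
    vocab: Vocabulary,
    train_labels: Optional[Sequence[str]] = None,
) -> Tuple[Model, List[Dict]]:
    """Joint MLM + contrastive pretraining.

    Per step: draw a class-balanced batch (when labels are given), apply
    masking, compute the MLM loss on the corrupted forward pass and — for
    w_cl > 0 — the contrastive loss on unmasked [CLS] embeddings, combine,
    and take an AdamW step at the scheduled rate.  Fully seeded; a w_cl=0
    run consumes identical random streams to a pure-MLM run and is
    bit-for-bit identical to it.
    """
    mcfg = model.config
    ids_all, pad_all, maskable_all = stack(train_set)
    vids, vpad, vmaskable = stack(val_set) if len(val_set) else (None, None, None)
    labels = np.asarray(train_labels) if train_labels is not None else None
    if labels is not None and len(labels) != len(train_set):
        raise ValueError("train_labels must align with train_set")

    sampler = (
        balanced_sampler(labels, config.batch_size, seed=config.seed)
        if labels is not None
        else None
    )
    rng_uniform = np.random.default_rng(config.seed + 1)
    rng_mask = np.random.default_rng(config.seed + 2)
    rng_dropout = np.random.default_rng(config.seed + 3)

    params = model.params
    opt = AdamW(params, config)
    history: List[Dict] = []
    val_losses: List[float] = []
    use_cl = config.w_cl > 0 and labels is not None

    for step in range(config.total_steps):
        if sampler is not None:
            idx = np.array([next(sampler) for _ in range(config.batch_size)])
        else:
            idx = rng_uniform.integers(0, len(train_set), size=config.batch_size)
        ids, pad, maskable = ids_all[idx], pad_all[idx], maskable_all[idx]
        mb = apply_masking((ids, maskable), vocab, rate=config.mask_rate,
                           seed=int(rng_mask.integers(0, 2**31 - 1)))
        drop_masks = make_dropout_masks(mcfg, ids.shape, rng_dropout)
        batch_labels = labels[idx] if use_cl else None

        def loss_fn(p):
            x = embed(p, mb.corrupted_ids)
            h, _, _ = encoder_forward(p, x, pad, mcfg, dropout_masks=drop_masks)
            l_mlm = mlm_loss(mlm_head(p, h, mcfg), mb.targets)
            if not use_cl:
                return l_mlm
            xc = embed(p, ids)
            hc, _, _ = encoder_forward(p, xc, pad, mcfg)
            l_cl = contrastive_loss(hc[:, 0, :], batch_labels, config.tau)
            return total_loss(l_mlm, l_cl, config.w_cl)

        lr = lr_schedule(step, config.total_steps, config, val_losses)
        value, grads = value_and_grad(loss_fn)(params)
        if not np.isfinite(value):
            raise RuntimeError(f"training diverged at step {step}: loss = {value}")
        params = opt.step(params, grads, lr)

        entry = {"step": step, "lr": lr, "loss": float(value)}
        if (step + 1) % config.eval_interval == 0 and vids is not None:
            val_mb = apply_masking((vids, vmaskable), vocab, rate=config.mask_rate,
                                   seed=config.seed + 10_007)
            xv = embed(params, val_mb.corrupted_ids)
            hv, _, _ = encoder_forward(params, xv, vpad, mcfg)
            vl = float(mlm_loss(mlm_head(params, hv, mcfg), val_mb.targets))
            val_losses.append(vl)
            entry["val_mlm_loss"] = vl
        history.append(entry)

    model.params = params
    return model, history


def validation_mlm_loss(model: Model, val_set: Sequence[EncodedSequence], vocab: Vocabulary,
                        rate: float = 0.15, seed: int = 10_007) -> float:
    """Deterministically masked validation MLM loss."""
    vids, vpad, vmaskable = stack(val_set)
    mb = apply_masking((vids, vmaskable), vocab, rate=rate, seed=seed)
    x = embed(model.params, mb.corrupted_ids)
    h, _, _ = encoder_forward(model.params, x, vpad, model.config)
    return float(mlm_loss(mlm_head(model.params, h, model.config), mb.targets))
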