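"""Embedding-quality metrics and downstream fine-tuning benchmarks.

External clustering indices (ARI, NMI) and the internal silhouette score
grade how well [CLS] embeddings separate biological groupings; subtype
classification fine-tunes a linear head on [CLS] and reports macro
precision/recall/F1 plus the multiclass (Gorodkin) MCC and a confusion
matrix; paratope prediction fine-tunes a per-residue binary head and is
scored with the six standard metrics (Precision, Recall, F1, MCC, AUROC,
APR), residues pooled across sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from scipy.spatial.distance import cdist
from sklearn.metrics import (
    adjusted_rand_score,
    average_precision_score,
    confusion_matrix as _sk_confusion,
    matthews_corrcoef,
    normalized_mutual_info_score,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .model import Model, cls_embedding, embed, encoder_forward
from .records import ParatopeRecord
from .tokenization import EncodedSequence, FULL_LENGTH, Vocabulary, encode, stack
from .training import AdamW, TrainingConfig, _tree_map

# ---------------------------------------------------------------------------
# Clustering indices


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Permutation-model-adjusted Rand index from the contingency table."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label arrays differ in length: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("ARI requires at least two elements")
    return float(adjusted_rand_score(a, b))


def normalized_mutual_information(labels_a: Sequence, labels_b: Sequence) -> float:
    """Mutual information normalized by the arithmetic mean of entropies."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label arrays differ in length: {a.shape} vs {b.shape}")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        warnings.warn("NMI degenerate: a partition has a single class, returning 0")
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def silhouette_score(embeddings: np.ndarray, labels: Sequence) -> float:
    """Mean silhouette (b − a)/max(a, b) with Euclidean distances.

    A point in a singleton cluster takes a = 0 (so its silhouette is 1
    whenever another cluster exists at positive distance).
    """
    X = np.asarray(embeddings, dtype=float)
    y = np.asarray(labels)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("embeddings and labels must align")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("silhouette is undefined for a single class")
    if X.shape[0] < 3:
        raise ValueError("silhouette requires at least 3 points")
    D = cdist(X, X)
    s = np.empty(X.shape[0])
    masks = {c: y == c for c in classes}
    for i in range(X.shape[0]):
        own = masks[y[i]].copy()
        own[i] = False
        a = D[i, own].mean() if own.any() else 0.0
        b = min(D[i, masks[c]].mean() for c in classes if c != y[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


# ---------------------------------------------------------------------------
# Reports


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    mcc: float
    auroc: Optional[float] = None
    apr: Optional[float] = None
    averaging: str = "macro"
    per_class: Dict[str, Dict[str, float]] = field(default_factory=dict)
    confusion: Optional[np.ndarray] = None
    classes: Optional[List] = None

    def to_dict(self) -> Dict:
        out = {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
            "averaging": self.averaging,
        }
        if self.auroc is not None:
            out["auroc"] = self.auroc
        if self.apr is not None:
            out["apr"] = self.apr
        if self.confusion is not None:
            out["confusion"] = self.confusion.tolist()
            out["classes"] = list(self.classes)
            out["per_class"] = self.per_class
        return out


def classification_report(
    predictions: Sequence, truth: Sequence, averaging: str = "macro"
) -> MetricsReport:
    """Macro-averaged P/R/F1, multiclass MCC, and the confusion matrix."""
    y_pred, y_true = np.asarray(predictions), np.asarray(truth)
    if y_pred.size == 0:
        raise ValueError("classification_report requires non-empty input")
    if y_pred.shape != y_true.shape:
        raise ValueError("predictions and truth must align")
    classes = sorted(set(y_true) | set(y_pred))
    p, r, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average=None, zero_division=0
    )
    cm = _sk_confusion(y_true, y_pred, labels=classes)
    pm, rm, fm, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average=averaging, zero_division=0
    )
    per_class = {
        str(c): {"precision": float(p[i]), "recall": float(r[i]), "f1": float(f1[i]), "support": int(support[i])}
        for i, c in enumerate(classes)
    }
    return MetricsReport(
        precision=float(pm),
        recall=float(rm),
        f1=float(fm),
        mcc=float(matthews_corrcoef(y_true, y_pred)),
        averaging=averaging,
        per_class=per_class,
        confusion=cm,
        classes=classes,
    )


def paratope_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> MetricsReport:
    """Six-metric paratope report on pooled per-residue scores."""
    s, y = np.asarray(scores, float), np.asarray(labels, int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC is undefined when labels contain a single class")
    pred = (s >= threshold).astype(int)
    p, r, f1, _ = precision_recall_fscore_support(y, pred, average="binary", zero_division=0)
    return MetricsReport(
        precision=float(p),
        recall=float(r),
        f1=float(f1),
        mcc=float(matthews_corrcoef(y, pred)),
        auroc=float(roc_auc_score(y, s)),
        apr=float(average_precision_score(y, s)),
        averaging="micro",
    )


# ---------------------------------------------------------------------------
# Fine-tuning


@dataclass
class FineTuneConfig:
    steps: int = 300
    lr: float = 5e-3
    batch_size: int = 32
    fine_tune_backbone: bool = False
    weight_decay: float = 0.0
    seed: int = 0


def _softmax_np(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class SubtypeClassifier:
    """Linear head on the [CLS] embedding (optionally with a fine-tuned
    backbone)."""

    model: Model
    head: dict
    classes_: List[str]

    def predict_proba(self, encodings: Sequence[EncodedSequence]) -> np.ndarray:
        z = cls_embedding(self.model, encodings)
        return _softmax_np(z @ self.head["w"] + self.head["b"])

    def predict(self, encodings: Sequence[EncodedSequence]) -> np.ndarray:
        return np.asarray(self.classes_)[self.predict_proba(encodings).argmax(axis=1)]

    def evaluate(self, encodings: Sequence[EncodedSequence], truth: Sequence[str]) -> MetricsReport:
        unseen = set(truth) - set(self.classes_)
        if unseen:
            raise ValueError(f"labels unseen during training: {sorted(unseen)}")
        return classification_report(self.predict(encodings), np.asarray(truth))


def fine_tune_classifier(
    model: Model,
    encodings: Sequence[EncodedSequence],
    labels: Sequence[str],
    config: Optional[FineTuneConfig] = None,
) -> SubtypeClassifier:
    """Cross-entropy training of a linear subtype head on [CLS]."""
    config = config or FineTuneConfig()
    if len(encodings) != len(labels):
        raise ValueError("encodings and labels must align")
    classes = sorted(set(labels))
    y = np.array([classes.index(l) for l in labels])
    onehot = np.eye(len(classes))[y]
    rng = np.random.default_rng(config.seed)
    D = model.config.hidden_dim
    head = {"w": rng.normal(0, 0.02, (D, len(classes))), "b": np.zeros(len(classes))}
    tc = TrainingConfig(weight_decay=config.weight_decay, seed=config.seed)
    ids, pad, _ = stack(encodings)

    if not config.fine_tune_backbone:
        Z = cls_embedding(model, encodings)  # frozen backbone: embed once

        def loss_fn(h, batch):
            logits = Z[batch] @ h["w"] + h["b"]
            m = anp.max(logits, axis=1)
            logz = m + anp.log(anp.sum(anp.exp(logits - m[:, None]), axis=1))
            return -anp.mean(anp.sum(logits * onehot[batch], axis=1) - logz)

        opt = AdamW(head, tc)
        for _ in range(config.steps):
            batch = rng.integers(0, len(encodings), size=min(config.batch_size, len(encodings)))
            _, g = value_and_grad(loss_fn)(head, batch)
            head = opt.step(head, g, config.lr)
        return SubtypeClassifier(model=model, head=head, classes_=classes)

    joint = {"backbone": model.params, "head": head}
    opt = AdamW(joint, tc)
    for _ in range(config.steps):
        batch = rng.integers(0, len(encodings), size=min(config.batch_size, len(encodings)))

        def loss_fn(p):
            x = embed(p["backbone"], ids[batch])
            h, _, _ = encoder_forward(p["backbone"], x, pad[batch], model.config)
            logits = h[:, 0, :] @ p["head"]["w"] + p["head"]["b"]
            m = anp.max(logits, axis=1)
            logz = m + anp.log(anp.sum(anp.exp(logits - m[:, None]), axis=1))
            return -anp.mean(anp.sum(logits * onehot[batch], axis=1) - logz)

        _, g = value_and_grad(loss_fn)(joint)
        joint = opt.step(joint, g, config.lr)
    model.params = joint["backbone"]
    return SubtypeClassifier(model=model, head=joint["head"], classes_=classes)


@dataclass
class ParatopeClassifier:
    """Per-residue binary head over final hidden states."""

    model: Model
    head: dict

    def predict_scores(self, encodings: Sequence[EncodedSequence]) -> List[np.ndarray]:
        ids, pad, _ = stack(encodings)
        x = embed(self.model.params, ids)
        h, _, _ = encoder_forward(self.model.params, x, pad, self.model.config)
        logits = np.asarray(h @ self.head["w"] + self.head["b"])
        return [
            1.0 / (1.0 + np.exp(-logits[i, enc.residue_positions]))
            for i, enc in enumerate(encodings)
        ]


def _paratope_arrays(
    records: Sequence[ParatopeRecord], vocab: Vocabulary, max_len: int
) -> Tuple[List[EncodedSequence], np.ndarray, np.ndarray]:
    """Encode paratope records and align labels to residue positions.

    Loss and evaluation cover residue positions only ([CLS]/[SEP]/
    metadata/[PAD] are excluded); labels truncate together with the
    residue segment.
    """
    encs, rows = [], []
    T = max_len
    label_mat = []
    for r in records:
        if len(r.labels) != len(r.sequence):
            raise ValueError(f"record {r.id!r}: label/sequence length mismatch")
        enc = encode(r, vocab, mode=FULL_LENGTH, max_len=max_len)
        pos = enc.residue_positions
        lab = np.full(T, -1, dtype=np.int64)
        lab[pos] = r.labels[: pos.size]
        encs.append(enc)
        label_mat.append(lab)
    labels = np.stack(label_mat)
    return encs, labels, labels >= 0


def fine_tune_paratope(
    model: Model,
    records: Sequence[ParatopeRecord],
    vocab: Vocabulary,
    config: Optional[FineTuneConfig] = None,
) -> ParatopeClassifier:
    """Class-weighted per-residue binary cross-entropy fine-tuning.

    Positives (contact residues) are up-weighted by the negative:positive
    ratio to counter paratope sparsity.  The backbone is fine-tuned by
    default: per-token discrimination benefits from adapting the
    representation, not just the head.
    """
    config = config or FineTuneConfig(fine_tune_backbone=True)
    encs, labels, valid = _paratope_arrays(records, vocab, model.config.max_len)
    ids, pad, _ = stack(encs)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("paratope fine-tuning requires both classes")
    w_pos = n_neg / n_pos
    weight = np.where(labels == 1, w_pos, 1.0) * valid
    y = (labels == 1).astype(float)
    rng = np.random.default_rng(config.seed)
    D = model.config.hidden_dim
    head = {"w": rng.normal(0, 0.02, D), "b": np.zeros(1)}
    tc = TrainingConfig(weight_decay=config.weight_decay, seed=config.seed)
    joint = {"backbone": model.params, "head": head} if config.fine_tune_backbone else head
    opt = AdamW(joint, tc)
    for _ in range(config.steps):
        batch = rng.integers(0, len(encs), size=min(config.batch_size, len(encs)))

        def loss_fn(p):
            bp = p["backbone"] if config.fine_tune_backbone else model.params
            hd = p["head"] if config.fine_tune_backbone else p
            x = embed(bp, ids[batch])
            h, _, _ = encoder_forward(bp, x, pad[batch], model.config)
            z = h @ hd["w"] + hd["b"]
            # weighted BCE via log-sigmoid, masked to residue positions
            logp1 = -anp.logaddexp(0.0, -z)
            logp0 = -anp.logaddexp(0.0, z)
            ll = y[batch] * logp1 + (1 - y[batch]) * logp0
            return -anp.sum(ll * weight[batch]) / anp.sum(weight[batch])

        _, g = value_and_grad(loss_fn)(joint)
        joint = opt.step(joint, g, config.lr)
    if config.fine_tune_backbone:
        model.params = joint["backbone"]
        head = joint["head"]
    else:
        head = joint
    return ParatopeClassifier(model=model, head=head)


def plot_embedding_projection(embeddings: np.ndarray, labels: Sequence, path, seed: int = 0):
    """Convenience 2-D UMAP projection of [CLS] embeddings, colored by a
    grouping (subtype, isotype, ...).  Requires the optional ``plot``
    extra (umap-learn + matplotlib); purely illustrative output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from umap import UMAP

    xy = UMAP(n_components=2, random_state=seed).fit_transform(np.asarray(embeddings))
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    for lab in np.unique(labels):
        m = labels == lab
        ax.scatter(xy[m, 0], xy[m, 1], s=8, label=str(lab), alpha=0.7)
    ax.legend(markerscale=2, fontsize=8)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def evaluate_paratope(
    classifier: ParatopeClassifier,
    records: Sequence[ParatopeRecord],
    vocab: Vocabulary,
    threshold: float = 0.5,
) -> MetricsReport:
    """Pooled six-metric report on a paratope record set."""
    encs, labels, valid = _paratope_arrays(records, vocab, classifier.model.config.max_len)
    scores = classifier.predict_scores(encs)
    pooled_scores = np.concatenate(scores)
    pooled_labels = np.concatenate([labels[i][valid[i]] for i in range(len(records))])
    return paratope_metrics(pooled_scores, pooled_labels, threshold=threshold)
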