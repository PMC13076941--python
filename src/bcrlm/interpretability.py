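"""Attention- and gradient-based attribution analyses.

Three complementary probes of what the encoder has learned:

* attention received per residue (aggregated over layers/heads), with
  paratope-enrichment statistics (what fraction of the top-ranked
  residues are true antigen contacts) and per-layer trajectories;
* integrated gradients from a zero embedding baseline, approximated by a
  midpoint Riemann sum along the straight-line path, with the
  completeness identity Σ attributions = f(input) − f(baseline) exposed
  for auditing;
* in-silico saturation mutagenesis of the top-attributed positions
  against matched random controls, summarized as the fold change in how
  often substitutions decrease the predicted-subtype probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import autograd.numpy as anp
import numpy as np
from autograd import grad

from .model import Model, embedding_output, encoder_forward, mlm_head
from .records import ParatopeRecord
from .tokenization import EncodedSequence
from .evaluation import SubtypeClassifier


@dataclass
class AttributionProfile:
    """Per-residue-position attribution scores for one sequence."""

    scores: np.ndarray  # one float per residue position
    positions: np.ndarray  # residue positions within the encoding
    method: str  # "attention" or "integrated_gradients"
    source_id: str = ""
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        self.positions = np.asarray(self.positions, int)
        if self.scores.shape != self.positions.shape:
            raise ValueError("scores and positions must align")
        if not np.isfinite(self.scores).all():
            raise ValueError("attribution scores must be finite")


# ---------------------------------------------------------------------------
# Attention-based scores


def residue_attention_scores(
    attention: np.ndarray,
    encoding: EncodedSequence,
    layer_set: Optional[Sequence[int]] = None,
    head_agg: str = "mean",
) -> AttributionProfile:
    """Mean attention *received* by each residue position.

    ``attention`` is the (n_layers, n_heads, T, T) tensor for one
    sequence.  For each selected layer and head the score of key
    position j is the mean attention paid to j by all non-pad query
    positions; heads are aggregated by ``head_agg`` and layers by mean.
    """
    A = np.asarray(attention)
    if A.ndim != 4:
        raise ValueError("attention must have shape (n_layers, n_heads, T, T)")
    layers = list(range(A.shape[0])) if layer_set is None else list(layer_set)
    if not layers:
        raise ValueError("layer_set must be non-empty")
    if head_agg not in ("mean", "max"):
        raise ValueError(f"head_agg must be 'mean' or 'max', got {head_agg!r}")
    queries = np.flatnonzero(encoding.pad_mask)
    recv = A[np.ix_(layers, range(A.shape[1]), queries)].mean(axis=2)  # (L, H, T)
    agg = recv.mean(axis=1) if head_agg == "mean" else recv.max(axis=1)  # (L, T)
    per_pos = agg.mean(axis=0)
    positions = encoding.residue_positions
    return AttributionProfile(
        scores=per_pos[positions],
        positions=positions,
        method="attention",
        source_id=encoding.source_id,
        meta={"layers": layers, "head_agg": head_agg},
    )


def _align_labels(
    profiles: Sequence[AttributionProfile], records: Sequence[ParatopeRecord]
) -> Tuple[np.ndarray, np.ndarray]:
    """Pool profile scores with per-residue paratope labels.

    Profile positions are the encoded residue positions in sequence
    order, so residue k of a profile corresponds to sequence position k
    (truncation drops the tail of both)."""
    if len(profiles) != len(records):
        raise ValueError("profiles and records must align")
    scores, labels = [], []
    for prof, rec in zip(profiles, records):
        k = prof.scores.size
        if k > len(rec.labels):
            raise ValueError(f"profile for {rec.id!r} longer than its label vector")
        scores.append(prof.scores)
        labels.append(rec.labels[:k])
    return np.concatenate(scores), np.concatenate(labels)


def attention_paratope_enrichment(
    profiles: Sequence[AttributionProfile],
    records: Sequence[ParatopeRecord],
    top_frac: float = 0.01,
) -> Tuple[float, float, float]:
    """Paratope share of the top-ranked residues versus the rest.

    Residue scores are pooled over all records and ranked; the top set
    is the ceiling(top_frac · N) highest scores, the background all
    remaining residues.  Returns (top_paratope_fraction,
    background_paratope_fraction, ratio).
    """
    scores, labels = _align_labels(profiles, records)
    n = scores.size
    k = math.ceil(top_frac * n)
    if k < 1 or n == 0:
        raise ValueError("top set is empty")
    order = np.argsort(-scores, kind="stable")
    top = order[:k]
    rest = order[k:]
    top_frac_paratope = float(labels[top].mean())
    bg_frac_paratope = float(labels[rest].mean()) if rest.size else float("nan")
    ratio = top_frac_paratope / bg_frac_paratope if bg_frac_paratope > 0 else float("inf")
    return top_frac_paratope, bg_frac_paratope, ratio


def layer_trajectory(
    attentions: Sequence[np.ndarray],
    encodings: Sequence[EncodedSequence],
    records: Sequence[ParatopeRecord],
) -> np.ndarray:
    """Per-layer mean attention received on binding vs non-binding residues.

    Returns an (n_layers, 2) table: column 0 = binding residues, column
    1 = non-binding, heads averaged, residues pooled over records.
    """
    if not (len(attentions) == len(encodings) == len(records)):
        raise ValueError("attentions, encodings and records must align")
    n_layers = np.asarray(attentions[0]).shape[0]
    sums = np.zeros((n_layers, 2))
    counts = np.zeros(2)
    for A, enc, rec in zip(attentions, encodings, records):
        A = np.asarray(A)
        queries = np.flatnonzero(enc.pad_mask)
        recv = A[:, :, queries].mean(axis=(1, 2))  # (L, T)
        pos = enc.residue_positions
        lab = rec.labels[: pos.size].astype(bool)
        for g, sel in enumerate((lab, ~lab)):
            if sel.any():
                sums[:, g] += recv[:, pos[sel]].sum(axis=1)
                counts[g] += sel.sum()
    return sums / np.maximum(counts, 1)


# ---------------------------------------------------------------------------
# Integrated gradients


def integrate_gradients_fn(
    f: Callable[[np.ndarray], float],
    x: np.ndarray,
    steps: int = 200,
    baseline: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, float, float]:
    """Midpoint-rule integrated gradients of a scalar function.

    Approximates attributions_d = x_d · ∫₀¹ ∂f/∂x_d(α·x) dα with a
    midpoint Riemann sum at α_k = (k + ½)/steps.  Returns
    (attributions, f(x), f(baseline)); for exact completeness the
    attributions over *all* coordinates sum to f(x) − f(baseline) as
    steps → ∞, and exactly at any step count when f is linear.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x, float)
    base = np.zeros_like(x) if baseline is None else np.asarray(baseline, float)
    g = grad(f)
    total = np.zeros_like(x)
    diff = x - base
    for k in range(steps):
        alpha = (k + 0.5) / steps
        total += np.asarray(g(base + alpha * diff))
    attributions = diff * total / steps
    return attributions, float(f(x)), float(f(base))


def _class_prob_fn(model: Model, classifier: SubtypeClassifier, enc: EncodedSequence, class_index: int):
    pad = enc.pad_mask[None, :]

    def f(x_emb):
        h, _, _ = encoder_forward(
            model.params, x_emb[None], pad, model.config, apply_embedding_ln=False
        )
        logits = h[:, 0, :] @ classifier.head["w"] + classifier.head["b"]
        m = anp.max(logits, axis=1)
        logz = m + anp.log(anp.sum(anp.exp(logits - m[:, None]), axis=1))
        return anp.exp(logits[0, class_index] - logz[0])

    return f


def _mlm_logit_fn(model: Model, enc: EncodedSequence, position: int, token_id: int):
    pad = enc.pad_mask[None, :]

    def f(x_emb):
        h, _, _ = encoder_forward(
            model.params, x_emb[None], pad, model.config, apply_embedding_ln=False
        )
        return mlm_head(model.params, h, model.config)[0, position, token_id]

    return f


def integrated_gradients(
    model: Model,
    enc: EncodedSequence,
    target,
    steps: int = 200,
    classifier: Optional[SubtypeClassifier] = None,
) -> AttributionProfile:
    """Integrated-gradients attribution for one encoded sequence.

    ``target`` selects the scalar: ``("class", label)`` (requires a
    fitted classifier; attributes the predicted probability of that
    subtype) or ``("mlm", position, token_id)`` (attributes that
    position/token logit).  Attribution happens in the embedding layer's
    output space; the zero baseline there zeroes both token and position
    contributions.  Per-dimension attributions are summed per token
    position and reported on residue positions; the full per-position
    sums and the completeness gap are kept in ``meta`` for auditing.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if target[0] == "class":
        if classifier is None:
            raise ValueError("class target requires a classifier")
        class_index = classifier.classes_.index(target[1])
        f = _class_prob_fn(model, classifier, enc, class_index)
    elif target[0] == "mlm":
        f = _mlm_logit_fn(model, enc, int(target[1]), int(target[2]))
    else:
        raise ValueError(f"unknown target kind {target[0]!r}")
    x = embedding_output(model.params, enc.ids[None], model.config)[0]
    attr, f_x, f_base = integrate_gradients_fn(f, x, steps=steps)
    per_position = attr.sum(axis=1)
    positions = enc.residue_positions
    return AttributionProfile(
        scores=per_position[positions],
        positions=positions,
        method="integrated_gradients",
        source_id=enc.source_id,
        meta={
            "steps": steps,
            "per_position_all": per_position,
            "f_input": f_x,
            "f_baseline": f_base,
            "completeness_gap": float(per_position.sum() - (f_x - f_base)),
        },
    )


def top_decile_positions(profile: AttributionProfile) -> np.ndarray:
    """Positions scoring at or above the 90th percentile (ties included).

    The returned set always contains at least ceiling(0.1·n) positions.
    """
    scores = profile.scores
    n = scores.size
    if n == 0:
        raise ValueError("empty attribution profile")
    k = math.ceil(0.1 * n)
    threshold = np.sort(scores)[::-1][k - 1]
    return profile.positions[scores >= threshold]


# ---------------------------------------------------------------------------
# Saturation mutagenesis


@dataclass
class MutagenesisResult:
    position: int
    original_residue: str
    substituted_residue: str
    delta: float  # change in probability of the original predicted subtype
    group: str  # "top_ig" or "random_control"


def saturation_mutagenesis(
    model: Model,
    classifier: SubtypeClassifier,
    enc: EncodedSequence,
    positions: Sequence[int],
    vocab,
    seed: int = 0,
) -> List[MutagenesisResult]:
    """Mutate each given position to all 19 alternative amino acids.

    ``positions`` (the top-attributed set) and an equal number of
    randomly drawn control positions (uniform over the remaining residue
    positions) are each substituted one at a time; Δ is the change in
    the probability of the originally predicted subtype.
    """
    positions = np.asarray(positions, int)
    residue_pos = enc.residue_positions
    if not np.isin(positions, residue_pos).all():
        raise ValueError("positions must be residue positions of the encoding")
    rng = np.random.default_rng(seed)
    pool = np.setdiff1d(residue_pos, positions)
    n_ctrl = min(positions.size, pool.size)
    controls = rng.choice(pool, size=n_ctrl, replace=False) if n_ctrl else np.array([], int)

    base_prob = classifier.predict_proba([enc])[0]
    orig_class = int(np.argmax(base_prob))
    p0 = base_prob[orig_class]
    aa_ids = vocab.amino_acid_ids

    variants, meta = [], []
    for group, pos_set in (("top_ig", positions), ("random_control", controls)):
        for pos in pos_set:
            current = int(enc.ids[pos])
            for sub in aa_ids:
                if int(sub) == current:
                    continue  # 19 alternatives only
                ids = enc.ids.copy()
                ids[pos] = sub
                variants.append(ids)
                meta.append((group, int(pos), current, int(sub)))

    results: List[MutagenesisResult] = []
    B = 64
    for start in range(0, len(variants), B):
        chunk = np.stack(variants[start : start + B])
        pad = np.repeat(enc.pad_mask[None], chunk.shape[0], axis=0)
        from .model import cls_embedding as _cls  # local to avoid cycle at import

        z = _cls(model, (chunk, pad))
        logits = z @ classifier.head["w"] + classifier.head["b"]
        logits = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        for row, (group, pos, cur, sub) in zip(probs, meta[start : start + B]):
            results.append(
                MutagenesisResult(
                    position=pos,
                    original_residue=vocab.id_to_token[cur],
                    substituted_residue=vocab.id_to_token[sub],
                    delta=float(row[orig_class] - p0),
                    group=group,
                )
            )
    return results


@dataclass
class FoldChange:
    fold: float
    infinite: bool
    top_decrease_fraction: float
    control_decrease_fraction: float


def mutagenesis_fold_change(results: Sequence[MutagenesisResult], eps: float = 0.01) -> FoldChange:
    """How much more often do top-position substitutions decrease the
    original subtype probability (Δ < −eps) than control substitutions?"""
    top = [r for r in results if r.group == "top_ig"]
    ctrl = [r for r in results if r.group == "random_control"]
    if not top or not ctrl:
        raise ValueError("both mutagenesis groups must be non-empty")
    f_top = float(np.mean([r.delta < -eps for r in top]))
    f_ctrl = float(np.mean([r.delta < -eps for r in ctrl]))
    if f_ctrl == 0:
        return FoldChange(fold=float("inf"), infinite=True,
                          top_decrease_fraction=f_top, control_decrease_fraction=f_ctrl)
    return FoldChange(fold=f_top / f_ctrl, infinite=False,
                      top_decrease_fraction=f_top, control_decrease_fraction=f_ctrl)


def motif_overlap_permutation_test(
    top_sets: Sequence[np.ndarray],
    true_sets: Sequence[np.ndarray],
    candidate_sets: Sequence[np.ndarray],
    n_permutations: int = 499,
    seed: int = 0,
) -> Tuple[float, float]:
    """One-sided permutation test for attribution/motif overlap.

    Observed statistic: pooled |top ∩ true| / |top| over records.  Null:
    each record's top set replaced by a uniformly random subset of its
    candidate positions, of the same size.  Returns
    (observed_overlap, p_value).
    """
    rng = np.random.default_rng(seed)
    tops = [np.asarray(t, int) for t in top_sets]
    trues = [set(map(int, t)) for t in true_sets]
    cands = [np.asarray(c, int) for c in candidate_sets]
    total_top = sum(t.size for t in tops)
    if total_top == 0:
        raise ValueError("empty top sets")

    def overlap(sets):
        hits = sum(len(trues[i] & set(map(int, s))) for i, s in enumerate(sets))
        return hits / total_top

    observed = overlap(tops)
    more_extreme = 0
    for _ in range(n_permutations):
        null_sets = [
            rng.choice(cands[i], size=tops[i].size, replace=False)
            for i in range(len(tops))
        ]
        if overlap(null_sets) >= observed:
            more_extreme += 1
    p = (1 + more_extreme) / (1 + n_permutations)
    return observed, p
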