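"""Bidirectional Transformer encoder with MLM, CLS and token heads.

A BERT-style post-layer-norm encoder implemented on numpy with reverse-
mode automatic differentiation (the ``autograd`` package), sized by a
:class:`ModelConfig`.  The full-scale preset — 12 layers, 12 heads,
hidden 768, feed-forward 3072, vocabulary 260, maximum length 148, an
MLM transform head with output weights tied to the token embeddings and
no pooler — totals ≈86 million trainable parameters.  Desk-scale
configurations (2 layers, hidden 32) train in minutes on one CPU.

All forward passes are pure functions of a parameter tree (nested dicts
and lists of numpy arrays), which is what makes the losses and
integrated-gradients attribution differentiable end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import autograd.numpy as anp
import numpy as np
from autograd.scipy.special import erf

from .tokenization import EncodedSequence, stack

NEG_INF = -1e9


@dataclass
class ModelConfig:
    n_layers: int
    n_heads: int
    hidden_dim: int
    ffn_dim: int
    vocab_size: int
    max_len: int
    dropout: float = 0.1
    seed: int = 0
    layer_norm_eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError(
                f"hidden_dim {self.hidden_dim} not divisible by n_heads {self.n_heads}"
            )
        if min(self.n_heads, self.hidden_dim, self.ffn_dim, self.vocab_size, self.max_len) < 1:
            raise ValueError("model dimensions must be positive")
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")


def paper_preset(seed: int = 0) -> ModelConfig:
    """The full-scale architecture: 12/12/768/3072, vocab 260, length 148."""
    return ModelConfig(
        n_layers=12, n_heads=12, hidden_dim=768, ffn_dim=3072, vocab_size=260, max_len=148, seed=seed
    )


def tiny_preset(vocab_size: int, max_len: int, seed: int = 0) -> ModelConfig:
    """Desk-scale configuration used throughout tests and demos."""
    return ModelConfig(
        n_layers=2, n_heads=2, hidden_dim=32, ffn_dim=64, vocab_size=vocab_size, max_len=max_len, seed=seed
    )


@dataclass
class Model:
    config: ModelConfig
    params: dict
    vocab_hash: Optional[str] = None


def init_model(config: ModelConfig, seed: Optional[int] = None, vocab_hash: Optional[str] = None) -> Model:
    """Deterministic initialization: N(0, 0.02²) weights, zero biases,
    unit layer-norm gains; learned positional embeddings of size max_len."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    D, F, V, T = config.hidden_dim, config.ffn_dim, config.vocab_size, config.max_len
    std = 0.02

    def w(*shape):
        return rng.normal(0.0, std, size=shape)

    layers = []
    for _ in range(config.n_layers):
        layers.append(
            {
                "wq": w(D, D), "bq": np.zeros(D),
                "wk": w(D, D), "bk": np.zeros(D),
                "wv": w(D, D), "bv": np.zeros(D),
                "wo": w(D, D), "bo": np.zeros(D),
                "ln1_g": np.ones(D), "ln1_b": np.zeros(D),
                "w1": w(D, F), "b1": np.zeros(F),
                "w2": w(F, D), "b2": np.zeros(D),
                "ln2_g": np.ones(D), "ln2_b": np.zeros(D),
            }
        )
    params = {
        "tok_emb": w(V, D),
        "pos_emb": w(T, D),
        "emb_ln_g": np.ones(D), "emb_ln_b": np.zeros(D),
        "layers": layers,
        # MLM transform head; output weights tied to tok_emb, free bias
        "mlm": {"w": w(D, D), "b": np.zeros(D), "ln_g": np.ones(D), "ln_b": np.zeros(D), "out_b": np.zeros(V)},
    }
    return Model(config=config, params=params, vocab_hash=vocab_hash)


def count_parameters(model: Model, scope: str = "encoder_with_mlm_head") -> int:
    """Exact trainable parameter count (tied weights counted once)."""
    if scope != "encoder_with_mlm_head":
        raise ValueError(f"unknown scope {scope!r}")

    def walk(node) -> int:
        if isinstance(node, dict):
            return sum(walk(v) for v in node.values())
        if isinstance(node, (list, tuple)):
            return sum(walk(v) for v in node)
        return int(np.asarray(node).size)

    return walk(model.params)


# ---------------------------------------------------------------------------
# Differentiable forward pieces (autograd-traceable)


def layer_norm(x, g, b, eps):
    m = anp.mean(x, axis=-1, keepdims=True)
    v = anp.var(x, axis=-1, keepdims=True)
    return (x - m) / anp.sqrt(v + eps) * g + b


def gelu(x):
    return 0.5 * x * (1.0 + erf(x / anp.sqrt(2.0)))


def softmax(x, axis=-1):
    x = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(x)
    return e / anp.sum(e, axis=axis, keepdims=True)


def embed(params, ids: np.ndarray) -> anp.ndarray:
    """Token + position embedding sum, before the embedding layer norm."""
    T = ids.shape[-1]
    return params["tok_emb"][ids] + params["pos_emb"][None, :T, :]


def embedding_output(params, ids: np.ndarray, config: "ModelConfig") -> np.ndarray:
    """The embedding layer's output: layer-normalized token + position sum.

    This is the attribution space for integrated gradients; its zero
    vector (zeroing both token and position contributions) is the IG
    baseline.
    """
    x = embed(params, ids)
    return np.asarray(layer_norm(x, params["emb_ln_g"], params["emb_ln_b"], config.layer_norm_eps))


def encoder_forward(
    params,
    x,
    key_mask: np.ndarray,
    config: ModelConfig,
    collect: bool = False,
    dropout_masks: Optional[list] = None,
    apply_embedding_ln: bool = True,
):
    """Run the encoder stack on embeddings ``x``.

    ``x`` is the pre-norm token+position sum by default; pass
    ``apply_embedding_ln=False`` when ``x`` is already the embedding
    layer's output (the integrated-gradients path).  Returns
    ``(h, hidden_states, attentions)``; the two lists are empty unless
    ``collect``.  ``dropout_masks`` is a list of precomputed
    inverted-dropout masks (embedding output, then two per layer) used
    only during training.
    """
    eps = config.layer_norm_eps
    B, T = key_mask.shape
    H = config.n_heads
    dh = config.hidden_dim // H
    mask_bias = np.where(key_mask, 0.0, NEG_INF)[:, None, None, :]  # (B,1,1,T)

    di = iter(dropout_masks) if dropout_masks is not None else None

    def drop(h):
        return h * next(di) if di is not None else h

    if apply_embedding_ln:
        x = layer_norm(x, params["emb_ln_g"], params["emb_ln_b"], eps)
    x = drop(x)
    hiddens = [x] if collect else []
    attns = []
    scale = 1.0 / np.sqrt(dh)
    for lp in params["layers"]:
        q = anp.transpose((x @ lp["wq"] + lp["bq"]).reshape(B, T, H, dh), (0, 2, 1, 3))
        k = anp.transpose((x @ lp["wk"] + lp["bk"]).reshape(B, T, H, dh), (0, 2, 1, 3))
        v = anp.transpose((x @ lp["wv"] + lp["bv"]).reshape(B, T, H, dh), (0, 2, 1, 3))
        scores = anp.einsum("bhid,bhjd->bhij", q, k) * scale + mask_bias
        a = softmax(scores)  # (B,H,T,T); pad keys get exactly zero weight
        if collect:
            attns.append(a)
        ctx = anp.transpose(anp.einsum("bhij,bhjd->bhid", a, v), (0, 2, 1, 3)).reshape(B, T, config.hidden_dim)
        x = layer_norm(x + drop(ctx @ lp["wo"] + lp["bo"]), lp["ln1_g"], lp["ln1_b"], eps)
        f = gelu(x @ lp["w1"] + lp["b1"]) @ lp["w2"] + lp["b2"]
        x = layer_norm(x + drop(f), lp["ln2_g"], lp["ln2_b"], eps)
        if collect:
            hiddens.append(x)
    return x, hiddens, attns


def mlm_head(params, h, config: ModelConfig):
    """dense → GELU → layer norm, output projection tied to token embeddings."""
    hp = params["mlm"]
    t = layer_norm(gelu(h @ hp["w"] + hp["b"]), hp["ln_g"], hp["ln_b"], config.layer_norm_eps)
    return t @ params["tok_emb"].T + hp["out_b"]


def make_dropout_masks(config: ModelConfig, shape_bt: Tuple[int, int], rng: np.random.Generator) -> Optional[list]:
    """Inverted-dropout masks for one training forward (None if p = 0)."""
    p = config.dropout
    if p <= 0:
        return None
    B, T = shape_bt
    n = 1 + 2 * config.n_layers
    return [
        (rng.random((B, T, config.hidden_dim)) >= p) / (1.0 - p)
        for _ in range(n)
    ]


# ---------------------------------------------------------------------------
# Inference API


@dataclass
class ForwardOutput:
    mlm_logits: np.ndarray  # (B, T, V)
    cls_embedding: np.ndarray  # (B, D)
    hidden_states: List[np.ndarray]  # n_layers+1 arrays of (B, T, D)
    attention: np.ndarray  # (B, n_layers, n_heads, T, T)


BatchLike = Union[Sequence[EncodedSequence], Tuple[np.ndarray, np.ndarray]]


def _as_arrays(batch: BatchLike) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(batch, tuple):
        ids, pad = batch
    else:
        ids, pad, _ = stack(batch)
    ids = np.asarray(ids)
    pad = np.asarray(pad, dtype=bool)
    if ids.ndim == 1:
        ids, pad = ids[None, :], pad[None, :]
    if ids.shape != pad.shape:
        raise ValueError(f"ids shape {ids.shape} != pad_mask shape {pad.shape}")
    return ids, pad


def forward(model: Model, batch: BatchLike) -> ForwardOutput:
    """Deterministic (evaluation-mode) forward pass with attention maps."""
    ids, pad = _as_arrays(batch)
    if ids.shape[1] != model.config.max_len:
        raise ValueError(
            f"sequence length {ids.shape[1]} != model max_len {model.config.max_len}"
        )
    if ids.min() < 0 or ids.max() >= model.config.vocab_size:
        raise ValueError("token id outside vocabulary range")
    x = embed(model.params, ids)
    h, hiddens, attns = encoder_forward(model.params, x, pad, model.config, collect=True)
    logits = mlm_head(model.params, h, model.config)
    attention = np.transpose(np.stack(attns), (1, 0, 2, 3, 4)) if attns else np.zeros(
        (ids.shape[0], 0, model.config.n_heads, ids.shape[1], ids.shape[1])
    )
    return ForwardOutput(
        mlm_logits=np.asarray(logits),
        cls_embedding=np.asarray(h[:, 0, :]),
        hidden_states=[np.asarray(a) for a in hiddens],
        attention=attention,
    )


def cls_embedding(model: Model, batch: BatchLike) -> np.ndarray:
    """Final-layer hidden state at the [CLS] position (no projection)."""
    ids, pad = _as_arrays(batch)
    x = embed(model.params, ids)
    h, _, _ = encoder_forward(model.params, x, pad, model.config)
    return np.asarray(h[:, 0, :])


# ---------------------------------------------------------------------------
# Checkpointing


def save_checkpoint(model: Model, path: Union[str, Path]) -> None:
    flat: Dict[str, np.ndarray] = {}

    def walk(node, prefix):
        if isinstance(node, dict):
            for k, v in node.items():
                walk(v, f"{prefix}.{k}" if prefix else k)
        elif isinstance(node, list):
            for i, v in enumerate(node):
                walk(v, f"{prefix}[{i}]")
        else:
            flat[prefix] = np.asarray(node)

    walk(model.params, "")
    meta = json.dumps({"config": asdict(model.config), "vocab_hash": model.vocab_hash})
    np.savez(path, __meta__=np.array(meta), **flat)


def load_checkpoint(path: Union[str, Path], expect_vocab_hash: Optional[str] = None) -> Model:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    if expect_vocab_hash is not None and meta["vocab_hash"] != expect_vocab_hash:
        raise ValueError(
            "vocabulary hash mismatch: checkpoint was trained with a different vocabulary"
        )
    config = ModelConfig(**meta["config"])
    model = init_model(config)

    def walk(node, prefix):
        if isinstance(node, dict):
            return {k: walk(v, f"{prefix}.{k}" if prefix else k) for k, v in node.items()}
        if isinstance(node, list):
            return [walk(v, f"{prefix}[{i}]") for i, v in enumerate(node)]
        return data[prefix]

    model.params = walk(model.params, "")
    model.vocab_hash = meta["vocab_hash"]
    return model
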