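"""Structured run configuration and the end-to-end pipeline.

A YAML file with nested ``data`` / ``model`` / ``training`` / ``eval`` /
``explain`` sections plus a global seed drives the full workflow:
simulate → curate → tokenize → pretrain → evaluate → explain.  The
schema is validated before any work happens, and every run writes its
resolved configuration and a manifest (config hash, vocabulary hash,
stage timings) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import io as bio
from .curation import curate_pipeline, max_cross_identity
from .evaluation import (
    FineTuneConfig,
    adjusted_rand_index,
    fine_tune_classifier,
    normalized_mutual_information,
    silhouette_score,
)
from .interpretability import (
    integrated_gradients,
    mutagenesis_fold_change,
    saturation_mutagenesis,
    top_decile_positions,
)
from .model import ModelConfig, cls_embedding, init_model, save_checkpoint
from .sim import SimConfig, build_germline_pools, simulate_repertoire
from .tokenization import FULL_LENGTH, HCDR3_MODE, build_vocabulary, encode_batch
from .training import TrainingConfig, train


class DataSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_records: int = Field(600, ge=1)
    motif_strength: float = Field(1.0, ge=0.0, le=1.0)
    heavy_fraction: float = Field(1.0, ge=0.0, le=1.0)
    subtype_labels: Optional[List[str]] = None
    mode: str = Field(HCDR3_MODE, pattern=f"^({FULL_LENGTH}|{HCDR3_MODE})$")
    max_len: int = Field(32, ge=8)
    identity_threshold: float = Field(0.95, gt=0.0, le=1.0)
    split_ratios: Tuple[float, float, float] = (80, 10, 10)
    n_v: int = Field(8, ge=1)
    n_d: int = Field(5, ge=1)
    n_j: int = Field(3, ge=1)


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_layers: int = Field(2, ge=0)
    n_heads: int = Field(2, ge=1)
    hidden_dim: int = Field(32, ge=4)
    ffn_dim: int = Field(64, ge=4)
    dropout: float = Field(0.1, ge=0.0, lt=1.0)


class TrainingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    w_cl: float = Field(0.5, ge=0.0, le=1.0)
    tau: float = Field(0.07, gt=0.0)
    peak_lr: float = Field(1e-3, gt=0.0)
    warmup_fraction: float = Field(0.05, gt=0.0, le=1.0)
    plateau_patience: int = Field(3, ge=1)
    plateau_factor: float = Field(0.3, gt=0.0, le=1.0)
    batch_size: int = Field(24, ge=2)
    total_steps: int = Field(300, ge=1)
    eval_interval: int = Field(100, ge=1)
    mask_rate: float = Field(0.15, gt=0.0, lt=1.0)


class EvalSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    probe_steps: int = Field(300, ge=1)
    probe_lr: float = Field(5e-3, gt=0.0)


class ExplainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ig_steps: int = Field(50, ge=1)
    n_records: int = Field(3, ge=1)
    decrease_eps: float = Field(0.01, gt=0.0)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "runs/demo"
    log_level: str = "INFO"
    data: DataSection = DataSection()
    model: ModelSection = ModelSection()
    training: TrainingSection = TrainingSection()
    eval: EvalSection = EvalSection()
    explain: ExplainSection = ExplainSection()


@dataclass
class ValidationReport:
    ok: bool
    errors: List[str]
    config: Optional[RunConfig] = None


def load_config(path: Union[str, Path]) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def validate_config(path: Union[str, Path]) -> ValidationReport:
    """Schema check only; errors carry the offending key path."""
    try:
        cfg = load_config(path)
    except ValidationError as err:
        msgs = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
        return ValidationReport(ok=False, errors=msgs)
    except yaml.YAMLError as err:
        return ValidationReport(ok=False, errors=[f"YAML parse error: {err}"])
    return ValidationReport(ok=True, errors=[], config=cfg)


PIPELINE_STAGES = ("simulate", "curate", "pretrain", "evaluate", "explain")


def run_pipeline(
    config: RunConfig,
    stages: Tuple[str, ...] = PIPELINE_STAGES,
) -> Path:
    """Run the configured workflow; returns the artifact directory.

    Stages are deterministic per seed; each run writes the resolved
    config, stage outputs and a manifest with provenance hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = config.model_dump()
    (out / "config.resolved.json").write_text(json.dumps(resolved, indent=2))
    config_hash = hashlib.sha256(json.dumps(resolved, sort_keys=True).encode()).hexdigest()
    manifest: Dict = {"config_hash": config_hash, "stages": {}, "seed": config.seed}
    timers: Dict[str, float] = {}

    d = config.data
    pools = build_germline_pools(n_v=d.n_v, n_d=d.n_d, n_j=d.n_j, seed=config.seed,
                                 n_light_v=4, n_light_j=2)
    vocab = build_vocabulary(pools.all_symbols())
    vocab.save(out / "vocab.tsv")
    manifest["vocab_hash"] = vocab.content_hash()

    sim_kwargs = dict(
        n_records=d.n_records,
        motif_strength=d.motif_strength,
        heavy_fraction=d.heavy_fraction,
        seed=config.seed,
    )
    if d.subtype_labels:
        k = len(d.subtype_labels)
        sim_kwargs["subtype_labels"] = tuple(d.subtype_labels)
        sim_kwargs["subtype_proportions"] = tuple([1.0 / k] * k)
    sim_cfg = SimConfig(**sim_kwargs)

    records = parts = None
    model = classifier = None
    train_encs = held_encs = None
    held_labels = train_labels = None

    for stage in stages:
        t0 = time.time()
        if stage == "simulate":
            records = simulate_repertoire(sim_cfg, pools)
            bio.write_airr(records, out / "repertoire.tsv")
            bio.write_fasta(records, out / "repertoire.fasta")
        elif stage == "curate":
            if records is None:
                records = bio.read_airr(out / "repertoire.tsv")
            parts, qc_report, _cmap = curate_pipeline(
                records, threshold=d.identity_threshold, ratios=d.split_ratios, seed=config.seed
            )
            bio.write_airr(parts.train, out / "train.tsv")
            bio.write_airr(parts.validation, out / "val.tsv")
            bio.write_airr(parts.test, out / "test.tsv")
            audit = max_cross_identity(parts.test, parts.train) if parts.test and parts.train else None
            (out / "qc_report.json").write_text(
                json.dumps({"rejections": qc_report, "max_test_train_identity": audit}, indent=2)
            )
        elif stage == "pretrain":
            if parts is None:
                raise RuntimeError("pretrain requires the curate stage")
            mc = ModelConfig(
                n_layers=config.model.n_layers,
                n_heads=config.model.n_heads,
                hidden_dim=config.model.hidden_dim,
                ffn_dim=config.model.ffn_dim,
                vocab_size=len(vocab),
                max_len=d.max_len,
                dropout=config.model.dropout,
                seed=config.seed,
            )
            model = init_model(mc, vocab_hash=vocab.content_hash())
            tc = TrainingConfig(seed=config.seed, **config.training.model_dump())
            train_encs = encode_batch(parts.train, vocab, mode=d.mode, max_len=d.max_len)
            val_encs = encode_batch(parts.validation, vocab, mode=d.mode, max_len=d.max_len)
            train_labels = [r.subtype for r in parts.train]
            model, history = train(model, train_encs, val_encs, tc, vocab, train_labels=train_labels)
            with open(out / "history.jsonl", "w") as fh:
                for entry in history:
                    fh.write(json.dumps(entry) + "\n")
            save_checkpoint(model, out / "checkpoint.npz")
        elif stage == "evaluate":
            if model is None:
                raise RuntimeError("evaluate requires the pretrain stage")
            held = parts.validation + parts.test
            held_encs = encode_batch(held, vocab, mode=d.mode, max_len=d.max_len)
            held_labels = [r.subtype for r in held]
            from sklearn.cluster import KMeans

            Z = cls_embedding(model, held_encs)
            k = len(set(held_labels))
            km = KMeans(n_clusters=k, n_init=10, random_state=config.seed).fit(Z)
            classifier = fine_tune_classifier(
                model, train_encs, train_labels,
                FineTuneConfig(steps=config.eval.probe_steps, lr=config.eval.probe_lr, seed=config.seed),
            )
            report = classifier.evaluate(held_encs, held_labels)
            metrics = {
                "embedding": {
                    "ari": adjusted_rand_index(held_labels, km.labels_),
                    "nmi": normalized_mutual_information(held_labels, km.labels_),
                    "silhouette": silhouette_score(Z, held_labels),
                },
                "subtype_classification": report.to_dict(),
            }
            (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        elif stage == "explain":
            if model is None or classifier is None:
                raise RuntimeError("explain requires the evaluate stage")
            ex = config.explain
            rows = []
            for enc, label in list(zip(held_encs, held_labels))[: ex.n_records]:
                profile = integrated_gradients(
                    model, enc, ("class", label), steps=ex.ig_steps, classifier=classifier
                )
                top = top_decile_positions(profile)
                muts = saturation_mutagenesis(model, classifier, enc, top, vocab, seed=config.seed)
                fc = mutagenesis_fold_change(muts, eps=ex.decrease_eps)
                rows.append(
                    {
                        "record": enc.source_id,
                        "subtype": label,
                        "top_positions": [int(p) for p in top],
                        "completeness_gap": profile.meta["completeness_gap"],
                        "fold_change": None if fc.infinite else fc.fold,
                        "fold_change_infinite": fc.infinite,
                        "top_decrease_fraction": fc.top_decrease_fraction,
                        "control_decrease_fraction": fc.control_decrease_fraction,
                    }
                )
            (out / "explain.json").write_text(json.dumps(rows, indent=2))
        else:
            raise ValueError(f"unknown stage {stage!r}")
        timers[stage] = round(time.time() - t0, 3)
        manifest["stages"][stage] = {"seconds": timers[stage]}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
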