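"""Shared fixtures: small germline pools, planted-signal repertoires, and
session-scoped tiny pretrained models reused across the slower tests."""

from __future__ import annotations

import numpy as np
import pytest

from bcrlm.curation import qc_filter
from bcrlm.evaluation import FineTuneConfig, fine_tune_classifier, fine_tune_paratope
from bcrlm.model import init_model, tiny_preset
from bcrlm.sim import SimConfig, build_germline_pools, simulate_paratope_set, simulate_repertoire
from bcrlm.tokenization import HCDR3_MODE, build_vocabulary, encode_batch
from bcrlm.training import TrainingConfig, train


@pytest.fixture(scope="session")
def small_pools():
    return build_germline_pools(n_v=6, n_d=4, n_j=3, n_light_v=4, n_light_j=2, seed=0)


@pytest.fixture(scope="session")
def small_vocab(small_pools):
    return build_vocabulary(small_pools.all_symbols())


@pytest.fixture(scope="session")
def planted_repertoire(small_pools):
    """Two-subtype repertoire with fully planted CDR3 motifs and matched
    isotype/SHM distributions, so the subtype signal is the motif only."""
    shared_iso = {s: (0.4, 0.1, 0.3, 0.15, 0.05) for s in ("naive", "plasma")}
    cfg = SimConfig(
        n_records=250,
        subtype_labels=("naive", "plasma"),
        subtype_proportions=(0.5, 0.5),
        shm_rate_per_subtype={"naive": 0.02, "plasma": 0.02},
        isotype_distribution_per_subtype=shared_iso,
        motif_strength=1.0,
        heavy_fraction=1.0,
        seed=2,
    )
    records = simulate_repertoire(cfg, small_pools)
    kept, _ = qc_filter(records)
    return kept, cfg


@pytest.fixture(scope="session")
def pretrained_tiny(planted_repertoire, small_pools, small_vocab):
    """Tiny encoder jointly pretrained (MLM + contrastive) on the planted
    repertoire, with its encodings, labels, training history and a fitted
    linear subtype probe."""
    kept, _cfg = planted_repertoire
    vocab = small_vocab
    encs = encode_batch(kept, vocab, mode=HCDR3_MODE, max_len=30)
    labels = [r.subtype for r in kept]
    model = init_model(tiny_preset(len(vocab), 30, seed=0))
    tc = TrainingConfig(
        w_cl=0.5, batch_size=24, total_steps=200, eval_interval=50, peak_lr=1e-3, seed=0
    )
    model, history = train(model, encs[:200], encs[200:220], tc, vocab, train_labels=labels[:200])
    classifier = fine_tune_classifier(
        model, encs[:200], labels[:200], FineTuneConfig(steps=200, seed=0)
    )
    return {
        "model": model,
        "classifier": classifier,
        "encodings": encs,
        "labels": labels,
        "records": kept,
        "vocab": vocab,
        "history": history,
    }


@pytest.fixture(scope="session")
def paratope_setup(small_vocab):
    """Short planted-motif paratope records with a fine-tuned per-residue
    classifier on a tiny backbone."""
    # extra_contacts=0 keeps every positive label deterministically
    # recoverable from sequence, so a tiny model can separate them
    records = simulate_paratope_set(120, motif="YYGMDV", seed=5, length_range=(30, 45), extra_contacts=0)
    vocab = small_vocab
    model = init_model(tiny_preset(len(vocab), 52, seed=1))
    train_recs, test_recs = records[:90], records[90:]
    clf = fine_tune_paratope(
        model, train_recs, vocab, FineTuneConfig(steps=150, lr=5e-3, batch_size=16, fine_tune_backbone=True, seed=1)
    )
    return {"classifier": clf, "train": train_recs, "test": test_recs, "vocab": vocab, "model": model}
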