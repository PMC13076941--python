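"""Masking statistics, loss oracles, sampler balance, LR schedule, and
joint-training behavior."""

import math
import warnings

import numpy as np
import pytest
from scipy.special import log_softmax

import bcrlm.training as training
from bcrlm.model import init_model, tiny_preset
from bcrlm.sim import SimConfig, simulate_repertoire
from bcrlm.curation import qc_filter
from bcrlm.tokenization import HCDR3_MODE, MASK, encode_batch, stack
from bcrlm.training import (
    IGNORE_INDEX,
    TrainingConfig,
    apply_masking,
    balanced_sampler,
    contrastive_loss,
    cosine_similarity,
    lr_schedule,
    mlm_loss,
    total_loss,
    train,
)


def big_maskable_batch(small_vocab, n_rows=900, t=148, real=130, seed=0):
    rng = np.random.default_rng(seed)
    aa = small_vocab.amino_acid_ids
    ids = rng.choice(aa, size=(n_rows, t))
    maskable = np.zeros((n_rows, t), bool)
    maskable[:, 1:real] = True  # position 0 plays the [CLS] role
    return ids, maskable


class TestMasking:
    def test_selection_and_corruption_fractions(self, small_vocab):
        ids, maskable = big_maskable_batch(small_vocab)
        n_maskable = maskable.sum()
        assert n_maskable > 100_000
        mb = apply_masking((ids, maskable), small_vocab, rate=0.15, seed=42)

        sel = mb.masked[maskable].mean()
        se_sel = math.sqrt(0.15 * 0.85 / n_maskable)
        assert abs(sel - 0.15) < 3 * se_sel

        n_sel = mb.masked.sum()
        frac_mask = (mb.corrupted_ids[mb.masked] == MASK).mean()
        assert abs(frac_mask - 0.80) < 3 * math.sqrt(0.8 * 0.2 / n_sel)

        # among selected: swapped-to-a-different-token happens w.p. 0.1·19/20,
        # observed-unchanged w.p. 0.1 + 0.1/20 (random draw may hit the original)
        changed = (mb.corrupted_ids != ids) & mb.masked & (mb.corrupted_ids != MASK)
        p_chg = 0.1 * 19 / 20
        assert abs(changed.sum() / n_sel - p_chg) < 3 * math.sqrt(p_chg * (1 - p_chg) / n_sel)
        unchanged = (mb.corrupted_ids == ids) & mb.masked
        p_unc = 0.1 + 0.1 / 20
        assert abs(unchanged.sum() / n_sel - p_unc) < 3 * math.sqrt(p_unc * (1 - p_unc) / n_sel)

    def test_targets_mark_exactly_the_masked_set(self, small_vocab):
        ids, maskable = big_maskable_batch(small_vocab, n_rows=20)
        mb = apply_masking((ids, maskable), small_vocab, seed=3)
        assert np.array_equal(mb.targets != IGNORE_INDEX, mb.masked)
        assert np.array_equal(mb.targets[mb.masked], ids[mb.masked])

    def test_special_and_pad_positions_never_selected(self, small_pools, small_vocab):
        cfg = SimConfig(n_records=50, heavy_fraction=1.0, seed=1)
        kept, _ = qc_filter(simulate_repertoire(cfg, small_pools))
        encs = encode_batch(kept, small_vocab, max_len=148)
        mb = apply_masking(encs, small_vocab, seed=9)
        _, pad, maskable = stack(encs)
        assert not mb.masked[~maskable].any()

    def test_invalid_rate_rejected(self, small_vocab):
        ids, maskable = big_maskable_batch(small_vocab, n_rows=2)
        with pytest.raises(ValueError):
            apply_masking((ids, maskable), small_vocab, rate=1.5)


class TestMlmLoss:
    def test_uniform_logits_single_mask_gives_log_vocab(self):
        V = 260
        logits = np.zeros((1, 5, V))
        targets = np.full((1, 5), IGNORE_INDEX)
        targets[0, 2] = 17
        assert mlm_loss(logits, targets) == pytest.approx(math.log(260), abs=1e-9)

    def test_concentrated_logits_drive_loss_to_zero(self):
        logits = np.zeros((1, 3, 10))
        logits[0, 1, 4] = 50.0
        targets = np.full((1, 3), IGNORE_INDEX)
        targets[0, 1] = 4
        assert mlm_loss(logits, targets) < 1e-8

    def test_loss_linear_in_masked_count(self):
        V = 260
        logits = np.zeros((1, 8, V))
        t1 = np.full((1, 8), IGNORE_INDEX)
        t1[0, 1] = 3
        t2 = t1.copy()
        t2[0, 5] = 7
        assert mlm_loss(logits, t2) == pytest.approx(2 * mlm_loss(logits, t1))

    def test_matches_independent_log_softmax_oracle(self):
        rng = np.random.default_rng(5)
        logits = rng.normal(size=(3, 6, 40))
        targets = np.full((3, 6), IGNORE_INDEX)
        for b in range(3):
            for pos in rng.choice(6, size=2, replace=False):
                targets[b, pos] = rng.integers(0, 40)
        lsm = log_softmax(logits, axis=-1)
        expected = 0.0
        for b in range(3):
            for pos in range(6):
                if targets[b, pos] != IGNORE_INDEX:
                    expected -= lsm[b, pos, targets[b, pos]]
        expected /= 3
        assert mlm_loss(logits, targets) == pytest.approx(expected, abs=1e-10)

    def test_no_masked_positions_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="no masked"):
            assert mlm_loss(np.zeros((1, 2, 5)), np.full((1, 2), IGNORE_INDEX)) == 0.0


class TestCosineSimilarity:
    def test_known_values(self):
        assert cosine_similarity([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)
        assert cosine_similarity([1.0, 1.0], [1.0, 0.0]) == pytest.approx(1 / math.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])


class TestContrastiveLoss:
    def test_hand_evaluated_three_point_oracle(self):
        """Anchors 1,2 (label A, identical unit vectors) vs 3 (label B,
        antipodal): each A-anchor contributes −log(e/(e+e^{−2}·e)) …
        worked out by scalar arithmetic to log(1 + e^{−2})."""
        emb = np.array([[1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        labels = ["A", "A", "B"]
        expected = math.log(1 + math.exp(-2.0))
        assert contrastive_loss(emb, labels, tau=1.0) == pytest.approx(expected, abs=1e-10)

    def test_identical_embeddings_give_uniform_softmax_value(self):
        emb = np.tile([0.3, 0.4], (4, 1))
        labels = ["A", "A", "B", "B"]
        # all similarities equal -> each positive log-prob is log(1/3)
        assert contrastive_loss(emb, labels, tau=0.5) == pytest.approx(math.log(3), abs=1e-10)

    def test_raising_positive_similarity_lowers_loss(self):
        labels = ["A", "A", "B"]
        base = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        closer = np.array([[1.0, 0.0], [0.9, 0.435889894], [-1.0, 0.0]])
        assert contrastive_loss(closer, labels, tau=1.0) < contrastive_loss(base, labels, tau=1.0)

    def test_permutation_and_rotation_invariance(self):
        rng = np.random.default_rng(11)
        emb = rng.normal(size=(8, 5))
        labels = np.array(list("AABBCCAB"))
        base = contrastive_loss(emb, labels, tau=0.2)
        perm = rng.permutation(8)
        assert contrastive_loss(emb[perm], labels[perm], tau=0.2) == pytest.approx(base, abs=1e-10)
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        assert contrastive_loss(emb @ q, labels, tau=0.2) == pytest.approx(base, abs=1e-8)

    def test_no_positive_pairs_warns_and_returns_zero(self):
        emb = np.eye(3)
        with pytest.warns(UserWarning, match="no anchor"):
            assert contrastive_loss(emb, ["A", "B", "C"], tau=1.0) == 0.0

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            contrastive_loss(np.eye(3), ["A", "A", "B"], tau=0.0)


class TestTotalLoss:
    @pytest.mark.parametrize(
        "l_mlm,l_cl,w,expected", [(3.0, 9.0, 0.0, 3.0), (3.0, 9.0, 1.0, 9.0), (2.0, 4.0, 0.25, 2.5)]
    )
    def test_convex_combination(self, l_mlm, l_cl, w, expected):
        assert total_loss(l_mlm, l_cl, w) == pytest.approx(expected)

    def test_value_lies_between_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, w = rng.normal(), rng.normal(), rng.random()
            v = total_loss(a, b, w)
            assert min(a, b) - 1e-12 <= v <= max(a, b) + 1e-12

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            total_loss(1.0, 1.0, 1.5)


class TestBalancedSampler:
    def test_imbalanced_classes_drawn_equally(self):
        labels = np.array(["big"] * 900 + ["small"] * 100)
        stream = balanced_sampler(labels, batch_size=10, seed=0)
        draws = np.array([next(stream) for _ in range(10_000)])
        frac_small = (draws >= 900).mean()
        assert abs(frac_small - 0.5) < 3 * math.sqrt(0.25 / 10_000)

    def test_single_class_yields_only_its_members(self):
        stream = balanced_sampler(["x"] * 7, batch_size=3, seed=1)
        assert all(0 <= next(stream) < 7 for _ in range(50))

    def test_same_seed_identical_prefix(self):
        labels = ["a"] * 5 + ["b"] * 5
        s1 = balanced_sampler(labels, 4, seed=3)
        s2 = balanced_sampler(labels, 4, seed=3)
        assert [next(s1) for _ in range(40)] == [next(s2) for _ in range(40)]

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            next(balanced_sampler([], 4, seed=0))


class TestLrSchedule:
    def test_zero_at_step_zero(self):
        assert lr_schedule(0, 1000, TrainingConfig()) == 0.0

    def test_peak_at_end_of_warmup(self):
        cfg = TrainingConfig(peak_lr=1e-4, warmup_fraction=0.05)
        assert lr_schedule(50, 1000, cfg) == pytest.approx(1e-4)

    def test_three_nonimproving_evals_decay_by_0p3(self):
        cfg = TrainingConfig(peak_lr=1e-4, plateau_patience=3, plateau_factor=0.3)
        history = [1.0, 1.1, 1.1, 1.1]  # best, then three without improvement
        assert lr_schedule(500, 1000, cfg, history) == pytest.approx(3e-5)

    def test_counter_resets_on_improvement(self):
        cfg = TrainingConfig(peak_lr=1e-4)
        history = [1.0, 1.1, 1.1, 0.9, 1.0, 1.0]  # improvement interrupts the streak
        assert lr_schedule(500, 1000, cfg, history) == pytest.approx(1e-4)

    def test_two_decays_compound(self):
        cfg = TrainingConfig(peak_lr=1e-4)
        history = [1.0] + [1.1] * 6
        assert lr_schedule(500, 1000, cfg, history) == pytest.approx(1e-4 * 0.09)


class TestTrainLoop:
    def test_validation_loss_improves_on_planted_repertoire(self, pretrained_tiny):
        vals = [h["val_mlm_loss"] for h in pretrained_tiny["history"] if "val_mlm_loss" in h]
        assert len(vals) >= 2
        assert vals[-1] < vals[0]

    def test_w_cl_zero_never_touches_the_contrastive_term(
        self, planted_repertoire, small_vocab, monkeypatch
    ):
        kept, _ = planted_repertoire
        encs = encode_batch(kept[:60], small_vocab, mode=HCDR3_MODE, max_len=30)
        labels = [r.subtype for r in kept[:60]]

        def boom(*a, **k):
            raise AssertionError("contrastive_loss must not be called when w_cl = 0")

        monkeypatch.setattr(training, "contrastive_loss", boom)
        model = init_model(tiny_preset(len(small_vocab), 30, seed=2))
        tc = TrainingConfig(w_cl=0.0, batch_size=8, total_steps=5, eval_interval=5, seed=4)
        model, history = train(model, encs[:50], encs[50:], tc, small_vocab, train_labels=labels[:50])
        assert len(history) == 5

    def test_identical_seeds_reproduce_parameters_bitwise(self, planted_repertoire, small_vocab):
        kept, _ = planted_repertoire
        encs = encode_batch(kept[:60], small_vocab, mode=HCDR3_MODE, max_len=30)
        labels = [r.subtype for r in kept[:60]]

        def run():
            model = init_model(tiny_preset(len(small_vocab), 30, seed=2))
            tc = TrainingConfig(w_cl=0.5, batch_size=8, total_steps=6, eval_interval=3, seed=4)
            model, _ = train(model, encs[:50], encs[50:], tc, small_vocab, train_labels=labels[:50])
            return model.params

        p1, p2 = run(), run()
        assert np.array_equal(p1["tok_emb"], p2["tok_emb"])
        assert np.array_equal(p1["layers"][0]["wq"], p2["layers"][0]["wq"])

    def test_within_subtype_similarity_exceeds_between(self, pretrained_tiny):
        """The contract the contrastive term optimizes: same-subtype [CLS]
        embeddings end up more cosine-similar than different-subtype ones."""
        from bcrlm.model import cls_embedding

        encs = pretrained_tiny["encodings"][220:]
        labels = np.asarray(pretrained_tiny["labels"][220:])
        Z = cls_embedding(pretrained_tiny["model"], encs)
        Z = Z / np.linalg.norm(Z, axis=1, keepdims=True)
        S = Z @ Z.T
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        assert S[same & off].mean() > S[~same].mean()
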