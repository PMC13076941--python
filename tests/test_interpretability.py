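"""Attribution contracts: attention aggregation oracles, enrichment null
calibration, integrated-gradients exactness/completeness/convergence,
top-decile tie rules, saturation mutagenesis and the fold statistic."""

import math

import numpy as np
import pytest

import autograd.numpy as anp

from bcrlm.interpretability import (
    AttributionProfile,
    MutagenesisResult,
    attention_paratope_enrichment,
    integrate_gradients_fn,
    integrated_gradients,
    layer_trajectory,
    motif_overlap_permutation_test,
    mutagenesis_fold_change,
    residue_attention_scores,
    saturation_mutagenesis,
    top_decile_positions,
)
from bcrlm.model import forward
from bcrlm.records import ParatopeRecord
from bcrlm.tokenization import CAT_RESIDUE, CAT_SPECIAL, EncodedSequence


def make_encoding(n_residues=8, total=12, source_id="x"):
    """[CLS] + residues + [SEP] + padding, no metadata (keeps tests small)."""
    ids = np.full(total, 1, dtype=np.int64)  # [PAD]
    ids[0] = 0
    ids[1 : 1 + n_residues] = np.arange(5, 5 + n_residues)
    ids[1 + n_residues] = 3
    pad = np.zeros(total, bool)
    pad[: n_residues + 2] = True
    cat = np.full(total, CAT_SPECIAL, dtype=np.int8)
    cat[1 : 1 + n_residues] = CAT_RESIDUE
    return EncodedSequence(ids=ids, pad_mask=pad, category=cat, source_id=source_id)


class TestResidueAttentionScores:
    def test_uniform_attention_gives_equal_scores(self):
        enc = make_encoding()
        T = enc.ids.size
        real = enc.pad_mask.sum()
        A = np.zeros((2, 3, T, T))
        A[:, :, :, :real] = 1.0 / real
        prof = residue_attention_scores(A, enc)
        assert np.allclose(prof.scores, prof.scores[0])

    def test_head_attending_to_one_position_wins_under_max(self):
        enc = make_encoding()
        T = enc.ids.size
        A = np.full((1, 2, T, T), 1.0 / T)
        A[0, 1, :, 4] = 1.0  # head 1 attends only to position 4
        prof = residue_attention_scores(A, enc, head_agg="max")
        assert prof.positions[np.argmax(prof.scores)] == 4

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(0)
        enc = make_encoding()
        T = enc.ids.size
        A = rng.random((3, 2, T, T))
        A /= A.sum(axis=-1, keepdims=True)
        prof = residue_attention_scores(A, enc)
        queries = np.flatnonzero(enc.pad_mask)
        for pos, score in zip(prof.positions, prof.scores):
            acc = [
                np.mean([A[l, h, q, pos] for q in queries])
                for l in range(3)
                for h in range(2)
            ]
            assert score == pytest.approx(np.mean(acc), abs=1e-9)

    def test_empty_layer_set_rejected(self):
        enc = make_encoding()
        with pytest.raises(ValueError):
            residue_attention_scores(np.zeros((1, 1, 12, 12)), enc, layer_set=[])


def profile_from_scores(scores, source_id="p"):
    scores = np.asarray(scores, float)
    return AttributionProfile(
        scores=scores, positions=np.arange(1, scores.size + 1), method="attention", source_id=source_id
    )


def paratope_from_labels(labels, rid="p"):
    labels = np.asarray(labels, int)
    seq = "A" * labels.size
    return ParatopeRecord(id=rid, chain="heavy", sequence=seq, labels=labels)


class TestEnrichment:
    def test_scores_identical_to_labels_give_top_fraction_one(self):
        labels = np.array([0, 1, 0, 1, 0, 0, 1, 0, 0, 0] * 20)
        profs = [profile_from_scores(labels.astype(float))]
        recs = [paratope_from_labels(labels)]
        top, bg, ratio = attention_paratope_enrichment(profs, recs, top_frac=0.01)
        assert top == 1.0 and ratio > 1.0

    def test_independent_scores_match_global_rate(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=10_000)
        scores = rng.random(10_000)
        profs = [profile_from_scores(scores)]
        recs = [paratope_from_labels(labels)]
        top, bg, _ = attention_paratope_enrichment(profs, recs, top_frac=0.05)
        rate = labels.mean()
        se = math.sqrt(rate * (1 - rate) / 500)
        assert abs(top - rate) < 4 * se
        assert abs(bg - rate) < 0.02

    def test_matches_sort_and_count_oracle(self):
        rng = np.random.default_rng(2)
        scores = rng.random(300)
        labels = rng.integers(0, 2, size=300)
        top, bg, _ = attention_paratope_enrichment(
            [profile_from_scores(scores)], [paratope_from_labels(labels)], top_frac=0.1
        )
        k = math.ceil(0.1 * 300)
        order = np.argsort(-scores, kind="stable")
        assert top == pytest.approx(labels[order[:k]].mean())
        assert bg == pytest.approx(labels[order[k:]].mean())


class TestLayerTrajectory:
    def test_output_length_and_oracle(self):
        rng = np.random.default_rng(3)
        enc = make_encoding()
        T = enc.ids.size
        A = rng.random((4, 2, T, T))
        A /= A.sum(axis=-1, keepdims=True)
        labels = np.array([1, 0, 0, 1, 0, 0, 0, 0])
        rec = paratope_from_labels(labels)
        traj = layer_trajectory([A], [enc], [rec])
        assert traj.shape == (4, 2)
        queries = np.flatnonzero(enc.pad_mask)
        recv = A[:, :, queries].mean(axis=(1, 2))
        pos = enc.residue_positions
        expected_binding = recv[:, pos[labels.astype(bool)]].mean(axis=1)
        assert np.allclose(traj[:, 0], expected_binding, atol=1e-12)

    def test_shuffled_labels_make_trajectories_coincide(self):
        rng = np.random.default_rng(4)
        encs, As, recs = [], [], []
        for i in range(30):
            enc = make_encoding(source_id=f"r{i}")
            T = enc.ids.size
            A = rng.random((3, 2, T, T))
            A /= A.sum(axis=-1, keepdims=True)
            labels = rng.permutation([1, 1, 0, 0, 0, 0, 0, 0])
            encs.append(enc), As.append(A), recs.append(paratope_from_labels(labels, rid=f"r{i}"))
        traj = layer_trajectory(As, encs, recs)
        assert np.allclose(traj[:, 0], traj[:, 1], atol=0.01)


class TestIntegratedGradientsCore:
    def test_linear_function_exact_at_any_step_count(self):
        rng = np.random.default_rng(5)
        w = rng.normal(size=(6, 4))
        x = rng.normal(size=(6, 4))

        def f(z):
            return anp.sum(z * w)

        for steps in (1, 3, 10):
            attr, fx, f0 = integrate_gradients_fn(f, x, steps=steps)
            assert np.allclose(attr, x * w, atol=1e-12)
            assert attr.sum() == pytest.approx(fx - f0, abs=1e-10)

    def test_riemann_error_shrinks_with_more_steps(self):
        rng = np.random.default_rng(6)
        W = rng.normal(size=(5, 5))
        x = rng.normal(size=5)

        def f(z):
            return anp.sum(anp.tanh(W @ anp.tanh(z)) ** 2)

        ref, _, _ = integrate_gradients_fn(f, x, steps=10_000)
        err10 = np.abs(integrate_gradients_fn(f, x, steps=10)[0] - ref).sum()
        err200 = np.abs(integrate_gradients_fn(f, x, steps=200)[0] - ref).sum()
        assert err200 < err10

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError):
            integrate_gradients_fn(lambda z: anp.sum(z), np.ones(3), steps=0)


class TestIntegratedGradientsOnModel:
    def test_completeness_within_one_percent_on_trained_model(self, pretrained_tiny):
        model = pretrained_tiny["model"]
        clf = pretrained_tiny["classifier"]
        enc = pretrained_tiny["encodings"][0]
        predicted = clf.predict([enc])[0]
        prof = integrated_gradients(model, enc, ("class", predicted), steps=200, classifier=clf)
        delta = prof.meta["f_input"] - prof.meta["f_baseline"]
        assert abs(delta) > 0.1
        assert abs(prof.meta["completeness_gap"] / delta) < 0.01

    def test_mlm_target_runs_and_reports_residue_positions(self, pretrained_tiny):
        model = pretrained_tiny["model"]
        enc = pretrained_tiny["encodings"][1]
        pos = int(enc.residue_positions[0])
        prof = integrated_gradients(model, enc, ("mlm", pos, int(enc.ids[pos])), steps=20)
        assert np.array_equal(prof.positions, enc.residue_positions)

    def test_planted_motif_positions_recovered(self, pretrained_tiny):
        """Top-decile IG positions of the subtype probe overlap the planted
        CDR3 motif more than chance (one-sided permutation p < 0.05)."""
        model = pretrained_tiny["model"]
        clf = pretrained_tiny["classifier"]
        records = pretrained_tiny["records"]
        encs = pretrained_tiny["encodings"]
        cfg_motifs = {"naive", "plasma"}
        tops, trues, cands = [], [], []
        for rec, enc in list(zip(records, encs))[:60]:
            prof = integrated_gradients(
                model, enc, ("class", rec.subtype), steps=25, classifier=clf
            )
            tops.append(top_decile_positions(prof))
            # hcdr3-mode residue k sits at encoded position k+1; the motif
            # is planted right after the cysteine anchor (indices 1..5)
            trues.append(np.arange(2, 7))
            cands.append(enc.residue_positions)
        observed, p = motif_overlap_permutation_test(tops, trues, cands, n_permutations=199, seed=0)
        assert p < 0.05


class TestTopDecile:
    def test_ten_distinct_scores_give_one_position(self):
        prof = profile_from_scores(np.arange(10, dtype=float))
        assert top_decile_positions(prof).tolist() == [10]

    def test_all_equal_scores_include_everything(self):
        prof = profile_from_scores(np.ones(7))
        assert top_decile_positions(prof).size == 7

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            scores = rng.random(rng.integers(5, 60))
            prof = profile_from_scores(scores)
            got = set(top_decile_positions(prof).tolist())
            k = math.ceil(0.1 * scores.size)
            thr = sorted(scores)[::-1][k - 1]
            expected = {int(p) for p, s in zip(prof.positions, scores) if s >= thr}
            assert got == expected and len(got) >= k


class TestSaturationMutagenesis:
    def test_row_count_and_no_self_substitution(self, pretrained_tiny):
        model = pretrained_tiny["model"]
        clf = pretrained_tiny["classifier"]
        vocab = pretrained_tiny["vocab"]
        enc = pretrained_tiny["encodings"][0]
        top = enc.residue_positions[:2]
        results = saturation_mutagenesis(model, clf, enc, top, vocab, seed=0)
        assert len(results) == 19 * (2 + 2)
        for r in results:
            assert r.substituted_residue != r.original_residue

    def test_constant_classifier_gives_zero_deltas(self, pretrained_tiny):
        import copy

        model = pretrained_tiny["model"]
        vocab = pretrained_tiny["vocab"]
        enc = pretrained_tiny["encodings"][0]
        clf = copy.deepcopy(pretrained_tiny["classifier"])
        clf.head["w"] = np.zeros_like(clf.head["w"])  # logits independent of input
        results = saturation_mutagenesis(model, clf, enc, enc.residue_positions[:2], vocab, seed=0)
        assert all(r.delta == pytest.approx(0.0, abs=1e-12) for r in results)

    def test_out_of_range_position_rejected(self, pretrained_tiny):
        with pytest.raises(ValueError):
            saturation_mutagenesis(
                pretrained_tiny["model"],
                pretrained_tiny["classifier"],
                pretrained_tiny["encodings"][0],
                [0],  # [CLS] is not a residue position
                pretrained_tiny["vocab"],
            )


def fake_results(top_deltas, ctrl_deltas):
    out = [
        MutagenesisResult(position=0, original_residue="A", substituted_residue="C", delta=d, group="top_ig")
        for d in top_deltas
    ]
    out += [
        MutagenesisResult(position=1, original_residue="A", substituted_residue="C", delta=d, group="random_control")
        for d in ctrl_deltas
    ]
    return out


class TestFoldChange:
    def test_identical_distributions_give_fold_one(self):
        deltas = [-0.5, -0.2, 0.1, 0.3]
        fc = mutagenesis_fold_change(fake_results(deltas, deltas))
        assert fc.fold == pytest.approx(1.0)

    def test_zero_control_decreases_flagged_infinite(self):
        fc = mutagenesis_fold_change(fake_results([-0.5, -0.4], [0.1, 0.2]))
        assert fc.infinite and math.isinf(fc.fold)

    def test_matches_count_oracle_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            top = rng.normal(-0.05, 0.2, size=50)
            ctrl = rng.normal(0.0, 0.2, size=50)
            fc = mutagenesis_fold_change(fake_results(top, ctrl), eps=0.01)
            f_top = np.mean(top < -0.01)
            f_ctrl = np.mean(ctrl < -0.01)
            if f_ctrl == 0:
                assert fc.infinite
            else:
                assert fc.fold == pytest.approx(f_top / f_ctrl)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mutagenesis_fold_change(fake_results([-0.5], []))


class TestAttentionOnModel:
    def test_enrichment_pipeline_runs_on_forward_output(self, paratope_setup):
        from bcrlm.tokenization import FULL_LENGTH, encode

        model = paratope_setup["model"]
        vocab = paratope_setup["vocab"]
        recs = paratope_setup["test"][:8]
        encs = [encode(r, vocab, mode=FULL_LENGTH, max_len=52) for r in recs]
        out = forward(model, encs)
        profs = [residue_attention_scores(out.attention[i], encs[i]) for i in range(len(encs))]
        top, bg, ratio = attention_paratope_enrichment(profs, recs, top_frac=0.05)
        assert 0.0 <= top <= 1.0 and 0.0 <= bg <= 1.0
        traj = layer_trajectory([out.attention[i] for i in range(len(encs))], encs, recs)
        assert traj.shape == (model.config.n_layers, 2)
        assert np.isfinite(traj).all()
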