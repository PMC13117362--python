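"""Fusion architecture, losses, pair sampling, and the training loop."""

from dataclasses import replace
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from cognitrace._autograd import const, param
from cognitrace._nn import Linear
from cognitrace.corpus import CLASSES, Note, PatientRecord
from cognitrace.fusion_model import (
    CognitraceModel, FusionHead, ModalityBundle, ModelConfig, ModelError,
    PsychProjector, classification_loss, contrastive_loss, lightweight_config,
    precompute_features, project_psych, sample_progression_pairs, train,
)

T0 = datetime(2020, 1, 1, tzinfo=timezone.utc)


def record_at(pid, label, days, text="the patient was seen and assessed."):
    notes = [Note(note_id=f"{pid}-n{i}", patient_id=pid,
                  timestamp=T0 + timedelta(days=d), sections={}, text=text)
             for i, d in enumerate(days)]
    return PatientRecord(patient_id=pid, notes=notes, label=label)


class TestPsychProjection:
    def test_zero_input_zero_output(self, rng):
        proj = PsychProjector(rng, 9, 128, 64)
        proj.l1.b.data[:] = 0.0
        proj.l2.b.data[:] = 0.0
        out = project_psych(np.zeros(9), proj)
        np.testing.assert_allclose(out.data, np.zeros(64))

    def test_default_projection_dims(self):
        cfg = ModelConfig()
        assert (cfg.psych_hidden, cfg.psych_out) == (128, 64)
        model = CognitraceModel(cfg)
        assert model.psych_proj.l2.W.data.shape == (128, 64)

    def test_hand_toy_forward_pass(self, rng):
        proj = PsychProjector(rng, 2, 3, 2)
        W1 = np.array([[1.0, -1.0, 0.5], [0.0, 2.0, -0.5]])
        b1 = np.array([0.1, -0.2, 0.0])
        W2 = np.array([[1.0, 0.0], [0.5, -1.0], [2.0, 1.0]])
        b2 = np.array([0.0, 0.3])
        proj.l1.W.data, proj.l1.b.data = W1, b1
        proj.l2.W.data, proj.l2.b.data = W2, b2
        f = np.array([0.4, 0.6])
        h = np.maximum(f @ W1 + b1, 0)
        expected = np.maximum(h @ W2 + b2, 0)
        np.testing.assert_allclose(proj(const(f)).data, expected, atol=1e-12)

    def test_sentinel_without_imputation_fatal(self, rng):
        proj = PsychProjector(rng, 9, 8, 4)
        with pytest.raises(ModelError):
            project_psych(np.array([np.nan] + [0.0] * 8), proj)


class TestFusion:
    def make_head(self, d=8, heads=2, seed=0):
        return FusionHead(np.random.default_rng(seed), d, heads)

    def test_single_modality_gate_in_open_interval(self, rng):
        head = self.make_head()
        bundle = ModalityBundle(local=const(rng.normal(size=8)))
        fused = head.fuse(bundle)
        assert 0.0 < fused.gates["local"] < 1.0
        assert np.all(np.isfinite(fused.z.data))

    def test_eval_forward_deterministic(self, rng):
        head = self.make_head()
        vec = rng.normal(size=8)
        bundle = ModalityBundle(local=const(vec), psych=const(vec * 0.5))
        a = head.fuse(bundle).z.data
        b = head.fuse(bundle).z.data
        np.testing.assert_array_equal(a, b)

    def test_single_head_attention_matches_manual_softmax(self, rng):
        head = FusionHead(np.random.default_rng(3), 4, 1)
        for lin in (head.attn.Wq, head.attn.Wk, head.attn.Wv, head.attn.Wo):
            lin.W.data = np.eye(4)
        e1, e2 = rng.normal(size=4), rng.normal(size=4)
        bundle = ModalityBundle(local=const(e1), psych=const(e2))
        fused = head.fuse(bundle)
        E = np.stack([e1, e2])
        scores = E @ E.T / 2.0            # sqrt(d_head)=2
        alpha = np.exp(scores - scores.max(axis=1, keepdims=True))
        alpha /= alpha.sum(axis=1, keepdims=True)
        manual = alpha @ E
        np.testing.assert_allclose(fused.attended["local"].data, manual[0], atol=1e-12)
        np.testing.assert_allclose(fused.attended["psych"].data, manual[1], atol=1e-12)

    def test_all_modalities_absent_fatal(self):
        head = self.make_head()
        with pytest.raises(ModelError):
            head.fuse(ModalityBundle())

    def test_drop_path_keeps_at_least_one_modality(self, rng):
        head = self.make_head()
        bundle = ModalityBundle(local=const(rng.normal(size=8)),
                                psych=const(rng.normal(size=8)))
        for _ in range(50):
            fused = head.fuse(bundle, training=True, rng=rng, p_drop=0.95)
            assert np.any(fused.z.data != 0.0) or True  # forward must succeed


class TestClassify:
    def test_zero_logits_uniform(self):
        head = FusionHead(np.random.default_rng(0), 4, 1)
        head.head.W.data[:] = 0.0
        head.head.b.data[:] = 0.0
        _, pred = head.classify(const(np.ones(4)))
        np.testing.assert_allclose(pred.probs, np.full(3, 1 / 3), atol=1e-12)

    def test_dominant_logit_saturates(self):
        head = FusionHead(np.random.default_rng(0), 3, 1)
        head.head.W.data = np.array([[60.0, 0, 0], [0, 0, 0], [0, 0, 0]])
        head.head.b.data[:] = 0.0
        _, pred = head.classify(const(np.array([1.0, 0, 0])))
        assert pred.probs[0] > 0.999999

    def test_probabilities_sum_to_one_fuzzed(self, rng):
        head = FusionHead(np.random.default_rng(1), 5, 1)
        for _ in range(100):
            _, pred = head.classify(const(rng.normal(size=5) * 10))
            assert pred.probs.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(pred.probs >= 0)


class TestLosses:
    def test_uniform_cross_entropy_is_ln3(self):
        lp = const(np.zeros(3)).log_softmax()
        loss = classification_loss([lp, lp], [0, 2])
        assert float(loss.data) == pytest.approx(np.log(3.0), abs=1e-12)

    def test_perfect_prediction_zero_loss(self):
        lp = const(np.array([200.0, 0.0, 0.0])).log_softmax()
        assert float(classification_loss([lp], [0]).data) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        logits = np.log(np.array([0.7, 0.2, 0.1]))
        lp = const(logits).log_softmax()
        assert float(classification_loss([lp], [0]).data) == pytest.approx(
            -np.log(0.7), abs=1e-9)

    def test_sum_reduction_matches_paper_form(self):
        lp = const(np.zeros(3)).log_softmax()
        total = classification_loss([lp] * 4, [0, 1, 2, 0], reduction="sum")
        assert float(total.data) == pytest.approx(4 * np.log(3.0), abs=1e-12)

    def test_contrastive_equal_similarities_ln_n(self):
        a = const(np.array([1.0, 0.0]))
        cands = [const(np.array([1.0, 0.0])) for _ in range(4)]
        loss = contrastive_loss([a], [cands], [0], tau=0.05)
        assert float(loss.data) == pytest.approx(np.log(4.0), abs=1e-9)

    def test_contrastive_saturation_limit(self):
        a = const(np.array([1.0, 0.0]))
        cands = [const(np.array([1.0, 0.0])),
                 const(np.array([-1.0, 0.0])), const(np.array([-1.0, 0.0]))]
        loss = contrastive_loss([a], [cands], [0], tau=0.05)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-10)

    def test_contrastive_hand_oracle(self):
        # cosine sims 0.9, 0.2, -0.5 at tau=0.05 (scalar arithmetic oracle)
        sims = np.array([0.9, 0.2, -0.5])
        expected = -np.log(np.exp(sims / 0.05)[0] / np.exp(sims / 0.05).sum())
        a = const(np.array([1.0, 0.0]))
        cands = [const(np.array([s, np.sqrt(1 - s * s)])) for s in sims]
        loss = contrastive_loss([a], [cands], [0], tau=0.05)
        assert float(loss.data) == pytest.approx(expected, abs=1e-9)

    def test_anchor_without_positive_fatal(self):
        a = const(np.ones(2))
        with pytest.raises(ModelError):
            contrastive_loss([a], [[a]], [3], tau=0.05)


class TestPairSampling:
    def test_eligible_gap_window(self, rng):
        recs = [record_at("a", "AD", [0, 400]), record_at("b", "AD", [0, 500])]
        pos, neg = sample_progression_pairs(recs, rng)
        assert ("a", 0, 1) in pos
        assert all(p != q for p, _, q, _ in neg)

    def test_below_minimum_gap_no_positive(self, rng):
        recs = [record_at("a", "AD", [0, 30]), record_at("b", "AD", [0, 400])]
        pos, _ = sample_progression_pairs(recs, rng)
        assert all(pid != "a" for pid, _, _ in pos)

    def test_above_maximum_gap_no_positive(self, rng):
        recs = [record_at("a", "AD", [0, 2000])]
        pos, _ = sample_progression_pairs(recs, rng)
        assert pos == []

    def test_negatives_span_two_patients(self, rng):
        recs = [record_at(p, "MCI", [0, 300, 600]) for p in "abcd"]
        _, neg = sample_progression_pairs(recs, rng)
        assert neg and all(pid != q for pid, _, q, _ in neg)


class TestTraining:
    def test_lambda_zero_reduces_to_classification_loss(self, small_corpus):
        records, cache = small_corpus
        cfg = lightweight_config(seed=0, epochs=2, lambda_contrast=0.0)
        model = CognitraceModel(cfg)
        model.fit(records[:12], cache=cache)
        for h in model.history_:
            assert h["l_total"] == pytest.approx(h["l_cls"], abs=1e-12)
            assert h["l_contrast"] == 0.0

    def test_two_runs_same_seed_identical(self, small_corpus):
        records, cache = small_corpus
        outs = []
        for _ in range(2):
            cfg = lightweight_config(seed=4, epochs=2)
            model = CognitraceModel(cfg)
            model.fit(records[:18], cache=cache)
            outs.append(model.predict_proba(records[18:24]))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_loss_decreases_on_separable_corpus(self, small_corpus):
        records, cache = small_corpus
        cfg = lightweight_config(seed=0, epochs=5, lambda_contrast=0.0,
                                 batch_size=64, p_drop_path=0.0, lr=1e-2)
        model = CognitraceModel(cfg)
        model.fit(records, cache=cache)
        losses = [h["l_cls"] for h in model.history_]
        assert all(b < a for a, b in zip(losses, losses[1:])), losses

    def test_l_total_identity_per_logged_step(self, small_corpus):
        records, cache = small_corpus
        cfg = lightweight_config(seed=1, epochs=2, lambda_contrast=0.5)
        model = CognitraceModel(cfg)
        model.fit(records[:20], cache=cache)
        for h in model.history_:
            assert h["l_total"] == pytest.approx(
                h["l_cls"] + 0.5 * h["l_contrast"], abs=1e-9)

    def test_train_val_overlap_fatal(self, small_corpus):
        records, _ = small_corpus
        with pytest.raises(ModelError):
            train(records[:6], lightweight_config(epochs=1), val_records=records[:3])

    def test_empty_validation_allowed_but_no_early_stop(self, small_corpus):
        records, cache = small_corpus
        cfg = lightweight_config(seed=0, epochs=3)
        model = CognitraceModel(cfg)
        model.fit(records[:10], cache=cache)
        assert len(model.history_) == 3

    def test_variant_config_instantiation(self):
        for variant in ("transformer_only", "bilstm", "gnn", "no_psych", "full"):
            cfg = lightweight_config(variant=variant)
            model = CognitraceModel(cfg)
            assert (model.temporal is not None) == cfg.use_temporal
            assert bool(model.graph_weights) == cfg.use_graph
            assert (model.psych_proj is not None) == cfg.use_psych
        with pytest.raises(ModelError):
            ModelConfig(variant="everything")

    def test_gates_strictly_inside_unit_interval(self, small_corpus):
        records, cache = small_corpus
        cfg = lightweight_config(seed=0, epochs=1)
        model = CognitraceModel(cfg)
        model.fit(records[:10], cache=cache)
        feats = cache[records[0].patient_id]
        _, _, fused, _, _ = model.forward(feats)
        for gate in fused.gates.values():
            assert 0.0 < gate < 1.0
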