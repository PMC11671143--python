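"""Re-ranking: encodings, rank-regularized loss, training, inference."""

import math

import numpy as np
import pytest

from mednorm.candgen import HashedNgramEncoder, build_dense_index, build_sparse_index, generate_candidates
from mednorm.corpus import NIL, Corpus, Document, EntityMention
from mednorm.kb import Concept
from mednorm.rerank import (
    LinearHashedBackbone,
    ScoringBackbone,
    TrainConfig,
    apply_reranker,
    build_instances,
    encode_concept,
    encode_mention_context,
    rank_regularized_loss,
    rank_regularized_loss_grad,
    softmax_loss,
    spearman_s_vs_c,
    train_reranker,
)


class TestMentionContextEncoding:
    def test_window_clips_left_context(self):
        doc = Document("d", [("Biopsie des Myokards", 0)])
        m = EntityMention("m", "d", [(12, 20)], "Myokards")
        # last 6 characters before the span are "e des " -> "e des"
        assert encode_mention_context(m, doc, 6) == "e des <m> Myokards </m>"

    def test_window_zero_is_markers_only(self):
        doc = Document("d", [("Biopsie des Myokards", 0)])
        m = EntityMention("m", "d", [(12, 20)], "Myokards")
        assert encode_mention_context(m, doc, 0) == "<m> Myokards </m>"

    def test_mention_at_document_start_has_no_left_padding(self):
        doc = Document("d", [("Lupus vulgaris is rare", 0)])
        m = EntityMention("m", "d", [(0, 5)], "Lupus")
        assert encode_mention_context(m, doc, 10) == "<m> Lupus </m> vulgaris"


class TestConceptEncoding:
    def test_canonical_name_only(self):
        c = Concept(id="X", canonical_name="aspirin", aliases={("aspirin", "en")})
        assert encode_concept(c) == "aspirin"

    def test_alias_priority_target_then_english_then_rest(self):
        c = Concept(
            id="X",
            canonical_name="Myokardinfarkt",
            aliases={
                ("Myokardinfarkt", "de"),
                ("Herzinfarkt", "de"),
                ("myocardial infarction", "en"),
                ("infarctus du myocarde", "fr"),
            },
        )
        out = encode_concept(c, max_aliases=2, target_language="de")
        assert out == "Myokardinfarkt | Herzinfarkt | myocardial infarction"

    def test_nil_encodes_as_unk(self):
        assert encode_concept(None) == "[UNK]"


class TestBuildInstances:
    def _corpus(self, gold, scores):
        from mednorm.candgen import CandidateSet

        doc = Document("d", [("some context here", 0)])
        m = EntityMention("m", "d", [(5, 12)], "context", gold_ids=gold)
        m.candidates = CandidateSet(
            mention_id="m", entries=scores, k=64
        )
        return Corpus(documents=[doc], mentions=[m])

    def test_gold_at_rank_three_is_hot_at_index_two(self, tiny_kb):
        corpus = self._corpus({"C3"}, [("C1", 0.9), ("C2", 0.5), ("C3", 0.4)])
        inst = build_instances(corpus, tiny_kb, TrainConfig())[0]
        assert inst.gold_index == 2
        assert inst.gold_onehot[2] == 1.0 and inst.gold_onehot.sum() == 1.0

    def test_gold_absent_hot_at_nil(self, tiny_kb):
        corpus = self._corpus({"C9"}, [("C1", 0.9), ("C2", 0.5)])
        inst = build_instances(corpus, tiny_kb, TrainConfig())[0]
        assert inst.candidate_ids[-1] == NIL
        assert inst.gold_index == len(inst.candidate_ids) - 1

    def test_nil_gets_zero_cg_score(self, tiny_kb):
        corpus = self._corpus({"C1"}, [("C1", 0.9), ("C2", 0.5)])
        inst = build_instances(corpus, tiny_kb, TrainConfig())[0]
        assert inst.cg_scores.tolist() == [0.9, 0.5, 0.0]
        assert inst.candidate_encodings[-1] == "[UNK]"

    def test_mention_without_candidates_skipped(self, tiny_kb):
        doc = Document("d", [("text", 0)])
        m = EntityMention("m", "d", [(0, 4)], "text", gold_ids={"C1"})
        corpus = Corpus(documents=[doc], mentions=[m])
        assert build_instances(corpus, tiny_kb, TrainConfig()) == []


class TestLoss:
    def test_two_equal_scores_give_log_two(self):
        assert softmax_loss(np.array([0.0, 0.0]), 0) == pytest.approx(math.log(2), abs=1e-12)

    @pytest.mark.parametrize("k", [2, 5, 17])
    def test_constant_scores_give_log_k(self, k):
        s = np.full(k, 3.7)
        assert softmax_loss(s, 0) == pytest.approx(math.log(k), abs=1e-12)

    def test_hand_evaluated_closed_form(self):
        # s=(2,0), i=0: -2 + log(e^2 + 1)
        expected = -2 + math.log(math.exp(2) + 1)
        assert softmax_loss(np.array([2.0, 0.0]), 0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.126928, abs=1e-6)

    def test_stable_for_large_scores(self):
        assert np.isfinite(softmax_loss(np.array([1000.0, 999.0]), 0))

    def test_lambda_zero_reduces_to_softmax_loss(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(2, 10)
            s = rng.normal(size=n)
            c = rng.uniform(size=n)
            y = np.zeros(n)
            y[rng.integers(n)] = 1.0
            gold = int(np.argmax(y))
            assert rank_regularized_loss(s, c, y, 0.0) == pytest.approx(
                softmax_loss(s, gold), abs=1e-12
            )

    def test_hand_evaluated_regularized_value(self):
        # softmax term 0.126928... plus lambda * ||s - c||^2 = 1.0
        s, c, y = np.array([2.0, 0.0]), np.array([1.0, 0.0]), np.array([1.0, 0.0])
        expected = -2 + math.log(math.exp(2) + 1) + 1.0
        assert rank_regularized_loss(s, c, y, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_zero_regularizer_when_scores_match_cg(self):
        s = np.array([0.9, 0.5, 0.0])
        y = np.array([1.0, 0.0, 0.0])
        assert rank_regularized_loss(s, s, y, 5.0) == pytest.approx(
            softmax_loss(s, 0), abs=1e-12
        )

    def test_loss_strictly_increasing_in_lambda_when_s_differs_from_c(self):
        s, c = np.array([1.0, 0.2]), np.array([0.5, 0.1])
        y = np.array([1.0, 0.0])
        values = [rank_regularized_loss(s, c, y, lam) for lam in (0.0, 0.5, 1.0, 2.0)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length mismatch"):
            rank_regularized_loss(np.zeros(3), np.zeros(2), np.array([1, 0, 0]), 1.0)

    def test_gradient_matches_central_finite_differences(self):
        rng = np.random.default_rng(42)
        eps = 1e-6
        for _ in range(50):
            n = int(rng.integers(2, 12))
            s = rng.normal(size=n)
            c = rng.uniform(size=n)
            y = np.zeros(n)
            y[rng.integers(n)] = 1.0
            lam = float(rng.uniform(0, 3))
            grad = rank_regularized_loss_grad(s, c, y, lam)
            for j in range(n):
                sp, sm = s.copy(), s.copy()
                sp[j] += eps
                sm[j] -= eps
                fd = (
                    rank_regularized_loss(sp, c, y, lam)
                    - rank_regularized_loss(sm, c, y, lam)
                ) / (2 * eps)
                assert grad[j] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class _CGCopyBackbone(ScoringBackbone):
    """Returns the CG score vector verbatim (identity re-ranker)."""

    def score_instance(self, instance):
        return instance.cg_scores.copy()

    def score(self, m, e):  # pragma: no cover - not used
        return 0.0


def _prepared(kb, corpus):
    indices = {
        "sparse": build_sparse_index(kb, 3),
        "dense": build_dense_index(kb, HashedNgramEncoder(128, 3)),
    }
    generate_candidates(corpus, indices, k=64)
    return corpus


class TestTrainAndApply:
    def test_zero_epochs_leaves_backbone_unchanged(self, small_kb, small_corpora):
        train, _ = small_corpora
        _prepared(small_kb, train)
        cfg = TrainConfig(epochs=0)
        instances = build_instances(train, small_kb, cfg)
        backbone = LinearHashedBackbone()
        before = backbone.weights.copy()
        train_reranker(instances, backbone, cfg)
        assert np.array_equal(backbone.weights, before)

    def test_training_is_deterministic(self, small_kb, small_corpora):
        train, _ = small_corpora
        _prepared(small_kb, train)
        cfg = TrainConfig(epochs=3, seed=1)
        instances = build_instances(train, small_kb, cfg)
        w = []
        for _ in range(2):
            bb = LinearHashedBackbone()
            train_reranker(instances, bb, cfg)
            w.append(bb.weights.copy())
        assert np.array_equal(w[0], w[1])

    def test_trained_model_beats_cg_on_separable_fixture(self, small_kb, small_corpora):
        train, test = small_corpora
        _prepared(small_kb, train)
        _prepared(small_kb, test)
        cfg = TrainConfig(lambda_reg=1.0, epochs=10, seed=5)
        instances = build_instances(train, small_kb, cfg)
        backbone = LinearHashedBackbone()
        train_reranker(instances, backbone, cfg)

        for m in test.mentions:
            m.prediction = m.candidates.entries[0][0]
        cg_acc = np.mean([m.prediction in m.gold_ids for m in test.mentions])
        apply_reranker(test, backbone, small_kb, cfg)
        rr_acc = np.mean([m.prediction in m.gold_ids for m in test.mentions])
        assert rr_acc > cg_acc

    def test_identity_backbone_preserves_cg_order(self, small_kb, small_corpora):
        _, test = small_corpora
        _prepared(small_kb, test)
        cfg = TrainConfig()
        apply_reranker(test, _CGCopyBackbone(), small_kb, cfg)
        for m in test.mentions:
            cg_top = m.candidates.entries[: cfg.k_train]
            assert m.reranked.ids[: len(cg_top)] == [cid for cid, _s in cg_top]

    def test_nil_scoring_backbone_abstains(self, small_kb, small_corpora):
        _, test = small_corpora
        _prepared(small_kb, test)

        class NilBackbone(ScoringBackbone):
            def score_instance(self, instance):
                s = np.zeros(len(instance.candidate_ids))
                s[-1] = 10.0
                return s

            def score(self, m, e):  # pragma: no cover
                return 0.0

        apply_reranker(test, NilBackbone(), small_kb, TrainConfig())
        assert all(m.prediction == NIL for m in test.mentions)

    def test_spearman_rises_with_lambda(self, small_kb, small_corpora):
        train, test = small_corpora
        _prepared(small_kb, train)
        _prepared(small_kb, test)
        cfg = TrainConfig(epochs=8, seed=2)
        tr = build_instances(train, small_kb, cfg)
        ho = build_instances(test, small_kb, cfg)
        rhos = {}
        for lam in (0.0, 10.0):
            bb = LinearHashedBackbone()
            train_reranker(tr, bb, TrainConfig(lambda_reg=lam, epochs=8, seed=2))
            rhos[lam] = spearman_s_vs_c(ho, bb)
        assert rhos[10.0] > rhos[0.0]


class TestModelPersistence:
    def test_save_load_round_trip(self, tmp_path):
        bb = LinearHashedBackbone(dim=2**12)
        bb.weights[[3, 7, 100]] = [0.5, -1.25, 3.0]
        path = tmp_path / "model.json"
        bb.save(path)
        loaded = LinearHashedBackbone.load(path)
        assert loaded.dim == bb.dim
        assert np.array_equal(loaded.weights, bb.weights)

    def test_version_tag_checked(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"format": "other", "dim": 4, "n": 3, "indices": [], "values": []}')
        with pytest.raises(ValueError, match="format"):
            LinearHashedBackbone.load(path)
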