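"""Classifier math, tokenization contract, training loop and prediction."""

import math
from decimal import Decimal, getcontext

import numpy as np
import pytest

from synoplab.classifier_core import (
    SynopsisClassifier,
    TrainConfig,
    bce_loss,
    encode,
    labelset_to_vector,
    sigmoid,
    train,
    vector_to_labelset,
)
from synoplab.corpus_io import LabelSet, LabelVocabulary, Synopsis, serialize_synopsis
from synoplab.encoders import CLS_ID, PAD_ID, HashingEncoder

from conftest import fit_on_split, planted_config


def sigmoid_highprec(x: float) -> float:
    """Independent evaluation of the logistic function at 50 digits."""
    getcontext().prec = 50
    d = Decimal(float(x))
    return float(1 / (1 + (-d).exp()))


def bce_brute(logits, targets, weights) -> float:
    """Element-by-element cross-entropy with high-precision sigmoids."""
    total = 0.0
    n = 0
    for i in range(len(logits)):
        for j in range(len(logits[i])):
            s = sigmoid_highprec(logits[i][j])
            y = targets[i][j]
            total += -weights[j] * (y * math.log(s) + (1 - y) * math.log(1 - s))
            n += 1
    return total / n


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert sigmoid(0.0) == 0.5

    def test_value_at_ten(self):
        assert sigmoid(10.0) == pytest.approx(0.9999546021312976, abs=1e-12)

    def test_symmetry(self):
        assert sigmoid(-2.0) == pytest.approx(1 - sigmoid(2.0), abs=1e-15)

    def test_saturates_without_overflow(self):
        assert sigmoid(1e4) == 1.0 and sigmoid(-1e4) == 0.0

    def test_matches_high_precision_on_random_inputs(self):
        rng = np.random.default_rng(0)
        xs = rng.normal(0, 5, size=200)
        for x in xs:
            assert sigmoid(float(x)) == pytest.approx(sigmoid_highprec(float(x)), abs=1e-9)


class TestBceLoss:
    def test_zero_logit_positive_target_is_ln2(self):
        assert bce_loss(np.array([[0.0]]), np.array([[1.0]])) == pytest.approx(math.log(2), abs=1e-12)

    def test_saturated_positive_is_near_zero(self):
        assert bce_loss(np.array([[20.0]]), np.array([[1.0]])) == pytest.approx(0.0, abs=1e-8)

    def test_batch_of_identical_items_equals_single(self):
        x = np.array([[1.3, -0.4]])
        y = np.array([[1.0, 0.0]])
        single = bce_loss(x, y)
        assert bce_loss(np.repeat(x, 5, axis=0), np.repeat(y, 5, axis=0)) == pytest.approx(single)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((2, 3)), np.zeros((2, 2)))

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            B, L = rng.integers(1, 6), rng.integers(1, 5)
            logits = rng.normal(0, 4, size=(B, L))
            targets = rng.integers(0, 2, size=(B, L)).astype(float)
            w = rng.uniform(0.5, 2.0, size=L)
            assert bce_loss(logits, targets, w) == pytest.approx(
                bce_brute(logits, targets, w), abs=1e-9
            )


class TestEncode:
    def test_empty_string_is_cls_plus_padding(self):
        enc = HashingEncoder(256, max_length=8)
        out = encode("", enc)
        assert out.token_ids[0] == CLS_ID
        assert np.all(out.token_ids[1:] == PAD_ID)
        assert out.attention_mask.tolist() == [1] + [0] * 7

    def test_deterministic(self):
        enc = HashingEncoder(256, max_length=16)
        a, b = encode("marrow aspirate", enc), encode("marrow aspirate", enc)
        assert np.array_equal(a.token_ids, b.token_ids)

    def test_overlong_input_truncated_to_maximum(self):
        enc = HashingEncoder(256, max_length=8)
        out = encode(" ".join(f"w{i}" for i in range(50)), enc)
        assert len(out.token_ids) == 8 and np.all(out.attention_mask == 1)


@pytest.fixture(scope="module")
def planted_model():
    from synoplab.synthetic_data import generate_corpus

    corpus, truth = generate_corpus(planted_config(150, seed=2))
    model = fit_on_split(corpus, TrainConfig(seed=0))
    return corpus, truth, model


class TestTrain:
    def test_single_epoch_returns_that_snapshot(self, gen300):
        corpus, _ = gen300
        model = fit_on_split(corpus, TrainConfig(seed=0, epochs=1))
        assert len(model.trace) == 1

    def test_same_seed_reproduces_metric_trace(self, gen300):
        corpus, _ = gen300
        a = fit_on_split(corpus, TrainConfig(seed=5, epochs=2))
        b = fit_on_split(corpus, TrainConfig(seed=5, epochs=2))
        assert a.trace == b.trace

    def test_best_epoch_dominates_trace(self, model300):
        best = model300.best_val_f1
        assert all(row["val_micro_f1"] <= best for row in model300.trace)

    def test_empty_split_rejected(self, gen300):
        corpus, _ = gen300
        cases = corpus.labeled_cases()
        with pytest.raises(ValueError):
            train([], cases[:3], TrainConfig())

    def test_validation_label_outside_vocabulary_rejected(self, gen300):
        corpus, _ = gen300
        cases = corpus.labeled_cases()
        vocab = LabelVocabulary(["normal"])
        with pytest.raises(ValueError):
            train(cases[:5], cases[5:8], TrainConfig(), vocab=vocab)

    def test_planted_corpus_reaches_high_f1(self, planted_model):
        _, _, model = planted_model
        assert model.best_val_f1 >= 0.95


class TestPredict:
    def test_thresholding_selects_expected_labels(self):
        vocab = LabelVocabulary(["a", "b", "c"])
        ls = vector_to_labelset(np.array([0.9, 0.4, 0.6]), vocab, 0.5)
        assert set(ls.labels) == {"a", "c"}

    def test_all_below_threshold_is_abstention(self):
        vocab = LabelVocabulary(["a", "b"])
        assert len(vector_to_labelset(np.array([0.2, 0.1]), vocab, 0.5)) == 0

    def test_scores_are_sigmoid_of_logits(self, model300, gen300):
        corpus, _ = gen300
        text = serialize_synopsis(corpus.synopsis(corpus.ids[0]))
        assert np.allclose(
            model300.score_texts([text]), sigmoid(model300.logits_texts([text])), atol=1e-6
        )

    def test_keyword_case_predicted_with_its_label(self, planted_model):
        corpus, truth, model = planted_model
        label = "acute myeloid leukemia"
        hits = 0
        carriers = [c for c in corpus.labeled_cases() if label in c.gold][:10]
        for c in carriers:
            _, pred = model.predict(c.synopsis)
            hits += label in pred
        assert hits >= 0.8 * len(carriers)

    def test_vocab_mismatch_rejected(self, model300, gen300):
        corpus, _ = gen300
        with pytest.raises(ValueError, match="mismatch"):
            model300.predict(corpus.synopsis(corpus.ids[0]), vocab=LabelVocabulary(["x"]))

    def test_target_vector_round_trip(self):
        vocab = LabelVocabulary(["a", "b", "c"])
        ls = LabelSet(["a", "c"])
        v = labelset_to_vector(ls, vocab)
        assert v.tolist() == [1.0, 0.0, 1.0]
        assert vector_to_labelset(v, vocab, 0.5).labels == ls.labels


class TestEmbedding:
    def test_deterministic_and_pure_function_of_text(self, model300):
        s1 = Synopsis("p", [("cellularity", "adequate"), ("comment", "none")])
        s2 = Synopsis("q", [("cellularity", "adequate"), ("comment", "none")])
        e1, e2 = model300.embed(s1), model300.embed(s2)
        assert np.array_equal(e1, model300.embed(s1))
        assert np.array_equal(e1, e2)

    def test_width_equals_encoder_width(self, model300):
        s = Synopsis("p", [("comment", "none")])
        assert model300.embed(s).shape == (model300.embedding_dim,)
        assert model300.embedding_dim == model300.cfg.embedding_dim


class TestPersistence:
    def test_save_load_round_trip(self, model300, gen300, tmp_path):
        corpus, _ = gen300
        model300.save(tmp_path / "model")
        back = SynopsisClassifier.load(tmp_path / "model")
        s = corpus.synopsis(corpus.ids[0])
        assert back.vocab == model300.vocab
        assert np.allclose(back.predict_scores(s), model300.predict_scores(s))
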