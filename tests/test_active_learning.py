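"""Rare-label sampling loop: rarity, candidate selection, full iterations."""

import numpy as np
import pytest

from synoplab.active_learning import (
    find_rare_labels,
    random_baseline,
    run_active_learning,
    run_iteration,
    sample_crl,
    select_candidates,
)
from synoplab.classifier_core import TrainConfig
from synoplab.corpus_io import Corpus, LabeledCase, LabelSet, LabelVocabulary, Synopsis
from synoplab.synthetic_data import (
    GeneratorConfig,
    SyntheticOracle,
    generate_corpus,
    unlabeled_pool,
)

FAST = TrainConfig(seed=0, epochs=3)


def labeled_with_counts(counts):
    cases = []
    k = 0
    for lab, n in counts.items():
        for _ in range(n):
            cases.append(LabeledCase(Synopsis(f"c{k}", [("f", "t")]), LabelSet([lab])))
            k += 1
    return Corpus(cases)


class TestFindRareLabels:
    def test_nineteen_is_rare_at_twenty(self):
        corpus = labeled_with_counts({"a": 19, "b": 25})
        assert find_rare_labels(corpus, 20) == {"a"}

    def test_exactly_twenty_is_not_rare(self):
        corpus = labeled_with_counts({"a": 20})
        assert find_rare_labels(corpus, 20) == set()

    def test_empty_corpus_every_vocab_label_rare(self):
        vocab = LabelVocabulary(["a", "b"])
        assert find_rare_labels(Corpus(), 20, vocab) == {"a", "b"}

    def test_threshold_below_one_rejected(self):
        with pytest.raises(ValueError):
            find_rare_labels(Corpus(), 0)


def score_table(vocab, spec):
    """spec: {case_id: {label: score}} -> dense score vectors."""
    out = {}
    for cid, labscores in spec.items():
        v = np.zeros(len(vocab))
        for lab, s in labscores.items():
            v[vocab.index(lab)] = s
        out[cid] = v
    return out


class TestSampleCrl:
    def test_requests_threshold_minus_count(self):
        vocab = LabelVocabulary(["a"])
        preds = score_table(vocab, {f"p{i}": {"a": 0.9} for i in range(10)})
        got = sample_crl(preds, {"a"}, 20, {"a": 18}, vocab, seed=0)
        assert len(got) == 2

    def test_satisfied_label_requests_nothing(self):
        vocab = LabelVocabulary(["a"])
        preds = score_table(vocab, {"p0": {"a": 0.9}})
        assert sample_crl(preds, set(), 20, {"a": 25}, vocab, seed=0) == set()

    def test_shared_candidate_deduplicated(self):
        vocab = LabelVocabulary(["a", "b"])
        preds = score_table(vocab, {"p0": {"a": 0.9, "b": 0.8}})
        got = sample_crl(preds, {"a", "b"}, 2, {"a": 1, "b": 1}, vocab, seed=0)
        assert got == {"p0"}

    def test_undersized_group_topped_up_by_ranking(self):
        vocab = LabelVocabulary(["a"])
        preds = score_table(vocab, {"hi": {"a": 0.45}, "mid": {"a": 0.30}, "lo": {"a": 0.05}})
        got = sample_crl(preds, {"a"}, 3, {"a": 1}, vocab, seed=0)
        assert got == {"hi", "mid"}


class TestSelectCandidates:
    def test_cap_triggers_threshold_decrement(self):
        vocab = LabelVocabulary(["a"])
        preds = score_table(vocab, {f"p{i}": {"a": 0.9} for i in range(200)})
        cands, working = select_candidates(preds, {"a": 0}, vocab, threshold=150,
                                           seed=0, cap=100, decrement=5)
        assert working < 150 and len(cands) <= 100

    def test_within_cap_keeps_threshold(self):
        vocab = LabelVocabulary(["a"])
        preds = score_table(vocab, {f"p{i}": {"a": 0.9} for i in range(50)})
        cands, working = select_candidates(preds, {"a": 0}, vocab, threshold=20,
                                           seed=0, cap=100, decrement=5)
        assert working == 20 and len(cands) == 20

    def test_threshold_driven_below_one_raises(self):
        vocab = LabelVocabulary([f"l{i}" for i in range(300)])
        preds = {f"p{i}": np.full(300, 0.9) for i in range(400)}
        with pytest.raises(RuntimeError):
            select_candidates(preds, {}, vocab, threshold=4, seed=0, cap=2, decrement=5)


@pytest.fixture(scope="module")
def small_pool():
    corpus, truth = generate_corpus(GeneratorConfig(n_cases=1200, seed=21))
    return corpus, truth


class TestRunIteration:
    def test_no_rare_labels_only_bumps_iteration(self, small_pool):
        from synoplab.active_learning import ALState

        corpus, truth = small_pool
        oracle = SyntheticOracle(truth)
        labeled = Corpus(list(corpus.labeled_cases())[:300])
        pool = unlabeled_pool(Corpus(list(corpus.labeled_cases())[300:]))
        vocab = LabelVocabulary(labeled.label_counts)
        state = ALState(labeled=labeled, unlabeled_pool=pool, vocabulary=vocab, threshold=1)
        before_ids = set(labeled.ids)
        new_state, _ = run_iteration(state, oracle, FAST)
        assert new_state.iteration == 1
        assert set(new_state.labeled.ids) == before_ids

    def test_enrichment_grows_rarest_labels(self, small_pool):
        from synoplab.active_learning import ALState

        corpus, truth = small_pool
        oracle = SyntheticOracle(truth)
        ids = oracle.sample_initial(corpus.ids, 60, np.random.default_rng(0))
        labeled = Corpus(corpus[i] for i in ids)
        pool = unlabeled_pool(Corpus(corpus[i] for i in corpus.ids if i not in set(ids)))
        vocab = LabelVocabulary(labeled.label_counts)
        state = ALState(labeled=labeled, unlabeled_pool=pool, vocabulary=vocab, threshold=10)
        new_state, _ = run_iteration(state, oracle, FAST)
        assert len(new_state.labeled) > 60
        assert new_state.history[-1]["cases_added"] > 0
        assert not set(new_state.labeled.ids) & set(new_state.unlabeled_pool.ids)


class TestRunActiveLearning:
    def test_terminates_balanced_and_discovers_hidden(self, small_pool):
        corpus, truth = small_pool
        oracle = SyntheticOracle(truth)
        state = run_active_learning(unlabeled_pool(corpus), oracle, FAST,
                                    initial_n=40, schedule=(5, 10), seed=0)
        counts = state.labeled.label_counts
        for lab in state.vocabulary.labels:
            if lab not in state.shortfall:
                assert counts.get(lab, 0) >= 10
        # hidden label has ample pool support here, so it must be found
        assert "basophilia" in state.vocabulary.labels
        assert oracle.reveal_events == ["basophilia"]

    def test_weakest_schedule_single_pass(self, small_pool):
        corpus, truth = small_pool
        state = run_active_learning(unlabeled_pool(corpus), SyntheticOracle(truth), FAST,
                                    initial_n=40, schedule=(1,), seed=0)
        assert state.iteration <= 1

    def test_unsupported_label_reported_short(self, small_pool):
        corpus, truth = small_pool
        # demand more cases of the rarest label than the whole pool holds
        support = corpus.label_counts["hypocellular"]
        state = run_active_learning(unlabeled_pool(corpus), SyntheticOracle(truth), FAST,
                                    initial_n=40, schedule=(support + 50,), seed=0,
                                    max_iterations=12)
        assert "hypocellular" in state.shortfall

    def test_labeled_set_grows_monotonically(self, small_pool):
        corpus, truth = small_pool
        state = run_active_learning(unlabeled_pool(corpus), SyntheticOracle(truth), FAST,
                                    initial_n=40, schedule=(5, 10), seed=1)
        sizes = [h["cases_added"] for h in state.history]
        assert all(s >= 0 for s in sizes)
        assert len(state.labeled) == sum(sizes)

    def test_budget_extension_reaches_budget(self, small_pool):
        corpus, truth = small_pool
        state = run_active_learning(unlabeled_pool(corpus), SyntheticOracle(truth), FAST,
                                    initial_n=40, schedule=(5, 10), seed=0, budget=200)
        assert len(state.labeled) >= 200


class TestRandomBaseline:
    def test_full_budget_takes_entire_pool(self, small_pool):
        corpus, truth = small_pool
        pool = unlabeled_pool(Corpus(list(corpus.labeled_cases())[:30]))
        got = random_baseline(pool, SyntheticOracle(truth), 30, seed=0)
        assert set(got.ids) == set(pool.ids)

    def test_deterministic_by_seed(self, small_pool):
        corpus, truth = small_pool
        pool = unlabeled_pool(corpus)
        a = random_baseline(pool, SyntheticOracle(truth), 50, seed=4)
        b = random_baseline(pool, SyntheticOracle(truth), 50, seed=4)
        assert a.ids == b.ids

    def test_rare_label_coverage_below_active_learning(self, small_pool):
        """At equal budget, random sampling covers rare labels less than the
        enrichment loop, in expectation over seeds."""
        corpus, truth = small_pool
        pool = unlabeled_pool(corpus)
        rare = [lab for lab, n in corpus.label_counts.items() if n < 60]
        al_cov, rand_cov = [], []
        for seed in range(2):
            state = run_active_learning(pool, SyntheticOracle(truth), FAST,
                                        initial_n=40, schedule=(5, 10), seed=seed)
            budget = len(state.labeled)
            rand = random_baseline(pool, SyntheticOracle(truth), budget, seed=seed)
            al_counts, r_counts = state.labeled.label_counts, rand.label_counts
            al_cov.append(np.mean([al_counts.get(lab, 0) for lab in rare]))
            rand_cov.append(np.mean([r_counts.get(lab, 0) for lab in rare]))
        assert np.mean(al_cov) > np.mean(rand_cov)
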