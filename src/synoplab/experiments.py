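"""Study-level experiments composed from the pipeline stages.

These are the desk-scale analogues of the study designs the package exists
to support: enrichment-vs-random-sampling arm comparisons at a fixed
labeling budget against a rare-label-enriched benchmark, and the final
model ensemble trained on repeated adapted-MCCV splits.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .active_learning import random_baseline, run_active_learning
from .classifier_core import SynopsisClassifier, TrainConfig, train
from .corpus_io import Corpus, LabelSet, LabelVocabulary
from .data_splits import al_stage_split, repeat_mccv
from .evaluation import EvalReport, evaluate

__all__ = ["fit_arm", "benchmark_micro_f1", "al_vs_random", "mccv_ensemble"]


def fit_arm(arm: Corpus, cfg: TrainConfig, seed: int) -> SynopsisClassifier:
    """Train on a labeled arm with the AL-stage 80/20 split."""
    split = al_stage_split(arm, ratio=0.2, seed=seed)
    return train(
        [arm[i] for i in split.train_ids],
        [arm[i] for i in split.validation_ids],
        replace(cfg, seed=seed),
    )


def benchmark_micro_f1(model: SynopsisClassifier, benchmark: Corpus,
                       full_vocab: LabelVocabulary, augmented: bool = False) -> float:
    """Micro-F1 of a model on a fixed benchmark, scored against the full
    label vocabulary (labels the model never saw count as misses)."""
    cases = benchmark.labeled_cases()
    pred = {}
    scores = model.predict_corpus_scores(benchmark, augmented=augmented)
    for c in cases:
        s = scores[c.case_id]
        labs = [lab for i, lab in enumerate(model.vocab.labels)
                if s[i] >= model.cfg.decision_threshold and lab in full_vocab]
        pred[c.case_id] = LabelSet(labs)
    gold = {c.case_id: c.gold for c in cases}
    return evaluate(pred, gold, full_vocab).micro_f1


def al_vs_random(
    pool: Corpus,
    make_oracle,
    benchmark: Corpus,
    full_vocab: LabelVocabulary,
    cfg: TrainConfig,
    budget: int = 400,
    seeds=(0, 1, 2, 3),
    schedule=(10, 15, 20),
    initial_n: int = 50,
) -> pd.DataFrame:
    """Enrichment arm vs uniform-sampling arm at equal labeling budget.

    Each seed runs the full active-learning loop to the budget, labels an
    equally sized uniform sample through a fresh oracle, trains one model
    per arm, and scores both on the same fixed benchmark.  Returns one row
    per (seed, arm).
    """
    rows = []
    for seed in seeds:
        state = run_active_learning(pool, make_oracle(), replace(cfg, seed=int(seed)),
                                    initial_n=initial_n, schedule=schedule,
                                    seed=int(seed), budget=budget)
        n = len(state.labeled)
        al_model = fit_arm(state.labeled, cfg, int(seed))
        rows.append({"seed": int(seed), "arm": "active", "n_labeled": n,
                     "micro_f1": benchmark_micro_f1(al_model, benchmark, full_vocab)})
        rand = random_baseline(pool, make_oracle(), n, seed=int(seed))
        rand_model = fit_arm(rand, cfg, int(seed))
        rows.append({"seed": int(seed), "arm": "random", "n_labeled": n,
                     "micro_f1": benchmark_micro_f1(rand_model, benchmark, full_vocab)})
    return pd.DataFrame(rows)


def mccv_ensemble(
    development: Corpus,
    cfg: TrainConfig,
    ratio: float = 0.2,
    n_repeats: int = 4,
    seeds=None,
) -> tuple[list[SynopsisClassifier], list[EvalReport]]:
    """Final models from repeated adapted-MCCV splits of a development set.

    Returns the fitted models and their validation reports; the mean and
    spread of the validation micro-F1 over repeats summarize final
    performance.
    """
    models, reports = [], []
    for split in repeat_mccv(development, ratio, n_repeats, seeds=seeds):
        model = train(
            [development[i] for i in split.train_ids],
            [development[i] for i in split.validation_ids],
            replace(cfg, seed=int(split.seed)),
        )
        models.append(model)
        val = Corpus(development[i] for i in split.validation_ids)
        pred = {}
        scores = model.predict_corpus_scores(val, augmented=False)
        for c in val.labeled_cases():
            s = scores[c.case_id]
            pred[c.case_id] = LabelSet(
                lab for i, lab in enumerate(model.vocab.labels)
                if s[i] >= model.cfg.decision_threshold
            )
        gold = {c.case_id: c.gold for c in val.labeled_cases()}
        reports.append(evaluate(pred, gold, model.vocab))
    return models, reports
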