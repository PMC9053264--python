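"""Rare-label active learning (CRL sampling).

Labels with fewer labeled cases than a threshold are *rare*; each iteration
trains a model on the current labeled set, predicts the unlabeled pool, and
samples ``threshold - count(label)`` pool cases from each rare label's
predicted group.  Whenever the candidate set exceeds a cap (default 100),
the working threshold drops by a decrement (default 5) and sampling is
redone, so the labeling oracle is never overwhelmed.  Verified candidates —
whose review may introduce brand-new labels — merge into the labeled set,
and iterations continue until no label is rare at the final threshold.

The labeling oracle is an interface: the synthetic generator supplies the
default implementation, and a file-based oracle supports human review
workflows (write a candidates CSV, read back a verified CSV).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .classifier_core import SynopsisClassifier, TrainConfig, train
from .corpus_io import Corpus, LabeledCase, LabelSet, LabelVocabulary
from .data_splits import al_stage_split

__all__ = [
    "ALState",
    "LabelOracle",
    "FileOracle",
    "find_rare_labels",
    "sample_crl",
    "select_candidates",
    "run_iteration",
    "run_active_learning",
    "random_baseline",
]

logger = logging.getLogger(__name__)


class LabelOracle(Protocol):
    """The labeling authority: verifies candidate cases' labels.

    Answers must be stable (same id, same answer); labels not yet in the
    vocabulary may be introduced only through the returned label sets.
    """

    def label(self, case_ids: Sequence[str]) -> dict[str, LabelSet]: ...


@dataclass
class ALState:
    labeled: Corpus
    unlabeled_pool: Corpus
    vocabulary: LabelVocabulary
    threshold: int
    iteration: int = 0
    history: list[dict] = field(default_factory=list)
    shortfall: dict[str, int] = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "state.json").write_text(json.dumps(
            {"iteration": self.iteration, "threshold": self.threshold,
             "vocabulary": self.vocabulary.labels,
             "labeled_ids": self.labeled.ids, "pool_ids": self.unlabeled_pool.ids,
             "history": self.history, "shortfall": self.shortfall}, indent=1))


def find_rare_labels(labeled: Corpus, threshold: int,
                     vocab: LabelVocabulary | None = None) -> set[str]:
    """Labels with strictly fewer labeled cases than ``threshold``."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts = labeled.label_counts
    labels = vocab.labels if vocab is not None else list(counts)
    return {lab for lab in labels if counts.get(lab, 0) < threshold}


def sample_crl(
    predictions: dict[str, np.ndarray],
    rare: set[str],
    threshold: int,
    labeled_counts: dict[str, int],
    vocab: LabelVocabulary,
    seed: int,
    decision_threshold: float = 0.5,
) -> set[str]:
    """Sample candidate pool cases for each rare label.

    For each rare label (processed rarest first, so the rarest labels claim
    shared candidates), ``threshold - count(label)`` cases are drawn
    uniformly at random from the pool cases the model predicts to carry that
    label; a case satisfying several rare labels appears once.  When the
    thresholded group is smaller than requested — common for labels the
    model has barely seen — the request is topped up with the unselected
    pool cases ranked highest by that label's score, so candidate selection
    stays model-guided even before the label is learnable.
    """
    rng = np.random.default_rng(seed)
    pool_ids = list(predictions)
    chosen: set[str] = set()
    for lab in sorted(rare, key=lambda l: (labeled_counts.get(l, 0), l)):
        need = threshold - labeled_counts.get(lab, 0)
        if need <= 0:
            continue
        j = vocab.index(lab)
        group = [cid for cid in pool_ids
                 if cid not in chosen and predictions[cid][j] >= decision_threshold]
        if len(group) >= need:
            picks = rng.choice(len(group), size=need, replace=False)
            chosen.update(group[i] for i in picks)
            continue
        chosen.update(group)
        short = need - len(group)
        below = [cid for cid in pool_ids
                 if cid not in chosen and predictions[cid][j] < decision_threshold]
        below.sort(key=lambda cid: -predictions[cid][j])
        logger.info("label %r: predicted group has %d cases, %d requested; "
                    "topping up with %d best-ranked", lab, len(group), need,
                    min(short, len(below)))
        chosen.update(below[:short])
    return chosen


def select_candidates(
    predictions: dict[str, np.ndarray],
    labeled_counts: dict[str, int],
    vocab: LabelVocabulary,
    threshold: int,
    seed: int,
    cap: int = 100,
    decrement: int = 5,
    decision_threshold: float = 0.5,
    exclude: frozenset[str] = frozenset(),
) -> tuple[set[str], int]:
    """CRL sampling with the cap-and-decrement rule.

    While the candidate set exceeds ``cap``, the working threshold drops by
    ``decrement`` and sampling is redone.  Labels in ``exclude`` (pool
    support exhausted) are never sampled for.  Returns the final candidate
    set and the working threshold it was drawn at.
    """
    working = threshold
    while True:
        rare = {lab for lab in vocab.labels
                if labeled_counts.get(lab, 0) < working and lab not in exclude}
        candidates = sample_crl(predictions, rare, working, labeled_counts, vocab,
                                seed=seed, decision_threshold=decision_threshold)
        if len(candidates) <= cap:
            return candidates, working
        working -= decrement
        if working < 1:
            raise RuntimeError("working threshold driven below 1 by the candidate cap")
        logger.info("candidate set of %d exceeds cap %d; lowering threshold to %d",
                    len(candidates), cap, working)


def _merge_verified(state: ALState, verified: dict[str, LabelSet]) -> tuple[list[str], list[str]]:
    """Move verified cases from pool to labeled; grow the vocabulary."""
    new_labels: list[str] = []
    added: list[str] = []
    for cid, gold in verified.items():
        for lab in gold:
            if state.vocabulary.add(lab):
                new_labels.append(lab)
        syn = state.unlabeled_pool.synopsis(cid)
        state.unlabeled_pool.remove(cid)
        state.labeled.add(LabeledCase(syn, gold))
        added.append(cid)
    return added, new_labels


def run_iteration(
    state: ALState,
    oracle: LabelOracle,
    model_cfg: TrainConfig,
    cap: int = 100,
    decrement: int = 5,
    exclude: frozenset[str] = frozenset(),
) -> tuple[ALState, SynopsisClassifier]:
    """One sampling-training-sampling iteration; returns new state + model."""
    counts = state.labeled.label_counts
    rare = find_rare_labels(state.labeled, state.threshold, state.vocabulary) - exclude
    seed = int(model_cfg.seed) + state.iteration

    split = al_stage_split(state.labeled, ratio=0.2, seed=seed)
    model = train(
        [state.labeled[i] for i in split.train_ids],
        [state.labeled[i] for i in split.validation_ids],
        replace(model_cfg, seed=seed),
        vocab=state.vocabulary,
    )

    new_state = ALState(
        labeled=state.labeled,
        unlabeled_pool=state.unlabeled_pool,
        vocabulary=state.vocabulary,
        threshold=state.threshold,
        iteration=state.iteration + 1,
        history=list(state.history),
        shortfall=dict(state.shortfall),
    )
    if not rare:
        new_state.history.append({"iteration": new_state.iteration, "threshold": state.threshold,
                                  "cases_added": 0, "new_labels": []})
        return new_state, model

    predictions = model.predict_corpus_scores(state.unlabeled_pool)
    candidates, working = select_candidates(
        predictions, counts, state.vocabulary, state.threshold, seed=seed,
        cap=cap, decrement=decrement, decision_threshold=model_cfg.decision_threshold,
        exclude=exclude,
    )
    verified = oracle.label(sorted(candidates))
    added, new_labels = _merge_verified(new_state, verified)
    new_state.history.append({
        "iteration": new_state.iteration, "threshold": working,
        "cases_added": len(added), "new_labels": new_labels,
    })
    return new_state, model


def run_active_learning(
    pool: Corpus,
    oracle: LabelOracle,
    model_cfg: TrainConfig,
    initial_n: int = 50,
    schedule: Sequence[int] = (10, 15, 20),
    cap: int = 100,
    decrement: int = 5,
    max_iterations: int = 50,
    seed: int = 0,
    budget: int | None = None,
) -> ALState:
    """The full loop: seed with a random sample, then enrich rare labels.

    Early phases use the lowered thresholds of the schedule; the final
    threshold defines termination: no label rare, or no further progress
    possible (pool or predicted-group exhaustion), in which case the
    remaining shortfalls are reported on the returned state.

    With a ``budget``, once the schedule is satisfied the threshold keeps
    rising (by the schedule's final step) and enrichment continues until the
    labeled set reaches the budget — the mechanism for spending a labeling
    budget beyond the balance point, as when the label set is suspected not
    to cover the data yet.
    """
    rng = np.random.default_rng(seed)
    pool = pool.subset(pool.ids)  # private working copy
    pool_ids = pool.ids
    if len(pool_ids) <= initial_n:
        raise ValueError("pool must be larger than the initial sample")
    if hasattr(oracle, "sample_initial"):
        init_ids = list(oracle.sample_initial(pool_ids, initial_n, rng))
    else:
        init_ids = [pool_ids[i] for i in rng.choice(len(pool_ids), size=initial_n, replace=False)]

    state = ALState(labeled=Corpus(), unlabeled_pool=pool,
                    vocabulary=LabelVocabulary(), threshold=int(schedule[0]))
    _merge_verified(state, oracle.label(init_ids))
    state.history.append({"iteration": 0, "threshold": None,
                          "cases_added": initial_n,
                          "new_labels": state.vocabulary.labels})

    final_threshold = int(schedule[-1])
    thresholds = [int(t) for t in schedule]
    if budget is not None:
        step = max(thresholds[-1] - (thresholds[-2] if len(thresholds) > 1 else 0), decrement)
        t = thresholds[-1]
        while t * len(state.vocabulary) < 4 * budget:  # generous upper bound
            t += step
            thresholds.append(t)
    exhausted: set[str] = set()
    strikes: dict[str, int] = {}
    for threshold in thresholds:
        if budget is not None and len(state.labeled) >= budget:
            break
        state.threshold = int(threshold)
        while state.iteration < max_iterations:
            if budget is not None and len(state.labeled) >= budget:
                break
            rare = find_rare_labels(state.labeled, state.threshold, state.vocabulary) - exhausted
            if not rare:
                break
            before = len(state.labeled)
            counts_before = state.labeled.label_counts
            state, _ = run_iteration(state, oracle, model_cfg, cap=cap,
                                     decrement=decrement, exclude=frozenset(exhausted))
            counts_after = state.labeled.label_counts
            # a rare label that gains nothing twice in a row has no reachable
            # pool support left; stop requesting it and report the shortfall
            for lab in rare:
                if counts_after.get(lab, 0) == counts_before.get(lab, 0):
                    strikes[lab] = strikes.get(lab, 0) + 1
                    if strikes[lab] >= 2:
                        exhausted.add(lab)
                        logger.warning("label %r appears exhausted; excluded from sampling", lab)
                else:
                    strikes[lab] = 0
            if len(state.labeled) == before:
                logger.warning("no progress at threshold %d; moving on", state.threshold)
                break

    counts = state.labeled.label_counts
    state.shortfall = {lab: final_threshold - counts.get(lab, 0)
                       for lab in state.vocabulary.labels
                       if counts.get(lab, 0) < final_threshold}
    if state.shortfall:
        logger.warning("terminated with shortfalls: %s", state.shortfall)
    return state


def random_baseline(pool: Corpus, oracle: LabelOracle, budget: int, seed: int = 0) -> Corpus:
    """Uniformly sampled, oracle-labeled comparison arm of the same budget."""
    ids = pool.ids
    if budget > len(ids):
        raise ValueError("budget exceeds pool size")
    rng = np.random.default_rng(seed)
    picks = [ids[i] for i in rng.choice(len(ids), size=budget, replace=False)]
    verified = oracle.label(picks)
    return Corpus(LabeledCase(pool.synopsis(cid), verified[cid]) for cid in picks)


class FileOracle:
    """Human-in-the-loop oracle: candidates out as CSV, verified labels in.

    ``label`` writes ``candidates.csv`` (case_id per row) and expects
    ``verified.csv`` (case_id, labels joined by '|') to exist in the same
    directory, e.g. filled in by a reviewing pathologist between runs.
    """

    def __init__(self, workdir: str | Path) -> None:
        self.workdir = Path(workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)

    def label(self, case_ids: Sequence[str]) -> dict[str, LabelSet]:
        cand = self.workdir / "candidates.csv"
        with cand.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["case_id"])
            for cid in case_ids:
                writer.writerow([cid])
        verified = self.workdir / "verified.csv"
        if not verified.exists():
            raise FileNotFoundError(
                f"wrote {cand}; awaiting reviewed labels in {verified} "
                "(columns: case_id, labels joined by '|')"
            )
        out: dict[str, LabelSet] = {}
        with verified.open() as fh:
            for row in csv.DictReader(fh):
                if row["case_id"] in set(case_ids):
                    out[row["case_id"]] = LabelSet(row["labels"].split("|"))
        return out
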