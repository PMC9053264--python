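"""Binary-relevance evaluation: per-label and micro-averaged P/R/F1.

Every (case, label) decision is an independent binary prediction, so each
label has its own confusion counts; micro-averaged metrics are computed from
the counts summed over labels, weighting every decision equally.  A 0/0
quotient (e.g. precision with no positive predictions) is reported as 0 and
flagged as degenerate rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus_io import LabelSet, LabelVocabulary

__all__ = ["ConfusionCounts", "EvalReport", "confusion", "metrics", "evaluate", "learning_curve"]


@dataclass
class ConfusionCounts:
    labels: list[str]
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    n_cases: int

    @property
    def tp_sum(self) -> int:
        return int(self.tp.sum())

    @property
    def fp_sum(self) -> int:
        return int(self.fp.sum())

    @property
    def fn_sum(self) -> int:
        return int(self.fn.sum())


@dataclass
class EvalReport:
    labels: list[str]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    degenerate: np.ndarray  # labels where some quotient was 0/0
    micro_precision: float
    micro_recall: float
    micro_f1: float
    macro_f1: float
    n_cases: int
    vocabulary_version: int | None = None
    per_label: dict[str, dict[str, float]] = field(init=False)

    def __post_init__(self) -> None:
        self.per_label = {
            lab: {
                "precision": float(self.precision[i]),
                "recall": float(self.recall[i]),
                "f1": float(self.f1[i]),
                "degenerate": bool(self.degenerate[i]),
            }
            for i, lab in enumerate(self.labels)
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": lab,
                "precision": float(self.precision[i]),
                "recall": float(self.recall[i]),
                "f1": float(self.f1[i]),
            }
            for i, lab in enumerate(self.labels)
        ]
        rows.append(
            {
                "label": "micro",
                "precision": self.micro_precision,
                "recall": self.micro_recall,
                "f1": self.micro_f1,
            }
        )
        return pd.DataFrame(rows)


def confusion(
    pred: dict[str, LabelSet],
    gold: dict[str, LabelSet],
    vocab: LabelVocabulary,
) -> ConfusionCounts:
    """Per-label binary confusion counts over a common set of case ids."""
    if set(pred) != set(gold):
        raise ValueError("pred and gold must cover the same case ids")
    labels = vocab.labels
    known = set(labels)
    L = len(labels)
    tp = np.zeros(L, dtype=np.int64)
    fp = np.zeros(L, dtype=np.int64)
    fn = np.zeros(L, dtype=np.int64)
    tn = np.zeros(L, dtype=np.int64)
    for cid in pred:
        p, g = set(pred[cid].labels), set(gold[cid].labels)
        unknown = (p | g) - known
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)} in case {cid!r}")
        for i, lab in enumerate(labels):
            in_p, in_g = lab in p, lab in g
            if in_p and in_g:
                tp[i] += 1
            elif in_p:
                fp[i] += 1
            elif in_g:
                fn[i] += 1
            else:
                tn[i] += 1
    return ConfusionCounts(labels, tp, fp, fn, tn, n_cases=len(pred))


def _safe_div(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    den = np.asarray(den, dtype=float)
    degenerate = (den == 0)
    out = np.where(degenerate, 0.0, np.asarray(num, dtype=float) / np.where(degenerate, 1.0, den))
    return out, degenerate


def metrics(counts: ConfusionCounts, vocabulary_version: int | None = None) -> EvalReport:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R), per label
    and micro-averaged from the summed counts."""
    prec, dp = _safe_div(counts.tp, counts.tp + counts.fp)
    rec, dr = _safe_div(counts.tp, counts.tp + counts.fn)
    f1, df = _safe_div(2 * prec * rec, prec + rec)
    degenerate = dp | dr | df

    tp_s, fp_s, fn_s = counts.tp_sum, counts.fp_sum, counts.fn_sum
    micro_p = tp_s / (tp_s + fp_s) if (tp_s + fp_s) else 0.0
    micro_r = tp_s / (tp_s + fn_s) if (tp_s + fn_s) else 0.0
    micro_f1 = 2 * micro_p * micro_r / (micro_p + micro_r) if (micro_p + micro_r) else 0.0
    return EvalReport(
        labels=counts.labels,
        precision=prec,
        recall=rec,
        f1=f1,
        degenerate=degenerate,
        micro_precision=float(micro_p),
        micro_recall=float(micro_r),
        micro_f1=float(micro_f1),
        macro_f1=float(f1.mean()) if len(f1) else 0.0,
        n_cases=counts.n_cases,
        vocabulary_version=vocabulary_version,
    )


def evaluate(pred: dict[str, LabelSet], gold: dict[str, LabelSet], vocab: LabelVocabulary) -> EvalReport:
    return metrics(confusion(pred, gold, vocab), vocabulary_version=vocab.version)


def learning_curve(
    corpus,
    vocab: LabelVocabulary,
    cfg,
    batch_size: int = 50,
    n_validation: int = 100,
    seeds: tuple[int, ...] = (0, 1, 2, 3),
) -> pd.DataFrame:
    """Micro-F1 as a function of training-set size against a fixed benchmark.

    The first ``n_validation`` labeled cases (in corpus order) are held out
    once as the benchmark validation set; models are trained on nested
    prefixes of the remainder in steps of ``batch_size`` and scored on that
    same benchmark, repeated over seeds.  Returns one row per budget with the
    mean micro-F1 and its standard error.
    """
    from dataclasses import replace

    from .classifier_core import train

    cases = corpus.labeled_cases()
    if len(cases) <= n_validation:
        raise ValueError("corpus smaller than the requested validation benchmark")
    val = cases[:n_validation]
    pool = cases[n_validation:]
    budgets = list(range(batch_size, len(pool) + 1, batch_size))
    if not budgets:
        raise ValueError("batch_size exceeds the training pool")
    rows = []
    for n_train in budgets:
        f1s = []
        for seed in seeds:
            model = train(pool[:n_train], val, replace(cfg, seed=int(seed)), vocab=vocab)
            f1s.append(model.best_val_f1)
        f1s_arr = np.asarray(f1s, dtype=float)
        sem = f1s_arr.std(ddof=1) / np.sqrt(len(f1s_arr)) if len(f1s_arr) > 1 else 0.0
        rows.append({"n_train": n_train, "mean_micro_f1": float(f1s_arr.mean()), "sem": float(sem)})
    return pd.DataFrame(rows)
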