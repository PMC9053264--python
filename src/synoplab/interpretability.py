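"""Word-knockout interpretability.

Removing a single word from a synopsis and re-predicting isolates that
word's contribution: since nothing else changed, the per-label change in the
output score is the word's *influence score* on each label.  Influence
scores are accumulated over a labeled corpus, grouped by the cases' gold
labels, summed, and finally each word's across-label sum vector is divided
by its own L2 norm, so every observed word carries a unit-norm influence
profile over the labels.

A "word" here is a whitespace-delimited, punctuation-stripped, case-folded
token of the description text — knockout operates on the raw text, before
any encoder tokenization, and removes all occurrences of the word at once.
Predictions use the canonical (identity-order, unaugmented) serialization so
the word is the only varying factor.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .corpus_io import Corpus, Synopsis, serialize_synopsis

__all__ = ["InfluenceTable", "normalize_word", "knockout_case", "build_influence_table", "top_k_words"]

_STRIP = string.punctuation


def normalize_word(token: str) -> str:
    return token.strip(_STRIP).lower()


def _case_words(s: Synopsis) -> list[str]:
    seen: dict[str, None] = {}
    for tok in s.description_text().split():
        w = normalize_word(tok)
        if w:
            seen.setdefault(w)
    return list(seen)


def _without_word(s: Synopsis, word: str) -> Synopsis:
    fields = []
    for name, desc in s.fields:
        kept = [tok for tok in desc.split() if normalize_word(tok) != word]
        fields.append((name, " ".join(kept)))
    return Synopsis(case_id=s.case_id, fields=fields, provenance=s.provenance)


def knockout_case(
    predict_fn: Callable[[Sequence[str]], np.ndarray],
    s: Synopsis,
    word: str,
) -> np.ndarray:
    """Per-label score delta caused by removing ``word`` from the case.

    ``predict_fn`` maps texts to an (n, n_labels) score array (a fitted
    model's ``score_texts``).  Returns original minus knocked-out scores;
    the zero vector when the word does not occur.
    """
    word = normalize_word(word)
    knocked = _without_word(s, word)
    if knocked.fields == s.fields:
        n_labels = np.asarray(predict_fn([serialize_synopsis(s)])).shape[1]
        return np.zeros(n_labels)
    scores = np.asarray(predict_fn([serialize_synopsis(s), serialize_synopsis(knocked)]))
    return scores[0] - scores[1]


@dataclass
class InfluenceTable:
    """Per (word, label) raw and L2-normalized knockout influence."""

    labels: list[str]
    words: list[str]
    raw: np.ndarray      # (n_words, n_labels) summed signed influences
    norm: np.ndarray     # raw rows divided by their own L2 norm
    support: np.ndarray  # (n_words, n_labels) contributing (case, word) counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, w in enumerate(self.words):
            for j, lab in enumerate(self.labels):
                if self.support[i, j]:
                    rows.append({"word": w, "label": lab, "raw_sum": self.raw[i, j],
                                 "norm": self.norm[i, j], "support": int(self.support[i, j])})
        return pd.DataFrame(rows)

    def heatmap_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(self.norm, index=self.words, columns=self.labels)


def build_influence_table(
    predict_fn: Callable[[Sequence[str]], np.ndarray],
    corpus: Corpus,
    labels: list[str],
    use_magnitude: bool = False,
) -> InfluenceTable:
    """Accumulate knockout influences over a labeled corpus.

    For every word occurring in any description, knockout deltas are
    computed on every case containing it; a case's delta for label Y
    contributes to (word, Y) only when Y is among that case's gold labels.
    Signed deltas are summed by default (``use_magnitude`` sums absolute
    values instead); each word's across-label sums are then divided by
    their L2 norm.
    """
    cases = corpus.labeled_cases()
    if not cases:
        raise ValueError("influence table requires a labeled corpus")
    lab_index = {lab: j for j, lab in enumerate(labels)}
    word_index: dict[str, int] = {}
    contributions: list[tuple[int, np.ndarray, list[int]]] = []

    for case in cases:
        s = case.synopsis
        gold_idx = [lab_index[lab] for lab in case.gold if lab in lab_index]
        words = _case_words(s)
        if not words or not gold_idx:
            continue
        base_text = serialize_synopsis(s)
        knocked_texts = [serialize_synopsis(_without_word(s, w)) for w in words]
        scores = np.asarray(predict_fn([base_text, *knocked_texts]))
        deltas = scores[0] - scores[1:]
        for w, delta in zip(words, deltas):
            wi = word_index.setdefault(w, len(word_index))
            contributions.append((wi, delta, gold_idx))

    n_words, n_labels = len(word_index), len(labels)
    raw = np.zeros((n_words, n_labels))
    support = np.zeros((n_words, n_labels), dtype=np.int64)
    for wi, delta, gold_idx in contributions:
        for j in gold_idx:
            raw[wi, j] += abs(delta[j]) if use_magnitude else delta[j]
            support[wi, j] += 1

    norms = np.linalg.norm(raw, axis=1, keepdims=True)
    norm = np.divide(raw, norms, out=np.zeros_like(raw), where=norms > 0)
    words = list(word_index)
    return InfluenceTable(labels=list(labels), words=words, raw=raw, norm=norm, support=support)


def top_k_words(table: InfluenceTable, label: str, k: int = 5) -> list[str]:
    """The k words with the highest normalized influence on ``label``.

    Descending by score; ties broken lexicographically.  Words never
    observed with that label are excluded.
    """
    if label not in table.labels:
        raise ValueError(f"unknown label {label!r}")
    j = table.labels.index(label)
    scored = [(table.norm[i, j], w) for i, w in enumerate(table.words) if table.support[i, j] > 0]
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [w for _, w in scored[:k]]
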