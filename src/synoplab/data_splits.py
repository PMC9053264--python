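"""Train/validation splitting.

Two splitters are provided:

* the active-learning-stage split, which first assigns at least one case per
  label to the training set (so a model can be trained on every label and
  help sample rare-label candidates) and then splits the remainder randomly
  to reach the requested 80/20 proportion overall;
* an adapted Monte-Carlo cross-validation split that guarantees every label
  a minimum number of validation cases: with ratio r, the floor of
  ``min_label_count * r``.  A first pass over the shuffled cases sends a
  case to validation whenever any of its labels is still below that minimum;
  a second pass over the reshuffled remainder fills validation up to
  ``n_cases * r`` and sends the rest to training.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus_io import Corpus

__all__ = ["SplitResult", "al_stage_split", "mccv_split", "repeat_mccv"]

logger = logging.getLogger(__name__)


@dataclass
class SplitResult:
    train_ids: list[str]
    validation_ids: list[str]
    ratio: float
    seed: int
    min_val_per_label: int = 0

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"train": self.train_ids, "validation": self.validation_ids,
             "seed": self.seed, "ratio": self.ratio}, indent=0))


def al_stage_split(corpus: Corpus, ratio: float = 0.2, seed: int = 0) -> SplitResult:
    """Split with every vocabulary label represented in training.

    One case per label is assigned to training first (rarest labels first,
    so singleton labels are secured); the rest is split randomly so that the
    overall validation fraction is as close to ``ratio`` as rounding allows.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    cases = corpus.labeled_cases()
    counts = corpus.label_counts
    if not counts:
        raise ValueError("corpus has no labeled cases")
    rng = np.random.default_rng(seed)
    by_id = {c.case_id: c for c in cases}
    ids = list(by_id)

    train: list[str] = []
    covered: set[str] = set()
    # rarest labels first; ties by name for determinism
    for lab in sorted(counts, key=lambda l: (counts[l], l)):
        if lab in covered:
            continue
        candidates = [i for i in ids if lab in by_id[i].gold and i not in train]
        if not candidates:
            raise ValueError(f"label {lab!r} has no labeled case")
        pick = candidates[rng.integers(len(candidates))]
        train.append(pick)
        covered.update(by_id[pick].gold)

    rest = [i for i in ids if i not in set(train)]
    n_val = round(len(ids) * ratio)
    if n_val > len(rest):
        logger.warning("per-label constraint saturates the split; validation gets %d cases", len(rest))
        n_val = len(rest)
    rest = list(rng.permutation(rest))
    validation = rest[:n_val]
    train.extend(rest[n_val:])
    return SplitResult(train, validation, ratio, seed)


def mccv_split(corpus: Corpus, validation_size_ratio: float, seed: int = 0) -> SplitResult:
    """Adapted Monte-Carlo CV split with a per-label validation floor."""
    if not 0 < validation_size_ratio < 1:
        raise ValueError("validation_size_ratio must be in (0, 1)")
    cases = corpus.labeled_cases()
    if not cases:
        raise ValueError("corpus has no labeled cases")
    counts = corpus.label_counts
    rng = np.random.default_rng(seed)

    validation_size = len(cases) * validation_size_ratio
    min_val = math.floor(min(counts.values()) * validation_size_ratio)
    if min_val == 0:
        logger.info("min label count * ratio < 1; per-label validation floor is 0")
    if int(validation_size) == 0:
        raise ValueError("validation size rounds to zero for this corpus and ratio")

    order = list(rng.permutation(len(cases)))
    val_counts: dict[str, int] = {lab: 0 for lab in counts}
    validation: list[str] = []
    tmp: list[int] = []
    for i in order:
        c = cases[i]
        if any(val_counts[lab] < min_val for lab in c.gold):
            validation.append(c.case_id)
            for lab in c.gold:
                val_counts[lab] += 1
        else:
            tmp.append(i)

    if len(validation) > validation_size:
        logger.info("first pass overfilled validation (%d > %.1f); overfill stands",
                    len(validation), validation_size)
    tmp = list(rng.permutation(tmp))
    train: list[str] = []
    for i in tmp:
        if len(validation) < validation_size:
            validation.append(cases[i].case_id)
        else:
            train.append(cases[i].case_id)
    return SplitResult(train, validation, validation_size_ratio, seed, min_val_per_label=min_val)


def repeat_mccv(corpus: Corpus, ratio: float, n_repeats: int, seeds=None) -> list[SplitResult]:
    """Independent adapted-MCCV splits, one per seed (four in the study design)."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if seeds is None:
        seeds = list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")
    return [mccv_split(corpus, ratio, seed=int(s)) for s in seeds]
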