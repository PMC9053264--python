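"""Field-order shuffle augmentation.

Because a synopsis' field order carries no meaning, permuting the fields
yields distinct text strings with identical semantic content.  Training uses
several permuted serializations of each case as extra views; prediction runs
the model over several permutations and keeps, per label, the maximum score
("augmented prediction").
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Sequence

import numpy as np

from .corpus_io import LabeledCase, Synopsis, serialize_synopsis

__all__ = ["sample_permutations", "augment_training", "augmented_predict"]

logger = logging.getLogger(__name__)

# Below this many fields every permutation can be enumerated cheaply.
_ENUMERATE_LIMIT = 7


def sample_permutations(n_fields: int, n_views: int, rng: np.random.Generator) -> list[tuple[int, ...]]:
    """Draw ``n_views`` permutations of ``range(n_fields)``.

    Without replacement while ``n_views`` does not exceed ``n_fields!``;
    beyond that permutations repeat (with a logged warning).
    """
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    n_fields = max(n_fields, 1)
    if n_fields < _ENUMERATE_LIMIT:
        total = math.factorial(n_fields)
        if n_views <= total:
            # distinct permutations: sample indices without replacement into
            # the full enumeration only when small; otherwise rejection-free
            # draw via permuted enumeration
            import itertools

            all_perms = list(itertools.permutations(range(n_fields)))
            idx = rng.choice(total, size=n_views, replace=False)
            return [all_perms[i] for i in idx]
        logger.warning(
            "requested %d views but only %d distinct permutations of %d fields; repeating",
            n_views,
            total,
            n_fields,
        )
        import itertools

        all_perms = list(itertools.permutations(range(n_fields)))
        idx = rng.choice(total, size=n_views, replace=True)
        return [all_perms[i] for i in idx]
    # many fields: collision probability is negligible, draw independently
    return [tuple(rng.permutation(n_fields)) for _ in range(n_views)]


def augment_training(
    case: LabeledCase,
    target: np.ndarray,
    n_views: int,
    rng: np.random.Generator | int,
) -> list[tuple[str, np.ndarray]]:
    """Serialize a labeled case under ``n_views`` permutations.

    Each view is paired with the unchanged target vector.  Deterministic
    given the generator state / seed.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    perms = sample_permutations(len(case.synopsis.fields), n_views, rng)
    return [(serialize_synopsis(case.synopsis, p), target) for p in perms]


def augmented_predict(
    predict_fn: Callable[[Sequence[str]], np.ndarray],
    s: Synopsis,
    n_views: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Element-wise maximum of ``predict_fn`` over permuted serializations.

    ``predict_fn`` maps a sequence of texts to an (n_texts, n_labels) score
    array with entries in [0, 1]; the result dominates every individual
    view's score component-wise.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    perms = sample_permutations(len(s.fields), n_views, rng)
    texts = [serialize_synopsis(s, p) for p in perms]
    scores = np.asarray(predict_fn(texts), dtype=float)
    if scores.ndim != 2 or scores.shape[0] != len(texts):
        raise ValueError(f"predict_fn returned shape {scores.shape}, expected ({len(texts)}, n_labels)")
    return scores.max(axis=0)
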