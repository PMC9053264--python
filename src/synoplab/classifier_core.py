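"""Binary-relevance classifier: head, loss, training loop, prediction.

The multi-label problem is transformed into independent binary predictions,
one per semantic label.  The classification head is a dropout layer (rate
0.5) followed by a fully connected layer producing one logit per label; a
sigmoid turns each logit into a score in (0, 1) and scores are thresholded
independently — no normalization across labels.

With the lightweight backend the encoder is a trainable tanh projection of
the hashed bag-of-tokens features, so the whole model is a small two-layer
network trained with decoupled-weight-decay Adam (AdamW) on binary
cross-entropy.  The model is snapshotted every epoch and the snapshot with
the best validation micro-average F1 is returned (ties: earliest epoch).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .augmentation import augmented_predict, sample_permutations
from .corpus_io import LabeledCase, LabelSet, LabelVocabulary, Synopsis, serialize_synopsis
from .encoders import EncodedInput, HashingEncoder, make_encoder
from .evaluation import evaluate

__all__ = [
    "TrainConfig",
    "sigmoid",
    "bce_loss",
    "encode",
    "train",
    "SynopsisClassifier",
    "labelset_to_vector",
    "vector_to_labelset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the classifier and its training loop."""

    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    epochs: int = 10
    dropout: float = 0.5
    batch_size: int = 8
    label_weights: tuple[float, ...] | None = None  # w_n of the loss; default all 1
    decision_threshold: float = 0.5
    seed: int = 0
    encoder_id: str = "lightweight"
    embedding_dim: int = 96
    hash_dim: int = 2048
    max_length: int = 256
    train_views: int = 3
    predict_views: int = 5
    augment_train: bool = True
    augment_validation: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def sigmoid(x):
    """Logistic function 1/(1+e^(-x)); saturates without overflow."""
    return expit(x)


def bce_loss(logits, targets, weights=None) -> float:
    """Weighted binary cross-entropy, mean over all (item, label) elements.

    Computed from logits in the numerically stable form
    ``w * (max(x, 0) - x*y + log(1 + e^(-|x|)))``.
    """
    x = np.asarray(logits, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: logits {x.shape} vs targets {y.shape}")
    elem = np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if x.ndim and w.shape != (x.shape[-1],):
            raise ValueError(f"weights shape {w.shape} does not match label count {x.shape[-1]}")
        elem = elem * w
    return float(np.mean(elem))


def encode(text: str, encoder) -> EncodedInput:
    """Deterministic tokenization of one text through the given encoder."""
    if text is None:
        raise ValueError("text must not be None")
    return encoder.encode(text)


def labelset_to_vector(ls: LabelSet, vocab: LabelVocabulary) -> np.ndarray:
    v = np.zeros(len(vocab), dtype=np.float64)
    for lab in ls:
        v[vocab.index(lab)] = 1.0
    return v


def vector_to_labelset(scores: np.ndarray, vocab: LabelVocabulary, threshold: float) -> LabelSet:
    return LabelSet(lab for i, lab in enumerate(vocab.labels) if scores[i] >= threshold)


class _AdamW:
    """Adam with decoupled weight decay; decay applies to matrices only."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float,
                 betas=(0.9, 0.99), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for k, g in grads.items():
            p = self.params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            if self.wd and not k.startswith("b"):
                update = update + self.wd * p
            p -= self.lr * update


class SynopsisClassifier:
    """A fitted binary-relevance model over a frozen vocabulary snapshot."""

    def __init__(self, encoder, vocab: LabelVocabulary, params: dict[str, np.ndarray],
                 cfg: TrainConfig, trace: list[dict]) -> None:
        self.encoder = encoder
        self.vocab = vocab
        self.params = params
        self.cfg = cfg
        self.trace = trace  # one row per epoch: epoch, train_loss, val_micro_f1

    # -- core forward ------------------------------------------------------

    def _features(self, texts: Sequence[str]):
        if isinstance(self.encoder, HashingEncoder):
            return self.encoder.features(list(texts))
        return self.encoder.cls_embeddings(list(texts))  # pragma: no cover - optional

    def _hidden(self, X) -> np.ndarray:
        return np.tanh(X @ self.params["W1"] + self.params["b1"])

    def logits_texts(self, texts: Sequence[str]) -> np.ndarray:
        H = self._hidden(self._features(texts))
        return H @ self.params["W2"] + self.params["b2"]

    def score_texts(self, texts: Sequence[str]) -> np.ndarray:
        """Per-label sigmoid scores, evaluation mode (no dropout)."""
        return sigmoid(self.logits_texts(texts))

    # -- synopsis-level API ------------------------------------------------

    @property
    def best_val_f1(self) -> float:
        return max(row["val_micro_f1"] for row in self.trace)

    @property
    def embedding_dim(self) -> int:
        return self.params["W1"].shape[1]

    def predict_scores(self, s: Synopsis, augmented: bool = True, seed: int | None = None) -> np.ndarray:
        if augmented:
            rng = np.random.default_rng(self.cfg.seed if seed is None else seed)
            return augmented_predict(self.score_texts, s, self.cfg.predict_views, rng)
        return self.score_texts([serialize_synopsis(s)])[0]

    def predict(self, s: Synopsis, augmented: bool = True, seed: int | None = None,
                vocab: LabelVocabulary | None = None) -> tuple[np.ndarray, LabelSet]:
        """Scores plus the thresholded label set (empty = abstention)."""
        if vocab is not None and vocab != self.vocab:
            raise ValueError("vocabulary mismatch between model and request")
        scores = self.predict_scores(s, augmented=augmented, seed=seed)
        labels = vector_to_labelset(scores, self.vocab, self.cfg.decision_threshold)
        if len(labels) == 0:
            logger.info("case %s: no label above threshold (abstention)", s.case_id)
        return scores, labels

    def predict_corpus_scores(self, corpus, augmented: bool = False) -> dict[str, np.ndarray]:
        """Batch scores for every case, canonical serialization by default."""
        ids = corpus.ids
        if not augmented:
            texts = [serialize_synopsis(corpus.synopsis(i)) for i in ids]
            scores = self.score_texts(texts)
            return {cid: scores[k] for k, cid in enumerate(ids)}
        return {cid: self.predict_scores(corpus.synopsis(cid), augmented=True) for cid in ids}

    def embed(self, s: Synopsis) -> np.ndarray:
        """Classification embedding under the canonical field order, eval mode."""
        return self.embed_texts([serialize_synopsis(s)])[0]

    def embed_texts(self, texts: Sequence[str]) -> np.ndarray:
        return self._hidden(self._features(texts))

    # -- persistence -------------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps(
            {**self.cfg.__dict__, "label_weights": list(self.cfg.label_weights or [])}, indent=2))
        (out / "vocabulary.json").write_text(json.dumps(self.vocab.labels, indent=0))
        np.savez(out / "params.npz", **self.params)
        import pandas as pd

        pd.DataFrame(self.trace).to_csv(out / "trace.csv", index=False)

    @classmethod
    def load(cls, out_dir: str | Path) -> "SynopsisClassifier":
        out = Path(out_dir)
        raw = json.loads((out / "config.json").read_text())
        raw["label_weights"] = tuple(raw["label_weights"]) or None
        cfg = TrainConfig(**raw)
        vocab = LabelVocabulary(json.loads((out / "vocabulary.json").read_text()))
        with np.load(out / "params.npz") as npz:
            params = {k: npz[k] for k in npz.files}
        import pandas as pd

        trace = pd.read_csv(out / "trace.csv").to_dict("records")
        return cls(make_encoder(cfg.encoder_id, cfg.hash_dim, cfg.max_length), vocab, params, cfg, trace)


def _epoch_texts(cases: list[LabeledCase], targets: np.ndarray, cfg: TrainConfig,
                 rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    if not cfg.augment_train or cfg.train_views < 1:
        return [serialize_synopsis(c.synopsis) for c in cases], targets
    texts: list[str] = []
    rows: list[int] = []
    for i, c in enumerate(cases):
        perms = sample_permutations(len(c.synopsis.fields), cfg.train_views, rng)
        for p in perms:
            texts.append(serialize_synopsis(c.synopsis, p))
            rows.append(i)
    return texts, targets[rows]


def train(
    train_cases: Sequence[LabeledCase],
    val_cases: Sequence[LabeledCase],
    cfg: TrainConfig,
    vocab: LabelVocabulary | None = None,
) -> SynopsisClassifier:
    """Fit the classifier, returning the best-validation-epoch snapshot.

    Field-shuffle augmentation is resampled every epoch; the validation
    micro-F1 after each epoch is recorded in the metric trace.  Fully
    deterministic given ``cfg.seed``.
    """
    train_cases = list(train_cases)
    val_cases = list(val_cases)
    if not train_cases or not val_cases:
        raise ValueError("both training and validation splits must be nonempty")
    if vocab is None:
        vocab = LabelVocabulary(
            dict.fromkeys(lab for c in [*train_cases, *val_cases] for lab in c.gold)
        )
    for c in val_cases:
        missing = set(c.gold.labels) - set(vocab.labels)
        if missing:
            raise ValueError(f"validation labels {sorted(missing)} absent from vocabulary")

    L = len(vocab)
    weights = np.ones(L) if cfg.label_weights is None else np.asarray(cfg.label_weights, dtype=float)
    if weights.shape != (L,):
        raise ValueError("label_weights length must equal vocabulary size")

    encoder = make_encoder(cfg.encoder_id, cfg.hash_dim, cfg.max_length)
    if not isinstance(encoder, HashingEncoder):  # pragma: no cover - optional backend
        raise NotImplementedError("the NumPy training loop supports the lightweight encoder")

    rng = np.random.default_rng(cfg.seed)
    d = cfg.embedding_dim
    params = {
        "W1": rng.normal(0.0, 0.05, size=(encoder.vocab_size, d)).astype(np.float32),
        "b1": np.zeros(d, dtype=np.float32),
        "W2": rng.normal(0.0, 0.2, size=(d, L)).astype(np.float32),
        "b2": np.zeros(L, dtype=np.float32),
    }
    opt = _AdamW(params, cfg.learning_rate, cfg.weight_decay)

    targets = np.stack([labelset_to_vector(c.gold, vocab) for c in train_cases])
    model = SynopsisClassifier(encoder, vocab.copy(), params, cfg, trace=[])
    val_gold = {c.case_id: c.gold for c in val_cases}
    val_texts = [serialize_synopsis(c.synopsis) for c in val_cases]

    snapshots: list[dict[str, np.ndarray]] = []
    keep = 1.0 - cfg.dropout
    for epoch in range(1, cfg.epochs + 1):
        texts, Y = _epoch_texts(train_cases, targets, cfg, rng)
        X = encoder.features(texts)
        order = rng.permutation(len(texts))
        losses = []
        for start in range(0, len(texts), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            Xb = X[idx]
            Yb = Y[idx]
            B = len(idx)
            H0 = Xb @ params["W1"] + params["b1"]
            H = np.tanh(H0)
            if cfg.dropout > 0:
                mask = (rng.random(H.shape) < keep) / keep
                Hd = H * mask
            else:
                mask = None
                Hd = H
            Z = Hd @ params["W2"] + params["b2"]
            losses.append(bce_loss(Z, Yb, weights))
            dZ = weights * (sigmoid(Z) - Yb) / (B * L)
            gW2 = Hd.T @ dZ
            gb2 = dZ.sum(axis=0)
            dHd = dZ @ params["W2"].T
            dH = dHd * mask if mask is not None else dHd
            dH0 = dH * (1.0 - H * H)
            gW1 = np.asarray((Xb.T @ dH0))
            gb1 = dH0.sum(axis=0)
            opt.step({"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2})

        if cfg.augment_validation:
            pred = {
                c.case_id: model.predict(c.synopsis, augmented=True, seed=cfg.seed)[1]
                for c in val_cases
            }
        else:
            val_scores = model.score_texts(val_texts)
            pred = {
                c.case_id: vector_to_labelset(val_scores[i], vocab, cfg.decision_threshold)
                for i, c in enumerate(val_cases)
            }
        report = evaluate(pred, val_gold, vocab)
        model.trace.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_micro_f1": report.micro_f1}
        )
        snapshots.append({k: v.copy() for k, v in params.items()})

    best = int(np.argmax([row["val_micro_f1"] for row in model.trace]))  # earliest on ties
    model.params = snapshots[best]
    return model
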