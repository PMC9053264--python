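"""Text encoder backends.

Two backends share one contract: ``encode`` turns a serialized synopsis into
an :class:`EncodedInput` (token ids, attention mask, segment ids, with a
designated classification position), and the encoder produces a fixed-width
real vector per text that the classification head consumes.

* ``lightweight`` — a deterministic hashing tokenizer plus a trainable
  projection: each text becomes a binary bag-of-hashed-tokens vector, and a
  tanh projection of that bag is the text's classification embedding.  It
  needs no pretrained weights and is the default backend.
* a pretrained bidirectional transformer (loaded lazily through the
  ``transformers`` library when installed), whose classification-token
  output plays the same role at width 768.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = ["EncodedInput", "HashingEncoder", "make_encoder", "PAD_ID", "CLS_ID"]

logger = logging.getLogger(__name__)

PAD_ID = 0
CLS_ID = 1
_N_SPECIAL = 2


@dataclass
class EncodedInput:
    """Fixed-length model input: ids, mask and segment ids of equal length."""

    token_ids: np.ndarray
    attention_mask: np.ndarray
    segment_ids: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.token_ids) == len(self.attention_mask) == len(self.segment_ids)):
            raise ValueError("token_ids, attention_mask and segment_ids must have equal length")


class HashingEncoder:
    """Deterministic hashing tokenizer + bag-of-tokens feature map.

    Tokens are case-folded whitespace tokens hashed into a fixed id space
    (stable across processes, unlike Python's builtin hash).  The feature
    vector of a text is binary presence over token ids; the trainable
    projection living in the classifier turns it into the embedding.
    """

    name = "lightweight"

    def __init__(self, vocab_size: int = 4096, max_length: int = 256) -> None:
        if vocab_size <= _N_SPECIAL:
            raise ValueError("vocab_size too small")
        self.vocab_size = int(vocab_size)
        self.max_length = int(max_length)
        self._cache: dict[str, int] = {}

    def token_id(self, token: str) -> int:
        tid = self._cache.get(token)
        if tid is None:
            digest = hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest()
            tid = int.from_bytes(digest, "big") % (self.vocab_size - _N_SPECIAL) + _N_SPECIAL
            self._cache[token] = tid
        return tid

    def _tokenize(self, text: str) -> list[str]:
        return text.lower().split()

    def encode(self, text: str) -> EncodedInput:
        """Tokenize to a fixed-length input with a leading classification slot."""
        ids = [CLS_ID] + [self.token_id(t) for t in self._tokenize(text)]
        if len(ids) > self.max_length:
            logger.warning("input of %d tokens truncated to %d", len(ids), self.max_length)
            ids = ids[: self.max_length]
        n = len(ids)
        pad = self.max_length - n
        token_ids = np.asarray(ids + [PAD_ID] * pad, dtype=np.int64)
        mask = np.asarray([1] * n + [0] * pad, dtype=np.int64)
        segs = np.zeros(self.max_length, dtype=np.int64)
        return EncodedInput(token_ids, mask, segs)

    def features(self, texts: list[str]) -> sparse.csr_matrix:
        """Binary presence matrix (n_texts × vocab_size) over hashed token ids.

        Truncation mirrors :meth:`encode`: only the first ``max_length - 1``
        tokens of a text contribute.
        """
        indptr = [0]
        indices: list[int] = []
        limit = self.max_length - 1  # one slot is the classification token
        for text in texts:
            toks = self._tokenize(text)[:limit]
            ids = sorted({self.token_id(t) for t in toks})
            indices.extend(ids)
            indptr.append(len(indices))
        data = np.ones(len(indices), dtype=np.float32)
        return sparse.csr_matrix(
            (data, np.asarray(indices, dtype=np.int64), np.asarray(indptr, dtype=np.int64)),
            shape=(len(texts), self.vocab_size),
        )


class TransformerEncoder:
    """Pretrained transformer backend (requires the ``transformers`` package).

    The classification-token output of the final layer (width 768 for the
    base model) is the text embedding; fine-tuning it is supported by the
    library's own training utilities and is out of scope for the NumPy head,
    so this backend is feature-extraction only.
    """

    def __init__(self, model_name: str, max_length: int = 256) -> None:
        try:
            from transformers import AutoModel, AutoTokenizer  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the transformer backend requires the 'transformers' package; "
                "install it or use encoder_id='lightweight'"
            ) from exc
        self.name = model_name
        self.max_length = max_length
        self._tokenizer = AutoTokenizer.from_pretrained(model_name)
        self._model = AutoModel.from_pretrained(model_name)
        self._model.eval()

    def encode(self, text: str) -> EncodedInput:  # pragma: no cover - optional
        out = self._tokenizer(
            text, padding="max_length", truncation=True, max_length=self.max_length
        )
        return EncodedInput(
            np.asarray(out["input_ids"]),
            np.asarray(out["attention_mask"]),
            np.asarray(out.get("token_type_ids", np.zeros(self.max_length, dtype=np.int64))),
        )

    def cls_embeddings(self, texts: list[str]) -> np.ndarray:  # pragma: no cover - optional
        import torch  # type: ignore

        batch = self._tokenizer(
            texts, padding=True, truncation=True, max_length=self.max_length, return_tensors="pt"
        )
        with torch.no_grad():
            out = self._model(**batch)
        return out.last_hidden_state[:, 0, :].numpy()


def make_encoder(encoder_id: str, hash_dim: int = 4096, max_length: int = 256):
    if encoder_id == "lightweight":
        return HashingEncoder(vocab_size=hash_dim, max_length=max_length)
    return TransformerEncoder(encoder_id, max_length=max_length)
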