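"""Embedding-space analyses: corpus embedding, 2-D projection, co-occurrence.

The classification embedding of each case is a point in a semantic space;
cases with similar morphological content should land nearby.  A seeded
t-SNE projection serves cluster inspection, and a symmetric label
co-occurrence matrix over predicted label sets supports chord-diagram style
rendering (the matrix, not the interactive figure, is the artifact).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .corpus_io import Corpus, LabelSet, LabelVocabulary

__all__ = ["embed_corpus", "project_2d", "cooccurrence", "export_scatter"]


def embed_corpus(model, corpus: Corpus) -> tuple[list[str], np.ndarray]:
    """One embedding row per case, in corpus order (canonical field order)."""
    ids = corpus.ids
    if not ids:
        return [], np.zeros((0, model.embedding_dim))
    from .corpus_io import serialize_synopsis

    texts = [serialize_synopsis(corpus.synopsis(cid)) for cid in ids]
    return ids, model.embed_texts(texts)


def project_2d(
    embeddings: np.ndarray,
    method: str = "tsne",
    seed: int = 0,
    perplexity: float = 30.0,
) -> np.ndarray:
    """Seeded 2-D projection of an (n, d) embedding matrix."""
    X = np.asarray(embeddings, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("projection needs at least 2 points")
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(perplexity, (n - 1) / 3)
        tsne = TSNE(n_components=2, random_state=seed, init="pca",
                    perplexity=max(perplexity, 1.0))
        return np.asarray(tsne.fit_transform(X))
    if method == "pca":
        from sklearn.decomposition import PCA

        return np.asarray(PCA(n_components=2, random_state=seed).fit_transform(X))
    raise ValueError(f"unknown projection method {method!r}")


def cooccurrence(predictions: dict[str, LabelSet], vocab: LabelVocabulary) -> np.ndarray:
    """Symmetric |vocab| x |vocab| predicted-label co-occurrence counts.

    counts[i, j] (i != j) is the number of cases predicted with both labels;
    the diagonal holds per-label prediction totals.
    """
    L = len(vocab)
    B = np.zeros((len(predictions), L), dtype=np.int64)
    for r, ls in enumerate(predictions.values()):
        for lab in ls:
            if lab not in vocab:
                raise ValueError(f"label {lab!r} not in vocabulary")
            B[r, vocab.index(lab)] = 1
    return B.T @ B


def export_scatter(
    coords: np.ndarray,
    labels: list[str],
    path: str | Path,
    title: str = "Synopsis embeddings (2-D projection)",
) -> None:
    """Static scatter of 2-D coordinates colored by label-combination."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = np.asarray(coords)
    fig, ax = plt.subplots(figsize=(8, 6))
    uniq = sorted(set(labels))
    cmap = plt.get_cmap("tab20")
    for k, lab in enumerate(uniq):
        mask = np.asarray([l == lab for l in labels])
        ax.scatter(coords[mask, 0], coords[mask, 1], s=12,
                   color=cmap(k % 20), label=lab if k < 20 else None)
    ax.set_title(title)
    ax.legend(fontsize=6, markerscale=1.5, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
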