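"""Shared fixtures: hand-built synopses and session-scoped trained models.

Model training is the expensive step, so fitted models are session-scoped
and shared across test modules; corpora sizes are chosen to keep the suite
fast while leaving the generator's imbalance and co-occurrence structure
intact.
"""

from __future__ import annotations

import pytest

from synoplab.classifier_core import TrainConfig, train
from synoplab.corpus_io import Corpus, LabeledCase, LabelSet, Synopsis
from synoplab.data_splits import al_stage_split
from synoplab.synthetic_data import GeneratorConfig, generate_corpus


def planted_config(n_cases: int, seed: int) -> GeneratorConfig:
    """Strict planted-keyword corpus over 5 labels, no co-occurrence."""
    labels = (
        "normal",
        "acute myeloid leukemia",
        "myelodysplastic syndrome",
        "plasma cell neoplasm",
        "lymphoproliferative disorder",
    )
    return GeneratorConfig(
        labels=labels,
        label_prior=(0.3, 0.25, 0.2, 0.15, 0.1),
        keywords={
            "normal": "unremarkable",
            "acute myeloid leukemia": "myeloblasts",
            "myelodysplastic syndrome": "dysplasia",
            "plasma cell neoplasm": "plasmacytosis",
            "lymphoproliferative disorder": "lymphocytosis",
        },
        label_field={lab: i % 6 for i, lab in enumerate(labels)},
        cooccur_pairs=(),
        hidden_labels=(),
        exception_prob=0.0,
        extra_label_prob=0.1,
        n_cases=n_cases,
        seed=seed,
    )


def cluster_config(n_cases: int, seed: int) -> GeneratorConfig:
    """Three well-separated single-label groups for embedding-space checks."""
    labels = ("acute myeloid leukemia", "plasma cell neoplasm", "lymphoproliferative disorder")
    return GeneratorConfig(
        labels=labels,
        label_prior=(0.4, 0.35, 0.25),
        keywords={
            "acute myeloid leukemia": "myeloblasts",
            "plasma cell neoplasm": "plasmacytosis",
            "lymphoproliferative disorder": "lymphocytosis",
        },
        label_field={lab: i for i, lab in enumerate(labels)},
        cooccur_pairs=(),
        hidden_labels=(),
        exception_prob=0.0,
        extra_label_prob=0.0,
        n_cases=n_cases,
        seed=seed,
    )


def fit_on_split(corpus: Corpus, cfg: TrainConfig, ratio: float = 0.2, split_seed: int = 0):
    split = al_stage_split(corpus, ratio=ratio, seed=split_seed)
    return train(
        [corpus[i] for i in split.train_ids],
        [corpus[i] for i in split.validation_ids],
        cfg,
    )


@pytest.fixture
def synopsis_abc() -> Synopsis:
    return Synopsis(
        case_id="c1",
        fields=[("cellularity", "hypercellular marrow"), ("comment", "see flow"), ("iron", "absent")],
    )


@pytest.fixture
def small_labeled_corpus() -> Corpus:
    def case(cid, labels, text="adequate aspirate"):
        return LabeledCase(Synopsis(cid, [("cellularity", text), ("comment", "none")]), LabelSet(labels))

    return Corpus(
        [
            case("a", ["normal"]),
            case("b", ["acute myeloid leukemia", "hypercellular"]),
            case("c", ["normal", "iron deficiency"]),
            case("d", ["hypercellular"]),
        ]
    )


@pytest.fixture(scope="session")
def gen300():
    """Default 12-label generator output at a test-friendly size."""
    return generate_corpus(GeneratorConfig(n_cases=300, seed=11))


@pytest.fixture(scope="session")
def model300(gen300):
    corpus, _ = gen300
    return fit_on_split(corpus, TrainConfig(seed=0))


@pytest.fixture(scope="session")
def cluster3():
    return generate_corpus(cluster_config(240, seed=3))


@pytest.fixture(scope="session")
def model_cluster3(cluster3):
    corpus, _ = cluster3
    return fit_on_split(corpus, TrainConfig(seed=0))
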