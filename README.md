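# synoplab

Semantic labeling of semi-structured pathology synopses.

Bone marrow aspirate synopses are semi-structured reports — ordered
`field: description` pairs (cellularity, erythropoiesis, granulopoiesis,
megakaryocytes, lymphocytes, comment) — that an expert reader maps to one or
more *semantic labels*: diagnostic categories such as "acute myeloid
leukemia" or descriptive findings such as "hypercellular".  synoplab is a
toolkit for building such a labeler with very little expert annotation:

* a **binary-relevance classifier** over text-encoder embeddings: each of
  the *L* labels is an independent binary decision, scored by a sigmoid on
  its logit and trained with weighted binary cross-entropy
  (`-w_n [y log σ(x) + (1-y) log(1-σ(x))]`, mean reduction) under AdamW
  (lr 1e-3, weight decay 1e-2, 10 epochs), keeping the epoch snapshot with
  the best validation micro-F1;
* a **rare-label active-learning loop**: labels with fewer than a threshold
  of labeled cases are rare; each iteration samples
  `threshold − count(label)` candidates per rare label from the model's
  predictions over the unlabeled pool (capped at 100 per review round, with
  automatic threshold decrements), sends them to a labeling oracle, and
  merges the verified cases — discovering brand-new labels along the way —
  until every label has ≥ 20 cases;
* **field-shuffle augmentation**: field order carries no meaning, so
  training uses permuted serializations and prediction takes the per-label
  max over permuted views;
* an **adapted Monte-Carlo cross-validation** splitter guaranteeing every
  label `floor(min_label_count × ratio)` validation cases;
* **word-knockout interpretability**: the per-label score change from
  deleting a word, summed over a labeled corpus by gold label and
  L2-normalized per word, with top-k word reports;
* **embedding analyses**: corpus embeddings, seeded t-SNE projection, and
  predicted-label co-occurrence matrices for chord-diagram export;
* a **synthetic synopsis generator** with planted ground truth (keywords,
  imbalanced priors, co-occurrence, a hidden label, injected noise), so the
  whole pipeline is testable without access-restricted clinical data, plus
  the default labeling oracle backed by it.

Everything runs on the built-in lightweight encoder (hashed bag-of-tokens
plus a trainable projection, pure NumPy — no pretrained weights needed); a
pretrained transformer encoder can be swapped in through the `transformers`
library where available.

## Worked example

```python
from synoplab import (GeneratorConfig, SyntheticOracle, TrainConfig,
                      generate_corpus, run_active_learning, unlabeled_pool,
                      build_influence_table, top_k_words)

corpus, truth = generate_corpus(GeneratorConfig(n_cases=5000, seed=7))
state = run_active_learning(unlabeled_pool(corpus), SyntheticOracle(truth),
                            TrainConfig(seed=0), initial_n=50,
                            schedule=(10, 15, 20), seed=0)
counts = state.labeled.label_counts
print(len(state.labeled), state.iteration, min(counts.values()))
```

prints

```
181 7 20
```

— starting from 50 randomly labeled cases, seven enrichment iterations
labeled 181 of the 5,000 pool cases (3.6%) and every one of the 12 labels, including
the initially unknown "basophilia" discovered during candidate review, ended
with at least 20 labeled cases.  Training a model on that set and asking
which words drive a label:

```python
from synoplab.experiments import fit_arm
model = fit_arm(state.labeled, TrainConfig(seed=0), seed=0)
table = build_influence_table(model.score_texts, state.labeled, model.vocab.labels)
print(top_k_words(table, "myelodysplastic syndrome", k=3))
```

```
['dysplasia', 'scattered', 'is']
```

— the top knockout word is the marker token the generator planted for that
label ("dysplasia"), with background filler words far behind; on real
synopses this report is the per-label list of words the model relies on.

A command-line interface wraps the same steps:

```bash
synoplab generate --n-cases 5000 --seed 7 --out pool.jsonl --truth truth.json
synoplab al-run --pool pool.jsonl --oracle synthetic --truth truth.json --out state/
synoplab train --corpus labeled.jsonl --out model/
synoplab predict --model model/ --input new.jsonl --out scores.jsonl
synoplab knockout --model model/ --corpus labeled.jsonl --out influence.csv
synoplab embed --model model/ --corpus labeled.jsonl --out-prefix emb
```

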