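# Methods

## Problem and model

A bone marrow aspirate synopsis is a semi-structured record of
`field: description` pairs (cellularity, erythropoiesis, granulopoiesis,
megakaryocytes, lymphocytes, a free-text comment) summarizing a
hematopathologist's morphological read of a specimen.  An expert end-reader
maps each synopsis to one or more *semantic labels* — broad diagnostic
categories ("acute myeloid leukemia", "myelodysplastic syndrome") or
descriptive findings ("hypercellular", "eosinophilia").  synoplab treats this
as multi-label text classification by *binary relevance* (BR): with a label
vocabulary of size *L*, each case's label set becomes a binary target vector
`y ∈ {0,1}^L` and the model makes *L* independent binary decisions.

The classifier is an encoder followed by a classification head.  The head is
a dropout layer (rate 0.5) and a fully connected layer from the encoder's
classification embedding to *L* logits; the logistic function
`S(x) = 1/(1+e^{-x})` turns each logit into an independent score in (0,1),
and labels with score ≥ a decision threshold (default 0.5) are predicted.
An empty prediction is reported as an abstention, never silently dropped.
The loss is weighted binary cross-entropy on logits,

```
l = -w_n [ y log σ(x) + (1-y) log(1-σ(x)) ]
```

reduced by the mean over all (item, label) elements of a batch; the
per-label weights `w_n` default to 1.  Optimization is Adam with decoupled
weight decay (learning rate 1e-3, weight decay 1e-2), 10 epochs, with a
parameter snapshot each epoch; the snapshot with the highest validation
micro-average F1 is returned (ties go to the earliest epoch, for
reproducibility).  Only the head sees dropout.

### Encoder backends

Two backends satisfy one contract (deterministic tokenization into token
ids / attention mask / segment ids with a designated classification
position, and one fixed-width embedding per text):

* **lightweight** (default): a hashing tokenizer (case-folded whitespace
  tokens, stable 64-bit hash into 2,046 bins plus two special ids) and a
  binary bag-of-tokens feature vector; a trainable `tanh` projection
  (2,048 × 96) of that bag is the classification embedding, so the whole
  model is a small two-layer network trainable in NumPy in seconds.  This
  backend requires no pretrained weights and is what every test and
  experiment here uses.
* **transformer**: any pretrained bidirectional-transformer encoder loaded
  through the `transformers` library (embedding width 768 for the base
  model), used for feature extraction when that library is installed.

Numerical choices for the lightweight backend: parameters in float32, init
`W1 ~ N(0, 0.05²)`, `W2 ~ N(0, 0.2²)`, biases zero; Adam `β = (0.9, 0.99)`,
`ε = 1e-8`; batch size 8.  At the fixed learning rate and epoch count these
give the optimizer enough well-scaled steps to saturate on planted-keyword
corpora; they were fixed once against generator output and are exposed in
`TrainConfig`.

## Augmentation

Field order in a synopsis carries no meaning, so permuting fields yields
distinct texts with identical content.  Serialization joins
`name: description` segments with `" ; "` — the semicolon is its own
whitespace token, which makes the serialized token multiset exactly
permutation-invariant.  Training resamples 3 permuted views per case per
epoch (interpreting augmentation as per-epoch resampling rather than a
one-time dataset expansion); prediction runs 5 permuted views and keeps the
per-label element-wise maximum.  View counts are config
(`augment.train_views` / `predict_views`); permutations are drawn without
replacement whenever the requested count does not exceed the factorial of
the field count.  Max is the only aggregation used by default; a mean option
exists behind a flag.  Note that the lightweight encoder's bag-of-tokens
features are themselves order-invariant, so augmentation is exercised
end-to-end but changes lightweight scores only through truncation edge
cases; with a transformer encoder the permuted views genuinely differ.

## Data splits

During active learning, the split first assigns at least one case per label
to training (rarest labels first) and then splits the remainder randomly to
reach an overall 80/20 proportion, so every label is learnable in every
iteration.  After active learning, the adapted Monte-Carlo cross-validation
splitter guarantees each label a minimum number of validation cases:
`min_val = floor(min_label_count × ratio)` (floor, so the guarantee is
always satisfiable); a first pass over the shuffled cases routes a case to
validation while any of its labels is under that minimum, a second pass
over the reshuffled remainder fills validation to `n × ratio` and sends the
rest to training.  Multi-label cases count toward every label they carry;
if the first pass overfills validation, the overfill stands (there is no
removal step) and is logged.  When `min_label_count × ratio < 1` the floor
is 0 and the guarantee is vacuous; this is logged, not an error.  Four
repeated splits train the final model ensemble, reported as mean ± sd
micro-F1.

## Active learning (rare-label enrichment)

Labels with fewer labeled cases than a threshold are *rare*.  Each
iteration: train on the current labeled set, score the unlabeled pool,
and request `threshold − count(label)` candidates per rare label from that
label's predicted group, deduplicated across labels with the rarest label
claiming shared candidates first.  While the candidate set exceeds 100, the
working threshold drops by 5 and sampling repeats, so a single review batch
stays tractable.  Verified candidates (whose review may reveal brand-new
labels) merge into the labeled set; the loop seeds itself with 50 randomly
sampled cases and runs the threshold schedule 10 → 15 → 20, terminating when
no label is rare at 20 or when no further progress is possible, in which
case the remaining per-label shortfalls are reported.  A rare label that
gains no new case in two consecutive iterations has spent its reachable
pool support; it is excluded from further sampling (its shortfall is still
reported), which keeps the loop from grinding on an unattainable quota.
With a labeling budget, the threshold continues to rise past the schedule
until the budget is spent.

One design choice departs from a pure thresholded group: when a rare
label's thresholded predicted group is smaller than the request — the
normal situation for a label the model has seen once or twice, whose scores
cannot yet clear 0.5 — the request is topped up with the unselected pool
cases ranked highest by that label's score.  Candidate selection therefore
stays model-guided at every stage, and the loop provably makes progress
whenever the pool still contains candidates; without the top-up, a
freshly discovered label can never accumulate enough cases to be learned.

The labeling oracle is an interface.  The synthetic generator provides the
default implementation (answers with generated gold labels, revealing a
hidden label's name the first time one of its cases is queried); a
file-based oracle (candidates CSV out, verified CSV in) supports human
review.

## Evaluation

Per-label precision, recall and F1 come from per-label binary confusion
counts; micro-averaged variants from the counts summed over labels, so
every (case, label) decision weighs equally.  A 0/0 quotient is reported as
0 and flagged degenerate — this penalizes empty predictions rather than
inflating scores.  Macro-F1 is computed for diagnostics but never used for
model selection.  The learning-curve experiment trains on nested prefixes
(batches of 50) against one fixed held-out benchmark and reports mean ±
standard error over seeds.

## Word knockout

Removing one word from a synopsis and re-predicting isolates that word's
contribution: the per-label score change is its *influence score*.  A word
is a whitespace-delimited, punctuation-stripped, case-folded token of the
description text; all occurrences are removed at once, and predictions use
the canonical identity-order, unaugmented serialization so the word is the
only varying factor.  Influences are summed (signed; a magnitude option
exists behind a flag) over every case containing the word, grouped by the
cases' *gold* labels, and each word's across-label sum vector is divided by
its own L2 norm, giving a unit-norm influence profile per observed word.
Top-k reports rank words per label by normalized influence, ties broken
lexicographically.

## Embedding analyses

Corpus embeddings (one classification embedding per case, canonical field
order, evaluation mode) feed a seeded t-SNE projection to 2-D (perplexity
30, capped at (n−1)/3; PCA initialization) for cluster inspection, and the
best-epoch model supplies the embeddings.  Predicted label sets feed a
symmetric co-occurrence matrix (off-diagonal: cases predicted with both
labels; diagonal: per-label totals) exported as CSV for chord-diagram
rendering; the rendering itself is out of scope, a static scatter is
provided instead.

## Synthetic data: what it emulates, and what it does not

The clinical corpus behind the original study is access-restricted, so the
generator emulates the structural features the method depends on: the
field:description schema; an imbalanced multi-label distribution (primary
label from a long-tailed prior — defaults 32% down to 0.3%, with the three
rarest labels at 0.6%/0.4%/0.3%, near the rare-threshold prevalence of
20/5,000 so that uniform sampling at practical budgets cannot cover them);
clinically flavored co-occurrence pairs (e.g. myeloproliferative neoplasm
with eosinophilia and basophilia); "normal"-exclusivity with the single
iron-deficiency exception; signature/boilerplate noise matched by the
default cleaning patterns; one hidden label (basophilia) withheld from the
initial random sample and reachable only through candidate review; and one
unique planted keyword per label, present in a label-appropriate field
exactly when the case carries the label.

That keyword determinism is deliberate: it makes classifier adequacy,
knockout faithfulness and embedding structure well-posed against known
ground truth, and it is what a linear-capacity model can saturate.  It is
also the generator's principal departure from real pathology text, where
label evidence is distributed, contextual and noisy.  Passing tests on this
corpus therefore demonstrate that the pipeline's mechanics (enrichment,
splitting, training, attribution, embedding) behave as designed — not that
the lightweight model would reach comparable F1 on clinical synopses.  A
keyword-dropout "hard mode" (off by default) degrades the determinism for
robustness studies.

## Experiment sizes

The packaged experiments use a 5,000-case pool (12 labels) for enrichment
runs, a 400-case labeling budget with 4 seeds for the arm comparison
against a rare-label-enriched benchmark (quota of 8 cases per label drawn
from 4,000 fresh cases), 300 cases for the planted-keyword (5-label) and
3-cluster corpora, and 100 labeled cases for influence tables.  These sizes
keep a full run in minutes on one CPU while leaving the imbalance regime
intact.

## Known limitations

* The lightweight encoder ignores word order entirely; syntactic phenomena
  (negation, qualifiers) are invisible to it.
* BR ignores label correlations by construction; like the original
  formulation it cannot learn the exclusiveness of "normal".
* The transformer backend is feature-extraction only; fine-tuning it is
  delegated to the `transformers` training stack and not reimplemented here.
* Thresholded label groups plus ranked top-up is one of several defensible
  candidate-selection rules; alternatives (least confidence, margin,
  entropy) are deliberately out of scope.
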