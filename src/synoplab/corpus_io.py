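"""Synopsis data model, text cleaning, serialization and on-disk formats.

A bone marrow aspirate synopsis is a semi-structured record: an ordered
sequence of ``field: description`` pairs (cellularity, erythropoiesis, ...)
whose *order carries no meaning* — the same morphological content can be
reported with the fields in any order.  That order-invariance is what the
augmentation module exploits, so it is enforced here at the data-model level:
serialization uses a separator that keeps the whitespace-token multiset
identical across field permutations.

Supported on-disk formats are JSON-lines (one case per line), a wide
delimited table (one column per field) and a long delimited table
(case_id, field_name, description).  All text is NFC-normalized on read.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "Synopsis",
    "LabelVocabulary",
    "LabelSet",
    "LabeledCase",
    "Corpus",
    "DEFAULT_NOISE_PATTERNS",
    "FIELD_SEPARATOR",
    "clean_text",
    "serialize_synopsis",
    "read_corpus",
    "write_corpus",
    "read_vocabulary",
    "write_vocabulary",
]

# Segment separator: the semicolon is surrounded by spaces so it is its own
# whitespace-delimited token, which makes the token multiset of a serialized
# synopsis invariant under field permutation (n segments always contribute
# exactly n-1 ";" tokens).
FIELD_SEPARATOR = " ; "

# Default removable-noise patterns.  Real laboratory exports embed doctor
# signatures and reporting-system boilerplate whose exact shape is
# site-specific; these defaults match the noise templates of the synthetic
# generator and are meant to be overridden in config for real deployments.
DEFAULT_NOISE_PATTERNS: tuple[str, ...] = (
    r"\[(?:electronically\s+)?signed:[^\]]*\]",
    r"reported\s+via\s+\S+\s+laboratory\s+information\s+system\.?",
    r"\bdictated\s+but\s+not\s+read\.?",
)


def clean_text(raw: str, noise_patterns: Sequence[str] = DEFAULT_NOISE_PATTERNS) -> str:
    """Remove configured noise patterns and normalize whitespace.

    Patterns are applied in order, case-insensitively; afterwards runs of
    internal whitespace collapse to single spaces and both ends are trimmed.
    The operation is idempotent.
    """
    text = unicodedata.normalize("NFC", raw)
    for pat in noise_patterns:
        text = re.sub(pat, " ", text, flags=re.IGNORECASE)
    return re.sub(r"\s+", " ", text).strip()


@dataclass
class Synopsis:
    """One case: an identifier plus ordered (field_name, description) pairs."""

    case_id: str
    fields: list[tuple[str, str]]
    provenance: str | None = None

    def __post_init__(self) -> None:
        names = [n for n, _ in self.fields]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate field names in case {self.case_id!r}: {names}")
        if any(not n for n in names):
            raise ValueError(f"empty field name in case {self.case_id!r}")

    @property
    def field_names(self) -> list[str]:
        return [n for n, _ in self.fields]

    def description_text(self) -> str:
        """All descriptions joined, used by word-level interpretability."""
        return " ".join(d for _, d in self.fields)

    def cleaned(self, noise_patterns: Sequence[str] = DEFAULT_NOISE_PATTERNS) -> "Synopsis":
        return Synopsis(
            case_id=self.case_id,
            fields=[(clean_text(n, noise_patterns), clean_text(d, noise_patterns)) for n, d in self.fields],
            provenance=self.provenance,
        )


def serialize_synopsis(s: Synopsis, order: Sequence[int] | None = None) -> str:
    """Serialize to a single text string under the given field permutation.

    ``order`` must be a permutation of ``range(len(s.fields))``; ``None``
    means the identity (canonical) order.
    """
    n = len(s.fields)
    if order is None:
        order = range(n)
    order = list(order)
    if sorted(order) != list(range(n)):
        raise ValueError(f"order {order!r} is not a permutation of 0..{n - 1}")
    return FIELD_SEPARATOR.join(f"{s.fields[i][0]}: {s.fields[i][1]}" for i in order)


class LabelVocabulary:
    """Ordered, append-only set of semantic label names.

    The index of an existing label never changes; ``version`` increments on
    every append so fitted models can detect stale vocabularies.
    """

    def __init__(self, labels: Iterable[str] = (), version: int = 0) -> None:
        self._labels: list[str] = []
        self._index: dict[str, int] = {}
        for lab in labels:
            if lab in self._index:
                raise ValueError(f"duplicate label {lab!r}")
            self._index[lab] = len(self._labels)
            self._labels.append(lab)
        self.version = int(version)

    @property
    def labels(self) -> list[str]:
        return list(self._labels)

    def __len__(self) -> int:
        return len(self._labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self._labels)

    def index(self, label: str) -> int:
        return self._index[label]

    def add(self, label: str) -> bool:
        """Append a new label; returns True if it was actually new."""
        if label in self._index:
            return False
        self._index[label] = len(self._labels)
        self._labels.append(label)
        self.version += 1
        return True

    def copy(self) -> "LabelVocabulary":
        return LabelVocabulary(self._labels, self.version)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LabelVocabulary) and other._labels == self._labels

    def __repr__(self) -> str:
        return f"LabelVocabulary({self._labels!r}, version={self.version})"


# The "normal" label is assigned mutually exclusively of abnormal labels,
# with a single sanctioned exception partner (iron deficiency).
EXCLUSIVE_LABEL = "normal"
EXCLUSIVE_EXCEPTION = "iron deficiency"


@dataclass(frozen=True)
class LabelSet:
    """A case's set of semantic labels."""

    labels: frozenset[str]

    def __init__(self, labels: Iterable[str]) -> None:
        object.__setattr__(self, "labels", frozenset(labels))

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    def validate_gold(
        self,
        vocab: LabelVocabulary | None = None,
        exclusive: str = EXCLUSIVE_LABEL,
        exception: str = EXCLUSIVE_EXCEPTION,
    ) -> None:
        """Check gold-label rules: non-empty, known labels, normal-exclusivity."""
        if not self.labels:
            raise ValueError("a labeled case must carry at least one label")
        if vocab is not None:
            unknown = self.labels - set(vocab.labels)
            if unknown:
                raise ValueError(f"labels not in vocabulary: {sorted(unknown)}")
        if exclusive in self.labels:
            others = self.labels - {exclusive, exception}
            if others:
                raise ValueError(
                    f"{exclusive!r} may co-occur only with {exception!r}, found {sorted(others)}"
                )


@dataclass
class LabeledCase:
    synopsis: Synopsis
    gold: LabelSet

    @property
    def case_id(self) -> str:
        return self.synopsis.case_id


class Corpus:
    """An ordered collection of cases (labeled or not) keyed by case_id."""

    def __init__(self, cases: Iterable[Synopsis | LabeledCase] = ()) -> None:
        self._cases: dict[str, Synopsis | LabeledCase] = {}
        for c in cases:
            self.add(c)

    def add(self, case: Synopsis | LabeledCase) -> None:
        cid = case.case_id
        if cid in self._cases:
            raise ValueError(f"duplicate case_id {cid!r}")
        self._cases[cid] = case

    def remove(self, case_id: str) -> Synopsis | LabeledCase:
        return self._cases.pop(case_id)

    def __len__(self) -> int:
        return len(self._cases)

    def __contains__(self, case_id: str) -> bool:
        return case_id in self._cases

    def __iter__(self) -> Iterator[Synopsis | LabeledCase]:
        return iter(self._cases.values())

    def __getitem__(self, case_id: str) -> Synopsis | LabeledCase:
        return self._cases[case_id]

    @property
    def ids(self) -> list[str]:
        return list(self._cases)

    def synopsis(self, case_id: str) -> Synopsis:
        c = self._cases[case_id]
        return c.synopsis if isinstance(c, LabeledCase) else c

    def labeled_cases(self) -> list[LabeledCase]:
        return [c for c in self._cases.values() if isinstance(c, LabeledCase)]

    @property
    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.labeled_cases():
            for lab in c.gold:
                counts[lab] = counts.get(lab, 0) + 1
        return counts

    def subset(self, ids: Iterable[str]) -> "Corpus":
        return Corpus(self._cases[i] for i in ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        if self.ids != other.ids:
            return False
        for i in self.ids:
            a, b = self._cases[i], other._cases[i]
            if isinstance(a, LabeledCase) != isinstance(b, LabeledCase):
                return False
            sa = a.synopsis if isinstance(a, LabeledCase) else a
            sb = b.synopsis if isinstance(b, LabeledCase) else b
            if sa.fields != sb.fields or sa.case_id != sb.case_id:
                return False
            if isinstance(a, LabeledCase) and a.gold.labels != b.gold.labels:
                return False
        return True


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

_LABEL_JOIN = "|"


def _case_to_record(case: Synopsis | LabeledCase) -> dict:
    s = case.synopsis if isinstance(case, LabeledCase) else case
    rec: dict = {"case_id": s.case_id, "fields": [[n, d] for n, d in s.fields]}
    if s.provenance is not None:
        rec["provenance"] = s.provenance
    if isinstance(case, LabeledCase):
        rec["labels"] = sorted(case.gold.labels)
    return rec


def _record_to_case(
    rec: dict, vocab: LabelVocabulary | None, strict: bool
) -> Synopsis | LabeledCase:
    if "case_id" not in rec or rec["case_id"] in (None, ""):
        raise ValueError(f"record missing case_id: {rec!r}")
    syn = Synopsis(
        case_id=unicodedata.normalize("NFC", str(rec["case_id"])),
        fields=[
            (unicodedata.normalize("NFC", str(n)), unicodedata.normalize("NFC", str(d)))
            for n, d in rec["fields"]
        ],
        provenance=rec.get("provenance"),
    )
    labels = rec.get("labels")
    if labels is None:
        return syn
    ls = LabelSet(labels)
    if strict and vocab is not None:
        ls.validate_gold(vocab)
    return LabeledCase(syn, ls)


def write_corpus(corpus: Corpus, path: str | Path, format: str = "jsonl") -> None:
    """Write a corpus; ``format`` is 'jsonl', 'wide' or 'long' (delimited)."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for case in corpus:
                fh.write(json.dumps(_case_to_record(case), ensure_ascii=False) + "\n")
    elif format == "wide":
        rows = []
        for case in corpus:
            rec = _case_to_record(case)
            row = {"case_id": rec["case_id"]}
            row.update({n: d for n, d in rec["fields"]})
            if "labels" in rec:
                row["labels"] = _LABEL_JOIN.join(rec["labels"])
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    elif format == "long":
        rows = []
        for case in corpus:
            rec = _case_to_record(case)
            for n, d in rec["fields"]:
                rows.append({"case_id": rec["case_id"], "field_name": n, "description": d})
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown corpus format {format!r}")


def read_corpus(
    path: str | Path,
    format: str = "jsonl",
    vocab: LabelVocabulary | None = None,
    strict: bool = False,
    sep: str = ",",
) -> Corpus:
    """Read a corpus; round-trips :func:`write_corpus` exactly."""
    path = Path(path)
    corpus = Corpus()
    if format == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    corpus.add(_record_to_case(json.loads(line), vocab, strict))
        return corpus
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "case_id" not in df.columns:
        raise ValueError("delimited corpus requires a case_id column")
    if format == "long":
        if not {"field_name", "description"} <= set(df.columns):
            raise ValueError("long format needs field_name and description columns")
        for cid, grp in df.groupby("case_id", sort=False):
            rec = {"case_id": cid, "fields": grp[["field_name", "description"]].values.tolist()}
            corpus.add(_record_to_case(rec, vocab, strict))
        return corpus
    if format == "wide":
        if df["case_id"].duplicated().any():
            dup = df.loc[df["case_id"].duplicated(), "case_id"].iloc[0]
            raise ValueError(f"duplicate case_id {dup!r}")
        field_cols = [c for c in df.columns if c not in ("case_id", "labels")]
        for _, row in df.iterrows():
            rec: dict = {
                "case_id": row["case_id"],
                "fields": [[c, row[c]] for c in field_cols if row[c] != ""],
            }
            if "labels" in df.columns and row["labels"] != "":
                rec["labels"] = row["labels"].split(_LABEL_JOIN)
            corpus.add(_record_to_case(rec, vocab, strict))
        return corpus
    raise ValueError(f"unknown corpus format {format!r}")


def write_vocabulary(vocab: LabelVocabulary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(vocab.labels, ensure_ascii=False, indent=0) + "\n")


def read_vocabulary(path: str | Path) -> LabelVocabulary:
    labels = json.loads(Path(path).read_text())
    if not isinstance(labels, list):
        raise ValueError("vocabulary file must be a JSON list of label names")
    return LabelVocabulary(labels)
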