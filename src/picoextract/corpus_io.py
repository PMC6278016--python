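"""Corpus containers and file I/O.

A corpus is a list of abstracts; an abstract is an ordered list of sentences,
each carrying optional section-header information and zero or more gold PICO
labels (a sentence may be both Population and Intervention, for instance).
Two on-disk representations are supported: a JSON document with one object per
abstract, and a flat CSV with one row per sentence.  Both round-trip through a
canonical writer.

The module also emits the whitespace-separated training-file layouts consumed
by the CRF trainer: the *standard* layout (one row per sentence/gold-label
pair) and the *redundant* layout (one row per sentence/candidate-label pair
with a trailing 0/1 prediction column).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

#: The six sentence labels of the PIBOSO-style scheme.
LABELS: tuple[str, ...] = (
    "POPULATION",
    "INTERVENTION",
    "OUTCOME",
    "BACKGROUND",
    "STUDYDESIGN",
    "OTHER",
)

#: The three elements the extraction pipeline ultimately reports.
PICO_ELEMENTS: tuple[str, ...] = ("POPULATION", "INTERVENTION", "OUTCOME")

HEADERS: tuple[str, ...] = ("OBJECTIVE", "METHOD", "RESULTS", "CONCLUSION", "NOHEADING")


class CorpusFormatError(ValueError):
    """Raised when a corpus file violates the documented schema."""


@dataclass
class SentenceRecord:
    """One sentence of an abstract.

    ``index`` is the 1-based ordinal of the sentence within its abstract; the
    rule stage's "first three sentences" condition reads it directly.
    """

    abstract_id: str
    index: int
    text: str
    raw_header: str | None = None
    normalized_header: str = "NOHEADING"
    gold_labels: tuple[str, ...] = ()
    predicted_labels: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.index < 1:
            raise CorpusFormatError(
                f"abstract {self.abstract_id}: sentence index {self.index} < 1"
            )
        if not self.text:
            raise CorpusFormatError(f"abstract {self.abstract_id}: empty sentence text")
        if self.normalized_header not in HEADERS:
            raise CorpusFormatError(
                f"abstract {self.abstract_id}: bad header {self.normalized_header!r}"
            )
        for lab in (*self.gold_labels, *self.predicted_labels):
            if lab not in LABELS:
                raise CorpusFormatError(
                    f"abstract {self.abstract_id} sentence {self.index}: "
                    f"unknown label {lab!r}"
                )


@dataclass
class AbstractRecord:
    abstract_id: str
    title: str
    keywords: tuple[str, ...] = ()
    sentences: list[SentenceRecord] = field(default_factory=list)

    @property
    def is_structured(self) -> bool:
        return any(s.raw_header is not None for s in self.sentences)

    def validate(self) -> None:
        if not self.title:
            raise CorpusFormatError(f"abstract {self.abstract_id}: empty title")
        for i, sent in enumerate(self.sentences, start=1):
            sent.validate()
            if sent.abstract_id != self.abstract_id:
                raise CorpusFormatError(
                    f"abstract {self.abstract_id}: sentence carries foreign id "
                    f"{sent.abstract_id!r}"
                )
            if sent.index != i:
                raise CorpusFormatError(
                    f"abstract {self.abstract_id}: sentence indices not contiguous "
                    f"(expected {i}, got {sent.index})"
                )


@dataclass
class LabeledCorpus:
    abstracts: list[AbstractRecord] = field(default_factory=list)
    provenance: str = ""

    def validate(self) -> None:
        seen: set[str] = set()
        for abstract in self.abstracts:
            if abstract.abstract_id in seen:
                raise CorpusFormatError(f"duplicate abstract id {abstract.abstract_id!r}")
            seen.add(abstract.abstract_id)
            abstract.validate()

    def ids(self) -> list[str]:
        return [a.abstract_id for a in self.abstracts]

    def __len__(self) -> int:
        return len(self.abstracts)

    def sentences(self) -> Iterable[SentenceRecord]:
        for abstract in self.abstracts:
            yield from abstract.sentences


# ---------------------------------------------------------------------------
# JSON / CSV readers and writers
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json", "csv"):
        return suffix
    raise CorpusFormatError(f"cannot infer corpus format from {path.name!r}")


def read_corpus(path: str | Path, format: str | None = None) -> LabeledCorpus:
    """Read a corpus file (JSON or CSV; inferred from the suffix by default)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        corpus = _read_json(path)
    elif fmt == "csv":
        corpus = _read_csv(path)
    else:
        raise CorpusFormatError(f"unknown corpus format {fmt!r}")
    corpus.validate()
    return corpus


def write_corpus(corpus: LabeledCorpus, path: str | Path, format: str | None = None) -> Path:
    """Write a corpus in canonical form (stable key order, 2-space indent)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(corpus_to_json(corpus), encoding="utf-8")
    elif fmt == "csv":
        _write_csv(corpus, path)
    else:
        raise CorpusFormatError(f"unknown corpus format {fmt!r}")
    return path


def corpus_to_json(corpus: LabeledCorpus) -> str:
    doc = {
        "provenance": corpus.provenance,
        "abstracts": [
            {
                "abstract_id": a.abstract_id,
                "title": a.title,
                "keywords": list(a.keywords),
                "sentences": [
                    {
                        "index": s.index,
                        "text": s.text,
                        "raw_header": s.raw_header,
                        "gold_labels": list(s.gold_labels),
                        "predicted_labels": list(s.predicted_labels),
                    }
                    for s in a.sentences
                ],
            }
            for a in corpus.abstracts
        ],
    }
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


def _read_json(path: Path) -> LabeledCorpus:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CorpusFormatError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "abstracts" not in doc:
        raise CorpusFormatError(f"{path}: top-level object must contain 'abstracts'")
    abstracts = []
    for entry in doc["abstracts"]:
        aid = str(entry.get("abstract_id", ""))
        if not aid:
            raise CorpusFormatError(f"{path}: abstract without 'abstract_id'")
        sentences = []
        for j, sent in enumerate(entry.get("sentences", []), start=1):
            sentences.append(
                SentenceRecord(
                    abstract_id=aid,
                    index=int(sent.get("index", j)),
                    text=str(sent.get("text", "")),
                    raw_header=sent.get("raw_header"),
                    gold_labels=tuple(sent.get("gold_labels", [])),
                    predicted_labels=tuple(sent.get("predicted_labels", [])),
                )
            )
        abstracts.append(
            AbstractRecord(
                abstract_id=aid,
                title=str(entry.get("title", "")),
                keywords=tuple(entry.get("keywords", [])),
                sentences=sentences,
            )
        )
    return LabeledCorpus(abstracts=abstracts, provenance=str(doc.get("provenance", "")))


_CSV_FIELDS = [
    "abstract_id",
    "title",
    "keywords",
    "index",
    "raw_header",
    "text",
    "gold_labels",
    "predicted_labels",
]


def _read_csv(path: Path) -> LabeledCorpus:
    abstracts: dict[str, AbstractRecord] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise CorpusFormatError(f"{path}: missing CSV columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            aid = row["abstract_id"]
            if not aid:
                raise CorpusFormatError(f"{path}:{lineno}: empty abstract_id")
            if aid not in abstracts:
                abstracts[aid] = AbstractRecord(
                    abstract_id=aid,
                    title=row["title"],
                    keywords=tuple(k for k in row["keywords"].split(";") if k),
                )
            try:
                index = int(row["index"])
            except ValueError as exc:
                raise CorpusFormatError(
                    f"{path}:{lineno} (abstract {aid}): bad index {row['index']!r}"
                ) from exc
            abstracts[aid].sentences.append(
                SentenceRecord(
                    abstract_id=aid,
                    index=index,
                    text=row["text"],
                    raw_header=row["raw_header"] or None,
                    gold_labels=tuple(x for x in row["gold_labels"].split(";") if x),
                    predicted_labels=tuple(
                        x for x in row["predicted_labels"].split(";") if x
                    ),
                )
            )
    return LabeledCorpus(abstracts=list(abstracts.values()))


def _write_csv(corpus: LabeledCorpus, path: Path) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for a in corpus.abstracts:
            for s in a.sentences:
                writer.writerow(
                    {
                        "abstract_id": a.abstract_id,
                        "title": a.title,
                        "keywords": ";".join(a.keywords),
                        "index": s.index,
                        "raw_header": s.raw_header or "",
                        "text": s.text,
                        "gold_labels": ";".join(s.gold_labels),
                        "predicted_labels": ";".join(s.predicted_labels),
                    }
                )


# ---------------------------------------------------------------------------
# CRF training-file layouts
# ---------------------------------------------------------------------------

def sentence_key(sentence: SentenceRecord) -> tuple[str, int]:
    return (sentence.abstract_id, sentence.index)


def write_feature_file(
    corpus: LabeledCorpus,
    vectors: Mapping[tuple[str, int], "FeatureVector"],
    path: str | Path,
    layout: str = "standard",
    candidate_labels: Sequence[str] = LABELS,
) -> Path:
    """Emit the whitespace-separated training file the CRF trainer consumes.

    standard  -> one row per (sentence, gold label): tokens ... LABEL
    redundant -> one row per (sentence, candidate label): tokens ... LABEL 0/1
    """
    if layout not in ("standard", "redundant"):
        raise ValueError(f"unknown layout {layout!r}")
    path = Path(path)
    lines: list[str] = []
    for sentence in corpus.sentences():
        key = sentence_key(sentence)
        if key not in vectors:
            raise KeyError(
                f"no feature vector for sentence {key[1]} of abstract {key[0]!r}"
            )
        tokens = vectors[key].crf_tokens()
        prefix = f"{sentence.abstract_id}_{sentence.index}"
        if layout == "standard":
            for label in sentence.gold_labels:
                lines.append(" ".join([prefix, *tokens, label]))
        else:
            gold = set(sentence.gold_labels)
            for label in candidate_labels:
                flag = "1" if label in gold else "0"
                lines.append(" ".join([prefix, *tokens, label, flag]))
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return path


def split_train_test(
    corpus: LabeledCorpus, train_ids: Iterable[str]
) -> tuple[LabeledCorpus, LabeledCorpus]:
    """Partition a corpus by abstract id; ids must exist in the corpus."""
    train_ids = set(train_ids)
    unknown = train_ids - set(corpus.ids())
    if unknown:
        raise KeyError(f"unknown abstract ids in train set: {sorted(unknown)}")
    train = LabeledCorpus(
        abstracts=[a for a in corpus.abstracts if a.abstract_id in train_ids],
        provenance=corpus.provenance,
    )
    test = LabeledCorpus(
        abstracts=[a for a in corpus.abstracts if a.abstract_id not in train_ids],
        provenance=corpus.provenance,
    )
    return train, test


def copy_abstract(abstract: AbstractRecord) -> AbstractRecord:
    """Deep-enough copy: sentence records are replaced, lists are new."""
    return AbstractRecord(
        abstract_id=abstract.abstract_id,
        title=abstract.title,
        keywords=abstract.keywords,
        sentences=[replace(s) for s in abstract.sentences],
    )
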