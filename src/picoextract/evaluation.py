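"""Precision / recall / F-score reporting and k-fold cross-validation.

Two granularities are first-class and every report names its mode:

* ``sentence_level`` — each (sentence, label) pair counts once: TP when the
  label is in both the predicted and gold sets, FP when predicted only, FN
  when gold only.
* ``abstract_level`` — judges the single sentence selected per element and
  abstract: TP when the selected sentence carries the element's gold label,
  FP when it does not, FN when an abstract with gold evidence for the element
  gets no selection or a wrong one.  A selected sentence with several gold
  labels is a TP for each element it matches.

Zero denominators yield an *undefined* metric (None), never NaN arithmetic;
undefined propagates to F.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import LabeledCorpus, PICO_ELEMENTS


def precision_recall_f(
    tp: int, fp: int, fn: int
) -> tuple[float | None, float | None, float | None]:
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f = None if (precision is None or recall is None) else 0.0
    else:
        f = 2 * precision * recall / (precision + recall)
    return precision, recall, f


@dataclass
class ElementScores:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float | None:
        return precision_recall_f(self.tp, self.fp, self.fn)[0]

    @property
    def recall(self) -> float | None:
        return precision_recall_f(self.tp, self.fp, self.fn)[1]

    @property
    def f_score(self) -> float | None:
        return precision_recall_f(self.tp, self.fp, self.fn)[2]


@dataclass
class EvalReport:
    mode: str
    per_element: dict[str, ElementScores] = field(default_factory=dict)
    missed_abstracts: dict[str, int] = field(default_factory=dict)

    def macro_f(self, elements: Sequence[str] = PICO_ELEMENTS) -> float:
        """Mean F over elements; undefined F counts as 0 (a class that is
        never predicted or never present contributes no credit)."""
        values = []
        for element in elements:
            f = self.per_element[element].f_score
            values.append(0.0 if f is None else f)
        return float(np.mean(values))

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "per_element": {
                e: {
                    "tp": s.tp,
                    "fp": s.fp,
                    "fn": s.fn,
                    "precision": s.precision,
                    "recall": s.recall,
                    "f_score": s.f_score,
                }
                for e, s in sorted(self.per_element.items())
            },
            "missed_abstracts": dict(sorted(self.missed_abstracts.items())),
        }


def evaluate_sentence_level(
    predictions: Mapping[tuple[str, int], set[str]],
    corpus: LabeledCorpus,
    elements: Sequence[str] = PICO_ELEMENTS,
) -> EvalReport:
    """Score per-sentence candidate label sets against gold label sets."""
    report = EvalReport(mode="sentence_level")
    for element in elements:
        report.per_element[element] = ElementScores()
    for sentence in corpus.sentences():
        key = (sentence.abstract_id, sentence.index)
        if key not in predictions:
            raise KeyError(f"no prediction for sentence {key}")
        predicted = predictions[key]
        gold = set(sentence.gold_labels)
        for element in elements:
            scores = report.per_element[element]
            if element in predicted and element in gold:
                scores.tp += 1
            elif element in predicted:
                scores.fp += 1
            elif element in gold:
                scores.fn += 1
    return report


def evaluate_abstract_level(
    selections: Mapping[str, Mapping[str, int | None]],
    corpus: LabeledCorpus,
    elements: Sequence[str] = PICO_ELEMENTS,
) -> EvalReport:
    """Score one selected sentence index (or None) per abstract and element.

    ``selections`` maps abstract_id -> {element: sentence index or None}.
    """
    known = {a.abstract_id for a in corpus.abstracts}
    unknown = set(selections) - known
    if unknown:
        raise KeyError(f"selections for unknown abstracts: {sorted(unknown)}")
    report = EvalReport(mode="abstract_level")
    for element in elements:
        report.per_element[element] = ElementScores()
        report.missed_abstracts[element] = 0
    for abstract in corpus.abstracts:
        chosen = selections.get(abstract.abstract_id, {})
        gold_indices = {
            element: {
                s.index for s in abstract.sentences if element in s.gold_labels
            }
            for element in elements
        }
        for element in elements:
            scores = report.per_element[element]
            index = chosen.get(element)
            has_gold = bool(gold_indices[element])
            if index is None:
                report.missed_abstracts[element] += 1
                if has_gold:
                    scores.fn += 1
            elif index in gold_indices[element]:
                scores.tp += 1
            else:
                scores.fp += 1
                if has_gold:
                    scores.fn += 1
    return report


def summarize_folds(reports: Sequence[EvalReport]) -> dict:
    """Mean and standard deviation of per-element F across folds (undefined
    F treated as 0, matching macro_f)."""
    out: dict = {"n_folds": len(reports), "per_element": {}}
    for element in reports[0].per_element:
        fs = [
            0.0 if r.per_element[element].f_score is None
            else r.per_element[element].f_score
            for r in reports
        ]
        out["per_element"][element] = {
            "mean_f": float(np.mean(fs)),
            "stdev_f": float(np.std(fs)),
        }
    return out


def cross_validate(
    corpus: LabeledCorpus,
    k: int = 5,
    config=None,
    seed: int = 0,
) -> tuple[list[EvalReport], dict]:
    """Abstract-level k-fold cross-validation of the full hybrid pipeline.

    Folds partition abstracts (no abstract straddles folds); the assignment
    is a seeded shuffle, so a given seed reproduces the folds exactly.
    Returns the per-fold abstract-level combined reports and a mean/stdev
    summary.
    """
    from .pipeline import PipelineConfig, run_hybrid  # local: avoids cycle

    if k < 2:
        raise ValueError("k must be >= 2")
    ids = corpus.ids()
    if k > len(ids):
        raise ValueError(f"k={k} exceeds corpus size {len(ids)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(ids)))
    folds = [sorted(ids[i] for i in order[j::k]) for j in range(k)]
    config = config or PipelineConfig()
    reports = []
    for fold_ids in folds:
        from .corpus_io import split_train_test

        test, train = split_train_test(corpus, fold_ids)  # fold = held-out
        result = run_hybrid(train, test, config)
        reports.append(result.combined_report)
    return reports, summarize_folds(reports)


def format_report_table(
    reports: Mapping[str, EvalReport], elements: Sequence[str] = ("POPULATION", "INTERVENTION")
) -> str:
    """Human-readable Precision/Recall/F table, one row per system
    (e.g. statistical stage, rule stage, combined) per metric."""

    def fmt(x: float | None) -> str:
        return "  n/a" if x is None else f"{100 * x:5.1f}%"

    lines = ["Metric      System        " + "  ".join(f"{e:>13}" for e in elements)]
    for metric in ("precision", "recall", "f_score"):
        for name, report in reports.items():
            cells = [fmt(getattr(report.per_element[e], metric)) for e in elements]
            lines.append(
                f"{metric:<11} {name:<13} " + "  ".join(f"{c:>13}" for c in cells)
            )
    return "\n".join(lines)
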