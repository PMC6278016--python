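"""Weighted selection of the most potential sentence per PICO element.

After CRF decoding, several sentences of an abstract may carry the same
candidate element.  Each candidate is scored with

    wTotal = wPoM + wPoT + wCo + wSe

* wPoM — positional weight, 2 or 0.  For P and I: 2 when the sentence sits in
  the METHOD section (structured abstracts) or in the first third
  (unstructured).  For O: 2 for the RESULTS section or the last third.
* wPoT — title-overlap weight, the value of f5.
* wCo  — coexistence weight, 2 when the candidate set contains both P and I
  (P/I scoring only; 0 for O).
* wSe  — semantic weight: f1+f2 for P, f3 for I, f4 for O.

The 2/0 positional and coexistence weights deliberately nudge rather than
dominate: they favour the typical location without overwhelming the semantic
evidence.  The highest total wins; ties go to the earliest sentence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .corpus_io import AbstractRecord, PICO_ELEMENTS, SentenceRecord
from .features import FeatureVector
from .preprocess import FIRST_THIRD, LAST_THIRD, relative_position


@dataclass(frozen=True)
class SelectionScore:
    w_pom: int
    w_pot: int
    w_co: int
    w_se: int

    @property
    def total(self) -> int:
        return self.w_pom + self.w_pot + self.w_co + self.w_se


def _positional_weight(
    element: str,
    vector: FeatureVector,
    index: int,
    abstract_len: int,
    is_structured: bool,
) -> int:
    if element in ("POPULATION", "INTERVENTION"):
        if is_structured:
            return 2 if vector.f7 == "METHOD" else 0
        return 2 if relative_position(index, abstract_len) == FIRST_THIRD else 0
    # OUTCOME
    if is_structured:
        return 2 if vector.f7 == "RESULTS" else 0
    return 2 if relative_position(index, abstract_len) == LAST_THIRD else 0


def score_sentence(
    element: str,
    sentence: SentenceRecord,
    vector: FeatureVector,
    candidates: set[str],
    is_structured: bool,
    abstract_len: int,
) -> SelectionScore:
    """wTotal components for one candidate sentence/element pair."""
    if element not in PICO_ELEMENTS:
        raise ValueError(f"element must be one of {PICO_ELEMENTS}, got {element!r}")
    if element not in candidates:
        raise ValueError(
            f"sentence {sentence.index} is not a candidate for {element}"
        )
    w_pom = _positional_weight(
        element, vector, sentence.index, abstract_len, is_structured
    )
    w_pot = vector.f5
    if element == "OUTCOME":
        w_co = 0
        w_se = vector.f4
    else:
        w_co = 2 if {"POPULATION", "INTERVENTION"} <= candidates else 0
        w_se = vector.f1 + vector.f2 if element == "POPULATION" else vector.f3
    return SelectionScore(w_pom=w_pom, w_pot=w_pot, w_co=w_co, w_se=w_se)


def select_best(
    element: str,
    abstract: AbstractRecord,
    scores: Mapping[int, SelectionScore],
) -> SentenceRecord | None:
    """Argmax-by-total candidate for one element; ties break to the earliest
    sentence; None signals a missed abstract (input to the rule stage)."""
    if not scores:
        return None
    best_index = min(scores, key=lambda i: (-scores[i].total, i))
    for sentence in abstract.sentences:
        if sentence.index == best_index:
            return sentence
    raise KeyError(f"score refers to unknown sentence index {best_index}")


def score_abstract_candidates(
    abstract: AbstractRecord,
    vectors: Mapping[tuple[str, int], FeatureVector],
    candidate_sets: list[set[str]],
) -> dict[str, dict[int, SelectionScore]]:
    """Scores for every (element, candidate sentence) pair of one abstract."""
    is_structured = abstract.is_structured
    n = len(abstract.sentences)
    out: dict[str, dict[int, SelectionScore]] = {e: {} for e in PICO_ELEMENTS}
    for sentence, candidates in zip(abstract.sentences, candidate_sets):
        vector = vectors[(abstract.abstract_id, sentence.index)]
        for element in PICO_ELEMENTS:
            if element in candidates:
                out[element][sentence.index] = score_sentence(
                    element, sentence, vector, candidates, is_structured, n
                )
    return out
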