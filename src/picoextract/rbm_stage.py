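"""Rule-based fallback for abstracts the CRF stage missed.

The statistical stage occasionally returns no candidate at all for the
Population or Intervention element of an abstract — especially for
unstructured abstracts, whose structural features are weak.  This stage
applies hand-written rules over the same semantic features to those missed
elements only; it never overrides a statistical selection.

Each rule is a disjunction of three clauses:

Population:  f1 >= 3  or  f2 >= 3
             or (f1 >= 1 or f2 >= 1) and header == METHOD
             or f2 >= 1 and header == NOHEADING and index < 4

Intervention: f3 >= 3
             or f3 >= 1 and header == METHOD
             or f3 >= 1 and header == NOHEADING and index < 4

The strong threshold 3 is the average semantic-feature value observed in
Population sentences; the METHOD clause relaxes it because P and I normally
live in the METHOD section, and the NOHEADING clause covers unstructured
abstracts, where these elements are usually within the first three
sentences.  Thresholds are configurable; lowering the strong threshold only
enlarges the hit set (the rules are monotone in f1, f2, f3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .corpus_io import AbstractRecord, SentenceRecord
from .features import FeatureVector
from .selection import SelectionScore, score_sentence

RBM_ELEMENTS = ("POPULATION", "INTERVENTION")


@dataclass(frozen=True)
class RuleThresholds:
    strong: int = 3   # semantic evidence alone suffices
    weak: int = 1     # suffices with positional support
    max_lead_sentence: int = 4  # "first three sentences": index < 4 (1-based)


DEFAULT_THRESHOLDS = RuleThresholds()


def rule_population(
    vector: FeatureVector,
    header: str,
    index: int,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    t = thresholds
    return (
        vector.f1 >= t.strong
        or vector.f2 >= t.strong
        or ((vector.f1 >= t.weak or vector.f2 >= t.weak) and header == "METHOD")
        or (
            vector.f2 >= t.weak
            and header == "NOHEADING"
            and index < t.max_lead_sentence
        )
    )


def rule_intervention(
    vector: FeatureVector,
    header: str,
    index: int,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    t = thresholds
    return (
        vector.f3 >= t.strong
        or (vector.f3 >= t.weak and header == "METHOD")
        or (
            vector.f3 >= t.weak
            and header == "NOHEADING"
            and index < t.max_lead_sentence
        )
    )


_RULES = {"POPULATION": rule_population, "INTERVENTION": rule_intervention}


def apply_rbm(
    abstract: AbstractRecord,
    missed_elements: Iterable[str],
    vectors: Mapping[tuple[str, int], FeatureVector],
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> dict[str, tuple[SentenceRecord, SelectionScore] | None]:
    """Evaluate the P/I rules on every sentence of an abstract for the
    elements the statistical stage missed.

    Rule-satisfying sentences compete through the same weighted scorer as
    statistical candidates (with the rule hits as the candidate set); the
    highest total wins, ties break earliest.  An element with no rule hit
    stays None (a not-applicable outcome).
    """
    missed = list(missed_elements)
    bad = [e for e in missed if e not in RBM_ELEMENTS]
    if bad:
        raise ValueError(
            f"rule stage only handles missed P/I elements, got {bad}; "
            "it must not override statistical selections"
        )
    n = len(abstract.sentences)
    # Candidate sets per sentence: which missed elements' rules fire.
    hits: dict[int, set[str]] = {}
    for sentence in abstract.sentences:
        vector = vectors[(abstract.abstract_id, sentence.index)]
        fired = {
            e
            for e in missed
            if _RULES[e](vector, sentence.normalized_header, sentence.index, thresholds)
        }
        if fired:
            hits[sentence.index] = fired
    result: dict[str, tuple[SentenceRecord, SelectionScore] | None] = {}
    for element in missed:
        best: tuple[int, SelectionScore] | None = None
        for sentence in abstract.sentences:
            fired = hits.get(sentence.index, set())
            if element not in fired:
                continue
            vector = vectors[(abstract.abstract_id, sentence.index)]
            score = score_sentence(
                element, sentence, vector, fired, abstract.is_structured, n
            )
            if best is None or score.total > best[1].total:
                best = (sentence.index, score)
        if best is None:
            result[element] = None
        else:
            sentence = abstract.sentences[best[0] - 1]
            result[element] = (sentence, best[1])
    return result
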