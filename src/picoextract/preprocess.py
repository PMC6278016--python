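"""Text rectification, sentence segmentation, tokenization, POS tagging,
header standardization and positional helpers.

Medical abstracts are full of periods that do not end sentences ("vs.",
"e.g.", "2.5 mg").  ``rectify_text`` shields those before segmentation by
swapping the ambiguous period for a one-dot-leader sentinel that
``segment_sentences`` restores after splitting.

Structured abstracts use dozens of header spellings for the same four
sections; ``standardize_header`` maps any known variant onto
OBJECTIVE / METHOD / RESULTS / CONCLUSION and degrades gracefully (to
NOHEADING, with a warning) on unknown ones.
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from pathlib import Path

from .corpus_io import AbstractRecord, SentenceRecord, copy_abstract

# Sentinel that cannot occur in input text; visually a period.
_DOT = "․"

#: Abbreviations whose trailing period must not end a sentence.
PROTECTED_ABBREVIATIONS = (
    "vs.", "e.g.", "i.e.", "etc.", "ca.", "cf.", "al.", "fig.", "no.", "st.", "dr.",
)

_DECIMAL_RE = re.compile(r"(?<=\d)\.(?=\d)")
_SENT_SPLIT_RE = re.compile(r"(?<=[.?!])\s+")


def rectify_text(raw: str) -> str:
    """Shield abbreviation and decimal periods so segmentation cannot split
    on them.  Identity on already-clean text; the sentinel is restored by
    :func:`segment_sentences`."""
    if not raw:
        return raw
    text = _DECIMAL_RE.sub(_DOT, raw)

    def _protect(match: re.Match) -> str:
        return match.group(0).replace(".", _DOT)

    for abbrev in PROTECTED_ABBREVIATIONS:
        pattern = re.compile(re.escape(abbrev), re.IGNORECASE)
        text = pattern.sub(_protect, text)
    return text


def segment_sentences(text: str) -> list[str]:
    """Split rectified text into sentences on ./?/! followed by whitespace.

    The concatenation of the output (modulo whitespace) equals the input;
    shielded periods are restored in the returned sentences.
    """
    if not text.strip():
        return []
    parts = _SENT_SPLIT_RE.split(text.strip())
    return [p.replace(_DOT, ".") for p in parts if p.strip()]


_TOKEN_RE = re.compile(
    r"\d+(?:\.\d+)+%?|[A-Za-z0-9%]+(?:[-'][A-Za-z0-9%]+)*"
)


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens; hyphen/apostrophe-joined runs stay together."""
    return [t.lower() for t in _TOKEN_RE.findall(text.replace(_DOT, "."))]


# ---------------------------------------------------------------------------
# POS tagging — a compact rule tagger (closed-class lookup + suffix rules).
# Coarse Penn-style tags; the bag-of-words feature only needs a stable,
# roughly correct tag per token.
# ---------------------------------------------------------------------------

_CLOSED_CLASS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT", "these": "DT",
    "those": "DT", "all": "DT", "each": "DT", "both": "DT", "some": "DT",
    "of": "IN", "in": "IN", "on": "IN", "for": "IN", "with": "IN", "by": "IN",
    "from": "IN", "to": "TO", "at": "IN", "as": "IN", "into": "IN", "after": "IN",
    "before": "IN", "between": "IN", "during": "IN", "among": "IN", "versus": "IN",
    "vs": "IN", "than": "IN", "and": "CC", "or": "CC", "but": "CC", "nor": "CC",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "has": "VBZ", "have": "VBP", "had": "VBD",
    "do": "VBP", "does": "VBZ", "did": "VBD", "can": "MD", "could": "MD",
    "may": "MD", "might": "MD", "will": "MD", "would": "MD", "should": "MD",
    "we": "PRP", "they": "PRP", "it": "PRP", "he": "PRP", "she": "PRP",
    "not": "RB", "no": "DT", "there": "EX", "who": "WP", "which": "WDT",
    "whose": "WP$", "when": "WRB", "where": "WRB", "while": "IN", "if": "IN",
    "more": "JJR", "most": "JJS", "less": "JJR", "least": "JJS",
}

_SUFFIX_RULES = (
    ("ing", "VBG"), ("edly", "RB"), ("ly", "RB"), ("ed", "VBD"),
    ("tion", "NN"), ("sion", "NN"), ("ment", "NN"), ("ness", "NN"),
    ("ity", "NN"), ("ism", "NN"), ("ous", "JJ"), ("ful", "JJ"),
    ("ive", "JJ"), ("ible", "JJ"), ("able", "JJ"), ("ic", "JJ"), ("al", "JJ"),
    ("ies", "NNS"), ("ses", "NNS"),
)

_NUM_RE = re.compile(r"^\d[\d.,%]*$")


def pos_tag(tokens: list[str]) -> list[str]:
    """Tag lowercased tokens with coarse Penn-style POS labels."""
    tags = []
    for tok in tokens:
        if tok in _CLOSED_CLASS:
            tags.append(_CLOSED_CLASS[tok])
        elif _NUM_RE.match(tok) or tok.endswith("%"):
            tags.append("CD")
        else:
            for suffix, tag in _SUFFIX_RULES:
                if len(tok) > len(suffix) + 2 and tok.endswith(suffix):
                    tags.append(tag)
                    break
            else:
                tags.append("NNS" if len(tok) > 4 and tok.endswith("s") else "NN")
    return tags


# ---------------------------------------------------------------------------
# Section-header standardization
# ---------------------------------------------------------------------------

#: Default raw-header variant -> common-header mapping.  Covers the published
#: exemplar variants plus frequent synonyms; user-extensible via CSV.
DEFAULT_HEADER_VARIANTS: dict[str, str] = {
    # OBJECTIVE family
    "AIM": "OBJECTIVE", "AIMS": "OBJECTIVE", "OBJECTIVE": "OBJECTIVE",
    "OBJECTIVES": "OBJECTIVE", "BACKGROUND AND OBJECTIVES": "OBJECTIVE",
    "BACKGROUND AND OBJECTIVE": "OBJECTIVE", "CONTEXT": "OBJECTIVE",
    "BACKGROUND": "OBJECTIVE", "PURPOSE": "OBJECTIVE", "INTRODUCTION": "OBJECTIVE",
    "GOAL": "OBJECTIVE", "RATIONALE": "OBJECTIVE",
    # METHOD family
    "DESIGN": "METHOD", "DESIGN AND METHODS": "METHOD", "PATIENT(S)": "METHOD",
    "INTERVENTION": "METHOD", "INTERVENTIONS": "METHOD", "METHOD": "METHOD",
    "METHODS": "METHOD", "METHODOLOGY": "METHOD", "PATIENTS": "METHOD",
    "PATIENTS AND METHODS": "METHOD", "SUBJECTS": "METHOD",
    "PARTICIPANTS": "METHOD", "SETTING": "METHOD", "STUDY DESIGN": "METHOD",
    "MATERIALS AND METHODS": "METHOD", "POPULATION": "METHOD",
    # RESULTS family
    "FINDINGS": "RESULTS", "MAIN RESULTS": "RESULTS", "OUTCOME MEASURES": "RESULTS",
    "RESULTS": "RESULTS", "RESULT": "RESULTS", "OUTCOMES": "RESULTS",
    "MAIN OUTCOME MEASURES": "RESULTS",
    # CONCLUSION family
    "CONCLUSION": "CONCLUSION", "CONCLUSIONS": "CONCLUSION",
    "DISCUSSION": "CONCLUSION", "IMPLICATIONS": "CONCLUSION",
    "SUMMARY": "CONCLUSION", "INTERPRETATION": "CONCLUSION",
    "COMMENT": "CONCLUSION",
}


class HeaderMap:
    """Case-insensitive raw header -> common header lookup."""

    def __init__(self, variants: dict[str, str] | None = None):
        source = DEFAULT_HEADER_VARIANTS if variants is None else variants
        self._map = {k.strip().upper(): v for k, v in source.items()}
        bad = {v for v in self._map.values()} - {
            "OBJECTIVE", "METHOD", "RESULTS", "CONCLUSION"
        }
        if bad:
            raise ValueError(f"header map targets outside common set: {sorted(bad)}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "HeaderMap":
        variants: dict[str, str] = {}
        with Path(path).open(newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#"):
                    continue
                variants[row[0]] = row[1].strip().upper()
        return cls(variants)

    def lookup(self, raw_header: str) -> str | None:
        return self._map.get(raw_header.strip().upper())

    def variants(self) -> dict[str, str]:
        return dict(self._map)


DEFAULT_HEADER_MAP = HeaderMap()


def standardize_header(raw_header: str, header_map: HeaderMap = DEFAULT_HEADER_MAP) -> str:
    """Map a raw section header onto a common header; unknown variants
    degrade to NOHEADING with a warning rather than raising."""
    if not raw_header:
        raise ValueError("raw_header must be non-empty")
    common = header_map.lookup(raw_header)
    if common is None:
        # Already-normalized input stays put (idempotence).
        upper = raw_header.strip().upper()
        if upper == "NOHEADING":
            return "NOHEADING"
        warnings.warn(f"unknown section header {raw_header!r}; using NOHEADING")
        return "NOHEADING"
    return common


def standardize_corpus_headers(
    abstract: AbstractRecord, header_map: HeaderMap = DEFAULT_HEADER_MAP
) -> AbstractRecord:
    """Fill ``normalized_header`` for every sentence from its raw header."""
    out = copy_abstract(abstract)
    for sent in out.sentences:
        if sent.raw_header is None:
            sent.normalized_header = "NOHEADING"
        else:
            sent.normalized_header = standardize_header(sent.raw_header, header_map)
    return out


# ---------------------------------------------------------------------------
# Pseudo-structuring of unstructured training abstracts
# ---------------------------------------------------------------------------

#: Gold label -> section used when fabricating headers for unstructured
#: training abstracts, so structural features stay informative.
PSEUDO_SECTION_BY_LABEL = {
    "BACKGROUND": "OBJECTIVE",
    "POPULATION": "METHOD",
    "INTERVENTION": "METHOD",
    "STUDYDESIGN": "METHOD",
    "OUTCOME": "RESULTS",
    "OTHER": "CONCLUSION",
}

_SECTION_ORDER = {"OBJECTIVE": 0, "METHOD": 1, "RESULTS": 2, "CONCLUSION": 3}


def pseudo_section_for(gold_labels: tuple[str, ...]) -> str:
    """Section a multi-label sentence lands in: the earliest section any of
    its labels maps to (P and I map identically, so ties are rare)."""
    sections = [PSEUDO_SECTION_BY_LABEL[lab] for lab in gold_labels]
    return min(sections, key=_SECTION_ORDER.__getitem__)


def pseudo_structure(abstract: AbstractRecord) -> AbstractRecord:
    """Assign gold-label-derived headers to an unstructured training abstract.

    Only headers change; text, order and labels are untouched.  Calling it on
    a structured abstract is a warned no-op; calling it without gold labels is
    an error (it would be test-time misuse).
    """
    if abstract.is_structured:
        warnings.warn(
            f"abstract {abstract.abstract_id!r} is already structured; "
            "pseudo_structure is a no-op"
        )
        return copy_abstract(abstract)
    if any(not s.gold_labels for s in abstract.sentences):
        raise ValueError(
            f"abstract {abstract.abstract_id!r} has sentences without gold labels; "
            "pseudo-structuring is a training-time operation"
        )
    out = copy_abstract(abstract)
    for sent in out.sentences:
        sent.normalized_header = pseudo_section_for(sent.gold_labels)
    return out


# ---------------------------------------------------------------------------
# Relative position (thirds, ceiling convention)
# ---------------------------------------------------------------------------

FIRST_THIRD = "FIRST_THIRD"
MIDDLE_THIRD = "MIDDLE_THIRD"
LAST_THIRD = "LAST_THIRD"


def relative_position(index: int, abstract_len: int) -> str:
    """Place a 1-based sentence index into thirds of its abstract.

    The first third takes ceil(L/3) sentences, the last third floor(L/3);
    abstracts shorter than 3 sentences are all FIRST_THIRD.
    """
    if not 1 <= index <= abstract_len:
        raise ValueError(f"index {index} out of range 1..{abstract_len}")
    if abstract_len < 3:
        return FIRST_THIRD
    first_end = math.ceil(abstract_len / 3)
    last_start = abstract_len - abstract_len // 3 + 1
    if index <= first_end:
        return FIRST_THIRD
    if index >= last_start:
        return LAST_THIRD
    return MIDDLE_THIRD
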