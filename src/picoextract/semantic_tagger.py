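"""Lexicon-based semantic tagging.

Assigns sentence tokens to four coarse semantic categories — demographic
(age/race/gender) cues, disorders, procedures & drugs, and outcome cues —
mirroring the role UMLS semantic groups play in clinical NLP pipelines.
Per-sentence hit counts feed the semantic features f1–f4, and the counts are
also rendered as categorical tokens (MPt_k, MP_k, MI_k, MT_k) for the CRF's
bag-of-words.

Lexicons are flat UTF-8 files, one term per line, ``#`` comments allowed;
multi-word terms are matched greedily longest-first, and the categories of a
bundle must be disjoint so a token counts for at most one category.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

CATEGORIES = (
    "PATIENT_DEMOGRAPHIC",
    "DISORDERS",
    "PROCEDURES_DRUGS",
    "OUTCOME_CUES",
)

#: categorical-token prefix per category (MT is handled separately from the
#: title-overlap count).
_CATEGORY_PREFIX = {
    "PATIENT_DEMOGRAPHIC": "MPt",
    "DISORDERS": "MP",
    "PROCEDURES_DRUGS": "MI",
    "OUTCOME_CUES": "MO",
}

_COUNT_FIELD = {
    "PATIENT_DEMOGRAPHIC": "n_demographic",
    "DISORDERS": "n_disorder",
    "PROCEDURES_DRUGS": "n_intervention",
    "OUTCOME_CUES": "n_outcome",
}


class LexiconConfigError(ValueError):
    """Raised for empty or overlapping lexicon bundles."""


@dataclass(frozen=True)
class Lexicon:
    category: str
    terms: frozenset[str]

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise LexiconConfigError(f"unknown lexicon category {self.category!r}")
        if not self.terms:
            raise LexiconConfigError(f"lexicon {self.category} has no terms")


class LexiconBundle:
    """Disjoint set of lexicons plus a phrase index for greedy matching."""

    def __init__(self, lexicons: Iterable[Lexicon]):
        self.lexicons: dict[str, Lexicon] = {}
        for lex in lexicons:
            if lex.category in self.lexicons:
                raise LexiconConfigError(f"duplicate category {lex.category}")
            self.lexicons[lex.category] = lex
        if not self.lexicons:
            raise LexiconConfigError("empty lexicon bundle")
        self._check_disjoint()
        # first token -> [(phrase tokens, category)], longest phrases first
        self._index: dict[str, list[tuple[tuple[str, ...], str]]] = {}
        for cat in CATEGORIES:
            if cat not in self.lexicons:
                continue
            for term in self.lexicons[cat].terms:
                toks = tuple(term.split())
                self._index.setdefault(toks[0], []).append((toks, cat))
        for entries in self._index.values():
            entries.sort(key=lambda e: -len(e[0]))

    def _check_disjoint(self) -> None:
        seen: dict[str, str] = {}
        for cat, lex in self.lexicons.items():
            for term in lex.terms:
                if term in seen:
                    raise LexiconConfigError(
                        f"term {term!r} appears in both {seen[term]} and {cat}"
                    )
                seen[term] = cat

    def categories(self) -> list[str]:
        return [c for c in CATEGORIES if c in self.lexicons]

    def terms(self, category: str) -> frozenset[str]:
        return self.lexicons[category].terms

    def match_at(self, tokens: list[str], i: int) -> tuple[int, str] | None:
        """Longest lexicon phrase starting at position ``i``; returns
        (phrase length, category) or None."""
        for phrase, cat in self._index.get(tokens[i], ()):
            if tuple(tokens[i : i + len(phrase)]) == phrase:
                return len(phrase), cat
        return None


@dataclass
class SemanticTags:
    """Per-token category assignments and per-sentence category counts."""

    token_categories: list[str | None] = field(default_factory=list)
    n_demographic: int = 0
    n_disorder: int = 0
    n_intervention: int = 0
    n_outcome: int = 0

    def count(self, category: str) -> int:
        return getattr(self, _COUNT_FIELD[category])


def load_lexicon(path: str | Path, category: str) -> Lexicon:
    terms = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip().lower()
        if line:
            terms.add(line)
    return Lexicon(category=category, terms=frozenset(terms))


_DEFAULT_FILES = {
    "PATIENT_DEMOGRAPHIC": "patient_demographic.txt",
    "DISORDERS": "disorders.txt",
    "PROCEDURES_DRUGS": "procedures_drugs.txt",
    "OUTCOME_CUES": "outcome_cues.txt",
}


def load_bundle(paths: Mapping[str, str | Path]) -> LexiconBundle:
    """Build a bundle from {category: file path}."""
    return LexiconBundle(load_lexicon(p, cat) for cat, p in paths.items())


def default_bundle() -> LexiconBundle:
    """The lexicons shipped with the package.

    These are the package's own curated term lists (the outcome-cue list in
    particular has no published reference inventory); they are sized for
    synthetic and desk-scale corpora and are meant to be replaced or extended
    for production use.
    """
    root = resources.files("picoextract").joinpath("data/lexicons")
    lexicons = []
    for cat, name in _DEFAULT_FILES.items():
        with resources.as_file(root.joinpath(name)) as path:
            lexicons.append(load_lexicon(path, cat))
    return LexiconBundle(lexicons)


def tag_sentence(tokens: list[str], bundle: LexiconBundle) -> SemanticTags:
    """Greedy longest-match tagging of a lowercased token list.

    Each matched phrase counts one hit for its category; a token belongs to
    at most one category (bundle disjointness plus left-to-right scan).
    """
    if not isinstance(bundle, LexiconBundle):
        raise LexiconConfigError("tag_sentence requires a LexiconBundle")
    tags = SemanticTags(token_categories=[None] * len(tokens))
    i = 0
    while i < len(tokens):
        hit = bundle.match_at(tokens, i)
        if hit is None:
            i += 1
            continue
        length, cat = hit
        for j in range(i, i + length):
            tags.token_categories[j] = cat
        setattr(tags, _COUNT_FIELD[cat], tags.count(cat) + 1)
        i += length
    return tags


_TOKEN_PATTERN = re.compile(r"^(MPt|MP|MI|MT)_(\d+)$")


def categorical_encoding(tags: SemanticTags, in_title_count: int) -> list[str]:
    """Render semantic counts as categorical tokens: MPt_k (demographic),
    MP_k (disorder), MI_k (intervention), MT_k (title overlap).  Zero counts
    emit nothing."""
    out = []
    if tags.n_demographic:
        out.append(f"MPt_{tags.n_demographic}")
    if tags.n_disorder:
        out.append(f"MP_{tags.n_disorder}")
    if tags.n_intervention:
        out.append(f"MI_{tags.n_intervention}")
    if in_title_count:
        out.append(f"MT_{in_title_count}")
    return out


def decode_categorical(tokens: Iterable[str]) -> dict[str, int]:
    """Parse categorical tokens back to {prefix: count} (round-trip check)."""
    counts: dict[str, int] = {}
    for tok in tokens:
        m = _TOKEN_PATTERN.match(tok)
        if m:
            counts[m.group(1)] = int(m.group(2))
    return counts
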