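"""Per-sentence feature vectors.

Ten features per sentence, three families:

* semantic — f1 demographic hits, f2 disorder hits, f3 procedure/drug hits,
  f4 outcome-cue hits (from the lexicon tagger);
* structural — f5 title overlap, f6 keyword overlap, f7 normalized section
  header, f8 length in words, f9 grouped structural position code;
* lexical — f10, the bag of ``word|POS`` unigrams.

f9 reconciles header and sentence number into one code: every sentence of a
headed section shares the section's code (OBJECTIVE 3, METHOD 6, RESULTS 12,
CONCLUSION 14 — roughly cumulative average section sizes), which clusters the
feature bag and so regularizes training.  Sentences without a header keep
their own index, capped at the last section code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus_io import AbstractRecord, SentenceRecord
from .preprocess import pos_tag, tokenize
from .semantic_tagger import LexiconBundle, categorical_encoding, tag_sentence

#: Grouped structural code per common section header.
SECTION_CODES = {"OBJECTIVE": 3, "METHOD": 6, "RESULTS": 12, "CONCLUSION": 14}

_MAX_CODE = max(SECTION_CODES.values())
_LEN_CAP = 30  # length token cap; longer sentences share one token


@dataclass
class FeatureVector:
    f1: int  # demographic hits
    f2: int  # disorder hits
    f3: int  # procedure/drug hits
    f4: int  # outcome-cue hits
    f5: int  # words shared with the title
    f6: int  # words shared with the keywords
    f7: str  # normalized header
    f8: int  # sentence length in words
    f9: int  # grouped structural position code
    f10: list[str] = field(default_factory=list)  # word|POS unigrams
    categorical: list[str] = field(default_factory=list)  # MPt_k, MP_k, MI_k, MT_k

    def crf_tokens(self) -> list[str]:
        """Flatten into the token bag the CRF observes at this position."""
        tokens = list(self.categorical)
        tokens.append(f"HDR={self.f7}")
        tokens.append(f"GRP={self.f9}")
        tokens.append(f"LEN={min(self.f8, _LEN_CAP)}")
        if self.f6:
            tokens.append(f"MK_{self.f6}")
        tokens.extend(self.f10)
        tokens.append("BIAS")
        return tokens


def group_structural(header: str, index: int, abstract_len: int) -> int:
    """Grouped position code: the section code for headed sentences, the raw
    sentence index (capped) when there is no header."""
    if header in SECTION_CODES:
        return SECTION_CODES[header]
    return min(index, _MAX_CODE)


def build_bow(tokens: list[str], pos_tags: list[str]) -> list[str]:
    """One ``word|POS`` token per input token, lowercased words."""
    if len(tokens) != len(pos_tags):
        raise ValueError(
            f"token/POS length mismatch: {len(tokens)} vs {len(pos_tags)}"
        )
    return [f"{t.lower()}|{p}" for t, p in zip(tokens, pos_tags)]


def extract_features(
    sentence: SentenceRecord,
    abstract: AbstractRecord,
    lexicons: LexiconBundle,
) -> FeatureVector:
    """The full 10-feature vector for one preprocessed sentence."""
    tokens = tokenize(sentence.text)
    if not tokens:
        raise ValueError(
            f"abstract {abstract.abstract_id} sentence {sentence.index}: no tokens"
        )
    tags = tag_sentence(tokens, lexicons)
    title_words = set(tokenize(abstract.title))
    keyword_words = set()
    for kw in abstract.keywords:
        keyword_words.update(tokenize(kw))
    sentence_words = set(tokens)
    f5 = len(sentence_words & title_words)
    f6 = len(sentence_words & keyword_words)
    f7 = sentence.normalized_header
    f9 = group_structural(f7, sentence.index, len(abstract.sentences))
    return FeatureVector(
        f1=tags.n_demographic,
        f2=tags.n_disorder,
        f3=tags.n_intervention,
        f4=tags.n_outcome,
        f5=f5,
        f6=f6,
        f7=f7,
        f8=len(tokens),
        f9=f9,
        f10=build_bow(tokens, pos_tag(tokens)),
        categorical=categorical_encoding(tags, f5),
    )


def extract_corpus_features(
    corpus, lexicons: LexiconBundle
) -> dict[tuple[str, int], FeatureVector]:
    """Feature vectors for every sentence, keyed by (abstract_id, index)."""
    vectors = {}
    for abstract in corpus.abstracts:
        for sentence in abstract.sentences:
            vectors[(abstract.abstract_id, sentence.index)] = extract_features(
                sentence, abstract, lexicons
            )
    return vectors
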