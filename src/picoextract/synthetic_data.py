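"""Synthetic labeled corpora with the statistical structure the pipeline
assumes.

The generator emulates a mixed collection of structured and unstructured
medical abstracts with a heavily skewed sentence-label distribution
(Population and Intervention sentences are rare; Outcome sentences are more
than a third of the corpus), non-standard header spellings, titles that share
vocabulary with the P/I sentences, and class-conditional vocabulary whose
informativeness is controlled by a single signal-strength dial ``s``:

* with probability ``s`` a sentence of class c draws terms from its class
  vocabulary (the shipped lexicons for P/I/O; closed side pools for
  Background/StudyDesign/Other) and, in structured abstracts, lands in its
  typical section (P/I/StudyDesign in METHOD, Outcome in RESULTS, Background
  in OBJECTIVE, Other in CONCLUSION); in unstructured abstracts P/I sentences
  gravitate to the first three positions and O to the last third;
* with probability ``1 - s`` the sentence is filler placed uniformly.

At s=1 the corpus is (nearly) separable; at s=0 labels are independent of
both vocabulary and position.  Everything is driven by one seed: the same
spec reproduces the corpus byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import AbstractRecord, LABELS, LabeledCorpus, SentenceRecord
from .semantic_tagger import Lexicon, LexiconBundle, default_bundle

#: Sentence-label proportions of the reference 1000-abstract training corpus.
DEFAULT_LABEL_DISTRIBUTION = {
    "POPULATION": 0.068,
    "INTERVENTION": 0.058,
    "OUTCOME": 0.366,
    "OTHER": 0.279,
    "STUDYDESIGN": 0.020,
    "BACKGROUND": 0.209,
}

#: 314 of the 800 training abstracts of the reference corpus are structured.
DEFAULT_STRUCTURED_FRACTION = 314 / 800

_FILLER = (
    "the a an of in and for with to on at by from this that these was were is "
    "are has have been not both during after under over study group groups "
    "data analysis using used based per two three four six eight twelve weeks "
    "months days period baseline total mean median level levels value values "
    "present presented describe described conducted performed collected "
    "recorded included assigned obtained available respective consecutive "
    "routine standard general current local regional annual initial final"
).split()

_BACKGROUND_POOL = (
    "evidence literature previous prior reports reported known unknown "
    "remains unclear poorly understood burden challenge important common "
    "increasingly worldwide debate question motivation little attention "
    "gap established emerging decade awareness demand"
).split()

_STUDYDESIGN_POOL = (
    "randomized randomised controlled trial double-blind single-blind "
    "crossover multicenter prospective retrospective observational pilot "
    "phase parallel pragmatic feasibility protocol allocation blinded "
    "stratified factorial"
).split()

_OTHER_POOL = (
    "conclude concluded suggest suggests further research needed future "
    "clinical practice guidelines recommend recommended consider overall "
    "interpretation caution warranted implication policy summary takeaway "
    "perspective limitations"
).split()

_SECTION_BY_LABEL = {
    "BACKGROUND": "OBJECTIVE",
    "POPULATION": "METHOD",
    "INTERVENTION": "METHOD",
    "STUDYDESIGN": "METHOD",
    "OUTCOME": "RESULTS",
    "OTHER": "CONCLUSION",
}
_SECTION_ORDER = ("OBJECTIVE", "METHOD", "RESULTS", "CONCLUSION")

#: Raw-header spellings the generator may emit per section, the common name
#: first; all resolve to the common header under the default header map.
_HEADER_SPELLINGS = {
    "OBJECTIVE": ["OBJECTIVE", "AIM", "BACKGROUND AND OBJECTIVES", "CONTEXT", "PURPOSE"],
    "METHOD": ["METHOD", "METHODS", "DESIGN", "DESIGN AND METHODS", "PATIENT(S)"],
    "RESULTS": ["RESULTS", "FINDINGS", "MAIN RESULTS", "OUTCOME MEASURES"],
    "CONCLUSION": ["CONCLUSION", "CONCLUSIONS", "DISCUSSION", "IMPLICATIONS", "SUMMARY"],
}


@dataclass
class GeneratorSpec:
    n_abstracts: int = 1000
    structured_fraction: float = DEFAULT_STRUCTURED_FRACTION
    label_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_DISTRIBUTION)
    )
    signal_strength: float = 0.9
    sentences_per_abstract: tuple[int, int] = (6, 12)
    sentence_length: tuple[int, int] = (8, 25)
    header_variant_noise: float = 0.3
    multi_label_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_abstracts < 1:
            raise ValueError("n_abstracts must be >= 1")
        if not 0 <= self.structured_fraction <= 1:
            raise ValueError("structured_fraction must be in [0, 1]")
        if set(self.label_distribution) != set(LABELS):
            raise ValueError(
                f"label_distribution must cover exactly {sorted(LABELS)}"
            )
        total = sum(self.label_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"label_distribution sums to {total}, not 1")
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must be in [0, 1]")
        lo, hi = self.sentences_per_abstract
        if not 1 <= lo <= hi:
            raise ValueError("bad sentences_per_abstract range")
        lo, hi = self.sentence_length
        if not 1 <= lo <= hi:
            raise ValueError("bad sentence_length range")


class _TermBank:
    """Sorted class-term pools aligned with a lexicon bundle."""

    def __init__(self, bundle: LexiconBundle):
        self.demographic = sorted(bundle.terms("PATIENT_DEMOGRAPHIC"))
        self.disorders = sorted(bundle.terms("DISORDERS"))
        self.procedures = sorted(bundle.terms("PROCEDURES_DRUGS"))
        self.outcomes = sorted(bundle.terms("OUTCOME_CUES"))


def _draw(rng: np.random.Generator, pool: list[str], n: int) -> list[str]:
    return [pool[int(i)] for i in rng.integers(0, len(pool), size=n)]


def _class_terms(
    rng: np.random.Generator, label: str, bank: _TermBank
) -> list[str]:
    """Signal chunks for one sentence of the given class."""
    if label == "POPULATION":
        return _draw(rng, bank.demographic, int(rng.integers(1, 3))) + _draw(
            rng, bank.disorders, int(rng.integers(1, 4))
        )
    if label == "INTERVENTION":
        return _draw(rng, bank.procedures, int(rng.integers(1, 5)))
    if label == "OUTCOME":
        # Results sentences restate the condition and intervention under
        # evaluation ("mortality in patients with X on drug Y fell"), so
        # outcome sentences share vocabulary with P and I.  Class evidence
        # is therefore ambiguous, and the rare P/I labels stay genuinely
        # hard to learn — the imbalance mechanism the corpus exhibits.
        chunks = _draw(rng, bank.outcomes, int(rng.integers(2, 5)))
        if rng.random() < 0.5:
            chunks += _draw(rng, bank.disorders, 1)
        if rng.random() < 0.4:
            chunks += _draw(rng, bank.procedures, 1)
        if rng.random() < 0.2:
            chunks += _draw(rng, bank.demographic, 1)
        return chunks
    if label == "BACKGROUND":
        # Background sentences overlap with P/I vocabulary: they introduce
        # the condition (and sometimes the population) under discussion.
        # This overlap is what makes the rare P label genuinely hard.
        chunks = _draw(rng, _BACKGROUND_POOL, int(rng.integers(2, 5)))
        if rng.random() < 0.6:
            chunks += _draw(rng, bank.disorders, int(rng.integers(1, 3)))
        if rng.random() < 0.3:
            chunks += _draw(rng, bank.demographic, 1)
        return chunks
    if label == "STUDYDESIGN":
        return _draw(rng, _STUDYDESIGN_POOL, int(rng.integers(2, 5)))
    # Concluding sentences often name the intervention they recommend.
    chunks = _draw(rng, _OTHER_POOL, int(rng.integers(2, 5)))
    if rng.random() < 0.3:
        chunks += _draw(rng, bank.procedures, 1)
    return chunks


def _assemble(rng: np.random.Generator, chunks: list[str], length: int) -> str:
    """Mix signal chunks (kept contiguous, so multi-word terms survive) with
    filler words up to roughly the requested length."""
    n_signal = sum(len(c.split()) for c in chunks)
    fillers = _draw(rng, _FILLER, max(length - n_signal, 2))
    parts = chunks + fillers
    rng.shuffle(parts)
    words = " ".join(parts).split()
    return words[0].capitalize() + " " + " ".join(words[1:]) + "."


def generate_corpus(
    spec: GeneratorSpec, bundle: LexiconBundle | None = None
) -> LabeledCorpus:
    """Generate a labeled corpus according to ``spec`` (seed-reproducible)."""
    spec.validate()
    bundle = bundle or default_bundle()
    bank = _TermBank(bundle)
    rng = np.random.default_rng(spec.seed)
    label_names = list(LABELS)
    probs = np.array([spec.label_distribution[l] for l in label_names])
    probs = probs / probs.sum()
    s = spec.signal_strength
    abstracts = []
    for a in range(spec.n_abstracts):
        aid = f"SYN{a:05d}"
        structured = bool(rng.random() < spec.structured_fraction)
        n_sent = int(rng.integers(spec.sentences_per_abstract[0],
                                  spec.sentences_per_abstract[1] + 1))
        drafts = []  # (labels, text, signalled, section or sort bucket)
        title_terms: list[str] = []
        for _ in range(n_sent):
            primary = label_names[int(rng.choice(len(label_names), p=probs))]
            labels = [primary]
            if primary in ("POPULATION", "INTERVENTION") and (
                rng.random() < spec.multi_label_rate
            ):
                labels.append(
                    "INTERVENTION" if primary == "POPULATION" else "POPULATION"
                )
            signalled = bool(rng.random() < s)
            length = int(rng.integers(spec.sentence_length[0],
                                      spec.sentence_length[1] + 1))
            if signalled:
                chunks = []
                for lab in labels:
                    chunks.extend(_class_terms(rng, lab, bank))
                if primary in ("POPULATION", "INTERVENTION"):
                    title_terms.extend(chunks[:2])
            else:
                chunks = []
            text = _assemble(rng, chunks, length)
            drafts.append((tuple(labels), text, signalled))
        # --- placement -----------------------------------------------------
        if structured:
            placed = []
            for labels, text, signalled in drafts:
                if signalled:
                    section = _SECTION_BY_LABEL[labels[0]]
                else:
                    section = _SECTION_ORDER[int(rng.integers(0, 4))]
                placed.append((_SECTION_ORDER.index(section), labels, text, section))
            placed.sort(key=lambda x: x[0])  # stable: in-section order kept
            sentences = []
            for i, (_, labels, text, section) in enumerate(placed, start=1):
                spellings = _HEADER_SPELLINGS[section]
                if rng.random() < spec.header_variant_noise:
                    raw = spellings[int(rng.integers(1, len(spellings)))]
                else:
                    raw = spellings[0]
                sentences.append(
                    SentenceRecord(
                        abstract_id=aid, index=i, text=text,
                        raw_header=raw, gold_labels=labels,
                    )
                )
        else:
            placed = []
            for labels, text, signalled in drafts:
                if signalled and labels[0] in ("POPULATION", "INTERVENTION"):
                    bucket = 0
                elif signalled and labels[0] == "OUTCOME":
                    bucket = 2
                else:
                    bucket = 1
                placed.append((bucket, labels, text))
            placed.sort(key=lambda x: x[0])
            sentences = [
                SentenceRecord(
                    abstract_id=aid, index=i, text=text,
                    raw_header=None, gold_labels=labels,
                )
                for i, (_, labels, text) in enumerate(placed, start=1)
            ]
        # --- title and keywords --------------------------------------------
        if not title_terms:
            title_terms = _draw(rng, bank.disorders, 1) + _draw(rng, bank.procedures, 1)
        seen: list[str] = []
        for term in title_terms:
            if term not in seen:
                seen.append(term)
        title_words = seen[:4] + _draw(rng, _FILLER, 2)
        title = " ".join(title_words).capitalize()
        keywords = tuple(
            dict.fromkeys(_draw(rng, bank.disorders, 2) + _draw(rng, bank.procedures, 1))
        )
        abstracts.append(
            AbstractRecord(
                abstract_id=aid, title=title, keywords=keywords, sentences=sentences
            )
        )
    corpus = LabeledCorpus(
        abstracts=abstracts,
        provenance=f"synthetic corpus (seed={spec.seed}, s={spec.signal_strength})",
    )
    corpus.validate()
    return corpus


# ---------------------------------------------------------------------------
# Worked fixture: four real candidate sentences with hand-set lexicons
# ---------------------------------------------------------------------------

_FIXTURE = [
    (
        "FX-P1",
        "Familial aggregation in breast cancer",
        "POPULATION",
        "An estimated 20% of all breast cancer or ovarian and breast cancer "
        "cases have familial aggregation.",
    ),
    (
        "FX-P2",
        "Implantable defibrillators in heart failure",
        "POPULATION",
        "Clinical trials such as the Sudden Cardiac Death Heart Failure Trial "
        "(SCD-HeFT) are currently underway to investigate the role of the "
        "implantable defibrillator in patients with heart failure.",
    ),
    (
        "FX-I1",
        "Tizanidine for spasticity",
        "INTERVENTION",
        "Tizanidine hydrochloride is a very useful medication in patients "
        "suffering from spasticity caused by MS, acquired brain injury or "
        "spinal cord injury.",
    ),
    (
        "FX-I2",
        "Laparoscopy for dialysis catheter dysfunction",
        "INTERVENTION",
        "Laparoscopy is highly accurate and effective in the management of "
        "peritoneal dialysis catheter dysfunction and results in prolongation "
        "of catheter life.",
    ),
]

_FIXTURE_FILLER = [
    "The study was conducted over a period of twelve months.",
    "Records were collected at baseline and at the final visit.",
]


def worked_lexicons() -> LexiconBundle:
    """Hand-set lexicon bundle under which each fixture sentence fires its
    element's extraction rule."""
    return LexiconBundle(
        [
            Lexicon("PATIENT_DEMOGRAPHIC", frozenset({"patients"})),
            Lexicon(
                "DISORDERS",
                frozenset(
                    {
                        "breast cancer",
                        "familial aggregation",
                        "heart failure",
                        "sudden cardiac death",
                        "spasticity",
                        "brain injury",
                        "spinal cord injury",
                    }
                ),
            ),
            Lexicon(
                "PROCEDURES_DRUGS",
                frozenset(
                    {
                        "tizanidine hydrochloride",
                        "medication",
                        "laparoscopy",
                        "peritoneal dialysis",
                        "catheter",
                    }
                ),
            ),
            Lexicon("OUTCOME_CUES", frozenset({"prolongation", "effective"})),
        ]
    )


def generate_worked_fixture() -> tuple[LabeledCorpus, LexiconBundle]:
    """A tiny fixed corpus of four unstructured abstracts, each embedding one
    real Population or Intervention candidate sentence in its first three
    sentences plus neutral filler, together with the hand-set lexicons under
    which each candidate fires its rule.  Content is fixed — identical bytes
    on every call."""
    abstracts = []
    for aid, title, label, target in _FIXTURE:
        texts = [_FIXTURE_FILLER[0], target, _FIXTURE_FILLER[1]]
        labels = [("OTHER",), (label,), ("OTHER",)]
        sentences = [
            SentenceRecord(
                abstract_id=aid, index=i, text=t, raw_header=None, gold_labels=l
            )
            for i, (t, l) in enumerate(zip(texts, labels), start=1)
        ]
        abstracts.append(
            AbstractRecord(abstract_id=aid, title=title, sentences=sentences)
        )
    corpus = LabeledCorpus(abstracts=abstracts, provenance="worked fixture")
    corpus.validate()
    return corpus, worked_lexicons()
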