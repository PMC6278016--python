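"""Apply the rule stage to real candidate sentences the CRF could miss.

The worked fixture embeds four genuine Population / Intervention sentences
from published abstracts inside tiny unstructured abstracts, with hand-set
lexicons.  The rules fire on semantic-feature thresholds: strong evidence
(3+ hits) anywhere, weak evidence (1+ hit) in the METHOD section or within
the first three sentences of an unstructured abstract.
"""

from picoextract import generate_worked_fixture
from picoextract.features import extract_corpus_features
from picoextract.pipeline import prepare_test_corpus
from picoextract.rbm_stage import apply_rbm

corpus, lexicons = generate_worked_fixture()
prepared = prepare_test_corpus(corpus)
vectors = extract_corpus_features(prepared, lexicons)

for abstract in prepared.abstracts:
    target = abstract.sentences[1]
    element = target.gold_labels[0]
    result = apply_rbm(abstract, [element], vectors)
    sentence, score = result[element]
    vec = vectors[(abstract.abstract_id, sentence.index)]
    print(f"{abstract.abstract_id} ({element}): picked sentence "
          f"{sentence.index}, f1={vec.f1} f2={vec.f2} f3={vec.f3}, "
          f"selection total {score.total}")
    print(f"   \"{sentence.text[:70]}...\"")
# Each abstract's candidate sits in the first three sentences with enough
# lexicon evidence, so the matching rule fires and selection picks it.
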