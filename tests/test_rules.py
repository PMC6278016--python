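import itertools

import pytest

from picoextract.corpus_io import AbstractRecord, SentenceRecord
from picoextract.features import FeatureVector
from picoextract.pipeline import prepare_test_corpus
from picoextract.features import extract_corpus_features
from picoextract.rbm_stage import (
    RuleThresholds,
    apply_rbm,
    rule_intervention,
    rule_population,
)
from picoextract.synthetic_data import generate_worked_fixture

HEADERS = ("METHOD", "NOHEADING", "RESULTS", "OBJECTIVE", "CONCLUSION")


def make_vector(f1=0, f2=0, f3=0, f7="NOHEADING"):
    return FeatureVector(
        f1=f1, f2=f2, f3=f3, f4=0, f5=0, f6=0, f7=f7, f8=10, f9=1, f10=[]
    )


def oracle_population(f1, f2, header, index):
    """Independently coded truth table: disjunction of the three clauses."""
    clause_semantic = f1 >= 3 or f2 >= 3
    clause_method = (f1 >= 1 or f2 >= 1) and header == "METHOD"
    clause_lead = f2 >= 1 and header == "NOHEADING" and index < 4
    return clause_semantic or clause_method or clause_lead


def oracle_intervention(f3, header, index):
    return (
        f3 >= 3
        or (f3 >= 1 and header == "METHOD")
        or (f3 >= 1 and header == "NOHEADING" and index < 4)
    )


class TestRules:
    def test_strong_semantic_evidence_fires_anywhere(self):
        assert rule_population(make_vector(f1=3), "CONCLUSION", 9)
        assert rule_intervention(make_vector(f3=3), "CONCLUSION", 9)

    def test_weak_evidence_needs_method_section(self):
        assert rule_population(make_vector(f1=1), "METHOD", 9)
        assert not rule_population(make_vector(f1=1), "RESULTS", 9)
        assert rule_intervention(make_vector(f3=1), "METHOD", 9)
        assert not rule_intervention(make_vector(), "METHOD", 9)

    def test_lead_sentence_clause_respects_position(self):
        assert rule_population(make_vector(f2=1), "NOHEADING", 3)
        assert not rule_population(make_vector(f2=1), "NOHEADING", 5)
        # the lead clause for P keys on the disorder count, not demographics
        assert not rule_population(make_vector(f1=1), "NOHEADING", 2)

    def test_exhaustive_truth_table_equivalence(self):
        """Full grid f1,f2,f3 in 0..5 x 5 headers x index 1..6 against the
        independently coded boolean oracle."""
        for f1, f2, f3, header, index in itertools.product(
            range(6), range(6), range(6), HEADERS, range(1, 7)
        ):
            vec = make_vector(f1=f1, f2=f2, f3=f3, f7=header)
            assert rule_population(vec, header, index) == oracle_population(
                f1, f2, header, index
            )
            assert rule_intervention(vec, header, index) == oracle_intervention(
                f3, header, index
            )

    def test_monotone_in_semantic_counts(self):
        for f1, f2, f3, header, index in itertools.product(
            range(5), range(5), range(5), HEADERS, (1, 4)
        ):
            lo_p = rule_population(make_vector(f1=f1, f2=f2), header, index)
            hi_p = rule_population(make_vector(f1=f1 + 1, f2=f2 + 1), header, index)
            assert hi_p or not lo_p
            lo_i = rule_intervention(make_vector(f3=f3), header, index)
            hi_i = rule_intervention(make_vector(f3=f3 + 1), header, index)
            assert hi_i or not lo_i

    def test_relaxing_strong_threshold_grows_hit_set(self):
        strict = RuleThresholds(strong=3)
        relaxed = RuleThresholds(strong=2)
        for f1, f2, header, index in itertools.product(
            range(5), range(5), HEADERS, (1, 5)
        ):
            vec = make_vector(f1=f1, f2=f2)
            if rule_population(vec, header, index, strict):
                assert rule_population(vec, header, index, relaxed)


class TestApplyRbm:
    def _abstract_with_vectors(self, specs):
        """specs: list of (text-placeholder vector, header)."""
        sentences = [
            SentenceRecord("A", i, "Placeholder text.", gold_labels=("OTHER",))
            for i in range(1, len(specs) + 1)
        ]
        for s, (_, header) in zip(sentences, specs):
            s.normalized_header = header
        abstract = AbstractRecord("A", "Title", sentences=sentences)
        vectors = {("A", i + 1): specs[i][0] for i in range(len(specs))}
        return abstract, vectors

    def test_single_rule_hit_selected(self):
        abstract, vectors = self._abstract_with_vectors(
            [
                (make_vector(), "NOHEADING"),
                (make_vector(f1=2, f7="METHOD"), "METHOD"),
            ]
        )
        # headers in vector and sentence agree; abstract counts as structured?
        abstract.sentences[1].raw_header = "METHODS"
        result = apply_rbm(abstract, ["POPULATION"], vectors)
        sentence, score = result["POPULATION"]
        assert sentence.index == 2
        assert score.w_se == 2

    def test_no_hit_stays_none(self):
        abstract, vectors = self._abstract_with_vectors(
            [(make_vector(), "NOHEADING"), (make_vector(), "NOHEADING")]
        )
        result = apply_rbm(abstract, ["INTERVENTION"], vectors)
        assert result["INTERVENTION"] is None

    def test_non_missed_element_rejected(self):
        abstract, vectors = self._abstract_with_vectors([(make_vector(), "NOHEADING")])
        with pytest.raises(ValueError, match="missed"):
            apply_rbm(abstract, ["OUTCOME"], vectors)

    def test_best_scoring_hit_wins_ties_earliest(self):
        # sentence 1 never fires (f3=0); 2 and 3 share the positional weight
        # (middle/last third of an unstructured 3-sentence abstract -> 0)
        abstract, vectors = self._abstract_with_vectors(
            [
                (make_vector(), "NOHEADING"),
                (make_vector(f3=3), "NOHEADING"),
                (make_vector(f3=4), "NOHEADING"),
            ]
        )
        sentence, _ = apply_rbm(abstract, ["INTERVENTION"], vectors)["INTERVENTION"]
        assert sentence.index == 3  # higher wSe beats earlier index
        vectors[("A", 3)] = make_vector(f3=3)
        sentence, _ = apply_rbm(abstract, ["INTERVENTION"], vectors)["INTERVENTION"]
        assert sentence.index == 2  # exact tie -> earliest


class TestWorkedFixture:
    def test_each_fixture_sentence_fires_its_rule(self):
        corpus, lexicons = generate_worked_fixture()
        prepared = prepare_test_corpus(corpus)
        vectors = extract_corpus_features(prepared, lexicons)
        rules = {"POPULATION": rule_population, "INTERVENTION": rule_intervention}
        for abstract in prepared.abstracts:
            target = abstract.sentences[1]  # candidate sits at index 2
            element = target.gold_labels[0]
            vec = vectors[(abstract.abstract_id, target.index)]
            assert rules[element](vec, target.normalized_header, target.index)

    def test_tizanidine_sentence_has_two_intervention_hits(self):
        corpus, lexicons = generate_worked_fixture()
        prepared = prepare_test_corpus(corpus)
        vectors = extract_corpus_features(prepared, lexicons)
        vec = vectors[("FX-I1", 2)]
        assert vec.f3 >= 2  # "tizanidine hydrochloride" + "medication"

    def test_fixture_is_byte_stable(self):
        from picoextract.corpus_io import corpus_to_json

        one, _ = generate_worked_fixture()
        two, _ = generate_worked_fixture()
        assert corpus_to_json(one) == corpus_to_json(two)

    def test_rbm_recovers_fixture_elements(self):
        corpus, lexicons = generate_worked_fixture()
        prepared = prepare_test_corpus(corpus)
        vectors = extract_corpus_features(prepared, lexicons)
        for abstract in prepared.abstracts:
            element = abstract.sentences[1].gold_labels[0]
            result = apply_rbm(abstract, [element], vectors)
            sentence, _ = result[element]
            assert sentence.index == 2
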