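import numpy as np
import pytest

from picoextract.corpus_io import AbstractRecord, LabeledCorpus, SentenceRecord
from picoextract.crf_stage import (
    CRFConfig,
    load_model,
    predict_with_repetition,
    save_model,
    train,
)
from picoextract.features import extract_corpus_features
from picoextract.pipeline import prepare_test_corpus


def separable_corpus(n_abstracts=12):
    """Each label comes with its own unmistakable token — linearly separable."""
    cue = {
        "POPULATION": "patients with diabetes enrolled",
        "INTERVENTION": "aspirin treatment administered daily",
        "OUTCOME": "mortality decreased significantly overall",
        "BACKGROUND": "previous literature remains unclear",
        "OTHER": "further research is needed",
    }
    labels = list(cue)
    abstracts = []
    for a in range(n_abstracts):
        aid = f"S{a}"
        sentences = []
        for i in range(1, 6):
            label = labels[(a + i) % len(labels)]
            sentences.append(
                SentenceRecord(
                    aid, i, cue[label].capitalize() + ".", gold_labels=(label,)
                )
            )
        abstracts.append(AbstractRecord(aid, "a study title", sentences=sentences))
    return LabeledCorpus(abstracts)


@pytest.fixture(scope="module")
def separable(bundle):
    corpus = prepare_test_corpus(separable_corpus())
    vectors = extract_corpus_features(corpus, bundle)
    model = train(corpus, vectors, CRFConfig(max_iterations=100))
    return corpus, vectors, model


class TestTraining:
    def test_separable_corpus_fits_perfectly(self, separable):
        corpus, vectors, model = separable
        for abstract in corpus.abstracts:
            decoded = predict_with_repetition(model, abstract, vectors, reps=1)
            gold = [set(s.gold_labels) for s in abstract.sentences]
            assert [sorted(c) for c in decoded] == [sorted(g) for g in gold]

    def test_same_seed_same_predictions(self, bundle):
        corpus = prepare_test_corpus(separable_corpus(6))
        vectors = extract_corpus_features(corpus, bundle)
        runs = []
        for _ in range(2):
            model = train(corpus, vectors, CRFConfig(max_iterations=50, random_seed=3))
            runs.append(
                [
                    predict_with_repetition(model, a, vectors, reps=3)
                    for a in corpus.abstracts
                ]
            )
        assert runs[0] == runs[1]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train(LabeledCorpus([]), {}, CRFConfig())

    def test_single_label_corpus_rejected(self, bundle):
        corpus = separable_corpus(2)
        for s in corpus.sentences():
            s.gold_labels = ("OTHER",)
        corpus = prepare_test_corpus(corpus)
        vectors = extract_corpus_features(corpus, bundle)
        with pytest.raises(ValueError, match="degenerate"):
            train(corpus, vectors, CRFConfig())

    def test_no_signal_gives_chance_level(self, bundle):
        """Labels shuffled independently of text: held-out macro-F must sit
        near the label-marginal chance level."""
        rng = np.random.default_rng(0)
        corpus = separable_corpus(30)
        labels = [s.gold_labels for s in corpus.sentences()]
        perm = rng.permutation(len(labels))
        for s, j in zip(corpus.sentences(), perm):
            s.gold_labels = labels[j]
        corpus = prepare_test_corpus(corpus)
        train_c = LabeledCorpus(corpus.abstracts[:20])
        test_c = LabeledCorpus(corpus.abstracts[20:])
        vectors = extract_corpus_features(corpus, bundle)
        model = train(train_c, vectors, CRFConfig(max_iterations=80))
        # chance F per label: 2pq/(p+q) with p true and q predicted marginals
        preds, golds = [], []
        for a in test_c.abstracts:
            decoded = predict_with_repetition(model, a, vectors, reps=1)
            preds += [next(iter(c)) for c in decoded]
            golds += [s.gold_labels[0] for s in a.sentences]
        observed = []
        chance = []
        for lab in set(golds):
            tp = sum(1 for p, g in zip(preds, golds) if p == g == lab)
            fp = sum(1 for p, g in zip(preds, golds) if p == lab != g)
            fn = sum(1 for p, g in zip(preds, golds) if g == lab != p)
            observed.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
            p = golds.count(lab) / len(golds)
            q = preds.count(lab) / len(preds)
            chance.append(2 * p * q / (p + q) if p + q else 0.0)
        assert abs(np.mean(observed) - np.mean(chance)) < 0.15


class TestRepetition:
    def test_reps_one_is_plain_decoding(self, separable):
        corpus, vectors, model = separable
        for abstract in corpus.abstracts[:3]:
            candidates = predict_with_repetition(model, abstract, vectors, reps=1)
            assert all(len(c) == 1 for c in candidates)
            plain = model.crf.viterbi(
                model.crf.encode_tokens(
                    [vectors[(abstract.abstract_id, s.index)].crf_tokens()
                     for s in abstract.sentences]
                )
            )
            assert [next(iter(c)) for c in candidates] == plain

    def test_union_contains_plain_prediction(self, separable):
        corpus, vectors, model = separable
        for abstract in corpus.abstracts:
            one = predict_with_repetition(model, abstract, vectors, reps=1)
            three = predict_with_repetition(model, abstract, vectors, reps=3)
            for a, b in zip(one, three):
                assert a <= b

    def test_candidate_sets_never_empty(self, separable):
        corpus, vectors, model = separable
        for abstract in corpus.abstracts:
            for c in predict_with_repetition(model, abstract, vectors, reps=3):
                assert c

    def test_invalid_reps(self, separable):
        corpus, vectors, model = separable
        with pytest.raises(ValueError):
            predict_with_repetition(model, corpus.abstracts[0], vectors, reps=0)


def test_model_round_trip(tmp_path, separable):
    corpus, vectors, model = separable
    path = save_model(model, tmp_path / "model.npz")
    loaded = load_model(path)
    abstract = corpus.abstracts[0]
    assert predict_with_repetition(loaded, abstract, vectors, reps=3) == (
        predict_with_repetition(model, abstract, vectors, reps=3)
    )
    assert loaded.config == model.config


def test_config_validation():
    with pytest.raises(ValueError):
        CRFConfig(gaussian_prior_variance=0).validate()
    with pytest.raises(ValueError):
        CRFConfig(training_proportion=0).validate()
    with pytest.raises(ValueError):
        CRFConfig(test_repetitions=0).validate()
    CRFConfig().validate()  # defaults are legal
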