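import math
import warnings

import pytest
from hypothesis import given, strategies as st

from picoextract.corpus_io import AbstractRecord, SentenceRecord
from picoextract.preprocess import (
    DEFAULT_HEADER_MAP,
    DEFAULT_HEADER_VARIANTS,
    FIRST_THIRD,
    LAST_THIRD,
    MIDDLE_THIRD,
    HeaderMap,
    pos_tag,
    pseudo_structure,
    rectify_text,
    relative_position,
    segment_sentences,
    standardize_header,
    tokenize,
)


class TestRectifyAndSegment:
    def test_abbreviations_and_decimals_do_not_split(self):
        text = "Group A vs. group B received 2.5 mg daily. Outcomes improved."
        sentences = segment_sentences(rectify_text(text))
        assert len(sentences) == 2
        assert "vs." in sentences[0] and "2.5 mg" in sentences[0]

    def test_empty_input(self):
        assert rectify_text("") == ""
        assert segment_sentences("") == []

    def test_plain_punctuation_split(self):
        assert segment_sentences("A. B? C!") == ["A.", "B?", "C!"]

    def test_length_preserved_within_tolerance(self):
        text = "Patients (e.g. adults vs. children) received 12.5 mg i.e. half."
        out = rectify_text(text)
        assert abs(len(out) - len(text)) <= 0.1 * len(text)

    def test_generated_paragraph_boundary_count(self):
        """Generator knows the true sentence count; segmentation must agree
        despite injected abbreviations and decimals."""
        templates = [
            "Patients received {x}.5 mg vs. placebo in week {i}.",
            "Lesions (e.g. nodules) shrank by {x}.{i} percent.",
            "Dose was adjusted, i.e. halved, on day {i}.",
        ]
        parts = [
            templates[i % 3].format(x=i % 7, i=i + 1) for i in range(50)
        ]
        text = " ".join(parts)
        assert len(segment_sentences(rectify_text(text))) == 50

    def test_segmentation_preserves_content(self):
        text = "First sentence here. Second one, with 2.5 mg. Third!"
        sentences = segment_sentences(rectify_text(text))
        assert " ".join(sentences).split() == text.split()


class TestHeaderStandardization:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("AIM", "OBJECTIVE"),
            ("BACKGROUND AND OBJECTIVES", "OBJECTIVE"),
            ("CONTEXT", "OBJECTIVE"),
            ("DESIGN AND METHODS", "METHOD"),
            ("PATIENT(S)", "METHOD"),
            ("INTERVENTION", "METHOD"),
            ("FINDINGS", "RESULTS"),
            ("MAIN RESULTS", "RESULTS"),
            ("OUTCOME MEASURES", "RESULTS"),
            ("DISCUSSION", "CONCLUSION"),
            ("IMPLICATIONS", "CONCLUSION"),
            ("SUMMARY", "CONCLUSION"),
        ],
    )
    def test_known_variants(self, raw, expected):
        assert standardize_header(raw) == expected

    def test_case_and_whitespace_insensitive(self):
        assert standardize_header("  aim ") == "OBJECTIVE"

    def test_unknown_header_degrades_with_warning(self):
        with pytest.warns(UserWarning, match="unknown section header"):
            assert standardize_header("ACKNOWLEDGEMENTS") == "NOHEADING"

    @given(st.text(min_size=1, max_size=30))
    def test_idempotent_on_arbitrary_headers(self, raw):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            once = standardize_header(raw)
            assert standardize_header(once) == once

    def test_csv_loading(self, tmp_path):
        path = tmp_path / "headers.csv"
        path.write_text("SYNOPSIS,CONCLUSION\nENROLMENT,METHOD\n")
        hmap = HeaderMap.from_csv(path)
        assert standardize_header("synopsis", hmap) == "CONCLUSION"


class TestPseudoStructure:
    def _abstract(self, labels):
        sentences = [
            SentenceRecord("A", i, f"Sentence {i} text.", None, gold_labels=labs)
            for i, labs in enumerate(labels, start=1)
        ]
        return AbstractRecord("A", "Title", sentences=sentences)

    @pytest.mark.parametrize(
        "labels,expected",
        [
            (("BACKGROUND",), "OBJECTIVE"),
            (("POPULATION",), "METHOD"),
            (("INTERVENTION",), "METHOD"),
            (("STUDYDESIGN",), "METHOD"),
            (("OUTCOME",), "RESULTS"),
            (("OTHER",), "CONCLUSION"),
            (("POPULATION", "INTERVENTION"), "METHOD"),
        ],
    )
    def test_label_to_section(self, labels, expected):
        out = pseudo_structure(self._abstract([labels]))
        assert out.sentences[0].normalized_header == expected

    def test_only_headers_change(self):
        abstract = self._abstract([("OUTCOME",), ("OTHER",)])
        out = pseudo_structure(abstract)
        assert [s.text for s in out.sentences] == [s.text for s in abstract.sentences]
        assert [s.gold_labels for s in out.sentences] == [
            s.gold_labels for s in abstract.sentences
        ]

    def test_structured_abstract_is_warned_noop(self):
        abstract = self._abstract([("OUTCOME",)])
        abstract.sentences[0].raw_header = "RESULTS"
        with pytest.warns(UserWarning, match="no-op"):
            out = pseudo_structure(abstract)
        assert out.sentences[0].normalized_header == "NOHEADING"

    def test_missing_gold_labels_is_error(self):
        abstract = self._abstract([()])
        with pytest.raises(ValueError, match="gold labels"):
            pseudo_structure(abstract)


class TestRelativePosition:
    def test_edges(self):
        assert relative_position(1, 9) == FIRST_THIRD
        assert relative_position(9, 9) == LAST_THIRD
        assert relative_position(5, 9) == MIDDLE_THIRD

    def test_short_abstracts_all_first(self):
        assert relative_position(2, 2) == FIRST_THIRD

    @pytest.mark.parametrize("length", range(3, 16))
    def test_thirds_against_arithmetic_oracle(self, length):
        positions = [relative_position(i, length) for i in range(1, length + 1)]
        counts = (
            positions.count(FIRST_THIRD),
            positions.count(MIDDLE_THIRD),
            positions.count(LAST_THIRD),
        )
        expected = (
            math.ceil(length / 3),
            length - math.ceil(length / 3) - length // 3,
            length // 3,
        )
        assert counts == expected
        # thirds appear in order
        assert positions == sorted(
            positions, key=[FIRST_THIRD, MIDDLE_THIRD, LAST_THIRD].index
        )

    def test_length_ten_counts(self):
        positions = [relative_position(i, 10) for i in range(1, 11)]
        assert (
            positions.count(FIRST_THIRD),
            positions.count(MIDDLE_THIRD),
            positions.count(LAST_THIRD),
        ) == (4, 3, 3)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            relative_position(0, 5)
        with pytest.raises(ValueError):
            relative_position(6, 5)


def test_default_map_covers_all_families():
    targets = set(DEFAULT_HEADER_VARIANTS.values())
    assert targets == {"OBJECTIVE", "METHOD", "RESULTS", "CONCLUSION"}
    assert DEFAULT_HEADER_MAP.lookup("METHODS") == "METHOD"


def test_pos_tagger_is_total_and_aligned():
    tokens = tokenize("Patients were randomized to receive 2.5 mg daily.")
    tags = pos_tag(tokens)
    assert len(tags) == len(tokens)
    assert tags[tokens.index("2.5")] == "CD"
    assert tags[tokens.index("were")] == "VBD"
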