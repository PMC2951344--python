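"""Frequency-based centrality: counts, relevancy weighting, the six strategies."""

import json
import math

import pytest

import figrank as fr
from figrank.textproc import IdfModel, TokenizerConfig

TOK = TokenizerConfig(stopwords=False, min_len=1)

# equal-weight IDF over the single-letter fixture vocabulary: every term has
# idf = ln(4/2), so cosines reduce to hand-checkable token-overlap ratios
FLAT_IDF = IdfModel(corpus_size=3, df={t: 1 for t in "abcdxyz"})


def _article(doc):
    return fr.parse_article_json(json.dumps(doc))


@pytest.fixture
def counting_article():
    """fig 1: 3 mentions (2 in R&D); fig 2: 1 mention (0 in R&D)."""
    return _article({
        "id": "c", "title": "t", "abstract": "a",
        "sections": [
            {"heading": "Introduction",
             "paragraphs": ["Fig. 1 appears early. Fig. 2 also."]},
            {"heading": "Results",
             "paragraphs": ["Fig. 1 shows data. Later Fig. 1 again."]},
            {"heading": "References", "paragraphs": ["Fig. 2 in cited work."]},
        ],
        "figures": [{"label": 1, "legend": ""}, {"label": 2, "legend": ""}],
    })


@pytest.fixture
def weighted_article():
    """R&D paragraph relevancies to the abstract are exactly 0.5 and 0.25.

    abstract = "a b c d"; paragraph "a" has cosine 1/(1*2) = 0.5, paragraph
    "a x y z" has 1/(2*2) = 0.25 under the flat IDF.  Figure 1 is mentioned
    twice in the first and once in the second (explicit mention override so
    the paragraph text stays clean).
    """
    return _article({
        "id": "w", "title": "t", "abstract": "a b c d",
        "sections": [{"heading": "Results", "paragraphs": ["a", "a x y z"]}],
        "figures": [{"label": 1, "legend": ""}],
        "mentions": [
            {"label": 1, "section_index": 0, "paragraph_index": 0},
            {"label": 1, "section_index": 0, "paragraph_index": 0},
            {"label": 1, "section_index": 0, "paragraph_index": 1},
        ],
    })


class TestCountMentions:
    def test_fulltext_and_rd_scopes(self, counting_article):
        assert fr.count_mentions(counting_article, "fulltext") == {1: 3, 2: 1}
        assert fr.count_mentions(counting_article, "rd") == {1: 2, 2: 0}

    def test_reference_mentions_never_counted(self, counting_article):
        # fig 2's references-section occurrence is invisible everywhere
        assert fr.count_mentions(counting_article, "fulltext")[2] == 1

    def test_no_rd_sections_warns(self, caplog):
        import logging
        art = _article({"id": "x", "title": "t", "abstract": "a",
                        "sections": [{"heading": "Introduction",
                                      "paragraphs": ["Fig. 1 here."]}],
                        "figures": [{"label": 1, "legend": ""}]})
        with caplog.at_level(logging.WARNING):
            counts = fr.count_mentions(art, "rd")
        assert counts == {1: 0}
        assert "no Results/Discussion" in caplog.text

    def test_scope_nesting(self, small_collection):
        arts, _ = small_collection
        for art in arts[:5]:
            full = fr.count_mentions(art, "fulltext")
            rd = fr.count_mentions(art, "rd")
            assert all(full[l] >= rd[l] for l in full)


class TestParagraphRelevancy:
    def test_identical_paragraph_scores_one(self):
        art = _article({"id": "x", "title": "t", "abstract": "a b",
                        "sections": [{"heading": "Results", "paragraphs": ["a b"]}],
                        "figures": []})
        (rel,) = fr.paragraph_relevancy(art, "abstract", FLAT_IDF, TOK)
        assert rel.relevancy == pytest.approx(1.0)

    def test_disjoint_paragraph_scores_zero(self):
        art = _article({"id": "x", "title": "a b", "abstract": "",
                        "sections": [{"heading": "Results", "paragraphs": ["x y"]}],
                        "figures": []})
        (rel,) = fr.paragraph_relevancy(art, "title", FLAT_IDF, TOK)
        assert rel.relevancy == 0.0

    def test_more_shared_terms_more_relevant(self, weighted_article):
        rels = fr.paragraph_relevancy(weighted_article, "abstract", FLAT_IDF, TOK)
        assert rels[0].relevancy == pytest.approx(0.5)
        assert rels[1].relevancy == pytest.approx(0.25)
        assert rels[0].relevancy > rels[1].relevancy

    def test_only_rd_paragraphs_scored(self, counting_article):
        rels = fr.paragraph_relevancy(counting_article, "abstract", FLAT_IDF, TOK)
        assert {(r.section_index) for r in rels} == {1}


class TestScoreFrequency:
    def test_interpolated_sums_over_paragraphs(self, weighted_article):
        scores = fr.score_frequency(weighted_article,
                                    fr.FrequencyConfig("wfreq-rd-abs"),
                                    FLAT_IDF, TOK)
        assert scores[1] == pytest.approx(2 * 0.5 + 1 * 0.25)

    def test_best_paragraph_variant_takes_maximum(self, weighted_article):
        scores = fr.score_frequency(weighted_article,
                                    fr.FrequencyConfig("wfreq-rd-para-abs"),
                                    FLAT_IDF, TOK)
        assert scores[1] == pytest.approx(2 * 0.5)

    def test_raw_count_strategies(self, counting_article):
        full = fr.score_frequency(counting_article, fr.FrequencyConfig("freq-fulltext"))
        rd = fr.score_frequency(counting_article, fr.FrequencyConfig("freq-rd"))
        assert full == {1: 3.0, 2: 1.0}
        assert rd == {1: 2.0, 2: 0.0}

    def test_unmentioned_figure_scores_zero(self, weighted_article):
        doc = fr.article_to_dict(weighted_article, include_mentions=True)
        doc["figures"].append({"label": 2, "legend": ""})
        art = _article(doc)
        scores = fr.score_frequency(art, fr.FrequencyConfig("wfreq-rd-abs"),
                                    FLAT_IDF, TOK)
        assert scores[2] == 0.0

    def test_weighted_needs_idf(self, weighted_article):
        with pytest.raises(ValueError, match="IDF"):
            fr.score_frequency(weighted_article, fr.FrequencyConfig("wfreq-rd-abs"))

    def test_zero_relevancy_degenerates_to_document_order(self):
        art = _article({"id": "x", "title": "t", "abstract": "q r s",
                        "sections": [{"heading": "Results",
                                      "paragraphs": ["Fig. 1 and Fig. 2 shown."]}],
                        "figures": [{"label": 1, "legend": ""},
                                    {"label": 2, "legend": ""}]})
        r = fr.rank_frequency(art, fr.FrequencyConfig("wfreq-rd-abs"), FLAT_IDF, TOK)
        assert r.order == (1, 2)
        assert all(v == 0.0 for v in r.scores.values())

    def test_unit_relevancy_limit_equals_freq_rd(self):
        """When every R&D paragraph matches the abstract exactly (relevancy 1),
        interpolated weighting reduces to the plain R&D count ranking."""
        doc = {
            "id": "lim", "title": "t", "abstract": "a b",
            "sections": [{"heading": "Results", "paragraphs": ["a b", "a b"]}],
            "figures": [{"label": 1, "legend": ""}, {"label": 2, "legend": ""},
                        {"label": 3, "legend": ""}],
            "mentions": [
                {"label": 2, "section_index": 0, "paragraph_index": 0},
                {"label": 2, "section_index": 0, "paragraph_index": 1},
                {"label": 3, "section_index": 0, "paragraph_index": 1},
                {"label": 1, "section_index": 0, "paragraph_index": 0},
                {"label": 2, "section_index": 0, "paragraph_index": 0},
            ],
        }
        art = _article(doc)
        weighted = fr.rank_frequency(art, fr.FrequencyConfig("wfreq-rd-abs"),
                                     FLAT_IDF, TOK)
        plain = fr.rank_frequency(art, fr.FrequencyConfig("freq-rd"))
        assert weighted.order == plain.order == (2, 1, 3)

    def test_adding_rd_mention_never_lowers_interpolated_score(self, weighted_article):
        before = fr.score_frequency(weighted_article, fr.FrequencyConfig("wfreq-rd-abs"),
                                    FLAT_IDF, TOK)[1]
        doc = fr.article_to_dict(weighted_article, include_mentions=True)
        doc["mentions"].append({"label": 1, "section_index": 0, "paragraph_index": 1})
        after = fr.score_frequency(_article(doc), fr.FrequencyConfig("wfreq-rd-abs"),
                                   FLAT_IDF, TOK)[1]
        assert after >= before
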