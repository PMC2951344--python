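import json

import pytest

import figrank as fr


def make_article_doc(**overrides):
    """A small, fully hand-checkable structured-article document."""
    doc = {
        "id": "toy-1",
        "title": "Kinase binding drives receptor clustering",
        "abstract": "Kinase binding controls receptor clustering on the membrane.",
        "sections": [
            {"heading": "Introduction",
             "paragraphs": ["Receptor biology background. Prior work exists."]},
            {"heading": "Results",
             "paragraphs": [
                 "As shown in Fig. 1, kinase binds the receptor. "
                 "Clustering follows binding. Fig. 1 also shows kinetics.",
                 "Figures 1 and 2 show complementary assays. "
                 "The control is in Fig. 2.",
             ]},
            {"heading": "Discussion",
             "paragraphs": ["We discuss clustering implications of Fig. 2."]},
            {"heading": "References",
             "paragraphs": ["Smith et al. Fig. 1 of some other paper."]},
        ],
        "figures": [
            {"label": 1, "legend": "Kinase binding assay with receptor."},
            {"label": 2, "legend": "Control experiment for clustering."},
        ],
        "gold": [2, 1],
    }
    doc.update(overrides)
    return doc


@pytest.fixture
def toy_article():
    return fr.parse_article_json(json.dumps(make_article_doc()))


@pytest.fixture(scope="session")
def small_collection():
    """20 synthetic articles with strong planted signal, plus their IDF."""
    cfg = fr.SynthConfig(n_articles=20, seed=11)
    arts = fr.generate_articles(cfg)
    return arts, fr.collection_idf(arts)
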