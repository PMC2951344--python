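"""Convenience layer: method registry, collection IDF, end-to-end evaluation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from .article import Article, article_text
from .combine import CombineConfig, combine_linear
from .frequency import FREQUENCY_METHODS, FrequencyConfig, rank_frequency
from .metrics import MetricReport, evaluate_collection
from .ranking import RankingResult
from .similarity import SIMILARITY_METHODS, SimilarityConfig, rank_similarity
from .textproc import DEFAULT_TOKENIZER, IdfModel, TokenizerConfig, build_idf

__all__ = ["ALL_METHODS", "collection_idf", "rank_article", "evaluate_methods",
           "config_hash"]

ALL_METHODS = SIMILARITY_METHODS + FREQUENCY_METHODS


def collection_idf(articles: Iterable[Article],
                   tokenizer: TokenizerConfig = DEFAULT_TOKENIZER) -> IdfModel:
    """Default desk-scale IDF: one document per article full text."""
    return build_idf((article_text(a, "fulltext") for a in articles), tokenizer)


def rank_article(article: Article, method_id: str, idf: IdfModel,
                 lam: float = 0.8, normalization: str = "minmax",
                 tokenizer: TokenizerConfig = DEFAULT_TOKENIZER) -> RankingResult:
    """Rank one article by any registered method id (or ``combined``)."""
    if method_id in SIMILARITY_METHODS:
        return rank_similarity(article, SimilarityConfig.from_method_id(method_id),
                               idf, tokenizer)
    if method_id in FREQUENCY_METHODS:
        return rank_frequency(article, FrequencyConfig(method_id), idf, tokenizer)
    if method_id == "combined":
        return combine_linear(article, CombineConfig(lam=lam, normalization=normalization),
                              idf, tokenizer)
    raise ValueError(f"unknown method id {method_id!r}")


def evaluate_methods(articles: Sequence[Article], methods: Sequence[str],
                     idf: IdfModel | None = None, lam: float = 0.8,
                     normalization: str = "minmax",
                     tokenizer: TokenizerConfig = DEFAULT_TOKENIZER) -> MetricReport:
    """Rank every gold-annotated article with every method and average.

    Builds the collection IDF when none is given.
    """
    gold_articles = [a for a in articles if a.gold is not None]
    if not gold_articles:
        raise ValueError("no gold-annotated articles to evaluate")
    if idf is None:
        idf = collection_idf(articles, tokenizer)
    pairs = {}
    for method in methods:
        pairs[method] = [
            (a.id, a.gold, rank_article(a, method, idf, lam, normalization, tokenizer))
            for a in gold_articles
        ]
    chash = config_hash({"methods": list(methods), "lambda": lam,
                         "normalization": normalization,
                         "tokenizer": tokenizer.describe(),
                         "idf_corpus_size": idf.corpus_size,
                         "idf_smoothing": idf.smoothing})
    return evaluate_collection(pairs, config_hash=chash)


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping (reported in outputs)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
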