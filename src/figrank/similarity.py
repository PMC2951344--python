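"""Similarity-based figure centrality.

A figure is scored by the TF*IDF cosine similarity between a figure
representation (its legend alone, or legend plus mentioning sentences) and
an article summary representation (title, abstract, or full text).  The
2x3 grid of representations yields six ranking systems:

    figlegend-title   figlegend-abstract   figlegend-fulltext
    figtext-title     figtext-abstract     figtext-fulltext
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .article import Article, article_text, figure_text
from .ranking import RankingResult, rank_from_scores
from .textproc import DEFAULT_TOKENIZER, IdfModel, TokenizerConfig, cosine, vectorize

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityConfig",
    "SIMILARITY_METHODS",
    "score_similarity",
    "rank_similarity",
    "rank_from_scores",
    "RankingResult",
]

FIGURE_REPS = ("legend", "figtext")
ARTICLE_REPS = ("title", "abstract", "fulltext")


@dataclass(frozen=True)
class SimilarityConfig:
    figure_rep: str = "figtext"
    article_rep: str = "abstract"

    def __post_init__(self) -> None:
        if self.figure_rep not in FIGURE_REPS:
            raise ValueError(f"figure_rep must be one of {FIGURE_REPS}")
        if self.article_rep not in ARTICLE_REPS:
            raise ValueError(f"article_rep must be one of {ARTICLE_REPS}")

    @property
    def method_id(self) -> str:
        rep = "figlegend" if self.figure_rep == "legend" else "figtext"
        return f"{rep}-{self.article_rep}"

    @classmethod
    def from_method_id(cls, method_id: str) -> "SimilarityConfig":
        try:
            fig, art = method_id.split("-")
            return cls(figure_rep={"figlegend": "legend", "figtext": "figtext"}[fig],
                       article_rep=art)
        except (ValueError, KeyError):
            raise ValueError(f"unknown similarity method {method_id!r}") from None


SIMILARITY_METHODS = tuple(
    SimilarityConfig(f, a).method_id for f in FIGURE_REPS for a in ARTICLE_REPS
)


def score_similarity(article: Article, cfg: SimilarityConfig, idf: IdfModel,
                     tokenizer: TokenizerConfig = DEFAULT_TOKENIZER) -> dict[int, float]:
    """Cosine centrality score of every figure under one representation pair."""
    anchor = vectorize(article_text(article, cfg.article_rep), idf, tokenizer)
    if anchor.norm == 0.0:
        logger.warning("article %s: empty %s representation, all similarity "
                       "scores 0", article.id, cfg.article_rep)
    scores = {}
    for lbl in article.labels:
        vec = vectorize(figure_text(article, lbl, cfg.figure_rep), idf, tokenizer)
        scores[lbl] = cosine(vec, anchor)
    return scores


def rank_similarity(article: Article, cfg: SimilarityConfig, idf: IdfModel,
                    tokenizer: TokenizerConfig = DEFAULT_TOKENIZER) -> RankingResult:
    """Full similarity ranking: scores plus the induced strict order."""
    scores = score_similarity(article, cfg, idf, tokenizer)
    return rank_from_scores(scores, cfg.method_id, doc_order=tuple(article.labels))
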