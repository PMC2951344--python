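"""Frequency-based figure centrality.

Figures that are referred to more often are taken to be more central.  Six
strategies, from raw counts to topical-relevancy weighting:

``freq-fulltext``
    mention count over the whole body text.
``freq-rd``
    mention count restricted to Results/Discussion (R&D) sections.
``wfreq-rd-para-title`` / ``wfreq-rd-para-abs``
    for each figure, take the most topic-relevant R&D paragraph that
    mentions it; score = (mentions there) x (paragraph relevancy to the
    title / abstract).
``wfreq-rd-title`` / ``wfreq-rd-abs``
    interpolate over all R&D paragraphs: score = sum of (mentions in
    paragraph) x (paragraph relevancy to the title / abstract).

Paragraph relevancy is the TF*IDF cosine between the paragraph and the
anchor text (title or abstract), using the same tokenizer and IDF model as
the similarity rankers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .article import Article
from .ranking import RankingResult, rank_from_scores
from .textproc import DEFAULT_TOKENIZER, IdfModel, TokenizerConfig, cosine, vectorize

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyConfig",
    "FREQUENCY_METHODS",
    "ParagraphRelevancy",
    "count_mentions",
    "paragraph_relevancy",
    "score_frequency",
    "rank_frequency",
]

FREQUENCY_METHODS = (
    "freq-fulltext",
    "freq-rd",
    "wfreq-rd-para-title",
    "wfreq-rd-para-abs",
    "wfreq-rd-title",
    "wfreq-rd-abs",
)


@dataclass(frozen=True)
class FrequencyConfig:
    strategy: str = "wfreq-rd-abs"

    def __post_init__(self) -> None:
        if self.strategy not in FREQUENCY_METHODS:
            raise ValueError(f"strategy must be one of {FREQUENCY_METHODS}")

    @property
    def method_id(self) -> str:
        return self.strategy

    @property
    def anchor(self) -> str | None:
        if self.strategy.endswith("-title"):
            return "title"
        if self.strategy.endswith("-abs"):
            return "abstract"
        return None


@dataclass(frozen=True)
class ParagraphRelevancy:
    section_index: int
    paragraph_index: int
    relevancy: float


def count_mentions(article: Article, scope: str = "fulltext") -> dict[int, int]:
    """Mention occurrences per figure, over the full body or R&D sections only."""
    if scope not in ("fulltext", "rd"):
        raise ValueError(f"scope must be 'fulltext' or 'rd', got {scope!r}")
    if scope == "rd" and not any(s.is_rd for s in article.sections):
        logger.warning("article %s: no Results/Discussion sections; R&D "
                       "mention counts are all zero", article.id)
    counts = {}
    for fig in article.figures:
        n = 0
        for m in fig.mentions:
            if scope == "rd" and not article.sections[m.section_index].is_rd:
                continue
            n += 1
        counts[fig.label] = n
    return counts


def paragraph_relevancy(article: Article, anchor: str, idf: IdfModel,
                        tokenizer: TokenizerConfig = DEFAULT_TOKENIZER
                        ) -> list[ParagraphRelevancy]:
    """Topical relevancy of every R&D paragraph to the title or abstract."""
    if anchor not in ("title", "abstract"):
        raise ValueError(f"anchor must be 'title' or 'abstract', got {anchor!r}")
    anchor_text = article.title if anchor == "title" else article.abstract
    anchor_vec = vectorize(anchor_text, idf, tokenizer)
    if anchor_vec.norm == 0.0:
        logger.warning("article %s: empty %s anchor, all relevancies 0",
                       article.id, anchor)
    out = []
    for si, sec in enumerate(article.sections):
        if not sec.is_rd:
            continue
        for pi, para in enumerate(sec.paragraphs):
            rel = cosine(vectorize(para, idf, tokenizer), anchor_vec)
            out.append(ParagraphRelevancy(si, pi, rel))
    return out


def _rd_paragraph_counts(article: Article) -> dict[int, dict[tuple[int, int], int]]:
    """Per-figure mention counts keyed by R&D (section, paragraph) locator."""
    counts: dict[int, dict[tuple[int, int], int]] = {}
    for fig in article.figures:
        per_para: dict[tuple[int, int], int] = {}
        for m in fig.mentions:
            if not article.sections[m.section_index].is_rd:
                continue
            key = (m.section_index, m.paragraph_index)
            per_para[key] = per_para.get(key, 0) + 1
        counts[fig.label] = per_para
    return counts


def score_frequency(article: Article, cfg: FrequencyConfig, idf: IdfModel | None = None,
                    tokenizer: TokenizerConfig = DEFAULT_TOKENIZER) -> dict[int, float]:
    """Frequency centrality score of every figure under one strategy.

    ``idf`` is only needed for the relevancy-weighted strategies.
    """
    if cfg.strategy == "freq-fulltext":
        return {l: float(n) for l, n in count_mentions(article, "fulltext").items()}
    if cfg.strategy == "freq-rd":
        return {l: float(n) for l, n in count_mentions(article, "rd").items()}

    if idf is None:
        raise ValueError(f"strategy {cfg.strategy!r} requires an IDF model")
    relevancies = paragraph_relevancy(article, cfg.anchor, idf, tokenizer)
    rel_by_para = {(r.section_index, r.paragraph_index): r.relevancy for r in relevancies}
    para_counts = _rd_paragraph_counts(article)

    scores: dict[int, float] = {}
    for lbl in article.labels:
        per_para = para_counts[lbl]
        if not per_para:
            scores[lbl] = 0.0
        elif cfg.strategy.startswith("wfreq-rd-para-"):
            # best mentioning paragraph: maximal relevancy, earliest on ties
            best = min(per_para, key=lambda k: (-rel_by_para.get(k, 0.0), k))
            scores[lbl] = per_para[best] * rel_by_para.get(best, 0.0)
        else:
            scores[lbl] = sum(n * rel_by_para.get(k, 0.0) for k, n in per_para.items())
    return scores


def rank_frequency(article: Article, cfg: FrequencyConfig, idf: IdfModel | None = None,
                   tokenizer: TokenizerConfig = DEFAULT_TOKENIZER) -> RankingResult:
    """Full frequency ranking: scores plus the induced strict order."""
    scores = score_frequency(article, cfg, idf, tokenizer)
    return rank_from_scores(scores, cfg.method_id, doc_order=tuple(article.labels))
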