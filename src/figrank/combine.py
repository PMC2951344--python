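"""Linear combination of a similarity and a frequency ranker.

The combined score of figure f is

    combined(f) = lambda * sim(f) + (1 - lambda) * freq(f)

with lambda in [0, 1]: 1 reproduces the similarity system, 0 the frequency
system.  Because cosine scores live in [0, 1] while weighted mention
frequencies are unbounded, both score sets are normalized per article
before mixing (min-max by default; rank-based offered as a scale-free
alternative; identity for callers that pre-normalize).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .article import Article
from .frequency import FREQUENCY_METHODS, FrequencyConfig, score_frequency
from .metrics import ALL_METRICS, evaluate_collection
from .ranking import RankingResult, rank_from_scores
from .similarity import SIMILARITY_METHODS, SimilarityConfig, score_similarity
from .textproc import DEFAULT_TOKENIZER, IdfModel, TokenizerConfig

__all__ = ["CombineConfig", "normalize_scores", "combine_linear", "sweep_lambda"]

NORMALIZATIONS = ("minmax", "rank", "none")


@dataclass(frozen=True)
class CombineConfig:
    lam: float = 0.8
    sim_method: str = "figtext-abstract"
    freq_method: str = "wfreq-rd-abs"
    normalization: str = "minmax"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        if self.sim_method not in SIMILARITY_METHODS:
            raise ValueError(f"unknown similarity method {self.sim_method!r}")
        if self.freq_method not in FREQUENCY_METHODS:
            raise ValueError(f"unknown frequency method {self.freq_method!r}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {NORMALIZATIONS}")

    @property
    def method_id(self) -> str:
        return f"combined(lambda={self.lam:g},{self.sim_method}+{self.freq_method})"


def normalize_scores(scores: Mapping[int, float], normalization: str = "minmax"
                     ) -> dict[int, float]:
    """Normalize one article's scores onto a common scale.

    minmax: affine map to [0, 1]; constant score sets map to 0.5.
    rank:   1 - (rank-1)/(n-1) from the induced strict order (1.0 for n=1).
    none:   identity.
    """
    if not scores:
        raise ValueError("cannot normalize an empty score set")
    if normalization == "none":
        return dict(scores)
    if normalization == "minmax":
        lo, hi = min(scores.values()), max(scores.values())
        if hi == lo:
            return {l: 0.5 for l in scores}
        return {l: (s - lo) / (hi - lo) for l, s in scores.items()}
    if normalization == "rank":
        order = rank_from_scores(dict(scores)).order
        n = len(order)
        if n == 1:
            return {order[0]: 1.0}
        return {l: 1.0 - i / (n - 1) for i, l in enumerate(order)}
    raise ValueError(f"normalization must be one of {NORMALIZATIONS}")


def combine_linear(article: Article, cfg: CombineConfig, idf: IdfModel,
                   tokenizer: TokenizerConfig = DEFAULT_TOKENIZER) -> RankingResult:
    """Rank one article's figures by the lambda-mix of two member systems."""
    sim = score_similarity(article, SimilarityConfig.from_method_id(cfg.sim_method),
                           idf, tokenizer)
    freq = score_frequency(article, FrequencyConfig(cfg.freq_method), idf, tokenizer)
    sim_n = normalize_scores(sim, cfg.normalization)
    freq_n = normalize_scores(freq, cfg.normalization)
    combined = {l: cfg.lam * sim_n[l] + (1.0 - cfg.lam) * freq_n[l] for l in sim_n}
    return rank_from_scores(combined, cfg.method_id, doc_order=tuple(article.labels))


def sweep_lambda(collection: Iterable[Article], idf: IdfModel,
                 grid: Sequence[float] | None = None,
                 cfg: CombineConfig = CombineConfig(),
                 tokenizer: TokenizerConfig = DEFAULT_TOKENIZER) -> pd.DataFrame:
    """Collection-mean metrics of the combined ranker at each lambda.

    Articles without a gold ranking are excluded (logged).  Returns one row
    per grid value with the five metric means; default grid is 0.0..1.0 in
    steps of 0.1.
    """
    if grid is None:
        grid = [round(0.1 * i, 1) for i in range(11)]
    articles = []
    for art in collection:
        if art.gold is None:
            import logging
            logging.getLogger(__name__).warning(
                "article %s has no gold ranking; excluded from sweep", art.id)
            continue
        articles.append(art)
    if not articles:
        raise ValueError("no gold-annotated articles in the collection")

    rows = []
    for lam in grid:
        lam_cfg = CombineConfig(lam=lam, sim_method=cfg.sim_method,
                                freq_method=cfg.freq_method,
                                normalization=cfg.normalization)
        triples = [(a.id, a.gold, combine_linear(a, lam_cfg, idf, tokenizer))
                   for a in articles]
        report = evaluate_collection({"combined": triples})
        rows.append({"lambda": lam, **{m: report.rows["combined"][m] for m in ALL_METRICS}})
    return pd.DataFrame(rows)
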