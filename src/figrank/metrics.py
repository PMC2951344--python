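"""Rank-evaluation metrics for figure ranking.

All metrics compare a system's strict figure order with the author-annotated
reference (gold) order of the same article.

MER
    fraction of figure pairs whose relative order the system gets wrong.
MWER
    wrong pairs weighted by their distance in the reference order:
    sum of d(i,j) over wrong pairs / sum of d(i,j) over all pairs,
    d(i,j) = |r_i - r_j| in reference ranks.
MWER-RK
    MWER with a logistic pair weight L(m) = 4 / (1 + e^m), m = min(r_i, r_j),
    so wrong pairs involving more important (higher-ranked) figures are
    penalized more.  For reference (1,2,3,4) this gives 0.108 for system
    output (2,1,3,4) but only 0.019 for (1,2,4,3), although their MER (0.167)
    and MWER (0.1) coincide.
ER-HR
    fraction of articles where the system's top figure is not the reference
    top figure.
WER-HR
    how far down the system placed the reference top figure, per article
    (SysRank - 1) / (numFig - 1), averaged; 0 for single-figure articles.

Collection means skip articles with fewer than two figures for the pairwise
metrics (MER/MWER/MWER-RK); such articles always score 0 on ER-HR/WER-HR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence, Union

import numpy as np
from scipy import stats

from .article import GoldRanking
from .ranking import RankingResult

logger = logging.getLogger(__name__)

__all__ = [
    "mer",
    "mwer",
    "mwer_rk",
    "er_hr",
    "wer_hr",
    "logistic_pair_weight",
    "random_top_baseline",
    "ArticleMetrics",
    "article_metrics",
    "MetricReport",
    "evaluate_collection",
    "paired_t_test",
    "PAIRWISE_METRICS",
    "ALL_METRICS",
]

PAIRWISE_METRICS = ("mer", "mwer", "mwer_rk")
ALL_METRICS = ("mer", "mwer", "mwer_rk", "er_hr", "wer_hr")

Order = Sequence[int]


def _as_order(ranking: Union[Order, GoldRanking, RankingResult]) -> tuple[int, ...]:
    if isinstance(ranking, GoldRanking):
        return ranking.order
    if isinstance(ranking, RankingResult):
        return ranking.order
    return tuple(ranking)


def _ranks(order: tuple[int, ...]) -> dict[int, int]:
    return {lbl: i + 1 for i, lbl in enumerate(order)}


def _check_pairwise(ref: tuple[int, ...], sys: tuple[int, ...]) -> None:
    if sorted(ref) != sorted(sys):
        raise ValueError(f"system order {sys} is not a permutation of reference {ref}")
    if len(ref) < 2:
        raise ValueError("pairwise metrics are undefined for fewer than 2 figures")


def logistic_pair_weight(min_rank: int) -> float:
    """Logistic penalty L(m) = 4/(1+e^m) on the pair's better reference rank."""
    return 4.0 / (1.0 + math.exp(min_rank))


def _wrong_pairs(ref: tuple[int, ...], sys: tuple[int, ...]):
    """Yield (d, min_rank, wrong) for every unordered figure pair."""
    r = _ranks(ref)
    s = _ranks(sys)
    for i, j in combinations(ref, 2):
        d = abs(r[i] - r[j])
        wrong = (r[i] - r[j]) * (s[i] - s[j]) < 0
        yield d, min(r[i], r[j]), wrong


def mer(ref, sys) -> float:
    """Mean error rate: wrongly ordered pairs / all pairs."""
    ref, sys = _as_order(ref), _as_order(sys)
    _check_pairwise(ref, sys)
    pairs = list(_wrong_pairs(ref, sys))
    return sum(w for _, _, w in pairs) / len(pairs)


def mwer(ref, sys) -> float:
    """Mean weighted error rate: reference-distance-weighted wrong pairs."""
    ref, sys = _as_order(ref), _as_order(sys)
    _check_pairwise(ref, sys)
    num = den = 0.0
    for d, _, wrong in _wrong_pairs(ref, sys):
        den += d
        if wrong:
            num += d
    return num / den


def mwer_rk(ref, sys) -> float:
    """MWER with the logistic reference-rank weight on wrong pairs."""
    ref, sys = _as_order(ref), _as_order(sys)
    _check_pairwise(ref, sys)
    num = den = 0.0
    for d, m, wrong in _wrong_pairs(ref, sys):
        den += d
        if wrong:
            num += d * logistic_pair_weight(m)
    return num / den


def _top_error(ref: tuple[int, ...], sys: tuple[int, ...]) -> float:
    """0/1 error of identifying the reference top figure (0 for 1 figure)."""
    if len(ref) < 2:
        return 0.0
    return 0.0 if sys[0] == ref[0] else 1.0


def _top_weighted_error(ref: tuple[int, ...], sys: tuple[int, ...]) -> float:
    """(SysRank(refTop) - 1) / (numFig - 1); 0 for single-figure articles."""
    n = len(ref)
    if n < 2:
        return 0.0
    sys_rank = sys.index(ref[0]) + 1
    return (sys_rank - 1) / (n - 1)


def er_hr(pairs: Iterable[tuple]) -> float:
    """Highest-rank error rate over a collection of (ref, sys) orders."""
    vals = [_top_error(_as_order(r), _as_order(s)) for r, s in pairs]
    if not vals:
        raise ValueError("er_hr needs at least one article")
    return float(np.mean(vals))


def wer_hr(pairs: Iterable[tuple]) -> float:
    """Weighted highest-rank error rate over a collection of (ref, sys) orders."""
    vals = [_top_weighted_error(_as_order(r), _as_order(s)) for r, s in pairs]
    if not vals:
        raise ValueError("wer_hr needs at least one article")
    return float(np.mean(vals))


def random_top_baseline(mean_figures: float = 5.9) -> float:
    """Expected ER-HR of picking the top figure uniformly at random from an
    article with ``mean_figures`` figures: 1 - 1/mean_figures."""
    if mean_figures < 1:
        raise ValueError("mean_figures must be >= 1")
    return 1.0 - 1.0 / mean_figures


# --------------------------------------------------------------------------
# per-article and collection reports
# --------------------------------------------------------------------------

@dataclass
class ArticleMetrics:
    article_id: str
    n_figures: int
    mer: float | None
    mwer: float | None
    mwer_rk: float | None
    er_hr: float
    wer_hr: float


def article_metrics(article_id: str, ref, sys) -> ArticleMetrics:
    """All five metric values for one article; pairwise metrics are None for
    articles with fewer than 2 figures."""
    ref, sys = _as_order(ref), _as_order(sys)
    n = len(ref)
    if n >= 2:
        vals = (mer(ref, sys), mwer(ref, sys), mwer_rk(ref, sys))
    else:
        vals = (None, None, None)
    return ArticleMetrics(article_id, n, *vals,
                          er_hr=_top_error(ref, sys),
                          wer_hr=_top_weighted_error(ref, sys))


@dataclass
class MetricReport:
    """Collection means per method, with per-article detail and exclusions."""

    rows: dict[str, dict[str, float]] = field(default_factory=dict)
    per_article: dict[str, list[ArticleMetrics]] = field(default_factory=dict)
    n_articles: int = 0
    n_excluded_pairwise: int = 0
    config_hash: str = ""

    def to_frame(self):
        """Report as a pandas DataFrame, one row per method."""
        import pandas as pd

        recs = []
        for method, means in self.rows.items():
            recs.append({"method_id": method, **means,
                         "n_articles": self.n_articles,
                         "n_excluded": self.n_excluded_pairwise,
                         "config_hash": self.config_hash})
        return pd.DataFrame(recs)


def evaluate_collection(pairs_by_method: dict[str, list[tuple[str, object, object]]],
                        config_hash: str = "") -> MetricReport:
    """Collection-mean metrics for several methods.

    ``pairs_by_method`` maps a method id to a list of
    ``(article_id, reference order, system order)`` triples.
    """
    report = MetricReport(config_hash=config_hash)
    for method, triples in pairs_by_method.items():
        if not triples:
            raise ValueError(f"method {method!r}: empty collection")
        details = [article_metrics(aid, ref, sys) for aid, ref, sys in triples]
        report.per_article[method] = details
        pairwise_vals = {
            m: [getattr(d, m) for d in details if getattr(d, m) is not None]
            for m in PAIRWISE_METRICS
        }
        excluded = sum(1 for d in details if d.mer is None)
        row = {}
        for m in PAIRWISE_METRICS:
            row[m] = float(np.mean(pairwise_vals[m])) if pairwise_vals[m] else float("nan")
        row["er_hr"] = float(np.mean([d.er_hr for d in details]))
        row["wer_hr"] = float(np.mean([d.wer_hr for d in details]))
        report.rows[method] = row
        report.n_articles = len(details)
        report.n_excluded_pairwise = excluded
        if excluded:
            logger.info("method %s: %d article(s) excluded from pairwise means",
                        method, excluded)
    return report


def paired_t_test(values_a: Sequence[float], values_b: Sequence[float]
                  ) -> tuple[float, float]:
    """Paired two-sided t test on per-article metric values.

    Degenerate case: when the paired differences have zero variance the test
    statistic is undefined; (0, 1) is returned for identical means, and
    (+/-inf, 0) with a warning for a constant nonzero difference.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-d samples with n >= 2")
    diff = a - b
    if np.ptp(diff) == 0.0:
        if diff[0] == 0.0:
            return 0.0, 1.0
        logger.warning("paired_t_test: constant nonzero difference; p -> 0 limit")
        return math.copysign(math.inf, diff[0]), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
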