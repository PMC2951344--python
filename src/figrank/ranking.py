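"""Ranking results and the global score→order rule.

Every ranking strategy produces a score per figure; the induced order is a
strict permutation of the article's figure labels (rank 1 = most important).
Exact score ties are broken by earlier document appearance, i.e. the lower
figure label wins — deterministic and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["RankingResult", "rank_from_scores"]


@dataclass
class RankingResult:
    method_id: str
    scores: dict[int, float]
    #: figure labels, rank 1 first
    order: tuple[int, ...] = ()
    tie_breaks_applied: int = 0

    def rank_of(self, label: int) -> int:
        """1-based system rank of ``label``."""
        return self.order.index(label) + 1


def rank_from_scores(scores: Mapping[int, float], method_id: str = "",
                     doc_order: tuple[int, ...] | None = None) -> RankingResult:
    """Sort scores descending into a strict ranking.

    ``doc_order`` gives the document appearance order of the labels used for
    tie-breaking; by default labels sort numerically, which coincides with
    appearance order for conventionally numbered figures.
    """
    labels = list(doc_order) if doc_order is not None else sorted(scores)
    if set(labels) != set(scores):
        raise ValueError("doc_order must be a permutation of the scored labels")
    position = {lbl: i for i, lbl in enumerate(labels)}
    order = tuple(sorted(labels, key=lambda l: (-scores[l], position[l])))
    distinct = len(set(scores.values()))
    tie_breaks = len(labels) - distinct
    return RankingResult(method_id=method_id, scores=dict(scores),
                         order=order, tie_breaks_applied=tie_breaks)
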