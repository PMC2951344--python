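"""Structured-article data model and text assembly.

An :class:`Article` is the in-memory form of the structured-article JSON
schema used throughout the package::

    {
      "id": "...",
      "title": "...",
      "abstract": "...",
      "sections": [{"heading": "...", "paragraphs": ["...", ...]}, ...],
      "figures":  [{"label": 1, "legend": "..."}, ...],
      "gold":     [labels, most important first]   // optional
      "mentions": [{"label": ..., "section_index": ..., "paragraph_index": ...,
                    "sentence_index": ..., "char_span": [s, e]}, ...]  // optional
    }

Figure labels are canonical positive integers ("Figure 3A" belongs to
figure 3).  Mentions of figures in the body text are located with a
regular-expression grammar covering the reference styles of major
bioscience journals ("Fig. 3A and B", "Figures 2-4", "FIGS. 1, 2 and 5").
All coordinates are 0-based; character spans are half-open.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional, Union

logger = logging.getLogger(__name__)

__all__ = [
    "Article",
    "Section",
    "FigureRecord",
    "FigureMention",
    "GoldRanking",
    "ArticleParseError",
    "parse_article_json",
    "article_to_dict",
    "detect_rd_sections",
    "extract_figure_mentions",
    "figure_text",
    "article_text",
    "segment_sentences",
]


class ArticleParseError(ValueError):
    """Raised when input does not satisfy the structured-article schema."""


# --------------------------------------------------------------------------
# data model
# --------------------------------------------------------------------------

@dataclass
class Section:
    heading: str
    paragraphs: list[str] = field(default_factory=list)
    #: Results-or-Discussion flag; pure function of the heading
    is_rd: bool = False

    @property
    def is_references(self) -> bool:
        return _heading_core(self.heading) in _REFERENCE_CORES


@dataclass(frozen=True, order=True)
class FigureMention:
    """One located textual reference to a figure (0-based coordinates)."""

    section_index: int
    paragraph_index: int
    sentence_index: int
    char_span: tuple[int, int]


@dataclass
class FigureRecord:
    label: int
    legend: str = ""
    display: Optional[str] = None
    mentions: list[FigureMention] = field(default_factory=list)


@dataclass(frozen=True)
class GoldRanking:
    """Strict author-annotated importance order, most important first."""

    order: tuple[int, ...]

    def rank_of(self, label: int) -> int:
        """1-based reference rank of ``label``."""
        return self.order.index(label) + 1


@dataclass
class Article:
    id: str
    title: str = ""
    abstract: str = ""
    sections: list[Section] = field(default_factory=list)
    figures: list[FigureRecord] = field(default_factory=list)
    gold: Optional[GoldRanking] = None

    @property
    def labels(self) -> list[int]:
        return [f.label for f in self.figures]

    def figure(self, label: int) -> FigureRecord:
        for f in self.figures:
            if f.label == label:
                return f
        raise KeyError(f"article {self.id!r} has no figure {label!r}")


# --------------------------------------------------------------------------
# section-heading classification
# --------------------------------------------------------------------------

_RD_PREFIXES = ("results", "discussion")
_REFERENCE_CORES = {"references", "literature cited", "bibliography"}


def _heading_core(heading: str) -> str:
    """Alphabetic core of a heading: numbering/punctuation stripped, lowered."""
    core = re.sub(r"^[\s\d.):(\-]+", "", heading)
    core = re.sub(r"[^A-Za-z ]+", " ", core)
    return " ".join(core.lower().split())


def _is_rd_heading(heading: str) -> bool:
    core = _heading_core(heading)
    return any(core.startswith(p) for p in _RD_PREFIXES)


def detect_rd_sections(article: Article) -> Article:
    """Set ``is_rd`` on every section from its heading (in place).

    A section counts as Results/Discussion when the alphabetic core of its
    heading starts with "results" or "discussion" — this covers "RESULTS",
    "3. Discussion", "Results and Discussion" and similar journal variants.
    """
    for sec in article.sections:
        sec.is_rd = _is_rd_heading(sec.heading)
    return article


# --------------------------------------------------------------------------
# sentence segmentation
# --------------------------------------------------------------------------

#: abbreviations whose trailing period never ends a sentence
_ABBREVIATIONS = {
    "fig", "figs", "et al", "al", "e.g", "i.e", "vs", "cf", "ca", "approx",
    "dr", "no", "nos", "ref", "refs", "eq", "eqs", "st", "jr", "sp", "spp",
}

_SENT_END = re.compile(r"[.!?]+(?=\s|$)")


def segment_sentences(paragraph: str) -> list[str]:
    """Rule-based sentence split with an abbreviation guard.

    The concatenation of the output reproduces the input modulo leading and
    trailing whitespace of each sentence.
    """
    if not paragraph.strip():
        return []
    boundaries: list[int] = []
    for m in _SENT_END.finditer(paragraph):
        prefix = paragraph[: m.start()]
        word = re.search(r"[\w.]+$", prefix)
        token = word.group(0).lower().rstrip(".") if word else ""
        if token in _ABBREVIATIONS:
            continue
        boundaries.append(m.end())
    sentences: list[str] = []
    start = 0
    for b in boundaries:
        chunk = paragraph[start:b].strip()
        if chunk:
            sentences.append(chunk)
        start = b
    tail = paragraph[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def _sentence_index_at(paragraph: str, offset: int) -> int:
    """Index of the sentence (per :func:`segment_sentences`) containing ``offset``."""
    sentences = segment_sentences(paragraph)
    pos = 0
    for i, s in enumerate(sentences):
        start = paragraph.index(s, pos)
        end = start + len(s)
        if offset < end:
            return i
        pos = end
    return max(len(sentences) - 1, 0)


# --------------------------------------------------------------------------
# figure-mention grammar
# --------------------------------------------------------------------------

# "Fig. 3", "Figs. 2 and 3", "Figures 2-4", "FIG 1A-C", "fig. 3A and B"
_NUM_ITEM = r"\d+[A-Za-z]?(?:\s*[-–—]\s*(?:\d+[A-Za-z]?|[A-Za-z]))?"
_PANEL_ITEM = r"[A-Za-z](?:\s*[-–—]\s*[A-Za-z])?"
_ITEM = rf"(?:{_NUM_ITEM}|{_PANEL_ITEM})"
_MENTION_RE = re.compile(
    rf"\b[Ff][Ii][Gg](?:[Uu][Rr][Ee])?[Ss]?\.?\s*"
    rf"(?P<items>{_NUM_ITEM}(?:\s*(?:,|and|&)\s*{_ITEM})*)",
    re.UNICODE,
)
_RANGE_SEP = re.compile(r"\s*[-–—]\s*")


def _parse_mention_items(items: str) -> list[int]:
    """Figure numbers referenced by the item list of one grammar match.

    Panel suffixes collapse to the parent figure; ranges expand; a figure
    number occurring twice in one match (e.g. "Fig. 3A and 3B") counts once.
    """
    labels: list[int] = []
    for raw in re.split(r"\s*(?:,|and|&)\s*", items):
        raw = raw.strip()
        if not raw or not raw[0].isdigit():
            continue  # bare panel letter: same figure as the previous item
        parts = _RANGE_SEP.split(raw)
        lo = int(re.match(r"\d+", parts[0]).group(0))
        if len(parts) == 2 and parts[1][0].isdigit():
            hi = int(re.match(r"\d+", parts[1]).group(0))
            span = range(lo, hi + 1) if hi >= lo else [lo]
        else:
            span = [lo]  # "3A-C": panel range within one figure
        for n in span:
            if n not in labels:
                labels.append(n)
    return labels


def extract_figure_mentions(article: Article) -> Article:
    """Locate every figure mention in the body text (in place, idempotent).

    Reference-list sections are skipped.  Mentions of undeclared figure
    numbers are dropped with a warning.  Existing mention lists are replaced,
    so re-running is idempotent.
    """
    declared = set(article.labels)
    by_label: dict[int, list[FigureMention]] = {lbl: [] for lbl in declared}
    for si, sec in enumerate(article.sections):
        if sec.is_references:
            continue
        for pi, para in enumerate(sec.paragraphs):
            for m in _MENTION_RE.finditer(para):
                span = (m.start(), m.end())
                sent = _sentence_index_at(para, m.start())
                for lbl in _parse_mention_items(m.group("items")):
                    if lbl not in declared:
                        logger.warning(
                            "article %s: mention of undeclared figure %d at "
                            "section %d paragraph %d dropped", article.id, lbl, si, pi
                        )
                        continue
                    by_label[lbl].append(FigureMention(si, pi, sent, span))
    for fig in article.figures:
        fig.mentions = sorted(by_label[fig.label])
    return article


# --------------------------------------------------------------------------
# text assembly
# --------------------------------------------------------------------------

def figure_text(article: Article, label: int, representation: str = "figtext") -> str:
    """Text representation of one figure.

    ``legend``  — the figure caption alone.
    ``figtext`` — the caption followed by every body sentence that mentions
    the figure, in document order, deduplicated at the sentence level.  A
    sentence mentioning several figures appears in each of their figtexts.
    """
    fig = article.figure(label)
    if representation == "legend":
        return fig.legend
    if representation != "figtext":
        raise ValueError(f"unknown figure representation {representation!r}")
    pieces = [fig.legend] if fig.legend else []
    seen: set[tuple[int, int, int]] = set()
    for men in fig.mentions:
        key = (men.section_index, men.paragraph_index, men.sentence_index)
        if key in seen:
            continue
        seen.add(key)
        para = article.sections[men.section_index].paragraphs[men.paragraph_index]
        sentences = segment_sentences(para)
        if men.sentence_index < len(sentences):
            pieces.append(sentences[men.sentence_index])
    return " ".join(pieces)


def article_text(article: Article, representation: str = "fulltext") -> str:
    """Article summary representation: ``title``, ``abstract`` or ``fulltext``.

    ``fulltext`` concatenates title, abstract, all body paragraphs except
    reference-list sections, and every figure legend.
    """
    if representation == "title":
        return article.title
    if representation == "abstract":
        if not article.abstract:
            logger.warning("article %s: empty abstract representation", article.id)
        return article.abstract
    if representation != "fulltext":
        raise ValueError(f"unknown article representation {representation!r}")
    pieces = [article.title, article.abstract]
    for sec in article.sections:
        if sec.is_references:
            continue
        pieces.extend(sec.paragraphs)
    pieces.extend(f.legend for f in article.figures)
    return " ".join(p for p in pieces if p)


# --------------------------------------------------------------------------
# JSON ingestion / serialization
# --------------------------------------------------------------------------

def _require(obj: dict, key: str, kind, where: str):
    if key not in obj:
        raise ArticleParseError(f"{where}: missing required field {key!r}")
    val = obj[key]
    if not isinstance(val, kind):
        raise ArticleParseError(
            f"{where}: field {key!r} must be {kind.__name__}, got {type(val).__name__}"
        )
    return val


def _coerce_label(value, where: str) -> int:
    if isinstance(value, bool):
        raise ArticleParseError(f"{where}: figure label must be an integer")
    if isinstance(value, int):
        lbl = value
    elif isinstance(value, str) and value.strip().isdigit():
        lbl = int(value.strip())
    else:
        raise ArticleParseError(f"{where}: figure label {value!r} is not a positive integer")
    if lbl < 1:
        raise ArticleParseError(f"{where}: figure label {lbl} must be >= 1")
    return lbl


def parse_article_json(source: Union[str, bytes, IO]) -> Article:
    """Parse a structured-article JSON document into an :class:`Article`.

    Mentions are recomputed from the body text unless the document carries an
    explicit ``mentions`` override.  A ``gold`` entry is validated as a strict
    permutation of the declared figure labels.  Results/Discussion flags are
    always set.
    """
    if hasattr(source, "read"):
        source = source.read()
    if isinstance(source, bytes):
        source = source.decode("utf-8")
    try:
        doc = json.loads(source)
    except json.JSONDecodeError as e:
        raise ArticleParseError(f"invalid JSON: {e}") from e
    if not isinstance(doc, dict):
        raise ArticleParseError("top-level JSON value must be an object")

    art_id = str(doc.get("id", ""))
    where = f"article {art_id!r}"
    title = _require(doc, "title", str, where)
    abstract = _require(doc, "abstract", str, where)
    if not title:
        logger.warning("%s: degenerate article (empty title)", where)

    sections = []
    for i, s in enumerate(_require(doc, "sections", list, where)):
        if not isinstance(s, dict):
            raise ArticleParseError(f"{where}: sections[{i}] must be an object")
        paragraphs = _require(s, "paragraphs", list, f"{where} sections[{i}]")
        if not all(isinstance(p, str) for p in paragraphs):
            raise ArticleParseError(f"{where}: sections[{i}].paragraphs must be strings")
        sections.append(Section(heading=str(s.get("heading", "")), paragraphs=list(paragraphs)))

    figures = []
    seen_labels: set[int] = set()
    for i, f in enumerate(_require(doc, "figures", list, where)):
        if not isinstance(f, dict):
            raise ArticleParseError(f"{where}: figures[{i}] must be an object")
        lbl = _coerce_label(f.get("label"), f"{where} figures[{i}]")
        if lbl in seen_labels:
            raise ArticleParseError(f"{where}: duplicate figure label {lbl}")
        seen_labels.add(lbl)
        figures.append(FigureRecord(label=lbl, legend=str(f.get("legend", "")),
                                    display=f.get("display")))

    gold = None
    if doc.get("gold") is not None:
        order = tuple(_coerce_label(x, f"{where} gold") for x in doc["gold"])
        if sorted(order) != sorted(seen_labels):
            raise ArticleParseError(
                f"{where}: gold ranking {list(order)} is not a permutation of "
                f"figure labels {sorted(seen_labels)}"
            )
        gold = GoldRanking(order=order)

    article = Article(id=art_id, title=title, abstract=abstract,
                      sections=sections, figures=figures, gold=gold)
    detect_rd_sections(article)
    if "mentions" in doc and doc["mentions"] is not None:
        _apply_mention_override(article, doc["mentions"], where)
    else:
        extract_figure_mentions(article)
    return article


def _apply_mention_override(article: Article, mentions: list, where: str) -> None:
    by_label: dict[int, list[FigureMention]] = {lbl: [] for lbl in article.labels}
    for i, m in enumerate(mentions):
        if not isinstance(m, dict):
            raise ArticleParseError(f"{where}: mentions[{i}] must be an object")
        lbl = _coerce_label(m.get("label"), f"{where} mentions[{i}]")
        if lbl not in by_label:
            raise ArticleParseError(f"{where}: mentions[{i}] refers to unknown figure {lbl}")
        span = m.get("char_span", [0, 0])
        men = FigureMention(
            section_index=int(m.get("section_index", 0)),
            paragraph_index=int(m.get("paragraph_index", 0)),
            sentence_index=int(m.get("sentence_index", 0)),
            char_span=(int(span[0]), int(span[1])),
        )
        if men.section_index >= len(article.sections):
            raise ArticleParseError(f"{where}: mentions[{i}] section index out of range")
        by_label[lbl].append(men)
    for fig in article.figures:
        fig.mentions = sorted(by_label[fig.label])


def article_to_dict(article: Article, include_mentions: bool = False) -> dict:
    """Serialize an Article back to the structured-article schema."""
    doc: dict = {
        "id": article.id,
        "title": article.title,
        "abstract": article.abstract,
        "sections": [
            {"heading": s.heading, "paragraphs": list(s.paragraphs)}
            for s in article.sections
        ],
        "figures": [
            {"label": f.label, "legend": f.legend}
            | ({"display": f.display} if f.display else {})
            for f in article.figures
        ],
    }
    if article.gold is not None:
        doc["gold"] = list(article.gold.order)
    if include_mentions:
        doc["mentions"] = [
            {
                "label": f.label,
                "section_index": m.section_index,
                "paragraph_index": m.paragraph_index,
                "sentence_index": m.sentence_index,
                "char_span": list(m.char_span),
            }
            for f in article.figures
            for m in f.mentions
        ]
    return doc
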