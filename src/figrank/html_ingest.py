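"""Best-effort conversion of generic article HTML to the structured schema.

Intended for lenient ingestion: landmarks (title, abstract, figure legends,
section headings) are located with configurable CSS-style selectors; any
content that cannot be mapped is concatenated into a catch-all body section
rather than dropped, and every lossy step is logged.

Only a practical subset of CSS selectors is supported (``tag``, ``.class``,
``#id``, ``tag.class``, ``tag#id`` and descendant chains thereof); they are
translated to XPath and evaluated with lxml.
"""

from __future__ import annotations

import logging
import re

import lxml.html

from .article import (Article, FigureRecord, Section, detect_rd_sections,
                      extract_figure_mentions)

logger = logging.getLogger(__name__)

__all__ = ["strip_html", "DEFAULT_SELECTORS", "css_to_xpath"]

DEFAULT_SELECTORS = {
    "title": "title",
    "abstract": ".abstract",
    "section_heading": "h2",
    "paragraph": "p",
    "legend": "figcaption",
}

_SIMPLE = re.compile(r"^(?P<tag>[a-zA-Z][\w-]*)?(?:(?P<kind>[.#])(?P<name>[\w-]+))?$")


def css_to_xpath(selector: str) -> str:
    """Translate a simple CSS selector (possibly a descendant chain) to XPath."""
    steps = []
    for part in selector.strip().split():
        m = _SIMPLE.match(part)
        if not m or (not m.group("tag") and not m.group("name")):
            raise ValueError(f"unsupported selector {part!r}")
        tag = m.group("tag") or "*"
        if m.group("kind") == ".":
            cls = m.group("name")
            steps.append(f"{tag}[contains(concat(' ', normalize-space(@class), ' '),"
                         f" ' {cls} ')]")
        elif m.group("kind") == "#":
            steps.append(f"{tag}[@id='{m.group('name')}']")
        else:
            steps.append(tag)
    return "//" + "//".join(steps)


def _text(el) -> str:
    """Visible text of an element with tags removed, whitespace collapsed."""
    return " ".join(el.text_content().split())


_LEGEND_LABEL = re.compile(r"^(?:figure|fig\.?)\s*(\d+)", re.IGNORECASE)


def strip_html(html: str | bytes, selectors: dict[str, str] | None = None,
               article_id: str = "") -> Article:
    """Strip article HTML to an :class:`Article` (lossy, never silent).

    Missing landmarks degrade gracefully: no title yields a degenerate
    article with a warning; paragraphs not under any recognized section
    heading are collected into a single "Body" section.  Figure legends are
    taken from the legend selector; a leading "Figure N" phrase supplies the
    label, otherwise legends are numbered in order of appearance.
    """
    sel = {**DEFAULT_SELECTORS, **(selectors or {})}
    root = lxml.html.fromstring(html)
    # keep one proxy per node alive so that identity bookkeeping is stable
    all_elems = list(root.iter())

    titles = root.xpath(css_to_xpath(sel["title"]))
    title = _text(titles[0]) if titles else ""
    if not title:
        logger.warning("no title found: degenerate article")

    abstracts = root.xpath(css_to_xpath(sel["abstract"]))
    abstract = _text(abstracts[0]) if abstracts else ""
    if not abstract:
        logger.warning("no abstract found; abstract left empty")

    legend_els = root.xpath(css_to_xpath(sel["legend"]))
    figures: list[FigureRecord] = []
    used: set[int] = set()
    for el in legend_els:
        text = _text(el)
        m = _LEGEND_LABEL.match(text)
        label = int(m.group(1)) if m else (max(used, default=0) + 1)
        if label in used:
            logger.warning("duplicate figure label %d in legends; skipped", label)
            continue
        used.add(label)
        figures.append(FigureRecord(label=label, legend=text))
    figures.sort(key=lambda f: f.label)

    # paragraphs grouped under the nearest preceding section heading
    heading_xp = css_to_xpath(sel["section_heading"])
    para_xp = css_to_xpath(sel["paragraph"])
    headings = root.xpath(heading_xp)
    claimed = {id(e) for e in legend_els} | {id(e) for e in abstracts}
    sections: list[Section] = []
    body = Section(heading="Body")
    order = {id(el): i for i, el in enumerate(all_elems)}
    heading_pos = sorted(((order[id(h)], _text(h)) for h in headings))
    for p in root.xpath(para_xp):
        if id(p) in claimed or any(id(a) in {id(x) for x in p.iterancestors()}
                                   for a in abstracts):
            continue
        text = _text(p)
        if not text:
            continue
        pos = order[id(p)]
        prev = [h for hp, h in heading_pos if hp < pos]
        if prev:
            heading = prev[-1]
            if not sections or sections[-1].heading != heading:
                sections.append(Section(heading=heading))
            sections[-1].paragraphs.append(text)
        else:
            body.paragraphs.append(text)
    if body.paragraphs:
        sections.insert(0, body)
        logger.info("collected %d unmapped paragraph(s) into a body section",
                    len(body.paragraphs))

    article = Article(id=article_id, title=title, abstract=abstract,
                      sections=sections, figures=figures)
    detect_rd_sections(article)
    extract_figure_mentions(article)
    return article
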