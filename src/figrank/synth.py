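"""Synthetic full-text articles with planted figure-importance signal.

The generator emulates the statistical structure of an author-annotated
corpus of bioscience articles: each article has a title and abstract drawn
from a per-article topic vocabulary, IMRaD-shaped sections, figures with
legends, body mentions of those figures, and a gold importance ranking.

Two independent signal channels are planted, matching the two ranking
families:

* similarity channel — the legend of the figure at gold rank k mixes topic
  terms with background terms; the topic mixture weight decays linearly in
  k and scales with ``sim_signal``;
* frequency channel — the number of body mentions of the rank-k figure
  decays linearly in k and scales with ``freq_signal``.

With both signals at 0 the articles carry no importance information at all
(legends are pure background, mention counts are exchangeable), so any
ranker's expected pairwise error is 0.5.  ``noise`` attenuates both planted
signals.  All randomness flows from the seed; the same seed reproduces the
same article byte for byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .article import Article, detect_rd_sections, extract_figure_mentions, \
    parse_article_json, article_to_dict, FigureRecord, GoldRanking, Section
from .stopwords import STOPWORDS

__all__ = ["SynthConfig", "generate_article", "generate_articles",
           "generate_collection", "vocabulary"]


@dataclass(frozen=True)
class SynthConfig:
    n_articles: int = 202
    fig_mean: float = 5.9
    fig_sd: float = 1.75
    fig_min: int = 2
    fig_max: int = 13
    vocab_size: int = 2000
    topic_size: int = 40
    sim_signal: float = 0.9
    freq_signal: float = 0.9
    noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sim_signal", "freq_signal", "noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_articles < 1:
            raise ValueError("n_articles must be >= 1")
        if not 1 <= self.fig_min <= self.fig_max:
            raise ValueError("need 1 <= fig_min <= fig_max")
        if not 1 <= self.topic_size < self.vocab_size:
            raise ValueError("need 1 <= topic_size < vocab_size")


# legend length, abstract length and the mention budget set how strong a
# fully-on signal is; chosen so sim_signal/freq_signal span "no information"
# to "strongly ordered" (see docs/methods.md)
_LEGEND_TOKENS = 170
_ABSTRACT_TOKENS = 150
_TITLE_TOKENS = 8
_MENTION_MAX = 22

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"


def vocabulary(size: int) -> list[str]:
    """Deterministic pseudo-word vocabulary (consonant-vowel trigram words).

    Pure function of ``size``: shared by every article so that collection
    IDF models are meaningful.  Words never collide with stopwords or with
    the figure-mention grammar.
    """
    syllables = [c + v for c in _CONSONANTS for v in _VOWELS]
    base = len(syllables)
    words = []
    i = 0
    while len(words) < size:
        a, rest = i % base, i // base
        b, c = rest % base, rest // base % base
        w = syllables[a] + syllables[b] + syllables[c]
        i += 1
        if w in STOPWORDS or w.startswith("fig"):
            continue
        words.append(w)
    return words


def _frac(rank: int, n: int) -> float:
    """Linear importance fraction: 1 at gold rank 1, 0 at gold rank n."""
    return 1.0 if n == 1 else 1.0 - (rank - 1) / (n - 1)


def _sentence(words: list[str]) -> str:
    return (" ".join(words)).capitalize() + "."


class _Sampler:
    """Draws token lists from a topic/background mixture.

    Topic tokens cycle through a shuffled topic list rather than being drawn
    iid: topical prose uses the topic vocabulary roughly evenly, and the
    near-uniform term profile keeps TF*IDF cosine noise driven by the
    planted mixture weights instead of multinomial multiplicity noise.
    """

    def __init__(self, rng: np.random.Generator, topic: list[str], background: list[str]):
        self.rng = rng
        self.topic = list(rng.permutation(topic))
        self.background = background
        self._cursor = 0

    def _next_topic(self) -> str:
        w = self.topic[self._cursor % len(self.topic)]
        self._cursor += 1
        return w

    def tokens(self, n: int, p_topic: float) -> list[str]:
        is_topic = self.rng.random(n) < p_topic
        bi = self.rng.integers(0, len(self.background), size=n)
        return [self._next_topic() if flag else self.background[b]
                for flag, b in zip(is_topic, bi)]

    def paragraph(self, n_sentences: int, tokens_per_sentence: int, p_topic: float) -> str:
        return " ".join(_sentence(self.tokens(tokens_per_sentence, p_topic))
                        for _ in range(n_sentences))


def generate_article(cfg: SynthConfig, seed: int, article_id: str | None = None) -> Article:
    """Generate one article with a planted gold ranking.

    ``seed`` fully determines the article.  Mentions and R&D flags are
    recomputed from the generated text through the ordinary parsing path,
    so the generator exercises the same machinery as real input.
    """
    rng = np.random.default_rng(seed)
    vocab = vocabulary(cfg.vocab_size)
    topic_idx = rng.choice(cfg.vocab_size, size=cfg.topic_size, replace=False)
    topic_set = set(int(i) for i in topic_idx)
    topic = [vocab[i] for i in sorted(topic_set)]
    background = [w for i, w in enumerate(vocab) if i not in topic_set]
    draw = _Sampler(rng, topic, background)

    n = int(np.clip(round(rng.normal(cfg.fig_mean, cfg.fig_sd)), cfg.fig_min, cfg.fig_max))
    labels = list(range(1, n + 1))
    gold = tuple(int(x) for x in rng.permutation(labels))
    gold_rank = {lbl: pos + 1 for pos, lbl in enumerate(gold)}
    attenuation = 1.0 - cfg.noise

    title = " ".join(draw.tokens(_TITLE_TOKENS, 1.0)).capitalize()
    abstract = draw.paragraph(5, _ABSTRACT_TOKENS // 5, 0.7)

    figures = []
    for lbl in labels:
        p_topic = cfg.sim_signal * _frac(gold_rank[lbl], n) * attenuation
        legend = _sentence(draw.tokens(_LEGEND_TOKENS, p_topic))
        figures.append(FigureRecord(label=lbl, legend=legend))

    # one Results paragraph per figure carries that figure's body mentions.
    # Mention sentences use the figure's own topic mixture (prose discussing
    # a central figure shares the article's topic), but all repeat mentions
    # are packed into one sentence so that the amount of mention-sentence
    # text — and hence the similarity channel — does not scale with the
    # mention count: the count itself is the only frequency-channel quantity
    results_paras = []
    for lbl in labels:
        frac = _frac(gold_rank[lbl], n)
        p_topic = cfg.sim_signal * frac * attenuation
        m = 1 + int(rng.binomial(_MENTION_MAX, cfg.freq_signal * frac * attenuation))
        sentences = [f"As shown in Fig. {lbl}, " + " ".join(draw.tokens(8, p_topic)) + "."]
        if m > 1:
            clauses = " and ".join(
                " ".join(draw.tokens(3, p_topic)) + f" (Fig. {lbl})"
                for _ in range(m - 1))
            sentences.append("The data show " + clauses + ".")
        sentences.append(_sentence(draw.tokens(8, 0.2)))
        results_paras.append(" ".join(sentences))

    sections = [
        Section("Introduction", [draw.paragraph(3, 10, 0.4), draw.paragraph(3, 10, 0.3)]),
        Section("Materials and Methods", [draw.paragraph(3, 10, 0.05),
                                          draw.paragraph(3, 10, 0.05)]),
        Section("Results", results_paras),
        Section("Discussion", [draw.paragraph(4, 10, 0.4)]),
        Section("References", [" ".join(draw.tokens(12, 0.0))]),
    ]

    article = Article(
        id=article_id or f"synth-{seed}",
        title=title,
        abstract=abstract,
        sections=sections,
        figures=figures,
        gold=GoldRanking(order=gold),
    )
    detect_rd_sections(article)
    extract_figure_mentions(article)
    return article


def _article_seeds(cfg: SynthConfig) -> list[int]:
    rng = np.random.default_rng(cfg.seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=cfg.n_articles)]


def generate_articles(cfg: SynthConfig) -> list[Article]:
    """Generate the whole collection in memory (deterministic in cfg.seed)."""
    return [generate_article(cfg, s, article_id=f"synth-{i:04d}")
            for i, s in enumerate(_article_seeds(cfg))]


def generate_collection(cfg: SynthConfig, out_dir: str | os.PathLike,
                        force: bool = False) -> Path:
    """Write the collection as article JSON files plus a manifest.

    Refuses to write into an existing non-empty directory unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)

    seeds = _article_seeds(cfg)
    files = []
    for i, s in enumerate(seeds):
        art = generate_article(cfg, s, article_id=f"synth-{i:04d}")
        name = f"{art.id}.json"
        (out / name).write_text(
            json.dumps(article_to_dict(art), sort_keys=True, indent=1) + "\n",
            encoding="utf-8")
        files.append(name)
    manifest = {"config": asdict(cfg), "per_article_seeds": seeds, "files": files}
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n", encoding="utf-8")
    return out


def load_collection(directory: str | os.PathLike) -> list[Article]:
    """Read every article JSON file in a directory (manifest excluded)."""
    out = []
    for path in sorted(Path(directory).glob("*.json")):
        if path.name == "manifest.json":
            continue
        out.append(parse_article_json(path.read_text(encoding="utf-8")))
    return out
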