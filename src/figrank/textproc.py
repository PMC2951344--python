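"""Tokenization, IDF models, TF*IDF sparse vectors and cosine similarity.

This is the numerical substrate shared by the similarity-based rankers and
the relevancy weights of the frequency-based rankers.  Term vectors are
plain sparse term→weight mappings; article-scale vocabularies are small
enough that dict arithmetic is both clear and fast.

The IDF model is pluggable: by default it is built from the evaluation
collection's own full texts (one document per article); a background
document-frequency table in TSV form may be supplied instead, standing in
for a literature-scale corpus.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Union
import re

from .stopwords import STOPWORDS, STOPWORDS_VERSION

__all__ = [
    "TokenizerConfig",
    "tokenize",
    "IdfModel",
    "build_idf",
    "TermVector",
    "vectorize",
    "cosine",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class TokenizerConfig:
    """Tokenizer policy: lowercased alphanumeric runs, short-token and
    stopword filters.  ``min_len=2`` and stopping on are the defaults used
    for all ranking computations."""

    stopwords: bool = True
    min_len: int = 2

    def describe(self) -> str:
        return f"tok(stop={int(self.stopwords)}v{STOPWORDS_VERSION},min={self.min_len})"


DEFAULT_TOKENIZER = TokenizerConfig()


def tokenize(text: str, config: TokenizerConfig = DEFAULT_TOKENIZER) -> list[str]:
    """Split text into lowercased alphanumeric tokens.

    Hyphens and all other non-alphanumeric characters separate tokens;
    tokens shorter than ``config.min_len`` are dropped, and stopwords are
    removed when enabled.  Deterministic by construction.
    """
    tokens = _TOKEN_RE.findall(text.lower())
    out = [t for t in tokens if len(t) >= config.min_len]
    if config.stopwords:
        out = [t for t in out if t not in STOPWORDS]
    return out


# --------------------------------------------------------------------------
# IDF model
# --------------------------------------------------------------------------

@dataclass
class IdfModel:
    """Document frequencies over a background corpus.

    ``smoothing="plus_one"`` gives idf(t) = ln((N+1)/(df+1)) with df=0 for
    unknown terms, keeping out-of-corpus terms finite; ``smoothing="raw"``
    gives ln(N/df) and is undefined (term skipped) for unknown terms.
    """

    corpus_size: int
    df: dict[str, int] = field(default_factory=dict)
    smoothing: str = "plus_one"

    def __post_init__(self) -> None:
        if self.corpus_size < 1:
            raise ValueError("corpus_size must be >= 1")
        if self.smoothing not in ("plus_one", "raw"):
            raise ValueError(f"unknown smoothing {self.smoothing!r}")
        for t, n in self.df.items():
            if not 1 <= n <= self.corpus_size:
                raise ValueError(f"df[{t!r}]={n} outside [1, corpus_size={self.corpus_size}]")

    def idf(self, term: str) -> float:
        n = self.df.get(term, 0)
        if self.smoothing == "plus_one":
            return math.log((self.corpus_size + 1) / (n + 1))
        if n == 0:
            return 0.0
        return math.log(self.corpus_size / n)

    # -- TSV round trip ----------------------------------------------------
    def save(self, path_or_file: Union[str, os.PathLike, IO[str]]) -> None:
        """Write the model as TSV: '#corpus_size=<int>' header then term<TAB>df."""
        own = isinstance(path_or_file, (str, os.PathLike))
        fh = open(path_or_file, "w", encoding="utf-8") if own else path_or_file
        try:
            fh.write(f"#corpus_size={self.corpus_size}\n")
            for term in sorted(self.df):
                fh.write(f"{term}\t{self.df[term]}\n")
        finally:
            if own:
                fh.close()

    @classmethod
    def load(cls, path_or_file: Union[str, os.PathLike, IO[str]],
             smoothing: str = "plus_one") -> "IdfModel":
        own = isinstance(path_or_file, (str, os.PathLike))
        fh = open(path_or_file, "r", encoding="utf-8") if own else path_or_file
        try:
            header = fh.readline().strip()
            m = re.match(r"#corpus_size=(\d+)$", header)
            if not m:
                raise ValueError(f"bad IDF file header: {header!r}")
            df: dict[str, int] = {}
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                term, _, count = line.partition("\t")
                df[term] = int(count)
            return cls(corpus_size=int(m.group(1)), df=df, smoothing=smoothing)
        finally:
            if own:
                fh.close()


def build_idf(documents: Iterable[str], config: TokenizerConfig = DEFAULT_TOKENIZER,
              smoothing: str = "plus_one") -> IdfModel:
    """Build an :class:`IdfModel` from a document collection.

    Each term's df is the number of documents containing it at least once.
    """
    df: dict[str, int] = {}
    n = 0
    for doc in documents:
        n += 1
        for term in set(tokenize(doc, config)):
            df[term] = df.get(term, 0) + 1
    if n == 0:
        raise ValueError("cannot build an IDF model from an empty collection")
    return IdfModel(corpus_size=n, df=df, smoothing=smoothing)


# --------------------------------------------------------------------------
# term vectors
# --------------------------------------------------------------------------

class TermVector:
    """Sparse non-negative term→weight mapping with a cached Euclidean norm."""

    __slots__ = ("weights", "norm")

    def __init__(self, weights: Mapping[str, float]):
        self.weights = {t: float(w) for t, w in weights.items() if w != 0.0}
        self.norm = math.sqrt(sum(w * w for w in self.weights.values()))

    def __len__(self) -> int:
        return len(self.weights)

    def __repr__(self) -> str:
        return f"TermVector({len(self.weights)} terms, norm={self.norm:.4g})"


def vectorize(text: str, idf: IdfModel,
              config: TokenizerConfig = DEFAULT_TOKENIZER) -> TermVector:
    """TF*IDF vector of a text: weight(t) = count(t) * idf(t)."""
    tf: dict[str, int] = {}
    for tok in tokenize(text, config):
        tf[tok] = tf.get(tok, 0) + 1
    return TermVector({t: n * idf.idf(t) for t, n in tf.items()})


def cosine(u: TermVector, v: TermVector) -> float:
    """Cosine similarity in [0, 1] for non-negative vectors; 0 if either is null."""
    if u.norm == 0.0 or v.norm == 0.0:
        return 0.0
    if len(u.weights) > len(v.weights):
        u, v = v, u
    dot = sum(w * v.weights.get(t, 0.0) for t, w in u.weights.items())
    return dot / (u.norm * v.norm)
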