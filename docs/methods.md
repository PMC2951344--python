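# Methods

## Document model and preprocessing

An article is a title, an abstract, ordered sections of paragraphs, and
figure records (integer label + legend), optionally with an author gold
ranking — a strict permutation of the figure labels, most important first.
All coordinates are 0-based and character spans half-open.

**Figure mentions** are located with a case-insensitive regular grammar
covering the reference styles of the major bioscience journals:
`Fig. 3`, `Figure 3`, `FIGS 1, 2 and 5`, ranges (`Figures 2–4`, hyphen or
en dash), and panel suffixes (`Fig. 3A and B`, `1A–C`). Panels collapse to
the parent figure; ranges and conjunctions expand; a figure referenced
twice within one grammar match counts once, while separate matches count
separately. Mentions of undeclared figure numbers are dropped with a
warning. Legends are not counted as mentions (a legend *is* the figure,
not a referral), and reference-list sections are excluded from both
mention counting and full-text assembly to avoid citation noise.

**Results/Discussion detection**: a section is R&D when the alphabetic
core of its heading (numbering and punctuation stripped, lowercased)
begins with "results" or "discussion". Zero R&D sections is legal; the
R&D-restricted strategies then see empty scope and score 0.

**Sentences** are split on terminator runs with an abbreviation guard
("Fig.", "et al.", "e.g.", …); concatenating the output reproduces the
input up to whitespace. FIGtext is the legend followed by every body
sentence containing a mention, in document order, deduplicated per
sentence; a sentence mentioning k figures appears in all k figtexts, since
there is no principled way to apportion it.

## Vector space

Tokens are lowercased alphanumeric runs (hyphens split), length ≥ 2,
with a small versioned stopword list (default on; stemming off — both
configurable, and the tokenizer configuration enters the report config
hash). TF is the raw count. IDF uses the smoothed form
ln((N+1)/(df+1)) with df = 0 for unknown terms, keeping out-of-corpus
terms finite; the raw ln(N/df) variant is available. Cosine is defined as
0 when either vector is null, so empty representations degrade to
document-order rankings rather than failures.

The IDF model is pluggable because a literature-scale background corpus is
out of scope: the default builds document frequencies from the evaluation
collection itself (one document per article full text), and an external
TSV (`#corpus_size=<int>` header, then `term<TAB>df` rows) overrides it.
Both routes go through the same `IdfModel`.

## Ranking systems

Similarity: score(f) = cos(v(figure rep), v(article rep)) over the
2×3 grid {legend, figtext} × {title, abstract, fulltext}.

Frequency: raw mention counts in full text or R&D scope; the weighted
variants multiply per-paragraph counts by paragraph→anchor cosine
relevancy, either in the figure's single most relevant mentioning
paragraph (ties: earliest paragraph) or summed over all R&D paragraphs.
"Most relevant paragraph" is restricted to paragraphs that actually
mention the figure — a figure with no mentioning R&D paragraph scores 0.
Paragraphs are taken as authored; no re-segmentation.

Scores induce a strict order: descending sort, exact ties broken by
earlier document appearance (lower label). The tie rule is global — every
ranking the package emits, including the degenerate all-zero case, is a
strict permutation, so the metrics never see ties.

Combination: combined(f) = λ·sim(f) + (1−λ)·freq(f) after per-article
normalization. Cosines live in [0,1] while weighted frequencies are
unbounded, so min-max normalization to [0,1] is the default (constant
score sets map to 0.5); rank normalization (1 − (rank−1)/(n−1)) is offered
as a scale-free alternative and `none` for callers that pre-normalize. At
λ ∈ {0, 1} the combined order provably equals the pure member's order
under every mode — the only behavior the combination is contractually
required to honor.

## Metrics

With reference ranks r and system ranks R over an article's figures:

- **MER** = (# pairs with sign(r_i−r_j) ≠ sign(R_i−R_j)) / C(n,2) —
  the Kendall-tau distance normalized by the pair count.
- **MWER** = Σ_wrong d(i,j) / Σ_all d(i,j), d(i,j) = |r_i − r_j|.
- **MWER-RK** = Σ_wrong d(i,j)·L(min(r_i,r_j)) / Σ_all d(i,j) with the
  logistic pair weight L(m) = 4/(1+e^m). The weight is calibrated so that
  for reference (1,2,3,4) the single-swap outputs (2,1,3,4) and (1,2,4,3)
  score 0.108 and 0.019: both have Σ_all d = 10 and one wrong pair of
  distance 1, so the values are L(1)/10 and L(3)/10. L is strictly
  decreasing, so for fixed distance a wrong pair higher in the reference
  always costs more. MWER-RK is 0 iff the order is perfect; unlike MWER it
  is not capped at 1 (L(1) ≈ 1.076).
- **ER-HR** = fraction of articles whose system top figure differs from
  the reference top figure.
- **WER-HR** = mean over articles of (R(refTop) − 1)/(n − 1) — the unique
  affine form that is 0 on agreement and 1 when the top figure is placed
  last; defined 0 for single-figure articles.

Articles with fewer than two figures are excluded from the pairwise-metric
means (exclusion counts are reported) and enter ER-HR/WER-HR as 0-error.
A uniform random top-figure pick on an article with n̄ figures has
expected ER-HR of 1 − 1/n̄, i.e. 0.831 at the corpus mean of 5.9.

The paired two-sided t test on per-article metric values delegates to
`scipy.stats.ttest_rel`; zero-variance differences return (0, 1) when the
means agree and the ±∞/0 limit (with a warning) otherwise.

## Synthetic articles

The generator emulates the statistics of an author-annotated corpus:
202 articles by default, figure counts drawn from N(5.9, 1.75²) rounded
and clipped to [2, 13], IMRaD sections plus a references section, and a
uniformly random gold permutation per article.

Two planted channels mirror the two ranking families. Writing
frac(k) = 1 − (k−1)/(n−1) for the linear importance profile and
a = 1 − noise:

- similarity channel — the legend of the gold-rank-k figure draws each
  token from the article's topic vocabulary with probability
  `sim_signal`·frac(k)·a, otherwise from the background vocabulary;
- frequency channel — that figure receives 1 + Binomial(22,
  `freq_signal`·frac(k)·a) body mentions in its Results paragraph.

Design choices worth knowing:

- *Channel separation.* Mention sentences use the figure's own topic
  mixture (prose about a central figure shares the article's topic), but
  all repeat mentions are packed into a single sentence, so the amount of
  mention text — and with it the similarity score — does not grow with the
  mention count. The count is the only frequency-channel quantity, which
  keeps the two rankers complementary and gives the λ sweep its interior
  optimum on mixed-strength collections.
- *Topic sampling.* Topic tokens cycle through a per-article shuffled
  topic list rather than being drawn iid: with a 40-word topic vocabulary,
  iid draws leave ~15% relative multinomial noise on the TF profile, which
  would drown the planted between-figure margins; cycling makes cosine
  noise a function of the mixture weights alone.
- *Depth constants.* Legends are 170 tokens, abstracts 150, titles 8, and
  the mention budget is 22 — the scale of a detailed multi-panel legend
  and of a heavily discussed central figure. They set how sharp a fully-on
  signal is: at signal 0.9/noise 0.1 the planted order is recovered almost
  perfectly, at 0 the articles carry no importance information at all
  (legends are pure background, mention counts are exchangeable, expected
  MER is exactly 0.5 against the independent gold permutation).
- *Vocabulary.* A deterministic pseudo-word vocabulary (2000
  consonant-vowel trigram words, shared across articles so collection IDF
  is meaningful; 40 topic words per article). Words never collide with
  stopwords or the mention grammar.

All randomness flows from the seed: the same seed yields byte-identical
article JSON, and collection generation derives per-article seeds from the
master seed (recorded in the manifest).

What the generator does **not** emulate: real biomedical prose and its
lexical burstiness, journal-specific HTML, correlated section/figure
structure, annotation inconsistency between authors, and a
literature-scale IDF background. Passing tests on synthetic collections
therefore demonstrate that the pipeline recovers a planted centrality
signal under controlled conditions — not the error rates the methods
achieve on real annotated articles.

## Problem sizes and numerical choices

The test suite evaluates synthetic collections of 100 articles (signal
recovery), 150 (λ sweep), and 1000 small ones (null calibration); the
whole suite runs in well under a minute on one CPU. Monte-Carlo checks use
10⁵ draws. Exact-value assertions use the printed 3-decimal precision
(±5·10⁻⁴); oracle-equivalence checks assert to 10⁻¹². Degenerate inputs —
empty representations, zero-relevancy anchors, articles without R&D
sections or without gold — degrade to warnings plus well-defined fallbacks
(zero scores, document-order ranking, exclusion from means) rather than
exceptions.

## Limitations

- The mention grammar covers the dominant citation styles but not free
  forms like "the previous figure" or "panels of the third figure".
- FIGtext draws mentioning sentences from all sections; restricting to
  particular sections is not implemented.
- Whether legends belong in the full-text representation and whether
  counting is sentence- or paragraph-granular are fixed choices here
  (legends in; counts per occurrence); both are localized in
  `article_text` / `count_mentions` if a different convention is needed.
- HTML ingestion is deliberately generic (landmark selectors, lossy with
  logging), not a substitute for publisher-specific scrapers; PDF and
  image processing are out of scope.
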