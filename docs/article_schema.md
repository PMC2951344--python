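# Structured-article JSON schema

One article per file, UTF-8 JSON object:

```json
{
  "id": "string, opaque identifier",
  "title": "string (may be empty: degenerate article, warned)",
  "abstract": "string (may be empty)",
  "sections": [
    {"heading": "Results", "paragraphs": ["text block", "..."]}
  ],
  "figures": [
    {"label": 1, "legend": "caption text", "display": "Figure 1 (optional)"}
  ],
  "gold": [2, 1],
  "mentions": [
    {"label": 1, "section_index": 0, "paragraph_index": 0,
     "sentence_index": 0, "char_span": [12, 18]}
  ]
}
```

Rules:

- `label` values are positive integers, unique per article; strings of
  digits are accepted and coerced.
- `gold` is optional; if present it must be a strict permutation of the
  figure labels, most important first.
- `mentions` is optional. When absent, mentions are recomputed from the
  section text with the built-in grammar; when present it is taken as an
  explicit override (all indices 0-based, `char_span` half-open within the
  paragraph).
- Section headings drive Results/Discussion and reference-list
  classification; see `docs/methods.md`.

`figrank synth` emits files in this schema; `figrank rank`/`eval`/`sweep`
and `figrank.parse_article_json` consume it.
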