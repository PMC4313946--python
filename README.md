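# figsummary

Unsupervised figure summarization for full-text biomedical articles.

Figures carry much of the evidence in a biomedical paper, but a caption
alone rarely suffices to understand one: the text that actually explains a
figure is scattered through the article and partly redundant. `figsummary`
extracts, for every figure, the sentences that discuss it — producing a
compact extractive summary that complements the caption — and evaluates
such selections intrinsically against expert-annotated gold standards.

## Systems

Given an article with sentences s and a figure with caption c, the package
implements five figure-specific summarizers:

| system        | selection rule |
|---------------|----------------|
| `similarity`  | top-n sentences by cos(s, c) over raw term-count vectors |
| `tfidf`       | top-n sentences by cos(s, c) over TF-IDF vectors |
| `surface_cue` | **all** sentences citing the figure ("Fig. k", "Figs. 1–3", "Figure 2A", ...) |
| `paragraph`   | **all** sentences of every paragraph containing a citing sentence |
| `hybrid`      | sentences of citing paragraphs, ranked by a centroid summarizer, top n |

plus three baselines (`random_sent`, `random_para`, and `centroid_full`, a
centroid summarizer over the whole article) and `figsum_heuristic`, a
section-based comparator that keeps the best caption/theme-scoring sentence
per IMRaD category.

TF-IDF treats the candidate sentences of one article as the document
collection: `w(t) = tf(t) · ln((N+1)/(df(t)+1))`, where N is the number of
candidate sentences and df(t) the number containing t. The centroid score
of a candidate sentence combines the summed mean-TF-IDF weight of its
centroid tokens, a positional component, and its overlap with the first
candidate. The summary length n defaults to the ceiling of the gold
standard's micro-average annotated sentences per figure.

## Evaluation

Sentence selection is scored per figure by precision, recall and F1 over
annotated sentence ids (micro = pool counts across figures; macro = average
per-figure ratios ± sd). Content overlap is scored with a recall-oriented
ROUGE variant: ROUGE-1/2 (clipped n-gram recall) and ROUGE-SU4
(skip-bigrams with gap ≤ 4, plus unigrams), applied sentence-best-match:
each summary sentence keeps its best score against any gold sentence, and
the per-figure value is the mean of those best scores. Paired t-tests and
Spearman rank correlations support system comparisons.

## Worked example

```python
from figsummary import summarize
from figsummary.synthetic import SynthParams, generate_article

synth = generate_article(SynthParams(seed=11), article_id="demo")
article = synth.article
print(synth.referring_sentences[1])
for name in ("surface_cue", "paragraph", "hybrid"):
    print(name, summarize(name, article, article.figure(1), n=3).document_order_ids)
```

prints

```
[28, 29, 35]
surface_cue [28, 29, 35]
paragraph [25, 26, 27, 28, 29, 35, 36, 37, 38, 39]
hybrid [28, 29, 35]
```

The generator planted citation cues for figure 1 in sentences 28, 29 and
35; `surface_cue` recovers exactly those, `paragraph` widens the selection
to their whole paragraphs, and `hybrid` re-ranks the paragraph pool and
keeps the top 3. The `examples/` directory holds one narrative script per
capability (parsing and features, the nine systems, evaluation, benchmark
statistics), and the `figsummary` CLI wires the same operations into
`summarize`, `evaluate`, `stats` and `simulate` subcommands.

## Input formats

- **Plain-text dialect** — first non-empty line is the title; paragraphs
  separated by blank lines; a line starting `#` is a section heading; a
  paragraph starting `ABSTRACT:` is the abstract; a paragraph starting
  `FIGURE <k>:` is figure k's caption (captions are excluded from the
  candidate sentence pool).
- **JATS-like XML subset** — `article-title`, `abstract`, `body` with
  `sec`/`title`/`p`, and `fig` with `label`/`caption`.
- **Gold standard JSON** —
  `{"article_id": {"<figure>": {"sentence_ids": [...], "reference_texts": [...]}}}`.

All files are UTF-8; sentence ids are 0-based in document order.

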