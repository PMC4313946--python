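# Methods

## Problem and scope

Given a full-text article and one of its figures, the task is extractive:
select the body sentences that discuss that figure. The package implements
unsupervised selectors only — similarity-based, citation-cue-based, and a
centroid-ranked hybrid — together with the intrinsic evaluation used to
compare them. Supervised selectors (per-feature Naive Bayes/SVM systems)
are deliberately out of scope; the feature matrix export exists so they
could be trained externally.

## Text model

An article is an ordered stream of sentences grouped into contiguous
paragraphs, plus figure records (number, label, caption). All indices are
0-based and character spans half-open; a single convention throughout
avoids off-by-one drift between modules. Captions are excluded from the
candidate sentence pool by construction of the parsers: a figure summary
is meant to complement the caption, not re-select it. Abstract sentences
are included in the pool (an `include_abstract` flag on both parsers turns
this off), since there is no principled reason a summarizing sentence
cannot sit in the abstract.

Sentence splitting is rule-based: a run of `.` `!` `?` (with trailing
closers) followed by whitespace and an uppercase letter or digit ends a
sentence, unless the period follows a protected abbreviation. The
protection list ships with "Fig", "Figs", "et al", "e.g", "i.e", "vs" and
single capital letters, and is configurable; "Fig." protection is load-
bearing, because the cue-based systems would otherwise never see an intact
"Fig. 2" citation. The splitter guarantees that its spans tile all
non-whitespace text, so no content is silently dropped.

## Features and weighting

Tokenization lowercases and splits on non-alphanumerics ("IL-2" →
`il`, `2`). Similarity features remove stopwords and do not stem; both
toggles are exposed. TF-IDF treats the candidate sentences of one article
as the collection:

    w(t) = tf(t) · ln((N + 1) / (df(t) + 1))

with N the candidate count and df(t) the number of sentences containing
t. The add-one smoothing serves two purposes: caption-only terms (df = 0)
get a finite weight, and a term present in every sentence gets weight
exactly 0. Caption similarity (feature over raw term counts) and TF-IDF
similarity (cosine of TF-IDF vectors) are kept distinct on purpose — they
are separate features and separate systems.

Figure citations are detected by a documented grammar: a head token
(fig/figs/figure/figures, optional period, any case) followed by a number
list supporting commas, "and"/"&", dash ranges ("Figs. 1–3" cites 1, 2
and 3) and panel letters ("2A" cites 2), with word boundaries so
"configure" never matches. The reference-sentence similarity feature
aggregates by maximum over the figure's citing sentences; max is the most
discriminative choice and the one documented here, since mean and sum
dilute the signal with unrelated citing sentences.

The cue-word feature tests for a phrase from a lexicon of generic
figure-describing cues ("shown in", "illustrates", "we observe", ...). The
shipped list (~35 phrases) is a documented stand-in for the published
140-item lexicon this feature is modelled on, which is external to this
package; a user-supplied lexicon file (one phrase per line, `#` comments)
replaces it.

## Centroid summarizer

The hybrid and whole-article baselines use an in-package centroid
summarizer in the MEAD tradition, parameterized and documented so results
are reproducible. For a candidate set of N_c sentences, the centroid is
the `centroid_size` (default 10) tokens with highest mean TF-IDF weight
across candidates. A candidate with 0-based document-order rank r scores

    score(s) = w_c · Σ_{t ∈ s ∩ centroid} centroid_weight(t)
             + w_p · (N_c − r) / N_c
             + w_f · cos(s, first candidate)

with default weights (1, 1, 1). The rank origin is a genuinely open
choice; 0-based is used so the first candidate receives a full positional
score of 1. Ties everywhere are broken toward the smaller sentence id;
score comparisons quantize at 1e-12 so tie-breaking is exact and
platform-stable.

## Systems

`surface_cue` and `paragraph` are uncapped — they extract *all* citing
sentences / citing paragraphs — while `similarity`, `tfidf` and `hybrid`
take a top-n cap. The summary length n defaults to the ceiling of the
gold standard's micro-average annotated sentences per figure (8 and 11
for the two shipped benchmarks). Random baselines draw from Python's
seeded Mersenne Twister (`random.Random`), named here so the baselines
are reproducible across platforms. The `figsum_heuristic` comparator
buckets sentences into IMRaD categories by matching section headings
against keyword synonym lists (unmatched headings fall into "results"),
scores each sentence by TF-IDF cosine with the caption plus with
title+abstract (standing in for the article's central theme), and keeps
the top sentence per category; the heading heuristic replaces a trained
section classifier and is labelled an approximation.

## Evaluation protocol

Selection quality: per-figure precision/recall/F1 over sentence-id sets.
Micro aggregation pools tp/system/gold counts across figures before the
ratios; macro averages per-figure ratios and reports the population
standard deviation. Both are computed side by side because summary tables
in this literature mix the two conventions. Empty summaries contribute
zeros rather than being skipped, preventing silent inflation.

Content overlap: ROUGE-N is clipped n-gram recall (matched n-gram count
over reference n-gram count); ROUGE-SU4 uses ordered skip-bigrams with at
most four intervening tokens plus unigrams (a flag can drop the
unigrams). The per-figure protocol is sentence-best-match: each summary
sentence is scored against every gold sentence, keeps its best score, and
the figure's value is the mean over summary sentences — so it rewards
each selected sentence for its closest annotated counterpart rather than
concatenating texts. ROUGE preprocessing defaults to lowercasing with
Porter stemming and stopwords kept (the common shared-task convention);
both toggles are exposed. The Porter stemmer is implemented in-package
(classic algorithm with the author's standard amendments) and verified
against canonical word/stem pairs.

Comparison statistics: a two-sided paired t-test on per-figure scores
(t = mean(d)/(sd(d, ddof=1)/√n); identical inputs return p = 1 by
convention, a constant nonzero difference returns p = 0), and Spearman
rank correlation with average ranks for ties and a t-approximation
p-value.

## Benchmark statistics

The package ships the per-article figure and annotated-sentence counts of
the two public gold standards (GS1: 19 articles / 94 figures / 678
sentences; GS2: 17 articles / 84 figures / 869 unique sentences). The
micro average is total sentences over total figures; the macro average is
the mean of per-article sentences-per-figure values. Per-article averages
are carried at one decimal place before the macro mean, and displayed
summary averages are truncated (not rounded) to two decimals — the
reporting conventions under which the published benchmark tables are
internally consistent (e.g. 869/84 = 10.345 is reported as 10.34). This
yields micro/macro 7.21/7.73 for GS1 and 10.34/10.44 for GS2, and derived
summary lengths n = 8 and n = 11.

## Synthetic data

The generator builds articles from integer-like synthetic tokens so that
overlap arithmetic is exact: linguistic realism is explicitly not a goal.
It emulates the structural properties the summarizers depend on —
paragraph grouping, explicit citation cues drawn from the reference
grammar, disjoint per-figure topic vocabularies shared between captions
and citing sentences (`caption_topic_overlap` controls the mixing) — and
plants the gold standard by one of three rules (citing sentences, citing
paragraphs, topic-richest sentences), each making one summarizer provably
optimal. Defaults are 8 paragraphs × 5 sentences, 3 figures with 3 citing
sentences each, a 12-token topic vocabulary per figure over a 120-token
background vocabulary, and caption overlap 0.7 — sized like a short
article section so tests run in seconds while every code path (multi-
paragraph spread, ties, empty cases) is exercised. Passing tests on this
corpus demonstrate contract correctness and recovery of planted
structure; they do not certify performance on real prose, where citation
phrasing, synonymy and annotation noise are the dominant difficulties.

## Known limitations

- The headline scores published for the real 19-article benchmark require
  the deposited annotations and source articles;
  `scripts/evaluate_benchmark.py` reproduces the full grid once those are
  supplied locally in the package's formats.
- The reference grammar covers the common citation surface forms but not
  free-text mentions ("the previous figure").
- The cue lexicon is a generic stand-in, and the IMRaD bucketing of
  `figsum_heuristic` is a heading heuristic, not a trained classifier.
- BM25-style similarity is not implemented; cosine is the only similarity
  kernel.
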