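"""Unsupervised figure summarizers and baselines.

Five figure-specific systems:

* ``similarity`` — top-n sentences by cosine similarity with the caption
  (raw term counts);
* ``tfidf`` — top-n sentences by cosine similarity of TF-IDF vectors with
  the caption;
* ``surface_cue`` — all sentences that explicitly cite the figure
  ("Fig. k" cues), uncapped;
* ``paragraph`` — all sentences of every paragraph containing a citing
  sentence, uncapped;
* ``hybrid`` — sentences of citing paragraphs ranked by the centroid
  summarizer, top n.

Three baselines: ``random_sent`` (n random sentences), ``random_para``
(first sentences of n random paragraphs), ``centroid_full`` (centroid
summarizer over the whole article, identical output for every figure of
the article).  ``figsum_heuristic`` is a section-based comparator: it
buckets sentences into Introduction/Methods/Results/Discussion by a
heading-keyword heuristic and keeps the top-scoring sentence per bucket,
scoring by TF-IDF cosine with the caption plus with title+abstract.

Ranking systems break score ties (absolute tolerance 1e-12) in favor of
the smaller sentence id; random systems use Python's seeded Mersenne
Twister for cross-platform reproducibility.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass
from collections import Counter
from typing import Callable, Mapping, Sequence

from .features import (
    TfidfIndex,
    TermVector,
    build_tfidf_index,
    cosine_similarity,
    referring_paragraph_ids,
    referring_sentence_ids,
    tfidf_vector,
)
from .model import Article, FigureRecord, FigureSummary, GoldStandard
from .text import tokenize

logger = logging.getLogger(__name__)

SCORE_TOL = 1e-12

SYSTEM_NAMES = (
    "similarity", "tfidf", "surface_cue", "paragraph", "hybrid",
    "random_sent", "random_para", "centroid_full", "figsum_heuristic",
)


@dataclass(frozen=True)
class CentroidParams:
    """Parameters of the centroid summarizer.

    ``centroid_size`` is the number of top mean-TF-IDF tokens retained as
    the centroid; the three weights mix the centroid-overlap, positional,
    and first-sentence-overlap components.
    """

    centroid_size: int = 10
    weight_centroid: float = 1.0
    weight_position: float = 1.0
    weight_first_overlap: float = 1.0

    def __post_init__(self) -> None:
        if self.centroid_size < 1:
            raise ValueError("centroid_size must be >= 1")
        if (self.weight_centroid == self.weight_position == self.weight_first_overlap == 0):
            raise ValueError("centroid weights must not all be zero")


def top_n_by_score(scores: Mapping[int, float], n: int) -> list[tuple[int, float]]:
    """Top-``n`` ids by score, ties (within 1e-12) broken by smaller id.

    Quantizing the sort key to the tolerance makes tie-breaking exact and
    platform-stable.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(
        scores.items(), key=lambda kv: (-round(kv[1] / SCORE_TOL) * SCORE_TOL, kv[0])
    )
    return ranked[:n]


def _ranked_summary(
    article: Article,
    figure: FigureRecord,
    system_name: str,
    scores: Mapping[int, float],
    n: int,
) -> FigureSummary:
    return FigureSummary(
        article_id=article.article_id,
        figure_number=figure.figure_number,
        system_name=system_name,
        selected=top_n_by_score(scores, n),
    )


def summarize_similarity(
    article: Article,
    figure: FigureRecord,
    n: int,
    index: TfidfIndex | None = None,
) -> FigureSummary:
    """Top-n sentences by caption cosine similarity over raw term counts."""
    if not figure.caption.strip():
        raise ValueError(
            f"figure {figure.figure_number} has an empty caption; "
            "use surface_cue or paragraph instead"
        )
    index = index or build_tfidf_index(article)
    caption_vec = TermVector.from_counts(tokenize(figure.caption, index.tokenizer_config))
    scores = {
        s.sentence_id: cosine_similarity(
            TermVector.from_counts(index.sentence_tokens[s.sentence_id]), caption_vec
        )
        for s in article.sentences
    }
    return _ranked_summary(article, figure, "similarity", scores, n)


def summarize_tfidf(
    article: Article,
    figure: FigureRecord,
    n: int,
    index: TfidfIndex | None = None,
) -> FigureSummary:
    """Top-n sentences by caption cosine similarity over TF-IDF vectors."""
    if not figure.caption.strip():
        raise ValueError(
            f"figure {figure.figure_number} has an empty caption; "
            "use surface_cue or paragraph instead"
        )
    index = index or build_tfidf_index(article)
    caption_vec = tfidf_vector(tokenize(figure.caption, index.tokenizer_config), index)
    scores = {
        s.sentence_id: cosine_similarity(
            tfidf_vector(index.sentence_tokens[s.sentence_id], index), caption_vec
        )
        for s in article.sentences
    }
    return _ranked_summary(article, figure, "tfidf", scores, n)


def summarize_surface_cue(article: Article, figure: FigureRecord) -> FigureSummary:
    """All sentences explicitly citing the figure, document order, uncapped."""
    ids = referring_sentence_ids(article, figure.figure_number)
    if not ids:
        logger.info(
            "article %r: no sentence cites figure %d; surface_cue summary is empty",
            article.article_id, figure.figure_number,
        )
    return FigureSummary(
        article_id=article.article_id,
        figure_number=figure.figure_number,
        system_name="surface_cue",
        selected=[(sid, None) for sid in ids],
    )


def summarize_paragraph(article: Article, figure: FigureRecord) -> FigureSummary:
    """All sentences of every paragraph citing the figure, uncapped."""
    paragraphs = referring_paragraph_ids(article, figure.figure_number)
    ids = [s.sentence_id for s in article.sentences if s.paragraph_id in paragraphs]
    return FigureSummary(
        article_id=article.article_id,
        figure_number=figure.figure_number,
        system_name="paragraph",
        selected=[(sid, None) for sid in ids],
    )


def centroid_scores(
    candidate_sentence_ids: Sequence[int],
    article: Article,
    index: TfidfIndex | None = None,
    params: CentroidParams = CentroidParams(),
) -> dict[int, float]:
    """Centroid-summarizer scores over a candidate sentence set.

    The centroid is the ``centroid_size`` tokens with highest mean TF-IDF
    weight across the candidates (ties by token string).  Each candidate's
    score combines three weighted components: the summed centroid weight
    of its distinct centroid tokens, a positional score ``(N_c - rank)/N_c``
    with 0-based rank among candidates in document order (first candidate
    scores 1), and the count-vector cosine with the first candidate.
    """
    if not candidate_sentence_ids:
        raise ValueError("candidate sentence set is empty")
    index = index or build_tfidf_index(article)
    candidates = sorted(set(candidate_sentence_ids))
    n_c = len(candidates)

    # mean tf-idf weight of each token across candidate sentences
    totals: Counter[str] = Counter()
    for sid in candidates:
        for tok, cnt in Counter(index.sentence_tokens[sid]).items():
            totals[tok] += cnt * index.idf(tok)
    mean_weight = {tok: w / n_c for tok, w in totals.items()}
    centroid = dict(
        sorted(mean_weight.items(), key=lambda kv: (-kv[1], kv[0]))[: params.centroid_size]
    )

    first_vec = TermVector.from_counts(index.sentence_tokens[candidates[0]])
    scores: dict[int, float] = {}
    for rank, sid in enumerate(candidates):
        tokens = set(index.sentence_tokens[sid])
        c_score = sum(w for tok, w in centroid.items() if tok in tokens)
        p_score = (n_c - rank) / n_c
        f_score = cosine_similarity(
            TermVector.from_counts(index.sentence_tokens[sid]), first_vec
        )
        scores[sid] = (
            params.weight_centroid * c_score
            + params.weight_position * p_score
            + params.weight_first_overlap * f_score
        )
    return scores


def summarize_hybrid(
    article: Article,
    figure: FigureRecord,
    n: int,
    params: CentroidParams = CentroidParams(),
    index: TfidfIndex | None = None,
) -> FigureSummary:
    """Centroid-ranked top-n sentences of the figure's citing paragraphs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    index = index or build_tfidf_index(article)
    paragraphs = referring_paragraph_ids(article, figure.figure_number)
    candidates = [s.sentence_id for s in article.sentences if s.paragraph_id in paragraphs]
    if not candidates:
        return FigureSummary(
            article_id=article.article_id,
            figure_number=figure.figure_number,
            system_name="hybrid",
            selected=[],
        )
    scores = centroid_scores(candidates, article, index, params)
    return _ranked_summary(article, figure, "hybrid", scores, n)


def baseline_random_sent(
    article: Article, figure: FigureRecord, n: int, seed: int
) -> FigureSummary:
    """n distinct sentences sampled uniformly without replacement (seeded)."""
    rng = random.Random(seed)
    ids = [s.sentence_id for s in article.sentences]
    k = min(n, len(ids))
    chosen = sorted(rng.sample(ids, k))
    return FigureSummary(
        article_id=article.article_id,
        figure_number=figure.figure_number,
        system_name="random_sent",
        selected=[(sid, None) for sid in chosen],
    )


def baseline_random_para(
    article: Article, figure: FigureRecord, n: int, seed: int
) -> FigureSummary:
    """First sentences of n uniformly sampled paragraphs (seeded)."""
    rng = random.Random(seed)
    paragraphs = article.paragraphs
    if n > len(paragraphs):
        logger.info(
            "article %r: requested %d paragraphs but only %d exist; using all",
            article.article_id, n, len(paragraphs),
        )
    k = min(n, len(paragraphs))
    chosen = rng.sample(range(len(paragraphs)), k)
    first_ids = sorted(paragraphs[i][1].start for i in chosen)
    return FigureSummary(
        article_id=article.article_id,
        figure_number=figure.figure_number,
        system_name="random_para",
        selected=[(sid, None) for sid in first_ids],
    )


def baseline_centroid_full(
    article: Article,
    figure: FigureRecord,
    n: int,
    params: CentroidParams = CentroidParams(),
    index: TfidfIndex | None = None,
) -> FigureSummary:
    """Centroid summarizer over all candidate sentences; figure-independent."""
    index = index or build_tfidf_index(article)
    all_ids = [s.sentence_id for s in article.sentences]
    scores = centroid_scores(all_ids, article, index, params)
    summary = _ranked_summary(article, figure, "centroid_full", scores, n)
    return summary


# ---------------------------------------------------------------------------
# section-based comparator

_IMRAD_KEYWORDS = {
    "introduction": ("introduction", "background",),
    "methods": ("method", "material", "experimental", "study design", "patients"),
    "results": ("result", "finding",),
    "discussion": ("discussion", "conclusion", "summary", "limitations"),
}


def _imrad_category(section_label: str | None) -> str:
    if section_label:
        low = section_label.lower()
        for category, keys in _IMRAD_KEYWORDS.items():
            if any(k in low for k in keys):
                return category
    return "results"


def baseline_figsum(
    article: Article,
    figure: FigureRecord,
    weights: tuple[float, float] = (1.0, 1.0),
    index: TfidfIndex | None = None,
) -> FigureSummary:
    """Section-based comparator: best sentence per IMRaD category.

    Sentences are bucketed by matching their section heading against
    documented keyword lists (unheaded sections fall into "results"); each
    is scored ``w1 * cos_tfidf(s, caption) + w2 * cos_tfidf(s, title +
    abstract)``, the title+abstract vector standing in for the article's
    central theme, and the top sentence per category (at most four
    sentences) forms the summary.
    """
    index = index or build_tfidf_index(article)
    if all(s.section_label is None for s in article.sentences):
        logger.info(
            "article %r has no section headings; all sentences fall in one category",
            article.article_id,
        )
    config = index.tokenizer_config
    caption_vec = tfidf_vector(tokenize(figure.caption, config), index)
    theme_text = article.title + " " + (article.abstract or "")
    theme_vec = tfidf_vector(tokenize(theme_text, config), index)
    w1, w2 = weights

    best: dict[str, tuple[float, int]] = {}
    for s in article.sentences:
        vec = tfidf_vector(index.sentence_tokens[s.sentence_id], index)
        score = w1 * cosine_similarity(vec, caption_vec) + w2 * cosine_similarity(vec, theme_vec)
        category = _imrad_category(s.section_label)
        incumbent = best.get(category)
        if incumbent is None or score > incumbent[0] + SCORE_TOL:
            best[category] = (score, s.sentence_id)
    ranked = sorted(((sc, sid) for sc, sid in best.values()), key=lambda t: (-t[0], t[1]))
    return FigureSummary(
        article_id=article.article_id,
        figure_number=figure.figure_number,
        system_name="figsum_heuristic",
        selected=[(sid, sc) for sc, sid in ranked],
    )


def default_n(gold: GoldStandard | float) -> int:
    """Summary length n: the ceiling of the gold standard's micro-average
    number of annotated sentences per figure."""
    if isinstance(gold, GoldStandard):
        if not gold.entries:
            raise ValueError("empty gold standard")
        micro = sum(len(ids) for ids in gold.entries.values()) / len(gold.entries)
    else:
        micro = float(gold)
    if micro <= 0:
        raise ValueError("micro average must be positive")
    return math.ceil(micro)


# ---------------------------------------------------------------------------
# dispatch

Summarizer = Callable[..., FigureSummary]


def summarize(
    system_name: str,
    article: Article,
    figure: FigureRecord,
    n: int | None = None,
    seed: int | None = None,
    params: CentroidParams = CentroidParams(),
    index: TfidfIndex | None = None,
) -> FigureSummary:
    """Run a summarizer selected by name (see :data:`SYSTEM_NAMES`)."""
    if system_name not in SYSTEM_NAMES:
        raise ValueError(
            f"unknown system {system_name!r}; valid names: {', '.join(SYSTEM_NAMES)}"
        )
    if system_name in ("random_sent", "random_para") and seed is None:
        raise ValueError(f"system {system_name!r} requires a seed")
    needs_n = system_name in (
        "similarity", "tfidf", "hybrid", "random_sent", "random_para", "centroid_full"
    )
    if needs_n and (n is None or n < 1):
        raise ValueError(f"system {system_name!r} requires n >= 1")
    if system_name == "similarity":
        return summarize_similarity(article, figure, n, index)
    if system_name == "tfidf":
        return summarize_tfidf(article, figure, n, index)
    if system_name == "surface_cue":
        return summarize_surface_cue(article, figure)
    if system_name == "paragraph":
        return summarize_paragraph(article, figure)
    if system_name == "hybrid":
        return summarize_hybrid(article, figure, n, params, index)
    if system_name == "random_sent":
        return baseline_random_sent(article, figure, n, seed)
    if system_name == "random_para":
        return baseline_random_para(article, figure, n, seed)
    if system_name == "centroid_full":
        return baseline_centroid_full(article, figure, n, params, index)
    return baseline_figsum(article, figure, index=index)
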