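"""Published statistics of the figure-summarization benchmark annotations.

The public benchmark ("Figure_Associated_Text_Summarization_and_Evaluation"
on figshare) annotates figures of 19 full-text biomedical articles with
the sentences that summarize each figure, under two annotation guidelines:

* **GS1** — biologists selected summarizing sentences for all 94 figures
  of the 19 articles (678 annotated sentences);
* **GS2** — seven annotators selected background/method/outcome/conclusion
  sentences for the 84 figures of a 17-article subset (869 unique
  sentences).

This module ships the per-article figure and annotated-sentence counts of
that benchmark so dataset-level statistics (totals, micro/macro averages,
and the derived summary length *n*) can be recomputed without the full
text corpus.  Per-article entries are ``(figure_count, sentence_count)``.
"""

from __future__ import annotations

from .evaluate import DatasetStatistics, dataset_statistics_from_counts
from .summarize import default_n

#: GS1: per-article (figures, annotated sentences) for articles 1..19.
GS1_COUNTS: dict[str, tuple[int, int]] = {
    "1": (3, 15), "2": (3, 54), "3": (7, 35), "4": (5, 43), "5": (4, 51),
    "6": (5, 42), "7": (9, 70), "8": (9, 42), "9": (5, 31), "10": (5, 32),
    "11": (6, 36), "12": (2, 15), "13": (3, 24), "14": (3, 15), "15": (3, 37),
    "16": (5, 46), "17": (7, 36), "18": (4, 25), "19": (6, 29),
}

#: GS2: per-article (figures, unique annotated sentences) for the
#: 17-article subset (articles 18 and 19 were not annotated).
GS2_COUNTS: dict[str, tuple[int, int]] = {
    "1": (3, 35), "2": (3, 35), "3": (7, 56), "4": (5, 51), "5": (4, 42),
    "6": (5, 54), "7": (9, 106), "8": (9, 57), "9": (5, 56), "10": (5, 42),
    "11": (6, 58), "12": (2, 12), "13": (3, 33), "14": (3, 38), "15": (3, 33),
    "16": (5, 62), "17": (7, 99),
}

#: number of body sentences per article (for article-length correlations)
ARTICLE_SENTENCE_COUNTS: dict[str, int] = {
    "1": 190, "2": 144, "3": 173, "4": 160, "5": 172, "6": 140, "7": 281,
    "8": 137, "9": 142, "10": 87, "11": 162, "12": 34, "13": 50, "14": 138,
    "15": 119, "16": 120, "17": 152, "18": 157, "19": 184,
}


def gs1_statistics() -> DatasetStatistics:
    """Dataset statistics of the GS1 benchmark annotations."""
    return dataset_statistics_from_counts(GS1_COUNTS)


def gs2_statistics() -> DatasetStatistics:
    """Dataset statistics of the GS2 benchmark annotations."""
    return dataset_statistics_from_counts(GS2_COUNTS)


def benchmark_default_n(dataset: str = "GS1") -> int:
    """The top-n summary length derived from a benchmark gold standard."""
    stats = gs1_statistics() if dataset.upper() == "GS1" else gs2_statistics()
    return default_n(stats.micro_average)
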