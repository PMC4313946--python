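"""Intrinsic evaluation: P/R/F1, sentence-best-match ROUGE, aggregation.

Sentence-selection quality is scored per figure by precision, recall and
F1 over annotated sentence ids:

    R = tp / |gold|,  P = tp / |system|,  F1 = 2PR / (P + R)

Content overlap is scored by a recall-oriented ROUGE variant: ROUGE-N is
clipped n-gram match count over reference n-gram count, and ROUGE-SU4
uses skip-bigrams with a maximum gap of four plus unigrams.  The
per-figure protocol matches each system sentence against every gold
sentence, keeps each system sentence's best score, and averages the best
scores over the summary ("sentence-best-match" averaging).

Aggregation is micro (pool tp/system/gold counts across figures, then
apply the formulas) or macro (average per-figure values, with population
standard deviation).  ROUGE tokenization defaults to lowercasing with
Porter stemming and stopwords kept; all toggles are exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .model import Article, FigureSummary, GoldStandard
from .text import ROUGE_CONFIG, TokenizerConfig, tokenize

ROUGE_METRICS = ("R1", "R2", "RSU4")


@dataclass(frozen=True)
class PRF:
    """Precision/recall/F1 with the underlying counts."""

    tp: int
    system_count: int
    gold_count: int

    @property
    def precision(self) -> float:
        return self.tp / self.system_count if self.system_count else 0.0

    @property
    def recall(self) -> float:
        return self.tp / self.gold_count if self.gold_count else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def prf(system_ids: set[int], gold_ids: set[int]) -> PRF:
    """Sentence-selection P/R/F1 of a system set against a gold set."""
    return PRF(
        tp=len(system_ids & gold_ids),
        system_count=len(system_ids),
        gold_count=len(gold_ids),
    )


@dataclass(frozen=True)
class AggregatePRF:
    """Aggregated P/R/F1 with dispersion (macro mode only)."""

    precision: float
    recall: float
    f1: float
    precision_sd: float = 0.0
    recall_sd: float = 0.0
    f1_sd: float = 0.0
    mode: str = "micro"
    n_figures: int = 0


def aggregate(per_figure: Sequence[PRF], mode: str = "micro") -> AggregatePRF:
    """Pool (micro) or average (macro) per-figure P/R/F1.

    Micro sums tp/system/gold counts across figures before applying the
    ratio formulas; macro averages the per-figure ratios and reports the
    population standard deviation.
    """
    if not per_figure:
        raise ValueError("no per-figure scores to aggregate")
    if mode == "micro":
        pooled = PRF(
            tp=sum(p.tp for p in per_figure),
            system_count=sum(p.system_count for p in per_figure),
            gold_count=sum(p.gold_count for p in per_figure),
        )
        return AggregatePRF(
            precision=pooled.precision, recall=pooled.recall, f1=pooled.f1,
            mode="micro", n_figures=len(per_figure),
        )
    if mode == "macro":
        ps = np.array([p.precision for p in per_figure])
        rs = np.array([p.recall for p in per_figure])
        fs = np.array([p.f1 for p in per_figure])
        return AggregatePRF(
            precision=float(ps.mean()), recall=float(rs.mean()), f1=float(fs.mean()),
            precision_sd=float(ps.std()), recall_sd=float(rs.std()), f1_sd=float(fs.std()),
            mode="macro", n_figures=len(per_figure),
        )
    raise ValueError(f"unknown aggregation mode {mode!r}")


# ---------------------------------------------------------------------------
# ROUGE


def ngram_multiset(tokens: Sequence[str], n: int) -> Counter:
    """All contiguous n-token windows with multiplicity."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def skip_bigram_multiset(
    tokens: Sequence[str], max_gap: int = 4, include_unigrams: bool = True
) -> Counter:
    """Ordered token pairs with at most ``max_gap`` intervening tokens.

    With ``include_unigrams`` the single tokens are added as well (the
    "SU" in ROUGE-SU4).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    grams: Counter = Counter()
    for i in range(len(tokens)):
        for j in range(i + 1, min(i + max_gap + 2, len(tokens))):
            grams[(tokens[i], tokens[j])] += 1
    if include_unigrams:
        for t in tokens:
            grams[(t,)] += 1
    return grams


@dataclass(frozen=True)
class RougeScore:
    metric: str
    value: float
    match_count: int
    reference_count: int


def _grams(tokens: Sequence[str], metric: str) -> Counter:
    if metric == "R1":
        return ngram_multiset(tokens, 1)
    if metric == "R2":
        return ngram_multiset(tokens, 2)
    if metric == "RSU4":
        return skip_bigram_multiset(tokens, max_gap=4, include_unigrams=True)
    raise ValueError(f"unknown ROUGE metric {metric!r} (expected R1, R2 or RSU4)")


def rouge_n(
    candidate_tokens: Sequence[str],
    reference_token_lists: Sequence[Sequence[str]],
    n: int,
) -> RougeScore:
    """Clipped n-gram recall of a candidate against reference(s)."""
    cand = ngram_multiset(candidate_tokens, n)
    match = total = 0
    for ref_tokens in reference_token_lists:
        ref = ngram_multiset(ref_tokens, n)
        total += sum(ref.values())
        match += sum(min(c, cand[g]) for g, c in ref.items())
    return RougeScore(
        metric=f"R{n}",
        value=match / total if total else 0.0,
        match_count=match,
        reference_count=total,
    )


def rouge_metric(
    candidate_tokens: Sequence[str],
    reference_token_lists: Sequence[Sequence[str]],
    metric: str,
) -> RougeScore:
    """ROUGE-1, ROUGE-2 or ROUGE-SU4 clipped recall."""
    if metric in ("R1", "R2"):
        return rouge_n(candidate_tokens, reference_token_lists, 1 if metric == "R1" else 2)
    cand = _grams(candidate_tokens, metric)
    match = total = 0
    for ref_tokens in reference_token_lists:
        ref = _grams(ref_tokens, metric)
        total += sum(ref.values())
        match += sum(min(c, cand[g]) for g, c in ref.items())
    return RougeScore(
        metric=metric,
        value=match / total if total else 0.0,
        match_count=match,
        reference_count=total,
    )


def figure_rouge(
    summary_sentences: Sequence[str],
    gold_sentences: Sequence[str],
    metric: str = "R1",
    config: TokenizerConfig = ROUGE_CONFIG,
) -> float:
    """Sentence-best-match ROUGE for one figure.

    Each summary sentence is scored against every gold sentence; its best
    score is kept, and the mean of the best scores over the summary is
    returned.  An empty summary scores 0.
    """
    if not gold_sentences:
        raise ValueError("empty gold sentence set")
    if not summary_sentences:
        return 0.0
    gold_tokens = [tokenize(g, config) for g in gold_sentences]
    best_scores = []
    for sent in summary_sentences:
        cand = tokenize(sent, config)
        best = max(rouge_metric(cand, [g], metric).value for g in gold_tokens)
        best_scores.append(best)
    return float(np.mean(best_scores))


# ---------------------------------------------------------------------------
# report


@dataclass
class FigureResult:
    """Scores of one system on one figure."""

    article_id: str
    figure_number: int
    system: str
    prf: PRF
    rouge: dict[str, float] = field(default_factory=dict)


@dataclass
class EvaluationReport:
    """Per-figure results plus micro/macro aggregates per system."""

    per_figure: list[FigureResult]

    def results_for(self, system: str) -> list[FigureResult]:
        return [r for r in self.per_figure if r.system == system]

    @property
    def systems(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.per_figure:
            seen.setdefault(r.system, None)
        return list(seen)

    def aggregate_prf(self, system: str, mode: str) -> AggregatePRF:
        return aggregate([r.prf for r in self.results_for(system)], mode)

    def aggregate_rouge(self, system: str, metric: str) -> tuple[float, float]:
        """Mean ± population sd of the per-figure ROUGE values."""
        vals = np.array([r.rouge[metric] for r in self.results_for(system)])
        if vals.size == 0:
            raise ValueError(f"no results for system {system!r}")
        return float(vals.mean()), float(vals.std())

    def to_rows(self) -> list[dict[str, object]]:
        rows: list[dict[str, object]] = []
        for r in self.per_figure:
            row: dict[str, object] = {
                "article_id": r.article_id,
                "figure_number": r.figure_number,
                "system": r.system,
                "precision": r.prf.precision,
                "recall": r.prf.recall,
                "f1": r.prf.f1,
                "tp": r.prf.tp,
                "system_count": r.prf.system_count,
                "gold_count": r.prf.gold_count,
            }
            row.update(r.rouge)
            rows.append(row)
        return rows

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(self.to_rows()).to_csv(path, sep="\t", index=False)

    def to_json(self, path: str) -> None:
        import json

        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_rows(), fh, indent=2)
            fh.write("\n")


def evaluate_summaries(
    summaries: Iterable[FigureSummary],
    gold: GoldStandard,
    articles: Mapping[str, Article],
    rouge_metrics: Sequence[str] = ROUGE_METRICS,
    rouge_config: TokenizerConfig = ROUGE_CONFIG,
) -> EvaluationReport:
    """Score each summary against the gold standard.

    P/R/F1 compares sentence-id sets.  ROUGE compares summary sentence
    texts against the gold sentence texts (the annotated sentences, or the
    free-text references when the gold standard carries them).  Empty
    summaries contribute zeros rather than being skipped.
    """
    results: list[FigureResult] = []
    for summary in summaries:
        key = (summary.article_id, summary.figure_number)
        if key not in gold.entries:
            raise ValueError(
                f"gold standard has no entry for article {key[0]!r} figure {key[1]}"
            )
        article = articles[summary.article_id]
        gold_ids = gold.entries[key]
        p = prf(summary.sentence_ids, gold_ids)
        refs = gold.reference_texts.get(key) or [
            article.sentences[i].text for i in sorted(gold_ids)
        ]
        summary_texts = [article.sentences[i].text for i in summary.document_order_ids]
        rouge = {
            m: figure_rouge(summary_texts, refs, m, rouge_config) for m in rouge_metrics
        }
        results.append(
            FigureResult(
                article_id=summary.article_id,
                figure_number=summary.figure_number,
                system=summary.system_name,
                prf=p,
                rouge=rouge,
            )
        )
    return EvaluationReport(per_figure=results)


# ---------------------------------------------------------------------------
# dataset statistics


@dataclass(frozen=True)
class DatasetStatistics:
    """Totals and averages of a gold standard over its articles.

    ``micro_average`` pools annotated sentences over all figures;
    ``macro_average`` is the mean of per-article sentences-per-figure
    averages.  Per-article averages are carried at one decimal place (the
    precision at which such per-article tables are reported) before the
    macro mean; :func:`format_average` truncates displayed summary
    averages to two decimals.
    """

    total_sentences: int
    total_figures: int
    micro_average: float
    macro_average: float
    per_article: dict[str, tuple[int, int, float]]  # id -> (figures, sentences, avg)


def format_average(value: float, decimals: int = 2) -> str:
    """Truncate (not round) an average for display."""
    factor = 10 ** decimals
    return f"{math.floor(value * factor) / factor:.{decimals}f}"


def dataset_statistics_from_counts(
    per_article_counts: Mapping[str, tuple[int, int]],
) -> DatasetStatistics:
    """Statistics from per-article ``(figure_count, annotated_sentence_count)``."""
    if not per_article_counts:
        raise ValueError("no articles")
    per_article: dict[str, tuple[int, int, float]] = {}
    total_figures = total_sentences = 0
    for article_id, (figs, sents) in per_article_counts.items():
        if figs < 1:
            raise ValueError(f"article {article_id!r}: figure count must be >= 1")
        avg = round(sents / figs, 1)
        per_article[article_id] = (figs, sents, avg)
        total_figures += figs
        total_sentences += sents
    return DatasetStatistics(
        total_sentences=total_sentences,
        total_figures=total_figures,
        micro_average=total_sentences / total_figures,
        macro_average=float(np.mean([a for (_, _, a) in per_article.values()])),
        per_article=per_article,
    )


def dataset_statistics(
    gold: GoldStandard, articles: Mapping[str, Article] | None = None
) -> DatasetStatistics:
    """Statistics of a gold standard (optionally validated against articles)."""
    if not gold.entries:
        raise ValueError("empty gold standard")
    if articles is not None:
        gold.validate_against(dict(articles))
    counts: dict[str, tuple[int, int]] = {}
    for (article_id, _fig), ids in gold.entries.items():
        figs, sents = counts.get(article_id, (0, 0))
        counts[article_id] = (figs + 1, sents + len(ids))
    return dataset_statistics_from_counts(counts)


def bootstrap_ci(
    per_figure_values: Sequence[float],
    n_resamples: int = 1000,
    confidence: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for a mean per-figure score.

    Optional companion to the point estimates: resamples figures with
    replacement ``n_resamples`` times and returns the central
    ``confidence`` interval of the resampled means.
    """
    if not per_figure_values:
        raise ValueError("no per-figure values")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    values = np.asarray(per_figure_values, dtype=float)
    means = rng.choice(values, size=(n_resamples, values.size), replace=True).mean(axis=1)
    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# comparison statistics


def paired_t_test(scores_a: Sequence[float], scores_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on per-figure scores.

    ``t = mean(d) / (sd(d, ddof=1) / sqrt(n))`` over the paired
    differences.  Identical inputs return ``(0, 1)`` by convention; a
    constant nonzero difference returns ``(±inf, 0)``.
    """
    if len(scores_a) != len(scores_b):
        raise ValueError("paired score lists must have equal length")
    if len(scores_a) < 2:
        raise ValueError("need at least 2 paired scores")
    d = np.asarray(scores_a, dtype=float) - np.asarray(scores_b, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, d.mean()), 0.0
    t = d.mean() / (sd / math.sqrt(len(d)))
    p = 2 * _sps.t.sf(abs(t), df=len(d) - 1)
    return float(t), float(p)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses the t approximation
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` with n-2 degrees of freedom.
    """
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("rank correlation is undefined for a constant vector")
    rho, p = _sps.spearmanr(np.asarray(x, float), np.asarray(y, float))
    return float(rho), float(p)
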