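"""Sentence-level features for figure summarization.

For each (sentence, figure) pair within one article the extractor
computes:

* IR features — cosine similarity of the sentence with the figure caption
  and the article title over raw term-count vectors, with the caption over
  TF-IDF vectors, and with the figure-referring sentences (max-aggregated);
* surface-cue features — whether the sentence itself refers to the figure
  ("Fig. 2"-style cues) and whether its paragraph contains a referring
  sentence;
* a hybrid feature — the centroid-summarizer score of the sentence
  restricted to figure-referring paragraphs;
* positional features — distance from article start/end and proximity
  (within 10 sentences) to a referring sentence;
* sentence length in tokens and presence of a generic cue word/phrase.

TF-IDF treats the candidate sentences of one article as the document
collection: ``weight(t) = tf(t) * ln((N + 1) / (df(t) + 1))`` with ``N``
the number of candidate sentences.  The add-one smoothing keeps weights
finite for caption-only terms and sends terms occurring in every sentence
to exactly zero.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Mapping

from .lexicon import DEFAULT_CUE_LEXICON
from .model import Article, FigureRecord
from .text import SIMILARITY_CONFIG, TokenizerConfig, tokenize


@dataclass(frozen=True)
class TermVector:
    """Sparse non-negative term-weight vector with a cached Euclidean norm."""

    weights: Mapping[str, float]
    norm: float = field(default=0.0)

    @staticmethod
    def from_weights(weights: Mapping[str, float]) -> "TermVector":
        weights = {t: w for t, w in weights.items() if w != 0.0}
        if any(w < 0 for w in weights.values()):
            raise ValueError("term weights must be non-negative")
        return TermVector(weights, math.sqrt(sum(w * w for w in weights.values())))

    @staticmethod
    def from_counts(tokens: Iterable[str]) -> "TermVector":
        return TermVector.from_weights(Counter(tokens))


def cosine_similarity(v1: TermVector, v2: TermVector) -> float:
    """Cosine of the angle between two term vectors; 0 if either is zero."""
    if v1.norm == 0.0 or v2.norm == 0.0:
        return 0.0
    if len(v1.weights) > len(v2.weights):
        v1, v2 = v2, v1
    dot = sum(w * v2.weights.get(t, 0.0) for t, w in v1.weights.items())
    return min(1.0, dot / (v1.norm * v2.norm))


@dataclass
class TfidfIndex:
    """Per-article TF-IDF statistics (sentences are the documents).

    ``document_count`` is the number of candidate sentences N;
    ``document_frequency`` maps each token to the number of sentences
    containing it at least once.
    """

    document_count: int
    document_frequency: dict[str, int]
    tokenizer_config: TokenizerConfig = SIMILARITY_CONFIG
    sentence_tokens: list[list[str]] = field(default_factory=list)

    def idf(self, token: str) -> float:
        df = self.document_frequency.get(token, 0)
        return math.log((self.document_count + 1) / (df + 1))


def build_tfidf_index(article: Article, config: TokenizerConfig = SIMILARITY_CONFIG) -> TfidfIndex:
    """Build the per-article TF-IDF index over candidate sentences."""
    if not article.sentences:
        raise ValueError(f"article {article.article_id!r} has no candidate sentences")
    sentence_tokens = [tokenize(s.text, config) for s in article.sentences]
    df: Counter[str] = Counter()
    for tokens in sentence_tokens:
        df.update(set(tokens))
    return TfidfIndex(
        document_count=len(article.sentences),
        document_frequency=dict(df),
        tokenizer_config=config,
        sentence_tokens=sentence_tokens,
    )


def tfidf_vector(token_list: Iterable[str], index: TfidfIndex) -> TermVector:
    """TF-IDF vector of a token list under ``index``'s smoothed idf."""
    tf = Counter(token_list)
    return TermVector.from_weights({t: c * index.idf(t) for t, c in tf.items()})


# ---------------------------------------------------------------------------
# figure reference detection

# head: "Fig" / "Figs" / "Figure" / "Figures", optional period; then a list of
# numbers (panel letters allowed) joined by commas, "and"/"&", or dash ranges.
_NUMLIST = r"\d+[A-Za-z]?(?:\s*(?:[-–—]|,|and\b|&)\s*\d+[A-Za-z]?)*"
_REF_RE = re.compile(
    rf"\bfig(?:ure)?(?P<plural>s)?\b\.?\s*\(?\s*(?P<nums>{_NUMLIST})",
    re.IGNORECASE,
)
_NUM_ITEM_RE = re.compile(r"(\d+)[A-Za-z]?")
_RANGE_RE = re.compile(r"(\d+)[A-Za-z]?\s*[-–—]\s*(\d+)[A-Za-z]?")


def detect_figure_references(sentence_text: str, figure_numbers: set[int]) -> set[int]:
    """Figure numbers of ``figure_numbers`` explicitly cited in the sentence.

    Handles "Fig. 2", "Figure 2A" (panel letters map to the figure number),
    comma/"and" lists, dash ranges ("Figs. 1-3"), parentheses, any case.
    Word boundaries prevent false hits inside words like "configure".
    """
    found: set[int] = set()
    for m in _REF_RE.finditer(sentence_text):
        numtext = m.group("nums")
        for rm in _RANGE_RE.finditer(numtext):
            lo, hi = int(rm.group(1)), int(rm.group(2))
            if lo <= hi:
                found.update(range(lo, hi + 1))
        for im in _NUM_ITEM_RE.finditer(numtext):
            found.add(int(im.group(1)))
    return found & figure_numbers


def referring_sentence_ids(article: Article, figure_number: int) -> list[int]:
    """Sentence ids of the article that cite the given figure."""
    fignums = article.figure_numbers or {figure_number}
    return [
        s.sentence_id
        for s in article.sentences
        if figure_number in detect_figure_references(s.text, fignums)
    ]


def referring_paragraph_ids(article: Article, figure_number: int) -> set[int]:
    """Paragraph ids containing at least one sentence citing the figure."""
    refs = referring_sentence_ids(article, figure_number)
    return {article.sentences[i].paragraph_id for i in refs}


# ---------------------------------------------------------------------------
# aggregate feature vector


@dataclass(frozen=True)
class FeatureVector:
    """All per-(sentence, figure) features; see module docstring."""

    caption_similarity: float
    title_similarity: float
    reference_sentence_similarity: float
    tfidf_score: float
    is_reference_sentence: bool
    in_reference_paragraph: bool
    hybrid_score: float
    distance_from_start: int
    distance_from_end: int
    within_10_of_reference: bool
    sentence_length: int
    has_cue_word: bool

    FIELDS = (
        "caption_similarity", "title_similarity", "reference_sentence_similarity",
        "tfidf_score", "is_reference_sentence", "in_reference_paragraph",
        "hybrid_score", "distance_from_start", "distance_from_end",
        "within_10_of_reference", "sentence_length", "has_cue_word",
    )


def _has_cue(sentence_text: str, cue_lexicon: Iterable[str]) -> bool:
    lowered = " ".join(re.findall(r"[a-z0-9]+", sentence_text.lower()))
    padded = f" {lowered} "
    return any(f" {cue} " in padded for cue in cue_lexicon)


def compute_features(
    article: Article,
    figure: FigureRecord,
    index: TfidfIndex | None = None,
    cue_lexicon: Iterable[str] | None = None,
    reference_window: int = 10,
) -> dict[int, FeatureVector]:
    """Compute a complete :class:`FeatureVector` per candidate sentence.

    ``reference_sentence_similarity`` is the maximum cosine similarity to
    any sentence citing this figure (0 if none).  ``hybrid_score`` is the
    centroid-summarizer score restricted to figure-referring paragraphs
    (0 for sentences outside them).
    """
    if figure.figure_number not in article.figure_numbers:
        raise KeyError(
            f"figure {figure.figure_number} does not belong to article {article.article_id!r}"
        )
    if index is None:
        index = build_tfidf_index(article)
    cues = [" ".join(tokenize(c, TokenizerConfig(False, False))) for c in
            (cue_lexicon if cue_lexicon is not None else DEFAULT_CUE_LEXICON)]

    config = index.tokenizer_config
    n = len(article.sentences)
    count_vectors = [TermVector.from_counts(toks) for toks in index.sentence_tokens]
    tfidf_vectors = [tfidf_vector(toks, index) for toks in index.sentence_tokens]
    caption_counts = TermVector.from_counts(tokenize(figure.caption, config))
    caption_tfidf = tfidf_vector(tokenize(figure.caption, config), index)
    title_counts = TermVector.from_counts(tokenize(article.title, config))

    ref_ids = referring_sentence_ids(article, figure.figure_number)
    ref_paragraphs = {article.sentences[i].paragraph_id for i in ref_ids}
    ref_set = set(ref_ids)

    # hybrid: centroid scores over sentences of referring paragraphs
    from .summarize import CentroidParams, centroid_scores  # local import: avoids cycle

    hybrid_candidates = [
        s.sentence_id for s in article.sentences if s.paragraph_id in ref_paragraphs
    ]
    hybrid = (
        centroid_scores(hybrid_candidates, article, index, CentroidParams())
        if hybrid_candidates
        else {}
    )

    out: dict[int, FeatureVector] = {}
    for s in article.sentences:
        sid = s.sentence_id
        ref_sim = max(
            (cosine_similarity(count_vectors[sid], count_vectors[r]) for r in ref_ids),
            default=0.0,
        )
        out[sid] = FeatureVector(
            caption_similarity=cosine_similarity(count_vectors[sid], caption_counts),
            title_similarity=cosine_similarity(count_vectors[sid], title_counts),
            reference_sentence_similarity=ref_sim,
            tfidf_score=cosine_similarity(tfidf_vectors[sid], caption_tfidf),
            is_reference_sentence=sid in ref_set,
            in_reference_paragraph=s.paragraph_id in ref_paragraphs,
            hybrid_score=hybrid.get(sid, 0.0),
            distance_from_start=sid,
            distance_from_end=n - 1 - sid,
            within_10_of_reference=any(abs(sid - r) <= reference_window for r in ref_ids),
            sentence_length=max(1, len(tokenize(s.text, TokenizerConfig(False, False)))),
            has_cue_word=_has_cue(s.text, cues),
        )
    return out


def features_to_tsv(features: Mapping[int, FeatureVector], path: str) -> None:
    """Export a feature matrix as TSV (header = feature names)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sentence_id\t" + "\t".join(FeatureVector.FIELDS) + "\n")
        for sid in sorted(features):
            fv = features[sid]
            row = [str(sid)] + [
                f"{getattr(fv, name):.6g}" if isinstance(getattr(fv, name), float)
                else str(int(getattr(fv, name)))
                for name in FeatureVector.FIELDS
            ]
            fh.write("\t".join(row) + "\n")
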