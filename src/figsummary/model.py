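"""Core data model for figure summarization.

An :class:`Article` is an ordered stream of :class:`Sentence` objects grouped
into contiguous paragraphs, together with the figures (label + caption) that
appear in it.  Figure captions are *not* part of the candidate sentence
stream: a figure summary complements the caption rather than repeating it.

All indices are 0-based; character spans are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class FormatError(ValueError):
    """Raised when an input document violates its documented format."""


@dataclass(frozen=True)
class Sentence:
    """One candidate sentence of an article.

    Parameters
    ----------
    sentence_id:
        0-based index in document order; consecutive within an article.
    text:
        The sentence text (non-empty after trimming).
    paragraph_id:
        0-based paragraph index; non-decreasing with ``sentence_id``.
    section_label:
        Raw heading text of the enclosing section, if any.
    char_span:
        ``(start, end)`` offsets into the source text, 0-based half-open.
    """

    sentence_id: int
    text: str
    paragraph_id: int
    section_label: str | None = None
    char_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError(f"sentence {self.sentence_id}: empty text")
        if self.sentence_id < 0 or self.paragraph_id < 0:
            raise ValueError("sentence_id and paragraph_id must be >= 0")


@dataclass(frozen=True)
class FigureRecord:
    """A figure's numeric identifier, printed label, and caption text."""

    figure_number: int
    label: str
    caption: str
    caption_missing: bool = False

    def __post_init__(self) -> None:
        if self.figure_number < 1:
            raise ValueError("figure_number must be a positive integer")
        if not self.caption.strip() and not self.caption_missing:
            raise ValueError(
                f"figure {self.figure_number}: empty caption must be flagged "
                "with caption_missing=True"
            )


@dataclass
class Article:
    """A parsed full-text article.

    Invariants (checked by :meth:`validate`): sentence ids are consecutive
    0..N-1 in document order, paragraph ids are non-decreasing, every
    sentence belongs to exactly one paragraph and paragraph ranges tile the
    sentence stream, figure numbers are unique.
    """

    article_id: str
    title: str
    sentences: list[Sentence] = field(default_factory=list)
    figures: list[FigureRecord] = field(default_factory=list)
    abstract: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for i, s in enumerate(self.sentences):
            if s.sentence_id != i:
                raise ValueError(
                    f"sentence ids must be consecutive; got {s.sentence_id} at {i}"
                )
            if i and s.paragraph_id < self.sentences[i - 1].paragraph_id:
                raise ValueError("paragraph_id must be non-decreasing")
        numbers = [f.figure_number for f in self.figures]
        if len(numbers) != len(set(numbers)):
            raise FormatError(f"duplicate figure numbers in article {self.article_id!r}")

    @property
    def paragraphs(self) -> list[tuple[int, range]]:
        """``(paragraph_id, sentence_id range)`` pairs, contiguous and tiling."""
        out: list[tuple[int, range]] = []
        start = 0
        for i in range(1, len(self.sentences) + 1):
            if i == len(self.sentences) or (
                self.sentences[i].paragraph_id != self.sentences[start].paragraph_id
            ):
                out.append((self.sentences[start].paragraph_id, range(start, i)))
                start = i
        return out

    def paragraph_sentence_ids(self, paragraph_id: int) -> list[int]:
        return [s.sentence_id for s in self.sentences if s.paragraph_id == paragraph_id]

    def figure(self, figure_number: int) -> FigureRecord:
        for f in self.figures:
            if f.figure_number == figure_number:
                return f
        raise KeyError(f"article {self.article_id!r} has no figure {figure_number}")

    @property
    def figure_numbers(self) -> set[int]:
        return {f.figure_number for f in self.figures}

    def __len__(self) -> int:
        return len(self.sentences)


@dataclass
class GoldStandard:
    """Per-figure annotated summary sentences for one or more articles.

    ``entries`` maps ``(article_id, figure_number)`` to the set of annotated
    sentence ids; ``reference_texts`` optionally carries free-text reference
    sentences for ROUGE-style evaluation.
    """

    entries: dict[tuple[str, int], set[int]] = field(default_factory=dict)
    reference_texts: dict[tuple[str, int], list[str]] = field(default_factory=dict)
    annotator_ids: dict[tuple[str, int], dict[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, ids in self.entries.items():
            if not ids:
                raise ValueError(f"gold entry {key} has an empty sentence set")

    def validate_against(self, articles: dict[str, Article]) -> None:
        """Check every referenced article/figure/sentence exists."""
        for (article_id, fignum), ids in self.entries.items():
            if article_id not in articles:
                raise ValueError(f"gold references unknown article {article_id!r}")
            art = articles[article_id]
            if fignum not in art.figure_numbers:
                raise ValueError(
                    f"gold references figure {fignum} absent from article {article_id!r}"
                )
            bad = [i for i in ids if not 0 <= i < len(art)]
            if bad:
                raise ValueError(
                    f"gold entry ({article_id!r}, {fignum}) references "
                    f"nonexistent sentence ids {sorted(bad)}"
                )

    def figures_of(self, article_id: str) -> list[int]:
        return sorted(f for (a, f) in self.entries if a == article_id)


@dataclass
class FigureSummary:
    """One system's ranked sentence selection for one figure.

    ``selected`` is ordered by rank (scores non-increasing when present);
    display output re-emits sentences in document order.
    """

    article_id: str
    figure_number: int
    system_name: str
    selected: list[tuple[int, float | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.selected]
        if len(ids) != len(set(ids)):
            raise ValueError("selected sentence ids must be unique")
        scores = [sc for _, sc in self.selected if sc is not None]
        if any(a < b - 1e-12 for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing in rank order")

    @property
    def sentence_ids(self) -> set[int]:
        return {sid for sid, _ in self.selected}

    @property
    def document_order_ids(self) -> list[int]:
        return sorted(self.sentence_ids)

    def __len__(self) -> int:
        return len(self.selected)
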