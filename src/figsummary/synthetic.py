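"""Synthetic articles with planted figure-reference structure.

The generator emulates the structure a figure summarizer relies on in a
real full-text article — paragraphs of sentences, figures with captions,
explicit citation cues ("Fig. 3") in known sentences, and captions that
share topic vocabulary with the sentences discussing their figure —
while stripping away real language.  Tokens are synthetic words
("w0017"-style background, "t2w005"-style figure-topic words) so overlap
arithmetic is exact and every planted quantity is recoverable.

Each figure owns a disjoint topic vocabulary.  ``refs_per_figure``
sentences per figure receive a citation cue plus topic tokens; captions
mix topic and background tokens in a controlled proportion.  The gold
standard is planted by one of three rules, each making a different
summarizer provably optimal:

* ``referring_sentences`` — gold is exactly the citing sentences (the
  surface-cue summarizer is optimal);
* ``referring_paragraphs`` — gold is every sentence of the citing
  paragraphs (the paragraph summarizer is optimal);
* ``topic_top_k`` — gold is the ``refs_per_figure`` sentences richest in
  the figure's topic vocabulary.

Articles are emitted in the plain-text dialect and parsed back through
the ordinary reader, so fixtures also exercise the I/O path.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field

from .io import parse_plaintext_article
from .model import Article, GoldStandard

GOLD_RULES = ("referring_sentences", "referring_paragraphs", "topic_top_k")

_SENTENCE_LEN = 8
_CAPTION_LEN = 10
_TOPIC_TOKENS_PER_REF = 4


@dataclass(frozen=True)
class SynthParams:
    """Generator settings; defaults give a small article-like document.

    ``caption_topic_overlap`` is the fraction of caption tokens drawn from
    the figure's topic vocabulary (the rest are background words);
    ``refs_per_figure`` citing sentences are planted per figure.
    """

    n_paragraphs: int = 8
    sentences_per_paragraph: int = 5
    n_figures: int = 3
    topic_vocab_size: int = 12
    background_vocab_size: int = 120
    caption_topic_overlap: float = 0.7
    refs_per_figure: int = 3
    gold_rule: str = "referring_sentences"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_paragraphs, self.sentences_per_paragraph) < 1:
            raise ValueError("paragraph counts must be positive")
        if self.n_figures < 0:
            raise ValueError("n_figures must be >= 0")
        if not 0.0 <= self.caption_topic_overlap <= 1.0:
            raise ValueError("caption_topic_overlap must lie in [0, 1]")
        if self.gold_rule not in GOLD_RULES:
            raise ValueError(f"gold_rule must be one of {GOLD_RULES}")
        total = self.n_paragraphs * self.sentences_per_paragraph
        if self.n_figures and self.refs_per_figure * self.n_figures > total:
            raise ValueError(
                "refs_per_figure * n_figures exceeds the number of sentences"
            )
        if self.refs_per_figure < 1:
            raise ValueError("refs_per_figure must be >= 1")
        if self.topic_vocab_size < _TOPIC_TOKENS_PER_REF:
            raise ValueError(
                f"topic_vocab_size must be >= {_TOPIC_TOKENS_PER_REF}"
            )


@dataclass
class SyntheticArticle:
    """A generated article with its gold standard and planting bookkeeping."""

    article: Article
    gold: GoldStandard
    raw_text: str
    referring_sentences: dict[int, list[int]] = field(default_factory=dict)
    referring_paragraphs: dict[int, set[int]] = field(default_factory=dict)

    def __iter__(self):
        return iter((self.article, self.gold))


def _topic_vocab(fignum: int, size: int) -> list[str]:
    return [f"t{fignum}w{i:03d}" for i in range(size)]


def _cue(rng: random.Random, fignum: int, tokens: list[str]) -> str:
    """A citing sentence using one of several cue phrasings."""
    body = " ".join(tokens)
    head, tail = tokens[0].capitalize(), " ".join(tokens[1:])
    variants = (
        f"As shown in Fig. {fignum}, {body}.",
        f"Figure {fignum} shows {body}.",
        f"{head} {tail} increased (Fig. {fignum}).",
        f"{head} {tail} are plotted in Fig. {fignum}.",
    )
    return variants[rng.randrange(len(variants))]


def generate_article(
    params: SynthParams, article_id: str = "synth"
) -> SyntheticArticle:
    """Generate one article with planted figures, cues, and gold standard.

    Deterministic for a fixed ``params.seed``; the returned bookkeeping
    records which sentences and paragraphs cite each figure.
    """
    rng = random.Random(params.seed)
    background = [f"w{i:04d}" for i in range(params.background_vocab_size)]
    topics = {
        f: _topic_vocab(f, params.topic_vocab_size)
        for f in range(1, params.n_figures + 1)
    }
    total = params.n_paragraphs * params.sentences_per_paragraph

    # assign disjoint citing slots to figures
    slots = rng.sample(range(total), params.refs_per_figure * params.n_figures)
    referring: dict[int, list[int]] = {}
    for i, f in enumerate(range(1, params.n_figures + 1)):
        referring[f] = sorted(
            slots[i * params.refs_per_figure : (i + 1) * params.refs_per_figure]
        )
    slot_figure = {s: f for f, ss in referring.items() for s in ss}

    def plain_sentence() -> str:
        tokens = rng.choices(background, k=_SENTENCE_LEN)
        return " ".join([tokens[0].capitalize()] + tokens[1:]) + "."

    sentences: list[str] = []
    for sid in range(total):
        f = slot_figure.get(sid)
        if f is None:
            sentences.append(plain_sentence())
        else:
            toks = rng.sample(topics[f], _TOPIC_TOKENS_PER_REF) + rng.choices(
                background, k=_SENTENCE_LEN - _TOPIC_TOKENS_PER_REF
            )
            rng.shuffle(toks)
            sentences.append(_cue(rng, f, toks))

    paragraphs = [
        sentences[p * params.sentences_per_paragraph : (p + 1) * params.sentences_per_paragraph]
        for p in range(params.n_paragraphs)
    ]

    captions: dict[int, str] = {}
    for f in range(1, params.n_figures + 1):
        k_topic = round(params.caption_topic_overlap * _CAPTION_LEN)
        k_topic = min(k_topic, params.topic_vocab_size)
        toks = rng.sample(topics[f], k_topic) + rng.choices(
            background, k=_CAPTION_LEN - k_topic
        )
        rng.shuffle(toks)
        captions[f] = " ".join(toks) + "."

    parts = [f"Synthetic article {article_id}", ""]
    for para in paragraphs:
        parts.append(" ".join(para))
        parts.append("")
    for f in sorted(captions):
        parts.append(f"FIGURE {f}: {captions[f]}")
        parts.append("")
    raw_text = "\n".join(parts)

    article = parse_plaintext_article(raw_text, article_id=article_id)
    if len(article) != total:
        raise AssertionError(
            f"generator/parser disagreement: planned {total} sentences, "
            f"parsed {len(article)}"
        )

    referring_paragraphs = {
        f: {article.sentences[s].paragraph_id for s in ids}
        for f, ids in referring.items()
    }

    entries: dict[tuple[str, int], set[int]] = {}
    for f in range(1, params.n_figures + 1):
        if params.gold_rule == "referring_sentences":
            gold_ids = set(referring[f])
        elif params.gold_rule == "referring_paragraphs":
            gold_ids = {
                s.sentence_id
                for s in article.sentences
                if s.paragraph_id in referring_paragraphs[f]
            }
        else:  # topic_top_k: sentences richest in the figure's topic vocabulary
            topic_set = set(topics[f])
            richness = [
                (
                    -sum(tok in topic_set for tok in re.findall(r"[a-z0-9]+", s.text.lower())),
                    s.sentence_id,
                )
                for s in article.sentences
            ]
            richness.sort()
            gold_ids = {sid for _, sid in richness[: params.refs_per_figure]}
        entries[(article_id, f)] = gold_ids

    gold = GoldStandard(entries=entries)
    return SyntheticArticle(
        article=article,
        gold=gold,
        raw_text=raw_text,
        referring_sentences=referring,
        referring_paragraphs=referring_paragraphs,
    )


def generate_corpus(
    n_articles: int,
    params: SynthParams,
    figures_per_article: list[int] | None = None,
) -> tuple[list[SyntheticArticle], GoldStandard]:
    """Generate a corpus of articles with one aggregate gold standard.

    Per-article seeds are derived deterministically from ``params.seed``.
    ``figures_per_article`` optionally overrides ``params.n_figures``
    article by article (to mirror a benchmark's per-article layout).
    """
    if figures_per_article is not None and len(figures_per_article) != n_articles:
        raise ValueError("figures_per_article length must equal n_articles")
    master = random.Random(params.seed)
    out: list[SyntheticArticle] = []
    entries: dict[tuple[str, int], set[int]] = {}
    for i in range(n_articles):
        sub_seed = master.randrange(2**31)
        n_figs = figures_per_article[i] if figures_per_article else params.n_figures
        p = SynthParams(
            n_paragraphs=params.n_paragraphs,
            sentences_per_paragraph=params.sentences_per_paragraph,
            n_figures=n_figs,
            topic_vocab_size=params.topic_vocab_size,
            background_vocab_size=params.background_vocab_size,
            caption_topic_overlap=params.caption_topic_overlap,
            refs_per_figure=params.refs_per_figure,
            gold_rule=params.gold_rule,
            seed=sub_seed,
        )
        synth = generate_article(p, article_id=f"synth{i + 1:02d}")
        out.append(synth)
        entries.update(synth.gold.entries)
    return out, GoldStandard(entries=entries)
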