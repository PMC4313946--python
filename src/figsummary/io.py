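"""Readers and writers for articles, gold standards, and summaries.

Three external formats are supported, all UTF-8:

* a plain-text article dialect: first non-empty line is the title;
  paragraphs are separated by blank lines; a paragraph whose first line
  starts with ``#`` is a section heading; a paragraph beginning
  ``ABSTRACT:`` is the abstract; a paragraph beginning ``FIGURE <k>:`` is
  the caption of figure *k* and is excluded from the candidate sentence
  stream;
* a JATS-like XML subset (``article-title``, ``abstract``, ``body`` with
  ``sec``/``title``/``p`` and ``fig``/``label``/``caption`` elements);
* a JSON gold standard ``{article_id: {figure_number: {"sentence_ids":
  [...], "reference_texts": [...]}}}``.

Sentence splitting is rule-based: a run of ``. ! ?`` followed by
whitespace and an uppercase letter or digit ends a sentence, unless the
period follows a protected abbreviation ("Fig", "et al", "e.g", ...).
"""

from __future__ import annotations

import json
import logging
import re
import string
from typing import IO, Iterable, Mapping

from lxml import etree

from .model import Article, FigureRecord, FigureSummary, FormatError, GoldStandard, Sentence

logger = logging.getLogger(__name__)

#: Abbreviations whose trailing period never ends a sentence.  Multi-character
#: entries match case-insensitively; single capital letters match exactly
#: (initials such as "J. Smith").
DEFAULT_ABBREVIATIONS: frozenset[str] = frozenset(
    {"Fig", "Figs", "et al", "e.g", "i.e", "vs", "cf", "etc", "ca", "approx",
     "Dr", "Prof", "No", "ref", "refs"}
    | set(string.ascii_uppercase)
)

_TERMINAL = ".!?"
_CLOSERS = ")]\"'”’"


def _protected_by_abbreviation(text: str, dot_pos: int, abbreviations: Iterable[str]) -> bool:
    """True if the period at ``dot_pos`` follows a protected abbreviation."""
    prefix = text[:dot_pos]
    for abbr in abbreviations:
        if len(abbr) == 1:
            match = prefix.endswith(abbr)
        else:
            match = prefix.lower().endswith(abbr.lower())
        if not match:
            continue
        before = dot_pos - len(abbr) - 1
        if before < 0 or not (text[before].isalnum() or text[before] == "."):
            return True
    return False


def split_sentences(
    raw_text: str,
    abbreviation_list: Iterable[str] = DEFAULT_ABBREVIATIONS,
) -> list[tuple[int, int]]:
    """Split ``raw_text`` into sentence spans.

    Returns 0-based half-open ``(start, end)`` spans, ordered and
    non-overlapping, that jointly cover every non-whitespace character.
    Empty or all-whitespace input yields an empty list.
    """
    abbreviations = tuple(abbreviation_list)
    spans: list[tuple[int, int]] = []
    n = len(raw_text)
    start = 0
    while start < n and raw_text[start].isspace():
        start += 1
    if start == n:
        return []

    i = start
    while i < n:
        ch = raw_text[i]
        if ch not in _TERMINAL:
            i += 1
            continue
        first_punct = i
        j = i
        while j < n and raw_text[j] in _TERMINAL:
            j += 1
        while j < n and raw_text[j] in _CLOSERS:
            j += 1
        # boundary requires whitespace then an uppercase letter or digit
        k = j
        while k < n and raw_text[k].isspace():
            k += 1
        is_boundary = j < n and k > j and k < n and (raw_text[k].isupper() or raw_text[k].isdigit())
        if is_boundary and raw_text[first_punct] == ".":
            if _protected_by_abbreviation(raw_text, first_punct, abbreviations):
                is_boundary = False
        if is_boundary:
            spans.append((start, j))
            start = k
            i = k
        else:
            i = j
    # trailing sentence (with or without terminal punctuation)
    end = n
    while end > start and raw_text[end - 1].isspace():
        end -= 1
    if end > start:
        spans.append((start, end))
    return spans


# ---------------------------------------------------------------------------
# plain-text article dialect


def _blocks(text: str) -> list[tuple[int, str]]:
    """Maximal runs of non-blank lines, as ``(offset, block_text)``."""
    out: list[tuple[int, str]] = []
    for m in re.finditer(r"(?:[^\n]*\S[^\n]*\n?)+", text):
        block = m.group(0)
        if block.strip():
            out.append((m.start(), block.rstrip("\n")))
    return out


_CAPTION_RE = re.compile(r"^FIGURE\s+(\S+?)\s*:\s*", re.IGNORECASE)
_ABSTRACT_RE = re.compile(r"^ABSTRACT\s*:\s*", re.IGNORECASE)


def parse_plaintext_article(
    raw_text: str,
    article_id: str = "article",
    abbreviation_list: Iterable[str] = DEFAULT_ABBREVIATIONS,
    include_abstract: bool = True,
) -> Article:
    """Parse the plain-text article dialect into an :class:`Article`.

    ``include_abstract`` controls whether abstract sentences join the
    candidate sentence pool (they do by default).
    """
    blocks = _blocks(raw_text)
    if not blocks:
        raise FormatError("empty article text")

    first_offset, first_block = blocks[0]
    first_lines = first_block.split("\n")
    title = first_lines[0].strip()
    rest = "\n".join(first_lines[1:]).strip()
    body_blocks: list[tuple[int, str]] = []
    if rest:
        body_blocks.append((first_offset + len(first_lines[0]) + 1, rest))
    body_blocks.extend(blocks[1:])

    abstract: str | None = None
    sentences: list[Sentence] = []
    figures: list[FigureRecord] = []
    seen_fignums: set[int] = set()
    paragraph_id = 0
    section_label: str | None = None

    def add_paragraph(offset: int, text_block: str, label: str | None) -> None:
        nonlocal paragraph_id
        spans = split_sentences(text_block, abbreviation_list)
        if not spans:
            return
        for s, e in spans:
            sent_text = re.sub(r"\s+", " ", text_block[s:e]).strip()
            sentences.append(
                Sentence(
                    sentence_id=len(sentences),
                    text=sent_text,
                    paragraph_id=paragraph_id,
                    section_label=label,
                    char_span=(offset + s, offset + e),
                )
            )
        paragraph_id += 1

    for offset, block in body_blocks:
        cap = _CAPTION_RE.match(block)
        if cap:
            token = cap.group(1)
            if not token.isdigit():
                raise FormatError(f"caption block with unparsable figure number {token!r}")
            fignum = int(token)
            if fignum in seen_fignums:
                raise FormatError(f"duplicate caption block for figure {fignum}")
            seen_fignums.add(fignum)
            caption = re.sub(r"\s+", " ", block[cap.end():]).strip()
            figures.append(
                FigureRecord(
                    figure_number=fignum,
                    label=f"Figure {fignum}",
                    caption=caption,
                    caption_missing=not caption,
                )
            )
            continue
        abs_m = _ABSTRACT_RE.match(block)
        if abs_m:
            abstract = re.sub(r"\s+", " ", block[abs_m.end():]).strip()
            if include_abstract and abstract:
                add_paragraph(offset + abs_m.end(), block[abs_m.end():], "Abstract")
            continue
        if block.lstrip().startswith("#"):
            head, _, rest_of_block = block.partition("\n")
            section_label = head.lstrip("# ").strip()
            if rest_of_block.strip():
                add_paragraph(offset + len(head) + 1, rest_of_block, section_label)
            continue
        add_paragraph(offset, block, section_label)

    figures.sort(key=lambda f: f.figure_number)
    return Article(
        article_id=article_id,
        title=title,
        sentences=sentences,
        figures=figures,
        abstract=abstract,
    )


# ---------------------------------------------------------------------------
# JATS-like XML subset


def _element_text(el: etree._Element, skip_tags: tuple[str, ...] = ()) -> str:
    parts: list[str] = []

    def walk(node: etree._Element) -> None:
        if node.text:
            parts.append(node.text)
        for child in node:
            if child.tag not in skip_tags:
                walk(child)
            if child.tail:
                parts.append(child.tail)

    walk(el)
    return re.sub(r"\s+", " ", "".join(parts)).strip()


def parse_xml_article(
    xml_document: str | bytes,
    article_id: str = "article",
    abbreviation_list: Iterable[str] = DEFAULT_ABBREVIATIONS,
    include_abstract: bool = True,
) -> Article:
    """Parse a JATS-like XML document into an :class:`Article`.

    Element order defines document order.  A ``fig`` without a numeric
    label is skipped with a warning; a ``fig`` without a caption yields a
    flagged empty caption.  Malformed XML raises :class:`FormatError`
    naming the error position.
    """
    if isinstance(xml_document, str):
        xml_document = xml_document.encode("utf-8")
    try:
        root = etree.fromstring(xml_document)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed XML at line {exc.lineno}, column {exc.position[1]}: {exc.msg}") from exc

    title_el = root.find(".//article-title")
    title = _element_text(title_el) if title_el is not None else ""
    abstract_el = root.find(".//abstract")
    abstract = _element_text(abstract_el) if abstract_el is not None else None

    sentences: list[Sentence] = []
    figures: list[FigureRecord] = []
    seen_fignums: set[int] = set()
    paragraph_id = 0

    def add_paragraph(text_block: str, label: str | None) -> None:
        nonlocal paragraph_id
        spans = split_sentences(text_block, abbreviation_list)
        if not spans:
            return
        for s, e in spans:
            sentences.append(
                Sentence(
                    sentence_id=len(sentences),
                    text=text_block[s:e],
                    paragraph_id=paragraph_id,
                    section_label=label,
                )
            )
        paragraph_id += 1

    def handle_fig(fig: etree._Element) -> None:
        label_el = fig.find("label")
        label_text = _element_text(label_el) if label_el is not None else fig.get("id", "")
        m = re.search(r"(\d+)", label_text)
        if not m:
            logger.warning("skipping figure without numeric label: %r", label_text)
            return
        fignum = int(m.group(1))
        if fignum in seen_fignums:
            raise FormatError(f"duplicate figure number {fignum}")
        seen_fignums.add(fignum)
        caption_el = fig.find("caption")
        caption = _element_text(caption_el) if caption_el is not None else ""
        figures.append(
            FigureRecord(
                figure_number=fignum,
                label=label_text or f"Figure {fignum}",
                caption=caption,
                caption_missing=not caption,
            )
        )

    def walk_body(node: etree._Element, label: str | None) -> None:
        for child in node:
            if child.tag == "sec":
                title_child = child.find("title")
                sec_label = _element_text(title_child) if title_child is not None else label
                walk_body(child, sec_label)
            elif child.tag == "p":
                for fig in child.findall(".//fig"):
                    handle_fig(fig)
                add_paragraph(_element_text(child, skip_tags=("fig",)), label)
            elif child.tag == "fig":
                handle_fig(child)

    if include_abstract and abstract:
        add_paragraph(abstract, "Abstract")
    body = root.find(".//body")
    if body is not None:
        walk_body(body, None)

    figures.sort(key=lambda f: f.figure_number)
    return Article(
        article_id=article_id,
        title=title,
        sentences=sentences,
        figures=figures,
        abstract=abstract,
    )


# ---------------------------------------------------------------------------
# gold standard JSON


def read_gold_standard(source: str | IO[str]) -> GoldStandard:
    """Read the JSON gold standard from a path or open stream."""
    if hasattr(source, "read"):
        data = json.load(source)  # type: ignore[arg-type]
    else:
        with open(source, encoding="utf-8") as fh:
            data = json.load(fh)
    if not isinstance(data, dict):
        raise FormatError("gold standard must be a JSON object keyed by article id")
    entries: dict[tuple[str, int], set[int]] = {}
    reference_texts: dict[tuple[str, int], list[str]] = {}
    for article_id, figmap in data.items():
        if not isinstance(figmap, dict):
            raise FormatError(f"article {article_id!r}: expected an object of figures")
        for figkey, payload in figmap.items():
            try:
                fignum = int(figkey)
            except (TypeError, ValueError):
                raise FormatError(
                    f"article {article_id!r}: figure key {figkey!r} is not an integer"
                ) from None
            if not isinstance(payload, dict) or "sentence_ids" not in payload:
                raise FormatError(
                    f"article {article_id!r} figure {figkey}: missing 'sentence_ids'"
                )
            ids = payload["sentence_ids"]
            if not isinstance(ids, list) or not ids:
                raise FormatError(
                    f"article {article_id!r} figure {figkey}: 'sentence_ids' must be a non-empty list"
                )
            for sid in ids:
                if isinstance(sid, bool) or not isinstance(sid, int) or sid < 0:
                    raise FormatError(
                        f"article {article_id!r} figure {figkey}: sentence id {sid!r} "
                        "is not a non-negative integer"
                    )
            entries[(article_id, fignum)] = set(ids)
            refs = payload.get("reference_texts")
            if refs is not None:
                if not isinstance(refs, list) or not all(isinstance(r, str) for r in refs):
                    raise FormatError(
                        f"article {article_id!r} figure {figkey}: 'reference_texts' "
                        "must be a list of strings"
                    )
                reference_texts[(article_id, fignum)] = list(refs)
    return GoldStandard(entries=entries, reference_texts=reference_texts)


def write_gold_standard(gold: GoldStandard, path: str) -> None:
    """Write a :class:`GoldStandard` in the JSON schema read back by
    :func:`read_gold_standard`."""
    data: dict[str, dict[str, dict[str, object]]] = {}
    for (article_id, fignum), ids in sorted(gold.entries.items()):
        payload: dict[str, object] = {"sentence_ids": sorted(ids)}
        refs = gold.reference_texts.get((article_id, fignum))
        if refs:
            payload["reference_texts"] = refs
        data.setdefault(article_id, {})[str(fignum)] = payload
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# summary output


def write_summaries(
    summaries: list[FigureSummary],
    path: str,
    format: str = "json",
    articles: Mapping[str, Article] | None = None,
) -> None:
    """Write figure summaries as machine JSON or human-readable text.

    The text form lists sentences in document order under a
    ``[Summary of Figure k]`` header; when ``articles`` is given the
    sentence texts are printed, otherwise the sentence ids.
    """
    if format == "json":
        data = [
            {
                "article_id": s.article_id,
                "figure_number": s.figure_number,
                "system": s.system_name,
                "selected": [
                    {"sentence_id": sid, "score": score} for sid, score in s.selected
                ],
            }
            for s in summaries
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=2)
            fh.write("\n")
    elif format == "text":
        with open(path, "w", encoding="utf-8") as fh:
            for s in summaries:
                fh.write(
                    f"[Summary of Figure {s.figure_number}] "
                    f"(article {s.article_id}, system {s.system_name})\n"
                )
                article = articles.get(s.article_id) if articles else None
                for sid in s.document_order_ids:
                    if article is not None:
                        fh.write(f"  {article.sentences[sid].text}\n")
                    else:
                        fh.write(f"  sentence {sid}\n")
                fh.write("\n")
    else:
        raise ValueError(f"unknown summary format {format!r} (expected 'json' or 'text')")


def read_summaries(source: str | IO[str]) -> list[FigureSummary]:
    """Read summaries written by :func:`write_summaries` in JSON form."""
    if hasattr(source, "read"):
        data = json.load(source)  # type: ignore[arg-type]
    else:
        with open(source, encoding="utf-8") as fh:
            data = json.load(fh)
    out: list[FigureSummary] = []
    for item in data:
        out.append(
            FigureSummary(
                article_id=item["article_id"],
                figure_number=item["figure_number"],
                system_name=item["system"],
                selected=[(d["sentence_id"], d["score"]) for d in item["selected"]],
            )
        )
    return out
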