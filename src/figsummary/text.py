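"""Tokenization for similarity features and ROUGE scoring.

Tokens are maximal runs of ASCII alphanumerics after lowercasing, so
"IL-2" yields ``["il", "2"]``.  Stopword removal and Porter stemming are
independent toggles: the similarity features default to stopword removal
without stemming, while ROUGE defaults to stemming with stopwords kept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from . import _porter

_TOKEN_RE = re.compile(r"[a-z0-9]+")

# A compact English stopword list (function words only; no domain terms).
STOPWORDS = frozenset(
    """a about above after again against all am an and any are as at be because
    been before being below between both but by can could did do does doing down
    during each few for from further had has have having he her here hers him his
    how i if in into is it its itself just me more most my no nor not of off on
    once only or other our ours out over own same she should so some such than
    that the their theirs them then there these they this those through to too
    under until up very was we were what when where which while who whom why will
    with would you your yours""".split()
)


@dataclass(frozen=True)
class TokenizerConfig:
    """Normalization settings shared by the TF-IDF index and ROUGE.

    ``remove_stopwords`` drops function words; ``stem`` applies the Porter
    stemmer to each surviving token.
    """

    remove_stopwords: bool = True
    stem: bool = False

    def key(self) -> tuple[bool, bool]:
        return (self.remove_stopwords, self.stem)


#: default for similarity features: stopwords removed, no stemming
SIMILARITY_CONFIG = TokenizerConfig(remove_stopwords=True, stem=False)
#: default for ROUGE: stopwords kept, Porter stemming on
ROUGE_CONFIG = TokenizerConfig(remove_stopwords=False, stem=True)


def tokenize(text: str, config: TokenizerConfig = SIMILARITY_CONFIG) -> list[str]:
    """Split ``text`` into normalized tokens.

    Lowercases, splits on non-alphanumerics, then optionally removes
    stopwords and applies Porter stemming, in that order.
    """
    tokens = _TOKEN_RE.findall(text.lower())
    if config.remove_stopwords:
        tokens = [t for t in tokens if t not in STOPWORDS]
    if config.stem:
        tokens = [_porter.stem(t) for t in tokens]
    return tokens


def porter_stem(word: str) -> str:
    """Porter stem of a single lowercase word (exposed for testing/tools)."""
    return _porter.stem(word)
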