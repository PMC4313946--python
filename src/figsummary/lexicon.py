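"""Cue word/phrase lexicon for the cue-word feature.

Authors signal document elements such as figures with characteristic
phrases ("as shown in", "illustrates", "we observe").  The full published
lexicon of 140 cues this feature was modelled on is external to this
package, so a documented default list of generic cues is shipped instead;
a user-supplied lexicon file (one phrase per line, UTF-8, ``#`` comments)
takes precedence when given.
"""

from __future__ import annotations

from typing import Iterable

DEFAULT_CUE_LEXICON: tuple[str, ...] = (
    "shows", "shown in", "as shown", "shown here", "illustrates",
    "illustrated in", "depicts", "depicted in", "demonstrates",
    "demonstrated in", "presents", "presented in", "displays",
    "displayed in", "indicates", "indicated in", "reveals", "revealed",
    "we observe", "we observed", "we found", "we report", "we show",
    "in summary", "in conclusion", "taken together", "consistent with",
    "compared to", "as seen in", "note that", "can be seen",
    "respectively", "representative", "plotted", "panel",
)


def load_cue_lexicon(path: str) -> tuple[str, ...]:
    """Read a cue lexicon file: one phrase per line, ``#`` starts a comment."""
    cues: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            phrase = line.split("#", 1)[0].strip().lower()
            if phrase:
                cues.append(phrase)
    return tuple(cues)


def normalize_cues(cues: Iterable[str]) -> tuple[str, ...]:
    """Lowercase and whitespace-normalize cue phrases."""
    return tuple(" ".join(c.lower().split()) for c in cues)
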