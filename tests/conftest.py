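import pytest

from figsummary import parse_plaintext_article
from figsummary.synthetic import SynthParams, generate_article

HEADED_ARTICLE = """Growth dynamics of cultured cells

ABSTRACT: We study cell growth. Cultures were tracked daily.

# Introduction
Cell growth underlies tissue development. Prior work measured colony size.

# Methods
We measured growth with imaging assays (Fig. 1). Control cultures lacked serum.

# Results
Growth increased twofold under serum. The growth curve saturated late (Fig. 2).
Saturation matched the logistic model.

# Discussion
Growth dynamics inform culture protocols.

FIGURE 1: Imaging assay layout for growth measurement.

FIGURE 2: Growth curve of cultured cells over ten days.
"""


@pytest.fixture
def headed_article():
    """A small sectioned article with two figures and citation cues."""
    return parse_plaintext_article(HEADED_ARTICLE, article_id="headed")


@pytest.fixture
def synth_article():
    """Deterministic synthetic article with planted referring sentences."""
    return generate_article(SynthParams(seed=42))


@pytest.fixture
def synth_factory():
    def make(**kwargs):
        return generate_article(SynthParams(**kwargs))

    return make
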