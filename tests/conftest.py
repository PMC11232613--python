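import pytest

from emovad.lexicon import EmotionLexicon, VADScore
from emovad.synthetic import gen_lexicon


@pytest.fixture
def toy_lexicon() -> EmotionLexicon:
    """Small hand-written lexicon used across the unit tests."""
    lex = EmotionLexicon(name="toy")
    lex.add("happy", VADScore(0.9, 0.6, 0.7))
    lex.add("sad", VADScore(0.1, 0.4, 0.3))
    lex.add("joy", VADScore(0.9, 0.7, 0.8))
    lex.add("fear", VADScore(0.1, 0.8, 0.3))
    lex.add("rooted", VADScore(0.51, 0.527, 0.5))
    lex.add("calm", VADScore(0.8, 0.1, 0.6))
    return lex


@pytest.fixture(scope="session")
def synthetic_lexicon() -> EmotionLexicon:
    """Seeded 240-term pseudo-word lexicon (session-scoped: it is pure)."""
    return gen_lexicon(240, seed=7)
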