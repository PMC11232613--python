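"""Rule-based VAD scorer: tokenize, detect negation scopes, look up, average.

The recognizer is the classic lexicon heuristic: every token found in the
VAD lexicon contributes its score; tokens inside a negation scope have
their valence mirrored (v -> 1 - v); the utterance score is the unweighted
component-wise mean of the contributions.  Utterances with no lexicon hit
score the scale midpoint (0.5, 0.5, 0.5), the neutral point of the cube.

Negation scope is a fixed forward window: a cue such as "not" or "n't"
marks the next ``scope_window`` tokens.  Arousal and dominance flipping is
configurable but off by default — negating "calm" does not necessarily
invert how activated the speaker is.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .lexicon import EmotionLexicon, VADScore

logger = logging.getLogger(__name__)

__all__ = [
    "NegationConfig",
    "tokenize",
    "detect_negations",
    "rule_score",
    "RuleVADRegressor",
]

DEFAULT_NEGATION_CUES = frozenset(
    {"not", "no", "never", "n't", "cannot", "neither", "nor", "without"}
)

NEUTRAL_SCORE = VADScore(0.5, 0.5, 0.5)

_PUNCT = string.punctuation + "‘’“”–—…"


@dataclass(frozen=True)
class NegationConfig:
    """Which tokens open a negation scope and what the scope does.

    scope_window: number of following tokens affected by a cue (>= 1).
    flip_*: which VAD components are mirrored (x -> 1 - x) inside a scope.
    """

    cues: frozenset[str] = DEFAULT_NEGATION_CUES
    scope_window: int = 3
    flip_valence: bool = True
    flip_arousal: bool = False
    flip_dominance: bool = False

    def __post_init__(self) -> None:
        if self.scope_window < 1:
            raise ValueError("scope_window must be >= 1")
        if not self.cues:
            raise ValueError("cues must be non-empty")
        object.__setattr__(self, "cues", frozenset(t.lower() for t in self.cues))


def tokenize(text: str) -> list[str]:
    """Lowercase, split on whitespace, strip outer punctuation, detach "n't".

    "I don't feel safe." -> [i, do, n't, feel, safe].  Punctuation is only
    stripped from token edges: "happy,happy" stays one token — no
    intra-token splitting is attempted.  Empty tokens are dropped.
    """
    tokens: list[str] = []
    for raw in text.lower().split():
        tok = raw.strip(_PUNCT)
        if not tok:
            continue
        if tok.endswith("n't") and len(tok) > 3:
            stem = tok[:-3]
            if stem:
                tokens.append(stem)
            tokens.append("n't")
        else:
            tokens.append(tok)
    return tokens


def detect_negations(tokens: list[str], config: NegationConfig | None = None) -> list[bool]:
    """Per-token mask: True iff the token sits inside some negation scope.

    ``mask[i]`` is True iff a cue occurs at position ``j < i`` with
    ``i - j <= scope_window``.  Cue tokens themselves are never marked;
    overlapping scopes union (the mask stays boolean, so a token is
    flipped at most once downstream).
    """
    config = config or NegationConfig()
    mask = [False] * len(tokens)
    for j, tok in enumerate(tokens):
        if tok in config.cues:
            for i in range(j + 1, min(j + config.scope_window + 1, len(tokens))):
                mask[i] = True
    for j, tok in enumerate(tokens):
        if tok in config.cues:
            mask[j] = False
    return mask


def _flip(score: VADScore, config: NegationConfig) -> VADScore:
    return VADScore(
        1.0 - score.valence if config.flip_valence else score.valence,
        1.0 - score.arousal if config.flip_arousal else score.arousal,
        1.0 - score.dominance if config.flip_dominance else score.dominance,
    )


def rule_score(
    text: str,
    lexicon: EmotionLexicon,
    config: NegationConfig | None = None,
) -> VADScore:
    """Score one utterance; see the module docstring for the procedure."""
    score, _, _ = score_with_details(text, lexicon, config)
    return score


def score_with_details(
    text: str,
    lexicon: EmotionLexicon,
    config: NegationConfig | None = None,
) -> tuple[VADScore, int, int]:
    """Like :func:`rule_score` plus (matched, negation-marked-and-matched) counts."""
    config = config or NegationConfig()
    tokens = tokenize(text)
    mask = detect_negations(tokens, config)
    contributions: list[VADScore] = []
    negated_matches = 0
    for tok, negated in zip(tokens, mask):
        hit = lexicon.lookup(tok)
        if hit is None:
            continue
        if negated:
            hit = _flip(hit, config)
            negated_matches += 1
        contributions.append(hit)
    if not contributions:
        logger.debug("no lexicon match in %r; returning neutral midpoint", text)
        return NEUTRAL_SCORE, 0, 0
    arr = np.array([c.as_tuple() for c in contributions], dtype=float)
    mean = arr.mean(axis=0)
    return VADScore(*mean), len(contributions), negated_matches


class RuleVADRegressor(BaseEstimator, RegressorMixin):
    """scikit-learn wrapper around the rule-based scorer.

    Parameters
    ----------
    lexicon : EmotionLexicon
        Word -> VAD dictionary consulted per token.
    cues : iterable of str
        Negation cue tokens.
    scope_window : int
        Tokens after a cue that fall inside its scope.
    flip_valence, flip_arousal, flip_dominance : bool
        Components mirrored inside a scope.

    The estimator has no trainable state; :meth:`fit` validates the
    configuration so the object composes with sklearn pipelines and
    model-selection utilities.
    """

    def __init__(
        self,
        lexicon: EmotionLexicon | None = None,
        cues: frozenset[str] = DEFAULT_NEGATION_CUES,
        scope_window: int = 3,
        flip_valence: bool = True,
        flip_arousal: bool = False,
        flip_dominance: bool = False,
    ):
        self.lexicon = lexicon
        self.cues = cues
        self.scope_window = scope_window
        self.flip_valence = flip_valence
        self.flip_arousal = flip_arousal
        self.flip_dominance = flip_dominance

    def _config(self) -> NegationConfig:
        return NegationConfig(
            cues=frozenset(self.cues),
            scope_window=self.scope_window,
            flip_valence=self.flip_valence,
            flip_arousal=self.flip_arousal,
            flip_dominance=self.flip_dominance,
        )

    def fit(self, X=None, y=None) -> "RuleVADRegressor":
        if self.lexicon is None or not isinstance(self.lexicon, EmotionLexicon):
            raise ValueError("RuleVADRegressor requires an EmotionLexicon")
        self._config()  # validates cue/window parameters
        self.lexicon_ = self.lexicon
        return self

    def predict(self, X: list[str]) -> np.ndarray:
        """Score each utterance; returns an (n, 3) array of V/A/D columns."""
        check_is_fitted(self, "lexicon_")
        config = self._config()
        out = np.empty((len(X), 3), dtype=float)
        for i, text in enumerate(X):
            out[i] = rule_score(text, self.lexicon_, config).as_tuple()
        return out
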