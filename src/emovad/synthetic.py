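"""Seeded generators for lexicons and corpora with known statistical structure.

These stand in for the real resources the pipeline consumes (a VAD
lexicon, categorical corpora, natively dimensional corpora) so that
every stage is testable without downloads.  The key property: a
dimensional corpus is generated *from* a lexicon, with gold defined as
the negation-aware mean of the component words' scores plus optional
clipped Gaussian noise — so at zero noise and zero out-of-vocabulary
rate the rule-based scorer reproduces gold exactly, giving an analytic
oracle (MSE 0, r 1), and a trainable model can recover the structure.

All generators are pure functions of their seed: identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import CategoricalExample, DimensionalExample, EmotionDataset, Provenance
from .lexicon import EmotionLexicon, VADScore
from .rules import NegationConfig, detect_negations

__all__ = [
    "SyntheticCorpusSpec",
    "gen_lexicon",
    "gen_dimensional_corpus",
    "gen_categorical_corpus",
    "gen_negation_cases",
]

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"
# OOV pseudo-words draw on letters absent from the lexicon alphabet, so
# an OOV token can never collide with a lexicon term
_OOV_CONSONANTS = "chjqwxy"


def _pseudo_word(rng: np.random.Generator, n_syllables: int, consonants: str) -> str:
    return "".join(
        rng.choice(list(consonants)) + rng.choice(list(_VOWELS))
        for _ in range(n_syllables)
    )


def gen_lexicon(n_terms: int, seed: int, name: str = "synthetic-lexicon") -> EmotionLexicon:
    """``n_terms`` distinct pronounceable pseudo-words, VAD ~ U[0,1]^3."""
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    lexicon = EmotionLexicon(name=name)
    n_syllables = max(2, math.ceil(math.log(max(n_terms, 2), 60)) + 1)
    while len(lexicon) < n_terms:
        term = _pseudo_word(rng, n_syllables, _CONSONANTS)
        if term in lexicon:
            continue
        v, a, d = rng.uniform(0.0, 1.0, size=3)
        lexicon.add(term, VADScore(v, a, d))
    return lexicon


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Recipe for a dimensional corpus; generation is pure in the spec."""

    n_examples: int
    lexicon: EmotionLexicon
    words_per_text: tuple[int, int] = (3, 8)
    noise_sd: float = 0.0
    oov_rate: float = 0.0
    negation_rate: float = 0.0
    seed: int = 0
    name: str = "synthetic"
    negation: NegationConfig = field(default_factory=NegationConfig)

    def __post_init__(self) -> None:
        if self.n_examples < 1:
            raise ValueError("n_examples must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for rate, label in ((self.oov_rate, "oov_rate"), (self.negation_rate, "negation_rate")):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{label} must lie in [0, 1)")
        lo, hi = self.words_per_text
        if lo < 1 or hi < lo:
            raise ValueError("words_per_text must be a (low, high) range with low >= 1")


def gen_dimensional_corpus(spec: SyntheticCorpusSpec) -> EmotionDataset:
    """Texts of lexicon words; gold = negation-aware mean (+ clipped noise).

    Each text samples ``k ~ U[words_per_text]`` lexicon words (with
    replacement).  With probability ``oov_rate`` a word is replaced by an
    out-of-vocabulary pseudo-word drawn from a disjoint alphabet; with
    probability ``negation_rate`` a negation cue ("not") is inserted
    before a word.  Gold is the mean of the in-lexicon words' scores with
    the configured negation flip applied inside cue scopes, then
    Gaussian noise (sd ``noise_sd``) is added and the result clipped to
    [0, 1] — so at ``noise_sd = oov_rate = 0`` gold coincides exactly
    with the rule scorer's output, whatever the negation rate.
    Texts whose words all fall out of vocabulary are resampled.
    """
    rng = np.random.default_rng(spec.seed)
    terms = spec.lexicon.terms()
    lo, hi = spec.words_per_text
    examples: list[DimensionalExample] = []
    while len(examples) < spec.n_examples:
        k = int(rng.integers(lo, hi + 1))
        tokens: list[str] = []
        for _ in range(k):
            if spec.negation_rate and rng.random() < spec.negation_rate:
                tokens.append("not")
            if spec.oov_rate and rng.random() < spec.oov_rate:
                tokens.append(_pseudo_word(rng, 3, _OOV_CONSONANTS))
            else:
                tokens.append(terms[int(rng.integers(len(terms)))])
        mask = detect_negations(tokens, spec.negation)
        contributions = []
        for tok, negated in zip(tokens, mask):
            score = spec.lexicon.lookup(tok)
            if score is None:
                continue
            v, a, d = score.as_tuple()
            if negated:
                if spec.negation.flip_valence:
                    v = 1.0 - v
                if spec.negation.flip_arousal:
                    a = 1.0 - a
                if spec.negation.flip_dominance:
                    d = 1.0 - d
            contributions.append((v, a, d))
        if not contributions:
            continue  # all-OOV text has no defined gold; resample
        gold = np.mean(contributions, axis=0)
        if spec.noise_sd:
            gold = np.clip(gold + rng.normal(0.0, spec.noise_sd, size=3), 0.0, 1.0)
        examples.append(DimensionalExample(" ".join(tokens), VADScore(*gold)))
    return EmotionDataset.from_examples(
        spec.name, examples, Provenance("native", (spec.name,))
    )


def gen_categorical_corpus(
    n_examples: int,
    categories: list[tuple[str, VADScore]],
    lexicon: EmotionLexicon,
    label_noise: float = 0.0,
    seed: int = 0,
    words_per_text: tuple[int, int] = (3, 8),
    neighbourhood: int = 20,
) -> list[CategoricalExample]:
    """Categorical corpus whose texts cluster around category anchors.

    Every example picks a category uniformly, builds its text from the
    ``neighbourhood`` lexicon words nearest (Euclidean, VAD space) the
    category's anchor point, and takes the category name as its label —
    switched to a uniformly random *other* category with probability
    ``label_noise``.  Category names must be lexicon terms, so that
    transforming the corpus back through the lexicon yields a learnable
    dimensional dataset.
    """
    if len(categories) < 2:
        raise ValueError("need at least 2 categories")
    if not 0.0 <= label_noise < 1.0:
        raise ValueError("label_noise must lie in [0, 1)")
    missing = [name for name, _ in categories if name not in lexicon]
    if missing:
        raise KeyError(f"anchor categories missing from lexicon: {missing}")
    rng = np.random.default_rng(seed)
    terms = lexicon.terms()
    coords = np.array([lexicon.entries[t].as_tuple() for t in terms])
    pools = []
    for _, anchor in categories:
        d2 = ((coords - np.array(anchor.as_tuple())) ** 2).sum(axis=1)
        pools.append([terms[i] for i in np.argsort(d2)[:neighbourhood]])

    lo, hi = words_per_text
    examples: list[CategoricalExample] = []
    for _ in range(n_examples):
        c = int(rng.integers(len(categories)))
        k = int(rng.integers(lo, hi + 1))
        words = [pools[c][int(rng.integers(len(pools[c])))] for _ in range(k)]
        label = categories[c][0]
        # the noise variates are drawn whether or not they are used, so the
        # same seed yields the same category/word choices at any label_noise
        u = rng.random()
        alt = int(rng.integers(len(categories) - 1))
        if u < label_noise:
            others = [name for name, _ in categories if name != label]
            label = others[alt]
        examples.append(CategoricalExample(" ".join(words), frozenset({label})))
    return examples


def gen_negation_cases(
    n: int, lexicon: EmotionLexicon, seed: int = 0
) -> list[tuple[str, VADScore]]:
    """n pairs ("w", score) / ("not w", valence-flipped score) — 2n texts."""
    if len(lexicon) == 0:
        raise ValueError("lexicon must be non-empty")
    rng = np.random.default_rng(seed)
    terms = lexicon.terms()
    cases: list[tuple[str, VADScore]] = []
    for _ in range(n):
        term = terms[int(rng.integers(len(terms)))]
        score = lexicon.entries[term]
        cases.append((term, score))
        cases.append(
            (f"not {term}", VADScore(1.0 - score.valence, score.arousal, score.dominance))
        )
    return cases
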