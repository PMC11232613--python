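"""Evaluation suite: per-dimension MSE / Pearson r and centroid categories.

Regression quality is reported per dimension (valence, arousal,
dominance) and as a "combined VAD" figure.  The combined figure is, by
default, computed on the *scalar average*: each triple is collapsed to
the mean of its three components and MSE / r are taken between the two
scalar series.  (With this construction the combined MSE can fall below
every per-dimension MSE because per-dimension errors of opposite sign
cancel in the average; the entrywise alternative — pooling all 3n
components, whose MSE is exactly the mean of the three per-dimension
MSEs — and the concatenated correlation are available under
``mode="entrywise"`` / ``mode="concatenated"``.)

For a categorical reading, predictions and gold scores are mapped to the
nearest of five anchor points in the valence-arousal plane (dominance is
ignored — the anchors are defined by VA pairs only).  The default
anchors are the lexicon entries *empty*, *threatened*, *tranquil*,
*excited* and *rooted*, chosen for being roughly equidistant both
numerically and semantically.  Precision/recall/F1 are one-vs-rest per
category; macro = unweighted mean of per-category F1, micro = F1 of the
pooled counts (identical to accuracy in this single-label, exhaustive
setting), average = support-weighted mean of per-category F1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

logger = logging.getLogger(__name__)

__all__ = [
    "CentroidMap",
    "DEFAULT_CENTROIDS",
    "EvaluationReport",
    "mse_per_dimension",
    "combined_vad_mse",
    "pearson_per_dimension",
    "combined_vad_r",
    "assign_category",
    "assign_categories",
    "categorical_report",
    "evaluate",
    "CentroidCategorizer",
]

DIMENSIONS = ("valence", "arousal", "dominance")


@dataclass(frozen=True)
class CentroidMap:
    """Ordered, named anchor points in the valence-arousal unit square.

    Order matters: ties in the nearest-centroid assignment break toward
    the earlier entry.
    """

    entries: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("need at least 2 centroids")
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("centroid names must be unique")
        for name, v, a in self.entries:
            if not (0.0 <= v <= 1.0 and 0.0 <= a <= 1.0):
                raise ValueError(f"centroid {name!r} outside the unit square")

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def coordinates(self) -> np.ndarray:
        """(k, 2) array of (valence, arousal) anchors, in map order."""
        return np.array([[v, a] for _, v, a in self.entries], dtype=float)


DEFAULT_CENTROIDS = CentroidMap(
    (
        ("empty", 0.188, 0.183),
        ("threatened", 0.052, 0.928),
        ("tranquil", 0.917, 0.094),
        ("excited", 0.908, 0.931),
        ("rooted", 0.51, 0.527),
    )
)


@dataclass
class EvaluationReport:
    """Container for the full regression + categorical metric set."""

    n_examples: int
    mse: dict[str, float]
    mse_combined: float
    pearson: dict[str, float]
    pearson_combined: float
    per_category: dict[str, dict[str, float]] = field(default_factory=dict)
    macro_f1: float = float("nan")
    micro_f1: float = float("nan")
    average_f1: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "n_examples": self.n_examples,
            "mse": dict(self.mse),
            "mse_combined": self.mse_combined,
            "pearson": dict(self.pearson),
            "pearson_combined": self.pearson_combined,
            "per_category": {k: dict(v) for k, v in self.per_category.items()},
            "macro_f1": self.macro_f1,
            "micro_f1": self.micro_f1,
            "average_f1": self.average_f1,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _check_pair(pred, gold) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if pred.ndim != 2 or pred.shape[1] != 3:
        raise ValueError("expected (n, 3) arrays of V/A/D triples")
    if pred.shape != gold.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {gold.shape}")
    if len(pred) == 0:
        raise ValueError("empty input")
    return pred, gold


def mse_per_dimension(pred, gold) -> tuple[float, float, float]:
    """Mean squared error separately for valence, arousal, dominance."""
    pred, gold = _check_pair(pred, gold)
    return tuple(np.mean((pred - gold) ** 2, axis=0))


def combined_vad_mse(pred, gold, mode: str = "scalar-average") -> float:
    """One combined MSE figure; see the module docstring for both modes."""
    pred, gold = _check_pair(pred, gold)
    if mode == "scalar-average":
        return float(np.mean((pred.mean(axis=1) - gold.mean(axis=1)) ** 2))
    if mode == "entrywise":
        return float(np.mean((pred - gold) ** 2))
    raise ValueError(f"unknown mode {mode!r}")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError(
            "Pearson correlation undefined for a zero-variance series"
        )
    return float(stats.pearsonr(x, y).statistic)


def pearson_per_dimension(pred, gold) -> tuple[float, float, float]:
    """Sample Pearson r per dimension; errors on zero-variance series."""
    pred, gold = _check_pair(pred, gold)
    if len(pred) < 2:
        raise ValueError("Pearson correlation needs at least 2 examples")
    return tuple(_pearson(pred[:, j], gold[:, j]) for j in range(3))


def combined_vad_r(pred, gold, mode: str = "scalar-average") -> float:
    """Combined Pearson r: correlate per-example means, or the stacked series."""
    pred, gold = _check_pair(pred, gold)
    if len(pred) < 2:
        raise ValueError("Pearson correlation needs at least 2 examples")
    if mode == "scalar-average":
        return _pearson(pred.mean(axis=1), gold.mean(axis=1))
    if mode == "concatenated":
        return _pearson(pred.ravel(order="F"), gold.ravel(order="F"))
    raise ValueError(f"unknown mode {mode!r}")


def assign_category(score, centroids: CentroidMap = DEFAULT_CENTROIDS) -> str:
    """Nearest centroid (Euclidean, VA plane only; dominance ignored).

    Ties break toward the centroid listed first in the map.
    """
    return assign_categories(np.atleast_2d(np.asarray(score, float)), centroids)[0]


def assign_categories(
    scores: np.ndarray, centroids: CentroidMap = DEFAULT_CENTROIDS
) -> list[str]:
    """Vectorized :func:`assign_category` for an (n, 2) or (n, 3) array."""
    scores = np.asarray(scores, dtype=float)
    va = scores[:, :2]
    d2 = ((va[:, None, :] - centroids.coordinates[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)  # argmin returns the first minimum: map-order ties
    names = centroids.names
    return [names[i] for i in idx]


def categorical_report(
    pred,
    gold,
    centroids: CentroidMap = DEFAULT_CENTROIDS,
) -> dict:
    """Map both sides through the centroids and score the categorization.

    Returns ``{"per_category": {name: {precision, recall, f1, support}},
    "macro_f1": ..., "micro_f1": ..., "average_f1": ...}``.  Categories
    with zero predicted positives get precision 0 (logged).
    """
    pred, gold = _check_pair(pred, gold)
    y_pred = assign_categories(pred, centroids)
    y_true = assign_categories(gold, centroids)
    labels = centroids.names
    p, r, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    empty_pred = [l for l, n in zip(labels, np.bincount(
        [labels.index(c) for c in y_pred], minlength=len(labels))) if n == 0]
    if empty_pred:
        logger.warning(
            "no predictions for categories %s; precision set to 0", empty_pred
        )
    per_category = {
        name: {
            "precision": float(p[i]),
            "recall": float(r[i]),
            "f1": float(f1[i]),
            "support": int(support[i]),
        }
        for i, name in enumerate(labels)
    }
    micro = float(np.mean(np.array(y_true) == np.array(y_pred)))
    total = support.sum()
    return {
        "per_category": per_category,
        "macro_f1": float(f1.mean()),
        "micro_f1": micro,  # pooled-count F1 == accuracy in this setting
        "average_f1": float((f1 * support).sum() / total) if total else 0.0,
    }


def evaluate(
    pred,
    gold,
    centroids: CentroidMap = DEFAULT_CENTROIDS,
    combined_mode: str = "scalar-average",
) -> EvaluationReport:
    """Full report: per-dimension + combined MSE and r, plus categorical F1."""
    pred, gold = _check_pair(pred, gold)
    mse = mse_per_dimension(pred, gold)
    r = pearson_per_dimension(pred, gold)
    cat = categorical_report(pred, gold, centroids)
    return EvaluationReport(
        n_examples=len(pred),
        mse=dict(zip(DIMENSIONS, map(float, mse))),
        mse_combined=combined_vad_mse(pred, gold, combined_mode),
        pearson=dict(zip(DIMENSIONS, map(float, r))),
        pearson_combined=combined_vad_r(pred, gold, combined_mode),
        per_category=cat["per_category"],
        macro_f1=cat["macro_f1"],
        micro_f1=cat["micro_f1"],
        average_f1=cat["average_f1"],
    )


class CentroidCategorizer:
    """Nearest-centroid mapper with a minimal sklearn-transformer surface.

    ``fit`` is stateless validation; ``predict`` maps (n, 2|3) VAD arrays
    to category names.
    """

    def __init__(self, centroids: CentroidMap = DEFAULT_CENTROIDS):
        self.centroids = centroids

    def get_params(self, deep: bool = True) -> dict:
        return {"centroids": self.centroids}

    def set_params(self, **params) -> "CentroidCategorizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "CentroidCategorizer":
        if not isinstance(self.centroids, CentroidMap):
            raise ValueError("centroids must be a CentroidMap")
        self.centroids_ = self.centroids
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "centroids_"):
            self.fit()
        return np.array(assign_categories(np.asarray(X, float), self.centroids_))
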