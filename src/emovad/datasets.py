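"""Corpus ingestion, categorical→dimensional transformation, pooling, splits.

Most emotion corpora carry categorical labels (joy, fear, ...).  To train
a dimensional regressor they are converted by looking each label word up
in a VAD lexicon and, for multi-label examples, averaging the looked-up
scores component-wise.  Natively dimensional corpora annotated on a
1–5 scale are mapped affinely onto the unit interval via (x - 1) / 4.
Transformed and native datasets are then pooled by plain concatenation
(no deduplication, so the pooled size is the exact sum of the parts) and
split train/validation/test with a seeded shuffle.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, replace
from typing import IO, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .lexicon import EmotionLexicon, VADScore

logger = logging.getLogger(__name__)

__all__ = [
    "CategoricalExample",
    "DimensionalExample",
    "Provenance",
    "EmotionDataset",
    "SplitSpec",
    "read_categorical_dataset",
    "read_dimensional_dataset",
    "write_dimensional_dataset",
    "labels_to_vad",
    "transform_dataset",
    "merge_datasets",
    "split_dataset",
    "DIALECTS",
]


@dataclass(frozen=True)
class CategoricalExample:
    """An utterance with one or more categorical emotion labels."""

    text: str
    labels: frozenset[str]

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("text must be non-empty")
        labels = frozenset(l for l in self.labels if l)
        if not labels:
            raise ValueError("at least one non-empty label required")
        object.__setattr__(self, "labels", labels)


@dataclass(frozen=True)
class DimensionalExample:
    """An utterance with a gold VAD annotation."""

    text: str
    gold: VADScore

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("text must be non-empty")


@dataclass(frozen=True)
class Provenance:
    kind: Literal["native", "transformed", "merged"]
    sources: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("provenance must list at least one source")


@dataclass
class EmotionDataset:
    """A named, ordered collection of (text, gold VAD) examples.

    Backed by a pandas DataFrame with columns
    ``text, valence, arousal, dominance``.
    """

    name: str
    df: pd.DataFrame
    provenance: Provenance

    def __post_init__(self) -> None:
        required = ["text", "valence", "arousal", "dominance"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset frame missing columns {missing}")
        self.df = self.df.loc[:, required].reset_index(drop=True)

    @classmethod
    def from_examples(
        cls,
        name: str,
        examples: Iterable[DimensionalExample],
        provenance: Provenance,
    ) -> "EmotionDataset":
        rows = [(e.text, *e.gold.as_tuple()) for e in examples]
        df = pd.DataFrame(rows, columns=["text", "valence", "arousal", "dominance"])
        return cls(name=name, df=df, provenance=provenance)

    @property
    def examples(self) -> list[DimensionalExample]:
        return [
            DimensionalExample(t, VADScore(v, a, d))
            for t, v, a, d in self.df.itertuples(index=False)
        ]

    @property
    def texts(self) -> list[str]:
        return self.df["text"].tolist()

    @property
    def vad(self) -> np.ndarray:
        """Gold scores as an (n, 3) float array, columns V/A/D."""
        return self.df[["valence", "arousal", "dominance"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions plus the shuffle seed."""

    fractions: tuple[float, float, float] = (0.784, 0.196, 0.02)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or not all(0 < f < 1 for f in self.fractions):
            raise ValueError("fractions must be three reals in (0, 1)")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 (tolerance 1e-9)")


# --------------------------------------------------------------------------
# readers
# --------------------------------------------------------------------------

#: Per-dialect column contracts for categorical corpora.
#:   fmt        — csv / tsv-headerless / jsonl
#:   text_col   — column holding the utterance
#:   label_col  — column holding the label(s)
#:   label_sep  — separator when several labels share one field
DIALECTS = {
    "goemotions-like": {"fmt": "tsv-headerless", "text_col": 0, "label_col": 1, "label_sep": ","},
    "isear-like": {"fmt": "csv", "text_col": "text", "label_col": "label", "label_sep": None},
    "crowdflower-like": {"fmt": "csv", "text_col": "content", "label_col": "sentiment", "label_sep": None},
    "generic-jsonl": {"fmt": "jsonl", "text_col": "text", "label_col": "labels", "label_sep": None},
}


def _as_stream(stream: IO[str] | str) -> IO[str]:
    if isinstance(stream, str):
        if "\n" not in stream and "\t" not in stream and not stream.lstrip().startswith("{"):
            return open(stream, encoding="utf-8")
        return io.StringIO(stream)
    return stream


def read_categorical_dataset(
    stream: IO[str] | str, dialect: str
) -> list[CategoricalExample]:
    """Read a categorical corpus in one of the supported dialects.

    Rows with empty text or an empty label set are dropped; the drop
    count is logged.  Raises ``KeyError`` for an unknown dialect and
    ``ValueError`` for a missing required column.
    """
    if dialect not in DIALECTS:
        raise KeyError(
            f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
        )
    spec = DIALECTS[dialect]
    fh = _as_stream(stream)
    examples: list[CategoricalExample] = []
    dropped = 0

    def emit(text, labels: Iterable[str]) -> None:
        nonlocal dropped
        text = str(text).strip() if text is not None and not pd.isna(text) else ""
        labels = frozenset(str(l).strip().lower() for l in labels if str(l).strip())
        if not text or not labels:
            dropped += 1
            return
        examples.append(CategoricalExample(text, labels))

    if spec["fmt"] == "jsonl":
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            if "text" not in rec:
                raise ValueError("generic-jsonl rows require a 'text' field")
            labels = rec.get("labels")
            if labels is None:
                labels = [rec["label"]] if "label" in rec else []
            elif isinstance(labels, str):
                labels = [labels]
            emit(rec.get("text"), labels)
    elif spec["fmt"] == "tsv-headerless":
        frame = pd.read_csv(fh, sep="\t", header=None, dtype=str, keep_default_na=False)
        if frame.shape[1] <= max(spec["text_col"], spec["label_col"]):
            raise ValueError(f"dialect {dialect!r} expects >= 2 tab-separated columns")
        for _, row in frame.iterrows():
            emit(row[spec["text_col"]], str(row[spec["label_col"]]).split(spec["label_sep"]))
    else:  # csv with header
        frame = pd.read_csv(fh, dtype=str, keep_default_na=False)
        for col in (spec["text_col"], spec["label_col"]):
            if col not in frame.columns:
                raise ValueError(f"dialect {dialect!r} requires column {col!r}")
        for _, row in frame.iterrows():
            raw = row[spec["label_col"]]
            labels = raw.split(spec["label_sep"]) if spec["label_sep"] else [raw]
            emit(row[spec["text_col"]], labels)

    if dropped:
        logger.info("read_categorical_dataset(%s): dropped %d empty rows", dialect, dropped)
    return examples


def read_dimensional_dataset(
    stream: IO[str] | str,
    scale: Literal["unit", "one-to-five"] = "unit",
    name: str = "dataset",
) -> EmotionDataset:
    """Read a natively dimensional corpus (CSV with header, or JSONL).

    Expected fields: ``text`` plus ``valence``/``arousal``/``dominance``
    (aliases ``V``/``A``/``D`` accepted in CSV).  Scores declared on the
    ``one-to-five`` scale are rescaled to [0, 1] via (x - 1) / 4; rows
    whose rescaled scores leave [0, 1] are rejected with a logged count.
    Non-numeric score fields raise ``ValueError``.
    """
    fh = _as_stream(stream)
    head = fh.read(1)
    fh.seek(0) if hasattr(fh, "seek") else None
    if head == "{":
        records = [json.loads(l) for l in fh if l.strip()]
        frame = pd.DataFrame.from_records(records)
    else:
        frame = pd.read_csv(fh)
        frame = frame.rename(columns={"V": "valence", "A": "arousal", "D": "dominance"})
    for col in ("text", "valence", "arousal", "dominance"):
        if col not in frame.columns:
            raise ValueError(f"dimensional corpus requires column {col!r}")

    scores = frame[["valence", "arousal", "dominance"]].apply(
        pd.to_numeric, errors="raise"
    ).to_numpy(dtype=float)
    if scale == "one-to-five":
        scores = (scores - 1.0) / 4.0
    elif scale != "unit":
        raise ValueError(f"unknown scale {scale!r}")

    texts = frame["text"].astype(str).str.strip()
    in_range = np.all((scores >= 0.0) & (scores <= 1.0), axis=1) & np.isfinite(
        scores
    ).all(axis=1)
    keep = in_range & (texts != "").to_numpy()
    rejected = int((~keep).sum())
    if rejected:
        logger.info("read_dimensional_dataset(%s): rejected %d rows", name, rejected)
    df = pd.DataFrame(
        {
            "text": texts[keep].to_numpy(),
            "valence": scores[keep, 0],
            "arousal": scores[keep, 1],
            "dominance": scores[keep, 2],
        }
    )
    return EmotionDataset(name=name, df=df, provenance=Provenance("native", (name,)))


def write_dimensional_dataset(ds: EmotionDataset, stream: IO[str] | str) -> None:
    """Write a dataset as JSONL with unit-scale scores, one record per line."""
    if isinstance(stream, str):
        with open(stream, "w", encoding="utf-8") as fh:
            write_dimensional_dataset(ds, fh)
        return
    for t, v, a, d in ds.df.itertuples(index=False):
        stream.write(
            json.dumps(
                {"text": t, "valence": v, "arousal": a, "dominance": d},
                ensure_ascii=False,
            )
            + "\n"
        )


# --------------------------------------------------------------------------
# transformation / pooling / splitting
# --------------------------------------------------------------------------

def labels_to_vad(
    labels: Iterable[str],
    lexicon: EmotionLexicon,
    missing_policy: Literal["skip", "error"] = "skip",
) -> VADScore | None:
    """Map a label set to the component-wise mean of the labels' lexicon scores.

    Under the ``skip`` policy labels absent from the lexicon are ignored;
    if none is found the function returns ``None`` (the caller drops the
    example).  Under ``error`` any absent label raises, naming it.
    """
    labels = [str(l).strip().lower() for l in labels]
    if not labels:
        raise ValueError("labels must be non-empty")
    found: list[VADScore] = []
    for label in labels:
        score = lexicon.lookup(label)
        if score is None:
            if missing_policy == "error":
                raise KeyError(f"label {label!r} not present in lexicon {lexicon.name!r}")
            continue
        found.append(score)
    if not found:
        return None
    arr = np.array([s.as_tuple() for s in found], dtype=float)
    return VADScore(*arr.mean(axis=0))


def transform_dataset(
    examples: Sequence[CategoricalExample],
    lexicon: EmotionLexicon,
    missing_policy: Literal["skip", "error"] = "skip",
    name: str = "transformed",
) -> EmotionDataset:
    """Convert a categorical corpus to a dimensional one via the lexicon.

    Input order is retained; examples whose labels all miss the lexicon
    are dropped (skip policy) with retained/dropped counts logged.
    """
    kept: list[DimensionalExample] = []
    dropped = 0
    for ex in examples:
        gold = labels_to_vad(ex.labels, lexicon, missing_policy)
        if gold is None:
            dropped += 1
            continue
        kept.append(DimensionalExample(ex.text, gold))
    logger.info(
        "transform_dataset(%s): retained %d, dropped %d", name, len(kept), dropped
    )
    ds = EmotionDataset.from_examples(name, kept, Provenance("transformed", (name,)))
    ds.dropped_count = dropped  # type: ignore[attr-defined]
    return ds


def merge_datasets(parts: Sequence[EmotionDataset], name: str = "merged") -> EmotionDataset:
    """Concatenate datasets in order; no deduplication.

    The pooled size is exactly the sum of the part sizes.
    """
    if not parts:
        raise ValueError("merge_datasets requires at least one part")
    df = pd.concat([p.df for p in parts], ignore_index=True)
    sources = tuple(s for p in parts for s in p.provenance.sources)
    return EmotionDataset(name=name, df=df, provenance=Provenance("merged", sources))


def split_dataset(
    ds: EmotionDataset, spec: SplitSpec
) -> tuple[EmotionDataset, EmotionDataset, EmotionDataset]:
    """Seeded-uniform-shuffle split into train/validation/test.

    Sizes: ``floor(N * f_train)`` and ``floor(N * f_val)``; the test part
    receives the remainder, so the three parts always partition the
    dataset.  Identical seeds reproduce identical splits.
    """
    n = len(ds)
    if n < 3:
        raise ValueError("split requires at least 3 examples")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_train = int(np.floor(n * spec.fractions[0]))
    n_val = int(np.floor(n * spec.fractions[1]))
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]

    def part(idx: np.ndarray, suffix: str) -> EmotionDataset:
        return EmotionDataset(
            name=f"{ds.name}-{suffix}",
            df=ds.df.iloc[idx].reset_index(drop=True),
            provenance=replace(ds.provenance),
        )

    return part(idx_train, "train"), part(idx_val, "validation"), part(idx_test, "test")
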