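"""Transformer-based VAD regression: encoder + dropout + 3-output linear head.

The training recipe: mean-squared-error loss, AdamW, base learning rate
3e-5, batch size 32, 20 epochs, dropout 0.1 before the head, no early
stopping and no learning-rate schedule beyond the optimizer's own
adaptivity.  Two encoder presets are built in:

``pretrained-base``
    The ALBERT-base layout (12 shared transformer blocks, hidden 768,
    12 heads, GELU feed-forward of 3072, factorized 128-dim embeddings
    over a 30k vocabulary): 11,685,891 trainable parameters including
    the 768x3+3 head.  No pretrained weights ship with the package;
    this preset names the architecture, and weights are randomly
    initialized unless a saved checkpoint is loaded.

``tiny-test``
    A 2-block, hidden-32, 2-head variant that trains from scratch in
    seconds on a CPU, used throughout the test-suite.

Text enters through a deliberately simple preprocessing layer: the
package's word tokenizer plus a vocabulary built from the training
corpus (most-frequent-first, capped at the spec's vocabulary size),
with [PAD]/[UNK]/[CLS] specials and truncation at ``max_sequence_length``.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .datasets import EmotionDataset
from .rules import tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "EncoderSpec",
    "TrainConfig",
    "TransformerVADRegressor",
    "ENCODER_PRESETS",
    "build_regressor",
    "train",
    "predict",
    "count_trainable_parameters",
]

PAD_ID, UNK_ID, CLS_ID = 0, 1, 2
N_SPECIALS = 3


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture of the text encoder.

    ``kind`` is ``pretrained-base`` (the published base configuration)
    or ``tiny-test``.  ``identifier`` names the checkpoint family for
    the base kind; it is informational unless a checkpoint is loaded.
    """

    kind: str = "tiny-test"
    num_layers: int = 2
    hidden_size: int = 32
    num_heads: int = 2
    embedding_size: int = 32
    intermediate_size: int = 64
    vocab_size: int = 512
    max_position: int = 128
    activation: str = "gelu"
    identifier: str = ""

    def __post_init__(self) -> None:
        if self.hidden_size % self.num_heads != 0:
            raise ValueError("hidden_size must be divisible by num_heads")
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")

    def to_transformer_config(self) -> nn.TransformerConfig:
        return nn.TransformerConfig(
            vocab_size=self.vocab_size,
            hidden_size=self.hidden_size,
            num_layers=self.num_layers,
            num_heads=self.num_heads,
            embedding_size=self.embedding_size,
            intermediate_size=self.intermediate_size,
            max_position=self.max_position,
        )


ENCODER_PRESETS: dict[str, EncoderSpec] = {
    "tiny-test": EncoderSpec(),
    "pretrained-base": EncoderSpec(
        kind="pretrained-base",
        num_layers=12,
        hidden_size=768,
        num_heads=12,
        embedding_size=128,
        intermediate_size=3072,
        vocab_size=30000,
        max_position=512,
        identifier="albert-en-base-v2",
    ),
}


@dataclass(frozen=True)
class TrainConfig:
    """The fixed training recipe; loss and optimizer are not pluggable."""

    loss: str = "mse"
    optimizer: str = "adamw"
    learning_rate: float = 3e-5
    batch_size: int = 32
    epochs: int = 20
    dropout: float = 0.1
    seed: int = 0
    max_sequence_length: int = 128
    weight_decay: float = 0.01

    def __post_init__(self) -> None:
        if self.loss != "mse" or self.optimizer != "adamw":
            raise ValueError("loss is fixed to 'mse' and optimizer to 'adamw'")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


def _resolve_spec(encoder: str | EncoderSpec) -> EncoderSpec:
    if isinstance(encoder, EncoderSpec):
        return encoder
    try:
        return ENCODER_PRESETS[encoder]
    except KeyError:
        raise ValueError(
            f"unknown encoder {encoder!r}; presets: {sorted(ENCODER_PRESETS)}"
        ) from None


class TransformerVADRegressor(BaseEstimator, RegressorMixin):
    """Encoder + dropout + linear-head regressor for V/A/D targets.

    Parameters mirror :class:`TrainConfig`; ``encoder`` is a preset name
    or an :class:`EncoderSpec`.  ``clamp`` clips predictions into [0, 1]
    at inference so outputs are valid VAD scores (raw head outputs are
    available via ``predict(..., clamp=False)`` for diagnostics).

    Fitted attributes: ``model_`` (parameter dict), ``config_``
    (transformer shape), ``vocab_`` (token -> id), ``history_``
    (per-epoch train/validation loss DataFrame).
    """

    def __init__(
        self,
        encoder: str | EncoderSpec = "tiny-test",
        learning_rate: float = 3e-5,
        batch_size: int = 32,
        epochs: int = 20,
        dropout: float = 0.1,
        weight_decay: float = 0.01,
        max_sequence_length: int = 128,
        warmup_fraction: float = 0.0,
        clip_norm: float | None = None,
        clamp: bool = True,
        random_state: int = 0,
    ):
        self.encoder = encoder
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout = dropout
        self.weight_decay = weight_decay
        self.max_sequence_length = max_sequence_length
        self.warmup_fraction = warmup_fraction
        self.clip_norm = clip_norm
        self.clamp = clamp
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    def initialize(self) -> "TransformerVADRegressor":
        """Build (seed-deterministic) untrained weights ahead of :meth:`fit`."""
        spec = _resolve_spec(self.encoder)
        self.encoder_spec_ = spec
        self.config_ = spec.to_transformer_config()
        rng = np.random.default_rng([int(self.random_state), 0])
        self.model_ = nn.init_parameters(self.config_, rng)
        self.vocab_ = {}
        self.history_ = pd.DataFrame(columns=["epoch", "train_loss", "val_loss"])
        return self

    def _build_vocab(self, texts: Sequence[str]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for text in texts:
            for tok in tokenize(text):
                counts[tok] = counts.get(tok, 0) + 1
        capacity = self.config_.vocab_size - N_SPECIALS
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:capacity]
        return {tok: i + N_SPECIALS for i, (tok, _) in enumerate(ranked)}

    def _encode(self, texts: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        max_body = min(self.max_sequence_length, self.config_.max_position) - 1
        rows = []
        for text in texts:
            ids = [CLS_ID] + [
                self.vocab_.get(tok, UNK_ID) for tok in tokenize(text)
            ][:max_body]
            rows.append(ids)
        width = max(len(r) for r in rows) if rows else 1
        ids = np.full((len(rows), width), PAD_ID, dtype=np.int64)
        mask = np.zeros((len(rows), width), dtype=bool)
        for i, r in enumerate(rows):
            ids[i, : len(r)] = r
            mask[i, : len(r)] = True
        return ids, mask

    # -- sklearn API -------------------------------------------------------

    def fit(self, X: Sequence[str], y, validation_data=None) -> "TransformerVADRegressor":
        """Train on utterances ``X`` and gold scores ``y`` (n x 3, in [0,1]).

        ``validation_data=(X_val, y_val)`` adds a per-epoch validation
        loss to ``history_``; validation never influences the weights
        (no early stopping, no model selection).
        """
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 3:
            raise ValueError("y must be an (n, 3) array of V/A/D scores")
        if len(X) == 0:
            raise ValueError("training set must be non-empty")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if np.any(~np.isfinite(y)) or y.min() < 0.0 or y.max() > 1.0:
            raise ValueError("gold scores must be finite and lie in [0, 1]")

        # (re)build from scratch: initialization is a pure function of
        # random_state, so build_regressor()+fit() and fit() alone coincide
        self.initialize()
        self.vocab_ = self._build_vocab(X)
        ids, mask = self._encode(X)

        val = None
        if validation_data is not None:
            Xv, yv = validation_data
            if len(Xv) == 0:
                raise ValueError("validation set must be non-empty when given")
            yv = np.asarray(yv, dtype=float)
            val = (self._encode(Xv), yv)

        rng = np.random.default_rng([int(self.random_state), 1])
        opt = nn.AdamW(
            self.model_,
            lr=self.learning_rate,
            weight_decay=self.weight_decay,
        )
        n = len(X)
        steps_per_epoch = -(-n // self.batch_size)
        warmup_steps = int(self.warmup_fraction * self.epochs * steps_per_epoch)
        step = 0
        history = []
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(n)
            total, seen = 0.0, 0
            for start in range(0, n, self.batch_size):
                step += 1
                if warmup_steps:
                    opt.lr = self.learning_rate * min(1.0, step / warmup_steps)
                sel = order[start : start + self.batch_size]
                bids, bmask = ids[sel], mask[sel]
                # re-pack to the batch's own max width to skip all-pad tail
                width = int(bmask.sum(axis=1).max())
                bids, bmask = bids[:, :width], bmask[:, :width]
                pred, cache = nn.forward(
                    self.model_, self.config_, bids, bmask,
                    dropout=self.dropout, rng=rng, train=True,
                )
                loss, dpred = nn.mse_loss(pred, y[sel])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "lower the learning rate or check the inputs"
                    )
                grads = nn.backward(self.model_, self.config_, cache, dpred)
                if self.clip_norm is not None:
                    gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
                    if gnorm > self.clip_norm:
                        scale = self.clip_norm / gnorm
                        for g in grads.values():
                            g *= scale
                opt.step(grads)
                total += loss * len(sel)
                seen += len(sel)
            train_loss = total / seen
            val_loss = np.nan
            if val is not None:
                (vids, vmask), yv = val
                vp = self._forward_eval(vids, vmask)
                val_loss = float(np.mean((vp - yv) ** 2))
            history.append((epoch, train_loss, val_loss))
            logger.info(
                "epoch %d/%d train_loss=%.6f val_loss=%s",
                epoch, self.epochs, train_loss,
                "n/a" if np.isnan(val_loss) else f"{val_loss:.6f}",
            )
        self.history_ = pd.DataFrame(
            history, columns=["epoch", "train_loss", "val_loss"]
        )
        return self

    def _forward_eval(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        preds = []
        for start in range(0, len(ids), 256):
            b = slice(start, start + 256)
            width = int(mask[b].sum(axis=1).max())
            p, _ = nn.forward(
                self.model_, self.config_, ids[b, :width], mask[b, :width]
            )
            preds.append(p)
        return np.vstack(preds)

    def predict(self, X: Sequence[str], clamp: bool | None = None) -> np.ndarray:
        """Predict one V/A/D triple per text (order-preserving, deterministic).

        Dropout is inactive at inference.  With ``clamp`` (default from
        the constructor) outputs are clipped into [0, 1].
        """
        check_is_fitted(self, "model_")
        if len(X) == 0:
            return np.empty((0, 3))
        ids, mask = self._encode(X)
        pred = self._forward_eval(ids, mask)
        if self.clamp if clamp is None else clamp:
            pred = np.clip(pred, 0.0, 1.0)
        return pred

    # -- persistence -------------------------------------------------------

    def save(self, directory: str) -> None:
        """Write a checkpoint: a JSON manifest plus an .npz weight archive."""
        check_is_fitted(self, "model_")
        os.makedirs(directory, exist_ok=True)
        manifest = {
            "encoder_spec": asdict(self.encoder_spec_),
            "params": self.get_params(deep=False) | {"encoder": None},
            "vocab": self.vocab_,
            "history": self.history_.to_dict(orient="list"),
        }
        with open(os.path.join(directory, "manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh)
        np.savez(os.path.join(directory, "weights.npz"), **self.model_)

    @classmethod
    def load(cls, directory: str) -> "TransformerVADRegressor":
        with open(os.path.join(directory, "manifest.json"), encoding="utf-8") as fh:
            manifest = json.load(fh)
        spec = EncoderSpec(**manifest["encoder_spec"])
        params = manifest["params"]
        params["encoder"] = spec
        est = cls(**params)
        est.encoder_spec_ = spec
        est.config_ = spec.to_transformer_config()
        with np.load(os.path.join(directory, "weights.npz")) as npz:
            est.model_ = {k: npz[k] for k in npz.files}
        est.vocab_ = manifest["vocab"]
        est.history_ = pd.DataFrame(manifest["history"])
        return est


# --------------------------------------------------------------------------
# thin functional wrappers
# --------------------------------------------------------------------------

def build_regressor(
    spec: EncoderSpec | str, config: TrainConfig | None = None
) -> TransformerVADRegressor:
    """Construct an untrained regressor with seed-initialized weights."""
    config = config or TrainConfig()
    est = TransformerVADRegressor(
        encoder=_resolve_spec(spec),
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        epochs=config.epochs,
        dropout=config.dropout,
        weight_decay=config.weight_decay,
        max_sequence_length=config.max_sequence_length,
        random_state=config.seed,
    )
    return est.initialize()


def train(
    model: TransformerVADRegressor,
    train_set: EmotionDataset,
    val_set: EmotionDataset,
    config: TrainConfig | None = None,
) -> TransformerVADRegressor:
    """Run the training recipe on dataset objects; returns the fitted model."""
    if config is not None:
        model.set_params(
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            epochs=config.epochs,
            dropout=config.dropout,
            weight_decay=config.weight_decay,
            max_sequence_length=config.max_sequence_length,
            random_state=config.seed,
        )
    return model.fit(
        train_set.texts, train_set.vad,
        validation_data=(val_set.texts, val_set.vad),
    )


def predict(
    model: TransformerVADRegressor, texts: Sequence[str], clamp: bool = True
) -> np.ndarray:
    return model.predict(texts, clamp=clamp)


def count_trainable_parameters(model: TransformerVADRegressor | EncoderSpec | str) -> int:
    """Total trainable scalars, encoder and head included.

    Accepts a (possibly unfitted) estimator, an :class:`EncoderSpec`, or
    a preset name; the count is computed from actual tensor shapes.
    """
    if isinstance(model, (str, EncoderSpec)):
        model = build_regressor(model)
    if not hasattr(model, "model_"):
        model.initialize()
    return nn.count_parameters(model.model_)
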