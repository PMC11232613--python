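"""Numpy transformer encoder with a linear regression head.

The architecture follows the ALBERT layout: a factorized word-embedding
(vocabulary -> a small embedding space, projected up to the hidden size)
and a single transformer block whose parameters are shared across all
layer applications.  Each block is post-norm: multi-head self-attention
with a residual connection and layer norm, then a GELU feed-forward with
a second residual and layer norm.  A tanh pooler reads the first
([CLS]) position and a bias-bearing linear head maps the pooled vector
to the regression outputs (three for V/A/D).

Everything here is plain numpy with analytic gradients — forward returns
a cache, :func:`backward` consumes it — plus a decoupled-weight-decay
Adam (AdamW) optimizer.  Gradient correctness is pinned by a
finite-difference test; cross-layer weight sharing simply accumulates
gradients over the layer applications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = [
    "TransformerConfig",
    "init_parameters",
    "count_parameters",
    "forward",
    "backward",
    "mse_loss",
    "AdamW",
]

MASK_NEG = -1.0e9  # additive logit for padded keys; exp() underflows to exactly 0


@dataclass(frozen=True)
class TransformerConfig:
    """Shapes of the encoder + head.

    ``embedding_size`` may be smaller than ``hidden_size`` (factorized
    embeddings); the up-projection exists iff they differ.  All layer
    applications share one parameter set, so ``num_layers`` changes
    compute depth but not the parameter count.
    """

    vocab_size: int
    hidden_size: int
    num_layers: int
    num_heads: int
    embedding_size: int
    intermediate_size: int
    max_position: int = 512
    type_vocab_size: int = 2
    layer_norm_eps: float = 1e-12
    n_outputs: int = 3

    def __post_init__(self) -> None:
        if self.hidden_size % self.num_heads != 0:
            raise ValueError(
                f"hidden_size {self.hidden_size} not divisible by "
                f"num_heads {self.num_heads}"
            )
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")

    @property
    def head_dim(self) -> int:
        return self.hidden_size // self.num_heads


def init_parameters(config: TransformerConfig, rng: np.random.Generator) -> dict:
    """Truncated-normal-free init: N(0, 0.02) weights, zero biases, unit LN gains."""
    E, H, I = config.embedding_size, config.hidden_size, config.intermediate_size
    sd = 0.02

    def w(*shape):
        return rng.normal(0.0, sd, size=shape)

    p = {
        "emb_tok": w(config.vocab_size, E),
        "emb_pos": w(config.max_position, E),
        "emb_type": w(config.type_vocab_size, E),
        "emb_ln_g": np.ones(E),
        "emb_ln_b": np.zeros(E),
        "attn_q_w": w(H, H), "attn_q_b": np.zeros(H),
        "attn_k_w": w(H, H), "attn_k_b": np.zeros(H),
        "attn_v_w": w(H, H), "attn_v_b": np.zeros(H),
        "attn_o_w": w(H, H), "attn_o_b": np.zeros(H),
        "attn_ln_g": np.ones(H), "attn_ln_b": np.zeros(H),
        "ffn_in_w": w(H, I), "ffn_in_b": np.zeros(I),
        "ffn_out_w": w(I, H), "ffn_out_b": np.zeros(H),
        "ffn_ln_g": np.ones(H), "ffn_ln_b": np.zeros(H),
        "pool_w": w(H, H), "pool_b": np.zeros(H),
        "head_w": w(H, config.n_outputs), "head_b": np.zeros(config.n_outputs),
    }
    if E != H:
        p["emb_proj_w"] = w(E, H)
        p["emb_proj_b"] = np.zeros(H)
    return p


def count_parameters(params: dict) -> int:
    """Total number of trainable scalars across all tensors."""
    return int(sum(v.size for v in params.values()))


# --------------------------------------------------------------------------
# primitive forward/backward pairs
# --------------------------------------------------------------------------

def _layer_norm(x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def _layer_norm_backward(dy: np.ndarray, cache) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xhat, inv, g = cache
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    return dx, dg, db


def _gelu(x: np.ndarray):
    cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
    return x * cdf, (x, cdf)


def _gelu_backward(dy: np.ndarray, cache) -> np.ndarray:
    x, cdf = cache
    pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
    return dy * (cdf + x * pdf)


def _softmax_lastaxis(s: np.ndarray) -> np.ndarray:
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def _split_heads(x: np.ndarray, nh: int) -> np.ndarray:
    B, L, H = x.shape
    return x.reshape(B, L, nh, H // nh).transpose(0, 2, 1, 3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    B, nh, L, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, L, nh * dh)


def _attention_forward(h, params, config, key_mask):
    """Multi-head self-attention; ``key_mask`` (B, L) True = real token."""
    nh, dh = config.num_heads, config.head_dim
    q = h @ params["attn_q_w"] + params["attn_q_b"]
    k = h @ params["attn_k_w"] + params["attn_k_b"]
    v = h @ params["attn_v_w"] + params["attn_v_b"]
    qh, kh, vh = (_split_heads(t, nh) for t in (q, k, v))
    scores = np.einsum("bnqd,bnkd->bnqk", qh, kh) / math.sqrt(dh)
    scores = scores + np.where(key_mask, 0.0, MASK_NEG)[:, None, None, :]
    attn = _softmax_lastaxis(scores)
    ctx = np.einsum("bnqk,bnkd->bnqd", attn, vh)
    merged = _merge_heads(ctx)
    out = merged @ params["attn_o_w"] + params["attn_o_b"]
    cache = (h, qh, kh, vh, attn, merged)
    return out, cache


def _attention_backward(dout, cache, params, config, grads):
    h, qh, kh, vh, attn, merged = cache
    nh, dh = config.num_heads, config.head_dim
    grads["attn_o_w"] += np.einsum("bli,blo->io", merged, dout)
    grads["attn_o_b"] += dout.sum(axis=(0, 1))
    dmerged = dout @ params["attn_o_w"].T
    dctx = _split_heads(dmerged, nh)
    dattn = np.einsum("bnqd,bnkd->bnqk", dctx, vh)
    dvh = np.einsum("bnqk,bnqd->bnkd", attn, dctx)
    ds = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
    ds = ds / math.sqrt(dh)
    dqh = np.einsum("bnqk,bnkd->bnqd", ds, kh)
    dkh = np.einsum("bnqk,bnqd->bnkd", ds, qh)
    dq, dk, dv = (_merge_heads(t) for t in (dqh, dkh, dvh))
    dh_total = np.zeros_like(h)
    for name, d in (("attn_q", dq), ("attn_k", dk), ("attn_v", dv)):
        grads[f"{name}_w"] += np.einsum("bli,blo->io", h, d)
        grads[f"{name}_b"] += d.sum(axis=(0, 1))
        dh_total += d @ params[f"{name}_w"].T
    return dh_total


def _block_forward(h, params, config, key_mask):
    attn_out, attn_cache = _attention_forward(h, params, config, key_mask)
    h1, ln1_cache = _layer_norm(
        h + attn_out, params["attn_ln_g"], params["attn_ln_b"], config.layer_norm_eps
    )
    pre = h1 @ params["ffn_in_w"] + params["ffn_in_b"]
    act, gelu_cache = _gelu(pre)
    ffn_out = act @ params["ffn_out_w"] + params["ffn_out_b"]
    h2, ln2_cache = _layer_norm(
        h1 + ffn_out, params["ffn_ln_g"], params["ffn_ln_b"], config.layer_norm_eps
    )
    return h2, (attn_cache, ln1_cache, h1, act, gelu_cache, ln2_cache)


def _block_backward(dh2, cache, params, config, grads):
    attn_cache, ln1_cache, h1, act, gelu_cache, ln2_cache = cache
    dsum2, dg2, db2 = _layer_norm_backward(dh2, ln2_cache)
    grads["ffn_ln_g"] += dg2
    grads["ffn_ln_b"] += db2
    # residual: h2 = LN(h1 + ffn(h1))
    dffn = dsum2
    grads["ffn_out_w"] += np.einsum("bli,blo->io", act, dffn)
    grads["ffn_out_b"] += dffn.sum(axis=(0, 1))
    dact = dffn @ params["ffn_out_w"].T
    dpre = _gelu_backward(dact, gelu_cache)
    grads["ffn_in_w"] += np.einsum("bli,blo->io", h1, dpre)
    grads["ffn_in_b"] += dpre.sum(axis=(0, 1))
    dh1 = dsum2 + dpre @ params["ffn_in_w"].T
    dsum1, dg1, db1 = _layer_norm_backward(dh1, ln1_cache)
    grads["attn_ln_g"] += dg1
    grads["attn_ln_b"] += db1
    dh = dsum1 + _attention_backward(dsum1, attn_cache, params, config, grads)
    return dh


def forward(
    params: dict,
    config: TransformerConfig,
    ids: np.ndarray,
    key_mask: np.ndarray,
    *,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    train: bool = False,
):
    """Run the full model on a padded id batch.

    ids : (B, L) int token ids (position 0 is [CLS]); key_mask : (B, L)
    bool, True where the token is real.  Dropout is applied to the pooled
    vector only when ``train`` is set and requires ``rng``.

    Returns (predictions (B, n_outputs), cache for :func:`backward`).
    """
    B, L = ids.shape
    if L > config.max_position:
        raise ValueError(f"sequence length {L} exceeds max_position {config.max_position}")
    x = params["emb_tok"][ids] + params["emb_pos"][:L][None, :, :] + params["emb_type"][0]
    x, emb_ln_cache = _layer_norm(
        x, params["emb_ln_g"], params["emb_ln_b"], config.layer_norm_eps
    )
    if "emb_proj_w" in params:
        h = x @ params["emb_proj_w"] + params["emb_proj_b"]
        proj_in = x
    else:
        h = x
        proj_in = None

    block_caches = []
    for _ in range(config.num_layers):
        h, cache = _block_forward(h, params, config, key_mask)
        block_caches.append(cache)

    cls = h[:, 0, :]
    pooled = np.tanh(cls @ params["pool_w"] + params["pool_b"])
    if train and dropout > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        drop_mask = (rng.random(pooled.shape) >= dropout) / (1.0 - dropout)
    else:
        drop_mask = np.ones_like(pooled)
    dropped = pooled * drop_mask
    pred = dropped @ params["head_w"] + params["head_b"]
    cache = (ids, key_mask, emb_ln_cache, proj_in, block_caches, cls, pooled,
             drop_mask, dropped)
    return pred, cache


def backward(params: dict, config: TransformerConfig, cache, dpred: np.ndarray) -> dict:
    """Gradients of the scalar loss w.r.t. every parameter tensor.

    Shared-block gradients accumulate over the ``num_layers`` applications.
    """
    (ids, key_mask, emb_ln_cache, proj_in, block_caches, cls, pooled,
     drop_mask, dropped) = cache
    B, L = ids.shape
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    grads["head_w"] += dropped.T @ dpred
    grads["head_b"] += dpred.sum(axis=0)
    ddropped = dpred @ params["head_w"].T
    dpooled = ddropped * drop_mask
    dz = dpooled * (1.0 - pooled * pooled)  # tanh'
    grads["pool_w"] += cls.T @ dz
    grads["pool_b"] += dz.sum(axis=0)
    dcls = dz @ params["pool_w"].T

    dh = np.zeros((B, L, config.hidden_size))
    dh[:, 0, :] = dcls
    for cache_i in reversed(block_caches):
        dh = _block_backward(dh, cache_i, params, config, grads)

    if proj_in is not None:
        grads["emb_proj_w"] += np.einsum("bli,blo->io", proj_in, dh)
        grads["emb_proj_b"] += dh.sum(axis=(0, 1))
        dx = dh @ params["emb_proj_w"].T
    else:
        dx = dh
    demb, dg, db = _layer_norm_backward(dx, emb_ln_cache)
    grads["emb_ln_g"] += dg
    grads["emb_ln_b"] += db
    np.add.at(grads["emb_tok"], ids, demb)
    grads["emb_pos"][:L] += demb.sum(axis=0)
    grads["emb_type"][0] += demb.sum(axis=(0, 1))
    return grads


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over every output scalar, and its gradient."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    dpred = 2.0 * diff / diff.size
    return loss, dpred


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay is skipped for biases and layer-norm parameters (names
    ending in ``_b`` or ``_g``), the usual convention.
    """

    def __init__(
        self,
        params: dict,
        lr: float = 3e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for name, p in self.params.items():
            g = grads[name]
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and not name.endswith(("_b", "_g")):
                update = update + self.weight_decay * p
            p -= self.lr * update
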