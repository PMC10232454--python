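"""Decoder-only transformer in NumPy with hand-written backward passes.

The network is the standard GPT-style stack: learned token + positional
embeddings, ``n_layers`` pre-norm decoder blocks

    z = x + MHA(LayerNorm(x))
    out = z + MLP(LayerNorm(z))

a final layer norm and a linear head, with causal masking inside the
attention so position *t* only ever sees positions <= *t*. All parameters are
float64 arrays in a flat name -> array dict; gradients mirror that dict.
Correctness of every backward pass is established against central finite
differences in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy.special import erf

_EPS_LN = 1e-5
_INIT_STD = 0.02


@dataclass(frozen=True)
class DecoderConfig:
    """Architecture hyperparameters of the causal decoder.

    Defaults follow the reference configuration: 4 layers, 8 heads,
    d_model 512, feed-forward width 1024, maximum sequence length 150.
    """

    vocab_size: int
    n_layers: int = 4
    n_heads: int = 8
    d_model: int = 512
    d_ff: int = 1024
    max_len: int = 150
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model {self.d_model} not divisible by n_heads {self.n_heads}"
            )
        if self.max_len < 2:
            raise ValueError("max_len must be >= 2 (one token plus [EOS])")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.vocab_size < 4:
            raise ValueError("vocab_size must include specials plus >= 1 token")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DecoderConfig":
        return cls(**d)


def init_params(cfg: DecoderConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Truncated-normal (sigma 0.02, clipped at 2 sigma) weights, zero biases."""

    def tn(*shape):
        w = rng.normal(0.0, _INIT_STD, size=shape)
        return np.clip(w, -2 * _INIT_STD, 2 * _INIT_STD)

    D, F, V, L = cfg.d_model, cfg.d_ff, cfg.vocab_size, cfg.max_len
    p: dict[str, np.ndarray] = {
        "tok_emb": tn(V, D),
        "pos_emb": tn(L, D),
        "lnf.g": np.ones(D),
        "lnf.b": np.zeros(D),
        "head.w": tn(D, V),
        "head.b": np.zeros(V),
    }
    for i in range(cfg.n_layers):
        p[f"l{i}.ln1.g"] = np.ones(D)
        p[f"l{i}.ln1.b"] = np.zeros(D)
        p[f"l{i}.ln2.g"] = np.ones(D)
        p[f"l{i}.ln2.b"] = np.zeros(D)
        for nm in ("wq", "wk", "wv", "wo"):
            p[f"l{i}.attn.{nm}"] = tn(D, D)
        for nm in ("bq", "bk", "bv", "bo"):
            p[f"l{i}.attn.{nm}"] = np.zeros(D)
        p[f"l{i}.mlp.w1"] = tn(D, F)
        p[f"l{i}.mlp.b1"] = np.zeros(F)
        p[f"l{i}.mlp.w2"] = tn(F, D)
        p[f"l{i}.mlp.b2"] = np.zeros(D)
    return p


# ---------------------------------------------------------------------------
# primitive ops (forward returns a cache consumed by the matching backward)
# ---------------------------------------------------------------------------

def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    z = x - m
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def _layernorm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _EPS_LN)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    axes = tuple(range(dy.ndim - 1))
    dg = (dy * xhat).sum(axis=axes)
    db = dy.sum(axis=axes)
    dxh = dy * g
    dx = inv * (
        dxh
        - dxh.mean(axis=-1, keepdims=True)
        - xhat * (dxh * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dg, db


def _linear_fwd(x, w, b):
    return x @ w + b, x


def _linear_bwd(dy, x, w):
    dx = dy @ w.T
    dw = x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
    db = dy.reshape(-1, dy.shape[-1]).sum(axis=0)
    return dx, dw, db


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _gelu_fwd(x):
    return 0.5 * x * (1.0 + erf(x / _SQRT2)), x


def _gelu_bwd(dy, x):
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return dy * (cdf + x * pdf)


def causal_mask(T: int) -> np.ndarray:
    """Boolean (T, T) matrix; True where attention is allowed (j <= i)."""
    return np.tril(np.ones((T, T), dtype=bool))


def attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
              mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Scaled dot-product attention ``softmax(Q K^T / sqrt(d)) V``.

    ``mask`` is boolean with True marking allowed key positions; masked
    entries receive ``-inf`` before the softmax, so each output row is a
    convex combination of the allowed value rows only.
    """
    d = Q.shape[-1]
    scores = Q @ np.swapaxes(K, -1, -2) / math.sqrt(d)
    if mask is not None:
        scores = np.where(mask, scores, -np.inf)
    return softmax(scores) @ V


def _mha_fwd(x, p, prefix, n_heads, mask, train, drop, rng):
    B, T, D = x.shape
    dh = D // n_heads
    q, _ = _linear_fwd(x, p[f"{prefix}.wq"], p[f"{prefix}.bq"])
    k, _ = _linear_fwd(x, p[f"{prefix}.wk"], p[f"{prefix}.bk"])
    v, _ = _linear_fwd(x, p[f"{prefix}.wv"], p[f"{prefix}.bv"])

    def split(a):  # (B,T,D) -> (B,H,T,dh)
        return a.reshape(B, T, n_heads, dh).transpose(0, 2, 1, 3)

    qh, kh, vh = split(q), split(k), split(v)
    scores = qh @ np.swapaxes(kh, -1, -2) / math.sqrt(dh)
    scores = np.where(mask, scores, -np.inf)
    A = softmax(scores)
    oh = A @ vh  # (B,H,T,dh)
    o = oh.transpose(0, 2, 1, 3).reshape(B, T, D)
    out, _ = _linear_fwd(o, p[f"{prefix}.wo"], p[f"{prefix}.bo"])
    dm = None
    if train and drop > 0.0:
        dm = (rng.random(out.shape) >= drop) / (1.0 - drop)
        out = out * dm
    cache = (x, qh, kh, vh, A, o, dm)
    return out, cache


def _mha_bwd(dout, p, prefix, n_heads, cache, grads):
    x, qh, kh, vh, A, o, dm = cache
    B, T, D = x.shape
    dh = D // n_heads
    if dm is not None:
        dout = dout * dm
    do, dwo, dbo = _linear_bwd(dout, o, p[f"{prefix}.wo"])
    grads[f"{prefix}.wo"] += dwo
    grads[f"{prefix}.bo"] += dbo
    doh = do.reshape(B, T, n_heads, dh).transpose(0, 2, 1, 3)
    dA = doh @ np.swapaxes(vh, -1, -2)
    dvh = np.swapaxes(A, -1, -2) @ doh
    dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    scale = 1.0 / math.sqrt(dh)
    dqh = dS @ kh * scale
    dkh = np.swapaxes(dS, -1, -2) @ qh * scale

    def unsplit(a):  # (B,H,T,dh) -> (B,T,D)
        return a.transpose(0, 2, 1, 3).reshape(B, T, D)

    dx = np.zeros_like(x)
    for nm, da in (("wq", unsplit(dqh)), ("wk", unsplit(dkh)), ("wv", unsplit(dvh))):
        dxi, dw, db = _linear_bwd(da, x, p[f"{prefix}.{nm}"])
        grads[f"{prefix}.{nm}"] += dw
        grads[f"{prefix}.b{nm[1]}"] += db
        dx += dxi
    return dx


def multi_head_attention(x: np.ndarray, params: dict[str, np.ndarray], prefix: str,
                         n_heads: int, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Multi-head attention over a (T, d_model) sequence or (B, T, d_model) batch."""
    squeeze = x.ndim == 2
    xb = x[None] if squeeze else x
    T = xb.shape[1]
    m = causal_mask(T) if mask is None else mask
    out, _ = _mha_fwd(xb, params, prefix, n_heads, m, False, 0.0, None)
    return out[0] if squeeze else out


def _block_fwd(x, p, i, n_heads, mask, train, drop, rng):
    h1, ln1c = _layernorm_fwd(x, p[f"l{i}.ln1.g"], p[f"l{i}.ln1.b"])
    a, mhac = _mha_fwd(h1, p, f"l{i}.attn", n_heads, mask, train, drop, rng)
    z = x + a
    h2, ln2c = _layernorm_fwd(z, p[f"l{i}.ln2.g"], p[f"l{i}.ln2.b"])
    u, _ = _linear_fwd(h2, p[f"l{i}.mlp.w1"], p[f"l{i}.mlp.b1"])
    gact, gcache = _gelu_fwd(u)
    m, _ = _linear_fwd(gact, p[f"l{i}.mlp.w2"], p[f"l{i}.mlp.b2"])
    dm = None
    if train and drop > 0.0:
        dm = (rng.random(m.shape) >= drop) / (1.0 - drop)
        m = m * dm
    out = z + m
    cache = (ln1c, mhac, z, ln2c, h2, gcache, gact, dm)
    return out, cache


def _block_bwd(dout, p, i, n_heads, cache, grads):
    ln1c, mhac, z, ln2c, h2, gcache, gact, dm = cache
    dmlp = dout if dm is None else dout * dm
    dg, dw2, db2 = _linear_bwd(dmlp, gact, p[f"l{i}.mlp.w2"])
    grads[f"l{i}.mlp.w2"] += dw2
    grads[f"l{i}.mlp.b2"] += db2
    du = _gelu_bwd(dg, gcache)
    dh2, dw1, db1 = _linear_bwd(du, h2, p[f"l{i}.mlp.w1"])
    grads[f"l{i}.mlp.w1"] += dw1
    grads[f"l{i}.mlp.b1"] += db1
    dz_ln, dg2, db2n = _layernorm_bwd(dh2, ln2c)
    grads[f"l{i}.ln2.g"] += dg2
    grads[f"l{i}.ln2.b"] += db2n
    dz = dout + dz_ln
    da = dz
    dh1 = _mha_bwd(da, p, f"l{i}.attn", n_heads, mhac, grads)
    dx_ln, dg1, db1n = _layernorm_bwd(dh1, ln1c)
    grads[f"l{i}.ln1.g"] += dg1
    grads[f"l{i}.ln1.b"] += db1n
    return dz + dx_ln


def decoder_block(x: np.ndarray, params: dict[str, np.ndarray], layer: int,
                  n_heads: int, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """One pre-norm decoder block (inference mode) on (T, D) or (B, T, D) input."""
    squeeze = x.ndim == 2
    xb = x[None] if squeeze else x
    T = xb.shape[1]
    m = causal_mask(T) if mask is None else mask
    out, _ = _block_fwd(xb, params, layer, n_heads, m, False, 0.0, None)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

def forward(params: dict[str, np.ndarray], cfg: DecoderConfig, ids: np.ndarray,
            *, train: bool = False, rng: Optional[np.random.Generator] = None,
            return_cache: bool = False):
    """Logits over the vocabulary for every position of every sequence.

    ``ids`` is an integer array (B, T); row *t* of the output conditions only
    on tokens at positions <= *t* (enforced by the causal mask).
    """
    ids = np.asarray(ids)
    if ids.ndim == 1:
        ids = ids[None]
    B, T = ids.shape
    if T > cfg.max_len:
        raise ValueError(f"sequence length {T} exceeds max_len {cfg.max_len}")
    drop = cfg.dropout if train else 0.0
    if train and drop > 0.0 and rng is None:
        raise ValueError("training-mode forward with dropout requires an rng")

    x = params["tok_emb"][ids] + params["pos_emb"][:T]
    emb_dm = None
    if train and drop > 0.0:
        emb_dm = (rng.random(x.shape) >= drop) / (1.0 - drop)
        x = x * emb_dm
    m = causal_mask(T)
    block_caches = []
    for i in range(cfg.n_layers):
        x, c = _block_fwd(x, params, i, cfg.n_heads, m, train, drop, rng)
        block_caches.append(c)
    h, lnfc = _layernorm_fwd(x, params["lnf.g"], params["lnf.b"])
    logits, _ = _linear_fwd(h, params["head.w"], params["head.b"])
    if not return_cache:
        return logits
    cache = (ids, emb_dm, block_caches, lnfc, h)
    return logits, cache


def backward(dlogits: np.ndarray, params: dict[str, np.ndarray], cfg: DecoderConfig,
             cache) -> dict[str, np.ndarray]:
    """Parameter gradients for a scalar loss with ``d loss / d logits`` given."""
    ids, emb_dm, block_caches, lnfc, h = cache
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dh, dwh, dbh = _linear_bwd(dlogits, h, params["head.w"])
    grads["head.w"] += dwh
    grads["head.b"] += dbh
    dx, dgf, dbf = _layernorm_bwd(dh, lnfc)
    grads["lnf.g"] += dgf
    grads["lnf.b"] += dbf
    for i in reversed(range(cfg.n_layers)):
        dx = _block_bwd(dx, params, i, cfg.n_heads, block_caches[i], grads)
    if emb_dm is not None:
        dx = dx * emb_dm
    np.add.at(grads["tok_emb"], ids, dx)
    grads["pos_emb"][: ids.shape[1]] += dx.sum(axis=0)
    return grads


def weighted_nll_loss(params: dict[str, np.ndarray], cfg: DecoderConfig,
                      inputs: np.ndarray, targets: np.ndarray,
                      weights: Optional[np.ndarray] = None, *,
                      train: bool = False,
                      rng: Optional[np.random.Generator] = None,
                      action_mask: Optional[np.ndarray] = None):
    """Position-weighted negative log-likelihood and its parameter gradients.

    loss = - sum_{b,t} w_{b,t} * ln softmax(logits)_{b,t}[target_{b,t}]

    ``targets`` entries < 0 are ignored. With ``weights=None`` the weights are
    1 / (#unignored positions): the mean next-token cross-entropy used for
    language-model training. Explicit weights implement the REINFORCE
    objective (w = G_t / batch). ``action_mask`` (bool, over the vocabulary)
    restricts the softmax support, matching the sampler's action space.
    """
    logits, cache = forward(params, cfg, inputs, train=train, rng=rng,
                            return_cache=True)
    if action_mask is not None:
        logits = np.where(action_mask, logits, -np.inf)
    B, T, V = logits.shape
    targets = np.asarray(targets)
    valid = targets >= 0
    tsafe = np.where(valid, targets, 0)
    logp = log_softmax(logits)
    picked = np.take_along_axis(logp, tsafe[..., None], axis=-1)[..., 0]
    picked = np.where(valid, picked, 0.0)  # ignored positions carry no loss
    if weights is None:
        n = max(int(valid.sum()), 1)
        w = valid / n
    else:
        w = np.where(valid, weights, 0.0)
    loss = -float((w * picked).sum())
    probs = np.exp(logp)
    probs = np.where(np.isfinite(logp), probs, 0.0)
    dlogits = probs * w[..., None]
    np.subtract.at(
        dlogits.reshape(-1, V), (np.arange(B * T), tsafe.reshape(-1)), w.reshape(-1)
    )
    grads = backward(dlogits, params, cfg, cache)
    return loss, grads


class Adam:
    """Adam optimizer over a flat parameter dict (in-place updates)."""

    def __init__(self, lr: float = 1e-4, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
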