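"""Minimal NumPy neural-network engine.

Dense / LayerNorm / Embedding / multi-head self-attention layers with
hand-written forward and backward passes, an Adam optimizer, and a masked
cross-entropy loss.  Every layer caches what its backward pass needs; call
``forward`` then ``backward`` in matching order.  Gradients accumulate into
``Parameter.grad`` so weight tying (e.g. a token-embedding table shared by
two encoders) works by sharing the Parameter object.

Computation defaults to float32 for speed; ``set_dtype(np.float64)``
switches precision globally (used by the finite-difference gradient checks
in the test suite).
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "Parameter", "Dense", "LayerNorm", "Embedding", "Dropout",
    "MultiHeadSelfAttention", "EncoderLayer", "TransformerEncoder",
    "Adam", "masked_cross_entropy", "relu",
]

_NEG_INF = -1e9

#: Global parameter/activation dtype; see :func:`set_dtype`.
DTYPE = np.float32


def set_dtype(dtype) -> None:
    """Set the dtype used by newly constructed layers (float32/float64)."""
    global DTYPE
    DTYPE = np.dtype(dtype).type


class Parameter:
    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _relu_grad(x: np.ndarray) -> np.ndarray:
    return (x > 0.0).astype(x.dtype)


class Dense:
    """Affine map on the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, name: str = ""):
        std = math.sqrt(2.0 / (d_in + d_out))
        self.W = Parameter(rng.normal(0.0, std, (d_in, d_out)), name + ".W")
        self.b = Parameter(np.zeros(d_out), name + ".b")
        self._x: Optional[np.ndarray] = None

    def params(self) -> List[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, d: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = d.reshape(-1, d.shape[-1])
        self.W.grad += x2.T @ d2
        self.b.grad += d2.sum(axis=0)
        return d @ self.W.data.T


class LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5, name: str = ""):
        self.gamma = Parameter(np.ones(dim), name + ".gamma")
        self.beta = Parameter(np.zeros(dim), name + ".beta")
        self.eps = eps

    def params(self) -> List[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma.data * self._xhat + self.beta.data

    def backward(self, d: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (d * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.beta.grad += d.reshape(-1, d.shape[-1]).sum(axis=0)
        dxhat = d * self.gamma.data
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class Embedding:
    def __init__(self, n: int, dim: int, rng: np.random.Generator, name: str = ""):
        self.table = Parameter(rng.normal(0.0, 0.02, (n, dim)), name + ".table")

    def params(self) -> List[Parameter]:
        return [self.table]

    def forward(self, ids: np.ndarray) -> np.ndarray:
        self._ids = ids
        return self.table.data[ids]

    def backward(self, d: np.ndarray) -> None:
        self.backward_for(self._ids, d)

    def backward_for(self, ids: np.ndarray, d: np.ndarray) -> None:
        # stateless variant so a table shared by several encoders survives
        # interleaved forward passes
        np.add.at(self.table.grad, ids, d)


class Dropout:
    """Inverted dropout; identity when not training or p == 0."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p <= 0.0:
            self._mask = None
            return x
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = np.multiply(u >= self.p, 1.0 / (1.0 - self.p),
                                 dtype=x.dtype)
        return x * self._mask

    def backward(self, d: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return d
        return d * self._mask


def _softmax_last(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention:
    def __init__(self, dim: int, n_heads: int, dropout: float,
                 rng: np.random.Generator, name: str = ""):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim, self.h = dim, n_heads
        self.dh = dim // n_heads
        self.wqkv = Dense(dim, 3 * dim, rng, name + ".wqkv")
        self.wo = Dense(dim, dim, rng, name + ".wo")
        # regularization lives on the residual branches (EncoderLayer);
        # attention probabilities are not dropped
        self.drop = Dropout(0.0, rng)

    def params(self) -> List[Parameter]:
        return self.wqkv.params() + self.wo.params()

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        return x.reshape(B, T, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, H, T, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, H * dh)

    def forward(self, x: np.ndarray, pad_mask: np.ndarray, training: bool) -> np.ndarray:
        """pad_mask: (B, T) bool, True where the position is real."""
        qkv = self.wqkv.forward(x)
        q = self._split(qkv[..., : self.dim])
        k = self._split(qkv[..., self.dim : 2 * self.dim])
        v = self._split(qkv[..., 2 * self.dim :])
        scores = q @ k.swapaxes(-1, -2) / x.dtype.type(math.sqrt(self.dh))
        bias = np.where(pad_mask, 0.0, _NEG_INF).astype(x.dtype)
        scores = scores + bias[:, None, None, :]
        attn = _softmax_last(scores)
        attn_d = self.drop.forward(attn, training)
        ctx = attn_d @ v
        self._q, self._k, self._v, self._attn = q, k, v, attn
        return self.wo.forward(self._merge(ctx))

    def backward(self, d: np.ndarray) -> np.ndarray:
        d_ctx = self._split(self.wo.backward(d))
        d_attn_d = d_ctx @ self._v.swapaxes(-1, -2)
        d_v = self._attn_dropped_T() @ d_ctx
        d_attn = self.drop.backward(d_attn_d)
        a = self._attn
        d_scores = a * (d_attn - (d_attn * a).sum(axis=-1, keepdims=True))
        d_scores /= math.sqrt(self.dh)
        d_q = d_scores @ self._k
        d_k = d_scores.swapaxes(-1, -2) @ self._q
        d_qkv = np.concatenate(
            [self._merge(d_q), self._merge(d_k), self._merge(d_v)], axis=-1)
        return self.wqkv.backward(d_qkv)

    def _attn_dropped_T(self) -> np.ndarray:
        a = self._attn
        if self.drop._mask is not None:
            a = a * self.drop._mask
        return a.swapaxes(-1, -2)


class EncoderLayer:
    """Transformer block: self-attention and position-wise FFN, each with
    residual connection, dropout and LayerNorm.

    ``pre_norm=True`` normalizes sublayer inputs (stable to optimize
    without warmup); ``pre_norm=False`` is the classic post-LN ordering.
    """

    def __init__(self, dim: int, n_heads: int, ffn_dim: int, dropout: float,
                 rng: np.random.Generator, name: str = "", pre_norm: bool = True):
        self.attn = MultiHeadSelfAttention(dim, n_heads, dropout, rng, name + ".attn")
        self.ln1 = LayerNorm(dim, name=name + ".ln1")
        self.fc1 = Dense(dim, ffn_dim, rng, name + ".fc1")
        self.fc2 = Dense(ffn_dim, dim, rng, name + ".fc2")
        self.ln2 = LayerNorm(dim, name=name + ".ln2")
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)
        self.pre_norm = pre_norm

    def params(self) -> List[Parameter]:
        return (self.attn.params() + self.ln1.params() + self.fc1.params()
                + self.fc2.params() + self.ln2.params())

    def forward(self, x: np.ndarray, pad_mask: np.ndarray, training: bool) -> np.ndarray:
        if self.pre_norm:
            a = self.attn.forward(self.ln1.forward(x), pad_mask, training)
            h = x + self.drop1.forward(a, training)
            f = self.fc1.forward(self.ln2.forward(h))
            self._f_pre = f
            f = self.fc2.forward(relu(f))
            return h + self.drop2.forward(f, training)
        a = self.drop1.forward(self.attn.forward(x, pad_mask, training), training)
        h = self.ln1.forward(x + a)
        f = self.fc1.forward(h)
        self._f_pre = f
        f = self.fc2.forward(relu(f))
        f = self.drop2.forward(f, training)
        return self.ln2.forward(h + f)

    def backward(self, d: np.ndarray) -> np.ndarray:
        if self.pre_norm:
            d_f = self.drop2.backward(d)
            d_g = self.fc2.backward(d_f)
            d_ln2 = self.fc1.backward(d_g * _relu_grad(self._f_pre))
            d_h = d + self.ln2.backward(d_ln2)
            d_a = self.drop1.backward(d_h)
            d_ln1 = self.attn.backward(d_a)
            return d_h + self.ln1.backward(d_ln1)
        d_hf = self.ln2.backward(d)
        d_f = self.drop2.backward(d_hf)
        d_g = self.fc2.backward(d_f)
        d_h = self.fc1.backward(d_g * _relu_grad(self._f_pre))
        d_h = d_h + d_hf
        d_xa = self.ln1.backward(d_h)
        d_a = self.drop1.backward(d_xa)
        return d_xa + self.attn.backward(d_a)


class TransformerEncoder:
    """Token + learned positional embeddings feeding a stack of blocks.

    ``inject`` replaces the position-0 token embedding with an externally
    supplied vector (used to condition the second encoder on the molecular
    embedding); its gradient is returned by ``backward``.
    """

    def __init__(self, token_emb: Embedding, n_layers: int, dim: int, n_heads: int,
                 dropout: float, max_positions: int, rng: np.random.Generator,
                 ffn_mult: int = 4, name: str = "enc", pre_norm: bool = True):
        self.token_emb = token_emb
        self.dim = dim
        self.pos = Parameter(rng.normal(0.0, 0.02, (max_positions, dim)), name + ".pos")
        self.layers = [
            EncoderLayer(dim, n_heads, ffn_mult * dim, dropout, rng,
                         f"{name}.layer{i}", pre_norm=pre_norm)
            for i in range(n_layers)
        ]
        self.pre_norm = pre_norm
        self.ln_f = LayerNorm(dim, name=name + ".ln_f") if pre_norm else None
        self.emb_drop = Dropout(0.0, rng)

    def params(self, own_only: bool = False) -> List[Parameter]:
        ps = [] if own_only else self.token_emb.params()
        ps = ps + [self.pos]
        for layer in self.layers:
            ps += layer.params()
        if self.ln_f is not None:
            ps += self.ln_f.params()
        return ps

    def forward(self, ids: np.ndarray, lengths: np.ndarray,
                inject: Optional[np.ndarray] = None, training: bool = False) -> np.ndarray:
        B, T = ids.shape
        if T > self.pos.data.shape[0]:
            raise ValueError(
                f"sequence length {T} exceeds max positions {self.pos.data.shape[0]}"
            )
        if inject is not None and inject.shape[-1] != self.dim:
            raise ValueError("injected embedding dimension mismatch")
        pad_mask = np.arange(T)[None, :] < np.asarray(lengths)[:, None]
        self._pad_mask = pad_mask
        self._inject = inject is not None
        self._ids = ids
        x = self.token_emb.forward(ids)
        if inject is not None:
            x = x.copy()
            x[:, 0, :] = inject
        x = x + self.pos.data[:T]
        x = self.emb_drop.forward(x, training)
        for layer in self.layers:
            x = layer.forward(x, pad_mask, training)
        if self.ln_f is not None:
            x = self.ln_f.forward(x)
        return x

    def backward(self, d: np.ndarray) -> Optional[np.ndarray]:
        if self.ln_f is not None:
            d = self.ln_f.backward(d)
        for layer in reversed(self.layers):
            d = layer.backward(d)
        d = self.emb_drop.backward(d)
        T = d.shape[1]
        self.pos.grad[:T] += d.sum(axis=0)
        d_inject = None
        if self._inject:
            d = d.copy()
            d_inject = d[:, 0, :].copy()
            d[:, 0, :] = 0.0
        self.token_emb.backward_for(self._ids, d)
        return d_inject


def masked_cross_entropy(logits: np.ndarray, target_ids: np.ndarray,
                         mask_flags: np.ndarray):
    """Mean cross-entropy over masked positions only.

    Returns (loss, d_logits, n_correct, n_masked); ``d_logits`` is dense
    with nonzero rows only at masked positions.
    """
    rows = logits[mask_flags].astype(np.float64)    # (M, V)
    targets = target_ids[mask_flags]                # (M,)
    M = rows.shape[0]
    if M == 0:
        raise ValueError("no masked positions in batch")
    z = rows - rows.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1))
    logp = z[np.arange(M), targets] - logsumexp
    loss = -logp.mean()
    probs = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)
    probs[np.arange(M), targets] -= 1.0
    d_logits = np.zeros_like(logits)
    d_logits[mask_flags] = (probs / M).astype(logits.dtype)
    n_correct = int((rows.argmax(axis=-1) == targets).sum())
    return loss, d_logits, n_correct, M


class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
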