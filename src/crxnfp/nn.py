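"""A compact BERT-style transformer encoder in NumPy with exact gradients.

Implements the reaction-fingerprint encoder: token + learned positional
embeddings, post-layer-norm transformer blocks (multi-head self-attention and
a GELU feed-forward network), and masked mean / [CLS] pooling. Forward passes
cache every intermediate so the backward pass computes exact analytic
gradients; the Adam optimizer and the warmup-then-linear-decay learning-rate
schedule used for contrastive fine-tuning live here too.

Shapes follow the (batch, tokens, hidden) convention throughout. All
computation is float64: the models trained here are small, and exact gradient
checks matter more than throughput.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import erf

__all__ = [
    "Vocabulary",
    "TransformerEncoderModel",
    "AdamOptimizer",
    "WarmupLinearSchedule",
    "mean_pool",
    "cosine",
    "cosine_mse_loss",
    "PAD_TOKEN",
    "CLS_TOKEN",
    "UNK_TOKEN",
]

PAD_TOKEN = "[PAD]"
CLS_TOKEN = "[CLS]"
UNK_TOKEN = "[UNK]"

_LN_EPS = 1e-12
_MASK_BIAS = -1e9
_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass
class Vocabulary:
    """Token ↔ id mapping with [PAD]/[CLS]/[UNK] specials at fixed positions."""

    tokens: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        specials = [PAD_TOKEN, CLS_TOKEN, UNK_TOKEN]
        ordered = specials + [t for t in self.tokens if t not in specials]
        self.tokens = ordered
        self._index = {t: i for i, t in enumerate(ordered)}

    @classmethod
    def from_corpus(cls, token_lists) -> "Vocabulary":
        seen: dict[str, None] = {}
        for toks in token_lists:
            for t in toks:
                seen.setdefault(t, None)
        return cls(tokens=sorted(seen))

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self._index[PAD_TOKEN]

    @property
    def cls_id(self) -> int:
        return self._index[CLS_TOKEN]

    @property
    def unk_id(self) -> int:
        return self._index[UNK_TOKEN]

    def encode(self, tokens) -> list[int]:
        unk = self.unk_id
        return [self._index.get(t, unk) for t in tokens]


def gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / math.sqrt(2.0))) + x * np.exp(-0.5 * x * x) / _SQRT_2PI


def _layer_norm_forward(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return xhat * gamma + beta, (xhat, inv, gamma)


def _layer_norm_backward(dout: np.ndarray, cache):
    xhat, inv, gamma = cache
    h = xhat.shape[-1]
    dgamma = (dout * xhat).sum(axis=tuple(range(dout.ndim - 1)))
    dbeta = dout.sum(axis=tuple(range(dout.ndim - 1)))
    dxhat = dout * gamma
    dx = inv / h * (
        h * dxhat
        - dxhat.sum(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
    )
    return dx, dgamma, dbeta


def mean_pool(token_vectors: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean over unmasked token vectors only.

    ``token_vectors`` is (T, H) or (B, T, H); ``mask`` is 1 for positions that
    participate in the mean (padding and, by default upstream, special tokens
    excluded). Raises if any sequence has no unmasked token.
    """
    vecs = np.asarray(token_vectors, dtype=float)
    m = np.asarray(mask, dtype=float)
    squeeze = vecs.ndim == 2
    if squeeze:
        vecs, m = vecs[None], m[None]
    counts = m.sum(axis=1)
    if np.any(counts == 0):
        raise ValueError("mean_pool received a fully masked sequence")
    pooled = (vecs * m[:, :, None]).sum(axis=1) / counts[:, None]
    return pooled[0] if squeeze else pooled


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two vectors; zero-norm input is an error."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def _batched_cosine(u: np.ndarray, v: np.ndarray):
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("cosine similarity undefined for a zero vector")
    dots = (u * v).sum(axis=1)
    cos = dots / (nu * nv)
    return cos, (nu, nv, dots)


def cosine_mse_loss(u: np.ndarray, v: np.ndarray, targets: np.ndarray):
    """Mean squared error between pairwise cosine similarities and targets.

    Returns (loss, cos, du, dv) with analytic gradients w.r.t. both embedding
    batches.
    """
    targets = np.asarray(targets, dtype=float)
    cos, (nu, nv, dots) = _batched_cosine(u, v)
    resid = cos - targets
    loss = float(np.mean(resid**2))
    dcos = 2.0 * resid / len(resid)
    # d cos / du = v/(|u||v|) - cos * u/|u|^2
    du = dcos[:, None] * (v / (nu * nv)[:, None] - cos[:, None] * u / (nu**2)[:, None])
    dv = dcos[:, None] * (u / (nu * nv)[:, None] - cos[:, None] * v / (nv**2)[:, None])
    return loss, cos, du, dv


class TransformerEncoderModel:
    """Post-LN transformer encoder over token-id sequences.

    Parameters live in ``self.params`` (name → float64 array) so the optimizer
    and checkpointing can treat the model as a flat collection of tensors.
    """

    def __init__(
        self,
        vocab_size: int,
        n_layers: int,
        hidden_size: int,
        ffn_size: int,
        n_heads: int,
        max_len: int = 256,
        seed: int = 0,
        init_std: float = 0.02,
    ):
        if hidden_size % n_heads != 0:
            raise ValueError("hidden_size must be divisible by n_heads")
        self.vocab_size = vocab_size
        self.n_layers = n_layers
        self.hidden_size = hidden_size
        self.ffn_size = ffn_size
        self.n_heads = n_heads
        self.head_dim = hidden_size // n_heads
        self.max_len = max_len
        rng = np.random.default_rng(seed)

        def norm(*shape):
            return rng.normal(0.0, init_std, size=shape)

        p: dict[str, np.ndarray] = {
            "tok_emb": norm(vocab_size, hidden_size),
            "pos_emb": norm(max_len, hidden_size),
            "ln_emb.g": np.ones(hidden_size),
            "ln_emb.b": np.zeros(hidden_size),
        }
        for l in range(n_layers):
            pre = f"layer{l}."
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[pre + name] = norm(hidden_size, hidden_size)
                p[pre + name.replace("W", "b")] = np.zeros(hidden_size)
            p[pre + "ln1.g"] = np.ones(hidden_size)
            p[pre + "ln1.b"] = np.zeros(hidden_size)
            p[pre + "W1"] = norm(hidden_size, ffn_size)
            p[pre + "b1"] = np.zeros(ffn_size)
            p[pre + "W2"] = norm(ffn_size, hidden_size)
            p[pre + "b2"] = np.zeros(hidden_size)
            p[pre + "ln2.g"] = np.ones(hidden_size)
            p[pre + "ln2.b"] = np.zeros(hidden_size)
        self.params = p

    # -- forward ---------------------------------------------------------

    def forward(self, ids: np.ndarray, attn_mask: np.ndarray, need_cache: bool = True):
        """Hidden states (B, T, H) for token ids with a 0/1 attention mask."""
        p = self.params
        B, T = ids.shape
        if T > self.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {self.max_len}")
        x = p["tok_emb"][ids] + p["pos_emb"][:T][None, :, :]
        x, ln_emb_cache = _layer_norm_forward(x, p["ln_emb.g"], p["ln_emb.b"])
        key_bias = (1.0 - attn_mask)[:, None, None, :] * _MASK_BIAS
        caches = []
        attn_probs = []
        for l in range(self.n_layers):
            pre = f"layer{l}."
            x0 = x
            q = x0 @ p[pre + "Wq"] + p[pre + "bq"]
            k = x0 @ p[pre + "Wk"] + p[pre + "bk"]
            v = x0 @ p[pre + "Wv"] + p[pre + "bv"]
            qh = self._split(q)
            kh = self._split(k)
            vh = self._split(v)
            scores = qh @ kh.transpose(0, 1, 3, 2) / math.sqrt(self.head_dim)
            scores = scores + key_bias
            scores -= scores.max(axis=-1, keepdims=True)
            att = np.exp(scores)
            att /= att.sum(axis=-1, keepdims=True)
            ctx = self._merge(att @ vh)
            attn_out = ctx @ p[pre + "Wo"] + p[pre + "bo"]
            y1 = x0 + attn_out
            x1, ln1_cache = _layer_norm_forward(y1, p[pre + "ln1.g"], p[pre + "ln1.b"])
            a = x1 @ p[pre + "W1"] + p[pre + "b1"]
            h = gelu(a)
            ffn_out = h @ p[pre + "W2"] + p[pre + "b2"]
            y2 = x1 + ffn_out
            x, ln2_cache = _layer_norm_forward(y2, p[pre + "ln2.g"], p[pre + "ln2.b"])
            attn_probs.append(att)
            if need_cache:
                caches.append((x0, qh, kh, vh, att, ctx, ln1_cache, x1, a, h, ln2_cache))
        cache = {
            "ids": ids,
            "T": T,
            "ln_emb": ln_emb_cache,
            "layers": caches,
            "attn": attn_probs,
        }
        return x, cache

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        return x.reshape(B, T, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, _, T, _ = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, self.hidden_size)

    # -- backward --------------------------------------------------------

    def backward(self, cache, d_hidden: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. every parameter.

        ``d_hidden`` is the loss gradient at the final hidden states (B, T, H).
        """
        p = self.params
        grads = {name: np.zeros_like(arr) for name, arr in p.items()}
        dx = d_hidden
        scale = 1.0 / math.sqrt(self.head_dim)
        for l in reversed(range(self.n_layers)):
            pre = f"layer{l}."
            (x0, qh, kh, vh, att, ctx, ln1_cache, x1, a, h, ln2_cache) = cache["layers"][l]
            dy2, dg, db = _layer_norm_backward(dx, ln2_cache)
            grads[pre + "ln2.g"] += dg
            grads[pre + "ln2.b"] += db
            d_ffn = dy2
            dx1 = dy2.copy()
            grads[pre + "W2"] += np.einsum("btf,bth->fh", h, d_ffn)
            grads[pre + "b2"] += d_ffn.sum(axis=(0, 1))
            dh = d_ffn @ p[pre + "W2"].T
            da = dh * gelu_grad(a)
            grads[pre + "W1"] += np.einsum("bth,btf->hf", x1, da)
            grads[pre + "b1"] += da.sum(axis=(0, 1))
            dx1 += da @ p[pre + "W1"].T
            dy1, dg, db = _layer_norm_backward(dx1, ln1_cache)
            grads[pre + "ln1.g"] += dg
            grads[pre + "ln1.b"] += db
            d_attn_out = dy1
            dx0 = dy1.copy()
            grads[pre + "Wo"] += np.einsum("bth,btk->hk", ctx, d_attn_out)
            grads[pre + "bo"] += d_attn_out.sum(axis=(0, 1))
            dctx = self._split(d_attn_out @ p[pre + "Wo"].T)
            datt = dctx @ vh.transpose(0, 1, 3, 2)
            dvh = att.transpose(0, 1, 3, 2) @ dctx
            dscores = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
            dqh = dscores @ kh * scale
            dkh = dscores.transpose(0, 1, 3, 2) @ qh * scale
            dq = self._merge(dqh)
            dk = self._merge(dkh)
            dv = self._merge(dvh)
            for name, d in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
                grads[pre + name] += np.einsum("bth,btk->hk", x0, d)
                grads[pre + name.replace("W", "b")] += d.sum(axis=(0, 1))
                dx0 += d @ p[pre + name].T
            dx = dx0
        d_emb, dg, db = _layer_norm_backward(dx, cache["ln_emb"])
        grads["ln_emb.g"] += dg
        grads["ln_emb.b"] += db
        np.add.at(grads["tok_emb"], cache["ids"], d_emb)
        grads["pos_emb"][: cache["T"]] += d_emb.sum(axis=0)
        return grads

    # -- utilities -------------------------------------------------------

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()


class WarmupLinearSchedule:
    """Linear warmup to ``max_lr`` over the first fraction of steps, then
    linear decay to zero at ``total_steps``."""

    def __init__(self, max_lr: float, total_steps: int, warmup_fraction: float = 0.1):
        if not 0.0 < warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must be in (0, 1)")
        self.max_lr = max_lr
        self.total_steps = max(int(total_steps), 1)
        self.warmup_steps = max(int(round(warmup_fraction * self.total_steps)), 1)

    def lr(self, step: int) -> float:
        """Learning rate for 1-based step index."""
        if step <= self.warmup_steps:
            return self.max_lr * step / self.warmup_steps
        remaining = self.total_steps - step
        span = max(self.total_steps - self.warmup_steps, 1)
        return self.max_lr * max(remaining, 0) / span


class AdamOptimizer:
    """Standard Adam on a named-parameter dict."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
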