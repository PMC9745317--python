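"""Minimal transformer encoder in numpy with hand-written backprop.

Implements exactly what the promoter classifier needs: token + learned
positional embeddings, pre-LayerNorm encoder blocks (multi-head
self-attention with key padding masks, ReLU feed-forward), a final
LayerNorm, BOS/mean pooling and a single-logit head. float64 throughout;
gradients are validated against finite differences in the test suite.

The module is deliberately self-contained: forward passes cache what the
matching backward pass needs, so a ``forward`` must be followed by at most
one ``backward`` before the next forward (the pattern of a plain training
loop). Inference never touches the caches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

_NEG_INF = -1e9


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for attr in vars(self).values():
            if isinstance(attr, Parameter):
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, d_in ** -0.5, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.weight.grad += x2.T @ dy2
        self.bias.grad += dy2.sum(axis=0)
        return dy @ self.weight.value.T


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        flat = dy.reshape(-1, dy.shape[-1])
        self.gamma.grad += (dy * xhat).reshape(-1, dy.shape[-1]).sum(axis=0)
        self.beta.grad += flat.sum(axis=0)
        dxhat = dy * self.gamma.value
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv_std * (dxhat - m1 - xhat * m2)


class Dropout(Module):
    """Inverted dropout with an externally supplied RNG for reproducibility."""

    def __init__(self, p: float):
        self.p = p
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        if not train or self.p <= 0.0:
            self._mask = 1.0
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


def _softmax_last(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Module):
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.d, self.h, self.dh = d, n_heads, d // n_heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.attn: np.ndarray | None = None  # (B, h, T, T), kept for export

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        return x.reshape(B, T, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, h, T, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * dh)

    def forward(self, x: np.ndarray, key_mask: np.ndarray) -> np.ndarray:
        # key_mask: (B, T) with 1 on valid tokens
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        scores = np.where(key_mask[:, None, None, :] > 0, scores, _NEG_INF)
        attn = _softmax_last(scores)
        ctx = attn @ v
        self._q, self._k, self._v, self.attn = q, k, v, attn
        return self.wo.forward(self._merge(ctx))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dctx = self._split(self.wo.backward(dy))
        attn, q, k, v = self.attn, self._q, self._k, self._v
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        # softmax backward; masked keys have attn == 0 so their grad vanishes
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(self.dh)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        return (
            self.wq.backward(self._merge(dq))
            + self.wk.backward(self._merge(dk))
            + self.wv.backward(self._merge(dv))
        )


class FeedForward(Module):
    def __init__(self, d: int, d_ff: int, rng: np.random.Generator):
        self.lin1 = Linear(d, d_ff, rng)
        self.lin2 = Linear(d_ff, d, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.lin1.forward(x)
        self._pos = h > 0
        return self.lin2.forward(np.maximum(h, 0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.lin2.backward(dy) * self._pos
        return self.lin1.backward(dh)


class EncoderBlock(Module):
    """Pre-LayerNorm block: x + Attn(LN(x)); then x + FF(LN(x))."""

    def __init__(self, d: int, n_heads: int, d_ff: int, dropout: float,
                 rng: np.random.Generator):
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, n_heads, rng)
        self.drop1 = Dropout(dropout)
        self.ln2 = LayerNorm(d)
        self.ff = FeedForward(d, d_ff, rng)
        self.drop2 = Dropout(dropout)

    def forward(self, x: np.ndarray, key_mask: np.ndarray, train: bool,
                rng: np.random.Generator) -> np.ndarray:
        a = x + self.drop1.forward(self.attn.forward(self.ln1.forward(x), key_mask),
                                   train, rng)
        return a + self.drop2.forward(self.ff.forward(self.ln2.forward(a)), train, rng)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        da = dy + self.ln2.backward(self.ff.backward(self.drop2.backward(dy)))
        return da + self.ln1.backward(self.attn.backward(self.drop1.backward(da)))


@dataclass
class EncoderConfig:
    """Architecture of the promoter encoder.

    The ``tiny`` preset (2 layers, 2 heads, width 64) is the tested,
    CPU-friendly configuration; ``paper`` mirrors a BERT-base-scale stack
    (12 layers x 12 heads = 144 attention modules) for users with
    accelerators.
    """

    n_layers: int = 2
    n_heads: int = 2
    embed_dim: int = 64
    feedforward_dim: int = 128
    dropout: float = 0.1
    max_len: int = 52
    pooling: str = "first_token"  # or "mean"

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.pooling not in ("first_token", "mean"):
            raise ValueError("pooling must be 'first_token' or 'mean'")


PRESETS: dict[str, dict] = {
    "tiny": dict(n_layers=2, n_heads=2, embed_dim=64, feedforward_dim=128),
    "paper": dict(n_layers=12, n_heads=12, embed_dim=768, feedforward_dim=3072),
}


class TransformerEncoder(Module):
    """Token-level encoder with a single-logit classification head."""

    def __init__(self, config: EncoderConfig, vocab_size: int, seed: int = 0):
        self.config = config
        self.vocab_size = vocab_size
        rng = np.random.default_rng(seed)
        d = config.embed_dim
        self.tok_emb = Parameter(rng.normal(0.0, 0.02, size=(vocab_size, d)))
        self.pos_emb = Parameter(rng.normal(0.0, 0.02, size=(config.max_len, d)))
        self.emb_drop = Dropout(config.dropout)
        self.blocks = [
            EncoderBlock(d, config.n_heads, config.feedforward_dim, config.dropout, rng)
            for _ in range(config.n_layers)
        ]
        self.ln_f = LayerNorm(d)
        self.head = Linear(d, 1, rng)
        self._drop_rng = np.random.default_rng(seed + 1)

    # -- forward / backward ------------------------------------------------
    def forward(
        self,
        ids: np.ndarray,
        mask: np.ndarray,
        train: bool = False,
        return_attention: bool = False,
    ):
        """Logits (B,) for a batch of token ids; optionally attention tensors.

        ``mask`` is (B, T) with 1 on non-PAD tokens.
        """
        B, T = ids.shape
        if T > self.config.max_len:
            raise ValueError(f"input length {T} exceeds max_len {self.config.max_len}")
        self._ids = ids
        x = self.tok_emb.value[ids] + self.pos_emb.value[:T]
        x = self.emb_drop.forward(x, train, self._drop_rng)
        for block in self.blocks:
            x = block.forward(x, mask, train, self._drop_rng)
        x = self.ln_f.forward(x)
        self._mask = mask
        if self.config.pooling == "first_token":
            pooled = x[:, 0, :]
        else:
            w = mask[:, :, None].astype(np.float64)
            self._mass = w.sum(axis=1)
            pooled = (x * w).sum(axis=1) / self._mass
        self._x_shape = x.shape
        logits = self.head.forward(pooled)[:, 0]
        if return_attention:
            return logits, np.stack([b.attn.attn for b in self.blocks], axis=0)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        dpooled = self.head.backward(dlogits[:, None])
        B, T, d = self._x_shape
        if self.config.pooling == "first_token":
            dx = np.zeros((B, T, d))
            dx[:, 0, :] = dpooled
        else:
            w = self._mask[:, :, None].astype(np.float64)
            dx = w * (dpooled[:, None, :] / self._mass[:, None, :])
        dx = self.ln_f.backward(dx)
        for block in reversed(self.blocks):
            dx = block.backward(dx)
        dx = self.emb_drop.backward(dx)
        np.add.at(self.tok_emb.grad, self._ids, dx)
        self.pos_emb.grad[:T] += dx.sum(axis=0)

    # -- (de)serialisation -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {"tok_emb": self.tok_emb.value, "pos_emb": self.pos_emb.value}
        for i, b in enumerate(self.blocks):
            pre = f"block{i}."
            state.update({
                pre + "ln1.gamma": b.ln1.gamma.value, pre + "ln1.beta": b.ln1.beta.value,
                pre + "ln2.gamma": b.ln2.gamma.value, pre + "ln2.beta": b.ln2.beta.value,
            })
            for name in ("wq", "wk", "wv", "wo"):
                lin = getattr(b.attn, name)
                state[pre + f"attn.{name}.weight"] = lin.weight.value
                state[pre + f"attn.{name}.bias"] = lin.bias.value
            for name in ("lin1", "lin2"):
                lin = getattr(b.ff, name)
                state[pre + f"ff.{name}.weight"] = lin.weight.value
                state[pre + f"ff.{name}.bias"] = lin.bias.value
        state["ln_f.gamma"] = self.ln_f.gamma.value
        state["ln_f.beta"] = self.ln_f.beta.value
        state["head.weight"] = self.head.weight.value
        state["head.bias"] = self.head.bias.value
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        if set(own) != set(state):
            raise ValueError("state dict keys do not match the architecture")
        self.tok_emb.value = np.array(state["tok_emb"], dtype=np.float64)
        self.pos_emb.value = np.array(state["pos_emb"], dtype=np.float64)
        for i, b in enumerate(self.blocks):
            pre = f"block{i}."
            b.ln1.gamma.value = np.array(state[pre + "ln1.gamma"])
            b.ln1.beta.value = np.array(state[pre + "ln1.beta"])
            b.ln2.gamma.value = np.array(state[pre + "ln2.gamma"])
            b.ln2.beta.value = np.array(state[pre + "ln2.beta"])
            for name in ("wq", "wk", "wv", "wo"):
                lin = getattr(b.attn, name)
                lin.weight.value = np.array(state[pre + f"attn.{name}.weight"])
                lin.bias.value = np.array(state[pre + f"attn.{name}.bias"])
            for name in ("lin1", "lin2"):
                lin = getattr(b.ff, name)
                lin.weight.value = np.array(state[pre + f"ff.{name}.weight"])
                lin.bias.value = np.array(state[pre + f"ff.{name}.bias"])
        self.ln_f.gamma.value = np.array(state["ln_f.gamma"])
        self.ln_f.beta.value = np.array(state["ln_f.beta"])
        self.head.weight.value = np.array(state["head.weight"])
        self.head.bias.value = np.array(state["head.bias"])
        for p in self.parameters():
            p.grad = np.zeros_like(p.value)


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
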