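"""Neural building blocks on top of :mod:`tcmgen.autodiff`.

Everything here is deliberately small: hidden sizes in the tens, single
sequences (no batching).  A :class:`Module` owns named parameters and
submodules and can round-trip its state through plain arrays for
checkpointing.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Linear", "Embedding", "GRUCell", "TransformerCore",
           "GRUCore", "Adam", "layer_norm"]


class Module:
    """Base class holding named parameters and child modules."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def add_param(self, name: str, data: np.ndarray) -> Tensor:
        t = Tensor(data, requires_grad=True)
        self._params[name] = t
        return t

    def add_child(self, name: str, child: "Module") -> "Module":
        self._children[name] = child
        return child

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for c in self._children.values():
            out.extend(c.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, c in self._children.items():
            out.update(c.named_parameters(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, v in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {v.data.shape}")
            v.data[...] = arr

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    s = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-s, s, size=shape)


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int, bias: bool = True):
        super().__init__()
        self.w = self.add_param("w", _uniform(rng, (d_in, d_out), d_in))
        self.b = self.add_param("b", np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.matmul(x, self.w)
        return ad.add(y, self.b) if self.b is not None else y


class Embedding(Module):
    def __init__(self, rng, n_tokens: int, d: int):
        super().__init__()
        self.table = self.add_param("table", rng.normal(0.0, 0.1, size=(n_tokens, d)))
        self.d = d

    def __call__(self, idx: int) -> Tensor:
        return ad.getitem(self.table, idx)


class GRUCell(Module):
    """Standard gated recurrent unit for one step on vectors."""

    def __init__(self, rng, d_in: int, d_hidden: int):
        super().__init__()
        d = d_in + d_hidden
        self.w_zr = self.add_param("w_zr", _uniform(rng, (d, 2 * d_hidden), d))
        self.b_zr = self.add_param("b_zr", np.zeros(2 * d_hidden))
        self.w_c = self.add_param("w_c", _uniform(rng, (d, d_hidden), d))
        self.b_c = self.add_param("b_c", np.zeros(d_hidden))
        self.d_hidden = d_hidden

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        dh = self.d_hidden
        cat = ad.concat([x, h])
        zr = ad.sigmoid(ad.add(ad.matmul(cat, self.w_zr), self.b_zr))
        z, r = zr[:dh], zr[dh:]
        cand = ad.tanh(ad.add(ad.matmul(ad.concat([x, ad.mul(r, h)]), self.w_c), self.b_c))
        return ad.add(ad.mul(ad.sub(1.0, z), h), ad.mul(z, cand))


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis, as a fused primitive."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gamma.data + beta.data, prev=(x, gamma, beta))
    if out.requires_grad:
        n = x.data.shape[-1]
        def _bw(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))
            if x.requires_grad:
                gx = g * gamma.data
                x._accumulate(inv * (gx - gx.mean(axis=-1, keepdims=True)
                                     - xhat * (gx * xhat).mean(axis=-1, keepdims=True)) )
        out._backward = _bw
    return out


class _Block(Module):
    """One pre-norm causal self-attention block."""

    def __init__(self, rng, d: int, n_heads: int):
        super().__init__()
        assert d % n_heads == 0
        self.d, self.n_heads, self.dh = d, n_heads, d // n_heads
        self.ln1_g = self.add_param("ln1_g", np.ones(d))
        self.ln1_b = self.add_param("ln1_b", np.zeros(d))
        self.qkv = self.add_child("qkv", Linear(rng, d, 3 * d))
        self.proj = self.add_child("proj", Linear(rng, d, d))
        self.ln2_g = self.add_param("ln2_g", np.ones(d))
        self.ln2_b = self.add_param("ln2_b", np.zeros(d))
        self.ff1 = self.add_child("ff1", Linear(rng, d, 2 * d))
        self.ff2 = self.add_child("ff2", Linear(rng, 2 * d, d))

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        d, nh, dh = self.d, self.n_heads, self.dh
        h = layer_norm(x, self.ln1_g, self.ln1_b)
        qkv = self.qkv(h)  # (T, 3d)
        heads = []
        for i in range(nh):
            q = qkv[:, i * dh:(i + 1) * dh]
            k = qkv[:, d + i * dh:d + (i + 1) * dh]
            v = qkv[:, 2 * d + i * dh:2 * d + (i + 1) * dh]
            scores = ad.scale(ad.matmul(q, _t(k)), 1.0 / np.sqrt(dh))
            scores = ad.add(scores, mask)
            att = ad.softmax(scores)
            heads.append(ad.matmul(att, v))
        x = ad.add(x, self.proj(ad.concat(heads, axis=1)))
        h = layer_norm(x, self.ln2_g, self.ln2_b)
        return ad.add(x, self.ff2(ad.relu(self.ff1(h))))


def _t(a: Tensor) -> Tensor:
    """Transpose a 2-D tensor."""
    out = Tensor(a.data.T, prev=(a,))
    if out.requires_grad:
        def _bw(g):
            a._accumulate(g.T)
        out._backward = _bw
    return out


class TransformerCore(Module):
    """Small causal transformer used as the autoregressive decoder core.

    Consumes the full conditioned token stream (context-injected embeddings
    of the generated prefix) and returns the hidden state at the last
    position.  The explicit previous-state argument of the recurrent
    contract is unused — the state is implicit in the prefix.
    """

    def __init__(self, rng, d: int, n_layers: int = 2, n_heads: int = 2):
        super().__init__()
        self.blocks = [self.add_child(f"block{i}", _Block(rng, d, n_heads))
                       for i in range(n_layers)]
        self.lnf_g = self.add_param("lnf_g", np.ones(d))
        self.lnf_b = self.add_param("lnf_b", np.zeros(d))
        self.pos = self.add_param("pos", rng.normal(0.0, 0.05, size=(64, d)))

    def __call__(self, stream: list[Tensor], s_prev: Tensor | None = None) -> Tensor:
        T = len(stream)
        x = ad.add(ad.stack(stream), ad.getitem(self.pos, slice(0, T)))
        mask = np.triu(np.full((T, T), -1e9), k=1)
        for b in self.blocks:
            x = b(x, mask)
        x = layer_norm(x, self.lnf_g, self.lnf_b)
        return x[T - 1]


class GRUCore(Module):
    """Recurrent alternative decoder core (single GRU cell over the stream)."""

    def __init__(self, rng, d: int, **_):
        super().__init__()
        self.cell = self.add_child("cell", GRUCell(rng, d, d))

    def __call__(self, stream: list[Tensor], s_prev: Tensor) -> Tensor:
        return self.cell(stream[-1], s_prev)


class Adam:
    """Adam optimiser (defaults: lr 1e-3, betas 0.9/0.999, eps 1e-6)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-6):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
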