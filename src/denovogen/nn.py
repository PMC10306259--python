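"""Neural-network building blocks on top of :mod:`denovogen.tensor`.

Layers initialize from an explicit ``numpy.random.Generator`` so that model
construction, training and sampling are fully reproducible under a seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module", "Linear", "Embedding", "LayerNorm", "LSTMCell", "GRUCell",
    "MultiHeadAttention", "FeedForward", "TransformerBlock", "Adam",
]


class Module:
    """Base class: recursive parameter collection and flat state dicts."""

    def parameters(self):
        params = []
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                params.append(val)
            elif isinstance(val, Module):
                params.extend(val.parameters())
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix=""):
        out = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
        return out

    def state_dict(self):
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, v in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {v.data.shape}")
            v.data = arr.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def _glorot(rng, fan_in, fan_out):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, n_in, n_out, rng, bias=True):
        self.W = Tensor(_glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y


class Embedding(Module):
    def __init__(self, n_tokens, dim, rng):
        self.W = Tensor(rng.normal(0.0, 0.1, size=(n_tokens, dim)),
                        requires_grad=True)

    def __call__(self, idx) -> Tensor:
        return self.W.take_rows(idx)


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        self.g = Tensor(np.ones(dim), requires_grad=True)
        self.b = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        g, b = self.g, self.b
        out = Tensor(xhat * g.data + b.data, _prev=(x, g, b))

        def bwd(grad):
            if g.requires_grad:
                g._accum((grad * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0))
            if b.requires_grad:
                b._accum(grad.reshape(-1, xhat.shape[-1]).sum(axis=0))
            if x.requires_grad:
                dy = grad * g.data
                n = xhat.shape[-1]
                dx = inv * (dy - dy.mean(axis=-1, keepdims=True)
                            - xhat * (dy * xhat).mean(axis=-1, keepdims=True))
                x._accum(dx)

        out._backward = bwd
        return out


class LSTMCell(Module):
    def __init__(self, n_in, n_hidden, rng):
        self.Wx = Tensor(_glorot(rng, n_in, 4 * n_hidden), requires_grad=True)
        self.Wh = Tensor(_glorot(rng, n_hidden, 4 * n_hidden), requires_grad=True)
        b = np.zeros(4 * n_hidden)
        b[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)
        self.n_hidden = n_hidden

    def __call__(self, x: Tensor, h: Tensor, c: Tensor):
        z = x @ self.Wx + h @ self.Wh + self.b
        n = self.n_hidden
        zi = Tensor(z.data[..., 0:n], _prev=(z,))
        zf = Tensor(z.data[..., n:2 * n], _prev=(z,))
        zo = Tensor(z.data[..., 2 * n:3 * n], _prev=(z,))
        zg = Tensor(z.data[..., 3 * n:4 * n], _prev=(z,))
        for t, sl in ((zi, slice(0, n)), (zf, slice(n, 2 * n)),
                      (zo, slice(2 * n, 3 * n)), (zg, slice(3 * n, 4 * n))):
            def make_bwd(sl=sl):
                def bwd(g):
                    if z.requires_grad:
                        if z.grad is None:
                            z.grad = np.zeros_like(z.data)
                        z.grad[..., sl] += g
                return bwd
            t._backward = make_bwd()
        i, f, o, g = zi.sigmoid(), zf.sigmoid(), zo.sigmoid(), zg.tanh()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


class GRUCell(Module):
    def __init__(self, n_in, n_hidden, rng):
        self.Wxz = Linear(n_in, n_hidden, rng)
        self.Whz = Linear(n_hidden, n_hidden, rng, bias=False)
        self.Wxr = Linear(n_in, n_hidden, rng)
        self.Whr = Linear(n_hidden, n_hidden, rng, bias=False)
        self.Wxn = Linear(n_in, n_hidden, rng)
        self.Whn = Linear(n_hidden, n_hidden, rng)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        zt = (self.Wxz(x) + self.Whz(h)).sigmoid()
        rt = (self.Wxr(x) + self.Whr(h)).sigmoid()
        nt = (self.Wxn(x) + self.Whn(rt * h)).tanh()
        one = Tensor(np.ones_like(zt.data))
        return (one - zt) * nt + zt * h


class MultiHeadAttention(Module):
    """Scaled dot-product attention; self- or cross- depending on kv input."""

    def __init__(self, dim, n_heads, rng):
        if dim % n_heads:
            raise ValueError("model dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.Wq = Linear(dim, dim, rng, bias=False)
        self.Wk = Linear(dim, dim, rng, bias=False)
        self.Wv = Linear(dim, dim, rng, bias=False)
        self.Wo = Linear(dim, dim, rng, bias=False)

    def __call__(self, x: Tensor, kv: Tensor | None = None,
                 causal: bool = False) -> Tensor:
        kv = x if kv is None else kv
        B, Tq, D = x.shape
        Tk = kv.shape[-2]
        H, d = self.n_heads, self.d_head
        q = _to_heads(self.Wq(x), B, Tq, H, d)
        k = _to_heads(self.Wk(kv), B, Tk, H, d)
        v = _to_heads(self.Wv(kv), B, Tk, H, d)
        att = q @ k.transpose_last2() * (1.0 / np.sqrt(d))
        if causal:
            mask = np.triu(np.ones((Tq, Tk), dtype=bool), k=1)
            att = att.masked_fill(mask, -1e30)
        w = att.softmax(axis=-1)
        out = w @ v                                   # (B,H,Tq,d)
        out = _from_heads(out, B, Tq, H, d)
        return self.Wo(out)


def _to_heads(t: Tensor, B, T, H, d) -> Tensor:
    out = Tensor(t.data.reshape(B, T, H, d).transpose(0, 2, 1, 3), _prev=(t,))

    def bwd(g):
        if t.requires_grad:
            t._accum(g.transpose(0, 2, 1, 3).reshape(B, T, H * d))

    out._backward = bwd
    return out


def _from_heads(t: Tensor, B, T, H, d) -> Tensor:
    out = Tensor(t.data.transpose(0, 2, 1, 3).reshape(B, T, H * d), _prev=(t,))

    def bwd(g):
        if t.requires_grad:
            t._accum(g.reshape(B, T, H, d).transpose(0, 2, 1, 3))

    out._backward = bwd
    return out


class FeedForward(Module):
    def __init__(self, dim, ff_dim, rng):
        self.fc1 = Linear(dim, ff_dim, rng)
        self.fc2 = Linear(ff_dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class TransformerBlock(Module):
    """Pre-norm block: self-attention (+ optional cross-attention) + FFN."""

    def __init__(self, dim, n_heads, ff_dim, rng, cross: bool = False):
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.ln1 = LayerNorm(dim)
        self.cross_attn = MultiHeadAttention(dim, n_heads, rng) if cross else None
        self.ln_cross = LayerNorm(dim) if cross else None
        self.ff = FeedForward(dim, ff_dim, rng)
        self.ln2 = LayerNorm(dim)

    def __call__(self, x: Tensor, memory: Tensor | None = None,
                 causal: bool = False) -> Tensor:
        x = x + self.attn(self.ln1(x), causal=causal)
        if self.cross_attn is not None and memory is not None:
            x = x + self.cross_attn(self.ln_cross(x), kv=memory)
        return x + self.ff(self.ln2(x))


class Adam:
    """Adam with fixed learning rate (no schedule)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
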