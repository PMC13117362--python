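"""Neural building blocks on top of the autodiff core.

Xavier-initialized dense layers, a single-direction LSTM cell stack, additive
attention, multi-head dot-product attention, and a decoupled-weight-decay Adam
optimizer. Everything is seeded explicitly; there is no hidden global RNG.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, concat_rows, param, stack_rows

__all__ = [
    "Linear", "LSTM", "BiLSTM", "AdditiveAttention", "MultiHeadAttention",
    "AdamW", "xavier",
]


def xavier(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Module:
    """Base class: recursive parameter collection."""

    def parameters(self):
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for x in v:
                    if isinstance(x, Module):
                        params.extend(x.parameters())
                    elif isinstance(x, Tensor) and x.requires_grad:
                        params.append(x)
        return params


class Linear(Module):
    def __init__(self, rng, d_in, d_out, bias=True):
        self.W = param(xavier(rng, d_in, d_out))
        self.b = param(np.zeros(d_out)) if bias else None

    def __call__(self, x):
        y = x @ self.W
        return y + self.b if self.b is not None else y


class LSTM(Module):
    """Single-layer LSTM over a sequence of 1-D input tensors."""

    def __init__(self, rng, d_in, d_hidden):
        self.d_hidden = d_hidden
        # one fused matrix for the i, f, g, o gates
        self.Wx = param(xavier(rng, d_in, 4 * d_hidden))
        self.Wh = param(xavier(rng, d_hidden, 4 * d_hidden))
        self.b = param(np.zeros(4 * d_hidden))

    def step(self, x, h, c):
        d = self.d_hidden
        z = x @ self.Wx + h @ self.Wh + self.b
        i = z.slice(slice(0, d)).sigmoid()
        f = z.slice(slice(d, 2 * d)).sigmoid()
        g = z.slice(slice(2 * d, 3 * d)).tanh()
        o = z.slice(slice(3 * d, 4 * d)).sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def __call__(self, xs):
        from ._autograd import const
        h = const(np.zeros(self.d_hidden))
        c = const(np.zeros(self.d_hidden))
        states = []
        for x in xs:
            h, c = self.step(x, h, c)
            states.append(h)
        return states


class BiLSTM(Module):
    """Stacked bidirectional LSTM; outputs per-step concatenated states."""

    def __init__(self, rng, d_in, d_hidden, n_layers=1):
        self.layers = []
        d = d_in
        for _ in range(n_layers):
            self.layers.append((LSTM(rng, d, d_hidden), LSTM(rng, d, d_hidden)))
            d = 2 * d_hidden
        self.d_out = d

    def parameters(self):
        params = []
        for fwd, bwd in self.layers:
            params.extend(fwd.parameters())
            params.extend(bwd.parameters())
        return params

    def __call__(self, xs):
        seq = list(xs)
        for fwd, bwd in self.layers:
            hf = fwd(seq)
            hb = bwd(seq[::-1])[::-1]
            seq = [concat_rows([f, b]) for f, b in zip(hf, hb)]
        return seq


class AdditiveAttention(Module):
    """tanh-scored additive attention with a learned context vector."""

    def __init__(self, rng, d_in, d_attn):
        self.proj = Linear(rng, d_in, d_attn)
        self.ctx = param(xavier(rng, d_attn, 1).ravel())

    def __call__(self, states):
        """states: list of 1-D tensors -> (pooled tensor, weight ndarray)."""
        H = stack_rows(states)               # (T, d)
        scores = self.proj(H).tanh() @ self.ctx   # (T,)
        alpha = scores.softmax()
        pooled = alpha @ H
        return pooled, alpha


class MultiHeadAttention(Module):
    """Scaled dot-product attention, queries and keys as row matrices."""

    def __init__(self, rng, d_model, n_heads):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.Wq = Linear(rng, d_model, d_model, bias=False)
        self.Wk = Linear(rng, d_model, d_model, bias=False)
        self.Wv = Linear(rng, d_model, d_model, bias=False)
        self.Wo = Linear(rng, d_model, d_model, bias=False)

    def __call__(self, queries, keys, return_weights=False):
        """queries: (m, d) tensor; keys/values: (n, d) tensor."""
        Q, K, V = self.Wq(queries), self.Wk(keys), self.Wv(keys)
        dh = self.d_head
        outs, weights = [], []
        for h in range(self.n_heads):
            sl = slice(h * dh, (h + 1) * dh)
            q, k, v = Q.slice((slice(None), sl)), K.slice((slice(None), sl)), V.slice((slice(None), sl))
            scores = (q @ k.T) * (1.0 / np.sqrt(dh))
            a = scores.softmax()
            outs.append(a @ v)
            weights.append(a.data.copy())
        cat = outs[0]
        if len(outs) > 1:
            # concatenate head outputs along the feature axis
            from ._autograd import Tensor as _T
            data = np.concatenate([o.data for o in outs], axis=1)
            cat = _T(data, parents=tuple(outs))
            sizes = [o.data.shape[1] for o in outs]

            def bw(g, outs=outs, sizes=sizes):
                off = 0
                for o, n in zip(outs, sizes):
                    o._accum(g[:, off:off + n])
                    off += n

            cat._backward = bw
        out = self.Wo(cat)
        if return_weights:
            return out, np.stack(weights)
        return out


class AdamW(Module):
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.01):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)
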