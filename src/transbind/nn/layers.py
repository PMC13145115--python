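"""Neural network layers composed from the autodiff primitives.

Parameters are initialized with the standard uniform fan-in scheme
U(-1/sqrt(fan_in), 1/sqrt(fan_in)) from a caller-supplied generator, so a
model built twice from the same seed has bit-identical weights.
"""

from __future__ import annotations

import numpy as np

from .tensor import (
    Tensor,
    concat,
    conv1d,
    dropout,
    layer_norm,
    max_pool1d,
    relu,
    sigmoid,
    softmax,
    tanh,
)

__all__ = [
    "Module",
    "Dense",
    "Conv1d",
    "BiLSTM",
    "MultiheadAttention",
    "TransformerEncoderLayer",
]


def _uniform_fan_in(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Container tracking named parameters and submodules."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for mn, m in self._modules.items():
            out.extend(m.named_parameters(prefix + mn + "."))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for n, p in own.items():
            if p.data.shape != state[n].shape:
                raise ValueError(f"shape mismatch for {n}")
            p.data[...] = state[n]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(_uniform_fan_in(rng, in_dim, (in_dim, out_dim)),
                             requires_grad=True)
        self.bias = (Tensor(_uniform_fan_in(rng, in_dim, (out_dim,)),
                            requires_grad=True) if bias else None)

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class Conv1d(Module):
    """Valid (unpadded) 1-D convolution over (B, L, C_in) input."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * kernel
        self.weight = Tensor(
            _uniform_fan_in(rng, fan_in, (filters, kernel, in_channels)),
            requires_grad=True,
        )
        self.bias = Tensor(_uniform_fan_in(rng, fan_in, (filters,)),
                           requires_grad=True)
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias)


class _LSTMDirection(Module):
    """One direction of one LSTM layer (gate order i, f, g, o)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.w_x = Tensor(_uniform_fan_in(rng, hidden, (in_dim, 4 * hidden)),
                          requires_grad=True)
        self.w_h = Tensor(_uniform_fan_in(rng, hidden, (hidden, 4 * hidden)),
                          requires_grad=True)
        self.bias = Tensor(_uniform_fan_in(rng, hidden, (4 * hidden,)),
                           requires_grad=True)

    def __call__(self, xs: list[Tensor], reverse: bool) -> list[Tensor]:
        B = xs[0].shape[0]
        h = Tensor(np.zeros((B, self.hidden)))
        c = Tensor(np.zeros((B, self.hidden)))
        order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
        out: list[Tensor | None] = [None] * len(xs)
        H = self.hidden
        for t in order:
            gates = xs[t] @ self.w_x + h @ self.w_h + self.bias
            i = sigmoid(gates[:, 0 * H : 1 * H])
            f = sigmoid(gates[:, 1 * H : 2 * H])
            g = tanh(gates[:, 2 * H : 3 * H])
            o = sigmoid(gates[:, 3 * H : 4 * H])
            c = f * c + i * g
            h = o * tanh(c)
            out[t] = h
        return out  # type: ignore[return-value]


class BiLSTM(Module):
    """Stacked bidirectional LSTM; outputs (B, L, 2*hidden)."""

    def __init__(self, in_dim: int, hidden: int, layers: int,
                 rng: np.random.Generator):
        super().__init__()
        self.layers = layers
        for li in range(layers):
            d = in_dim if li == 0 else 2 * hidden
            setattr(self, f"fwd{li}", _LSTMDirection(d, hidden, rng))
            setattr(self, f"bwd{li}", _LSTMDirection(d, hidden, rng))

    def __call__(self, x: Tensor) -> Tensor:
        L = x.shape[1]
        xs = [x[:, t, :] for t in range(L)]
        for li in range(self.layers):
            f = getattr(self, f"fwd{li}")(xs, reverse=False)
            b = getattr(self, f"bwd{li}")(xs, reverse=True)
            xs = [concat([f[t], b[t]], axis=-1) for t in range(L)]
        stacked = concat([h.reshape(h.shape[0], 1, h.shape[1]) for h in xs], axis=1)
        return stacked


class MultiheadAttention(Module):
    """Scaled dot-product attention with h heads and an output projection.

    Query/key/value inputs are (B, T, q_dim) / (B, L, kv_dim); attention is
    softmax(q k^T / sqrt(d_head)) per head, heads concatenated then linearly
    projected back to attn_dim.
    """

    def __init__(self, q_dim: int, kv_dim: int, attn_dim: int, heads: int,
                 rng: np.random.Generator):
        super().__init__()
        if attn_dim % heads:
            raise ValueError(f"attention dim {attn_dim} not divisible by {heads} heads")
        self.heads = heads
        self.d_head = attn_dim // heads
        self.attn_dim = attn_dim
        self.w_q = Dense(q_dim, attn_dim, rng, bias=False)
        self.w_k = Dense(kv_dim, attn_dim, rng, bias=False)
        self.w_v = Dense(kv_dim, attn_dim, rng, bias=False)
        self.w_o = Dense(attn_dim, attn_dim, rng, bias=False)

    def __call__(self, query: Tensor, keyval: Tensor,
                 return_weights: bool = False):
        B, T, _ = query.shape
        L = keyval.shape[1]
        h, dh = self.heads, self.d_head

        def split_heads(x: Tensor, n: int) -> Tensor:
            # (B, n, h*dh) -> (B, h, n, dh)
            return x.reshape(B, n, h, dh).transpose(0, 2, 1, 3)

        q = split_heads(self.w_q(query), T)
        k = split_heads(self.w_k(keyval), L)
        v = split_heads(self.w_v(keyval), L)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        weights = softmax(scores, axis=-1)  # (B, h, T, L)
        attended = weights @ v  # (B, h, T, dh)
        merged = attended.transpose(0, 2, 1, 3).reshape(B, T, h * dh)
        out = self.w_o(merged)
        if return_weights:
            return out, weights
        return out


class TransformerEncoderLayer(Module):
    """Pre-norm transformer encoder block (self-attention + FFN)."""

    def __init__(self, dim: int, heads: int, ffn_dim: int, dropout_p: float,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = MultiheadAttention(dim, dim, dim, heads, rng)
        self.ffn1 = Dense(dim, ffn_dim, rng)
        self.ffn2 = Dense(ffn_dim, dim, rng)
        self.ln1_g = Tensor(np.ones(dim), requires_grad=True)
        self.ln1_b = Tensor(np.zeros(dim), requires_grad=True)
        self.ln2_g = Tensor(np.ones(dim), requires_grad=True)
        self.ln2_b = Tensor(np.zeros(dim), requires_grad=True)
        self.dropout_p = dropout_p

    def __call__(self, x: Tensor, rng: np.random.Generator,
                 training: bool) -> Tensor:
        a = layer_norm(x, self.ln1_g, self.ln1_b)
        x = x + self.attn(a, a)
        f = layer_norm(x, self.ln2_g, self.ln2_b)
        f = relu(self.ffn1(f))
        f = dropout(f, self.dropout_p, rng, training)
        x = x + self.ffn2(f)
        return x
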