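"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The denoising network is small (tens of atoms, embedding dims in the tens),
so a straightforward define-by-run tape over dense NumPy ops is fast enough
for CPU training.  Only the operations the network needs are implemented:
broadcast arithmetic, two-operand einsum, linear layers, softmax, layer
normalisation building blocks, and elementwise nonlinearities.

Gradient conventions follow the usual vector-Jacobian products; every op is
checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "Adam",
    "concat",
    "einsum",
    "relu",
    "sigmoid",
    "softmax",
    "log_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # ------------------------------------------------------------------ tape
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = _ensure(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-_ensure(other))

    def __rsub__(self, other):
        return _ensure(other) + (-self)

    def __mul__(self, other):
        other = _ensure(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __pow__(self, p: float):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accumulate(g * p * a.data ** (p - 1))

        return Tensor._make(a.data ** p, (a,), bw)

    def __truediv__(self, other):
        return self * (_ensure(other) ** -1.0)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accumulate(full)

        return Tensor._make(a.data[idx], (a,), bw)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def bw(g):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(*shape), (a,), bw)

    def transpose(self, *axes):
        a = self
        axes_t = axes or tuple(reversed(range(a.data.ndim)))
        inv = np.argsort(axes_t)

        def bw(g):
            if a.requires_grad:
                a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes_t), (a,), bw)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def detach(self):
        return Tensor(self.data.copy())


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


# ---------------------------------------------------------------- functions


def relu(x: Tensor) -> Tensor:
    x = _ensure(x)
    mask = x.data > 0

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    x = _ensure(x)
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    return Tensor._make(s, (x,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = _ensure(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - dot))

    return Tensor._make(s, (x,), bw)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = _ensure(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    s = np.exp(out_data)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g - s * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out_data, (x,), bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def einsum(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum.  Restrictions (asserted): explicit output, no
    ellipsis, no repeated labels within one operand, and every input label
    appears in the output or in the other operand."""
    a, b = _ensure(a), _ensure(b)
    ins, out = spec.replace(" ", "").split("->")
    sa, sb = ins.split(",")
    assert "." not in spec and len(set(sa)) == len(sa) and len(set(sb)) == len(sb)
    assert set(sa) <= set(out) | set(sb) and set(sb) <= set(out) | set(sa)

    def bw(g):
        if a.requires_grad:
            a._accumulate(np.einsum(f"{out},{sb}->{sa}", g, b.data))
        if b.requires_grad:
            b._accumulate(np.einsum(f"{out},{sa}->{sb}", g, a.data))

    return Tensor._make(np.einsum(spec, a.data, b.data), (a, b), bw)


# ------------------------------------------------------------------ modules


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Parameter container with recursive traversal (no buffers, no modes)."""

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out[key] = val
            elif isinstance(val, Module):
                out.update(val.named_parameters(key + "."))
            elif isinstance(val, (list, tuple)):
                for k, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{k}."))
        return out

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=float)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = arr.copy()


class Linear(Module):
    """Affine map on the last axis; LeCun-normal init, optionally zero init.

    Residual-branch output projections are zero-initialised so every block
    starts as the identity, which keeps early training stable.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False, bias: bool = True):
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            w = rng.normal(scale=1.0 / np.sqrt(d_in), size=(d_in, d_out))
        self.W = Parameter(w)
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        x = _ensure(x)
        W = self.W
        out_data = x.data @ W.data

        def bw(g):
            if x.requires_grad:
                x._accumulate(g @ W.data.T)
            if W.requires_grad:
                W._accumulate(
                    x.data.reshape(-1, x.data.shape[-1]).T
                    @ g.reshape(-1, g.shape[-1])
                )

        y = Tensor._make(out_data, (x, W), bw)
        if self.b is not None:
            y = y + self.b
        return y


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma + self.beta


class Adam:
    """Adam with optional global-gradient-norm clipping."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = 10.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
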