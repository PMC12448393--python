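"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

The fusion network is small (a few thousand parameters) and must train
deterministically on one CPU in double precision, so the engine is a plain
tape-based design: every operation records its parents together with a
closure that maps the upstream gradient to each parent's gradient
contribution.  All arithmetic is float64 and no global state is kept, which
makes two identical forward passes bit-identical.

Only the operations the network needs are provided: broadcast arithmetic,
(batched) matmul, concatenation, slicing, relu/sigmoid/exp/log, a fused
softmax and layer-norm along the last axis, reductions, and a same-padded
1-D convolution implemented via an im2col matrix product.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


def _as_array(x) -> Array:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # axes broadcast from size 1
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence[tuple["Tensor", Callable[[Array], Array]]] = (),
    ):
        self.data = _as_array(data)
        self.grad: Array | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p, _ in parents)
        self._parents = tuple((p, fn) for p, fn in parents if p.requires_grad)

    # ------------------------------------------------------------------ utils
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # --------------------------------------------------------------- backward
    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological sort over the tape
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in visited:
                    stack.append((parent, False))
        grads: dict[int, Array] = {id(self): _as_array(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = np.zeros_like(node.data)
            node.grad = node.grad + g
            for parent, fn in node._parents:
                contrib = fn(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + contrib
                else:
                    grads[id(parent)] = contrib
        # interior nodes keep their grads too; callers read only leaves

    # -------------------------------------------------------------- operators
    def __add__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return Tensor(
            self.data + other.data,
            parents=[
                (self, lambda g: _unbroadcast(g, self.shape)),
                (other, lambda g: _unbroadcast(g, other.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.data, parents=[(self, lambda g: -g)])

    def __sub__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other) -> "Tensor":
        return Tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return Tensor(
            self.data * other.data,
            parents=[
                (self, lambda g: _unbroadcast(g * other.data, self.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        e = float(exponent)
        out = self.data ** e
        return Tensor(out, parents=[(self, lambda g: g * e * self.data ** (e - 1.0))])

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self.data, other.data

        def grad_a(g: Array) -> Array:
            ga = np.matmul(g, np.swapaxes(b, -1, -2)) if b.ndim >= 2 else np.outer(g, b)
            return _unbroadcast(ga, self.shape)

        def grad_b(g: Array) -> Array:
            gb = np.matmul(np.swapaxes(a, -1, -2), g) if a.ndim >= 2 else np.outer(a, g)
            return _unbroadcast(gb, other.shape)

        return Tensor(np.matmul(a, b), parents=[(self, grad_a), (other, grad_b)])

    def __getitem__(self, idx) -> "Tensor":
        def grad_fn(g: Array) -> Array:
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return full

        return Tensor(self.data[idx], parents=[(self, grad_fn)])

    # ------------------------------------------------------------ shape ops
    def reshape(self, *shape) -> "Tensor":
        return Tensor(
            self.data.reshape(*shape),
            parents=[(self, lambda g: g.reshape(self.shape))],
        )

    def swapaxes(self, a: int, b: int) -> "Tensor":
        return Tensor(
            np.swapaxes(self.data, a, b),
            parents=[(self, lambda g: np.swapaxes(g, a, b))],
        )

    @property
    def T(self) -> "Tensor":
        return self.swapaxes(-1, -2)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def grad_fn(g: Array) -> Array:
            if axis is None:
                return np.broadcast_to(g, self.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.shape).copy()

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=[(self, grad_fn)])

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---------------------------------------------------------- nonlinearities
    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor(np.where(mask, self.data, 0.0), parents=[(self, lambda g: g * mask)])

    def sigmoid(self) -> "Tensor":
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(out, parents=[(self, lambda g: g * out * (1.0 - out))])

    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return Tensor(out, parents=[(self, lambda g: g * out)])

    def log(self) -> "Tensor":
        return Tensor(np.log(self.data), parents=[(self, lambda g: g / self.data)])

    def clip(self, lo: float, hi: float) -> "Tensor":
        mask = (self.data > lo) & (self.data < hi)
        return Tensor(
            np.clip(self.data, lo, hi), parents=[(self, lambda g: g * mask)]
        )


# --------------------------------------------------------------------- fused
def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def grad_fn(g: Array) -> Array:
        return s * (g - (g * s).sum(axis=axis, keepdims=True))

    return Tensor(s, parents=[(x, grad_fn)])


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gamma.data + beta.data
    n = x.shape[-1]

    def grad_x(g: Array) -> Array:
        gy = g * gamma.data
        return inv * (gy - gy.mean(axis=-1, keepdims=True) - xhat * (gy * xhat).mean(axis=-1, keepdims=True))

    def grad_gamma(g: Array) -> Array:
        return _unbroadcast(g * xhat, gamma.shape)

    def grad_beta(g: Array) -> Array:
        return _unbroadcast(g, beta.shape)

    return Tensor(out, parents=[(x, grad_x), (gamma, grad_gamma), (beta, grad_beta)])


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_grad(i: int):
        lo, hi = offsets[i], offsets[i + 1]

        def grad_fn(g: Array) -> Array:
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            return g[tuple(sl)]

        return grad_fn

    return Tensor(
        np.concatenate(datas, axis=axis),
        parents=[(t, make_grad(i)) for i, t in enumerate(tensors)],
    )


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded 1-D convolution along the first axis.

    x: (L, C_in); weight: (k, C_in, C_out); bias: (C_out) -> (L, C_out).
    Implemented as an im2col matrix product so the backward pass reduces to
    two matmuls and a col2im scatter.
    """
    L, c_in = x.shape
    k, wc_in, c_out = weight.shape
    if wc_in != c_in:
        raise ValueError(f"conv1d channel mismatch: input {c_in}, weight {wc_in}")
    if k % 2 != 1:
        raise ValueError("conv1d_same requires an odd kernel size")
    pad = k // 2
    xp = np.zeros((L + 2 * pad, c_in))
    xp[pad : pad + L] = x.data
    # windows: (L, k, C_in)
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=0)  # (L, C_in, k)
    col = np.ascontiguousarray(win.transpose(0, 2, 1)).reshape(L, k * c_in)
    w2 = weight.data.reshape(k * c_in, c_out)
    out = col @ w2 + bias.data

    def grad_x(g: Array) -> Array:
        gcol = g @ w2.T  # (L, k*C_in)
        gcol = gcol.reshape(L, k, c_in)
        gxp = np.zeros_like(xp)
        for j in range(k):
            gxp[j : j + L] += gcol[:, j, :]
        return gxp[pad : pad + L]

    def grad_w(g: Array) -> Array:
        return (col.T @ g).reshape(k, c_in, c_out)

    def grad_b(g: Array) -> Array:
        return g.sum(axis=0)

    return Tensor(out, parents=[(x, grad_x), (weight, grad_w), (bias, grad_b)])


def relu(x: Tensor) -> Tensor:
    return x.relu()


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


# ----------------------------------------------------------------- parameters
class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Parameter:
    """Variance-scaled uniform initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Parameter(rng.uniform(-bound, bound, size=shape))


class Adam:
    """Adam with optional cosine-annealed learning rate."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        cosine_t_max: int | None = None,
    ):
        self.params = list(params)
        self.base_lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.cosine_t_max = cosine_t_max
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    @property
    def lr(self) -> float:
        if self.cosine_t_max is None:
            return self.base_lr
        frac = min(self.t / max(self.cosine_t_max, 1), 1.0)
        return 0.5 * self.base_lr * (1.0 + np.cos(np.pi * frac))

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        lr = self.lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
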