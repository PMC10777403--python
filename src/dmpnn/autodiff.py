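"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine provides exactly the operations the message-passing encoder,
feed-forward readouts and loss menu need: dense linear algebra, pointwise
nonlinearities, reductions, concatenation, row gather / segment scatter-add
(the two primitives of vectorized message passing on graphs), and a softmax.

All arithmetic is float64.  Gradients are accumulated into ``Tensor.grad``
by :meth:`Tensor.backward`, which performs a topological sweep over the
recorded tape.  Broadcasting follows NumPy semantics; gradients of
broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_rows"]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -g * self.data / other.data ** 2, other.data.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        out._backward = bw
        return out

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = bw
        return out

    def leaky_relu(self, slope: float = 0.1):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, slope * self.data),
                     _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.where(mask, 1.0, slope))
        out._backward = bw
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y ** 2))
        out._backward = bw
        return out

    def sigmoid(self):
        y = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # numerically stable
        out = Tensor(y, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))
        out._backward = bw
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * y)
        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bw
        return out

    def softplus(self):
        # log(1 + e^x), stable for large |x|
        y = np.logaddexp(0.0, self.data)
        out = Tensor(y, _parents=(self,))
        sig = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def bw(g):
            if self.requires_grad:
                self._accum(g * sig)
        out._backward = bw
        return out

    def lgamma(self):
        from scipy.special import gammaln, psi
        out = Tensor(gammaln(self.data), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * psi(self.data))
        out._backward = bw
        return out

    def digamma(self):
        from scipy.special import psi, polygamma
        out = Tensor(psi(self.data), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * polygamma(1, self.data))
        out._backward = bw
        return out

    def abs(self):
        s = np.sign(self.data)
        out = Tensor(np.abs(self.data), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * s)
        out._backward = bw
        return out

    def clamp_min(self, lo: float):
        mask = self.data > lo
        out = Tensor(np.maximum(self.data, lo), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = bw
        return out

    # -- reductions and shaping -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bw
        return out

    # -- graph primitives -----------------------------------------------
    def gather_rows(self, index: np.ndarray):
        """Rows ``self[index]`` with scatter-add backward."""
        index = np.asarray(index, dtype=np.intp)
        out = Tensor(self.data[index], _parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, index, g)
                self._accum(full)
        out._backward = bw
        return out

    def segment_sum(self, index: np.ndarray, n_segments: int):
        """Sum rows of ``self`` into ``n_segments`` buckets given by ``index``."""
        index = np.asarray(index, dtype=np.intp)
        shape = (n_segments,) + self.data.shape[1:]
        y = np.zeros(shape, dtype=np.float64)
        np.add.at(y, index, self.data)
        out = Tensor(y, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g[index])
        out._backward = bw
        return out

    def softmax(self, axis: int = -1):
        """Softmax along ``axis`` (shift-invariant, stable)."""
        z = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = z.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def dropout(self, rate: float, rng: np.random.Generator | None):
        """Inverted dropout; identity when ``rng`` is None or rate == 0."""
        if rng is None or rate <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= rate) / (1.0 - rate)
        return self * Tensor(mask)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with split backward."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    out._backward = bw
    return out


def stack_rows(tensors: list[Tensor]) -> Tensor:
    """Stack 1-D tensors into a 2-D tensor (rows)."""
    out = Tensor(np.stack([t.data for t in tensors], axis=0),
                 _parents=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(g[i])
    out._backward = bw
    return out
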