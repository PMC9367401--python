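"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the two small networks in this package on a
CPU: dense layers, 2-D strided convolution, circular (wrap-around) shifts for
cyclic contour graphs, bilinear feature sampling, max pooling over vertices,
and the two losses (smooth-L1 and softmax cross-entropy).  Everything is
float64 and single-threaded-deterministic.

The graph is built eagerly: each op returns a new :class:`Tensor` holding its
parents and a closure that routes the upstream gradient.  ``Tensor.backward``
runs a topological sweep.  No broadcasting subtleties beyond what the ops
below explicitly support.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "relu",
    "linear",
    "conv2d",
    "cyclic_unfold",
    "roll",
    "take_rows",
    "concat",
    "max_over_rows",
    "bilinear_sample",
    "smooth_l1",
    "softmax_cross_entropy",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: training graphs can exceed recursion depth
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _op(self.data + other.data, (self, other))

        def back(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _op(self.data * other.data, (self, other))

        def back(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _op(self.data @ other.data, (self, other))

        def back(g):
            if self.requires_grad or self._parents:
                self._accum(g @ other.data.T)
            if other.requires_grad or other._parents:
                other._accum(self.data.T @ g)

        out._backward = back
        return out

    def reshape(self, *shape):
        out = _op(self.data.reshape(*shape), (self,))
        src_shape = self.data.shape
        out._backward = lambda g: self._accum(g.reshape(src_shape))
        return out

    def sum(self):
        out = _op(np.array(self.data.sum()), (self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape).copy())
        return out

    def mean(self):
        n = self.data.size
        return self.sum() * (1.0 / n)


def _op(data, parents) -> Tensor:
    t = Tensor(data)
    t._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return t


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    out = _op(np.maximum(x.data, 0.0), (x,))
    mask = x.data > 0
    out._backward = lambda g: x._accum(g * mask)
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Row-major dense layer: ``x @ w + b`` with ``w`` of shape (d_in, d_out)."""
    y = x @ w
    return y if b is None else y + b


def roll(x: Tensor, shift: int) -> Tensor:
    """Cyclic shift of rows (axis 0); the wrap-around of a cycle graph."""
    out = _op(np.roll(x.data, shift, axis=0), (x,))
    out._backward = lambda g: x._accum(np.roll(g, -shift, axis=0))
    return out


def transpose2d(x: Tensor) -> Tensor:
    out = _op(x.data.T.copy(), (x,))
    out._backward = lambda g: x._accum(g.T)
    return out


def cyclic_unfold(x: Tensor, k: int) -> Tensor:
    """Stack the k cyclic neighborhoods of each row: (n, d) -> (n, k*d).

    Column block j holds ``x[(i + j - (k-1)//2) mod n]`` for output row i, so a
    circular convolution becomes one dense matmul with a (k*d, d_out) kernel.
    """
    if k % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {k}")
    c = (k - 1) // 2
    blocks = [np.roll(x.data, c - j, axis=0) for j in range(k)]
    out = _op(np.concatenate(blocks, axis=1), (x,))
    d = x.data.shape[1]

    def back(g):
        acc = np.zeros_like(x.data)
        for j in range(k):
            acc += np.roll(g[:, j * d : (j + 1) * d], j - c, axis=0)
        x._accum(acc)

    out._backward = back
    return out


def take_rows(x: Tensor, idx) -> Tensor:
    idx = np.asarray(idx, dtype=int)
    out = _op(x.data[idx], (x,))

    def back(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, idx, g)
        x._accum(acc)

    out._backward = back
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = _op(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def back(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    out._backward = back
    return out


def max_over_rows(x: Tensor) -> Tensor:
    """Column-wise maximum over rows: (n, d) -> (1, d); global contour feature."""
    arg = np.argmax(x.data, axis=0)
    out = _op(x.data[arg, np.arange(x.data.shape[1])][None, :], (x,))

    def back(g):
        acc = np.zeros_like(x.data)
        acc[arg, np.arange(x.data.shape[1])] = g[0]
        x._accum(acc)

    out._backward = back
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) on a single image.

    ``x``: (C_in, H, W); ``w``: (C_out, C_in, kh, kw); ``b``: (C_out,).
    Returns (C_out, H_out, W_out).
    """
    cin, h, wd = x.data.shape
    cout, cin2, kh, kw = w.data.shape
    if cin != cin2:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin2}")
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (wd + 2 * pad - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (cin, ho, wo, kh, kw)
    cols = win.transpose(0, 3, 4, 1, 2).reshape(cin * kh * kw, ho * wo)
    w2 = w.data.reshape(cout, -1)
    out_data = (w2 @ cols).reshape(cout, ho, wo)
    if b is not None:
        out_data = out_data + b.data[:, None, None]
    out = _op(out_data, (x, w, b) if b is not None else (x, w))

    def back(g):
        g2 = g.reshape(cout, -1)
        if w.requires_grad or w._parents:
            w._accum((g2 @ cols.T).reshape(w.data.shape))
        if b is not None and (b.requires_grad or b._parents):
            b._accum(g.sum(axis=(1, 2)))
        if x.requires_grad or x._parents:
            dcols = (w2.T @ g2).reshape(cin, kh, kw, ho, wo)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[:, i, j]
            x._accum(dxp[:, pad : pad + h, pad : pad + wd] if pad else dxp)

    out._backward = back
    return out


def bilinear_sample(grid: Tensor, pts: np.ndarray) -> Tensor:
    """Bilinearly sample a (C, H, W) grid at continuous (x, y) grid coordinates.

    ``pts`` is an (n, 2) constant array in grid units where (0, 0) is the
    center of cell (0, 0); coordinates are clamped to the grid.  Gradients
    flow into the grid only (sampling locations are treated as constants).
    """
    c, h, w = grid.data.shape
    x = np.clip(pts[:, 0], 0.0, w - 1.0)
    y = np.clip(pts[:, 1], 0.0, h - 1.0)
    x0 = np.clip(np.floor(x).astype(int), 0, w - 1)
    y0 = np.clip(np.floor(y).astype(int), 0, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = x - x0
    fy = y - y0
    w00 = (1 - fx) * (1 - fy)
    w01 = fx * (1 - fy)
    w10 = (1 - fx) * fy
    w11 = fx * fy
    g = grid.data
    out_data = (
        g[:, y0, x0] * w00 + g[:, y0, x1] * w01 + g[:, y1, x0] * w10 + g[:, y1, x1] * w11
    ).T  # (n, C)
    out = _op(out_data, (grid,))

    def back(gr):
        acc = np.zeros_like(grid.data)
        gt = gr.T  # (C, n)
        np.add.at(acc, (slice(None), y0, x0), gt * w00)
        np.add.at(acc, (slice(None), y0, x1), gt * w01)
        np.add.at(acc, (slice(None), y1, x0), gt * w10)
        np.add.at(acc, (slice(None), y1, x1), gt * w11)
        grid._accum(acc)

    out._backward = back
    return out


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0) -> Tensor:
    """Mean smooth-L1 (Huber) loss: quadratic below ``beta``, linear above."""
    d = pred.data - np.asarray(target, dtype=np.float64)
    a = np.abs(d)
    loss = np.where(a < beta, 0.5 * d * d / beta, a - 0.5 * beta)
    out = _op(np.array(loss.mean()), (pred,))
    n = d.size
    dgrad = np.where(a < beta, d / beta, np.sign(d)) / n

    out._backward = lambda g: pred._accum(g * dgrad)
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over rows; ``labels`` are integer class indices."""
    labels = np.asarray(labels, dtype=int)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-300)).mean()
    out = _op(np.array(loss), (logits,))
    onehot = np.zeros_like(p)
    onehot[np.arange(n), labels] = 1.0

    out._backward = lambda g: logits._accum(g * (p - onehot) / n)
    return out
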