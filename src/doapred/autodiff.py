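"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical substrate for the recurrent networks in this package:
a small define-by-run tape with the handful of primitives a GRU regressor,
cosine distribution distances and softmax importance weights need.  Arrays
are float64 throughout; gradients are accumulated into ``Tensor.grad`` by
:func:`backward`, which walks the tape iteratively (graphs here span tens of
thousands of nodes, well past Python's recursion limit).

Broadcasting follows numpy semantics; the backward pass sums gradients over
broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "add",
    "mul",
    "matmul",
    "tanh",
    "sigmoid",
    "relu",
    "exp",
    "log",
    "sqrt",
    "softmax",
    "concat",
    "stack",
    "backward",
]


class Tensor:
    """A node in the computation graph wrapping an ``ndarray``.

    Parameters with ``requires_grad=True`` receive accumulated gradients in
    ``.grad`` after :func:`backward`.  Interior nodes created by primitives
    carry their parents and a local backward closure.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        """A new leaf sharing this node's values but cut from the tape."""
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __pow__(self, p):
        return powc(self, float(p))

    def __getitem__(self, idx):
        return take(self, idx)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _node(data, parents, backward_fn) -> Tensor:
    return Tensor(data, _parents=tuple(parents), _backward=backward_fn)


# -- primitives -----------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bw(g):
        return (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def bw(g):
        return (_unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape))

    return _node(out_data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bw(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return _node(out_data, (a, b), bw)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def bw(g):
        return (
            _unbroadcast(g / b.data, a.data.shape),
            _unbroadcast(-g * a.data / (b.data**2), b.data.shape),
        )

    return _node(out_data, (a, b), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bw(g):
        ga = g @ b.data.swapaxes(-1, -2)
        gb = a.data.swapaxes(-1, -2) @ g
        return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))

    return _node(out_data, (a, b), bw)


def powc(a: Tensor, p: float) -> Tensor:
    out_data = a.data**p

    def bw(g):
        return (g * p * a.data ** (p - 1.0),)

    return _node(out_data, (a,), bw)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def bw(g):
        return (g * out_data,)

    return _node(out_data, (a,), bw)


def log(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def bw(g):
        return (g / a.data,)

    return _node(out_data, (a,), bw)


def sqrt(a: Tensor) -> Tensor:
    out_data = np.sqrt(a.data)

    def bw(g):
        return (g * 0.5 / out_data,)

    return _node(out_data, (a,), bw)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def bw(g):
        return (g * (1.0 - out_data**2),)

    return _node(out_data, (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 0.5 * (np.tanh(0.5 * a.data) + 1.0)  # numerically stable

    def bw(g):
        return (g * out_data * (1.0 - out_data),)

    return _node(out_data, (a,), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0.0)

    def bw(g):
        return (g * mask,)

    return _node(out_data, (a,), bw)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(a2 % a.data.ndim for a2 in axes):
                g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return _node(out_data, (a,), bw)


def mean_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def bw(g):
        return (g.reshape(a.data.shape),)

    return _node(out_data, (a,), bw)


def _is_basic_index(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(i, (int, np.integer, slice)) or i is None for i in items)


def take(a: Tensor, idx) -> Tensor:
    out_data = a.data[idx]
    basic = _is_basic_index(idx)  # basic indexing never repeats elements

    def bw(g):
        ga = np.zeros_like(a.data)
        if basic:
            ga[idx] += g
        else:
            np.add.at(ga, idx, g)
        return (ga,)

    return _node(out_data, (a,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(out_data, tensors, bw)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        return tuple(np.moveaxis(g, axis, 0))

    return _node(out_data, tensors, bw)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    """Softmax composed from primitives (max-shifted for stability)."""
    shift = Tensor(a.data.max(axis=axis, keepdims=True))  # constant shift
    e = exp(sub(a, shift))
    return div(e, sum_(e, axis=axis, keepdims=True))


try:  # JIT-compiled recurrence kernels; numpy fallback below keeps parity
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a standard dependency here
    _njit = None


def _gru_fwd_py(gi, Whh, bhh, hs, rzs, ns, hn_pre):
    V, B, threeh = gi.shape
    h = threeh // 3
    ht = np.zeros((B, h))
    for t in range(V):
        gh = ht @ Whh + bhh
        rz = 0.5 * (np.tanh(0.5 * (gi[t, :, :2 * h] + gh[:, :2 * h])) + 1.0)
        r, z = rz[:, :h], rz[:, h:]
        n = np.tanh(gi[t, :, 2 * h:] + r * gh[:, 2 * h:])
        ht = n + z * (ht - n)
        hs[t], rzs[t], ns[t], hn_pre[t] = ht, rz, n, gh[:, 2 * h:]


def _gru_bwd_py(gv, hs, rzs, ns, hn_pre, WhhT, dgh_all, dn_all):
    V, B, h = gv.shape
    dh_next = np.zeros((B, h))
    zeros_h = np.zeros((B, h))
    for t in range(V - 1, -1, -1):
        h_prev = hs[t - 1] if t > 0 else zeros_h
        rz, n, hn = rzs[t], ns[t], hn_pre[t]
        r, z = rz[:, :h], rz[:, h:]
        dh = gv[t] + dh_next
        dn_pre = dh * (1.0 - z) * (1.0 - n**2)
        dgh_all[t, :, :h] = dn_pre * hn * r * (1.0 - r)
        dgh_all[t, :, h:2 * h] = dh * (h_prev - n) * z * (1.0 - z)
        dgh_all[t, :, 2 * h:] = dn_pre * r
        dn_all[t] = dn_pre
        dh_next = dh * z + dgh_all[t] @ WhhT


if _njit is not None:
    import math

    @_njit(cache=True)
    def _gru_fwd_nb(gi, Whh, bhh, hs, rzs, ns, hn_pre):  # pragma: no cover - jit
        V, B, threeh = gi.shape
        h = threeh // 3
        ht = np.zeros((B, h))
        for t in range(V):
            gh = np.dot(ht, Whh)
            for b in range(B):
                for j in range(h):
                    r = 1.0 / (1.0 + math.exp(-(gi[t, b, j] + gh[b, j] + bhh[j])))
                    z = 1.0 / (1.0 + math.exp(-(gi[t, b, h + j] + gh[b, h + j] + bhh[h + j])))
                    hn = gh[b, 2 * h + j] + bhh[2 * h + j]
                    n = math.tanh(gi[t, b, 2 * h + j] + r * hn)
                    new_h = n + z * (ht[b, j] - n)
                    rzs[t, b, j] = r
                    rzs[t, b, h + j] = z
                    ns[t, b, j] = n
                    hn_pre[t, b, j] = hn
                    hs[t, b, j] = new_h
                    ht[b, j] = new_h

    @_njit(cache=True)
    def _gru_bwd_nb(gv, hs, rzs, ns, hn_pre, WhhT, dgh_all, dn_all):  # pragma: no cover - jit
        V, B, h = gv.shape
        dh_next = np.zeros((B, h))
        for t in range(V - 1, -1, -1):
            for b in range(B):
                for j in range(h):
                    h_prev = hs[t - 1, b, j] if t > 0 else 0.0
                    r = rzs[t, b, j]
                    z = rzs[t, b, h + j]
                    n = ns[t, b, j]
                    hn = hn_pre[t, b, j]
                    dh = gv[t, b, j] + dh_next[b, j]
                    dn_pre = dh * (1.0 - z) * (1.0 - n * n)
                    dgh_all[t, b, j] = dn_pre * hn * r * (1.0 - r)
                    dgh_all[t, b, h + j] = dh * (h_prev - n) * z * (1.0 - z)
                    dgh_all[t, b, 2 * h + j] = dn_pre * r
                    dn_all[t, b, j] = dn_pre
                    dh_next[b, j] = dh * z  # matmul part added below
            dh_next += np.dot(dgh_all[t], WhhT)
else:  # pragma: no cover
    _gru_fwd_nb = None
    _gru_bwd_nb = None


def gru_sequence(x: Tensor, W_ih: Tensor, W_hh: Tensor, b_ih: Tensor, b_hh: Tensor) -> Tensor:
    """Fused GRU layer over a (batch, V, d) input -> (batch, V, hidden).

    One tape node for the whole recurrence, with a hand-written
    backpropagation-through-time backward — the recurrent loop is the hot
    path of training and per-step tape nodes dominate its cost otherwise.
    Gate layout along the 3h axis is (reset, update, candidate):

        r_t = sigmoid(x_t W_ir + b_ir + h_{t-1} W_hr + b_hr)
        z_t = sigmoid(x_t W_iz + b_iz + h_{t-1} W_hz + b_hz)
        n_t = tanh(x_t W_in + b_in + r_t * (h_{t-1} W_hn + b_hn))
        h_t = (1 - z_t) * n_t + z_t * h_{t-1}
    """
    xd = x.data
    B, V, _ = xd.shape
    h = W_hh.data.shape[0]
    # time-major (V, B, .) internal layout keeps every per-step slab
    # contiguous, which is what makes the python-level recurrence viable
    xv = np.ascontiguousarray(xd.swapaxes(0, 1))
    gi = xv @ W_ih.data + b_ih.data  # (V, B, 3h) input projections
    hs = np.empty((V, B, h))
    rzs = np.empty((V, B, 2 * h))  # sigmoid gates
    ns = np.empty((V, B, h))
    hn_pre = np.empty((V, B, h))  # h_{t-1} W_hn + b_hn, needed for backward
    Whh = np.ascontiguousarray(W_hh.data)
    fwd = _gru_fwd_nb if _gru_fwd_nb is not None else _gru_fwd_py
    fwd(gi, Whh, np.ascontiguousarray(b_hh.data), hs, rzs, ns, hn_pre)

    def bw(g):
        gv = np.ascontiguousarray(np.asarray(g).swapaxes(0, 1))  # (V, B, h)
        dgh_all = np.empty((V, B, 3 * h))  # hidden-path gate grads
        dn_all = np.empty((V, B, h))  # candidate-gate pre-activation grads
        WhhT = np.ascontiguousarray(Whh.T)
        bwd = _gru_bwd_nb if _gru_bwd_nb is not None else _gru_bwd_py
        bwd(gv, hs, rzs, ns, hn_pre, WhhT, dgh_all, dn_all)
        # input-path gate grads share the r/z blocks; the candidate block
        # differs (dn_pre vs dn_pre * r)
        dgi = dgh_all.copy()
        dgi[:, :, 2 * h:] = dn_all
        dx = np.ascontiguousarray((dgi @ W_ih.data.T).swapaxes(0, 1))
        dW_ih = np.tensordot(xv, dgi, axes=([0, 1], [0, 1]))
        db_ih = dgi.sum(axis=(0, 1))
        # accumulate the recurrent weight grad in one flat matmul:
        # sum_t h_{t-1}^T dgh_t with h_{-1} = 0
        h_prev_flat = np.concatenate([np.zeros((1, B, h)), hs[:-1]]).reshape(V * B, h)
        dW_hh = h_prev_flat.T @ dgh_all.reshape(V * B, 3 * h)
        db_hh = dgh_all.sum(axis=(0, 1))
        return (dx, dW_ih, dW_hh, db_ih, db_hh)

    out = np.ascontiguousarray(hs.swapaxes(0, 1))  # (B, V, h)
    return _node(out, (x, W_ih, W_hh, b_ih, b_hh), bw)


# -- backward pass --------------------------------------------------------

def backward(root: Tensor, grad=None) -> None:
    """Accumulate d(root)/d(leaf) into every reachable leaf's ``.grad``.

    ``root`` is typically a scalar loss; ``grad`` defaults to ones.
    """
    if grad is None:
        grad = np.ones_like(root.data)
    # iterative topological order (DFS with explicit stack)
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack_ = [(root, False)]
    while stack_:
        node, processed = stack_.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack_.append((node, True))
        for p in node._parents:
            if id(p) not in visited:
                stack_.append((p, False))

    grads: dict[int, np.ndarray] = {id(root): np.asarray(grad, dtype=np.float64)}
    for node in reversed(topo):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if node.requires_grad:
            node.grad = g if node.grad is None else node.grad + g
        if node._backward is None:
            continue
        parent_grads = node._backward(g)
        for p, pg in zip(node._parents, parent_grads):
            if pg is None:
                continue
            acc = grads.get(id(p))
            grads[id(p)] = pg if acc is None else acc + pg


def zero_grads(params) -> None:
    """Reset ``.grad`` on an iterable (or dict) of parameter tensors."""
    if isinstance(params, dict):
        params = params.values()
    for p in params:
        p.grad = None
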