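"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations needed by the segmentation network are provided:
2-D convolution, non-overlapping transposed convolution, max-pooling,
batch normalization, ReLU/sigmoid, zero-padding, channel concatenation
and elementwise addition.  Each op builds a node in a dynamic graph;
``Tensor.backward`` runs a topological sweep accumulating gradients
into leaf tensors (the parameters).

Convolutions are evaluated by im2col + matmul; their backward pass
scatters gradients with k*k strided adds, so everything stays
vectorised numpy.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """A node in the autodiff graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    def backward(self, seed=None):
        """Backpropagate from this node (scalar unless ``seed`` given)."""
        if seed is None:
            if self.data.size != 1:
                raise ValueError("backward() without seed requires a scalar output")
            seed = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(node):
            stack = [(node, iter(node._parents))]
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        self.grad = np.asarray(seed, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, (x,))

    def bwd(g):
        x._accumulate(g * mask)

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    # clip keeps exp() in range; float32-exact outside +/-30 anyway
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -30.0, 30.0)))
    out = Tensor(s, (x,))

    def bwd(g):
        x._accumulate(g * s * (1.0 - s))

    out._backward = bwd
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"add shape mismatch {a.data.shape} vs {b.data.shape}")
    out = Tensor(a.data + b.data, (a, b))

    def bwd(g):
        a._accumulate(g)
        b._accumulate(g)

    out._backward = bwd
    return out


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), (a, b))

    def bwd(g):
        a._accumulate(g[:, :ca])
        b._accumulate(g[:, ca:])

    out._backward = bwd
    return out


def zero_pad2d(x: Tensor, pad: int) -> Tensor:
    if pad == 0:
        return x
    out = Tensor(
        np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))), (x,)
    )

    def bwd(g):
        x._accumulate(g[:, :, pad:-pad, pad:-pad])

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """Cross-correlation of NCHW input with (Cout, Cin, k, k) kernels."""
    n, cin, h, wd = x.data.shape
    cout, cin_w, k, k2 = w.data.shape
    assert k == k2 and cin == cin_w, "kernel/input channel mismatch"
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # (n, cin, ho, wo, k, k) -> (n*ho*wo, cin*k*k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cin * k * k)
    wm = w.data.reshape(cout, cin * k * k)
    y = cols @ wm.T
    y = y.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2) + b.data.reshape(1, cout, 1, 1)
    out = Tensor(y, (x, w, b))

    def bwd(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, cout)
        w._accumulate((g2.T @ cols).reshape(w.data.shape))
        b._accumulate(g.sum(axis=(0, 2, 3)))
        dcols = (g2 @ wm).reshape(n, ho, wo, cin, k, k)
        # (n, cin, k, k, ho, wo) contiguous so the scatter adds stream
        dt = np.ascontiguousarray(dcols.transpose(0, 3, 4, 5, 1, 2))
        gxp = np.zeros((n, cin, hp, wp), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                    dt[:, :, i, j]
                )
        x._accumulate(gxp[:, :, pad : hp - pad, pad : wp - pad] if pad else gxp)

    out._backward = bwd
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor, factor: int = 2) -> Tensor:
    """Transposed convolution with kernel == stride == factor (exact x{factor} upsample).

    Weight layout (Cin, Cout, k, k).  Non-overlapping, so forward is a
    single einsum scatter.
    """
    n, cin, h, wd = x.data.shape
    cin_w, cout, k, _ = w.data.shape
    assert cin == cin_w and k == factor
    y = np.einsum("ncij,coab->noiajb", x.data, w.data, optimize=True)
    y = y.reshape(n, cout, h * k, wd * k) + b.data.reshape(1, cout, 1, 1)
    out = Tensor(y, (x, w, b))

    def bwd(g):
        g6 = g.reshape(n, cout, h, k, wd, k).transpose(0, 1, 2, 4, 3, 5)
        # g6: (n, cout, h, w, k, k)
        x._accumulate(np.einsum("noijab,coab->ncij", g6, w.data, optimize=True))
        w._accumulate(np.einsum("ncij,noijab->coab", x.data, g6, optimize=True))
        b._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = bwd
    return out


def max_pool2d(x: Tensor, kernel: int, stride: int, pad: int = 0) -> Tensor:
    n, c, h, w = x.data.shape
    if pad:
        xp = np.pad(
            x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
            constant_values=-np.inf,
        )
    else:
        xp = x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kernel) // stride + 1
    wo = (wp - kernel) // stride + 1
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, (x,))

    def bwd(g):
        gxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
        for t in range(kernel * kernel):
            i, j = divmod(t, kernel)
            sel = (idx == t) * g
            gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += sel
        if pad:
            gxp = gxp[:, :, pad:-pad, pad:-pad]
        x._accumulate(gxp)

    out._backward = bwd
    return out


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.9,
    eps: float = 1e-5,
) -> Tensor:
    n, c, h, w = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= momentum
        running_mean += (1 - momentum) * mu
        running_var *= momentum
        running_var += (1 - momentum) * var
    else:
        mu, var = running_mean, running_var
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, c, 1, 1)) * ivar.reshape(1, c, 1, 1)
    y = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)
    out = Tensor(y, (x, gamma, beta))
    m = n * h * w

    def bwd(g):
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        dxhat = g * gamma.data.reshape(1, c, 1, 1)
        if training:
            s1 = dxhat.sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
            s2 = (dxhat * xhat).sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
            dx = (ivar.reshape(1, c, 1, 1) / m) * (m * dxhat - s1 - xhat * s2)
        else:
            dx = dxhat * ivar.reshape(1, c, 1, 1)
        x._accumulate(dx)

    out._backward = bwd
    return out
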