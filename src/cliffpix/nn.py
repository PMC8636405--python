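"""A small, self-contained convolutional network on NumPy.

Implements exactly the layers needed by the pair-image classifier:
2D convolution (stride 1, "same" padding), ReLU, 2x2 max-pooling,
inverted dropout, flatten, dense layers, a fused softmax cross-entropy
loss and the Adam optimizer.  All arithmetic is float32, channels-last.

Two implementation choices matter for single-CPU throughput:

* Convolutions are evaluated image by image as an im2col copy into a
  persistent buffer followed by one BLAS matrix multiply.  The column
  buffer is laid out in the natural memory order of
  ``sliding_window_view`` (channel, ky, kx), so no strided transpose is
  ever materialized, and the weights are stored (Cin, k, k, Cout) to
  match.

* Every layer and the optimizer write into preallocated, reused output
  and scratch arrays.  The activation tensors here are tens of MB, and
  allocating them afresh each step makes page-fault handling - not
  floating point - the bottleneck.

Every layer retains what it needs for backpropagation, and the
:class:`Sequential` container can run a partial backward pass from the
class logits down to an intermediate convolutional activation, which is
what gradient-weighted class-activation mapping requires.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import UsageError


class _BufferPool:
    """Named, shape-keyed reusable arrays (zeroed once at creation)."""

    def __init__(self):
        self._bufs: dict = {}

    def get(self, name: str, shape: tuple, dtype=np.float32) -> np.ndarray:
        key = (name, shape, np.dtype(dtype))
        buf = self._bufs.get(key)
        if buf is None:
            buf = np.zeros(shape, dtype=dtype)
            self._bufs[key] = buf
        return buf

    def clear(self) -> None:
        self._bufs.clear()


class Layer:
    name: str = "layer"

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs; empty for stateless layers."""
        return []

    def release_buffers(self) -> None:
        """Drop reusable work buffers (parameters are kept).

        Batch-sized activation buffers dominate a trained model's
        footprint; releasing them after training/prediction keeps
        several models resident at once.  They are re-allocated lazily
        at the next forward pass.
        """
        pool = getattr(self, "_pool", None)
        if pool is not None:
            pool.clear()


class InputCenter(Layer):
    """Subtract a constant from the input (identity in the backward pass).

    Pair images are white-background line art, so raw pixels sit at 1.0
    almost everywhere; shifting white to 0 keeps early activations
    sparse and avoids correlated saturation of the first layers.  The
    shift is equivalent to a particular bias initialization of the first
    convolution.
    """

    def __init__(self, offset: float = 1.0, name: str = "center"):
        self.offset = np.float32(offset)
        self.name = name
        self._pool = _BufferPool()

    def forward(self, x, train=False, rng=None):
        out = self._pool.get("out", x.shape)
        np.subtract(x, self.offset, out=out)
        return out

    def backward(self, dout):
        return dout


class Conv2D(Layer):
    """Stride-1 same-padding convolution, weights stored (Cin, k, k, Cout).

    ``compute_input_grad`` can be disabled for the first layer of a
    network, where the gradient with respect to the input is unused.
    """

    def __init__(
        self,
        k: int,
        c_in: int,
        c_out: int,
        name: str,
        rng: np.random.Generator,
        compute_input_grad: bool = True,
    ):
        if k % 2 != 1:
            raise UsageError("Conv2D: only odd kernel sizes supported")
        self.k, self.c_in, self.c_out, self.name = k, c_in, c_out, name
        self.compute_input_grad = compute_input_grad
        fan_in = k * k * c_in
        self.W = (rng.standard_normal((c_in, k, k, c_out)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._pool = _BufferPool()

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    # column buffers are kept near this size so they stay cache-resident
    _COL_BUF_BYTES = 22_000_000

    def _block_rows(self, w: int, c: int) -> int:
        per_row = w * c * self.k * self.k * 4
        return max(1, self._COL_BUF_BYTES // per_row)

    def _conv_image(
        self,
        src: np.ndarray,
        pad_buf: np.ndarray,
        col_buf: np.ndarray,
        weight_mat: np.ndarray,
        out_mat: np.ndarray,
    ) -> None:
        """Same-padding correlation of one image, blocked over rows."""
        p = self.k // 2
        h, w, c = src.shape
        pad_buf[p : p + h, p : p + w, :] = src
        block = self._block_rows(w, c)
        for r0 in range(0, h, block):
            b = min(block, h - r0)
            windows = sliding_window_view(pad_buf[r0 : r0 + b + 2 * p], (self.k, self.k), axis=(0, 1))
            cols = col_buf[: b * w]
            np.copyto(cols.reshape(b, w, c, self.k, self.k), windows)
            np.matmul(cols, weight_mat, out=out_mat[r0 * w : (r0 + b) * w])

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        if c != self.c_in:
            raise UsageError(f"{self.name}: expected {self.c_in} channels, got {c}")
        self._x = x
        p = self.k // 2
        pad_buf = self._pool.get("pad", (h + 2 * p, w + 2 * p, c))
        col_buf = self._pool.get("col", (self._block_rows(w, c) * w, c * self.k * self.k))
        out = self._pool.get("out", (n, h, w, self.c_out))
        wm = self.W.reshape(-1, self.c_out)
        for i in range(n):
            self._conv_image(x[i], pad_buf, col_buf, wm, out[i].reshape(h * w, self.c_out))
        out += self.b
        return out

    def backward(self, dout):
        x = self._x
        n, h, w, _ = x.shape
        p = self.k // 2
        c = self.c_in
        pad_buf = self._pool.get("pad", (h + 2 * p, w + 2 * p, c))
        block = self._block_rows(w, c)
        col_buf = self._pool.get("col", (block * w, c * self.k * self.k))
        dw_scratch = self._pool.get("dw", self.dW.reshape(-1, self.c_out).shape)
        self.dW[...] = 0.0
        dwm = self.dW.reshape(-1, self.c_out)
        for i in range(n):
            pad_buf[p : p + h, p : p + w, :] = x[i]
            dout_mat = dout[i].reshape(h * w, self.c_out)
            for r0 in range(0, h, block):
                b = min(block, h - r0)
                windows = sliding_window_view(
                    pad_buf[r0 : r0 + b + 2 * p], (self.k, self.k), axis=(0, 1)
                )
                cols = col_buf[: b * w]
                np.copyto(cols.reshape(b, w, c, self.k, self.k), windows)
                np.matmul(cols.T, dout_mat[r0 * w : (r0 + b) * w], out=dw_scratch)
                dwm += dw_scratch
        self.db[...] = dout.sum(axis=(0, 1, 2))
        if not self.compute_input_grad:
            return None
        # gradient w.r.t. input: correlate dout with the flipped, transposed kernel
        w_back = self._pool.get("wback", (self.c_out * self.k * self.k, self.c_in))
        np.copyto(
            w_back.reshape(self.c_out, self.k, self.k, self.c_in),
            self.W[:, ::-1, ::-1, :].transpose(3, 1, 2, 0),
        )
        pad_o = self._pool.get("pad_back", (h + 2 * p, w + 2 * p, self.c_out))
        col_o = self._pool.get(
            "col_back", (self._block_rows(w, self.c_out) * w, self.c_out * self.k * self.k)
        )
        dx = self._pool.get("dx", x.shape)
        for i in range(n):
            # the blocked correlation applies unchanged with dout as the image
            self._conv_image(dout[i], pad_o, col_o, w_back, dx[i].reshape(h * w, self.c_in))
        return dx


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self._pool = _BufferPool()

    def forward(self, x, train=False, rng=None):
        mask = self._pool.get("mask", x.shape, dtype=bool)
        out = self._pool.get("out", x.shape)
        np.greater(x, 0, out=mask)
        np.multiply(x, mask, out=out)
        self._mask = mask
        return out

    def backward(self, dout):
        dx = self._pool.get("dx", dout.shape)
        np.multiply(dout, self._mask, out=dx)
        return dx


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (trailing odd row/column dropped)."""

    def __init__(self, name: str = "pool"):
        self.name = name
        self._pool = _BufferPool()

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xv = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        out = self._pool.get("out", (n, h2, w2, c))
        np.max(xv, axis=(2, 4), out=out)
        mask = self._pool.get("mask", xv.shape, dtype=bool)
        np.equal(xv, out[:, :, None, :, None, :], out=mask)
        self._mask = mask
        return out

    def backward(self, dout):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dx = self._pool.get("dx", self._in_shape)
        if h % 2 or w % 2:
            dx[...] = 0.0  # trailing row/column receives no gradient
        dxv = dx[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        np.multiply(self._mask, dout[:, :, None, :, None, :], out=dxv)
        return dx


class Dropout(Layer):
    """Inverted dropout: identity at inference time."""

    def __init__(self, rate: float, name: str = "dropout"):
        if not 0.0 <= rate < 1.0:
            raise UsageError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.name = name
        self._pool = _BufferPool()

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise UsageError("Dropout in training mode needs an rng")
        mask = self._pool.get("mask", x.shape)
        keep_mask = self._pool.get("keep", x.shape, dtype=bool)
        out = self._pool.get("out", x.shape)
        rng.random(dtype=np.float32, out=mask)
        np.greater_equal(mask, self.rate, out=keep_mask)
        np.multiply(keep_mask, np.float32(1.0 / (1.0 - self.rate)), out=mask)
        np.multiply(x, mask, out=out)
        self._mask = mask
        return out

    def backward(self, dout):
        if self._mask is None:
            return dout
        dx = self._pool.get("dx", dout.shape)
        np.multiply(dout, self._mask, out=dx)
        return dx


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, name: str, rng: np.random.Generator):
        self.name = name
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._pool = _BufferPool()

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        out = self._pool.get("out", (x.shape[0], self.W.shape[1]))
        np.matmul(x, self.W, out=out)
        out += self.b
        return out

    def backward(self, dout):
        np.matmul(self._x.T, dout, out=self.dW)
        self.db[...] = dout.sum(axis=0)
        dx = self._pool.get("dx", self._x.shape)
        np.matmul(dout, self.W.T, out=dx)
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, onehot: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    eps = np.float32(1e-12)
    ll = -(onehot * np.log(p + eps)).sum(axis=1)
    if sample_weight is None:
        loss = float(ll.mean())
        dlogits = (p - onehot) / np.float32(len(ll))
    else:
        wsum = float(sample_weight.sum())
        loss = float((ll * sample_weight).sum() / wsum)
        dlogits = (p - onehot) * (sample_weight[:, None] / np.float32(wsum))
    return loss, dlogits.astype(np.float32)


class Sequential:
    """Ordered layer stack with full and partial backward passes."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self._by_name = {layer.name: layer for layer in layers}

    def __getitem__(self, name: str) -> Layer:
        if name not in self._by_name:
            raise UsageError(f"unknown layer {name!r}; have {sorted(self._by_name)}")
        return self._by_name[name]

    def forward(self, x, train=False, rng=None, collect: bool = False):
        """Run the stack; with ``collect`` also return each layer's output."""
        outputs = {}
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
            if collect:
                outputs[layer.name] = x
        return (x, outputs) if collect else x

    def backward(self, dout, to_layer: str | None = None):
        """Backpropagate from the logits.

        With ``to_layer`` the pass stops just above that layer and
        returns the gradient with respect to its *output* (the quantity
        class-activation mapping needs); otherwise the full pass runs
        and the gradient w.r.t. the network input is returned.
        """
        for layer in reversed(self.layers):
            if to_layer is not None and layer.name == to_layer:
                return dout
            dout = layer.backward(dout)
        if to_layer is not None:
            raise UsageError(f"unknown layer {to_layer!r}")
        return dout

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def release_buffers(self) -> None:
        for layer in self.layers:
            layer.release_buffers()

    def get_weights(self) -> dict[str, np.ndarray]:
        weights = {}
        for layer in self.layers:
            for attr in ("W", "b"):
                if hasattr(layer, attr):
                    weights[f"{layer.name}.{attr}"] = getattr(layer, attr)
        return weights

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for key, value in weights.items():
            name, attr = key.rsplit(".", 1)
            layer = self[name]
            target = getattr(layer, attr)
            if target.shape != value.shape:
                raise UsageError(f"{key}: shape {value.shape} != {target.shape}")
            target[...] = value.astype(np.float32)


class Adam:
    """Adam with bias correction.

    Moment and scratch arrays are allocated once per parameter and
    updated strictly in place; large fresh temporaries per step would
    dominate the runtime of the big dense layer.
    """

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._state: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def step(self, params) -> None:
        self.t += 1
        b1, b2 = np.float32(self.beta1), np.float32(self.beta2)
        one_m_b1, one_m_b2 = np.float32(1.0 - self.beta1), np.float32(1.0 - self.beta2)
        lr_t = np.float32(
            self.lr * np.sqrt(1.0 - self.beta2**self.t) / (1.0 - self.beta1**self.t)
        )
        for p, g in params:
            key = id(p)
            if key not in self._state:
                self._state[key] = (np.zeros_like(p), np.zeros_like(p), np.zeros_like(p))
            m, v, scratch = self._state[key]
            m *= b1
            np.multiply(g, one_m_b1, out=scratch)
            m += scratch
            v *= b2
            np.multiply(g, g, out=scratch)
            scratch *= one_m_b2
            v += scratch
            np.sqrt(v, out=scratch)
            scratch += np.float32(self.eps)
            np.divide(m, scratch, out=scratch)
            scratch *= lr_t
            p -= scratch
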