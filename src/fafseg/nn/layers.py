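"""Convolution, pooling and resampling primitives (forward + backward).

All tensors are channel-first float32: ``(N, C, H, W)``.  3x3
convolutions use 'same' zero padding and are evaluated as one GEMM per
batch over im2col patches; the patch axis is ordered ``(u, v, c)`` and
kernels are reordered to match at call time.  Max pooling is 2x2 stride
2 and records the argmax location ("switch") of every window, which
serves both the backward pass and deconvnet switch-unpooling.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "im2col3", "conv3x3_forward", "conv3x3_backward",
    "conv1x1_forward", "conv1x1_backward",
    "maxpool2", "maxpool2_backward", "unpool2",
    "upsample2", "upsample2_backward",
    "relu", "sigmoid",
]


def relu(x):
    return np.maximum(x, 0.0)


def sigmoid(x):
    out = np.empty_like(x, dtype=np.float64 if x.dtype == np.float64 else np.float32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class BufferPool:
    """Reusable scratch arrays keyed by name, to avoid page-fault churn.

    im2col materializes ~9x the input tensor per convolution; allocating
    those buffers afresh every step costs more than the copies
    themselves.  The network keeps one pool per instance and hands out
    stable per-layer buffers.
    """

    def __init__(self):
        self._buffers: dict = {}

    def get(self, key, shape, dtype=np.float32) -> np.ndarray:
        arr = self._buffers.get(key)
        if arr is None or arr.shape != tuple(shape) or arr.dtype != dtype:
            arr = np.empty(shape, dtype)
            self._buffers[key] = arr
        return arr


def im2col3(x: np.ndarray, out: np.ndarray | None = None,
            pad_buf: np.ndarray | None = None) -> np.ndarray:
    """3x3 'same' patches of ``x`` as a ``(N, 9*C, H*W)`` array."""
    N, C, H, W = x.shape
    if pad_buf is not None:
        pad_buf[:, :, 0, :] = 0
        pad_buf[:, :, -1, :] = 0
        pad_buf[:, :, :, 0] = 0
        pad_buf[:, :, :, -1] = 0
        pad_buf[:, :, 1:-1, 1:-1] = x
        xp = pad_buf
    else:
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = out if out is not None else np.empty((N, 9 * C, H * W), dtype=x.dtype)
    k = 0
    for u in range(3):
        for v in range(3):
            dst = cols[:, k * C:(k + 1) * C, :].reshape(N, C, H, W)
            np.copyto(dst, xp[:, :, u:u + H, v:v + W])
            k += 1
    return cols


def _kernel_matrix(W: np.ndarray) -> np.ndarray:
    """(F, C, 3, 3) kernel -> (F, 9*C) matrix in im2col's (u, v, c) order."""
    F = W.shape[0]
    return np.ascontiguousarray(W.transpose(0, 2, 3, 1)).reshape(F, -1)


def conv3x3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray | None,
                    pool: "BufferPool | None" = None, key: str = ""):
    """'Same' 3x3 convolution; returns (output, patch columns for backward)."""
    N, C, H, Wd = x.shape
    F = W.shape[0]
    if pool is not None:
        cols = im2col3(
            x,
            out=pool.get(key + ":cols", (N, 9 * C, H * Wd), x.dtype),
            pad_buf=pool.get(key + ":pad", (N, C, H + 2, Wd + 2), x.dtype),
        )
        y = np.matmul(_kernel_matrix(W), cols,
                      out=pool.get(key + ":y", (N, F, H * Wd), x.dtype))
    else:
        cols = im2col3(x)
        y = np.matmul(_kernel_matrix(W), cols)
    if b is not None:
        y += b.reshape(1, F, 1)
    return y.reshape(N, F, H, Wd), cols


def conv3x3_backward(dy: np.ndarray, cols: np.ndarray, W: np.ndarray, x_shape,
                     pool: "BufferPool | None" = None, key: str = "",
                     need_dx: bool = True):
    """Gradients of a 3x3 convolution: returns (dx, dW, db).

    ``need_dx=False`` skips the input gradient (useful at the first
    layer, whose input is the image).
    """
    N, C, H, Wd = x_shape
    F = W.shape[0]
    dy_mat = dy.reshape(N, F, H * Wd)
    # batched GEMM against the transposed view (BLAS handles the stride,
    # avoiding tensordot's explicit copy of the patch matrix)
    dWm = np.matmul(dy_mat, cols.transpose(0, 2, 1)).sum(axis=0)      # (F, 9C)
    dW = np.ascontiguousarray(dWm.reshape(F, 3, 3, C).transpose(0, 3, 1, 2))
    db = dy.sum(axis=(0, 2, 3))
    if not need_dx:
        return None, dW, db
    # dx is the 'same' convolution of dy with the flipped, transposed kernel
    W_bwd = np.ascontiguousarray(W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    dx, _ = conv3x3_forward(dy, W_bwd, None, pool=pool, key=key + ":bwd")
    return dx, dW, db


def conv1x1_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray | None):
    """Pointwise convolution with ``W`` of shape (F, C)."""
    N, C, H, Wd = x.shape
    F = W.shape[0]
    y = np.matmul(W, x.reshape(N, C, H * Wd))
    if b is not None:
        y += b.reshape(1, F, 1)
    return y.reshape(N, F, H, Wd)


def conv1x1_backward(dy: np.ndarray, x: np.ndarray, W: np.ndarray):
    N, C, H, Wd = x.shape
    F = W.shape[0]
    dy_mat = dy.reshape(N, F, H * Wd)
    x_mat = x.reshape(N, C, H * Wd)
    dW = np.tensordot(dy_mat, x_mat, axes=([0, 2], [0, 2]))
    db = dy.sum(axis=(0, 2, 3))
    dx = np.matmul(W.T, dy_mat).reshape(N, C, H, Wd)
    return dx, dW, db


def maxpool2(x: np.ndarray):
    """2x2 stride-2 max pooling; returns (pooled, switches).

    ``switches`` holds, per output pixel, the argmax index 0..3 into its
    2x2 window in (row-major) order -- the location information the
    deconvnet unpooling places values back into.
    """
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2 requires even spatial dims, got {H}x{W}")
    h, w = H // 2, W // 2
    xr = np.ascontiguousarray(
        x.reshape(N, C, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5)
    ).reshape(N, C, h, w, 4)
    sw = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, sw[..., None], axis=-1)[..., 0]
    return y, sw


def unpool2(y: np.ndarray, switches: np.ndarray, out_shape):
    """Place pooled values back at their recorded switch locations (zeros elsewhere)."""
    N, C, H, W = out_shape
    h, w = H // 2, W // 2
    buf = np.zeros((N, C, h, w, 4), dtype=y.dtype)
    np.put_along_axis(buf, switches[..., None], y[..., None], axis=-1)
    return np.ascontiguousarray(
        buf.reshape(N, C, h, w, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    ).reshape(N, C, H, W)


# pooling's backward pass routes gradients exactly like switch-unpooling
maxpool2_backward = unpool2


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour 2x upsampling."""
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    N, C, H, W = dy.shape
    return dy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))
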