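"""Strided valid 3D convolution primitives and their adjoints.

Everything in this package that looks like a network is built from two
operations on (batch, y, x, t, channel) arrays:

* :func:`conv3d` — valid (no padding) cross-correlation with a stride, used
  by every hidden layer;
* :func:`conv_transpose3d` — fractionally-strided convolution (zero dilation
  followed by a full convolution), used by the prediction head so that its
  output regains the spatial size of the layer input.

The adjoint functions return exact gradients of a scalar loss with respect
to the kernels or the input activity; they are what the hand-written
backpropagation in :mod:`predstack.model` relies on, and they are verified
against numerical differentiation in the test-suite.

Axis conventions: arrays are ``(n, y, x, t, c)``; kernels are
``(out_c, in_c, ky, kx, kt)`` for :func:`conv3d` and ``(out_c, in_c, ky, kx)``
(temporal depth one) for the head. ``y`` increases downward, ``x`` rightward.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv3d",
    "conv3d_grad_w",
    "conv_windows",
    "conv_output_shape",
    "conv_transpose3d",
    "conv_transpose3d_grad_m",
    "conv_transpose3d_grad_h",
]


def conv_output_shape(in_shape, kernel, stride):
    """Valid-convolution output length per axis: floor((n - k) / s) + 1."""
    out = []
    for n, k, s in zip(in_shape, kernel, stride):
        if k > n:
            raise ValueError(f"kernel size {k} exceeds input size {n}")
        out.append((n - k) // s + 1)
    return tuple(out)


def conv_windows(u, kernel, stride):
    """Strided sliding windows of ``u``.

    Returns a contiguous array of shape
    ``(n, yh, xh, th, c, ky, kx, kt)``; materialising it once per minibatch
    lets the forward pass and the kernel gradient share the same copy.
    """
    ky, kx, kt = kernel
    sy, sx, st = stride
    v = sliding_window_view(u, (ky, kx, kt), axis=(1, 2, 3))
    v = v[:, ::sy, ::sx, ::st]
    return np.ascontiguousarray(v)


def conv3d(u, w, stride=(1, 1, 1), windows=None):
    """Valid strided cross-correlation.

    Parameters
    ----------
    u : ndarray, shape (n, y, x, t, in_c)
    w : ndarray, shape (out_c, in_c, ky, kx, kt)
    stride : (sy, sx, st)
    windows : optional pre-computed :func:`conv_windows` of ``u``.

    Returns
    -------
    ndarray, shape (n, yh, xh, th, out_c)
    """
    if u.ndim != 5:
        raise ValueError(f"input must be (n, y, x, t, c), got ndim={u.ndim}")
    if w.ndim != 5:
        raise ValueError(f"kernel must be (out_c, in_c, ky, kx, kt), got ndim={w.ndim}")
    if u.shape[4] != w.shape[1]:
        raise ValueError(
            f"channel axis mismatch: input has {u.shape[4]} channels, "
            f"kernel expects {w.shape[1]}"
        )
    for ax, name in zip((1, 2, 3), ("y", "x", "t")):
        if w.shape[ax + 1] > u.shape[ax]:
            raise ValueError(
                f"kernel exceeds input along axis {name!r}: "
                f"{w.shape[ax + 1]} > {u.shape[ax]}"
            )
    if windows is None:
        windows = conv_windows(u, w.shape[2:], stride)
    # contract over (in_c, ky, kx, kt)
    return np.tensordot(windows, w, axes=([4, 5, 6, 7], [1, 2, 3, 4]))


def conv3d_grad_w(u, grad_h, kernel, stride, windows=None):
    """Gradient of a scalar loss w.r.t. the conv3d kernel.

    ``grad_h`` is dLoss/dH with H = conv3d(u, w, stride). Returns an array
    shaped like the kernel, (out_c, in_c, ky, kx, kt).
    """
    if windows is None:
        windows = conv_windows(u, kernel, stride)
    # windows: (n, yh, xh, th, in_c, ky, kx, kt); grad_h: (n, yh, xh, th, out_c)
    g = np.tensordot(grad_h, windows, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
    return g  # (out_c, in_c, ky, kx, kt)


def _transpose_out_size(n, k, s):
    return (n - 1) * s + k


def conv_transpose3d(h, m, stride=(1, 1, 1)):
    """Fractionally-strided (transposed) convolution of the prediction head.

    Equivalent to inserting ``s - 1`` zeros between adjacent elements of
    ``h`` along each spatial axis and then applying a full spatial
    convolution with ``m``. The head kernel has temporal depth one, so time
    is carried through unchanged.

    Parameters
    ----------
    h : ndarray, shape (n, yh, xh, th, j)
    m : ndarray, shape (k, j, ky, kx)
    stride : (sy, sx, st); st must be 1 (temporal stride is 1 in all stacks).

    Returns
    -------
    ndarray, shape (n, (yh-1)*sy + ky, (xh-1)*sx + kx, th, k)
    """
    sy, sx, st = stride
    if st != 1:
        raise ValueError("temporal stride of the prediction head must be 1")
    n, yh, xh, th, j = h.shape
    k, j2, ky, kx = m.shape
    if j2 != j:
        raise ValueError(
            f"channel axis mismatch: activity has {j} channels, head kernel expects {j2}"
        )
    y_out = _transpose_out_size(yh, ky, sy)
    x_out = _transpose_out_size(xh, kx, sx)
    out = np.zeros((n, y_out, x_out, th, k), dtype=np.result_type(h, m))
    for dy in range(ky):
        for dx in range(kx):
            out[:, dy : dy + sy * yh : sy, dx : dx + sx * xh : sx] += (
                h @ m[:, :, dy, dx].T
            )
    return out


def conv_transpose3d_grad_m(h, grad_v, kernel_yx, stride=(1, 1, 1)):
    """Gradient of a scalar loss w.r.t. the head kernel m (k, j, ky, kx)."""
    sy, sx, _ = stride
    ky, kx = kernel_yx
    n, yh, xh, th, j = h.shape
    k = grad_v.shape[4]
    out = np.empty((k, j, ky, kx), dtype=np.result_type(h, grad_v))
    hf = h.reshape(-1, j)
    for dy in range(ky):
        for dx in range(kx):
            g = grad_v[:, dy : dy + sy * yh : sy, dx : dx + sx * xh : sx]
            out[:, :, dy, dx] = g.reshape(-1, k).T @ hf
    return out


def conv_transpose3d_grad_h(grad_v, m, stride=(1, 1, 1), h_shape=None):
    """Gradient of a scalar loss w.r.t. the head input activity h."""
    sy, sx, _ = stride
    k, j, ky, kx = m.shape
    n, y_out, x_out, th, k2 = grad_v.shape
    if h_shape is None:
        yh = (y_out - ky) // sy + 1
        xh = (x_out - kx) // sx + 1
    else:
        yh, xh = h_shape
    out = np.zeros((n, yh, xh, th, j), dtype=np.result_type(grad_v, m))
    for dy in range(ky):
        for dx in range(kx):
            g = grad_v[:, dy : dy + sy * yh : sy, dx : dx + sx * xh : sx]
            out += g @ m[:, :, dy, dx]
    return out
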