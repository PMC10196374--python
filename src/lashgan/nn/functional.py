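"""Convolution primitives on NCHW float arrays.

Forward, input-gradient and weight-gradient of a strided 2-D convolution,
written as a short loop over the k*k kernel offsets so each term is a single
BLAS ``tensordot``.  The transposed convolution is expressed through the same
three primitives (its forward is the input-gradient of a virtual forward
convolution), which keeps the adjoint relationships exact by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv2d",
    "conv2d_grad_input",
    "conv2d_grad_weight",
    "conv_out_size",
]


def conv_out_size(size: int, kernel: int, stride: int, pad: int) -> int:
    """Spatial output size of a convolution along one axis."""
    return (size + 2 * pad - kernel) // stride + 1


def _pad(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def conv2d(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """y[n,co,h,w] = sum_{ci,i,j} x_pad[n,ci,h*s+i,w*s+j] * w[co,ci,i,j]."""
    n, ci, h, wd = x.shape
    co, ci_w, k, _ = w.shape
    if ci != ci_w:
        raise ValueError(f"channel mismatch: input has {ci}, weight expects {ci_w}")
    ho = conv_out_size(h, k, stride, pad)
    wo = conv_out_size(wd, k, stride, pad)
    xp = _pad(x, pad)
    out = np.zeros((n, ho, wo, co), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            xs = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
            # (n,ci,ho,wo) x (co,ci) -> (n,ho,wo,co)
            out += np.tensordot(xs, w[:, :, i, j], axes=([1], [1]))
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


def conv2d_grad_input(
    gy: np.ndarray,
    w: np.ndarray,
    input_hw: tuple[int, int],
    stride: int,
    pad: int,
) -> np.ndarray:
    """Adjoint of :func:`conv2d` with respect to its input."""
    n, co, ho, wo = gy.shape
    co_w, ci, k, _ = w.shape
    if co != co_w:
        raise ValueError(f"channel mismatch: grad has {co}, weight expects {co_w}")
    h, wd = input_hw
    gxp = np.zeros((n, ci, h + 2 * pad, wd + 2 * pad), dtype=gy.dtype)
    for i in range(k):
        for j in range(k):
            # (n,co,ho,wo) x (co,ci) -> (n,ho,wo,ci)
            g = np.tensordot(gy, w[:, :, i, j], axes=([1], [0]))
            gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                g.transpose(0, 3, 1, 2)
            )
    if pad == 0:
        return gxp
    return np.ascontiguousarray(gxp[:, :, pad : pad + h, pad : pad + wd])


def conv2d_grad_weight(
    x: np.ndarray, gy: np.ndarray, kernel: int, stride: int, pad: int
) -> np.ndarray:
    """Adjoint of :func:`conv2d` with respect to its weight."""
    n, ci, h, wd = x.shape
    _, co, ho, wo = gy.shape
    xp = _pad(x, pad)
    gw = np.zeros((co, ci, kernel, kernel), dtype=x.dtype)
    for i in range(kernel):
        for j in range(kernel):
            xs = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
            gw[:, :, i, j] = np.tensordot(gy, xs, axes=([0, 2, 3], [0, 2, 3]))
    return gw
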