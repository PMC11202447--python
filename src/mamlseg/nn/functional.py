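"""Low-level 3D convolution primitives with explicit gradients.

All operators take batched arrays shaped ``(B, C, D, H, W)``.  Convolutions
use "same"-style padding ``k // 2``; transpose convolutions use padding
``k // 2`` and output padding ``stride - 1`` so a stride-``s`` transpose
convolution exactly inverts the spatial down-scaling of a stride-``s``
convolution on extents divisible by ``s``.

The implementation decomposes each convolution into one matrix product per
kernel offset (27 for a 3x3x3 kernel) over strided array views, which keeps
memory low and routes the arithmetic through BLAS.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "conv3d",
    "conv3d_grad",
    "conv_transpose3d",
    "conv_transpose3d_grad",
]


def _out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 1) -> np.ndarray:
    """Cross-correlate ``x (B,Ci,D,H,W)`` with ``w (Co,Ci,k,k,k)`` plus bias."""
    B, Ci, D, H, W = x.shape
    Co, Ci2, k = w.shape[0], w.shape[1], w.shape[2]
    assert Ci == Ci2, (Ci, Ci2)
    p = k // 2
    s = stride
    Do, Ho, Wo = (_out_size(n, k, s, p) for n in (D, H, W))
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    acc = np.zeros((B, Do, Ho, Wo, Co), dtype=x.dtype)
    for a, bb, c in product(range(k), repeat=3):
        xs = xp[:, :, a:a + s * (Do - 1) + 1:s,
                bb:bb + s * (Ho - 1) + 1:s,
                c:c + s * (Wo - 1) + 1:s]
        acc += np.tensordot(xs, w[:, :, a, bb, c], axes=([1], [1]))
    y = np.moveaxis(acc, -1, 1)
    y += b[None, :, None, None, None]
    return np.ascontiguousarray(y)


def conv3d_grad(x: np.ndarray, w: np.ndarray, stride: int,
                gy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of :func:`conv3d` w.r.t. input, weight and bias."""
    B, Ci, D, H, W = x.shape
    Co, _, k = w.shape[0], w.shape[1], w.shape[2]
    p = k // 2
    s = stride
    _, _, Do, Ho, Wo = gy.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    gxp = np.zeros_like(xp)
    gw = np.zeros_like(w)
    gym = np.moveaxis(gy, 1, -1)  # (B,Do,Ho,Wo,Co)
    for a, bb, c in product(range(k), repeat=3):
        sl = (slice(None), slice(None),
              slice(a, a + s * (Do - 1) + 1, s),
              slice(bb, bb + s * (Ho - 1) + 1, s),
              slice(c, c + s * (Wo - 1) + 1, s))
        xs = xp[sl]
        # gw[o,i,a,bb,c] = sum_{b,d,h,w} xs[b,i,d,h,w] * gy[b,o,d,h,w]
        gw[:, :, a, bb, c] = np.tensordot(gym, xs, axes=([0, 1, 2, 3], [0, 2, 3, 4]))
        # scatter input gradient
        gxp[sl] += np.moveaxis(np.tensordot(gym, w[:, :, a, bb, c], axes=([4], [0])), -1, 1)
    gb = gy.sum(axis=(0, 2, 3, 4))
    gx = gxp[:, :, p:p + D, p:p + H, p:p + W]
    return np.ascontiguousarray(gx), gw, gb


def conv_transpose3d(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                     stride: int = 1) -> np.ndarray:
    """Transpose convolution; ``w`` shaped ``(Ci, Co, k, k, k)``.

    Output extent is ``(n - 1) * s - 2 * (k // 2) + k + (s - 1)``, i.e. ``n * s``
    for odd ``k``.
    """
    B, Ci, D, H, W = x.shape
    Co, k = w.shape[1], w.shape[2]
    p = k // 2
    s = stride
    op = s - 1
    outD, outH, outW = ((n - 1) * s - 2 * p + k + op for n in (D, H, W))
    fullD, fullH, fullW = ((n - 1) * s + k for n in (D, H, W))
    full = np.zeros((B, Co, fullD, fullH, fullW), dtype=x.dtype)
    xm = np.moveaxis(x, 1, -1)  # (B,D,H,W,Ci)
    for a, bb, c in product(range(k), repeat=3):
        t = np.tensordot(xm, w[:, :, a, bb, c], axes=([4], [0]))  # (B,D,H,W,Co)
        full[:, :, a:a + s * (D - 1) + 1:s,
             bb:bb + s * (H - 1) + 1:s,
             c:c + s * (W - 1) + 1:s] += np.moveaxis(t, -1, 1)
    y = full[:, :, p:p + outD, p:p + outH, p:p + outW]
    y = y + b[None, :, None, None, None]
    return np.ascontiguousarray(y)


def conv_transpose3d_grad(x: np.ndarray, w: np.ndarray, stride: int,
                          gy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of :func:`conv_transpose3d` w.r.t. input, weight and bias."""
    B, Ci, D, H, W = x.shape
    Co, k = w.shape[1], w.shape[2]
    p = k // 2
    s = stride
    fullD, fullH, fullW = ((n - 1) * s + k for n in (D, H, W))
    _, _, outD, outH, outW = gy.shape
    gfull = np.zeros((B, Co, fullD, fullH, fullW), dtype=gy.dtype)
    gfull[:, :, p:p + outD, p:p + outH, p:p + outW] = gy
    gx = np.zeros_like(x)
    gw = np.zeros_like(w)
    xm = np.moveaxis(x, 1, -1)
    gxm = np.moveaxis(gx, 1, -1)  # view; writes propagate to gx
    for a, bb, c in product(range(k), repeat=3):
        gs = gfull[:, :, a:a + s * (D - 1) + 1:s,
                   bb:bb + s * (H - 1) + 1:s,
                   c:c + s * (W - 1) + 1:s]  # (B,Co,D,H,W)
        gsm = np.moveaxis(gs, 1, -1)  # (B,D,H,W,Co)
        gxm += np.tensordot(gsm, w[:, :, a, bb, c], axes=([4], [1]))
        gw[:, :, a, bb, c] = np.tensordot(xm, gsm, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
    gb = gy.sum(axis=(0, 2, 3, 4))
    return gx, gw, gb
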