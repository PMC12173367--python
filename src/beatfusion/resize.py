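"""Cubic-convolution (bicubic) resizing for 1-D segments and 2-D feature maps.

Resizing is expressed as multiplication by a precomputed interpolation
matrix, so the operation is exactly linear in its input.  That makes the
gradient of a resize trivially available (the transposed matrix), which the
neural-network fusion layer relies on, and it lets the segmentation code
resize heart-rate-dependent crops to fixed lengths deterministically.

The kernel is the Keys cubic-convolution kernel with a = -0.5, the standard
"bicubic" choice.  Source coordinates are mapped edge-aligned
(``x = i * (n_src - 1) / (n_dst - 1)``) and the signal is extended past its
ends by linear extrapolation, so constants and straight lines are
reproduced exactly, including at the boundaries.
"""

from __future__ import annotations

import numpy as np

_A = -0.5  # Keys kernel free parameter


def _keys_kernel(s: np.ndarray) -> np.ndarray:
    s = np.abs(s)
    w = np.zeros_like(s)
    m1 = s <= 1.0
    m2 = (s > 1.0) & (s < 2.0)
    w[m1] = (_A + 2.0) * s[m1] ** 3 - (_A + 3.0) * s[m1] ** 2 + 1.0
    w[m2] = _A * s[m2] ** 3 - 5.0 * _A * s[m2] ** 2 + 8.0 * _A * s[m2] - 4.0 * _A
    return w


def resize_matrix(n_src: int, n_dst: int) -> np.ndarray:
    """Dense (n_dst, n_src) matrix M such that ``M @ x`` bicubically resizes x.

    Out-of-range taps are folded back into the two boundary samples using
    linear extrapolation (f[-1] = 2 f[0] - f[1] and symmetrically at the far
    end), so the matrix rows always sum to 1.
    """
    if n_src < 4:
        raise ValueError(f"cubic resize needs at least 4 source samples, got {n_src}")
    if n_dst < 2:
        raise ValueError(f"target length must be >= 2, got {n_dst}")
    M = np.zeros((n_dst, n_src))
    scale = (n_src - 1) / (n_dst - 1)
    for i in range(n_dst):
        x = i * scale
        base = int(np.floor(x))
        taps = np.arange(base - 1, base + 3)
        w = _keys_kernel(x - taps)
        for t, wt in zip(taps, w):
            if wt == 0.0:
                continue
            if t < 0:
                # f[t] = f[0] + t*(f[0]-f[1]) for t<0 under linear extrapolation
                M[i, 0] += wt * (1 - t)
                M[i, 1] += wt * t
            elif t >= n_src:
                d = t - (n_src - 1)
                M[i, n_src - 1] += wt * (1 + d)
                M[i, n_src - 2] += wt * (-d)
            else:
                M[i, t] += wt
    return M


def resize_1d(segment: np.ndarray, target_len: int) -> np.ndarray:
    """Resize a 1-D sequence to ``target_len`` samples by cubic convolution.

    The sequence is treated as a 1 x N image; an identity-length resize
    returns the input values exactly.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ValueError("resize_1d expects a 1-D sequence")
    if segment.size < 4:
        raise ValueError("segment too short for cubic resize (need >= 4 samples)")
    if target_len < 4:
        raise ValueError("target_len must be >= 4")
    if target_len == segment.size:
        return segment.copy()
    return resize_matrix(segment.size, target_len) @ segment


def resize_2d(image: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Bicubic resize of a 2-D array (or a stack ``(..., H, W)``) per plane."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape[-2], image.shape[-1]
    th, tw = target_shape
    R = resize_matrix(h, th) if h != th else np.eye(h)
    C = resize_matrix(w, tw) if w != tw else np.eye(w)
    return np.einsum("ij,...jk,lk->...il", R, image, C)
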