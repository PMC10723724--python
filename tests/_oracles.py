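"""Independent brute-force oracles used to cross-check the fast paths.

These are deliberately naive: dense 2-D convolution with an explicitly
constructed truncated Gaussian kernel and symmetric (half-sample
reflect) padding.  They share no code with the package's scipy-backed
implementations.
"""

import math

import numpy as np


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    radius = math.ceil(3.0 * sigma)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def dense_gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Direct (non-separable) 2-D convolution with reflect padding."""
    k1 = gaussian_kernel_1d(sigma)
    radius = (len(k1) - 1) // 2
    kernel = np.outer(k1, k1)
    padded = np.pad(np.asarray(img, dtype=float), radius, mode="symmetric")
    h, w = img.shape
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            window = padded[i:i + 2 * radius + 1, j:j + 2 * radius + 1]
            out[i, j] = float((window * kernel).sum())
    return out


def dense_dog(img: np.ndarray, sigma1: float, sigma2: float) -> np.ndarray:
    """DoG via the dense blur, normalized by its max absolute value."""
    raw = dense_gaussian_blur(img, sigma1) - dense_gaussian_blur(img, sigma2)
    peak = np.abs(raw).max()
    return raw / peak if peak > 1e-10 else np.zeros_like(raw)
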