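"""False-color RGBA rendering of quaternion grids.

The unit vector part maps to color and the real part (sequencing depth) to
opacity: R = s(b), G = s(c), B = s(d) with the sigmoid s(x) = 1/(1 + e^(-2x))
— so a zero coefficient is mid-gray 0.5 and the bounded coefficients never
saturate — while alpha winsorizes depth at a high quantile, applies
log(x - min + 1) and rescales to [0, 1].  Locations with no reads are fully
transparent; the deepest-covered (least uncertain) locations are fully
opaque.
"""

from __future__ import annotations

import warnings

import numpy as np
from PIL import Image

from .st_io import OCC_EMPTY, QuaternionGrid

__all__ = ["to_rgba", "write_png", "write_grayscale_png", "sigmoid"]

EMPTY_RGB = 0.5  # invisible at alpha 0; neutral if composited anyway


def sigmoid(x):
    """The channel transform s(x) = 1 / (1 + exp(-2x))."""
    return 1.0 / (1.0 + np.exp(-2.0 * np.asarray(x, dtype=float)))


def to_rgba(grid: QuaternionGrid, alpha_quantile: float = 0.9) -> np.ndarray:
    """Map a quaternion grid to an (R, C, 4) float image in [0, 1]."""
    if not (0.0 < alpha_quantile <= 1.0):
        raise ValueError("alpha_quantile must be in (0, 1]")
    q = grid.quaternions
    empty = grid.occupancy == OCC_EMPTY
    img = np.empty(q.shape + (4,), dtype=float)
    img[..., 0] = sigmoid(q.b)
    img[..., 1] = sigmoid(q.c)
    img[..., 2] = sigmoid(q.d)
    img[..., 0][empty] = EMPTY_RGB
    img[..., 1][empty] = EMPTY_RGB
    img[..., 2][empty] = EMPTY_RGB

    a = q.a.copy()
    nonempty = ~empty
    if not nonempty.any():
        img[..., 3] = 0.0
        return img
    cap = np.quantile(a[nonempty], alpha_quantile)
    a = np.minimum(a, cap)
    amin = a[nonempty].min()
    la = np.log(a - amin + 1.0)
    lmax = la[nonempty].max()
    if lmax == 0.0:
        warnings.warn(
            "all real parts equal: opacity set to 1 everywhere", UserWarning
        )
        alpha = np.ones_like(la)
    else:
        alpha = la / lmax
    alpha[empty] = 0.0
    img[..., 3] = alpha
    return img


def _quantize(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 4:
        raise ValueError("image must be (R, C, 4)")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    return np.round(255.0 * img).astype(np.uint8)


def write_png(img: np.ndarray, path) -> None:
    """Write an 8-bit RGBA PNG (values quantized by round(255 v))."""
    Image.fromarray(_quantize(img), mode="RGBA").save(path, format="PNG")


def write_grayscale_png(values: np.ndarray, path) -> None:
    """Linearly rescale a non-negative map to [0, 1] and write grayscale PNG."""
    v = np.asarray(values, dtype=float)
    vmax = v.max()
    scaled = v / vmax if vmax > 0 else np.zeros_like(v)
    Image.fromarray(np.round(255.0 * scaled).astype(np.uint8), mode="L").save(
        path, format="PNG"
    )
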