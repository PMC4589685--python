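"""Independent brute-force oracles used by the tests.

These deliberately avoid the library routines the implementation calls
(scipy.ndimage morphology / convolution), using explicit shifting and
loops instead, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def shift_bool(mask: np.ndarray, dy: int, dx: int, fill: bool) -> np.ndarray:
    """Shift a boolean image by (dy, dx), filling vacated pixels with ``fill``."""
    out = np.full_like(mask, fill)
    h, w = mask.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = mask[ys_src, xs_src]
    return out


def brute_erode(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Binary erosion by explicit AND over the structuring-element offsets
    (pixels outside the image count as background)."""
    cy, cx = se.shape[0] // 2, se.shape[1] // 2
    out = np.ones_like(mask, dtype=bool)
    for oy, ox in zip(*np.nonzero(se)):
        out &= shift_bool(mask.astype(bool), cy - oy, cx - ox, fill=False)
    return out


def brute_dilate(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Binary dilation by explicit OR over the structuring-element offsets."""
    cy, cx = se.shape[0] // 2, se.shape[1] // 2
    out = np.zeros_like(mask, dtype=bool)
    for oy, ox in zip(*np.nonzero(se)):
        out |= shift_bool(mask.astype(bool), oy - cy, ox - cx, fill=False)
    return out


def brute_open(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    return brute_dilate(brute_erode(mask, se), se)


def brute_correlate_reflect(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct-sum cross-correlation with reflect ('symmetric') padding."""
    kh, kw = kernel.shape
    cy, cx = kh // 2, kw // 2
    padded = np.pad(img, ((cy, cy), (cx, cx)), mode="symmetric")
    h, w = img.shape
    out = np.zeros_like(img, dtype=float)
    for i in range(h):
        for j in range(w):
            out[i, j] = np.sum(padded[i : i + kh, j : j + kw] * kernel)
    return out
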