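"""Vessel/background classification of gray-scale filter responses.

The real-valued response is linearly quantized to 8 bits and thresholded at
the gray level maximizing the between-class (interclass) variance of the
histogram — Otsu's criterion.  Pixels strictly above the threshold are
classified as vessel.
"""

from __future__ import annotations

import numpy as np

__all__ = ["quantize", "histogram256", "otsu_threshold", "segment"]


def quantize(response) -> np.ndarray:
    """Min-max rescale a real-valued response to integer gray levels 0-255.

    Rounds half up; a constant input maps to all zeros.
    """
    arr = np.asarray(response, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("response contains non-finite values")
    lo = arr.min()
    span = arr.max() - lo
    if span == 0:
        return np.zeros(arr.shape, dtype=np.uint8)
    scaled = (arr - lo) / span * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)


def histogram256(levels) -> np.ndarray:
    """Counts of gray levels 0-255 in an 8-bit image."""
    arr = np.asarray(levels)
    if arr.size == 0:
        raise ValueError("empty input")
    return np.bincount(arr.ravel().astype(np.int64), minlength=256)[:256]


def otsu_threshold(hist) -> int:
    """Gray level t in 0-255 maximizing the between-class variance.

    The two classes are {levels <= t} and {levels > t}; the between-class
    variance is w0(t) * w1(t) * (mu0(t) - mu1(t))^2.  Ties are broken by the
    smallest t.  Equivalent to a brute-force scan of all 256 candidates.
    """
    counts = np.asarray(hist, dtype=float)
    if counts.shape != (256,):
        raise ValueError(f"expected 256 histogram bins, got shape {counts.shape}")
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    p = counts / total
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(p)
    cum_mean = np.cumsum(p * levels)
    mu_total = cum_mean[-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    between = np.zeros(256)
    # w0*w1*(mu0-mu1)^2 == (mu_T*w0 - cum_mean)^2 / (w0*w1)
    between[valid] = (mu_total * w0[valid] - cum_mean[valid]) ** 2 / (
        w0[valid] * w1[valid]
    )
    return int(np.argmax(between))


def segment(response) -> np.ndarray:
    """Binary vessel mask from a filter response (foreground = vessel).

    Accepts a ``FilterResponse`` or a bare 2-D array; quantizes to 8 bits and
    keeps pixels strictly above the Otsu threshold of the image histogram.
    """
    arr = np.asarray(getattr(response, "response", response), dtype=float)
    q = quantize(arr)
    t = otsu_threshold(histogram256(q))
    return q > t
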