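"""Single-scale oriented Gabor filter bank for curvilinear-structure enhancement.

A Gabor kernel is a 2-D Gaussian envelope modulated by a cosine,

    g(x, y) = 1/(2 pi sx sy) * exp(-(x^2/sx^2 + y^2/sy^2)/2) * cos(2 pi f0 x),

rotated into a bank of ``kappa`` evenly spaced orientations covering
[-pi/2, pi/2).  The bank is parameterised the way the vessel-detection
literature does:

``tau``
    average thickness, in pixels, of the tubular structures to detect.  It
    fixes the cross-sectional Gaussian spread through the FWHM relation
    ``sigma_x = tau / (2 sqrt(2 ln 2))`` and the modulation frequency
    ``f0 = 1/(2 tau)``, which puts one positive cosine lobe across one
    structure width.
``ell``
    elongation of the kernel along the structure, ``sigma_y = ell * sigma_x``.
``kappa``
    number of oriented kernels; the angular step is ``180/kappa`` degrees.

Enhancing an image keeps, per pixel, the maximum response over all
orientations.  Kernels are zero-mean (the DC component is subtracted after
truncation) so a flat background produces exactly zero response.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import fft as _fft

__all__ = [
    "FWHM_FACTOR",
    "GaborParams",
    "OrientedKernel",
    "FilterResponse",
    "orientation_angles",
    "kernel_radius",
    "build_kernel",
    "bank_responses",
    "enhance",
]

#: conversion between full width at half maximum and Gaussian sigma
FWHM_FACTOR: float = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclasses.dataclass(frozen=True)
class GaborParams:
    """Parameters of a single-scale Gabor filter bank.

    Parameters
    ----------
    tau : int
        Average thickness (pixels) of the structures to detect, >= 1.
    ell : float
        Elongation of the kernel along the structure axis, > 0.
    kappa : int, default 180
        Number of evenly spaced orientations in [-pi/2, pi/2).
    """

    tau: int
    ell: float
    kappa: int = 180

    def __post_init__(self) -> None:
        if not (self.tau >= 1 and float(self.tau) == int(self.tau)):
            raise ValueError(f"tau must be an integer >= 1, got {self.tau!r}")
        if not (self.ell > 0 and math.isfinite(self.ell)):
            raise ValueError(f"ell must be a positive finite real, got {self.ell!r}")
        if self.kappa < 1:
            raise ValueError(f"kappa must be >= 1, got {self.kappa!r}")

    @property
    def sigma_x(self) -> float:
        """Cross-sectional Gaussian spread, ``tau / (2 sqrt(2 ln 2))`` (pixels)."""
        return self.tau / FWHM_FACTOR

    @property
    def sigma_y(self) -> float:
        """Longitudinal Gaussian spread, ``ell * sigma_x`` (pixels)."""
        return self.ell * self.sigma_x

    @property
    def f0(self) -> float:
        """Frequency of the modulating cosine, ``1/(2 tau)`` (cycles/pixel).

        The half-period — the width of the central positive lobe of the
        cosine — then equals ``tau``, so the kernel's excitatory core spans
        exactly one structure width and tau is the thickness to which the
        bank is matched.  With ``f0 = 1/tau`` the excitatory lobe would span
        only half a structure width and the best-responding tau would sit
        near twice the true thickness.
        """
        return 1.0 / (2.0 * self.tau)


@dataclasses.dataclass(frozen=True)
class OrientedKernel:
    """A single oriented Gabor kernel on an odd-sided integer pixel grid."""

    theta: float
    coeffs: np.ndarray

    @property
    def radius(self) -> int:
        return self.coeffs.shape[0] // 2


@dataclasses.dataclass
class FilterResponse:
    """Per-pixel maximum Gabor response over all orientations.

    Attributes
    ----------
    response : ndarray
        Maximum filter response, same shape as the input image.
    best_theta : ndarray
        Orientation (radians) attaining the maximum at each pixel.
    """

    response: np.ndarray
    best_theta: np.ndarray


def orientation_angles(kappa: int) -> np.ndarray:
    """Return ``kappa`` evenly spaced angles covering [-pi/2, pi/2).

    The grid is half-open so that theta and theta + pi (the same undirected
    orientation) are never both present; the angular step is 180/kappa
    degrees.
    """
    if kappa < 1:
        raise ValueError(f"kappa must be >= 1, got {kappa!r}")
    return -np.pi / 2 + np.arange(kappa) * (np.pi / kappa)


def kernel_radius(params: GaborParams) -> int:
    """Natural truncation radius, ``ceil(3 * max(sigma_x, sigma_y))`` pixels."""
    return int(math.ceil(3.0 * max(params.sigma_x, params.sigma_y)))


def _kernel_values(
    params: GaborParams, theta: float, radius: int, remove_dc: bool
) -> np.ndarray:
    sx, sy, f0 = params.sigma_x, params.sigma_y, params.f0
    if not (math.isfinite(sx) and math.isfinite(sy)):
        raise ValueError(f"non-finite kernel spread for params {params!r}")
    offsets = np.arange(-radius, radius + 1, dtype=float)
    x = offsets[np.newaxis, :]
    y = offsets[:, np.newaxis]
    # analytic evaluation at coordinates rotated by -theta; no resampling
    xr = x * math.cos(theta) + y * math.sin(theta)
    yr = -x * math.sin(theta) + y * math.cos(theta)
    g = (
        (1.0 / (2.0 * math.pi * sx * sy))
        * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2))
        * np.cos(2.0 * math.pi * f0 * xr)
    )
    if remove_dc:
        g -= g.mean()
    return g


def build_kernel(
    params: GaborParams,
    theta: float,
    *,
    max_radius: int | None = None,
    remove_dc: bool = True,
) -> OrientedKernel:
    """Build one oriented Gabor kernel.

    The support is truncated at ``+-ceil(3 * max(sigma_x, sigma_y))`` in each
    axis (odd side, exact center pixel), optionally capped at ``max_radius``
    so oversized kernels can be clipped to a field of view.  The mean is
    subtracted after truncation unless ``remove_dc`` is false.
    """
    if not math.isfinite(theta):
        raise ValueError(f"theta must be finite, got {theta!r}")
    radius = kernel_radius(params)
    if max_radius is not None:
        radius = min(radius, int(max_radius))
    return OrientedKernel(theta=float(theta), coeffs=_kernel_values(params, theta, radius, remove_dc))


class _Convolver:
    """FFT-domain convolution of one image, padded once with mirrored borders.

    The image is padded by ``pad`` pixels on every side with symmetric
    (mirror) boundary handling and transformed once; each kernel then costs
    one forward and one inverse transform.  Any kernel radius up to ``pad``
    yields results identical to direct spatial convolution with symmetric
    boundaries.
    """

    def __init__(self, image: np.ndarray, pad: int):
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {image.shape}")
        if not np.all(np.isfinite(image)):
            raise ValueError("image contains non-finite values")
        self.shape = image.shape
        self.pad = int(pad)
        padded = np.pad(image, self.pad, mode="symmetric")
        # fft shape must hold the full linear convolution of padded image and kernel
        self._fft_shape = (
            _fft.next_fast_len(padded.shape[0] + 2 * self.pad),
            _fft.next_fast_len(padded.shape[1] + 2 * self.pad),
        )
        self._image_fft = _fft.rfft2(padded, s=self._fft_shape)

    def convolve_many(self, kernels: np.ndarray) -> np.ndarray:
        """Convolve with a stack of kernels of shape (k, s, s), s = 2r+1 <= 2*pad+1.

        Returns responses of shape (k, H, W), equal to 'same'-mode spatial
        convolution of the original image with symmetric boundary padding.
        """
        kernels = np.asarray(kernels, dtype=float)
        r = kernels.shape[-1] // 2
        if r > self.pad:
            raise ValueError(f"kernel radius {r} exceeds padding {self.pad}")
        kf = _fft.rfft2(kernels, s=self._fft_shape, axes=(-2, -1))
        return self.convolve_with_fft(kf, r)

    def convolve_with_fft(self, kernels_fft: np.ndarray, radius: int) -> np.ndarray:
        """Convolve with pre-transformed kernels of half-support ``radius``."""
        conv = _fft.irfft2(
            self._image_fft * kernels_fft, s=self._fft_shape, axes=(-2, -1)
        )
        h, w = self.shape
        off = self.pad + radius
        return conv[..., off : off + h, off : off + w]


def bank_responses(
    convolvers: Sequence[_Convolver],
    params: GaborParams,
    radius: int,
    chunk: int = 8,
) -> list[FilterResponse]:
    """Max-over-orientations responses of several same-shape images.

    All convolvers must share the same FFT plan shape so each oriented
    kernel is transformed once and reused across every image.
    """
    thetas = orientation_angles(params.kappa)
    shapes = {c._fft_shape for c in convolvers}
    if len(shapes) != 1:
        raise ValueError("all convolvers must share one FFT shape")
    best = [np.full(c.shape, -np.inf) for c in convolvers]
    best_theta = [np.zeros(c.shape) for c in convolvers]
    for start in range(0, len(thetas), chunk):
        block = thetas[start : start + chunk]
        kernels = np.stack(
            [_kernel_values(params, t, radius, remove_dc=True) for t in block]
        )
        kf = _fft.rfft2(kernels, s=convolvers[0]._fft_shape, axes=(-2, -1))
        for j, conv in enumerate(convolvers):
            resp = conv.convolve_with_fft(kf, radius)
            for i, t in enumerate(block):
                better = resp[i] > best[j]
                best[j] = np.where(better, resp[i], best[j])
                best_theta[j] = np.where(better, t, best_theta[j])
    return [
        FilterResponse(response=b, best_theta=bt) for b, bt in zip(best, best_theta)
    ]


def _max_response(
    convolver: _Convolver,
    params: GaborParams,
    radius: int,
    chunk: int = 8,
) -> FilterResponse:
    return bank_responses([convolver], params, radius, chunk)[0]


def enhance(
    image: np.ndarray,
    params: GaborParams,
    *,
    max_radius: int | None = None,
) -> FilterResponse:
    """Enhance an image with the oriented Gabor bank.

    The image is convolved (frequency domain, symmetric boundary padding)
    with every kernel of the bank; per pixel the maximum response and the
    orientation attaining it are kept.  The image must be pre-inverted so the
    structures of interest are bright ridges.

    Pass ``max_radius`` to clip kernels to a maximum half-support (e.g. to
    fit a small field of view); by default the natural 3-sigma support is
    used and an image smaller than the kernel raises ``ValueError``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {image.shape}")
    radius = kernel_radius(params)
    if max_radius is not None:
        radius = min(radius, int(max_radius))
    side = 2 * radius + 1
    if side > min(image.shape):
        raise ValueError(
            f"image of shape {image.shape} is smaller than the kernel support; "
            f"minimum image size is {side}x{side} (or pass max_radius<="
            f"{(min(image.shape) - 1) // 2})"
        )
    convolver = _Convolver(image, pad=radius)
    return _max_response(convolver, params, radius)


def export_kernel_pgm(kernel: OrientedKernel, path) -> None:
    """Write a kernel as an 8-bit PGM image (min-max scaled) for inspection."""
    c = kernel.coeffs
    span = c.max() - c.min()
    scaled = np.zeros_like(c) if span == 0 else (c - c.min()) / span * 255.0
    data = np.floor(scaled + 0.5).astype(np.uint8)
    h, w = data.shape
    with open(path, "wb") as fh:
        fh.write(f"P5\n{w} {h}\n255\n".encode())
        fh.write(data.tobytes())
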