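"""Feature 3 -- Gabor texture energy of the monitor image at the gaze target.

Edge frequency is a strong predictor of where people look, so the
amount of band-pass texture in a gaze-centered region of the monitor
image is used as the third selection cue. The filter bank holds the
real parts of rotated, amplitude-scaled copies of the mother Gabor
wavelet

    g(x, y) = 1/(2 pi sx sy) * exp(-(x^2/sx^2 + y^2/sy^2)/2) * cos(2 pi W x)

with K orientations (theta = n*pi/K) and P+1 scales (gain a^-m); the
default K=4, P=3 gives the 16-kernel bank. Each kernel is DC-removed so
constant regions score exactly zero. The feature is the mean absolute
filter response over all kernels and ROI pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ROIOffScreenError

__all__ = [
    "GaborParams",
    "FilterBank",
    "ROISpec",
    "gabor_kernel",
    "build_bank",
    "texture_score",
]


@dataclass(frozen=True)
class GaborParams:
    """Bank geometry: spatial sigmas (px), radial frequency W (cycles/px),
    K orientations, P+1 scales with gain base a."""

    sigma_x: float = 2.0
    sigma_y: float = 2.0
    radial_freq: float = 0.25
    n_orientations: int = 4
    n_scales: int = 4  # P + 1
    scale_base: float = np.sqrt(2.0)

    def __post_init__(self) -> None:
        if self.n_orientations < 1 or self.n_scales < 1:
            raise ValueError("need K >= 1 orientations and P+1 >= 1 scales")
        if self.scale_base <= 1.0:
            raise ValueError("scale base a must exceed 1")


@dataclass
class FilterBank:
    """K x (P+1) real kernels labeled by (scale m, orientation n)."""

    kernels: list[np.ndarray]
    labels: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.kernels)


@dataclass(frozen=True)
class ROISpec:
    """Gaze-centered texture window on the monitor image (half sizes in px)."""

    center: tuple[float, float]
    half_width: int = 50
    half_height: int = 50


def gabor_kernel(
    params: GaborParams,
    m: int,
    n: int,
    support: int | None = None,
    remove_dc: bool = True,
) -> np.ndarray:
    """Real Gabor wavelet kernel at scale index ``m``, orientation index ``n``.

    The kernel is a^-m * Re{g(x', y')} on the integer grid, with
    x' = x cos(theta) + y sin(theta), y' = -x sin(theta) + y cos(theta),
    theta = n*pi/K. ``support`` is the half-size in pixels (default
    4 * max sigma, giving an odd kernel).
    """
    if not (0 <= m < params.n_scales):
        raise ValueError("scale index m out of range")
    if not (0 <= n < params.n_orientations):
        raise ValueError("orientation index n out of range")
    if support is None:
        support = int(np.ceil(4.0 * max(params.sigma_x, params.sigma_y)))
    theta = n * np.pi / params.n_orientations
    y, x = np.mgrid[-support : support + 1, -support : support + 1].astype(float)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    sx, sy = params.sigma_x, params.sigma_y
    envelope = np.exp(-0.5 * (xr**2 / sx**2 + yr**2 / sy**2)) / (2.0 * np.pi * sx * sy)
    kernel = params.scale_base ** (-m) * envelope * np.cos(2.0 * np.pi * params.radial_freq * xr)
    if remove_dc:
        kernel = kernel - kernel.mean()
    return kernel


def build_bank(params: GaborParams | None = None, support: int | None = None) -> FilterBank:
    """All K x (P+1) kernels; defaults give the 16-filter bank."""
    params = params or GaborParams()
    kernels, labels = [], []
    for m in range(params.n_scales):
        for n in range(params.n_orientations):
            kernels.append(gabor_kernel(params, m, n, support))
            labels.append((m, n))
    return FilterBank(kernels=kernels, labels=labels)


def clip_roi(image_shape: tuple[int, int], roi: ROISpec) -> tuple[slice, slice]:
    """Integer pixel window of the ROI clipped to the image; errors when empty."""
    cx, cy = roi.center
    x0 = max(0, int(round(cx)) - roi.half_width)
    x1 = min(image_shape[1], int(round(cx)) + roi.half_width + 1)
    y0 = max(0, int(round(cy)) - roi.half_height)
    y1 = min(image_shape[0], int(round(cy)) + roi.half_height + 1)
    if x0 >= x1 or y0 >= y1:
        raise ROIOffScreenError("ROI off-screen")
    return slice(y0, y1), slice(x0, x1)


def texture_score(monitor_image: np.ndarray, roi: ROISpec, bank: FilterBank) -> float:
    """Raw Feature 3: mean |Gabor response| over all kernels and ROI pixels.

    Color screenshots are averaged to luminance first. Convolution uses
    reflect padding at the ROI borders.
    """
    img = np.asarray(monitor_image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    window = img[clip_roi(img.shape, roi)]
    total = 0.0
    for kernel in bank.kernels:
        resp = ndimage.convolve(window, kernel, mode="reflect")
        total += float(np.abs(resp).mean())
    return total / len(bank.kernels)
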