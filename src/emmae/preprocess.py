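"""Micrograph normalization, enhancement and resizing.

The background of a cryo-EM micrograph varies with ice thickness, exposure
and other acquisition parameters.  To standardize it, the local mean and
standard deviation are estimated at every pixel under a circular mask whose
diameter equals the particle diameter, and the image is mapped to

    X'(r) = (X(r) - mu(r)) / sigma(r),

so the background becomes zero-mean, unit-variance noise.  The local
statistics are computed in the Fourier domain as cross-correlations with
the mask,

    mu(r)     = (1/|M0|) IFT{ FT(X)  FT(M0)* },
    sigma2(r) = (1/|M0|) IFT{ FT(X^2) FT(M0)* } - mu(r)^2,

which implies a periodic (wrap-around) boundary convention.  The normalized
image is then denoised with a Wiener filter, contrast-enhanced with CLAHE,
and edge-preservingly smoothed with a guided filter that uses the CLAHE
image as its guide, before resizing to the working resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import wiener
from skimage import exposure
from skimage.transform import resize as _sk_resize

from .config import RunConfig
from .errors import ContractViolationError
from .io_formats import MicrographImage

__all__ = [
    "CircularMask",
    "LocalStats",
    "circular_mask",
    "local_stats",
    "local_normalize",
    "enhance",
    "resize_working",
    "preprocess_micrograph",
]


@dataclass
class CircularMask:
    """Binary disc of a given pixel diameter, centered on the image grid."""

    mask: np.ndarray
    area: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class LocalStats:
    """Per-pixel local mean and standard deviation under a circular mask."""

    mu: np.ndarray
    sigma: np.ndarray
    eps: float


def circular_mask(shape: tuple[int, int], diameter_px: float) -> CircularMask:
    """Disc of ``diameter_px`` centered at (rows//2, cols//2).

    Pixels whose center lies within diameter/2 of the disc center are set.
    The integer-centered construction is symmetric under 180-degree
    rotation, so correlation with it is equivalent to convolution.
    """
    rows, cols = shape
    if diameter_px <= 0:
        raise ContractViolationError("mask diameter must be positive")
    if diameter_px >= min(rows, cols):
        raise ContractViolationError("mask must be smaller than the image")
    cy, cx = rows // 2, cols // 2
    yy, xx = np.ogrid[:rows, :cols]
    mask = ((yy - cy) ** 2 + (xx - cx) ** 2) <= (diameter_px / 2.0) ** 2
    area = int(mask.sum())
    if area == 0:
        raise ContractViolationError("circular mask has zero area")
    return CircularMask(mask=mask.astype(np.float64), area=area)


def local_stats(X: MicrographImage | np.ndarray, m: CircularMask) -> LocalStats:
    """FFT local mean/std of ``X`` under mask ``m`` (periodic boundaries)."""
    pixels = X.pixels if isinstance(X, MicrographImage) else np.asarray(X, float)
    if m.shape != pixels.shape:
        raise ContractViolationError("mask shape must match the image")
    if m.area == 0:
        raise ContractViolationError("zero-area mask")
    # shift the disc center to the origin so the correlation is centered
    kernel = np.fft.ifftshift(m.mask)
    Fm = np.fft.fft2(kernel)
    mu = np.fft.ifft2(np.fft.fft2(pixels) * np.conj(Fm)).real / m.area
    ex2 = np.fft.ifft2(np.fft.fft2(pixels**2) * np.conj(Fm)).real / m.area
    var = np.maximum(ex2 - mu**2, 0.0)  # clamp FFT round-off
    return LocalStats(mu=mu, sigma=np.sqrt(var), eps=0.0)


def local_normalize(X: MicrographImage, diameter_px: float) -> MicrographImage:
    """Standardize the background to zero mean / unit std at particle scale."""
    if diameter_px < 3:
        raise ContractViolationError("particle diameter must be >= 3 px")
    m = circular_mask(X.shape, diameter_px)
    stats = local_stats(X, m)
    eps = max(1e-6 * float(X.pixels.std()), 1e-12)
    out = (X.pixels - stats.mu) / np.maximum(stats.sigma, eps)
    return MicrographImage(
        pixels=out,
        id=X.id,
        pixel_size_A=X.pixel_size_A,
        original_shape=X.original_shape,
    )


def _guided_filter(
    p: np.ndarray, guide: np.ndarray, radius: int, eps: float
) -> np.ndarray:
    """Edge-preserving smoothing of ``p`` steered by ``guide``.

    Box-filter formulation: within each window the output is an affine
    function of the guide, q = a*I + b, with a = cov(I,p)/(var(I)+eps).
    """
    size = 2 * radius + 1

    def box(img: np.ndarray) -> np.ndarray:
        return uniform_filter(img, size=size, mode="reflect")

    mean_I = box(guide)
    mean_p = box(p)
    corr_Ip = box(guide * p)
    corr_II = box(guide * guide)
    var_I = corr_II - mean_I**2
    cov_Ip = corr_Ip - mean_I * mean_p
    a = cov_Ip / (var_I + eps)
    b = mean_p - a * mean_I
    return box(a) * guide + box(b)


def enhance(X: MicrographImage, diameter_px: float, cfg: RunConfig | None = None) -> MicrographImage:
    """Wiener denoising, CLAHE contrast enhancement and guided filtering.

    The Wiener-denoised image is min-max rescaled to [0, 1]; CLAHE is run on
    it (clip limit ``cfg.clahe_clip_limit`` in per-256-bin units over an
    8x8 tile grid); the guided filter then smooths the Wiener image using
    the CLAHE result as its guide.  Output values lie in [0, 1].
    """
    cfg = cfg or RunConfig()
    if not np.all(np.isfinite(X.pixels)):
        raise ContractViolationError("enhance requires finite input")
    den = wiener(X.pixels, (cfg.wiener_window, cfg.wiener_window))
    lo, hi = float(den.min()), float(den.max())
    den01 = (den - lo) / (hi - lo) if hi > lo else np.zeros_like(den)

    rows, cols = den01.shape
    kernel = (max(rows // cfg.clahe_tiles, 1), max(cols // cfg.clahe_tiles, 1))
    clahe = exposure.equalize_adapthist(
        den01, kernel_size=kernel, clip_limit=cfg.clahe_clip_limit / 256.0
    )
    radius = max(int(round(diameter_px / 4.0)), 1)
    out = _guided_filter(den01, clahe, radius, cfg.guided_eps)
    out = np.clip(out, 0.0, 1.0)
    return MicrographImage(
        pixels=out,
        id=X.id,
        pixel_size_A=X.pixel_size_A,
        original_shape=X.original_shape,
    )


def resize_working(
    X: MicrographImage, working_size: int
) -> tuple[MicrographImage, float, float]:
    """Bilinear resize to ``working_size`` square; returns (image, sx, sy).

    ``sx`` and ``sy`` are the working/original scale factors per axis
    (multiply original-frame coordinates by them to reach the working
    frame).  Anti-aliasing is enabled when downscaling.
    """
    rows, cols = X.shape
    sy = working_size / rows
    sx = working_size / cols
    if rows == working_size and cols == working_size:
        out = X.pixels
    else:
        out = _sk_resize(
            X.pixels,
            (working_size, working_size),
            order=1,
            anti_aliasing=(sy < 1.0 or sx < 1.0),
            preserve_range=True,
        )
    img = MicrographImage(
        pixels=out,
        id=X.id,
        pixel_size_A=X.pixel_size_A,
        original_shape=(rows, cols),
    )
    return img, sx, sy


def preprocess_micrograph(
    X: MicrographImage, diameter_px: float, cfg: RunConfig | None = None
) -> tuple[MicrographImage, float, float, float]:
    """Full chain: normalize -> enhance at native resolution -> resize.

    ``diameter_px`` is the particle diameter in original-frame pixels.
    Returns (working image, sx, sy, diameter in working-frame pixels);
    the working-frame diameter uses the mean of the two axis scales.
    """
    cfg = cfg or RunConfig()
    norm = local_normalize(X, diameter_px)
    enh = enhance(norm, diameter_px, cfg)
    work, sx, sy = resize_working(enh, cfg.working_size)
    return work, sx, sy, diameter_px * (sx + sy) / 2.0
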