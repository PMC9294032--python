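"""Intensity similarity metrics for coarse DRR-to-radiograph matching.

Five metrics drive the coarse spatial search: mutual information (MI),
gradient intensity (GI), peak signal-to-noise ratio (PSNR), the structural
similarity index (SSIM) and normalized cross-correlation (NCC).  All operate
on two equally-sized, equally-resampled images.

The metric functions themselves take raw arrays; because the DRR and the
radiograph come from different modalities with incommensurate intensity
scales, the search pipeline first min-max normalizes *each* image to a
common ``[0, PEAK]`` range (:func:`minmax_scale`) — without a shared scale
PSNR and MSE are meaningless across modalities.

Conventions: entropies are in bits; MI uses 32 equal-width bins by default;
GI gradients are Sobel estimates scaled by pixel spacing; SSIM uses the
standard 11x11 Gaussian window (sigma 1.5) with stabilizing constants
``C1 = (0.01 L)^2``, ``C2 = (0.03 L)^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SimilarityScore",
    "ZeroVarianceError",
    "METRICS",
    "minmax_scale",
    "mutual_information",
    "gradient_intensity",
    "psnr",
    "ssim",
    "ncc",
    "compute_metric",
    "image_gradients",
]

PEAK = 255.0  # common intensity range used by the search pipeline


class ZeroVarianceError(ValueError):
    """Raised when a correlation-type score is undefined (constant image)."""


@dataclass(frozen=True)
class SimilarityScore:
    metric: str
    value: float

    def __float__(self) -> float:
        return float(self.value)


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def minmax_scale(img: np.ndarray, peak: float = PEAK) -> np.ndarray:
    """Min-max scale an image to ``[0, peak]`` (constant images map to 0)."""
    img = np.asarray(img, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) * (peak / (hi - lo))


# --------------------------------------------------------------------------
# mutual information
# --------------------------------------------------------------------------

def mutual_information(a: np.ndarray, b: np.ndarray, n_bins: int = 32) -> SimilarityScore:
    """Histogram-estimated mutual information ``H(A) + H(B) - H(A,B)`` in bits.

    Each image is binned into ``n_bins`` equal-width bins over its own
    range; a constant image has zero entropy, hence zero MI with anything.
    """
    a, b = _check_pair(a, b)
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")

    def edges(x: np.ndarray) -> np.ndarray:
        lo, hi = x.min(), x.max()
        if hi == lo:
            hi = lo + 1.0
        return np.linspace(lo, hi, n_bins + 1)

    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=[edges(a), edges(b)])
    p_ab = joint / joint.sum()
    p_a = p_ab.sum(axis=1)
    p_b = p_ab.sum(axis=0)

    def entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    mi = entropy(p_a) + entropy(p_b) - entropy(p_ab.ravel())
    return SimilarityScore("mi", max(mi, 0.0))


# --------------------------------------------------------------------------
# gradient intensity
# --------------------------------------------------------------------------

def image_gradients(img: np.ndarray, spacing: tuple[float, float] = (1.0, 1.0)
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Sobel gradient components ``(d/dv, d/du)`` in intensity per mm."""
    img = np.asarray(img, dtype=np.float64)
    # scipy's Sobel kernel ([-1,0,1] x [1,2,1]) estimates 8x the per-pixel
    # central difference
    gv = ndimage.sobel(img, axis=0, mode="nearest") / (8.0 * spacing[0])
    gu = ndimage.sobel(img, axis=1, mode="nearest") / (8.0 * spacing[1])
    return gv, gu


def gradient_intensity(a: np.ndarray, b: np.ndarray,
                       spacing: tuple[float, float] = (1.0, 1.0)) -> SimilarityScore:
    """Gradient intensity: ``sum w * min(|grad A|, |grad B|)`` with the
    weight ``w = (cos(alpha) + 1)/2`` built from the angle ``alpha`` between
    the two gradient vectors.

    Pixels where either gradient vanishes contribute zero (the min is zero),
    which makes the metric robust to structures present in only one image.
    """
    a, b = _check_pair(a, b)
    gav, gau = image_gradients(a, spacing)
    gbv, gbu = image_gradients(b, spacing)
    mag_a = np.hypot(gav, gau)
    mag_b = np.hypot(gbv, gbu)
    denom = mag_a * mag_b
    valid = denom > 0
    cos_alpha = np.zeros_like(denom)
    np.divide(gav * gbv + gau * gbu, denom, out=cos_alpha, where=valid)
    np.clip(cos_alpha, -1.0, 1.0, out=cos_alpha)
    w = (cos_alpha + 1.0) / 2.0
    gi = float((w * np.minimum(mag_a, mag_b))[valid].sum())
    return SimilarityScore("gi", gi)


# --------------------------------------------------------------------------
# PSNR
# --------------------------------------------------------------------------

def psnr(a: np.ndarray, b: np.ndarray, peak: float = PEAK) -> SimilarityScore:
    """``10 log10(R^2 / MSE)`` in dB; identical images score ``+inf``."""
    a, b = _check_pair(a, b)
    if peak <= 0:
        raise ValueError(f"peak must be positive, got {peak}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return SimilarityScore("psnr", math.inf)
    return SimilarityScore("psnr", 10.0 * math.log10(peak * peak / mse))


# --------------------------------------------------------------------------
# SSIM
# --------------------------------------------------------------------------

def ssim(a: np.ndarray, b: np.ndarray, data_range: float = PEAK,
         sigma: float = 1.5, win_size: int = 11,
         k1: float = 0.01, k2: float = 0.03) -> SimilarityScore:
    """Mean local SSIM with a Gaussian window (standard formulation).

    Local means/variances/covariance are Gaussian-weighted (sigma 1.5 over
    an 11x11 support); the luminance-contrast-structure product uses the
    usual stabilizers ``C1 = (k1 L)^2`` and ``C2 = (k2 L)^2``.  The mean is
    taken over the interior (a ``win_size//2`` border is cropped).
    """
    a, b = _check_pair(a, b)
    if min(a.shape) < win_size:
        raise ValueError(f"images smaller than the {win_size}x{win_size} SSIM window")
    truncate = (win_size - 1) / 2.0 / sigma

    def filt(x: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(x, sigma, truncate=truncate)

    ux, uy = filt(a), filt(b)
    uxx, uyy, uxy = filt(a * a), filt(b * b), filt(a * b)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    num = (2 * ux * uy + c1) * (2 * vxy + c2)
    den = (ux ** 2 + uy ** 2 + c1) * (vx + vy + c2)
    smap = num / den
    pad = (win_size - 1) // 2
    value = float(np.mean(smap[pad:-pad, pad:-pad]))
    return SimilarityScore("ssim", min(max(value, -1.0), 1.0))


# --------------------------------------------------------------------------
# NCC
# --------------------------------------------------------------------------

def ncc(a: np.ndarray, b: np.ndarray) -> SimilarityScore:
    """Pearson correlation coefficient over all pixels.

    Raises :class:`ZeroVarianceError` when either image is constant (the
    coefficient is undefined).
    """
    a, b = _check_pair(a, b)
    da = a - a.mean()
    db = b - b.mean()
    na = math.sqrt(float((da * da).sum()))
    nb = math.sqrt(float((db * db).sum()))
    if na == 0.0 or nb == 0.0:
        raise ZeroVarianceError("NCC undefined for a constant image")
    value = float((da * db).sum() / (na * nb))
    return SimilarityScore("ncc", min(max(value, -1.0), 1.0))


METRICS = {
    "mi": mutual_information,
    "gi": gradient_intensity,
    "psnr": psnr,
    "ssim": ssim,
    "ncc": ncc,
}


def compute_metric(metric: str, a: np.ndarray, b: np.ndarray, *,
                   normalize: bool = True, n_bins: int = 32) -> SimilarityScore:
    """Score an image pair with one named metric.

    With ``normalize=True`` (the search-pipeline path) both images are first
    independently min-max scaled to ``[0, 255]``.
    """
    metric = metric.lower()
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if normalize:
        a = minmax_scale(a)
        b = minmax_scale(b)
    if metric == "mi":
        return mutual_information(a, b, n_bins=n_bins)
    return METRICS[metric](a, b)
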