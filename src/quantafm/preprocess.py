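"""Denoising of AFM topographs before binarization.

Two stages, both optional and individually tunable:

1. :func:`denoise_nlm` — non-local means, flattening patchy background
   variation while preserving ridge-like filaments.
2. :func:`smooth` — mean + median + anisotropic frequency-domain low-pass.
   The low-pass attenuates *vertical* spatial frequencies only, because the
   dominant raster artifact of a scanning probe is horizontal stripe noise
   (row-to-row offsets), which lives in high vertical frequencies.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi
from scipy.stats import median_abs_deviation
from skimage.restoration import denoise_nl_means

from .afm_io import AFMImage


def estimate_background_sigma(img: AFMImage) -> float:
    """Robust noise scale: MAD of the image, normal-consistent.

    Filaments and particles cover a small area fraction, so the median
    absolute deviation is dominated by background pixels.
    """
    return float(median_abs_deviation(img.pixels, axis=None, scale="normal"))


def denoise_nlm(
    img: AFMImage,
    patch_px: int = 5,
    search_px: int = 13,
    strength: float | None = None,
) -> AFMImage:
    """Non-local means denoising.

    ``strength`` is the filtering parameter h; when None it is tied to the
    estimated background sigma (1.15 σ, the usual NLM heuristic).
    """
    if patch_px <= 0 or patch_px % 2 == 0 or search_px <= 0 or search_px % 2 == 0:
        raise ValueError("patch_px and search_px must be odd positive integers")
    if patch_px >= search_px:
        raise ValueError("patch_px must be smaller than search_px")
    if strength is None or strength == 0:
        strength = 1.15 * max(estimate_background_sigma(img), 1e-6)
    if strength <= 0:
        raise ValueError("strength must be positive")
    out = denoise_nl_means(
        img.pixels,
        patch_size=patch_px,
        patch_distance=search_px // 2,
        h=strength,
        fast_mode=True,
        preserve_range=True,
    )
    return img.with_pixels(out)


def _lowpass_vertical(pixels: np.ndarray, cutoff: float) -> np.ndarray:
    """Gaussian low-pass on vertical spatial frequency only.

    ``cutoff`` is the half-power frequency as a fraction of Nyquist.
    Horizontal frequencies pass unattenuated, so filament edges along
    the fast-scan axis stay sharp while row-stripe noise is suppressed.
    """
    n_rows = pixels.shape[0]
    fy = np.fft.fftfreq(n_rows, d=1.0)[:, None]  # cycles/px, Nyquist = 0.5
    fc = cutoff * 0.5
    gain = np.exp(-np.log(2.0) * (fy / fc) ** 2)
    spec = np.fft.fft(pixels, axis=0)
    return np.real(np.fft.ifft(spec * gain, axis=0))


def smooth(
    img: AFMImage,
    mean_px: int = 3,
    median_px: int = 3,
    lowpass_cutoff: float = 0.35,
) -> AFMImage:
    """Mean → median → anisotropic low-pass smoothing chain."""
    if mean_px <= 0 or mean_px % 2 == 0 or median_px <= 0 or median_px % 2 == 0:
        raise ValueError("kernel sizes must be odd positive integers")
    if not (0 < lowpass_cutoff <= 0.5):
        raise ValueError("lowpass_cutoff must lie in (0, 0.5]")
    out = ndi.uniform_filter(img.pixels, size=mean_px, mode="nearest")
    out = ndi.median_filter(out, size=median_px, mode="nearest")
    out = _lowpass_vertical(out, lowpass_cutoff)
    return img.with_pixels(out)


def preprocess(img: AFMImage, cfg) -> AFMImage:
    """Full denoising chain under a :class:`~quantafm.afm_io.PipelineConfig`."""
    out = img
    if cfg.enable_nlm:
        out = denoise_nlm(out, cfg.nlm_patch_px, cfg.nlm_search_px,
                          cfg.nlm_strength or None)
    if cfg.enable_smooth:
        out = smooth(out, cfg.mean_px, cfg.median_px, cfg.lowpass_cutoff)
    return out
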