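"""Two-pass Otsu segmentation with background equalization and size filtering.

A first Otsu binarization yields a rough mask.  Contaminations — bright
connected regions far larger than any DNA fragment — drag the second-pass
threshold upward, so their intensities are reset to the mean background
level first ("background equalization").  A second Otsu pass on the
equalized image then gives the refined mask, from which components outside
a physical area window are discarded.

8-connectivity is used throughout: a one-pixel-wide diagonal filament must
remain a single object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .afm_io import AFMImage

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class BinaryMask:
    pixels: np.ndarray  # 2-D bool
    nm_per_px: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)


@dataclass
class LabeledObjects:
    """Connected components surviving the area filter.

    ``labels`` uses 0 for background and consecutive integers 1..n_objects.
    """

    labels: np.ndarray
    n_objects: int
    nm_per_px: float
    areas_px: dict[int, int] = field(default_factory=dict)
    border_labels: set[int] = field(default_factory=set)

    def area_nm2(self, label: int) -> float:
        return self.areas_px[label] * self.nm_per_px**2

    def mask_of(self, label: int) -> np.ndarray:
        if label not in self.areas_px:
            raise KeyError(f"no object with label {label}")
        return self.labels == label


def otsu_threshold(img: AFMImage) -> float:
    """Otsu's optimum over the 256-bin intensity histogram.

    Returns the threshold t maximizing between-class variance, where the
    foreground class is ``intensity > t``.  Ties break toward the lower
    threshold.
    """
    pixels = img.pixels
    if np.ptp(pixels) == 0:
        raise ValueError("constant image has a degenerate histogram")
    hist, _ = np.histogram(pixels, bins=256, range=(0, 256))
    p = hist.astype(np.float64) / hist.sum()
    omega = np.cumsum(p)                # P(class0) for t = 0..255
    mu = np.cumsum(p * np.arange(256))  # first moment
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    return float(np.argmax(sigma_b))  # argmax takes the first (lowest) maximizer


def threshold_mask(img: AFMImage, threshold: float) -> BinaryMask:
    return BinaryMask(img.pixels > threshold, img.nm_per_px)


def equalize_background(
    img: AFMImage,
    mask: BinaryMask,
    max_object_area_nm2: float,
    background_level: float = 90.0,
) -> AFMImage:
    """Reset contaminated regions to the mean background intensity.

    Connected foreground components larger than ``max_object_area_nm2``
    count as contaminations; their pixels, plus any pixel above
    ``background_level`` belonging to them, are replaced by the mean of
    the background (non-mask) pixels.  Everything else is untouched.
    """
    if mask.pixels.shape != img.pixels.shape:
        raise ValueError("mask shape does not match image shape")
    labels, n = ndi.label(mask.pixels, structure=_STRUCT8)
    if n == 0:
        return img
    px_area = img.nm_per_px**2
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    big = np.flatnonzero(areas * px_area > max_object_area_nm2) + 1
    if big.size == 0:
        return img
    contaminated = np.isin(labels, big)
    # Grow contaminations into their above-background halo: any region above
    # the background level that touches a contamination is part of it.
    halo_labels, n_halo = ndi.label(img.pixels > background_level, structure=_STRUCT8)
    if n_halo:
        touched = np.unique(halo_labels[contaminated])
        touched = touched[touched > 0]
        if touched.size:
            contaminated |= np.isin(halo_labels, touched)
    background = ~mask.pixels
    bg_mean = float(img.pixels[background].mean()) if background.any() else 0.0
    out = img.pixels.copy()
    out[contaminated] = bg_mean
    return img.with_pixels(out)


def binarize_and_filter(
    img: AFMImage,
    min_area_nm2: float,
    max_area_nm2: float,
) -> LabeledObjects:
    """Second-pass Otsu binarization plus physical size filtering.

    Components with area outside [min, max] nm² are discarded; components
    touching the image border survive but are recorded in
    ``border_labels`` for downstream QC.
    """
    if not (0 < min_area_nm2 < max_area_nm2):
        raise ValueError("need 0 < min_area_nm2 < max_area_nm2")
    t = otsu_threshold(img)
    raw_labels, n = ndi.label(img.pixels > t, structure=_STRUCT8)
    px_area = img.nm_per_px**2
    out = np.zeros_like(raw_labels)
    areas: dict[int, int] = {}
    border: set[int] = set()
    next_label = 0
    if n:
        counts = np.bincount(raw_labels.ravel(), minlength=n + 1)
        edge = np.zeros_like(raw_labels, dtype=bool)
        edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
        edge_labels = set(np.unique(raw_labels[edge])) - {0}
        for lab in range(1, n + 1):
            area_nm2 = counts[lab] * px_area
            if min_area_nm2 <= area_nm2 <= max_area_nm2:
                next_label += 1
                out[raw_labels == lab] = next_label
                areas[next_label] = int(counts[lab])
                if lab in edge_labels:
                    border.add(next_label)
    return LabeledObjects(out, next_label, img.nm_per_px, areas, border)


def segment(img: AFMImage, cfg) -> LabeledObjects:
    """Full two-pass segmentation under a pipeline configuration."""
    min_a, max_a = cfg.derived_area_window_nm2()
    t0 = otsu_threshold(img)
    rough = threshold_mask(img, t0)
    equalized = equalize_background(img, rough, max_a, cfg.background_level)
    return binarize_and_filter(equalized, min_a, max_a)
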