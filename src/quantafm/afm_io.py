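"""Image loading, run configuration and per-object result tables.

AFM topographs arrive as pre-flattened grayscale rasters (TIFF or PNG).
Pixel calibration is *never* read from file metadata — vendor exports are
inconsistent — but supplied as a scalar, defaulting to a 2 μm scan imaged
at 1024 × 1024 px (1.953125 nm/px).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

DEFAULT_NM_PER_PX = 2000.0 / 1024.0  # 2 μm scan at 1024 px

#: CSV column order for per-object records.
RECORD_COLUMNS = [
    "source_id",
    "object_id",
    "object_kind",
    "total_length_nm",
    "radius_nm",
    "theta_deg",
    "short_arm_nm",
    "long_arm_nm",
    "short_arm_corr_nm",
    "long_arm_corr_nm",
    "lw_bp",
    "sa_ratio_c",
    "qc_flags",
]


@dataclass
class AFMImage:
    """A calibrated 2-D height map on the 8-bit intensity scale.

    Parameters
    ----------
    pixels
        2-D float array, values in [0, 255]; higher = taller.
    nm_per_px
        Physical size of one (square) pixel in nm.
    source_id
        Free-text provenance label (typically the file name).
    """

    pixels: np.ndarray
    nm_per_px: float = DEFAULT_NM_PER_PX
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if self.nm_per_px <= 0:
            raise ValueError("nm_per_px must be positive")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0 or hi > 255:
            raise ValueError(f"intensities outside [0, 255]: [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "AFMImage":
        """Same calibration and provenance, new pixel data."""
        return AFMImage(np.clip(pixels, 0, 255), self.nm_per_px, self.source_id)


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis pipeline.

    Lengths are nm, intensities on the 8-bit scale.  The Hough radius
    interval default spans the apparent (tip-broadened) nucleosome radius,
    roughly twice the crystallographic 5.5 nm.
    """

    nm_per_px: float = DEFAULT_NM_PER_PX
    fragment_bp: int = 464
    nm_per_bp: float = 0.34
    known_radius_nm: float = 5.5
    hough_radius_nm: tuple[float, float] = (8.5, 14.0625)
    hough_sensitivity: float = 0.93
    background_level: float = 90.0
    angle_fit_px: int = 5
    length_window_nm: tuple[float, float] = (65.0, 155.0)
    sa_ratio_min: float = 0.3
    free_dna_mean_nm: float = 158.2
    rng_seed: int = 0
    # preprocessing
    nlm_patch_px: int = 5
    nlm_search_px: int = 13
    nlm_strength: float = 0.0  # 0 → auto from background MAD
    mean_px: int = 3
    median_px: int = 3
    lowpass_cutoff: float = 0.35
    enable_nlm: bool = True
    enable_smooth: bool = True
    # segmentation area window, nm^2 (0 → derived from geometry)
    min_area_nm2: float = 0.0
    max_area_nm2: float = 0.0
    max_gap_px: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.hough_radius_nm
        if not (0 < lo < hi):
            raise ValueError("hough_radius_nm must be a non-degenerate positive interval")
        if not (0 < self.hough_sensitivity < 1):
            raise ValueError("hough_sensitivity must lie in (0, 1)")
        if not (0 <= self.sa_ratio_min <= 0.5):
            raise ValueError("sa_ratio_min must lie in [0, 0.5]")
        for name in ("nm_per_px", "nm_per_bp", "known_radius_nm", "free_dna_mean_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def derived_area_window_nm2(self) -> tuple[float, float]:
        """Area bounds for object filtering, from fragment geometry.

        Minimum: a quarter of the minimal free-DNA footprint (length-window
        lower bound × ~2 px width).  Maximum: four times the footprint of a
        nucleosome-bearing fragment.
        """
        if self.min_area_nm2 > 0 and self.max_area_nm2 > 0:
            return (self.min_area_nm2, self.max_area_nm2)
        width_nm = 2.0 * self.nm_per_px
        lo = 0.25 * self.length_window_nm[0] * width_nm
        frag_nm = self.fragment_bp * self.nm_per_bp
        disk = np.pi * self.hough_radius_nm[1] ** 2
        hi = 4.0 * (frag_nm * width_nm + disk)
        return (lo, hi)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}}
        for key in ("hough_radius_nm", "length_window_nm"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class QuantRecord:
    """Per-object derived quantities, one row of the result table."""

    source_id: str
    object_id: int
    object_kind: str  # "free_dna" | "nucleosome"
    total_length_nm: float = np.nan
    radius_nm: float = np.nan
    theta_deg: float = np.nan
    short_arm_nm: float = np.nan
    long_arm_nm: float = np.nan
    short_arm_corr_nm: float = np.nan
    long_arm_corr_nm: float = np.nan
    lw_bp: float = np.nan
    sa_ratio_c: float = np.nan
    qc_flags: tuple[str, ...] = field(default_factory=tuple)


def load_image(path: str | Path, nm_per_px: float = DEFAULT_NM_PER_PX) -> AFMImage:
    """Read a single-channel grayscale TIFF/PNG as an :class:`AFMImage`.

    Intensities are rescaled linearly to [0, 255] when the source bit
    depth differs; an already-8-bit image passes through unchanged.
    """
    path = Path(path)
    if nm_per_px <= 0:
        raise ValueError("nm_per_px must be positive")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        raise ValueError(f"expected single-channel image, got {arr.shape[-1]} channels")
    if arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim}")
    arr = arr.astype(np.float64)
    if arr.max() > 255:  # deeper than 8 bit → linear rescale so max = 255
        arr = arr * (255.0 / arr.max())
    return AFMImage(arr, nm_per_px=nm_per_px, source_id=path.name)


def write_records(records: list[QuantRecord], path: str | Path) -> None:
    """Write per-object records to CSV (header always present)."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["qc_flags"] = ";".join(r.qc_flags)
        rows.append(d)
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df.to_csv(path, index=False)


def read_records(path: str | Path) -> list[QuantRecord]:
    """Read back a CSV written by :func:`write_records`."""
    df = pd.read_csv(path, keep_default_na=True)
    records = []
    for _, row in df.iterrows():
        flags = row["qc_flags"]
        flags = tuple(str(flags).split(";")) if isinstance(flags, str) and flags else ()
        records.append(
            QuantRecord(
                source_id=str(row["source_id"]),
                object_id=int(row["object_id"]),
                object_kind=str(row["object_kind"]),
                total_length_nm=float(row["total_length_nm"]),
                radius_nm=float(row["radius_nm"]),
                theta_deg=float(row["theta_deg"]),
                short_arm_nm=float(row["short_arm_nm"]),
                long_arm_nm=float(row["long_arm_nm"]),
                short_arm_corr_nm=float(row["short_arm_corr_nm"]),
                long_arm_corr_nm=float(row["long_arm_corr_nm"]),
                lw_bp=float(row["lw_bp"]),
                sa_ratio_c=float(row["sa_ratio_c"]),
                qc_flags=flags,
            )
        )
    return records
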