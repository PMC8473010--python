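"""Lipid-domain morphometry on height images and masks.

Lo domains appear as round patches standing ~1 nm proud of the Ld
background in AFM height images (or as dark patches in dye-excluding
confocal images).  This module segments such domains, measures per-domain
area, perimeter and circularity (4π·area/perimeter², 1 for a perfect
circle), and quantifies the Lo-Ld height mismatch — the particle-analysis
workflow familiar from ImageJ, built on scikit-image.

The perimeter uses the Crofton (multi-direction intercept) estimator:
counting boundary pixels systematically overestimates the perimeter of a
rasterised smooth shape and would deflate every circularity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "HeightImage",
    "circularity",
    "segment_domains",
    "measure_domains",
    "height_mismatch",
    "shape_change_summary",
    "read_image",
]


@dataclass
class HeightImage:
    """A 2D AFM height image (nm) with physical pixel size (µm/px)."""

    heights: np.ndarray
    pixel_size: float = 1.0
    mask: np.ndarray | None = None  # optional phase mask (True = Lo)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("height image must be 2D")
        if not np.isfinite(self.heights).all():
            raise ValueError("height image contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def circularity(area: float, perimeter: float) -> float:
    """4π·area / perimeter² — 1 for a circle, < 1 otherwise."""
    return 4.0 * np.pi * area / perimeter**2


def segment_domains(
    image: np.ndarray | HeightImage,
    threshold: float | str = "otsu",
    min_area: int = 4,
    bright_domains: bool = True,
) -> np.ndarray:
    """Threshold + connected components (8-connectivity) + size filter.

    ``threshold="otsu"`` picks the threshold from the image histogram; a
    float uses that value directly.  ``bright_domains`` selects pixels
    above the threshold (AFM height: Lo is brighter); set False for
    dye-exclusion images where domains are dark.  Components smaller than
    ``min_area`` pixels are dropped.  A constant image yields zero
    domains.
    """
    img = image.heights if isinstance(image, HeightImage) else np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=int)
    thr = threshold_otsu(img) if threshold == "otsu" else float(threshold)
    binary = img > thr if bright_domains else img < thr
    labels = measure.label(binary, connectivity=2)
    if min_area > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area)
        labels[np.isin(labels, small)] = 0
    # relabel 1..K contiguously
    return measure.label(labels > 0, connectivity=2)


def measure_domains(labels: np.ndarray, pixel_size: float = 1.0) -> pd.DataFrame:
    """Per-domain area, perimeter, circularity and centroid.

    Areas are pixel counts scaled by ``pixel_size²`` (µm² when
    pixel_size is in µm/px); perimeters use the Crofton estimator.
    Circularity is clipped to 1.0 on output; a raw value above 1 (a
    discretisation artefact of very small domains) sets ``clipped``.
    Empty mask -> empty table.
    """
    labels = np.asarray(labels)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    records = []
    for rp in measure.regionprops(labels):
        area = rp.area * pixel_size**2
        perimeter = rp.perimeter_crofton * pixel_size
        if perimeter <= 0:
            continue  # degenerate single-pixel artefact
        raw = circularity(area, perimeter)
        records.append(
            {
                "label": rp.label,
                "area": area,
                "perimeter": perimeter,
                "circularity": min(raw, 1.0),
                "clipped": raw > 1.0,
                "centroid_row": rp.centroid[0],
                "centroid_col": rp.centroid[1],
                "pixel_size": pixel_size,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "label",
            "area",
            "perimeter",
            "circularity",
            "clipped",
            "centroid_row",
            "centroid_col",
            "pixel_size",
        ],
    )


def height_mismatch(
    image: HeightImage | np.ndarray,
    phase_mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Mean Lo height minus mean Ld height, in nm.

    ``phase_mask`` (True = Lo) defaults to the mask stored on the image.
    Returns ``(mismatch, sd)`` where sd is the sample SD of per-domain
    mismatches (each connected Lo domain's mean height minus the global
    Ld mean); NaN when fewer than 2 domains.
    """
    if isinstance(image, HeightImage):
        heights = image.heights
        if phase_mask is None:
            phase_mask = image.mask
    else:
        heights = np.asarray(image, dtype=float)
    if phase_mask is None:
        raise ValueError("a phase mask is required")
    mask = np.asarray(phase_mask, dtype=bool)
    if mask.shape != heights.shape:
        raise ValueError("mask shape does not match image")
    if mask.all() or not mask.any():
        raise ValueError("mask must contain both Lo and Ld pixels")
    ld_mean = heights[~mask].mean()
    mismatch = float(heights[mask].mean() - ld_mean)
    domains = measure.label(mask, connectivity=2)
    per_domain = [
        heights[domains == lab].mean() - ld_mean for lab in range(1, domains.max() + 1)
    ]
    sd = float(np.std(per_domain, ddof=1)) if len(per_domain) >= 2 else float("nan")
    return mismatch, sd


def shape_change_summary(table_before: pd.DataFrame, table_after: pd.DataFrame) -> dict:
    """Percent change in mean area, perimeter and circularity.

    ``100 * (mean_after - mean_before) / mean_before`` per metric, e.g.
    to quantify how much a treatment shrank or roughened the domains.
    """
    if len(table_before) == 0 or len(table_after) == 0:
        raise ValueError("both domain tables must be non-empty")
    out = {}
    for metric in ("area", "perimeter", "circularity"):
        before = table_before[metric].mean()
        after = table_after[metric].mean()
        if before == 0:
            raise ValueError(f"zero baseline mean for {metric}")
        out[metric] = 100.0 * (after - before) / before
    return out


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2D image from TIFF or a plain numeric text matrix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    return np.loadtxt(path, ndmin=2)
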