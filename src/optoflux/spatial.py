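"""Detection of metabolically active regions in calibrated analyte maps.

A region is "active" where the local analyte value is depressed below a
robust background estimate (median of pixels outside any supplied cell mask)
by more than a threshold -- by default k times the median absolute deviation
of the background, so that detection tracks contrast against the surrounding
well rather than absolute values, which drift between wells.  Detected
components are gated by a minimum area and labelled deterministically in
row-major first-pixel order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from skimage.measure import label as _label, regionprops

from .errors import DataError
from .imaging import AnalyteMap


@dataclass(frozen=True)
class DetectionParams:
    k_mad: float = 5.0  # depression threshold in background MADs
    abs_threshold: float | None = None  # absolute depression, overrides k*MAD
    min_area_mm2: float = 0.1

    def __post_init__(self) -> None:
        if not self.k_mad > 0:
            raise DataError("k_mad must be > 0")


@dataclass
class RegionSet:
    labels: np.ndarray  # H x W int, 0 = background
    table: pd.DataFrame  # region_id, area_mm2, mean_depression, centroid_x, centroid_y
    background: float
    threshold: float

    def __len__(self) -> int:
        return len(self.table)

    def mask(self, region_id: int | None = None) -> np.ndarray:
        return self.labels > 0 if region_id is None else self.labels == region_id


def _relabel_rowmajor(labels: np.ndarray) -> np.ndarray:
    """Renumber components by the row-major order of their first pixel."""
    flat = labels.ravel()
    seen: dict[int, int] = {}
    for v in flat[flat > 0]:
        if v not in seen:
            seen[v] = len(seen) + 1
    out = np.zeros_like(labels)
    for old, new in seen.items():
        out[labels == old] = new
    return out


def detect_active_regions(m: AnalyteMap, params: DetectionParams = DetectionParams(),
                          cell_mask: np.ndarray | None = None) -> RegionSet:
    """Segment pixels whose depression below background exceeds the threshold.

    ``cell_mask`` optionally marks pixels known to contain cells; background
    statistics are then taken outside it, otherwise globally.
    """
    valid = m.valid() & np.isfinite(m.values)
    if not valid.any():
        raise DataError("map has no valid pixels")
    bg_sel = valid if cell_mask is None else (valid & ~cell_mask)
    if not bg_sel.any():
        bg_sel = valid
    bg_pixels = m.values[bg_sel]
    background = float(np.median(bg_pixels))
    depression = background - m.values
    if params.abs_threshold is not None:
        threshold = float(params.abs_threshold)
    else:
        mad = float(np.median(np.abs(bg_pixels - background)))
        threshold = params.k_mad * mad
    detect = valid & (depression > threshold)

    px_area_mm2 = m.pixel_size_mm ** 2
    min_px = params.min_area_mm2 / px_area_mm2
    labels = _relabel_rowmajor(_label(detect, connectivity=2))
    rows = []
    keep = np.zeros_like(labels)
    next_id = 1
    for region in regionprops(labels):
        if region.area < min_px:
            continue
        comp = labels == region.label
        cy, cx = region.centroid
        rows.append({"region_id": next_id, "area_mm2": region.area * px_area_mm2,
                     "mean_depression": float(depression[comp].mean()),
                     "centroid_x": cx, "centroid_y": cy})
        keep[comp] = next_id
        next_id += 1
    table = pd.DataFrame(rows, columns=["region_id", "area_mm2", "mean_depression",
                                        "centroid_x", "centroid_y"])
    return RegionSet(labels=keep, table=table, background=background, threshold=threshold)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 0.0


def time_to_detection(maps: Sequence[AnalyteMap], truth_mask: np.ndarray,
                      params: DetectionParams = DetectionParams(),
                      iou_threshold: float = 0.3,
                      cell_mask: np.ndarray | None = None) -> float | None:
    """First timestamp (minutes) at which any detected region overlaps the
    ground-truth mask with IoU >= ``iou_threshold``; None if never."""
    for m in maps:
        regions = detect_active_regions(m, params, cell_mask=cell_mask)
        for rid in regions.table["region_id"]:
            if iou(regions.mask(int(rid)), truth_mask) >= iou_threshold:
                return m.timestamp_s / 60.0
    return None


def areal_density(cell_count: int, area_cm2: float,
                  rounding: Literal["none", "floor-to-thousand"] = "none") -> float:
    """Convert a cell count on a growth area to cells/cm^2.

    The floor-to-thousand presentation mode reports e.g. 2000 cells on
    0.03 cm^2 (66,666.7 raw) as 66,000 cells/cm^2.
    """
    if cell_count < 0:
        raise DataError("cell_count must be >= 0")
    if not area_cm2 > 0:
        raise DataError("area must be positive")
    raw = cell_count / area_cm2
    if rounding == "floor-to-thousand":
        return float(np.floor(raw / 1000.0) * 1000.0)
    return raw


def overlay_outline(m: AnalyteMap, masks: Sequence[np.ndarray],
                    colors: Sequence[tuple[int, int, int]],
                    value_range: tuple[float, float] | None = None,
                    colormap: str = "viridis",
                    path: str | Path | None = None) -> np.ndarray:
    """Colormapped analyte map with 1-px mask outlines burned in.

    Outlines are the morphological gradient (mask minus its erosion) of each
    boolean mask, drawn in the paired RGB colour.  Returns the uint8 RGB
    composite; optionally also writes it as PNG.
    """
    import matplotlib
    import matplotlib.colors as mcolors

    if len(masks) != len(colors):
        raise DataError("need one colour per mask")
    vmin, vmax = value_range if value_range is not None else \
        (np.nanmin(m.values), np.nanmax(m.values))
    norm = mcolors.Normalize(vmin=vmin, vmax=vmax, clip=True)
    rgba = matplotlib.colormaps[colormap](norm(np.nan_to_num(m.values, nan=vmin)))
    rgb = (rgba[:, :, :3] * 255).astype(np.uint8)
    for mask, color in zip(masks, colors):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != m.values.shape:
            raise DataError("outline mask shape does not match map shape")
        if mask.any():
            edge = mask & ~binary_erosion(mask)
            rgb[edge] = color
    if path is not None:
        import imageio.v3 as iio
        iio.imwrite(Path(path), rgb)
    return rgb


def regions_to_csv(regions: RegionSet, path: str | Path) -> None:
    regions.table.to_csv(path, index=False)
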