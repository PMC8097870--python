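"""From raw two-channel frame stacks to calibrated analyte maps and series.

Pipeline order is fixed: per-pixel ratio (sensitive / reference), one-point
adjustment (OPA) in ratio space, Gaussian noise filtering in ratio space,
calibration inversion, then ROI / per-well extraction.  Smoothing and OPA act
on ratios because both the camera noise and the illumination mismatch are
generated in intensity space, where the ratio is their natural carrier.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from . import calibration as _cal
from .calibration import FLAG_INVALID, FLAG_OK, O2Calibration, PhCalibration
from .errors import DataError, GeometryError
from .kinetics import TimeSeries


@dataclass
class FrameStack:
    """Time-ordered raw sensor frames, shape (T, H, W, 2), camera units."""

    frames: np.ndarray
    timestamps_s: np.ndarray
    channel_roles: dict  # {"sensitive": idx, "reference": idx}
    pixel_size_mm: float
    batch_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 2:
            raise DataError(f"frames must have shape (T, H, W, 2), got {self.frames.shape}")
        if self.timestamps_s.shape != (self.frames.shape[0],):
            raise DataError("one timestamp per frame required")
        if self.frames.shape[0] >= 2 and np.any(np.diff(self.timestamps_s) <= 0):
            raise DataError("timestamps must be strictly increasing")
        if np.any(self.frames < 0):
            raise DataError("intensities must be non-negative")
        if set(self.channel_roles) != {"sensitive", "reference"}:
            raise DataError("channel_roles must map 'sensitive' and 'reference'")
        if not self.pixel_size_mm > 0:
            raise DataError("pixel_size_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class RatioMap:
    """Per-pixel sensitive/reference ratio; NaN marks invalid pixels."""

    values: np.ndarray
    pixel_size_mm: float
    timestamp_s: float


@dataclass
class AnalyteMap:
    """Calibrated per-pixel field with flags (0 ok, 1 clamped, 2 invalid)."""

    values: np.ndarray
    analyte: str  # "O2_percent_airsat" | "pH"
    pixel_size_mm: float
    timestamp_s: float
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.flags is None:
            self.flags = np.full(self.values.shape, FLAG_OK, dtype=np.uint8)

    def valid(self) -> np.ndarray:
        return self.flags != FLAG_INVALID


@dataclass
class RoiMask:
    mask: np.ndarray
    label: str = "roi"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise DataError(f"ROI {self.label!r} is empty")


@dataclass
class PlateLayout:
    """Circular-well grid, ordered row-major A1..H12 for a 96-well plate."""

    n_rows: int
    n_cols: int
    centers_px: np.ndarray  # (n_rows*n_cols, 2) as (row, col)
    radius_px: float

    def __post_init__(self) -> None:
        self.centers_px = np.asarray(self.centers_px, dtype=float)
        if self.centers_px.shape != (self.n_rows * self.n_cols, 2):
            raise GeometryError("need one centre per well")

    @classmethod
    def regular(cls, image_shape: tuple[int, int], n_rows: int = 8, n_cols: int = 12,
                radius_fraction: float = 0.8) -> "PlateLayout":
        """Evenly pitched grid filling the image; disc radius defaults to 80%
        of half the well pitch."""
        h, w = image_shape
        pitch_r, pitch_c = h / n_rows, w / n_cols
        rows = (np.arange(n_rows) + 0.5) * pitch_r
        cols = (np.arange(n_cols) + 0.5) * pitch_c
        centers = np.array([(r, c) for r in rows for c in cols])
        radius = radius_fraction * min(pitch_r, pitch_c) / 2.0
        return cls(n_rows, n_cols, centers, radius)

    def well_names(self) -> list[str]:
        return [f"{chr(ord('A') + r)}{c + 1}"
                for r in range(self.n_rows) for c in range(self.n_cols)]

    def well_mask(self, index: int, shape: tuple[int, int]) -> np.ndarray:
        cy, cx = self.centers_px[index]
        yy, xx = np.ogrid[:shape[0], :shape[1]]
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= self.radius_px ** 2

    def check_bounds(self, shape: tuple[int, int]) -> None:
        for cy, cx in self.centers_px:
            if not (self.radius_px <= cy <= shape[0] - self.radius_px
                    and self.radius_px <= cx <= shape[1] - self.radius_px):
                raise GeometryError(f"well at ({cy:.1f}, {cx:.1f}) extends outside the image")


@dataclass
class IlluminationField:
    """Multiplicative ratio-space correction from a uniform calibration plate."""

    correction: np.ndarray  # H x W factors (pixel mode) or per-well scalars (plate mode)
    reference_value: float
    layout: PlateLayout | None = None

    @property
    def plate_mode(self) -> bool:
        return self.layout is not None


# ---------------------------------------------------------------------------
# stack I/O (multi-page TIFF + JSON sidecar; pages alternate channels)

def write_frame_stack(stack: FrameStack, directory: str | Path,
                      stem: str = "stack") -> Path:
    """Write a stack as multi-page TIFF (page order t0c0, t0c1, t1c0, ...)
    with a JSON sidecar declaring the layout.  Returns the TIFF path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tif_path = directory / f"{stem}.tif"
    pages = stack.frames.transpose(0, 3, 1, 2).reshape(-1, *stack.frames.shape[1:3])
    tifffile.imwrite(tif_path, pages.astype(np.float32))
    meta = {
        "page_layout": "time-major, channels interleaved per timepoint",
        "n_frames": stack.n_frames,
        "timestamps_s": stack.timestamps_s.tolist(),
        "channel_roles": stack.channel_roles,
        "pixel_size_mm": stack.pixel_size_mm,
        "batch_id": stack.batch_id,
    }
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=2) + "\n")
    return tif_path


def load_frame_stack(tif_path: str | Path) -> FrameStack:
    tif_path = Path(tif_path)
    meta = json.loads(tif_path.with_suffix(".json").read_text())
    pages = tifffile.imread(tif_path)
    t = meta["n_frames"]
    frames = pages.reshape(t, 2, *pages.shape[1:]).transpose(0, 2, 3, 1)
    return FrameStack(frames=frames, timestamps_s=np.array(meta["timestamps_s"]),
                      channel_roles=meta["channel_roles"],
                      pixel_size_mm=meta["pixel_size_mm"], batch_id=meta["batch_id"])


def write_analyte_maps(maps: Sequence[AnalyteMap], directory: str | Path,
                       stem: str = "maps") -> Path:
    """Persist calibrated maps as a float TIFF stack plus flag stack and a
    JSON sidecar with timestamps/analyte/pixel size."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{stem}.tif"
    tifffile.imwrite(path, np.stack([m.values for m in maps]).astype(np.float32))
    tifffile.imwrite(directory / f"{stem}_flags.tif",
                     np.stack([m.flags for m in maps]))
    meta = {"analyte": maps[0].analyte, "pixel_size_mm": maps[0].pixel_size_mm,
            "timestamps_s": [m.timestamp_s for m in maps]}
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=2) + "\n")
    return path


def load_analyte_maps(path: str | Path) -> list[AnalyteMap]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    values = tifffile.imread(path)
    flags_path = path.with_name(path.stem + "_flags.tif")
    flags = tifffile.imread(flags_path) if flags_path.exists() else None
    return [AnalyteMap(values=values[i], analyte=meta["analyte"],
                       pixel_size_mm=meta["pixel_size_mm"], timestamp_s=t,
                       flags=None if flags is None else flags[i])
            for i, t in enumerate(meta["timestamps_s"])]


# ---------------------------------------------------------------------------
# core operations

def compute_ratio(stack: FrameStack, t_index: int, eps: float | None = None) -> RatioMap:
    """Sensitive/reference ratio at one timepoint.

    Pixels whose reference intensity falls below ``eps`` (default: 1% of the
    reference channel's maximum over the stack) become NaN.
    """
    if not (0 <= t_index < stack.n_frames):
        raise DataError(f"t_index {t_index} out of range [0, {stack.n_frames})")
    ref = stack.frames[t_index, :, :, stack.channel_roles["reference"]]
    sens = stack.frames[t_index, :, :, stack.channel_roles["sensitive"]]
    if eps is None:
        peak = stack.frames[:, :, :, stack.channel_roles["reference"]].max()
        eps = 0.01 * peak if peak > 0 else 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(ref >= eps, sens / ref, np.nan)
    return RatioMap(values=values, pixel_size_mm=stack.pixel_size_mm,
                    timestamp_s=float(stack.timestamps_s[t_index]))


def smooth(m, smoothing_factor: float):
    """Gaussian noise filter with sigma = smoothing_factor pixels.

    NaN/invalid pixels are excluded by normalised convolution (the kernel is
    renormalised over valid pixels).  Factor 0 is the identity.
    """
    if smoothing_factor < 0:
        raise DataError("smoothing factor must be >= 0")
    if smoothing_factor == 0:
        return replace(m, values=m.values.copy())
    vals = m.values
    valid = np.isfinite(vals)
    if isinstance(m, AnalyteMap):
        valid &= m.valid()
    v = np.where(valid, vals, 0.0)
    w = valid.astype(float)
    vb = gaussian_filter(v, sigma=smoothing_factor, mode="nearest")
    wb = gaussian_filter(w, sigma=smoothing_factor, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(wb > 0, vb / wb, np.nan)
    out[~valid] = np.nan if not isinstance(m, AnalyteMap) else vals[~valid]
    return replace(m, values=out)


def apply_calibration(rmap: RatioMap, cal, batch_id: str | None = None) -> AnalyteMap:
    """Invert a ratio map through a fitted calibration.

    Emits a warning when the calibration's batch does not match the stack's.
    """
    if batch_id is not None and cal.batch_id and batch_id != cal.batch_id:
        warnings.warn(f"calibration batch {cal.batch_id!r} does not match "
                      f"stack batch {batch_id!r}", stacklevel=2)
    values, flags = _cal.invert_ratio(rmap.values, cal)
    analyte = "O2_percent_airsat" if isinstance(cal, O2Calibration) else "pH"
    return AnalyteMap(values=values, analyte=analyte, pixel_size_mm=rmap.pixel_size_mm,
                      timestamp_s=rmap.timestamp_s, flags=flags)


def fit_illumination(uniform_map: RatioMap, expected_value: float,
                     layout: PlateLayout | None = None) -> IlluminationField:
    """One-point adjustment (OPA) field from a spatially uniform plate.

    Pixel mode: per-pixel factor expected/observed in ratio space.  Plate
    mode: one scalar per well from the well-mean ratio.  The caller is
    responsible for the plate truly being at one analyte value everywhere.
    """
    obs = uniform_map.values
    if layout is None:
        if np.any(obs[np.isfinite(obs)] <= 0):
            raise DataError("observed ratios must be positive for OPA fitting")
        corr = expected_value / obs
    else:
        layout.check_bounds(obs.shape)
        corr = np.empty(layout.n_rows * layout.n_cols)
        for i in range(corr.size):
            wm = obs[layout.well_mask(i, obs.shape)]
            mean = np.nanmean(wm)
            if not mean > 0:
                raise DataError(f"well {layout.well_names()[i]} has non-positive mean ratio")
            corr[i] = expected_value / mean
    med = float(np.nanmedian(corr))
    if not 0.5 <= med <= 2.0:
        warnings.warn(f"median OPA factor {med:.3g} outside the [0.5, 2] sanity band",
                      stacklevel=2)
    return IlluminationField(correction=corr, reference_value=expected_value, layout=layout)


def apply_opa(m: RatioMap, field: IlluminationField) -> RatioMap:
    """Multiplicative OPA correction in ratio space (before calibration)."""
    if field.plate_mode:
        out = m.values.copy()
        for i in range(field.correction.size):
            wm = field.layout.well_mask(i, m.values.shape)
            out[wm] = m.values[wm] * field.correction[i]
    else:
        if field.correction.shape != m.values.shape:
            raise DataError(f"OPA field shape {field.correction.shape} does not match "
                            f"map shape {m.values.shape}")
        out = m.values * field.correction
    return replace(m, values=out)


def extract_roi_timeseries(maps: Sequence[AnalyteMap], roi: RoiMask,
                           min_valid_fraction: float = 0.5) -> TimeSeries:
    """ROI-mean trajectory over a sequence of calibrated maps.

    Invalid pixels are excluded from the mean; a timepoint whose valid
    fraction inside the ROI falls below ``min_valid_fraction`` is flagged as
    a gap rather than silently dropped.
    """
    if not maps:
        raise DataError("no maps supplied")
    n_roi = int(roi.mask.sum())
    times, values, gaps, n_valid = [], [], [], []
    for m in maps:
        if m.values.shape != roi.mask.shape:
            raise DataError("ROI mask shape does not match map shape")
        ok = roi.mask & m.valid() & np.isfinite(m.values)
        k = int(ok.sum())
        times.append(m.timestamp_s)
        n_valid.append(k)
        if k < min_valid_fraction * n_roi or k == 0:
            values.append(np.nan)
            gaps.append(True)
        else:
            values.append(float(m.values[ok].mean()))
            gaps.append(False)
    return TimeSeries(analyte=maps[0].analyte, times_s=np.array(times),
                      values=np.array(values), gaps=np.array(gaps),
                      n_valid=np.array(n_valid))


def extract_wells(m: AnalyteMap, layout: PlateLayout) -> pd.DataFrame:
    """NaN-aware per-well mean values, ordered row-major A1..H12.

    Returns a DataFrame with columns well, time_s, value, n_valid; a fully
    invalid well yields NaN with n_valid 0.
    """
    layout.check_bounds(m.values.shape)
    rows = []
    for i, name in enumerate(layout.well_names()):
        wm = layout.well_mask(i, m.values.shape)
        ok = wm & m.valid() & np.isfinite(m.values)
        k = int(ok.sum())
        val = float(m.values[ok].mean()) if k else np.nan
        rows.append({"well": name, "time_s": m.timestamp_s, "value": val, "n_valid": k})
    return pd.DataFrame(rows)


def render_heatmap(m: AnalyteMap, path: str | Path, value_range: tuple[float, float],
                   colormap: str = "viridis", outline_mask: np.ndarray | None = None,
                   outline_color: str = "white") -> Path:
    """Write a PNG heat map with a colour bar and fixed value->colour mapping.

    Output bytes are deterministic for fixed input and settings.  An optional
    boolean mask is drawn as a contrasting outline (see also
    ``spatial.overlay_outline`` for pixel-level composites).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4), dpi=100)
    im = ax.imshow(m.values, cmap=colormap, vmin=value_range[0], vmax=value_range[1],
                   interpolation="nearest", origin="upper")
    fig.colorbar(im, ax=ax, label=m.analyte)
    if outline_mask is not None:
        if outline_mask.shape != m.values.shape:
            raise DataError("outline mask shape does not match map shape")
        from skimage.segmentation import find_boundaries
        edge = find_boundaries(outline_mask, mode="inner")
        overlay = np.zeros((*edge.shape, 4))
        import matplotlib.colors as mcolors
        overlay[edge] = mcolors.to_rgba(outline_color)
        ax.imshow(overlay, interpolation="nearest", origin="upper")
    ax.set_title(f"t = {m.timestamp_s:.0f} s")
    ax.set_xticks([]), ax.set_yticks([])
    path = Path(path)
    fig.savefig(path, metadata={"Software": None})
    plt.close(fig)
    return path
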