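"""Synthetic micro-respirator: ground-truth physics and frame rendering.

The simulator provides known-answer inputs for every downstream stage.  Its
physical model is a single effective 2-D medium layer trapped between the
cell lawn and the sensor foil: each analyte field F (pO2 in % air saturation,
or pH) obeys

    dF/dt = D_eff * laplacian(F) - k * rho(x) * (reference_height / height),

with zero-flux (Neumann) boundaries, where rho is the areal cell density
(cells/cm^2) and k the per-density consumption/acidification coefficient of
the local cell type.  Chamber height enters only through the ratio
reference_height/height: lowering the sensor plunger onto the cells thins
the layer and accelerates apparent depletion, which is the micro-respirator
rationale.  pH is treated as a directly diffusing deviation field with
buffering folded into k_ph; O2 is clipped at 0.

Optics: the reference channel is a flat exposure-scaled level G0, the
sensitive channel is ratio_model(F) * M(x) times that level, where M is a
per-pixel illumination-mismatch field (what the one-point adjustment later
corrects).  Noise is a shot-like multiplicative Gaussian term with
SD proportional to sqrt(intensity) plus additive Gaussian read noise.

Default coefficients emulate the study conditions this pipeline targets:
a tumour-cell lawn at 66,000 cells/cm^2 (the detection-limit density of
roughly 2000 cells on 0.03 cm^2) depletes O2 at about 4%/min and acidifies
at about 0.016 pH/min, so that active patches become visible within a few
minutes and a 30-60 min acquisition spans the usable linear range.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator
from skimage.draw import disk as _disk, polygon as _polygon

from .errors import ConfigurationError, DataError, GeometryError, SamplingError
from .imaging import AnalyteMap, FrameStack

REF_LEVEL = 1000.0  # reference-channel intensity at exposure_scale 1, camera units
MAX_SUBSTEPS = 100_000
CM2_PER_MM2 = 0.01


class CellType(BaseModel):
    """Per-type areal density and metabolic coefficients.

    ``k_o2``: (% air-sat/s) per (cells/cm^2) at the reference chamber height.
    ``k_ph``: (pH/s) per (cells/cm^2).
    """
    model_config = ConfigDict(extra="forbid")

    density: float = Field(ge=0)
    k_o2: float = Field(default=0.0, ge=0)
    k_ph: float = Field(default=0.0, ge=0)
    nucleus_radius_px: float = Field(default=4.0, gt=0)


class Chamber(BaseModel):
    model_config = ConfigDict(extra="forbid")

    height_mm: float = Field(default=0.1, gt=0)
    reference_height_mm: float = Field(default=0.1, gt=0)
    D_eff_mm2_per_s: float = Field(default=1e-3, ge=0)


class Patch(BaseModel):
    """A region of one cell type: axis-aligned rectangle (half-open pixel
    bounds r0,c0,r1,c1), disc (cy,cx,radius_px) or polygon (row,col vertices).
    """
    model_config = ConfigDict(extra="forbid")

    shape: Literal["rect", "disc", "polygon"]
    params: list
    cell_type: str


class SceneSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    grid_shape: tuple[int, int]
    pixel_size_mm: float = Field(default=0.1, gt=0)
    patches: list[Patch] = []
    cell_types: dict[str, CellType] = {}
    chamber: Chamber = Chamber()
    initial_o2_pct: float = 100.0
    initial_ph: float = 7.4

    @field_validator("grid_shape")
    @classmethod
    def _positive_grid(cls, v):
        if v[0] < 1 or v[1] < 1:
            raise ValueError("grid_shape must be positive")
        return v

    @property
    def pixel_area_cm2(self) -> float:
        return self.pixel_size_mm ** 2 * CM2_PER_MM2


class AcquisitionSpec(BaseModel):
    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    interval_s: float = Field(default=20.0, gt=0)
    duration_s: float = Field(default=3600.0, gt=0)
    exposure_scale: float = Field(default=1.0, gt=0)
    illumination_mismatch: Optional[np.ndarray] = None  # ratio bias field M(x), median ~1
    read_noise_sd: float = Field(default=5.0, ge=0)  # camera units
    shot_noise: bool = True
    seed: int = 0

    @field_validator("illumination_mismatch", mode="before")
    @classmethod
    def _as_array(cls, v):
        if v is None:
            return None
        arr = np.asarray(v, dtype=float)
        if np.any(arr <= 0):
            raise ValueError("illumination mismatch must be strictly positive")
        return arr

    @field_validator("duration_s")
    @classmethod
    def _duration_ok(cls, v, info):
        if "interval_s" in info.data and v < info.data["interval_s"]:
            raise ValueError("duration_s must be >= interval_s")
        return v


def patch_mask(spec: SceneSpec, patch: Patch) -> np.ndarray:
    """Boolean pixel mask of one patch; raises GeometryError outside grid."""
    h, w = spec.grid_shape
    mask = np.zeros((h, w), dtype=bool)
    if patch.shape == "rect":
        r0, c0, r1, c1 = (int(v) for v in patch.params)
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise GeometryError(f"rect {patch.params} outside grid {spec.grid_shape}")
        mask[r0:r1, c0:c1] = True
    elif patch.shape == "disc":
        cy, cx, rad = patch.params
        if cy - rad < 0 or cx - rad < 0 or cy + rad > h or cx + rad > w:
            raise GeometryError(f"disc {patch.params} outside grid {spec.grid_shape}")
        rr, cc = _disk((cy, cx), rad, shape=(h, w))
        mask[rr, cc] = True
    else:
        pts = np.asarray(patch.params, dtype=float)
        if pts.min() < 0 or pts[:, 0].max() > h or pts[:, 1].max() > w:
            raise GeometryError("polygon vertices outside grid")
        rr, cc = _polygon(pts[:, 0], pts[:, 1], shape=(h, w))
        mask[rr, cc] = True
    return mask


def build_density_map(spec: SceneSpec) -> np.ndarray:
    """Areal cell density (cells/cm^2) on the simulation grid.

    Piecewise constant: each patch carries its cell type's density; zero
    elsewhere.  Overlapping patches are a geometry error.
    """
    density = np.zeros(spec.grid_shape)
    occupied = np.zeros(spec.grid_shape, dtype=bool)
    for patch in spec.patches:
        if patch.cell_type not in spec.cell_types:
            raise GeometryError(f"unknown cell type {patch.cell_type!r}")
        mask = patch_mask(spec, patch)
        if (occupied & mask).any():
            raise GeometryError(f"patch {patch.cell_type!r} overlaps an earlier patch")
        occupied |= mask
        density[mask] = spec.cell_types[patch.cell_type].density
    return density


def _coefficient_map(spec: SceneSpec, analyte: str) -> np.ndarray:
    """k * rho per pixel (analyte units per second at reference height)."""
    attr = "k_o2" if analyte == "O2" else "k_ph"
    out = np.zeros(spec.grid_shape)
    occupied = np.zeros(spec.grid_shape, dtype=bool)
    for patch in spec.patches:
        mask = patch_mask(spec, patch)
        if (occupied & mask).any():
            raise GeometryError(f"patch {patch.cell_type!r} overlaps an earlier patch")
        occupied |= mask
        ct = spec.cell_types[patch.cell_type]
        out[mask] = getattr(ct, attr) * ct.density
    return out


def _laplacian(f: np.ndarray, dx: float) -> np.ndarray:
    """5-point Laplacian with zero-flux (mirrored-edge) boundaries."""
    p = np.pad(f, 1, mode="edge")
    return (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * f) / (dx * dx)


def simulate_fields(spec: SceneSpec, acq: AcquisitionSpec,
                    analyte: Literal["O2", "pH"] = "O2") -> list[AnalyteMap]:
    """Integrate the reaction-diffusion field, one map per acquisition time.

    Forward Euler with automatic sub-stepping to meet the explicit stability
    bound dt <= dx^2 / (4 D_eff); a configuration error is raised if the
    required sub-step count exceeds the bound.
    """
    if analyte not in ("O2", "pH"):
        raise DataError(f"analyte must be 'O2' or 'pH', got {analyte!r}")
    dx = spec.pixel_size_mm
    d_eff = spec.chamber.D_eff_mm2_per_s
    height_factor = spec.chamber.reference_height_mm / spec.chamber.height_mm
    sink = _coefficient_map(spec, analyte) * height_factor  # units/s

    n_frames = int(math.floor(acq.duration_s / acq.interval_s)) + 1
    if d_eff > 0:
        dt_max = 0.25 * dx * dx / d_eff
        n_sub = max(1, int(math.ceil(acq.interval_s / dt_max)))
    else:
        n_sub = 1
    if n_sub > MAX_SUBSTEPS:
        raise ConfigurationError(
            f"stability requires {n_sub} sub-steps per interval (> {MAX_SUBSTEPS}); "
            "coarsen the grid or lower D_eff")
    dt = acq.interval_s / n_sub

    f0 = spec.initial_o2_pct if analyte == "O2" else spec.initial_ph
    f = np.full(spec.grid_shape, float(f0))
    label = "O2_percent_airsat" if analyte == "O2" else "pH"
    maps = [AnalyteMap(values=f.copy(), analyte=label,
                       pixel_size_mm=dx, timestamp_s=0.0)]
    for n in range(1, n_frames):
        for _ in range(n_sub):
            if d_eff > 0:
                f = f + dt * (d_eff * _laplacian(f, dx) - sink)
            else:
                f = f - dt * sink
            if analyte == "O2":
                np.maximum(f, 0.0, out=f)
        maps.append(AnalyteMap(values=f.copy(), analyte=label,
                               pixel_size_mm=dx, timestamp_s=n * acq.interval_s))
    return maps


def render_frames(maps: list[AnalyteMap], cal, acq: AcquisitionSpec) -> FrameStack:
    """Forward optical model: analyte maps -> 2-channel raw frame stack.

    reference = exposure_scale * G0 * (1 + noise)
    sensitive = ratio_model(F) * M(x) * exposure_scale * G0 * (1 + noise)

    Identical (maps, cal, acq) including the seed give a bit-identical stack.
    """
    from .calibration import O2Calibration, PhCalibration

    if not maps:
        raise DataError("no maps to render")
    shape = maps[0].values.shape
    m_field = acq.illumination_mismatch
    if m_field is None:
        m_field = np.ones(shape)
    elif m_field.shape != shape:
        raise DataError("illumination mismatch shape does not match the grid")

    if isinstance(cal, O2Calibration):
        for am in maps:
            if np.any(am.values < 0):
                raise DataError("O2 maps must be >= 0 for rendering")
    elif isinstance(cal, PhCalibration):
        lo, hi = cal.ph_range
        for am in maps:
            if np.any(am.values < lo) or np.any(am.values > hi):
                raise DataError(f"pH maps must lie within the calibrated range {cal.ph_range}")

    rng = np.random.default_rng([acq.seed, 0])
    level = acq.exposure_scale * REF_LEVEL
    frames = np.empty((len(maps), *shape, 2))
    for i, am in enumerate(maps):
        sens = cal.ratio(am.values) * m_field * level
        ref = np.full(shape, level)
        for j, chan in enumerate((sens, ref)):
            out = chan.copy()
            if acq.shot_noise:
                out = out + np.sqrt(np.maximum(out, 0.0)) * rng.standard_normal(shape)
            if acq.read_noise_sd > 0:
                out = out + acq.read_noise_sd * rng.standard_normal(shape)
            frames[i, :, :, j] = np.maximum(out, 0.0)
    timestamps = np.array([am.timestamp_s for am in maps])
    return FrameStack(frames=frames, timestamps_s=timestamps,
                      channel_roles={"sensitive": 0, "reference": 1},
                      pixel_size_mm=maps[0].pixel_size_mm, batch_id=cal.batch_id)


# ---------------------------------------------------------------------------
# nuclei rendering

def sample_positions(mask: np.ndarray, n: int, rng: np.random.Generator,
                     min_separation_px: float | None = None,
                     max_tries_per_point: int = 200) -> np.ndarray:
    """Uniform (row, col) positions within a mask, with optional rejection
    sampling to enforce a minimum pairwise separation."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0 and n > 0:
        raise SamplingError("cannot place nuclei in an empty mask")
    placed: list[tuple[float, float]] = []
    tries = 0
    limit = max(1, n) * max_tries_per_point
    while len(placed) < n:
        if tries >= limit:
            raise SamplingError(
                f"placed {len(placed)}/{n} nuclei after {tries} tries; "
                "minimum separation infeasible for this density")
        tries += 1
        k = rng.integers(rows.size)
        p = (rows[k] + rng.random(), cols[k] + rng.random())
        if min_separation_px is not None and placed:
            d2 = min((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 for q in placed)
            if d2 < min_separation_px ** 2:
                continue
        placed.append(p)
    return np.array(placed).reshape(n, 2)


def render_spot_image(shape: tuple[int, int], centroids_rc: np.ndarray,
                      radius_px: float, amplitude: float = 20000.0,
                      background: float = 200.0, read_noise_sd: float = 5.0,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Sum of Gaussian spots (sigma = radius/2) + background + read noise,
    quantised to a 16-bit grayscale image."""
    img = np.full(shape, float(background))
    sigma = radius_px / 2.0
    half = int(math.ceil(4 * sigma))
    for r, c in np.atleast_2d(centroids_rc) if len(centroids_rc) else []:
        r0, r1 = max(0, int(r) - half), min(shape[0], int(r) + half + 1)
        c0, c1 = max(0, int(c) - half), min(shape[1], int(c) + half + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * sigma * sigma))
    if read_noise_sd > 0 and rng is not None:
        img = img + read_noise_sd * rng.standard_normal(shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def render_nuclei_image(spec: SceneSpec, acq: AcquisitionSpec,
                        min_separation_px: float | None = None,
                        amplitude: float = 20000.0, background: float = 200.0,
                        scale: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Hoechst-like 16-bit nuclei image plus ground-truth centroids.

    The expected nucleus count per patch is density x patch area; positions
    are sampled uniformly within each patch.  ``scale`` is the magnification
    of the fluorescence microscope relative to the sensor grid (nuclei-image
    pixels per sensor pixel); nucleus radii and the minimum separation are
    in nuclei-image pixels.  Returns (image, centroids) with centroids as an
    (n, 2) array of (x_px, y_px) = (col, row) in nuclei-image pixels.
    """
    rng = np.random.default_rng([acq.seed, 1])
    shape = (int(round(spec.grid_shape[0] * scale)), int(round(spec.grid_shape[1] * scale)))
    all_rc = []
    for patch in spec.patches:
        ct = spec.cell_types[patch.cell_type]
        mask = patch_mask(spec, patch)
        n = int(round(ct.density * mask.sum() * spec.pixel_area_cm2))
        if n:
            sep = None if min_separation_px is None else min_separation_px / scale
            rc = sample_positions(mask, n, rng, sep) * scale
            all_rc.append((rc, ct.nucleus_radius_px))
    img = np.full(shape, float(background))
    for rc, radius in all_rc:
        img += render_spot_image(shape, rc, radius, amplitude, 0.0, 0.0).astype(float)
    if acq.read_noise_sd > 0:
        img = img + acq.read_noise_sd * rng.standard_normal(shape)
    image = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    if all_rc:
        rc = np.vstack([p for p, _ in all_rc])
        centroids = rc[:, ::-1]  # (x, y)
    else:
        centroids = np.empty((0, 2))
    return image, centroids


# ---------------------------------------------------------------------------
# ground truth / config I/O

def write_ground_truth(directory: str | Path, density: np.ndarray,
                       centroids_xy: np.ndarray, nuclei_image: np.ndarray | None = None
                       ) -> None:
    """Persist the simulator's truth: density raster (TIFF), centroid CSV and
    optionally the rendered nuclei image (16-bit TIFF)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "density_truth.tif", density.astype(np.float32))
    pd.DataFrame({"x_px": centroids_xy[:, 0], "y_px": centroids_xy[:, 1]}
                 ).to_csv(directory / "nuclei_truth.csv", index=False)
    if nuclei_image is not None:
        tifffile.imwrite(directory / "nuclei.tif", nuclei_image)


def scene_from_yaml(path: str | Path) -> SceneSpec:
    """Schema-validated scene config (unknown keys rejected)."""
    return SceneSpec.model_validate(yaml.safe_load(Path(path).read_text()))


def acquisition_from_yaml(path: str | Path) -> AcquisitionSpec:
    return AcquisitionSpec.model_validate(yaml.safe_load(Path(path).read_text()))


def default_scene(grid: tuple[int, int] = (64, 64), pixel_size_mm: float = 0.1,
                  density: float = 66_000.0) -> SceneSpec:
    """A single tumour-cell square patch at the detection-limit density on a
    quiescent background; the workhorse test scene."""
    h, w = grid
    return SceneSpec(
        grid_shape=grid, pixel_size_mm=pixel_size_mm,
        patches=[Patch(shape="rect", params=[h // 4, w // 4, 3 * h // 4, 3 * w // 4],
                       cell_type="tumour")],
        cell_types={"tumour": CellType(density=density, k_o2=1e-6, k_ph=4e-9)},
        chamber=Chamber(height_mm=0.1, reference_height_mm=0.1, D_eff_mm2_per_s=1e-3),
    )
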