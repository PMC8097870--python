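"""Orchestration: one validated config drives the full stage chain.

Stage order is fixed: simulate (optional) -> ratio -> OPA -> smooth ->
calibrate -> ROI/wells -> kinetics -> spatial -> stats.  Every product is
listed in a manifest with its SHA-256 checksum; re-running an identical
config with the same seed reproduces the manifest bit for bit.  All
randomness derives from the single global seed through named per-stage
substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import imaging, kinetics, nuclei, simulate, spatial, stats
from .calibration import O2Calibration, PhCalibration, save_calibration
from .errors import ConfigurationError
from .imaging import RoiMask

log = logging.getLogger("optoflux")


class O2CalibrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    R0: float = 1.6
    Ksv: float = 0.03
    batch_id: str = "synthetic-batch"


class PhCalibrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    R_acid: float = 0.5
    R_base: float = 2.0
    pKa: float = 7.0
    s: float = 1.0
    batch_id: str = "synthetic-batch"


class KineticsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    r2_threshold: float = 0.99
    min_fraction: float = 0.3
    min_points: int = 10


class DetectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_mad: float = 5.0
    min_area_mm2: float = 0.1


class NucleiConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_area_px: int = 10
    max_area_px: int = 400
    declump: str = "none"
    scale: float = 8.0  # nuclei-image pixels per sensor pixel (microscope magnification)


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected."""
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    analyte: str = "O2"  # "O2" | "pH"
    scene: simulate.SceneSpec
    acquisition: simulate.AcquisitionSpec = simulate.AcquisitionSpec()
    o2_calibration: O2CalibrationConfig = O2CalibrationConfig()
    ph_calibration: PhCalibrationConfig = PhCalibrationConfig()
    smoothing_factor: float = 2.0
    apply_opa: bool = False
    kinetics: KineticsConfig = KineticsConfig()
    detection: DetectionConfig = DetectionConfig()
    nuclei: NucleiConfig = NucleiConfig()
    stats_input_csv: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            return cls.model_validate(yaml.safe_load(Path(path).read_text()))
        except ValidationError as exc:
            raise ConfigurationError(str(exc)) from exc

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()

    def calibration(self):
        if self.analyte == "O2":
            c = self.o2_calibration
            return O2Calibration(R0=c.R0, Ksv=c.Ksv, batch_id=c.batch_id)
        c = self.ph_calibration
        return PhCalibration(R_acid=c.R_acid, R_base=c.R_base, pKa=c.pKa, s=c.s,
                             batch_id=c.batch_id)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full chain on a synthetic scene; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    cal = config.calibration()
    acq = config.acquisition.model_copy(update={"seed": config.seed})
    analyte = config.analyte

    def stage(name):
        log.info("stage=%s elapsed=%.1fs", name, time.time() - t_start)

    # --- simulate + render ------------------------------------------------
    stage("simulate")
    truth_maps = simulate.simulate_fields(config.scene, acq, analyte)
    stack = simulate.render_frames(truth_maps, cal, acq)
    imaging.write_frame_stack(stack, outdir, stem="stack")
    density = simulate.build_density_map(config.scene)
    nuc_img, nuc_truth = simulate.render_nuclei_image(config.scene, acq,
                                                      scale=config.nuclei.scale)
    simulate.write_ground_truth(outdir / "truth", density, nuc_truth, nuc_img)
    save_calibration(cal, outdir / "calibration.json")

    # --- ratio -> OPA -> smooth -> calibrate ------------------------------
    stage("convert")
    opa_field = None
    if config.apply_opa and acq.illumination_mismatch is not None:
        # uniform plate at the initial analyte value, same optics, held-out seed
        flat_scene = config.scene.model_copy(update={"patches": []})
        flat_maps = simulate.simulate_fields(flat_scene, acq.model_copy(
            update={"duration_s": acq.interval_s, "seed": config.seed + 1}), analyte)
        flat_stack = simulate.render_frames(flat_maps[:1], cal, acq.model_copy(
            update={"seed": config.seed + 1}))
        flat_ratio = imaging.compute_ratio(flat_stack, 0)
        expected = float(cal.ratio(
            config.scene.initial_o2_pct if analyte == "O2" else config.scene.initial_ph))
        opa_field = imaging.fit_illumination(flat_ratio, expected)

    maps = []
    for t in range(stack.n_frames):
        rmap = imaging.compute_ratio(stack, t)
        if opa_field is not None:
            rmap = imaging.apply_opa(rmap, opa_field)
        rmap = imaging.smooth(rmap, config.smoothing_factor)
        maps.append(imaging.apply_calibration(rmap, cal, batch_id=stack.batch_id))
    imaging.write_analyte_maps(maps, outdir, stem="maps")

    # --- nuclei counts per patch ------------------------------------------
    stage("nuclei")
    params = nuclei.NucleiParams(min_area_px=config.nuclei.min_area_px,
                                 max_area_px=config.nuclei.max_area_px,
                                 declump=config.nuclei.declump,
                                 exclude_border=False)
    count_res = nuclei.count_nuclei(nuc_img, params)
    nuclei.counts_to_csv({"full": count_res}, outdir / "nuclei_counts.csv",
                         outdir / "nuclei_centroids.csv")

    # --- ROI series + kinetics --------------------------------------------
    stage("kinetics")
    series: dict[str, kinetics.TimeSeries] = {}
    rates: dict[str, kinetics.RateResult] = {}
    kind = "OCR" if analyte == "O2" else "ECAR"
    for idx, patch in enumerate(config.scene.patches):
        mask = simulate.patch_mask(config.scene, patch)
        label = f"{patch.cell_type}_{idx}"
        ts = imaging.extract_roi_timeseries(maps, RoiMask(mask, label))
        ts.to_csv(outdir / f"series_{label}.csv")
        series[label] = ts
        if count_res.count:
            # centroids are in nuclei-image pixels; map back to the sensor grid
            sensor_rc = count_res.centroids[:, ::-1] / config.nuclei.scale
            rows = sensor_rc[:, 0].astype(int).clip(0, mask.shape[0] - 1)
            cols = sensor_rc[:, 1].astype(int).clip(0, mask.shape[1] - 1)
            cells = int(mask[rows, cols].sum())
        else:
            cells = 0
        if cells > 0:
            rates[label] = kinetics.estimate_rate(
                ts, cells, kind, config.kinetics.r2_threshold,
                config.kinetics.min_fraction, config.kinetics.min_points)
    if rates:
        kinetics.rates_to_csv(rates, series, outdir / "rates.csv")

    # --- spatial detection + heat map --------------------------------------
    stage("spatial")
    last = maps[-1]
    regions = spatial.detect_active_regions(
        last, spatial.DetectionParams(k_mad=config.detection.k_mad,
                                      min_area_mm2=config.detection.min_area_mm2))
    spatial.regions_to_csv(regions, outdir / "regions.csv")
    vr = (0.0, config.scene.initial_o2_pct) if analyte == "O2" else \
        (config.scene.initial_ph - 1.0, config.scene.initial_ph)
    imaging.render_heatmap(last, outdir / "heatmap.png", value_range=vr,
                           outline_mask=regions.mask())

    # --- stats --------------------------------------------------------------
    if config.stats_input_csv:
        stage("stats")
        result = stats.compare_groups(stats.GroupData.from_csv(config.stats_input_csv))
        stats.write_report(result, outdir / "comparisons.csv", outdir / "comparisons.txt")

    # --- manifest -----------------------------------------------------------
    stage("manifest")
    products = sorted(p for p in outdir.rglob("*") if p.is_file()
                      and p.name != "manifest.json")
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "products": {str(p.relative_to(outdir)): _sha256(p) for p in products},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path
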