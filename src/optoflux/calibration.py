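"""Ratio <-> analyte response models for O2 and pH sensor foils.

The oxygen foil follows Stern-Volmer collisional quenching,

    R(C) = R0 / (1 + Ksv * C),

with ``C`` the dissolved oxygen in % air saturation, ``R0`` the two-channel
intensity ratio of the fully deoxygenated foil and ``Ksv`` the quenching
constant per % air saturation.  The pH foil follows a four-parameter
log-sigmoid in pH,

    R(pH) = R_acid + (R_base - R_acid) / (1 + 10**(s * (pKa - pH))),

which is the standard single-pKa optode response.  Each physical batch of
sensor foils gets its own calibration object; fitted calibrations serialise
to small JSON sidecar files keyed by batch id.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import CalibrationError, DataError

# per-pixel flag codes, shared with the imaging stage
FLAG_OK = 0
FLAG_CLAMPED = 1
FLAG_INVALID = 2


@dataclass(frozen=True)
class CalibrationTable:
    """Measured (analyte value, mean ratio[, ratio SD]) calibration points."""

    analyte: np.ndarray
    ratio: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.analyte, dtype=float)
        r = np.asarray(self.ratio, dtype=float)
        if a.ndim != 1 or a.shape != r.shape:
            raise DataError("analyte and ratio must be 1-D arrays of equal length")
        if len(np.unique(a)) != a.size:
            raise DataError("analyte values must be distinct")
        if np.any(r <= 0) or not np.all(np.isfinite(r)):
            raise DataError("ratios must be positive and finite")
        object.__setattr__(self, "analyte", a)
        object.__setattr__(self, "ratio", r)
        if self.sd is not None:
            object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))

    @classmethod
    def from_points(cls, points: Sequence[tuple]) -> "CalibrationTable":
        arr = [(p[0], p[1]) for p in points]
        a, r = zip(*arr)
        sd = [p[2] for p in points if len(p) > 2]
        return cls(np.array(a), np.array(r), np.array(sd) if len(sd) == len(arr) else None)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationTable":
        df = pd.read_csv(path, float_precision="round_trip")
        sd = df["sd"].to_numpy() if "sd" in df.columns else None
        return cls(df["analyte"].to_numpy(), df["ratio"].to_numpy(), sd)

    def to_csv(self, path: str | Path) -> None:
        cols = {"analyte": self.analyte, "ratio": self.ratio}
        if self.sd is not None:
            cols["sd"] = self.sd
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass(frozen=True)
class O2Calibration:
    """Stern-Volmer response of one O2 sensor-foil batch."""

    R0: float
    Ksv: float
    batch_id: str = ""
    residual: float = 0.0

    def __post_init__(self) -> None:
        if not (self.R0 > 0 and self.Ksv > 0):
            raise CalibrationError(f"require R0 > 0 and Ksv > 0, got R0={self.R0}, Ksv={self.Ksv}")

    def ratio(self, po2):
        """Forward model: expected ratio at ``po2`` (% air saturation)."""
        return self.R0 / (1.0 + self.Ksv * np.asarray(po2, dtype=float))


@dataclass(frozen=True)
class PhCalibration:
    """Four-parameter log-sigmoid response of one pH sensor-foil batch.

    ``ph_range`` is the calibrated pH interval (the buffer series end points);
    out-of-range ratios clamp to these end points.
    """

    R_acid: float
    R_base: float
    pKa: float
    s: float
    ph_range: tuple[float, float] = (5.0, 8.5)
    batch_id: str = ""
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.R_acid == self.R_base:
            raise CalibrationError("degenerate pH calibration: R_acid == R_base")
        if not self.s > 0:
            raise CalibrationError(f"slope factor must be > 0, got s={self.s}")

    def ratio(self, ph):
        """Forward model: expected ratio at ``ph``."""
        ph = np.asarray(ph, dtype=float)
        return self.R_acid + (self.R_base - self.R_acid) / (1.0 + 10.0 ** (self.s * (self.pKa - ph)))


def fit_o2_calibration(table: CalibrationTable, batch_id: str = "") -> O2Calibration:
    """Fit the Stern-Volmer model.

    Two points use the exact closed form; more points use least squares on
    1/R, which is linear in the analyte value.
    """
    c, r = table.analyte, table.ratio
    if c.size < 2:
        raise DataError("O2 calibration needs at least 2 points")
    if c.size == 2:
        order = np.argsort(c)
        (c1, c2), (r1, r2) = c[order], r[order]
        if r2 >= r1:
            raise CalibrationError("no quenching: ratio does not decrease with pO2")
        b = (1.0 / r2 - 1.0 / r1) / (c2 - c1)
        a = 1.0 / r1 - b * c1
        return O2Calibration(R0=1.0 / a, Ksv=b / a, batch_id=batch_id)
    # 1/R = 1/R0 + (Ksv/R0)*C
    b, a = np.polyfit(c, 1.0 / r, 1)
    if a <= 0 or b <= 0:
        raise CalibrationError("fit yielded non-physical Stern-Volmer parameters")
    cal = O2Calibration(R0=1.0 / a, Ksv=b / a, batch_id=batch_id)
    resid = float(np.linalg.norm(cal.ratio(c) - r))
    return O2Calibration(R0=cal.R0, Ksv=cal.Ksv, batch_id=batch_id, residual=resid)


def fit_ph_calibration(table: CalibrationTable, batch_id: str = "") -> PhCalibration:
    """Nonlinear least-squares fit of the log-sigmoid pH response.

    Initial guesses: asymptotes from the extreme-pH points, pKa from the
    mid-ratio crossing, s = 1.  The fitted curve must be strictly monotone
    over the calibrated range.
    """
    if table.analyte.size < 4:
        raise DataError("pH calibration needs at least 4 points")
    order = np.argsort(table.analyte)
    ph, r = table.analyte[order], table.ratio[order]

    r_acid0, r_base0 = r[0], r[-1]
    mid = 0.5 * (r_acid0 + r_base0)
    pka0 = float(np.interp(mid, r, ph)) if r[-1] > r[0] else float(np.interp(mid, r[::-1], ph[::-1]))

    def model(x, ra, rb, pka, s):
        return ra + (rb - ra) / (1.0 + 10.0 ** (s * (pka - x)))

    try:
        popt, _ = curve_fit(model, ph, r, p0=[r_acid0, r_base0, pka0, 1.0], maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise CalibrationError(f"pH calibration did not converge: {exc}") from exc
    ra, rb, pka, s = (float(v) for v in popt)
    if s < 0:  # equivalent curve with swapped asymptotes and positive slope
        ra, rb, s = rb, ra, -s
    resid = float(np.linalg.norm(model(ph, ra, rb, pka, s) - r))
    cal = PhCalibration(R_acid=ra, R_base=rb, pKa=pka, s=s,
                        ph_range=(float(ph[0]), float(ph[-1])),
                        batch_id=batch_id, residual=resid)
    sweep = cal.ratio(np.linspace(cal.ph_range[0], cal.ph_range[1], 201))
    d = np.diff(sweep)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise CalibrationError(
            f"fitted pH curve is not monotone on {cal.ph_range}; residual={resid:.3g}")
    return cal


def ratio_to_po2(ratio, cal: O2Calibration):
    """Invert the Stern-Volmer model: C = (R0/ratio - 1)/Ksv.

    Returns ``(po2, flags)``.  Ratios above R0 (super-saturation artefacts)
    clamp to 0 with FLAG_CLAMPED; NaN propagates with FLAG_INVALID.
    """
    r = np.asarray(ratio, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    nan = np.isnan(r)
    if np.any(r[~nan] <= 0):
        raise DataError("ratios must be positive")
    with np.errstate(invalid="ignore"):
        po2 = (cal.R0 / r - 1.0) / cal.Ksv
    flags = np.full(r.shape, FLAG_OK, dtype=np.uint8)
    over = ~nan & (po2 < 0)
    po2[over] = 0.0
    flags[over] = FLAG_CLAMPED
    flags[nan] = FLAG_INVALID
    if scalar:
        return float(po2[0]), int(flags[0])
    return po2, flags


def ratio_to_ph(ratio, cal: PhCalibration):
    """Invert the log-sigmoid model.

    pH = pKa - (1/s) * log10((R_base - ratio)/(ratio - R_acid)), adjusted for
    orientation.  Ratios at or beyond an asymptote clamp to the nearest
    calibrated end-point pH with FLAG_CLAMPED; NaN propagates FLAG_INVALID.
    Returns ``(ph, flags)``.
    """
    r = np.asarray(ratio, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r).copy()
    nan = np.isnan(r)
    flags = np.full(r.shape, FLAG_OK, dtype=np.uint8)
    flags[nan] = FLAG_INVALID

    lo_r, hi_r = min(cal.R_acid, cal.R_base), max(cal.R_acid, cal.R_base)
    # pH at which the model attains each ratio extreme
    rising = cal.R_base > cal.R_acid  # ratio increases with pH
    ph_at_lo = cal.ph_range[0] if rising else cal.ph_range[1]
    ph_at_hi = cal.ph_range[1] if rising else cal.ph_range[0]

    ph = np.full(r.shape, np.nan)
    inside = ~nan & (r > lo_r) & (r < hi_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        ph[inside] = cal.pKa - (1.0 / cal.s) * np.log10(
            (cal.R_base - r[inside]) / (r[inside] - cal.R_acid))
    low = ~nan & (r <= lo_r)
    high = ~nan & (r >= hi_r)
    ph[low] = ph_at_lo
    ph[high] = ph_at_hi
    flags[low | high] = FLAG_CLAMPED
    if scalar:
        return float(ph[0]), int(flags[0])
    return ph, flags


def invert_ratio(ratio, cal):
    """Dispatch ratio inversion on the calibration type."""
    if isinstance(cal, O2Calibration):
        return ratio_to_po2(ratio, cal)
    if isinstance(cal, PhCalibration):
        return ratio_to_ph(ratio, cal)
    raise TypeError(f"unsupported calibration type {type(cal)!r}")


_MODEL_NAMES = {O2Calibration: "stern-volmer", PhCalibration: "log-sigmoid"}


def save_calibration(cal, path: str | Path) -> None:
    """Serialise a fitted calibration to a JSON sidecar file."""
    d: dict = {"model": _MODEL_NAMES[type(cal)], "batch_id": cal.batch_id,
               "residual": cal.residual}
    if isinstance(cal, O2Calibration):
        d["parameters"] = {"R0": cal.R0, "Ksv": cal.Ksv}
    else:
        d["parameters"] = {"R_acid": cal.R_acid, "R_base": cal.R_base,
                           "pKa": cal.pKa, "s": cal.s}
        d["ph_range"] = list(cal.ph_range)
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def load_calibration(path: str | Path):
    d = json.loads(Path(path).read_text())
    p = d["parameters"]
    if d["model"] == "stern-volmer":
        return O2Calibration(R0=p["R0"], Ksv=p["Ksv"], batch_id=d.get("batch_id", ""),
                             residual=d.get("residual", 0.0))
    if d["model"] == "log-sigmoid":
        return PhCalibration(R_acid=p["R_acid"], R_base=p["R_base"], pKa=p["pKa"], s=p["s"],
                             ph_range=tuple(d.get("ph_range", (5.0, 8.5))),
                             batch_id=d.get("batch_id", ""), residual=d.get("residual", 0.0))
    raise DataError(f"unknown calibration model {d['model']!r}")
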