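"""OCR/ECAR estimation from ROI time series.

A measurement trace (pO2 in % air saturation, or pH) is reduced to a rate in
three steps: locate the linear range, fit an ordinary-least-squares slope on
it, and normalise the slope to the number of cells under the sensor.  The
normalisation follows the field convention for micro-respirator read-outs:

    OCR_norm  = (-slope [%O2/s]  / cells) * 1e7
    ECAR_norm = (-slope [mpH/min] / cells) * 1e4,   1 pH/s = 60,000 mpH/min

so that consumption and acidification (falling signals) come out positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DataError

MIN_POINTS_DEFAULT = 10
PH_PER_S_TO_MPH_PER_MIN = 60_000.0
OCR_FACTOR = 1e7
ECAR_FACTOR = 1e4


@dataclass
class TimeSeries:
    """ROI-averaged analyte trajectory with per-sample gap flags."""

    analyte: str
    times_s: np.ndarray
    values: np.ndarray
    gaps: np.ndarray | None = None
    n_valid: np.ndarray | None = None  # valid-pixel count per timepoint, if known

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise DataError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise DataError("timestamps must be strictly increasing")
        if self.gaps is None:
            self.gaps = np.zeros(self.times_s.shape, dtype=bool)
        else:
            self.gaps = np.asarray(self.gaps, dtype=bool)

    def valid(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) of non-gap samples."""
        m = ~self.gaps
        return self.times_s[m], self.values[m]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times_s, "value": self.values,
                      "gap": self.gaps.astype(int)}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, analyte: str = "") -> "TimeSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        gaps = df["gap"].to_numpy(dtype=bool) if "gap" in df.columns else None
        return cls(analyte, df["time_s"].to_numpy(), df["value"].to_numpy(), gaps)


@dataclass(frozen=True)
class Window:
    """Half-open sample-index window [start, stop) over the valid samples."""

    start: int
    stop: int
    r2: float
    sub_threshold: bool = False

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class LinearFit:
    slope: float  # analyte units per second
    intercept: float
    r2: float
    window: Window
    zero_variance: bool = False


@dataclass(frozen=True)
class RateResult:
    kind: Literal["OCR", "ECAR"]
    raw_slope: float  # OCR: %O2/s; ECAR: mpH/min
    cell_count: int
    normalized_rate: float
    factor: float
    fit: LinearFit | None = None


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    """Closed-form OLS: returns (slope, intercept, r2, zero_variance).

    r2 is defined as 0 for a zero-variance (constant) response.
    """
    n = t.size
    if n < 2:
        raise DataError("need at least 2 points for a slope")
    tm, ym = t.mean(), y.mean()
    stt = float(np.sum((t - tm) ** 2))
    sty = float(np.sum((t - tm) * (y - ym)))
    syy = float(np.sum((y - ym) ** 2))
    slope = sty / stt
    intercept = ym - slope * tm
    # constant response up to fp rounding: r2 defined as 0 by convention
    if syy <= n * (1e-12 * max(1.0, abs(ym))) ** 2:
        return 0.0, ym, 0.0, True
    return slope, intercept, (sty * sty) / (stt * syy), False


def fit_slope(ts: TimeSeries, window: Window) -> LinearFit:
    """OLS slope on the valid samples inside ``window``."""
    t, y = ts.valid()
    if not (0 <= window.start < window.stop <= t.size):
        raise DataError(f"window {window.start}:{window.stop} outside series of length {t.size}")
    slope, intercept, r2, zv = _ols(t[window.start:window.stop], y[window.start:window.stop])
    return LinearFit(slope=slope, intercept=intercept, r2=r2, window=window, zero_variance=zv)


def find_linear_range(ts: TimeSeries, r2_threshold: float = 0.99,
                      min_fraction: float = 0.3,
                      min_points: int = MIN_POINTS_DEFAULT) -> Window:
    """Longest contiguous window whose OLS r-squared meets the threshold.

    Candidate windows span the non-gap samples and must contain at least
    ``max(min_points, ceil(min_fraction * T))`` of them.  Among qualifying
    windows the longest wins; ties go to the earliest start.  If no window
    qualifies, the minimum-length window maximising r-squared is returned
    with ``sub_threshold=True``.
    """
    t, y = ts.valid()
    n = t.size
    if n < min_points:
        raise DataError(f"series has {n} non-gap samples; need >= {min_points}")
    min_len = max(min_points, int(np.ceil(min_fraction * n)))

    # prefix sums give O(1) per-window OLS statistics
    def cum(x):
        c = np.zeros(n + 1)
        np.cumsum(x, out=c[1:])
        return c
    ct, cy, ctt, cyy, cty = cum(t), cum(y), cum(t * t), cum(y * y), cum(t * y)

    def window_r2(i: int, j: int) -> float:
        m = j - i
        st = ct[j] - ct[i]
        sy = cy[j] - cy[i]
        stt = (ctt[j] - ctt[i]) - st * st / m
        syy = (cyy[j] - cyy[i]) - sy * sy / m
        sty = (cty[j] - cty[i]) - st * sy / m
        if syy <= 0 or stt <= 0:
            return 0.0
        return min(1.0, (sty * sty) / (stt * syy))

    best: Window | None = None
    for i in range(0, n - min_len + 1):
        for j in range(i + min_len, n + 1):
            r2 = window_r2(i, j)
            if r2 >= r2_threshold:
                if best is None or (j - i) > len(best):
                    best = Window(i, j, r2)
    if best is not None:
        return best
    # fall back: best r2 at minimum length
    fb_best = None
    for i in range(0, n - min_len + 1):
        r2 = window_r2(i, i + min_len)
        if fb_best is None or r2 > fb_best.r2:
            fb_best = Window(i, i + min_len, r2, sub_threshold=True)
    return fb_best


def normalize_rate(fit: LinearFit, cell_count: int, kind: Literal["OCR", "ECAR"]) -> RateResult:
    """Cell-number normalisation of a fitted slope.

    OCR: slope in %O2/s, normalised as (-slope/cells)*1e7.  ECAR: slope in
    pH/s, converted to mpH/min (x60,000), then (-slope/cells)*1e4.  A rising
    signal (negative consumption) yields a negative normalised rate and a
    warning.
    """
    if cell_count <= 0:
        raise DataError(f"cell_count must be positive, got {cell_count}")
    if kind == "OCR":
        raw = fit.slope
        factor = OCR_FACTOR
    elif kind == "ECAR":
        raw = fit.slope * PH_PER_S_TO_MPH_PER_MIN
        factor = ECAR_FACTOR
    else:
        raise DataError(f"kind must be 'OCR' or 'ECAR', got {kind!r}")
    normalized = (-raw / cell_count) * factor
    if normalized < 0:
        warnings.warn(f"{kind} signal increases over the fitted window; "
                      "normalised rate is negative", stacklevel=2)
    return RateResult(kind=kind, raw_slope=raw, cell_count=cell_count,
                      normalized_rate=normalized, factor=factor, fit=fit)


def estimate_rate(ts: TimeSeries, cell_count: int, kind: Literal["OCR", "ECAR"],
                  r2_threshold: float = 0.99, min_fraction: float = 0.3,
                  min_points: int = MIN_POINTS_DEFAULT) -> RateResult:
    """Convenience chain: linear range -> slope -> normalisation."""
    window = find_linear_range(ts, r2_threshold, min_fraction, min_points)
    return normalize_rate(fit_slope(ts, window), cell_count, kind)


def rates_to_csv(rates: dict[str, RateResult], ts_by_roi: dict[str, TimeSeries],
                 path: str | Path) -> None:
    """Write the per-ROI rate table with the window in seconds."""
    rows = []
    for roi, r in rates.items():
        t, _ = ts_by_roi[roi].valid()
        w = r.fit.window
        rows.append({
            "roi": roi, "kind": r.kind, "raw_slope": r.raw_slope,
            "units": "%O2/s" if r.kind == "OCR" else "mpH/min",
            "window_start_s": t[w.start], "window_end_s": t[w.stop - 1],
            "r2": r.fit.r2, "cell_count": r.cell_count,
            "normalized_rate": r.normalized_rate,
            "sub_threshold_window": int(w.sub_threshold),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
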