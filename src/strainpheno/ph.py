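"""Environmental pH inference from BCECF dual-excitation fluorescence.

BCECF is a ratiometric pH dye: the ratio R = F490/F440 of emission at
535 nm under excitation at 490 vs 440 nm rises monotonically with medium
pH.  A per-experiment calibration curve of (pH, R) knots measured in
buffered medium maps ratios back to pH.  Background fluorescence is
subtracted per timepoint using a matched dye-free sister well before the
ratio is formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .plates import PlateReaderRun


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone piecewise-linear pH <-> ratio mapping from measured knots.

    Both knot vectors must be strictly increasing: the BCECF ratio rises
    with pH, and monotonicity is what makes the curve invertible.
    """

    ph_knots: tuple[float, ...]
    ratio_knots: tuple[float, ...]

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph_knots, dtype=float)
        r = np.asarray(self.ratio_knots, dtype=float)
        if ph.size < 2 or r.size != ph.size:
            raise ValueError("calibration needs >= 2 (pH, ratio) knots")
        if np.any(np.diff(ph) <= 0):
            raise ValueError("calibration pH knots must be strictly increasing")
        if np.any(np.diff(r) <= 0):
            raise ValueError(
                "calibration ratios must increase with pH (curve not invertible)"
            )

    @property
    def ph_range(self) -> tuple[float, float]:
        return (self.ph_knots[0], self.ph_knots[-1])

    def ph_to_ratio(self, ph) -> np.ndarray:
        """Forward interpolation; clamps outside the knot hull."""
        return np.interp(np.asarray(ph, dtype=float), self.ph_knots, self.ratio_knots)

    def contains_ph(self, ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        return (ph >= self.ph_knots[0]) & (ph <= self.ph_knots[-1])


def fit_calibration(pairs: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Build a calibration curve from measured (pH, ratio) knots.

    Knots are sorted by pH; ratios that do not increase strictly with pH
    are a hard error because the inverse map would be ill-defined.
    """
    if len(pairs) < 2:
        raise ValueError("calibration needs >= 2 (pH, ratio) pairs")
    ordered = sorted((float(p), float(r)) for p, r in pairs)
    ph = tuple(p for p, _ in ordered)
    ratio = tuple(r for _, r in ordered)
    return CalibrationCurve(ph_knots=ph, ratio_knots=ratio)


def read_calibration_csv(path: str | Path) -> CalibrationCurve:
    df = pd.read_csv(path)
    if not {"pH", "ratio"}.issubset(df.columns):
        raise ValueError("calibration CSV needs columns pH, ratio")
    return fit_calibration(list(zip(df["pH"], df["ratio"])))


def write_calibration_csv(curve: CalibrationCurve, path: str | Path) -> None:
    pd.DataFrame({"pH": curve.ph_knots, "ratio": curve.ratio_knots}).to_csv(
        path, index=False
    )


@dataclass
class RatioSeries:
    """Background-subtracted F490/F440 ratio with per-point validity flags."""

    times: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.ratio)
        self.valid = np.asarray(self.valid, dtype=bool)


def compute_ratio(f490, f440, background490, background440, times=None) -> RatioSeries:
    """Form R(t) = (F490 - bg490) / (F440 - bg440) per timepoint.

    Backgrounds come from the matched BCECF-free replicate and may be
    scalars or per-timepoint series.  Points where the denominator is
    non-positive are flagged missing rather than raising.
    """
    f490 = np.asarray(f490, dtype=float)
    f440 = np.asarray(f440, dtype=float)
    num = f490 - np.asarray(background490, dtype=float)
    den = f440 - np.asarray(background440, dtype=float)
    valid = np.isfinite(num) & np.isfinite(den) & (den > 0)
    ratio = np.full_like(f490, np.nan)
    np.divide(num, den, out=ratio, where=valid)
    if times is None:
        times = np.arange(f490.size, dtype=float)
    return RatioSeries(times=times, ratio=ratio, valid=valid)


def ratio_to_ph(
    series: RatioSeries | np.ndarray, curve: CalibrationCurve
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the calibration: ratio -> pH.

    Returns ``(ph, in_range)``.  Ratios outside the knot hull clamp to the
    boundary pH and are flagged ``in_range=False``; invalid ratio points
    propagate as NaN.
    """
    if isinstance(series, RatioSeries):
        r = series.ratio
        valid = series.valid
    else:
        r = np.asarray(series, dtype=float)
        valid = np.isfinite(r)
    ph = np.full(r.shape, np.nan)
    lo, hi = curve.ratio_knots[0], curve.ratio_knots[-1]
    in_range = valid & (r >= lo) & (r <= hi)
    ph[valid] = np.interp(r[valid], curve.ratio_knots, curve.ph_knots)
    return ph, in_range


def match_background_well(run: PlateReaderRun, well: str) -> str:
    """Find the BCECF-free sister replicate for a dye-loaded well."""
    meta = run.meta(well)
    candidates = run.wells_where(
        strain=meta.strain,
        condition_type=meta.condition_type,
        condition_value=meta.condition_value,
        bcecf=False,
    )
    if not candidates:
        raise ValueError(f"no BCECF-free sister well for {well}")
    return candidates[0].well


def infer_plate_ph(run: PlateReaderRun, curve: CalibrationCurve) -> pd.DataFrame:
    """Per-timepoint medium pH for every BCECF well of a run.

    Backgrounds are subtracted per timepoint from the matched dye-free
    sister well; if the sister series has gaps its time-mean fills in.
    Returns a long DataFrame (well, time_h, ratio, ph, in_range).
    """
    records = []
    for meta in run.wells_where(bcecf=True):
        bg_well = match_background_well(run, meta.well)
        f490 = run.series(meta.well, "F490")
        f440 = run.series(meta.well, "F440")
        bg490 = run.series(bg_well, "F490")
        bg440 = run.series(bg_well, "F440")
        for bg in (bg490, bg440):
            gaps = ~np.isfinite(bg)
            if gaps.any():
                bg[gaps] = np.nanmean(bg)
        series = compute_ratio(f490, f440, bg490, bg440, times=run.times)
        ph, in_range = ratio_to_ph(series, curve)
        if not in_range.all():
            warnings.warn(
                f"well {meta.well}: {int((~in_range).sum())} point(s) outside "
                "the calibration range were clamped",
                stacklevel=2,
            )
        records.append(
            pd.DataFrame(
                {
                    "well": meta.well,
                    "time_h": run.times,
                    "ratio": series.ratio,
                    "ph": ph,
                    "in_range": in_range,
                }
            )
        )
    if not records:
        return pd.DataFrame(columns=["well", "time_h", "ratio", "ph", "in_range"])
    return pd.concat(records, ignore_index=True)
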