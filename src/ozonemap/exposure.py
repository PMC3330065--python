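"""Station-level ozone exposure metrics from hourly concentration series.

Computes, per station and vegetation season (April-September by default):

* seasonal mean concentration (ppb), valid only above a minimum data
  capture (75% of possible hours by default);
* AOT40F, the accumulated excess over 40 ppb during daylight hours
  (ppb.h), with a proportional correction for incomplete capture applied
  below a 90% daylight-capture threshold to prevent underestimation;
* mean afternoon concentration and the afternoon increment (afternoon
  mean minus whole-day mean), the quantity whose strong altitude
  dependence drives the afternoon-regression interpolation methods.

All timestamps are interpreted in one fixed timezone (no DST shifts);
concentrations are ppb throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of the station-metric table
METRIC_COLUMNS = [
    "station_id", "x_km", "y_km", "altitude_m",
    "capture", "capture_daylight", "capture_afternoon",
    "seasonal_mean_ppb", "aot40f_ppbh", "aot40f_corrected_ppbh",
    "aot40_afternoon_ppbh", "afternoon_mean_ppb", "increment_ppb",
]


@dataclass
class StationSeries:
    """One station's hourly concentration record with validity flags."""

    station_id: str
    index: pd.DatetimeIndex
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.index = pd.DatetimeIndex(self.index)
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.index)
        if len(self.values) != n or len(self.valid) != n:
            raise ValueError("timestamps, values and flags must align")
        if n > 1:
            deltas = np.diff(self.index.asi8)
            if not np.all(deltas == 3_600_000_000_000):
                raise ValueError("timestamps must be strictly increasing at "
                                 "hourly spacing")
        ok = self.values[self.valid]
        if ok.size and (not np.all(np.isfinite(ok)) or np.any(ok < 0)):
            raise ValueError("valid concentrations must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.index)


@dataclass(frozen=True)
class SeasonWindow:
    """Averaging/accumulation window and the clock-hour sub-windows.

    ``daylight`` bounds the AOT40 accumulation (half-open clock hours,
    default 08-20, i.e. twelve hourly values per day); ``afternoon``
    bounds the afternoon mean (default 12-18) and must lie inside the
    daylight window.  Dates are inclusive.
    """

    start: date = date(2007, 4, 1)
    end: date = date(2007, 9, 30)
    daylight: tuple[int, int] = (8, 20)
    afternoon: tuple[int, int] = (12, 18)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("season start must precede season end")
        for lo, hi in (self.daylight, self.afternoon):
            if not (0 <= lo < hi <= 24):
                raise ValueError("clock-hour windows must satisfy 0 <= lo < hi <= 24")
        if not (self.daylight[0] <= self.afternoon[0]
                and self.afternoon[1] <= self.daylight[1]):
            raise ValueError("afternoon window must lie within the daylight window")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def hours_per_day(self, scope: str) -> int:
        if scope == "whole_day":
            return 24
        if scope == "daylight":
            return self.daylight[1] - self.daylight[0]
        if scope == "afternoon":
            return self.afternoon[1] - self.afternoon[0]
        raise ValueError(f"unknown scope {scope!r}")

    def possible_hours(self, scope: str = "whole_day") -> int:
        return self.n_days * self.hours_per_day(scope)

    def scope_mask(self, index: pd.DatetimeIndex, scope: str = "whole_day") -> np.ndarray:
        """Boolean mask of timestamps inside the window under a scope."""
        dates = index.normalize()
        mask = (dates >= pd.Timestamp(self.start)) & (dates <= pd.Timestamp(self.end))
        if scope == "daylight":
            mask &= (index.hour >= self.daylight[0]) & (index.hour < self.daylight[1])
        elif scope == "afternoon":
            mask &= (index.hour >= self.afternoon[0]) & (index.hour < self.afternoon[1])
        elif scope != "whole_day":
            raise ValueError(f"unknown scope {scope!r}")
        return np.asarray(mask)


def data_capture(series: StationSeries, window: SeasonWindow,
                 scope: str = "whole_day") -> float:
    """Fraction of possible hours in the window that carry a valid value.

    Hours absent from the record count as missing, so the denominator is
    the full calendar complement of the window under the given scope.
    """
    possible = window.possible_hours(scope)
    if possible == 0:
        raise ValueError("window contains no possible hours")
    mask = window.scope_mask(series.index, scope)
    return float(np.count_nonzero(series.valid & mask)) / possible


def seasonal_mean(series: StationSeries, window: SeasonWindow,
                  min_capture: float = 0.75) -> float | None:
    """Mean of valid hourly values in the season, or None below capture.

    Stations below the capture threshold are excluded (flagged absent),
    never zero-filled.
    """
    if not 0 < min_capture <= 1:
        raise ValueError("min_capture must lie in (0, 1]")
    cap = data_capture(series, window, "whole_day")
    if cap < min_capture:
        logger.warning("station %s: seasonal mean absent, capture %.3f below %.2f",
                       series.station_id, cap, min_capture)
        return None
    mask = window.scope_mask(series.index) & series.valid
    return float(series.values[mask].mean())


def aot40(series: StationSeries, window: SeasonWindow,
          threshold: float = 40.0, scope: str = "daylight") -> float:
    """Accumulated exposure over a threshold (ppb.h), daylight hours only.

    Sums the strict excess max(value - threshold, 0) over valid hours in
    the given clock-hour scope; hours exactly at the threshold contribute
    zero.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    mask = window.scope_mask(series.index, scope) & series.valid
    excess = np.maximum(series.values[mask] - threshold, 0.0)
    return float(excess.sum())


def correct_aot40(raw: float, capture_daylight: float,
                  correction_threshold: float = 0.90) -> float:
    """Scale an AOT40 value for incomplete data capture.

    Below the correction threshold the measured value is multiplied by
    (possible daylight hours / valid daylight hours), i.e. divided by the
    capture fraction, so that missing hours do not bias the cumulative
    index low.  At or above the threshold the value passes unchanged.
    """
    if not 0 < capture_daylight <= 1:
        raise ValueError("capture_daylight must lie in (0, 1]")
    if raw < 0:
        raise ValueError("AOT40 cannot be negative")
    if capture_daylight >= correction_threshold:
        return float(raw)
    return float(raw / capture_daylight)


def afternoon_mean(series: StationSeries, window: SeasonWindow,
                   min_capture: float = 0.75) -> float | None:
    """Mean of valid values in the afternoon clock window, or None."""
    cap = data_capture(series, window, "afternoon")
    if cap < min_capture:
        logger.warning("station %s: afternoon mean absent, capture %.3f",
                       series.station_id, cap)
        return None
    mask = window.scope_mask(series.index, "afternoon") & series.valid
    return float(series.values[mask].mean())


def afternoon_increment(series: StationSeries, window: SeasonWindow,
                        min_capture: float = 0.75) -> float | None:
    """Afternoon mean minus whole-day seasonal mean (ppb); may be negative."""
    aft = afternoon_mean(series, window, min_capture)
    whole = seasonal_mean(series, window, min_capture)
    if aft is None or whole is None:
        return None
    return aft - whole


def compute_station_metrics(series_list: list[StationSeries],
                            stations: pd.DataFrame,
                            window: SeasonWindow | None = None,
                            min_capture: float = 0.75,
                            correction_threshold: float = 0.90,
                            aot40_threshold: float = 40.0) -> pd.DataFrame:
    """Derive the full per-station metric table from hourly series.

    ``stations`` supplies ``station_id, x_km, y_km, altitude_m``.  AOT40F
    is computed when daylight capture reaches ``min_capture`` and
    corrected below ``correction_threshold``; the afternoon-window AOT40
    analogue (used by the afternoon-regression methods on AOT40F) is
    handled the same way with its own capture.
    """
    window = window or SeasonWindow()
    meta = stations.set_index("station_id")
    rows = []
    for series in series_list:
        sid = series.station_id
        if sid not in meta.index:
            raise KeyError(f"station {sid!r} missing from metadata")
        cap = data_capture(series, window, "whole_day")
        cap_day = data_capture(series, window, "daylight")
        cap_aft = data_capture(series, window, "afternoon")
        mean = seasonal_mean(series, window, min_capture)
        aft = afternoon_mean(series, window, min_capture)
        inc = (aft - mean) if (aft is not None and mean is not None) else None

        if cap_day >= min_capture:
            raw = aot40(series, window, aot40_threshold, "daylight")
            corrected = correct_aot40(raw, cap_day, correction_threshold)
        else:
            logger.warning("station %s: AOT40F absent, daylight capture %.3f",
                           sid, cap_day)
            raw = corrected = None
        if cap_aft >= min_capture:
            raw_aft = aot40(series, window, aot40_threshold, "afternoon")
            aot_aft = correct_aot40(raw_aft, cap_aft, correction_threshold)
        else:
            aot_aft = None

        rows.append({
            "station_id": sid,
            "x_km": float(meta.loc[sid, "x_km"]),
            "y_km": float(meta.loc[sid, "y_km"]),
            "altitude_m": float(meta.loc[sid, "altitude_m"]),
            "capture": cap,
            "capture_daylight": cap_day,
            "capture_afternoon": cap_aft,
            "seasonal_mean_ppb": np.nan if mean is None else mean,
            "aot40f_ppbh": np.nan if raw is None else raw,
            "aot40f_corrected_ppbh": np.nan if corrected is None else corrected,
            "aot40_afternoon_ppbh": np.nan if aot_aft is None else aot_aft,
            "afternoon_mean_ppb": np.nan if aft is None else aft,
            "increment_ppb": np.nan if inc is None else inc,
        })
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def read_hourly_csv(path) -> list[StationSeries]:
    """Read the hourly CSV (station_id, timestamp, o3_ppb, valid)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for sid, grp in df.groupby("station_id", sort=True):
        grp = grp.sort_values("timestamp")
        out.append(StationSeries(
            station_id=str(sid),
            index=pd.DatetimeIndex(grp["timestamp"]),
            values=grp["o3_ppb"].to_numpy(float),
            valid=grp["valid"].to_numpy().astype(bool),
        ))
    return out


def write_hourly_csv(path, series_list: list[StationSeries]) -> None:
    frames = [
        pd.DataFrame({
            "station_id": s.station_id,
            "timestamp": s.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "o3_ppb": np.round(s.values, 4),
            "valid": s.valid.astype(int),
        })
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)


def read_metrics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("station_id", "x_km", "y_km", "altitude_m") if c not in df]
    if missing:
        raise ValueError(f"metric table missing columns: {missing}")
    dup = df.duplicated(subset=["x_km", "y_km"], keep=False)
    if dup.any():
        ids = df.loc[dup, "station_id"].tolist()
        raise ValueError(f"duplicate station coordinates: {ids}")
    return df


def write_metrics_csv(path, metrics: pd.DataFrame) -> None:
    metrics.to_csv(Path(path), index=False)
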