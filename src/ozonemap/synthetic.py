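"""Synthetic rural ozone networks with the structure the analysis assumes.

The generator emulates a sparse national monitoring network: roughly two
dozen rural stations over ~79 000 km2, a seasonal-mean ozone field with
a strong linear altitude component plus a spatially correlated residual,
hourly series with a diurnal cycle whose afternoon increment depends on
altitude, and configurable missing-data patterns.  Every quantity is
deterministic under the configuration seed.

Units: coordinates km, altitudes m, concentrations ppb, exposure ppb.h.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

from ozonemap.exposure import SeasonWindow, StationSeries
from ozonemap.gridding import CovariateGrid

logger = logging.getLogger(__name__)

_COV_MODELS = ("exponential", "gaussian", "spherical")


@dataclass(frozen=True)
class FieldConfig:
    """Study conditions for one synthetic network and season.

    The defaults describe the regime the pipeline is designed for: a
    280 x 280 km domain (~78 400 km2) sampled on a 10 km grid, 24
    stations biased toward high terrain, seasonal means of roughly
    36 + 0.01 * altitude ppb with an exponential-covariance residual of
    4 ppb2 sill and 50 km range, an afternoon increment of about 6 ppb
    at sea level shrinking with altitude, 4 ppb hourly noise, and 5%
    missing hours.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 280.0, 280.0)
    grid_step: float = 10.0
    n_stations: int = 24
    regression_intercept: float = 36.0   # ppb at sea level
    regression_slope: float = 0.01       # ppb per m altitude
    residual_sill: float = 4.0           # ppb2
    residual_range: float = 50.0         # km
    residual_model: str = "exponential"
    diurnal_amplitude: float = 6.0       # afternoon increment at sea level, ppb
    increment_slope: float = -0.004      # ppb per m altitude
    noise_sd: float = 4.0                # hourly measurement noise, ppb
    missing_fraction: float = 0.05
    season_start: date = date(2007, 4, 1)
    season_end: date = date(2007, 9, 30)
    max_altitude: float = 1300.0         # m
    relief_scale: float = 35.0           # broad terrain correlation length, km
    relief_detail_scale: float = 8.0     # fine ridge/valley scale, km
    relief_detail_weight: float = 0.45   # share of fine-scale relief variance
    relief_gain: float = 1.5             # spread of the altitude distribution
    border_relief: float = 1.5           # strength of the border-mountain ridge
    station_altitude_bias: float = 2.0   # >0 favours high-altitude cells
    flat_terrain: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError("domain extent has zero or negative area")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.n_stations < 3:
            raise ValueError("need at least three stations")
        if self.residual_range <= 0 or self.residual_sill < 0:
            raise ValueError("residual_range must be > 0 and residual_sill >= 0")
        if self.residual_model not in _COV_MODELS:
            raise ValueError(f"residual_model must be one of {_COV_MODELS}")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.season_start >= self.season_end:
            raise ValueError("season_start must precede season_end")

    @property
    def shape(self) -> tuple[int, int]:
        x0, y0, x1, y1 = self.extent
        return (int(round((y1 - y0) / self.grid_step)),
                int(round((x1 - x0) / self.grid_step)))

    def season_window(self) -> SeasonWindow:
        return SeasonWindow(start=self.season_start, end=self.season_end)


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated season."""

    dem: CovariateGrid
    mean_field: np.ndarray          # true seasonal mean per grid cell, ppb
    stations: pd.DataFrame          # station_id, x_km, y_km, altitude_m,
                                    # true_mean_ppb, true_increment_ppb
    intercept: float
    slope: float


def _covariance(model: str, h: np.ndarray, sill: float, rng_km: float) -> np.ndarray:
    if model == "exponential":
        c = np.exp(-h / rng_km)
    elif model == "gaussian":
        c = np.exp(-((h / rng_km) ** 2))
    else:  # spherical
        r = np.clip(h / rng_km, 0.0, 1.0)
        c = 1.0 - (1.5 * r - 0.5 * r ** 3)
    return sill * c


def _grf(points: np.ndarray, model: str, sill: float, rng_km: float,
         rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian random field at arbitrary points by Cholesky.

    Exact at desk scale (a few thousand points); the covariance matrix
    gets a tiny diagonal jitter for numerical positive-definiteness.
    """
    if sill == 0:
        return np.zeros(len(points))
    from scipy.spatial.distance import cdist
    c = _covariance(model, cdist(points, points), sill, rng_km)
    c[np.diag_indices_from(c)] += 1e-8 * sill
    try:
        factor = np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        # smooth (gaussian) covariances can be numerically semidefinite
        vals, vecs = np.linalg.eigh(c)
        factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return factor @ rng.standard_normal(len(points))


def _cell_points(config: FieldConfig) -> tuple[CovariateGrid, np.ndarray]:
    shape = config.shape
    grid = CovariateGrid(config.extent[0], config.extent[1], config.grid_step,
                         np.zeros(shape))
    xg, yg = grid.center_mesh()
    return grid, np.column_stack([xg.ravel(), yg.ravel()])


def generate_dem(config: FieldConfig, rng: np.random.Generator | None = None
                 ) -> CovariateGrid:
    """A bounded synthetic terrain on the configured grid.

    Two Gaussian random fields -- a broad one at the terrain correlation
    length and a fine one at the ridge/valley scale, mixed by
    ``relief_detail_weight`` -- plus a deterministic term raising the
    domain border (a basin rimmed by mountains, where the monitoring
    network clusters) are squashed through a logistic map onto
    [0, max_altitude].  The fine component keeps altitude varying below
    the station spacing, as real rugged terrain does.
    """
    grid, pts = _cell_points(config)
    if config.flat_terrain:
        return grid
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    w = config.relief_detail_weight
    f = (np.sqrt(1.0 - w ** 2) * _grf(pts, "gaussian", 1.0, config.relief_scale, rng)
         + w * _grf(pts, "exponential", 1.0, config.relief_detail_scale, rng))
    x0, y0, x1, y1 = config.extent
    d_edge = np.minimum.reduce([pts[:, 0] - x0, x1 - pts[:, 0],
                                pts[:, 1] - y0, y1 - pts[:, 1]])
    ridge = np.exp(-d_edge / (0.15 * min(x1 - x0, y1 - y0)))
    f = config.relief_gain * (f + config.border_relief * ridge - 0.5)
    alt = config.max_altitude / (1.0 + np.exp(-f))
    grid.values = alt.reshape(config.shape)
    return grid


def generate_stations(config: FieldConfig, dem: CovariateGrid,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Place stations on distinct grid cells, optionally biased uphill.

    With ``station_altitude_bias`` b > 0 a cell's selection weight is
    exp(b * altitude / max_altitude), reproducing a network with more
    sites in border mountain areas than in the interior.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_cells = dem.values.size
    if config.n_stations > n_cells:
        raise ValueError(f"{config.n_stations} stations exceed {n_cells} grid cells")
    alt = dem.values.ravel()
    scale = max(config.max_altitude, 1.0)
    w = np.exp(config.station_altitude_bias * alt / scale)
    p = w / w.sum()
    idx = rng.choice(n_cells, size=config.n_stations, replace=False, p=p)
    idx.sort()
    rows, cols = np.unravel_index(idx, dem.shape)
    xc, yc = dem.x_centers(), dem.y_centers()
    return pd.DataFrame({
        "station_id": [f"ST{i + 1:02d}" for i in range(config.n_stations)],
        "x_km": xc[cols],
        "y_km": yc[rows],
        "altitude_m": alt[idx],
        "cell_index": idx,
    })


def generate_seasonal_field(config: FieldConfig, dem: CovariateGrid,
                            stations: pd.DataFrame | None = None,
                            rng: np.random.Generator | None = None
                            ) -> SyntheticTruth:
    """True seasonal-mean field: linear altitude trend + correlated residual.

    mean(s) = intercept + slope * altitude(s) + eps(s), with eps a
    zero-mean Gaussian random field of the configured covariance, so the
    altitude regression and the residual kriging stage each have a real
    signal to recover.
    """
    master = rng if rng is not None else np.random.default_rng(config.seed)
    if stations is None:
        stations = generate_stations(config, dem, master)
    _, pts = _cell_points(config)
    eps = _grf(pts, config.residual_model, config.residual_sill,
               config.residual_range, master)
    alt = dem.values.ravel()
    mean = config.regression_intercept + config.regression_slope * alt + eps

    st = stations.copy()
    cell = st["cell_index"].to_numpy()
    st["true_mean_ppb"] = mean[cell]
    inc = config.diurnal_amplitude + config.increment_slope * st["altitude_m"]
    st["true_increment_ppb"] = np.maximum(inc, 0.0)
    return SyntheticTruth(dem=dem, mean_field=mean.reshape(config.shape),
                          stations=st, intercept=config.regression_intercept,
                          slope=config.regression_slope)


def _diurnal_shape(hours: np.ndarray, window: SeasonWindow) -> tuple[np.ndarray, float]:
    """Cosine cycle peaking mid-afternoon, exactly zero-mean over 24 h.

    Returns the unit-amplitude shape per hour and its mean over the
    afternoon clock window, used to scale amplitudes so that the
    afternoon increment hits its configured target.
    """
    peak = 0.5 * (window.afternoon[0] + window.afternoon[1])
    shape = np.cos(2 * np.pi * (hours - peak) / 24.0)
    aft_hours = np.arange(window.afternoon[0], window.afternoon[1])
    aft_mean = float(np.cos(2 * np.pi * (aft_hours - peak) / 24.0).mean())
    return shape, aft_mean


def generate_hourly_series(truth: SyntheticTruth, config: FieldConfig,
                           rng: np.random.Generator | None = None
                           ) -> list[StationSeries]:
    """Hourly series per station: mean + diurnal cycle + white noise.

    The cycle sums to zero over each day, so a full-capture noise-free
    series averages exactly to the station's true seasonal mean, and its
    amplitude is scaled per station so the afternoon increment equals
    the (altitude-dependent) true increment.  Values are floored at zero.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    window = config.season_window()
    index = pd.date_range(pd.Timestamp(config.season_start),
                          pd.Timestamp(config.season_end) + pd.Timedelta(hours=23),
                          freq="h")
    hours = index.hour.to_numpy()
    shape, aft_mean = _diurnal_shape(hours, window)
    out = []
    for row in truth.stations.itertuples():
        amp = row.true_increment_ppb / aft_mean
        values = row.true_mean_ppb + amp * shape
        if config.noise_sd > 0:
            values = values + rng.normal(0.0, config.noise_sd, len(index))
        values = np.maximum(values, 0.0)
        out.append(StationSeries(station_id=row.station_id, index=index,
                                 values=values,
                                 valid=np.ones(len(index), dtype=bool)))
    return out


def apply_missingness(series: StationSeries, config: FieldConfig,
                      rng: np.random.Generator | None = None,
                      pattern: str = "random",
                      block_hours: int = 48) -> StationSeries:
    """Flag ~missing_fraction of hours invalid, randomly or in blocks.

    The block pattern drops consecutive runs (instrument outages) of
    ``block_hours`` until the target count is reached; runs may overlap.
    """
    if config.missing_fraction == 0:
        return series
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = len(series)
    valid = series.valid.copy()
    target = int(round(config.missing_fraction * n))
    if pattern == "random":
        drop = rng.random(n) < config.missing_fraction
        valid &= ~drop
    elif pattern == "block":
        invalid = np.zeros(n, dtype=bool)
        guard = 0
        while invalid.sum() < target and guard < 10 * n:
            start = int(rng.integers(0, n))
            invalid[start:start + block_hours] = True
            guard += 1
        valid &= ~invalid
    else:
        raise ValueError(f"unknown missingness pattern {pattern!r}")
    return StationSeries(series.station_id, series.index, series.values, valid)


@dataclass
class SimulationResult:
    """Everything one seeded simulation produced."""

    config: FieldConfig
    truth: SyntheticTruth
    series: list[StationSeries]


def simulate(config: FieldConfig, missing_pattern: str = "random") -> SimulationResult:
    """Full seeded simulation: DEM, stations, truth field, hourly series.

    One master seed is expanded into independent per-stage substreams so
    that, e.g., changing the noise level does not reshuffle the terrain.
    """
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(config.seed).spawn(5)]
    dem = generate_dem(config, streams[0])
    stations = generate_stations(config, dem, streams[1])
    truth = generate_seasonal_field(config, dem, stations, streams[2])
    series = generate_hourly_series(truth, config, streams[3])
    series = [apply_missingness(s, config, streams[4], pattern=missing_pattern)
              for s in series]
    return SimulationResult(config=config, truth=truth, series=series)


def station_metrics_from_truth(truth: SyntheticTruth, config: FieldConfig,
                               rng: np.random.Generator | None = None
                               ) -> pd.DataFrame:
    """Station-metric table derived directly from the truth field.

    A fast path equivalent, in distribution, to generating hourly series
    and running the exposure stage at full capture: the seasonal mean is
    the true station value plus the standard error that hourly noise
    leaves after averaging, and the afternoon mean adds the true
    increment plus its (larger) averaging error.  Used by large
    replicate experiments where the hourly stage would dominate runtime.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    window = config.season_window()
    n_hours = window.possible_hours("whole_day")
    n_aft = window.possible_hours("afternoon")
    st = truth.stations
    se_mean = config.noise_sd / np.sqrt(n_hours)
    se_aft = config.noise_sd / np.sqrt(n_aft)
    seasonal = st["true_mean_ppb"].to_numpy() + rng.normal(0, se_mean, len(st))
    afternoon = (st["true_mean_ppb"].to_numpy()
                 + st["true_increment_ppb"].to_numpy()
                 + rng.normal(0, se_aft, len(st)))
    return pd.DataFrame({
        "station_id": st["station_id"],
        "x_km": st["x_km"],
        "y_km": st["y_km"],
        "altitude_m": st["altitude_m"],
        "capture": 1.0,
        "seasonal_mean_ppb": seasonal,
        "afternoon_mean_ppb": afternoon,
        "increment_ppb": afternoon - seasonal,
    })


def write_stations_csv(path, stations: pd.DataFrame) -> None:
    stations[["station_id", "x_km", "y_km", "altitude_m"]].to_csv(path, index=False)


def read_stations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"station_id", "x_km", "y_km", "altitude_m"}
    if not need <= set(df.columns):
        raise ValueError(f"station metadata must contain {sorted(need)}")
    return df
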