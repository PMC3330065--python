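"""Leave-one-out cross-validation, RMSE, relative uncertainty, ranking.

Each station is predicted in turn from all the others with the full
method refitted on the reduced network (regression and variogram
included, unless the all-station variogram is explicitly frozen), and
the map uncertainty is summarised as

    RMSE = sqrt( (1/N) * sum_i (Z(s_i) - Zhat(s_i))^2 )

with the relative uncertainty 100 * RMSE / network mean, displayed as a
whole percent (rounded half-up).  Methods are compared by their RMSE
averaged over periods (years), with competition ranking: tied methods
share the lowest rank and the following rank is skipped (1, 1, 3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ozonemap.interpolation import (
    METHOD_ACRONYMS,
    MethodSpec,
    fit_station_variogram,
    make_interpolator,
)

logger = logging.getLogger(__name__)


def rmse(measured, predicted=None) -> float:
    """Root mean square error of predicted against measured values."""
    if predicted is None:  # accept a list of (measured, predicted) pairs
        pairs = np.asarray(measured, dtype=float)
        if pairs.size == 0:
            raise ValueError("rmse of an empty set is undefined")
        measured, predicted = pairs[:, 0], pairs[:, 1]
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.size == 0:
        raise ValueError("rmse of an empty set is undefined")
    if not (np.all(np.isfinite(measured)) and np.all(np.isfinite(predicted))):
        raise ValueError("rmse requires finite values")
    return float(np.sqrt(np.mean((measured - predicted) ** 2)))


def relative_uncertainty(rmse_value: float, network_mean: float) -> float:
    """Map RMSE as a percentage of the network mean (unrounded)."""
    if network_mean <= 0:
        raise ValueError("network mean must be positive")
    return 100.0 * rmse_value / network_mean


def display_percent(pct: float) -> int:
    """Whole-percent display value, rounding halves up (12.9 -> 13)."""
    return int(math.floor(pct + 0.5))


def sampling_density(area_km2: float, n_stations: int) -> float:
    """Area served per monitor, km2 (e.g. 79 000 / 24 ~ 3 292)."""
    if n_stations <= 0:
        raise ValueError("need at least one station")
    return area_km2 / n_stations


@dataclass
class CVResult:
    """One method's leave-one-out cross-validation on one metric."""

    method: str
    metric_name: str
    table: pd.DataFrame          # station_id, measured, predicted, error
    rmse: float
    network_mean: float
    relative_uncertainty_pct: float
    n_failed: int = 0

    @property
    def display_pct(self) -> int:
        return display_percent(self.relative_uncertainty_pct)


def loocv(metrics: pd.DataFrame, spec: MethodSpec,
          metric_name: str = "seasonal_mean_ppb",
          refit_variogram: bool = True) -> CVResult:
    """Leave-one-out cross-validation of one method on one metric.

    Stations lacking the metric are excluded up front.  By default every
    fold refits the complete method, variogram included, on the reduced
    network; ``refit_variogram=False`` freezes the all-station variogram
    across folds instead (both behaviours are defensible readings of
    GIS-software cross-validation and are logged).  A fold whose fit
    fails is excluded from the RMSE and counted.
    """
    # canonical station order: results must not depend on row order
    usable = (metrics.dropna(subset=[metric_name])
              .sort_values(["x_km", "y_km"], kind="mergesort")
              .reset_index(drop=True))
    if len(usable) < 4:
        raise ValueError(f"LOOCV needs at least 4 stations with {metric_name}; "
                         f"got {len(usable)}")
    frozen = None
    if not refit_variogram:
        frozen = fit_station_variogram(
            usable[["x_km", "y_km"]].to_numpy(float),
            usable[metric_name].to_numpy(float),
            model=spec.variogram_model, n_bins=spec.variogram_bins)
        logger.info("LOOCV %s: variogram frozen at %s", spec.acronym, frozen)

    rows, n_failed = [], 0
    for i in range(len(usable)):
        train = usable.drop(index=i)
        held = usable.iloc[i]
        try:
            interp = make_interpolator(spec, train, metric_name, variogram=frozen)
            pred = interp.predict(
                np.array([held["x_km"]]), np.array([held["y_km"]]),
                np.array([held["altitude_m"]]))
            pred = float(np.asarray(pred).ravel()[0])
            if not np.isfinite(pred):
                raise RuntimeError("non-finite prediction")
        except Exception as exc:  # a broken fold must not sink the study
            logger.warning("LOOCV %s fold %s failed: %s",
                           spec.acronym, held["station_id"], exc)
            n_failed += 1
            continue
        rows.append({"station_id": held["station_id"],
                     "measured": float(held[metric_name]),
                     "predicted": pred})
    if not rows:
        raise RuntimeError(f"every LOOCV fold failed for {spec.acronym}")
    table = pd.DataFrame(rows)
    table["error"] = table["predicted"] - table["measured"]
    err = rmse(table["measured"], table["predicted"])
    mean = float(table["measured"].mean())
    return CVResult(method=spec.acronym, metric_name=metric_name, table=table,
                    rmse=err, network_mean=mean,
                    relative_uncertainty_pct=relative_uncertainty(err, mean),
                    n_failed=n_failed)


def crossval_all(metrics: pd.DataFrame, metric_name: str = "seasonal_mean_ppb",
                 specs: list[MethodSpec] | None = None,
                 refit_variogram: bool = True) -> dict[str, CVResult]:
    """LOOCV of every configured method on one metric table."""
    if specs is None:
        specs = [MethodSpec(a) for a in METHOD_ACRONYMS]
    return {s.acronym: loocv(metrics, s, metric_name, refit_variogram)
            for s in specs}


def rank_methods(rmse_by_period: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Average per-period RMSEs and rank methods, competition style.

    ``rmse_by_period`` has methods as the index and one column per
    period.  Averages are displayed at ``decimals`` places (2 for ppb
    concentrations, 0 for ppb.h exposures) and ties are detected at that
    display precision, which is how two methods averaging 3.23 can share
    rank 1 while the next receives rank 3.  Missing entries are an
    error: every method must be evaluated in every period.
    """
    if rmse_by_period.isna().any().any():
        gaps = [(m, p) for m in rmse_by_period.index
                for p in rmse_by_period.columns
                if pd.isna(rmse_by_period.loc[m, p])]
        raise ValueError(f"missing method/period RMSEs: {gaps}")
    avg = rmse_by_period.mean(axis=1)
    shown = avg.round(decimals)
    rank = pd.Series(
        [1 + int((shown < v).sum()) for v in shown], index=shown.index,
        name="rank")
    out = rmse_by_period.copy()
    out["average"] = shown if decimals > 0 else shown.astype(int)
    out["rank"] = rank
    return out.sort_values(["rank", "average"]).rename_axis("method")
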