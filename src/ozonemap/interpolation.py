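"""The eleven spatial interpolation methods, behind one fit/predict surface.

Three methods use measured values only:

* ``IDW``  -- inverse distance weighting, weights proportional to d^-k;
* ``RBF``  -- radial basis functions with a constant term, an exact
  interpolator obtained from an (n+1)-dimensional linear system;
* ``OK``   -- ordinary kriging with weights from a fitted semivariogram,
  constrained to sum to one.

The remainder combine measurements with altitude as the auxiliary
covariate:

* ``LR``            -- ordinary least squares of the metric on altitude;
* ``LR+res_IDW/RBF/OK``  -- the regression prediction plus a spatial
  interpolation of its station residuals (regression kriging when the
  residual method is OK);
* ``ALR``           -- ordinary kriging of mean afternoon values minus an
  altitude regression of the afternoon increment;
* ``ALR+res_IDW/RBF/OK`` -- ALR plus interpolated residuals of the
  whole-day metric.

All predictors use a global neighbourhood (every station enters every
prediction) and planar distances in km.  Duplicate station coordinates
are rejected rather than jittered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import linregress

logger = logging.getLogger(__name__)

METHOD_ACRONYMS = (
    "IDW", "RBF", "OK", "LR",
    "LR+res_IDW", "LR+res_RBF", "LR+res_OK",
    "ALR", "ALR+res_IDW", "ALR+res_RBF", "ALR+res_OK",
)

VARIOGRAM_MODELS = ("spherical", "exponential", "gaussian")
RBF_KERNELS = ("thin_plate", "multiquadric", "gaussian")

#: metric column -> column holding its afternoon-window analogue
AFTERNOON_ANALOGUE = {
    "seasonal_mean_ppb": "afternoon_mean_ppb",
    "aot40f_corrected_ppbh": "aot40_afternoon_ppbh",
    "aot40f_ppbh": "aot40_afternoon_ppbh",
}


# ---------------------------------------------------------------------------
# semivariogram

@dataclass(frozen=True)
class Variogram:
    """An isotropic semivariogram model gamma(h).

    ``range_km`` is the direct scale parameter of each family:
    spherical reaches its sill exactly at the range; the exponential and
    gaussian families use gamma(h) = nugget + psill * (1 - exp(-h/a))
    and its squared-argument analogue.
    """

    model: str = "spherical"
    nugget: float = 0.0
    psill: float = 1.0
    range_km: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in VARIOGRAM_MODELS:
            raise ValueError(f"unknown variogram model {self.model!r}; "
                             f"choose from {VARIOGRAM_MODELS}")
        if self.nugget < 0 or self.psill < 0 or self.range_km <= 0:
            raise ValueError("variogram requires nugget >= 0, psill >= 0, range > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def gamma(self, h) -> np.ndarray:
        """Semivariance at lag h (km); gamma(0) = 0 by convention."""
        h = np.asarray(h, dtype=float)
        a = self.range_km
        if self.model == "spherical":
            r = np.clip(h / a, 0.0, 1.0)
            struct = 1.5 * r - 0.5 * r ** 3
        elif self.model == "exponential":
            struct = 1.0 - np.exp(-h / a)
        else:  # gaussian
            struct = 1.0 - np.exp(-((h / a) ** 2))
        g = self.nugget + self.psill * struct
        return np.where(h > 0, g, 0.0)


def empirical_semivariogram(xy: np.ndarray, values: np.ndarray,
                            n_bins: int = 10,
                            max_lag: float | None = None) -> pd.DataFrame:
    """Method-of-moments semivariogram estimate on distance bins.

    gamma_hat(h) = mean over station pairs in the bin of half the squared
    value difference.  ``max_lag`` defaults to half the maximum pairwise
    distance; empty bins are dropped.  Returns (lag, gamma, n_pairs).
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(xy) < 2:
        raise ValueError("need at least two stations")
    d = pdist(xy)
    if np.all(d == 0):
        raise ValueError("all stations are coincident")
    sq = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    if max_lag is None:
        max_lag = 0.5 * d.max()
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d > lo) & (d <= hi)
        if not sel.any():
            continue
        rows.append({"lag": float(d[sel].mean()),
                     "gamma": float(sq[sel].mean()),
                     "n_pairs": int(sel.sum())})
    return pd.DataFrame(rows, columns=["lag", "gamma", "n_pairs"])


def fit_variogram(empirical: pd.DataFrame, model: str = "spherical") -> Variogram:
    """Weighted least-squares fit of a variogram family to binned estimates.

    Residuals are weighted by the square root of each bin's pair count.
    Requires at least three bins; raises on fewer (callers wanting the
    deterministic fallback use :func:`fit_station_variogram`).
    """
    if len(empirical) < 3:
        raise ValueError("variogram fit needs at least three non-empty bins")
    lags = empirical["lag"].to_numpy(float)
    gammas = empirical["gamma"].to_numpy(float)
    w = np.sqrt(empirical["n_pairs"].to_numpy(float))

    # fit in normalized units so convergence does not depend on the
    # metric's scale (gamma is ~1e1 for ppb but ~1e7 for ppb.h)
    gmax = max(gammas.max(), 1e-300)
    lmax = lags.max()
    gs, ls = gammas / gmax, lags / lmax
    x0 = np.array([0.0, 1.0, 0.5])
    lo = np.array([0.0, 0.0, 1e-6])
    hi = np.array([2.0, 3.0, 4.0])

    def resid(p):
        vg = Variogram(model, p[0], p[1], p[2])
        return w * (vg.gamma(ls) - gs)

    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
    if not np.all(np.isfinite(sol.x)) or sol.x[0] + sol.x[1] <= 0:
        raise RuntimeError("variogram least-squares fit did not converge")
    nugget, psill, rng = (float(v) for v in sol.x)
    return Variogram(model, nugget * gmax, psill * gmax, rng * lmax)


def fit_station_variogram(xy: np.ndarray, values: np.ndarray,
                          model: str = "spherical", n_bins: int = 10,
                          max_lag: float | None = None) -> Variogram:
    """Empirical estimate plus model fit, with a deterministic fallback.

    If the fit fails (too few bins, degenerate values, non-convergence)
    the fallback is a spherical model with zero nugget, the sample
    variance as sill, and half the maximum pairwise distance as range,
    reported at warning level.
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    try:
        emp = empirical_semivariogram(xy, values, n_bins=n_bins, max_lag=max_lag)
        vg = fit_variogram(emp, model=model)
        if vg.sill <= 0:
            raise RuntimeError("degenerate fitted sill")
        return vg
    except (ValueError, RuntimeError) as exc:
        half_max = 0.5 * float(pdist(xy).max())
        sill = max(float(np.var(values)), 1e-12)
        logger.warning("variogram fit failed (%s); falling back to spherical "
                       "nugget=0 sill=%.4g range=%.4g", exc, sill, half_max)
        return Variogram("spherical", 0.0, sill, max(half_max, 1e-6))


# ---------------------------------------------------------------------------
# elementary predictors

def _check_no_duplicates(xy: np.ndarray, ids=None) -> None:
    d = squareform(pdist(xy))
    np.fill_diagonal(d, np.inf)
    i, j = np.where(d < 1e-12)
    if len(i):
        a, b = int(i[0]), int(j[0])
        pair = (ids[a], ids[b]) if ids is not None else (a, b)
        raise ValueError(f"duplicate station coordinates: {pair[0]} and {pair[1]}")


def idw_predict(xy: np.ndarray, values: np.ndarray, targets: np.ndarray,
                power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted prediction at target points.

    Weights are d^-power normalised to sum to one; a target coincident
    with a station returns that station's value exactly.  Predictions are
    convex combinations, hence bounded by the data range.
    """
    if power <= 0:
        raise ValueError("IDW power must be positive")
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    values = np.asarray(values, dtype=float)
    if len(xy) == 0:
        raise ValueError("IDW needs at least one station")
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    d = cdist(targets, xy)
    out = np.empty(len(targets))
    hit_t, hit_s = np.where(d < 1e-12)
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[~np.isfinite(w)] = 0.0
    denom = w.sum(axis=1)
    denom[denom == 0] = 1.0
    out = (w * values).sum(axis=1) / denom
    out[hit_t] = values[hit_s]
    return out


def _rbf_kernel(name: str, d: np.ndarray, eps: float) -> np.ndarray:
    if name == "thin_plate":
        with np.errstate(divide="ignore", invalid="ignore"):
            k = d ** 2 * np.log(d)
        return np.where(d > 0, k, 0.0)
    if name == "multiquadric":
        return np.sqrt(d ** 2 + eps ** 2)
    if name == "gaussian":
        return np.exp(-((d / eps) ** 2))
    raise ValueError(f"unknown RBF kernel {name!r}; choose from {RBF_KERNELS}")


class RBFInterpolator:
    """Exact radial-basis-function interpolator with a constant term.

    Solves the (n+1)-dimensional system  sum_j w_j Phi(d_ij) + w_{n+1}
    = Z(s_i)  together with the side condition sum_j w_j = 0 that makes
    the constant term well determined; with all-equal data the weights
    vanish and the constant reproduces the common value everywhere.
    The default kernel is the thin-plate spline Phi(d) = d^2 log d, the
    minimum-curvature spline in two dimensions.
    """

    needs_altitude = False

    def __init__(self, xy, values, kernel: str = "thin_plate",
                 epsilon: float | None = None, ids=None):
        self.xy = np.atleast_2d(np.asarray(xy, dtype=float))
        self.values = np.asarray(values, dtype=float)
        n = len(self.xy)
        if n < 3:
            raise ValueError("RBF needs at least three stations")
        _check_no_duplicates(self.xy, ids)
        self.kernel = kernel
        if epsilon is None:
            d = squareform(pdist(self.xy))
            np.fill_diagonal(d, np.inf)
            epsilon = float(np.median(d.min(axis=1)))  # median NN distance
        self.epsilon = epsilon
        phi = _rbf_kernel(kernel, cdist(self.xy, self.xy), epsilon)
        a = np.zeros((n + 1, n + 1))
        a[:n, :n] = phi
        a[:n, n] = 1.0
        a[n, :n] = 1.0
        b = np.zeros(n + 1)
        b[:n] = self.values
        try:
            sol = np.linalg.solve(a, b)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular RBF system: {exc}") from exc
        self.weights = sol[:n]
        self.constant = float(sol[n])

    def predict(self, x, y, altitude=None) -> np.ndarray:
        targets = np.column_stack([np.atleast_1d(np.asarray(x, float)),
                                   np.atleast_1d(np.asarray(y, float))])
        phi = _rbf_kernel(self.kernel, cdist(targets, self.xy), self.epsilon)
        return phi @ self.weights + self.constant


def ok_predict(xy: np.ndarray, values: np.ndarray, variogram: Variogram,
               targets: np.ndarray,
               return_variance: bool = False):
    """Ordinary-kriging prediction (and variance) at target points.

    For each target, the weights lambda solve the augmented system
    ``sum_j lambda_j gamma(s_i - s_j) + m = gamma(s_0 - s_i)`` with the
    unbiasedness constraint ``sum lambda_j = 1``; the prediction is
    ``sum lambda_i Z(s_i)`` and the kriging variance is ``sum lambda_i
    gamma(s_0 - s_i) + m`` (clamped at zero against round-off).
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    values = np.asarray(values, dtype=float)
    n = len(xy)
    if n < 2:
        raise ValueError("ordinary kriging needs at least two stations")
    _check_no_duplicates(xy)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))

    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = variogram.gamma(cdist(xy, xy))
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    try:
        a_inv = np.linalg.inv(a)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular kriging matrix: {exc}") from exc

    b = np.zeros((n + 1, len(targets)))
    b[:n] = variogram.gamma(cdist(xy, targets))
    b[n] = 1.0
    # one matrix-vector product per target: batch and single-point calls
    # then agree bit for bit (gemm and gemv round differently)
    sol = np.column_stack([a_inv @ b[:, j] for j in range(b.shape[1])])
    lam, m = sol[:n], sol[n]
    wsum = lam.sum(axis=0)
    if np.any(np.abs(wsum - 1.0) > 1e-8):
        raise RuntimeError("kriging weights failed the unbiasedness constraint")
    pred = lam.T @ values
    if not return_variance:
        return pred
    var = np.maximum((lam * b[:n]).sum(axis=0) + m, 0.0)
    return pred, var


# ---------------------------------------------------------------------------
# altitude regression

@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least squares of a station metric on altitude."""

    intercept: float
    slope: float
    r_squared: float
    stderr_slope: float
    altitudes: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)

    def predict(self, altitude) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(altitude, dtype=float)


def fit_lr(altitudes: np.ndarray, values: np.ndarray) -> RegressionFit:
    """Fit metric = c + a1 * altitude by OLS; residuals sum to zero."""
    altitudes = np.asarray(altitudes, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(altitudes) < 3:
        raise ValueError("altitude regression needs at least three stations")
    if np.ptp(altitudes) == 0:
        raise ValueError("altitude has zero variance; regression undefined")
    res = linregress(altitudes, values)
    fitted = res.intercept + res.slope * altitudes
    return RegressionFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue ** 2),
        stderr_slope=float(res.stderr),
        altitudes=altitudes,
        residuals=values - fitted,
    )


# ---------------------------------------------------------------------------
# fit/predict wrappers over the closed method set

@dataclass(frozen=True)
class MethodSpec:
    """Configuration of one of the eleven interpolation methods."""

    acronym: str
    idw_power: float = 2.0
    rbf_kernel: str = "thin_plate"
    variogram_model: str = "spherical"
    variogram_bins: int = 10

    def __post_init__(self) -> None:
        if self.acronym not in METHOD_ACRONYMS:
            raise ValueError(f"unknown method {self.acronym!r}; the valid "
                             f"acronyms are {', '.join(METHOD_ACRONYMS)}")

    @property
    def uses_altitude(self) -> bool:
        return self.acronym not in ("IDW", "RBF", "OK")

    @property
    def residual_method(self) -> str | None:
        if "+res_" in self.acronym:
            return self.acronym.split("+res_")[1]
        return None


class IDWInterpolator:
    needs_altitude = False

    def __init__(self, xy, values, power: float = 2.0, ids=None):
        self.xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if len(self.xy) > 1:
            _check_no_duplicates(self.xy, ids)
        self.values = np.asarray(values, dtype=float)
        self.power = power

    def predict(self, x, y, altitude=None) -> np.ndarray:
        targets = np.column_stack([np.atleast_1d(np.asarray(x, float)),
                                   np.atleast_1d(np.asarray(y, float))])
        return idw_predict(self.xy, self.values, targets, self.power)


class OKInterpolator:
    needs_altitude = False

    def __init__(self, xy, values, variogram: Variogram | None = None,
                 variogram_model: str = "spherical", variogram_bins: int = 10,
                 ids=None):
        self.xy = np.atleast_2d(np.asarray(xy, dtype=float))
        _check_no_duplicates(self.xy, ids)
        self.values = np.asarray(values, dtype=float)
        if variogram is None:
            variogram = fit_station_variogram(self.xy, self.values,
                                              model=variogram_model,
                                              n_bins=variogram_bins)
        self.variogram = variogram

    def predict(self, x, y, altitude=None) -> np.ndarray:
        targets = np.column_stack([np.atleast_1d(np.asarray(x, float)),
                                   np.atleast_1d(np.asarray(y, float))])
        return ok_predict(self.xy, self.values, self.variogram, targets)

    def predict_with_variance(self, x, y):
        targets = np.column_stack([np.atleast_1d(np.asarray(x, float)),
                                   np.atleast_1d(np.asarray(y, float))])
        return ok_predict(self.xy, self.values, self.variogram, targets,
                          return_variance=True)


class LRInterpolator:
    """Altitude regression alone: prediction ignores location."""

    needs_altitude = True

    def __init__(self, altitudes, values):
        self.fit = fit_lr(altitudes, values)

    def predict(self, x, y, altitude=None) -> np.ndarray:
        if altitude is None:
            raise ValueError("LR prediction requires target altitude")
        return np.atleast_1d(self.fit.predict(altitude))


def _residual_interpolator(method: str, xy, residuals, spec: MethodSpec,
                           variogram: Variogram | None = None, ids=None):
    if method == "IDW":
        return IDWInterpolator(xy, residuals, spec.idw_power, ids=ids)
    if method == "RBF":
        return RBFInterpolator(xy, residuals, spec.rbf_kernel, ids=ids)
    if method == "OK":
        return OKInterpolator(xy, residuals, variogram=variogram,
                              variogram_model=spec.variogram_model,
                              variogram_bins=spec.variogram_bins, ids=ids)
    raise ValueError(f"unknown residual method {method!r}")


class LRResidualInterpolator:
    """Regression on altitude plus spatial interpolation of its residuals.

    With OK as the residual method this is regression kriging, the
    configuration that performs best on altitude-dominated ozone fields.
    """

    needs_altitude = True

    def __init__(self, xy, altitudes, values, spec: MethodSpec,
                 residual_variogram: Variogram | None = None, ids=None):
        self.fit = fit_lr(altitudes, values)
        self.residual_interp = _residual_interpolator(
            spec.residual_method, xy, self.fit.residuals, spec,
            variogram=residual_variogram, ids=ids)

    def predict(self, x, y, altitude=None) -> np.ndarray:
        if altitude is None:
            raise ValueError("LR+res prediction requires target altitude")
        trend = self.fit.predict(altitude)
        return np.atleast_1d(trend) + self.residual_interp.predict(x, y)


class ALRInterpolator:
    """Kriged afternoon field minus an altitude regression of the increment.

    The afternoon increment (afternoon minus whole-day value) shrinks
    with altitude, so subtracting its regression prediction converts an
    interpolated afternoon surface into a whole-day estimate.
    """

    needs_altitude = True

    def __init__(self, xy, altitudes, afternoon_values, increments,
                 spec: MethodSpec, afternoon_variogram: Variogram | None = None,
                 ids=None):
        self.increment_fit = fit_lr(altitudes, increments)
        self.afternoon_interp = OKInterpolator(
            xy, afternoon_values, variogram=afternoon_variogram,
            variogram_model=spec.variogram_model,
            variogram_bins=spec.variogram_bins, ids=ids)

    def predict(self, x, y, altitude=None) -> np.ndarray:
        if altitude is None:
            raise ValueError("ALR prediction requires target altitude")
        rho = self.afternoon_interp.predict(x, y)
        return rho - np.atleast_1d(self.increment_fit.predict(altitude))


class ALRResidualInterpolator:
    """ALR plus spatial interpolation of its whole-day residuals."""

    needs_altitude = True

    def __init__(self, xy, altitudes, values, afternoon_values, increments,
                 spec: MethodSpec, afternoon_variogram: Variogram | None = None,
                 residual_variogram: Variogram | None = None, ids=None):
        self.alr = ALRInterpolator(xy, altitudes, afternoon_values, increments,
                                   spec, afternoon_variogram, ids=ids)
        at_stations = self.alr.predict(xy[:, 0], xy[:, 1], altitudes)
        self.residuals = np.asarray(values, dtype=float) - at_stations
        self.residual_interp = _residual_interpolator(
            spec.residual_method, xy, self.residuals, spec,
            variogram=residual_variogram, ids=ids)

    def predict(self, x, y, altitude=None) -> np.ndarray:
        if altitude is None:
            raise ValueError("ALR+res prediction requires target altitude")
        return self.alr.predict(x, y, altitude) + self.residual_interp.predict(x, y)


def make_interpolator(spec: MethodSpec, metrics: pd.DataFrame,
                      metric_name: str = "seasonal_mean_ppb",
                      variogram: Variogram | None = None):
    """Fit the method described by ``spec`` on a station-metric table.

    ``metrics`` needs ``x_km, y_km, altitude_m`` and the metric column;
    ALR-family methods additionally need the afternoon analogue column
    (``afternoon_mean_ppb`` for concentrations, ``aot40_afternoon_ppbh``
    for AOT40F).  Stations with the metric absent are dropped with a
    warning.  ``variogram`` optionally freezes a prefitted model instead
    of refitting from the supplied stations (used to hold the all-station
    variogram fixed across cross-validation folds).
    """
    required = ["x_km", "y_km", "altitude_m", metric_name]
    alr_family = spec.acronym.startswith("ALR")
    if alr_family:
        if metric_name not in AFTERNOON_ANALOGUE:
            raise ValueError(f"no afternoon analogue defined for {metric_name!r}")
        aft_col = AFTERNOON_ANALOGUE[metric_name]
        required.append(aft_col)
    missing_cols = [c for c in required if c not in metrics.columns]
    if missing_cols:
        raise ValueError(f"metric table missing columns: {missing_cols}")

    usable = metrics.dropna(subset=[c for c in required if c != "station_id"])
    dropped = len(metrics) - len(usable)
    if dropped:
        logger.warning("%d station(s) dropped for missing %s", dropped, metric_name)
    xy = usable[["x_km", "y_km"]].to_numpy(float)
    alt = usable["altitude_m"].to_numpy(float)
    z = usable[metric_name].to_numpy(float)
    ids = usable["station_id"].to_numpy() if "station_id" in usable else None

    acro = spec.acronym
    if acro == "IDW":
        return IDWInterpolator(xy, z, spec.idw_power, ids=ids)
    if acro == "RBF":
        return RBFInterpolator(xy, z, spec.rbf_kernel, ids=ids)
    if acro == "OK":
        return OKInterpolator(xy, z, variogram=variogram,
                              variogram_model=spec.variogram_model,
                              variogram_bins=spec.variogram_bins, ids=ids)
    if acro == "LR":
        return LRInterpolator(alt, z)
    if acro.startswith("LR+res_"):
        return LRResidualInterpolator(xy, alt, z, spec,
                                      residual_variogram=variogram, ids=ids)
    aft = usable[aft_col].to_numpy(float)
    inc = aft - z
    if acro == "ALR":
        return ALRInterpolator(xy, alt, aft, inc, spec,
                               afternoon_variogram=variogram, ids=ids)
    return ALRResidualInterpolator(xy, alt, z, aft, inc, spec,
                                   afternoon_variogram=variogram, ids=ids)


def default_method_specs(**overrides) -> list[MethodSpec]:
    """One MethodSpec per acronym, in canonical order."""
    return [MethodSpec(acronym=a, **overrides) for a in METHOD_ACRONYMS]
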