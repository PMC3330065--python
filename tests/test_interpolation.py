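"""Interpolation methods against hand calculations and dense-solve oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from ozonemap.interpolation import (
    METHOD_ACRONYMS,
    MethodSpec,
    RBFInterpolator,
    Variogram,
    _rbf_kernel,
    empirical_semivariogram,
    fit_lr,
    fit_station_variogram,
    fit_variogram,
    idw_predict,
    make_interpolator,
    ok_predict,
)


def random_network(n, seed, extent=200.0, lo=20.0, hi=60.0):
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0.0, extent, (n, 2))
    z = rng.uniform(lo, hi, n)
    return xy, z


# --------------------------------------------------------------------------
# oracles, written independently of the implementation

def ok_oracle(xy, z, vg, target):
    """Dense solve of the ordinary-kriging system with semivariances."""
    n = len(xy)
    a = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            a[i, j] = vg.gamma(np.linalg.norm(xy[i] - xy[j]))
        a[i, n] = 1.0
        a[n, i] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        b[i] = vg.gamma(np.linalg.norm(target - xy[i]))
    b[n] = 1.0
    lam = np.linalg.solve(a, b)[:n]
    return float(lam @ z), lam


def rbf_oracle(xy, z, kernel, eps, target):
    """Dense solve of the RBF system with a constant term."""
    n = len(xy)
    a = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            a[i, j] = float(_rbf_kernel(kernel, np.array(
                np.linalg.norm(xy[i] - xy[j])), eps))
        a[i, n] = 1.0
        a[n, i] = 1.0
    b = np.append(z, 0.0)
    w = np.linalg.solve(a, b)
    phi = np.array([float(_rbf_kernel(kernel, np.array(
        np.linalg.norm(target - xy[i])), eps)) for i in range(n)])
    return float(phi @ w[:n] + w[n])


def idw_oracle(xy, z, target, k):
    num = den = 0.0
    for i in range(len(xy)):
        d = np.linalg.norm(target - xy[i])
        num += z[i] / d ** k
        den += 1.0 / d ** k
    return num / den


# --------------------------------------------------------------------------

class TestIdw:
    def test_single_station_collapses_to_its_value(self):
        p = idw_predict([[0.0, 0.0]], [37.2], [[55.0, -3.0]])
        assert p[0] == 37.2

    @pytest.mark.parametrize("k", [0.5, 1.0, 2.0, 3.0])
    def test_equidistant_symmetry(self, k):
        xy = [[0.0, 0.0], [0.0, 2.0]]
        p = idw_predict(xy, [10.0, 20.0], [[1.0, 1.0]], power=k)
        assert p[0] == pytest.approx(15.0)

    def test_hand_evaluated_weighting(self):
        # distances 1 and 2, values 10 and 20, k=2:
        # (10/1 + 20/4) / (1 + 1/4) = 12
        xy = [[0.0, 0.0], [0.0, 3.0]]
        p = idw_predict(xy, [10.0, 20.0], [[0.0, 1.0]], power=2.0)
        assert p[0] == pytest.approx(12.0)

    def test_exact_at_station_and_bounded(self):
        xy, z = random_network(12, 5)
        at_station = idw_predict(xy, z, xy)
        np.testing.assert_allclose(at_station, z, atol=1e-12)
        rng = np.random.default_rng(6)
        targets = rng.uniform(-50.0, 250.0, (200, 2))
        p = idw_predict(xy, z, targets)
        assert np.all(p >= z.min() - 1e-12) and np.all(p <= z.max() + 1e-12)

    def test_empty_station_list_rejected(self):
        with pytest.raises(ValueError):
            idw_predict(np.empty((0, 2)), [], [[0.0, 0.0]])


class TestRbf:
    def test_exact_interpolation_at_stations(self):
        xy, z = random_network(10, 1)
        r = RBFInterpolator(xy, z)
        np.testing.assert_allclose(r.predict(xy[:, 0], xy[:, 1]), z, atol=1e-8)

    def test_constant_field_reproduced_everywhere(self):
        xy, _ = random_network(8, 2)
        r = RBFInterpolator(xy, np.full(8, 7.25))
        rng = np.random.default_rng(3)
        t = rng.uniform(-100.0, 300.0, (50, 2))
        np.testing.assert_allclose(r.predict(t[:, 0], t[:, 1]), 7.25, atol=1e-8)

    @pytest.mark.parametrize("kernel", ["thin_plate", "multiquadric", "gaussian"])
    def test_matches_dense_solve_oracle(self, kernel):
        xy, z = random_network(5, 4)
        r = RBFInterpolator(xy, z, kernel=kernel)
        rng = np.random.default_rng(5)
        for t in rng.uniform(0.0, 200.0, (10, 2)):
            expect = rbf_oracle(xy, z, kernel, r.epsilon, t)
            got = r.predict(np.array([t[0]]), np.array([t[1]]))[0]
            assert got == pytest.approx(expect, abs=1e-8)

    def test_duplicate_stations_named_in_error(self):
        xy = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="A.*C|duplicate"):
            RBFInterpolator(xy, [1.0, 2.0, 3.0, 4.0], ids=list("ABCD"))


class TestEmpiricalVariogram:
    def test_constant_field_has_zero_semivariance(self):
        xy, _ = random_network(10, 7)
        emp = empirical_semivariogram(xy, np.full(10, 3.0))
        assert (emp["gamma"] == 0.0).all()

    def test_two_stations_single_pair(self):
        emp = empirical_semivariogram([[0.0, 0.0], [10.0, 0.0]], [1.0, 5.0],
                                      n_bins=1, max_lag=20.0)
        assert len(emp) == 1
        assert emp["gamma"].iloc[0] == 8.0  # half of 4^2
        assert emp["n_pairs"].iloc[0] == 1

    def test_coincident_stations_rejected(self):
        with pytest.raises(ValueError):
            empirical_semivariogram([[0.0, 0.0], [0.0, 0.0]], [1.0, 2.0])

    def test_tracks_exponential_covariance_closed_form(self):
        # dense network sampling a field with known covariance: binned
        # estimates should follow sill * (1 - exp(-h/range))
        import dataclasses
        from ozonemap import synthetic
        c = dataclasses.replace(synthetic.FieldConfig(seed=3), n_stations=250,
                                regression_slope=0.0)
        dem = synthetic.generate_dem(c)
        truth = synthetic.generate_seasonal_field(c, dem)
        emp = empirical_semivariogram(
            truth.stations[["x_km", "y_km"]].to_numpy(float),
            truth.stations["true_mean_ppb"].to_numpy(float))
        expect = c.residual_sill * (1.0 - np.exp(-emp["lag"] / c.residual_range))
        # field-level fluctuation allows a loose band only
        assert np.corrcoef(emp["gamma"], expect)[0, 1] > 0.8
        np.testing.assert_allclose(emp["gamma"], expect,
                                   atol=0.6 * c.residual_sill)


class TestVariogramFit:
    def test_exact_recovery_from_model_curve(self):
        vg = Variogram("spherical", 2.0, 7.5, 90.0)
        lags = np.linspace(5.0, 140.0, 12)
        emp = pd.DataFrame({"lag": lags, "gamma": vg.gamma(lags), "n_pairs": 20})
        fit = fit_variogram(emp, "spherical")
        assert fit.nugget == pytest.approx(2.0, abs=1e-6)
        assert fit.psill == pytest.approx(7.5, abs=1e-6)
        assert fit.range_km == pytest.approx(90.0, abs=1e-4)

    def test_flat_empirical_fits_pure_nugget(self):
        emp = pd.DataFrame({"lag": np.linspace(10.0, 100.0, 8),
                            "gamma": 5.0, "n_pairs": 30})
        fit = fit_variogram(emp, "spherical")
        assert fit.psill == pytest.approx(0.0, abs=1e-6)
        assert fit.nugget == pytest.approx(5.0, abs=1e-6)

    def test_fallback_on_degenerate_input(self, caplog):
        # two stations: not enough bins to fit, deterministic fallback
        xy = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        z = np.array([1.0, 2.0, 3.0])
        with caplog.at_level("WARNING"):
            vg = fit_station_variogram(xy, z)
        assert vg.model == "spherical"
        assert vg.nugget == 0.0
        assert vg.range_km == pytest.approx(10.0)  # half the max distance
        assert vg.psill == pytest.approx(np.var(z))
        assert any("fall" in r.message for r in caplog.records)

    def test_parameter_bounds_enforced(self):
        with pytest.raises(ValueError):
            Variogram("spherical", -1.0, 1.0, 10.0)
        with pytest.raises(ValueError):
            Variogram("wavy", 0.0, 1.0, 10.0)


class TestOrdinaryKriging:
    def test_pure_nugget_gives_arithmetic_mean(self):
        # solving the system by hand for gamma = nugget (h>0): all
        # weights equal 1/n, so the prediction is the plain average
        xy, z = random_network(7, 8)
        vg = Variogram("spherical", nugget=3.0, psill=0.0, range_km=50.0)
        p = ok_predict(xy, z, vg, [[500.0, 500.0]])
        assert p[0] == pytest.approx(z.mean(), abs=1e-10)

    def test_nugget_free_kriging_is_exact_at_stations(self):
        xy, z = random_network(9, 9)
        vg = Variogram("exponential", 0.0, 5.0, 60.0)
        p = ok_predict(xy, z, vg, xy)
        np.testing.assert_allclose(p, z, atol=1e-8)

    def test_matches_dense_solve_oracle(self):
        xy, z = random_network(6, 10)
        vg = Variogram("spherical", 0.4, 6.0, 80.0)
        rng = np.random.default_rng(11)
        for t in rng.uniform(0.0, 200.0, (10, 2)):
            expect, lam = ok_oracle(xy, z, vg, t)
            assert abs(lam.sum() - 1.0) < 1e-10
            got = ok_predict(xy, z, vg, t[None, :])[0]
            assert got == pytest.approx(expect, abs=1e-8)

    def test_kriging_variance_nonnegative(self):
        xy, z = random_network(8, 12)
        vg = Variogram("spherical", 0.5, 4.0, 70.0)
        _, var = ok_predict(xy, z, vg, np.random.default_rng(0).uniform(
            0, 200, (20, 2)), return_variance=True)
        assert np.all(var >= 0.0)

    def test_duplicate_coordinates_rejected(self):
        xy = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="duplicate"):
            ok_predict(xy, [1.0, 2.0, 3.0], Variogram(), [[5.0, 5.0]])


class TestAltitudeRegression:
    def test_exact_linear_data(self):
        alt = np.array([0.0, 250.0, 500.0, 1000.0])
        z = 30.0 + 0.01 * alt
        fit = fit_lr(alt, z)
        assert fit.intercept == pytest.approx(30.0)
        assert fit.slope == pytest.approx(0.01)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(13)
        alt = rng.uniform(100.0, 1300.0, 24)
        z = 30.0 + 0.01 * alt + rng.normal(0.0, 2.0, 24)
        fit = fit_lr(alt, z)
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-9)

    def test_flat_generator_gives_near_zero_slope(self):
        rng = np.random.default_rng(14)
        alt = rng.uniform(100.0, 1300.0, 24)
        z = np.full(24, 40.0)
        fit = fit_lr(alt, z)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_zero_altitude_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_lr(np.full(5, 500.0), np.arange(5.0))


class TestMethodDispatch:
    def test_unknown_acronym_lists_valid_names(self):
        with pytest.raises(ValueError) as err:
            MethodSpec("KRIG")
        assert "ALR+res_OK" in str(err.value)

    def test_idw_spec_ignores_altitude(self, linear_metrics):
        interp = make_interpolator(MethodSpec("IDW"), linear_metrics)
        a = interp.predict(np.array([50.0]), np.array([50.0]))
        b = interp.predict(np.array([50.0]), np.array([50.0]),
                           np.array([9999.0]))
        assert a[0] == b[0]
        assert not interp.needs_altitude

    def test_lr_prediction_is_linear_in_altitude(self, linear_metrics):
        interp = make_interpolator(MethodSpec("LR"), linear_metrics)
        alts = np.array([0.0, 500.0, 1000.0])
        p = interp.predict(np.zeros(3), np.zeros(3), alts)
        np.testing.assert_allclose(p, [30.0, 35.0, 40.0], atol=1e-9)

    def test_lr_res_ok_on_residual_free_data_stays_linear(self, linear_metrics):
        interp = make_interpolator(MethodSpec("LR+res_OK"), linear_metrics)
        p = interp.predict(np.array([40.0]), np.array([160.0]),
                           np.array([700.0]))
        assert p[0] == pytest.approx(30.0 + 0.01 * 700.0, abs=1e-6)

    def test_every_acronym_fits_and_predicts(self, station_metrics):
        for acro in METHOD_ACRONYMS:
            interp = make_interpolator(MethodSpec(acro), station_metrics)
            p = interp.predict(np.array([140.0]), np.array([140.0]),
                               np.array([600.0]))
            assert np.isfinite(p[0])


class TestAfternoonRegressionMethods:
    def test_zero_increment_reduces_to_afternoon_kriging(self, linear_metrics):
        m = linear_metrics.copy()
        m["afternoon_mean_ppb"] = m["seasonal_mean_ppb"]
        m["increment_ppb"] = 0.0
        alr = make_interpolator(MethodSpec("ALR"), m)
        ok = make_interpolator(MethodSpec("OK"), m)
        x, y = np.array([75.0]), np.array([110.0])
        assert alr.predict(x, y, np.array([400.0]))[0] == pytest.approx(
            ok.predict(x, y)[0], abs=1e-9)

    def test_constant_afternoon_minus_linear_increment(self):
        # afternoon field constant at 50; increment exactly 2 + 0.001*alt;
        # whole-day estimate at 1000 m must be 50 - 3 = 47
        rng = np.random.default_rng(15)
        n = 10
        alt = np.linspace(0.0, 1300.0, n)
        m = pd.DataFrame({
            "station_id": [f"S{i}" for i in range(n)],
            "x_km": rng.uniform(0, 200, n), "y_km": rng.uniform(0, 200, n),
            "altitude_m": alt,
            "seasonal_mean_ppb": 50.0 - (2.0 + 0.001 * alt),
            "afternoon_mean_ppb": np.full(n, 50.0),
            "increment_ppb": 2.0 + 0.001 * alt,
        })
        alr = make_interpolator(MethodSpec("ALR"), m)
        p = alr.predict(np.array([100.0]), np.array([100.0]),
                        np.array([1000.0]))
        assert p[0] == pytest.approx(47.0, abs=1e-6)

    def test_alr_residual_collapses_to_alr_when_residuals_vanish(self):
        rng = np.random.default_rng(16)
        n = 10
        alt = np.linspace(0.0, 1300.0, n)
        m = pd.DataFrame({
            "station_id": [f"S{i}" for i in range(n)],
            "x_km": rng.uniform(0, 200, n), "y_km": rng.uniform(0, 200, n),
            "altitude_m": alt,
            "seasonal_mean_ppb": 50.0 - (2.0 + 0.001 * alt),
            "afternoon_mean_ppb": np.full(n, 50.0),
            "increment_ppb": 2.0 + 0.001 * alt,
        })
        alr = make_interpolator(MethodSpec("ALR"), m)
        alr_res = make_interpolator(MethodSpec("ALR+res_IDW"), m)
        x, y, a = np.array([55.0]), np.array([77.0]), np.array([800.0])
        assert alr_res.predict(x, y, a)[0] == pytest.approx(
            alr.predict(x, y, a)[0], abs=1e-6)


class TestRigidMotionInvariance:
    @pytest.mark.parametrize("acro", ["IDW", "RBF", "OK"])
    def test_predictions_unchanged_under_rotation_translation(self, acro):
        xy, z = random_network(10, 17)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        shift = np.array([310.0, -45.0])
        xy2 = xy @ rot.T + shift
        target = np.array([[80.0, 120.0]])
        target2 = target @ rot.T + shift
        if acro == "IDW":
            a = idw_predict(xy, z, target)[0]
            b = idw_predict(xy2, z, target2)[0]
        elif acro == "RBF":
            r1 = RBFInterpolator(xy, z)
            r2 = RBFInterpolator(xy2, z, epsilon=r1.epsilon)
            a = r1.predict(target[:, 0], target[:, 1])[0]
            b = r2.predict(target2[:, 0], target2[:, 1])[0]
        else:
            vg = Variogram("spherical", 0.3, 5.0, 80.0)
            a = ok_predict(xy, z, vg, target)[0]
            b = ok_predict(xy2, z, vg, target2)[0]
        assert a == pytest.approx(b, abs=1e-8)
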