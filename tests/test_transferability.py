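"""Climatologies, station-to-training-set distances, and the R^2-simulation
regression with its quality-class accuracy."""

import numpy as np
import pandas as pd
import pytest

from fluxbridge import (
    DistanceCache,
    classification_accuracy,
    default_registry,
    doy_climatology,
    fit_rsm,
    pairwise_ds,
    predict_r2,
    quality_class,
    training_set_distance,
)
from fluxbridge.transferability import DOYClimatology, RSModel


def make_clim(sid, values_by_factor, static=None):
    """Climatology with explicit per-DOY values (NaN = unobserved)."""
    daily = pd.DataFrame(
        {k: np.asarray(v, dtype=float) for k, v in values_by_factor.items()},
        index=range(1, 366),
    )
    return DOYClimatology(sid, daily, static or {})


def full_series(values):
    out = np.full(365, np.nan)
    out[: len(values)] = values
    return out


class TestDoyClimatology:
    def test_multi_year_mean_and_leap_day_dropped(self, registry):
        rows = []
        for year, val in ((2011, 2.0), (2012, 4.0)):
            rows.append({"station_id": "S", "year": year, "doy": 100, "ta": val})
        # a leap-day record that must not appear
        rows.append({"station_id": "S", "year": 2012, "doy": 366, "ta": 99.0})
        clim = doy_climatology(pd.DataFrame(rows), registry)
        assert clim.daily.loc[100, "ta"] == pytest.approx(3.0)
        assert len(clim.daily) == 365  # DOY index 1..365 only

    def test_single_year_equals_that_year(self, registry, small_processed):
        _, records = small_processed
        sid = records["station_id"].iloc[0]
        blk = records[records["station_id"] == sid]
        clim = doy_climatology(blk, registry)
        one_year = blk[blk["doy"] <= 365].set_index("doy")
        np.testing.assert_allclose(
            clim.daily["ta"].to_numpy(), one_year["ta"].to_numpy()
        )

    def test_static_factors_collapse_to_scalars(self, registry, small_processed):
        _, records = small_processed
        sid = records["station_id"].iloc[0]
        clim = doy_climatology(records[records["station_id"] == sid], registry)
        assert set(registry.static_names()) <= set(clim.static)
        assert np.isscalar(clim.static["elevation"])


class TestPairwiseDs:
    def test_identical_climatologies_have_zero_distance(self):
        x = make_clim("a", {"ta": full_series(np.arange(60))})
        assert pairwise_ds(x, x, "ta")[0] == 0.0

    def test_root_sum_of_squares_on_common_days(self):
        x = make_clim("a", {"ta": full_series([1.0, 2.0])})
        y = make_clim("b", {"ta": full_series([4.0, 6.0])})
        d, t = pairwise_ds(x, y, "ta", t_min=2)
        assert d == pytest.approx(5.0)  # sqrt(9 + 16)
        assert t == 2

    def test_static_factor_absolute_difference(self):
        x = make_clim("a", {}, static={"elevation": 100.0})
        y = make_clim("b", {}, static={"elevation": 130.0})
        d, t = pairwise_ds(x, y, "elevation")
        assert d == pytest.approx(30.0) and t == 1

    def test_undefined_below_overlap_threshold(self):
        x = make_clim("a", {"ta": full_series(np.arange(10))})
        y = make_clim("b", {"ta": full_series(np.arange(10) + 1)})
        d, t = pairwise_ds(x, y, "ta", t_min=30)
        assert np.isnan(d) and t == 10

    def test_symmetry_and_triangle_inequality(self, rng):
        """On shared-coverage random climatologies, ds is a metric."""
        for _ in range(25):
            clims = [
                make_clim(str(i), {"ta": full_series(rng.normal(size=90))})
                for i in range(3)
            ]
            d = {
                (i, j): pairwise_ds(clims[i], clims[j], "ta", t_min=30)[0]
                for i in range(3)
                for j in range(3)
            }
            assert d[(0, 1)] == pytest.approx(d[(1, 0)], rel=1e-12)
            assert d[(0, 2)] <= d[(0, 1)] + d[(1, 2)] + 1e-12


class TestTrainingSetDistance:
    def test_mean_of_pairwise(self):
        x = make_clim("x", {"ta": full_series([0.0] * 40)})
        trains = [
            make_clim(str(v), {"ta": full_series([v / np.sqrt(40)] * 40)})
            for v in (1.0, 2.0, 6.0)
        ]
        d = training_set_distance(x, trains, "ta", t_min=30)
        assert d == pytest.approx(3.0, rel=1e-12)

    def test_single_training_station_is_its_ds(self):
        x = make_clim("x", {"ta": full_series([1.0, 2.0])})
        y = make_clim("y", {"ta": full_series([4.0, 6.0])})
        assert training_set_distance(x, [y], "ta", t_min=2) == pytest.approx(5.0)

    def test_cache_matches_bruteforce(self, registry, small_climatologies):
        """The precomputed distance cache agrees with the direct per-pair
        computation to 1e-12."""
        cache = DistanceCache(small_climatologies, registry)
        sids = list(small_climatologies)
        x = sids[0]
        train = sids[1:5]
        for factor in ("ta", "fpar", "elevation"):
            brute = training_set_distance(
                small_climatologies[x],
                [small_climatologies[t] for t in train],
                factor,
            )
            assert cache.training_set_distance(x, train, factor) == pytest.approx(
                brute, rel=1e-12
            )


def dataset1_frame(X, y, names):
    df = pd.DataFrame(X, columns=[f"d_{n}" for n in names])
    df["r2"] = y
    return df


class TestFitRsm:
    def test_exact_linear_data_recovered(self, registry, rng):
        names = registry.feature_names("WRS")
        X = np.abs(rng.normal(size=(40, len(names))))
        y = 0.9 - 0.05 * X[:, 0] - 0.02 * X[:, 1]
        rsm = fit_rsm(dataset1_frame(X, y, names), registry, "WRS", "Overall", "NEE")
        assert rsm.intercept == pytest.approx(0.9, abs=1e-8)
        assert rsm.coefficients[0] == pytest.approx(-0.05, abs=1e-8)
        assert rsm.coefficients[1] == pytest.approx(-0.02, abs=1e-8)
        assert abs(rsm.coefficients[2:]).max() < 1e-8
        assert rsm.r2_rsm == pytest.approx(1.0)

    def test_constant_response_gives_zero_slopes(self, registry, rng):
        names = registry.feature_names("WRS")
        X = np.abs(rng.normal(size=(30, len(names))))
        rsm = fit_rsm(
            dataset1_frame(X, np.full(30, 0.7), names),
            registry, "WRS", "Overall", "WF",
        )
        assert rsm.intercept == pytest.approx(0.7, abs=1e-9)
        assert abs(rsm.coefficients).max() < 1e-9

    def test_matches_normal_equations_oracle(self, registry, rng):
        """OLS coefficients equal the closed-form (X'X)^-1 X'y solution."""
        names = registry.feature_names("WRS")[:3]
        sub_registry = default_registry()
        X = np.abs(rng.normal(size=(50, len(sub_registry.feature_names("WRS")))))
        y = rng.normal(size=50)
        # oracle on the first three factors; make the rest exact collinear
        # copies is unnecessary — fit the full frame, compare on the design
        df = dataset1_frame(X, y, sub_registry.feature_names("WRS"))
        rsm = fit_rsm(df, sub_registry, "WRS", "Overall", "NEE", max_vif=None)
        design = np.column_stack([np.ones(50), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert rsm.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(rsm.coefficients, beta[1:], atol=1e-8)

    def test_fitted_mean_equals_observed_mean(self, registry, rng):
        """Intercept OLS reproduces the mean response exactly."""
        names = registry.feature_names("WRS")
        X = np.abs(rng.normal(size=(60, len(names))))
        y = rng.uniform(-0.5, 1.0, size=60)
        rsm = fit_rsm(dataset1_frame(X, y, names), registry, "WRS", "Overall", "NEE")
        fitted = rsm.intercept + X @ rsm.coefficients
        assert fitted.mean() == pytest.approx(y.mean(), abs=1e-9)

    def test_collinear_column_dropped_and_fit_proceeds(self, registry, rng):
        names = registry.feature_names("WRS")
        X = np.abs(rng.normal(size=(40, len(names))))
        X[:, 1] = 2.0 * X[:, 0]  # exact collinearity
        y = 0.8 - 0.1 * X[:, 0]
        rsm = fit_rsm(dataset1_frame(X, y, names), registry, "WRS", "Overall", "NEE")
        assert len(rsm.dropped) >= 1
        pred = rsm.intercept + X @ rsm.coefficients
        np.testing.assert_allclose(pred, y, atol=1e-8)

    def test_too_few_samples_rejected(self, registry, rng):
        names = registry.feature_names("WRS")
        X = np.abs(rng.normal(size=(5, len(names))))
        with pytest.raises(ValueError):
            fit_rsm(dataset1_frame(X, np.ones(5), names), registry, "WRS", "O", "NEE")


class TestPredictAndClassify:
    @staticmethod
    def rsm_with(intercept, coefs):
        coefs = np.asarray(coefs, dtype=float)
        return RSModel(
            category="Overall", scenario="WRS", target="NEE",
            intercept=intercept, coefficients=coefs,
            factor_names=tuple(f"f{i}" for i in range(len(coefs))),
            dropped=(), n_samples=10, r2_rsm=0.5, adj_r2=0.4,
            f_stat=1.0, p_value=0.5,
        )

    def test_dot_product_arithmetic(self):
        assert predict_r2(self.rsm_with(0.8, [-0.1]), [2.0]) == pytest.approx(0.6)
        assert predict_r2(self.rsm_with(0.9, [-0.05, -0.02]), [4.0, 5.0]) == pytest.approx(0.6)

    def test_zero_distances_give_intercept(self):
        assert predict_r2(self.rsm_with(0.83, [-0.1, -0.2]), [0.0, 0.0]) == pytest.approx(0.83)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            predict_r2(self.rsm_with(0.8, [-0.1]), [1.0, 2.0])

    @pytest.mark.parametrize(
        "r2, cls",
        [(0.49, 1), (0.5, 2), (0.69, 2), (0.7, 3), (0.95, 3), (-0.3, 1)],
    )
    def test_quality_class_boundaries(self, r2, cls):
        assert quality_class(r2) == cls

    def test_classification_accuracy_hand_example(self):
        # classes (1,2,3) vs (1,2,2) -> 2/3
        acc = classification_accuracy([0.4, 0.6, 0.8], [0.45, 0.65, 0.55])
        assert acc == pytest.approx(2 / 3)

    def test_perfect_prediction_full_accuracy(self, rng):
        r2 = rng.uniform(0, 1, size=50)
        assert classification_accuracy(r2, r2) == 1.0
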