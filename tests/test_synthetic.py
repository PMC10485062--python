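"""Synthetic station-network generator: calendars, determinism, flux truth,
missingness structure and the out-of-distribution contract."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

from fluxbridge import (
    DistanceCache,
    NetworkConfig,
    build_climatologies,
    compute_vpd,
    generate_network,
    inject_missing,
)
from fluxbridge.preprocess import add_vpd
from fluxbridge.synthetic import uniform_category_mix


class TestGenerateNetwork:
    def test_one_record_per_calendar_day(self):
        cfg = NetworkConfig(n_flux_stations=6, n_met_stations=4, years=(2010,), seed=1)
        _, records, _ = generate_network(cfg)
        assert records["station_id"].nunique() == 10
        assert (records.groupby("station_id").size() == 365).all()

    def test_leap_day_generated(self, small_network):
        _, _, records, _ = small_network  # 2012 is a leap year
        assert (records["doy"] == 366).any()
        assert (records.groupby("station_id").size() == 366).all()

    def test_same_seed_identical_different_seed_differs(self):
        cfg = NetworkConfig(n_flux_stations=4, n_met_stations=2, years=(2011,), seed=7)
        _, a, _ = generate_network(cfg)
        _, b, _ = generate_network(cfg)
        pd.testing.assert_frame_equal(a, b)
        cfg2 = NetworkConfig(n_flux_stations=4, n_met_stations=2, years=(2011,), seed=8)
        _, c, _ = generate_network(cfg2)
        assert not a["ta"].equals(c["ta"])

    def test_met_stations_carry_no_fluxes(self, small_network):
        _, metas, records, _ = small_network
        met_ids = {m.station_id for m in metas if m.role == "meteorological"}
        met = records[records["station_id"].isin(met_ids)]
        assert met["nee"].isna().all() and met["wf"].isna().all()
        flux = records[~records["station_id"].isin(met_ids)]
        assert flux["nee"].notna().all()

    def test_zero_noise_fluxes_equal_closed_form(self):
        """With the noise switched off, NEE and WF are exact functions of the
        emitted covariates and the latent parameters."""
        cfg = NetworkConfig(
            n_flux_stations=4, n_met_stations=1, years=(2010,),
            noise_sd_nee=0.0, noise_sd_wf=0.0, seed=3,
        )
        metas, records, truths = generate_network(cfg)
        for m in metas:
            if m.role != "flux":
                continue
            blk = records[records["station_id"] == m.station_id]
            t = truths[m.station_id]
            vpd = compute_vpd(blk["ta"].to_numpy(), blk["td"].to_numpy())
            nee = t.nee(blk["dsr"].to_numpy(), blk["fpar"].to_numpy(), vpd, blk["ta"].to_numpy())
            wf = t.wf(blk["dsr"].to_numpy(), blk["fpar"].to_numpy(), vpd)
            np.testing.assert_allclose(blk["nee"].to_numpy(), nee, rtol=1e-12)
            np.testing.assert_allclose(blk["wf"].to_numpy(), wf, rtol=1e-12)

    def test_multi_year_wf_means_positive(self, small_network):
        _, metas, records, _ = small_network
        flux_ids = [m.station_id for m in metas if m.role == "flux"]
        means = records[records["station_id"].isin(flux_ids)].groupby("station_id")["wf"].mean()
        assert (means > 0).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(years=())
        with pytest.raises(ValueError):
            NetworkConfig(missing_rate=1.5)
        bad_mix = {k: v * 2 for k, v in uniform_category_mix().items()}
        with pytest.raises(ValueError):
            NetworkConfig(category_mix=bad_mix)

    def test_zero_noise_nonlinear_fit_recovers_parameters(self):
        """A per-station fit of the light-response/Q10 form on noiseless data
        recovers the generating amplitude and base respiration within 1%."""
        cfg = NetworkConfig(
            n_flux_stations=3, n_met_stations=1, years=(2010, 2011),
            noise_sd_nee=0.0, noise_sd_wf=0.0, seed=13,
        )
        metas, records, truths = generate_network(cfg)
        m = next(m for m in metas if m.role == "flux")
        blk = records[records["station_id"] == m.station_id]
        t = truths[m.station_id]
        vpd = compute_vpd(blk["ta"].to_numpy(), blk["td"].to_numpy())
        X = np.vstack([blk["dsr"], blk["fpar"], vpd, blk["ta"]])

        def form(x, gpp_max, r0):
            dsr, fpar, vpd_, ta = x
            return (
                -gpp_max * dsr / (dsr + t.k_i) * fpar * np.exp(-t.k_v * vpd_)
                + r0 * t.q10 ** ((ta - 10.0) / 10.0)
            )

        popt, _ = curve_fit(form, X, blk["nee"].to_numpy(), p0=[5.0, 1.0])
        assert popt[0] == pytest.approx(t.gpp_max, rel=0.01)
        assert popt[1] == pytest.approx(t.r0, rel=0.01)


class TestInjectMissing:
    def test_zero_rate_is_identity(self, small_network):
        _, _, records, _ = small_network
        out = inject_missing(records, 0.0, 7, seed=1)
        pd.testing.assert_frame_equal(out, records)

    def test_rate_within_binomial_band(self):
        cfg = NetworkConfig(n_flux_stations=1, n_met_stations=1,
                            years=tuple(range(2006, 2016)), seed=5)
        _, records, _ = generate_network(cfg)
        out = inject_missing(records, 0.10, 7, seed=2)
        one = out[out["station_id"] == out["station_id"].iloc[0]]
        n_missing = one["fpar"].isna().sum()
        assert 365 - 73 <= n_missing <= 365 + 73  # 3650 days at 10%

    def test_no_run_exceeds_max_gap(self):
        cfg = NetworkConfig(n_flux_stations=2, n_met_stations=1,
                            years=(2010, 2011, 2012), seed=9)
        _, records, _ = generate_network(cfg)
        out = inject_missing(records, 0.15, 7, seed=3)
        for _, blk in out.groupby("station_id"):
            isna = blk["evi"].isna().to_numpy()
            run, longest = 0, 0
            for flag in isna:
                run = run + 1 if flag else 0
                longest = max(longest, run)
            assert longest <= 7

    def test_long_gap_flag_inserts_overlong_runs(self):
        cfg = NetworkConfig(n_flux_stations=1, n_met_stations=1, years=(2010,), seed=4)
        _, records, _ = generate_network(cfg)
        out = inject_missing(records, 0.0, 7, seed=6, n_long_gaps=1)
        blk = out[out["station_id"] == out["station_id"].iloc[0]]
        isna = blk["fpar"].isna().to_numpy()
        runs, run = [], 0
        for flag in isna:
            run = run + 1 if flag else 0
            if run:
                runs.append(run)
        assert max(runs) == 10  # max_gap_days + 3

    def test_fluxes_never_removed(self, small_network):
        _, metas, records, _ = small_network
        out = inject_missing(records, 0.2, 7, seed=8)
        assert out["nee"].isna().sum() == records["nee"].isna().sum()
        assert out["ta"].isna().sum() == records["ta"].isna().sum()


class TestOODContract:
    def test_ood_station_is_farther_from_flux_pool(self, registry):
        """A met station shifted two offset-sd out sits farther (mean
        per-factor distance) from the flux pool than an unshifted one, in
        nearly all seeds."""
        hits = 0
        trials = 20
        for seed in range(trials):
            cfg = NetworkConfig(
                n_flux_stations=8, n_met_stations=2, years=(2010,),
                ood_shift=2.0, n_ood_met_stations=1, seed=100 + seed,
            )
            metas, records, _ = generate_network(cfg)
            clims = build_climatologies(add_vpd(records), registry)
            cache = DistanceCache(clims, registry)
            flux_ids = [m.station_id for m in metas if m.role == "flux"]
            met = {m.is_ood: m.station_id for m in metas if m.role == "meteorological"}
            names = registry.daily_names()

            def mean_dist(sid):
                return np.nanmean(
                    [cache.training_set_distance(sid, flux_ids, f) for f in names]
                )

            hits += mean_dist(met[True]) > mean_dist(met[False])
        assert hits >= 0.95 * trials
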