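"""Lagged log-log regression of indoor on outdoor concentration."""

import numpy as np
import pandas as pd
import pytest

import classair as ca

from conftest import START


def windows_from(values, start=START, location="indoor"):
    values = np.asarray(values, dtype=float)
    ws = pd.DatetimeIndex(start + pd.to_timedelta(np.arange(len(values)) * 30, unit="m"))
    return ca.WindowedSeries(ws, values, np.ones(len(values)),
                             pd.Timedelta(minutes=30), "total_ufp", location)


def make_design(n=500, beta_outdoor=1.0, beta_hepa=-1.2, noise_sd=0.1,
                schools=("A", "B"), seed=0):
    """Rows generated exactly from the log-log model."""
    rng = np.random.default_rng(seed)
    school = rng.choice(schools, n)
    school_effect = {s: 0.3 * i for i, s in enumerate(sorted(set(schools)))}
    hepa = rng.integers(0, 2, n)
    log_out = np.log(rng.uniform(1000, 20000, n))
    log_in = (
        np.array([school_effect[s] for s in school])
        + beta_outdoor * log_out
        + beta_hepa * hepa
        + rng.normal(0, noise_sd, n)
    )
    return ca.RegressionDesign(pd.DataFrame({
        "log_indoor": log_in,
        "log_outdoor_lagged": log_out,
        "hepa": hepa,
        "school": school,
    }))


class TestBuildDesign:
    def test_all_zero_indoor_errors(self):
        indoor = windows_from(np.zeros(20))
        outdoor = windows_from(np.full(20, 5000.0), location="outdoor")
        with pytest.raises(ValueError, match="nonpositive"):
            ca.build_design(indoor, outdoor, [], school="E")

    def test_zero_lag_identity(self):
        vals = np.linspace(1000, 5000, 10)
        indoor = windows_from(vals)
        outdoor = windows_from(vals, location="outdoor")
        hepa = [(START, START + pd.Timedelta(hours=5), 850.0)]
        d = ca.build_design(indoor, outdoor, hepa, school="A",
                            lag=pd.Timedelta(0))
        np.testing.assert_allclose(d.frame["log_indoor"],
                                   d.frame["log_outdoor_lagged"])
        assert d.dropped_zero_rows == 0

    def test_lag_shifts_pairing(self):
        outdoor = windows_from(np.arange(1, 11, dtype=float), location="outdoor")
        indoor = windows_from(np.arange(101, 111, dtype=float))
        d = ca.build_design(indoor, outdoor, [], school="A",
                            lag=pd.Timedelta(minutes=30))
        # indoor window t pairs with outdoor window t-30min
        assert len(d) == 9
        np.testing.assert_allclose(
            np.exp(d.frame["log_outdoor_lagged"]), np.arange(1, 10))
        np.testing.assert_allclose(np.exp(d.frame["log_indoor"]),
                                   np.arange(102, 111))

    def test_row_count_on_simulated_session(self, quiet_zone):
        sim = ca.simulate_session(quiet_zone, duration_h=12, seed=3)
        wi = ca.window_average(sim.indoor)
        wo = ca.window_average(sim.outdoor)
        d = ca.build_design(wi, wo, [], school="A")
        alignable = len(
            set(wi.window_starts) & set(wo.window_starts + pd.Timedelta(minutes=30))
        )
        assert len(d) == alignable - d.dropped_zero_rows

    def test_zero_rows_dropped_and_flagged(self):
        vals = np.full(20, 3000.0)
        vals[:6] = 0.0  # 30% of rows unusable
        indoor = windows_from(vals)
        outdoor = windows_from(np.full(20, 5000.0), location="outdoor")
        with pytest.warns(UserWarning, match="dropped"):
            d = ca.build_design(indoor, outdoor, [], school="E",
                                lag=pd.Timedelta(0))
        assert d.dropped_zero_rows == 6
        assert d.flagged_schools == ("E",)


class TestFitLogLog:
    def test_recovers_hepa_coefficient(self):
        fit = ca.fit_loglog(make_design(beta_hepa=-1.2, seed=1))
        assert fit.beta_hepa == pytest.approx(-1.2, abs=0.05)
        assert fit.beta_outdoor == pytest.approx(1.0, abs=0.05)

    def test_noiseless_slope_exact(self):
        fit = ca.fit_loglog(make_design(noise_sd=0.0, seed=2))
        assert fit.beta_outdoor == pytest.approx(1.0, abs=1e-9)
        assert fit.beta_hepa == pytest.approx(-1.2, abs=1e-9)

    def test_constant_hepa_column_rejected(self):
        d = make_design(seed=3)
        d.frame["hepa"] = 0
        with pytest.raises(ValueError, match="hepa"):
            ca.fit_loglog(d)

    def test_school_effects_relative_to_reference(self):
        fit = ca.fit_loglog(make_design(noise_sd=0.0, schools=("A", "B", "C"), seed=4))
        eff = fit.school_effects
        assert eff["A"] == 0.0
        assert eff["B"] == pytest.approx(0.3, abs=1e-8)
        assert eff["C"] == pytest.approx(0.6, abs=1e-8)

    def test_row_permutation_leaves_coefficients(self):
        d = make_design(seed=5)
        fit1 = ca.fit_loglog(d)
        rng = np.random.default_rng(0)
        perm = ca.RegressionDesign(
            d.frame.sample(frac=1, random_state=1).reset_index(drop=True))
        fit2 = ca.fit_loglog(perm)
        np.testing.assert_allclose(fit1.params, fit2.params, rtol=1e-9)

    def test_too_few_rows_rejected(self):
        d = make_design(n=6, schools=("A",), seed=6)
        with pytest.raises(ValueError, match="rows"):
            ca.fit_loglog(d)


class TestPredictIndoor:
    def test_identity_model_returns_outdoor_level(self):
        fit = ca.fit_loglog(make_design(beta_outdoor=1.0, beta_hepa=-1.0,
                                        schools=("A",), noise_sd=0.0, seed=7))
        point, lo, hi = fit.predict_indoor(5000.0, school="A", hepa=0)
        assert point == pytest.approx(5000.0, rel=1e-6)
        assert lo <= point <= hi

    def test_hepa_scales_prediction_by_exp_beta(self):
        fit = ca.fit_loglog(make_design(beta_hepa=np.log(0.29), noise_sd=0.05, seed=8))
        off, _, _ = fit.predict_indoor(5000.0, school="A", hepa=0)
        on, _, _ = fit.predict_indoor(5000.0, school="A", hepa=1)
        assert on / off == pytest.approx(np.exp(fit.beta_hepa), rel=1e-9)

    def test_unknown_school_error(self):
        fit = ca.fit_loglog(make_design(seed=9))
        with pytest.raises(ValueError, match="school"):
            fit.predict_indoor(5000.0, school="Z")

    def test_prediction_brackets_simulated_steady_state(self, quiet_zone):
        # at outdoor 5000 #/cc the model-implied indoor level is
        # steady_state_ratio * 5000; with a clean, slowly varying outdoor
        # driver (so the lagged pairing is exact) and window-level indoor
        # measurement noise, the prediction CI brackets it
        cadr = ca.cfm_to_m3h(500)
        day = pd.Timedelta(days=1)
        src = ca.OutdoorSourceConfig(diurnal_amplitude=2000, plume_rate=0.0,
                                     noise_cv=0.0, drift_sd=0.0)
        expected = quiet_zone.steady_state_ratio(0.0) * 5000.0
        covered = 0
        for rep in range(10):
            rng = np.random.default_rng(900 + rep)
            out_off = ca.simulate_outdoor(src, 24, 10, seed=900 + rep)
            in_off = ca.simulate_indoor(out_off, quiet_zone)
            out_on = ca.simulate_outdoor(src, 24, 10, seed=950 + rep,
                                         start=START + day)
            on_iv = [(START + day, START + 2 * day, cadr)]
            in_on = ca.simulate_indoor(out_on, quiet_zone, on_iv)

            def noisy_windows(s):
                w = ca.window_average(s)
                w.means = w.means * rng.lognormal(-0.5 * 0.05**2, 0.05, len(w))
                return w

            d_off = ca.build_design(noisy_windows(in_off),
                                    ca.window_average(out_off), [], school="A")
            d_on = ca.build_design(noisy_windows(in_on),
                                   ca.window_average(out_on), on_iv, school="A")
            fit = ca.HepaLogLogModel.from_designs([d_off, d_on]).fit()
            _, lo, hi = fit.predict_indoor(5000.0, school="A", hepa=0)
            covered += lo <= expected <= hi
        assert covered >= 9


class TestRegressionEffectiveness:
    def test_zero_coefficient_zero_effect(self):
        fit = ca.fit_loglog(make_design(beta_hepa=0.0, noise_sd=0.05, seed=10))
        res = ca.regression_effectiveness(fit)
        assert res.effectiveness == pytest.approx(0.0, abs=0.05)

    def test_log029_gives_71_percent(self):
        fit = ca.fit_loglog(make_design(beta_hepa=np.log(0.29), noise_sd=0.0, seed=11))
        res = ca.regression_effectiveness(fit)
        assert res.effectiveness == pytest.approx(0.71, abs=1e-9)
        assert res.ci_low <= res.effectiveness <= res.ci_high

    def test_recovery_on_simulated_sessions(self):
        # true effectiveness 0.63 under 500-CFM cleaning of a 250-m3 room
        zone = ca.ZoneConfig(volume=250, aer=1.5, deposition=0.5)
        cadr = ca.cfm_to_m3h(500)
        truth = 1 - zone.steady_state_ratio(cadr) / zone.steady_state_ratio(0.0)
        covered, errs = 0, []
        day = pd.Timedelta(days=1)
        for rep in range(10):
            off = ca.simulate_session(zone, duration_h=24, seed=400 + rep)
            on = ca.simulate_session(zone, duration_h=24, seed=800 + rep,
                                     start=START + day,
                                     hepa_intervals=[(START + day, START + 2 * day, cadr)])
            d_off = ca.build_design(ca.window_average(off.indoor),
                                    ca.window_average(off.outdoor), [], school="A")
            d_on = ca.build_design(ca.window_average(on.indoor),
                                   ca.window_average(on.outdoor),
                                   [(START + day, START + 2 * day, cadr)], school="A")
            res = ca.HepaLogLogModel.from_designs([d_off, d_on]).fit().effectiveness()
            errs.append(abs(res.effectiveness - truth))
            covered += res.ci_low <= truth <= res.ci_high
        assert np.median(errs) < 0.05
        assert covered >= 8

    def test_ratio_and_regression_routes_agree(self):
        zone = ca.ZoneConfig(volume=250, aer=1.5, deposition=0.5)
        cadr = ca.cfm_to_m3h(500)
        day = pd.Timedelta(days=1)
        off = ca.simulate_session(zone, duration_h=24, seed=55)
        on = ca.simulate_session(zone, duration_h=24, seed=56, start=START + day,
                                 hepa_intervals=[(START + day, START + 2 * day, cadr)])
        wi_off, wo_off = ca.window_average(off.indoor), ca.window_average(off.outdoor)
        wi_on, wo_on = ca.window_average(on.indoor), ca.window_average(on.outdoor)
        before = ca.compute_infiltration(wi_off, wo_off, "off", seed=1)
        after = ca.compute_infiltration(wi_on, wo_on, "on", seed=1)
        eff_ratio = ca.compute_effectiveness(before, after, seed=1)
        d_off = ca.build_design(wi_off, wo_off, [], school="A")
        d_on = ca.build_design(wi_on, wo_on,
                               [(START + day, START + 2 * day, cadr)], school="A")
        eff_reg = ca.HepaLogLogModel.from_designs([d_off, d_on]).fit().effectiveness()
        assert abs(eff_ratio.effectiveness - eff_reg.effectiveness) < 0.05
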