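import numpy as np
import pandas as pd
import pytest

import pelagia as pg
from pelagia.trends import (ActivityTrendModel, _whiten, build_activity_panel,
                            quasiflightless_summary)


def flat_trend(dsd):
    dsd = np.asarray(dsd, dtype=float)
    one = np.ones_like(dsd)
    return np.stack([0.15 * one, 0.62 * one, 0.20 * one], axis=-1)


def logit_ar_panel(n_birds=10, n_days=120, rho=0.6, sd=0.6, seed=0):
    """Panel whose float response is AR(1) on the logit scale by construction
    (well-specified for the corExp working model)."""
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_birds):
        eps = np.zeros(n_days)
        eps[0] = rng.normal(0, sd)
        for t in range(1, n_days):
            eps[t] = rho * eps[t - 1] + rng.normal(0, sd * np.sqrt(1 - rho ** 2))
        dsd = np.arange(n_days)
        mu = 1 / (1 + np.exp(-(0.4 + eps)))
        rows.append(pd.DataFrame({
            "bird_id": f"b{b}", "species": ["LAAL", "BFAL"][b % 2], "dsd": dsd,
            "phase": np.where(dsd < 10, "outbound",
                              np.where(dsd >= n_days - 9, "inbound",
                                       "overwinter")),
            "float_prop": np.clip(mu, 1e-3, 1 - 1e-3),
            "flight_prop": 0.1, "forage_prop": 0.1, "flight_any": 1,
            "daily_km": 60.0, "excluded_min": 0.0}))
    return pd.concat(rows, ignore_index=True)


class TestValidation:
    def test_requires_two_birds_and_50_days(self):
        p = pg.simulate_activity_panel(n_birds=1, n_days=100, seed=0)
        with pytest.raises(ValueError):
            ActivityTrendModel(p, "float")
        p2 = pg.simulate_activity_panel(n_birds=4, n_days=10, seed=0)
        with pytest.raises(ValueError):
            ActivityTrendModel(p2, "float")
        with pytest.raises(ValueError):
            ActivityTrendModel(pg.simulate_activity_panel(seed=0), "altitude")


class TestRecovery:
    def test_u_shaped_flight_trend_minimum_recovered(self):
        """Injected flight minimum at DSD 50 is found inside [40, 60]."""
        panel = pg.simulate_activity_panel(n_birds=12, n_days=145, seed=10)
        res = ActivityTrendModel(panel, "flight_hurdle").fit()
        fitted = res.expected_flight(panel)
        per_dsd = pd.DataFrame({"dsd": panel["dsd"], "f": fitted}) \
            .groupby("dsd")["f"].mean()
        assert 40 <= per_dsd.idxmin() <= 60

    def test_species_null_eliminated_on_constant_panel(self):
        panel = pg.simulate_activity_panel(n_birds=12, n_days=145, seed=2,
                                           trend_shape=flat_trend)
        res = ActivityTrendModel(panel, "float").fit()
        assert not res.has_term("species")
        assert not res.has_term("s(dsd):species")

    def test_smooth_frame_provides_ci_band(self):
        panel = pg.simulate_activity_panel(n_birds=8, n_days=120, seed=4)
        res = ActivityTrendModel(panel, "float").fit(select=False)
        sf = res.smooth_frame(species="LAAL")
        assert (sf["eta_lo"] < sf["eta"]).all()
        assert (sf["eta"] < sf["eta_hi"]).all()
        assert ((sf["prop"] >= 0) & (sf["prop"] <= 1)).all()

    def test_fitted_proportions_in_unit_interval(self):
        panel = pg.simulate_activity_panel(n_birds=8, n_days=120, seed=4)
        res = ActivityTrendModel(panel, "forage").fit(select=False)
        assert ((res.fittedvalues >= 0) & (res.fittedvalues <= 1)).all()


class TestHurdle:
    def test_all_zero_flight_skips_positive_stage(self):
        panel = pg.simulate_activity_panel(n_birds=6, n_days=100, seed=2)
        panel["flight_prop"] = 0.0
        panel["flight_any"] = 0
        res = ActivityTrendModel(panel, "flight_hurdle").fit(select=False)
        assert res.positive is None
        assert any("skipped" in d for d in res.diagnostics)
        assert res.binary is not None

    def test_hurdle_expectation_consistent_with_observed_mean(self):
        panel = pg.simulate_activity_panel(n_birds=12, n_days=120, seed=6)
        res = ActivityTrendModel(panel, "flight_hurdle").fit(select=False)
        expected = res.expected_flight(panel)
        assert np.nanmean(expected) == pytest.approx(
            panel["flight_prop"].mean(), abs=0.05)
        assert "Hurdle" in res.summary()


class TestSelection:
    def test_trace_is_monotone_never_readds(self):
        panel = pg.simulate_activity_panel(n_birds=12, n_days=145, seed=3,
                                           trend_shape=flat_trend)
        res = ActivityTrendModel(panel, "float").fit()
        dropped = [s["dropped"] for s in res.selection_trace]
        assert len(dropped) == len(set(dropped))
        for name in dropped:
            assert not res.has_term(name)

    def test_retained_terms_all_significant(self):
        panel = pg.simulate_activity_panel(n_birds=12, n_days=145, seed=3)
        res = ActivityTrendModel(panel, "float").fit(alpha=0.05)
        droppable = res.term_table  # table only holds retained terms
        # every droppable retained term is significant at alpha
        names = {t.name: t for t in res.design.terms}
        for _, row in droppable.iterrows():
            t = names[row["term"]]
            if t.droppable and not any(row["term"] in o.requires
                                       for o in res.design.terms):
                assert row["p"] <= 0.05


class TestTemporalCorrelation:
    def test_corexp_range_recovered_on_ar_panel(self):
        panel = logit_ar_panel(rho=0.6, seed=0)
        res = ActivityTrendModel(panel, "float").fit(select=False)
        true_range = -1.0 / np.log(0.6)  # ~1.96 days
        assert res.corr_range is not None
        assert 0.4 * true_range < res.corr_range < 2.5 * true_range

    def test_whitening_reduces_lag1_residual_correlation(self):
        panel = logit_ar_panel(rho=0.6, seed=1)
        res = ActivityTrendModel(panel, "float").fit(select=False)
        fit = res.fit
        y = np.clip(panel["float_prop"].values, 1e-6, 1 - 1e-6)
        mu = fit["mu"]
        w = np.clip(mu * (1 - mu), 1e-5, None)
        e = (y - mu) / w

        def lag1(v):
            codes = pd.factorize(panel["bird_id"])[0]
            ok = (np.diff(panel["dsd"].values) == 1) & (np.diff(codes) == 0)
            return abs(np.corrcoef(v[:-1][ok], v[1:][ok])[0, 1])

        codes = panel["bird_id"].values
        ew, _ = _whiten(e[:, None], e, w, pd.factorize(codes)[0],
                        panel["dsd"].values.astype(float),
                        fit["sigma_b2"], fit["phi"], fit["corr_range"])
        assert lag1(ew[:, 0]) < lag1(e * np.sqrt(w))


class TestQuasiFlightless:
    def test_full_float_window_counts_equal_window_length(self):
        days = np.arange(20, 90)
        panel = pd.DataFrame({
            "bird_id": "b0", "species": "LAAL", "dsd": days,
            "phase": "overwinter", "flight_prop": 0.0, "float_prop": 1.0,
            "forage_prop": 0.0, "flight_any": 0, "daily_km": 10.0,
            "excluded_min": 0.0})
        qf = quasiflightless_summary(panel, window=(30, 70))
        row = qf.per_bird.iloc[0]
        assert row["n_days"] == 41
        assert row["zero_flight_days"] == 41
        assert row["all_float_days"] == 41

    def test_threshold_boundaries_strict(self):
        panel = pd.DataFrame({
            "bird_id": "b0", "species": "LAAL", "dsd": [40, 41],
            "phase": "overwinter", "flight_prop": [0.05, 0.0],
            "float_prop": [0.85, 0.95], "forage_prop": [0.1, 0.05],
            "flight_any": [1, 0], "daily_km": 10.0, "excluded_min": 0.0})
        qf = quasiflightless_summary(panel)
        row = qf.per_bird.iloc[0]
        assert row["float_gt80_days"] == 2
        assert row["float_gt90_days"] == 1  # 0.85 counts >80% but not >90%
        assert row["zero_flight_days"] == 1

    def test_window_outside_range_warns_and_empties(self):
        panel = pd.DataFrame({
            "bird_id": "b0", "species": "LAAL", "dsd": [0, 1, 2],
            "phase": "outbound", "flight_prop": 0.2, "float_prop": 0.6,
            "forage_prop": 0.2, "flight_any": 1, "daily_km": 100.0,
            "excluded_min": 0.0})
        with pytest.warns(UserWarning):
            qf = quasiflightless_summary(panel, window=(30, 70))
        assert len(qf.cohort) == 0

    def test_cohort_scale_matches_study_regime(self):
        """Under study-like conditions the mean number of zero-flight days in
        the 30-70 DSD window is in the tens of days (field scale ~21-25)."""
        panel = pg.simulate_activity_panel(n_birds=12, n_days=145, seed=5)
        qf = quasiflightless_summary(panel)
        assert (qf.cohort["zero_flight_mean"] > 10).all()
        assert (qf.cohort["zero_flight_mean"] < 41).all()


class TestBuildPanel:
    def test_panel_from_budgets_and_records(self, bird0, bird0_budget):
        rec = pg.phenology_from_track(bird0["track"], bird0["cfg"].colony)
        budgets = bird0_budget["budget"]
        panel = build_activity_panel(budgets, {"bird00": rec},
                                     {"bird00": "LAAL"})
        assert (panel["phase"] != "").all()
        assert panel["dsd"].min() == 0
        assert (panel["flight_any"] == (panel["flight_prop"] > 0)).all()


class TestExternalCrossCheck:
    def test_smooth_agrees_with_mgcv_reference(self, tmp_path):
        """The penalized-spline fit matches an independent mgcv quasi-binomial
        GAM on a panel without bird-level structure."""
        import subprocess
        rng = np.random.default_rng(12)
        n_days = 140
        rows = []
        for b in range(4):
            dsd = np.arange(n_days)
            mu = 1 / (1 + np.exp(-(0.5 - 1.8 * np.exp(-((dsd - 60) / 25.0) ** 2))))
            y = np.clip(mu + 0.08 * rng.normal(size=n_days), 1e-3, 1 - 1e-3)
            rows.append(pd.DataFrame({
                "bird_id": f"b{b}", "species": "LAAL", "dsd": dsd,
                "phase": np.where(dsd < 10, "outbound",
                                  np.where(dsd >= 130, "inbound", "overwinter")),
                "float_prop": y, "flight_prop": 0.1, "forage_prop": 0.1,
                "flight_any": 1, "daily_km": 50.0, "excluded_min": 0.0}))
        panel = pd.concat(rows, ignore_index=True)
        res = ActivityTrendModel(panel, "float",
                                 use_temporal_corr=False).fit(select=False)
        grid = pd.DataFrame({"dsd": np.arange(n_days, dtype=float),
                             "species": "LAAL", "phase": "overwinter"})
        mine = res.predict(grid)

        csv = tmp_path / "panel.csv"
        out = tmp_path / "pred.csv"
        panel[["dsd", "float_prop"]].to_csv(csv, index=False)
        rscript = (
            f"d <- read.csv('{csv}');"
            "library(mgcv);"
            "m <- gam(float_prop ~ s(dsd, k=10), family=quasibinomial, data=d);"
            f"p <- predict(m, newdata=data.frame(dsd=0:{n_days - 1}),"
            " type='response');"
            f"write.csv(data.frame(p=p), '{out}', row.names=FALSE)")
        subprocess.run(["Rscript", "-e", rscript], check=True,
                       capture_output=True)
        theirs = pd.read_csv(out)["p"].values
        assert np.corrcoef(mine, theirs)[0, 1] > 0.98
        assert np.mean(np.abs(mine - theirs)) < 0.03
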