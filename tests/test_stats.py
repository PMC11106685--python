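"""Aggregation, mixed / count models, LRT, ratios and the cluster bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from floralwastage.stats import (
    EstimateError,
    FitError,
    aggregate_means,
    cluster_bootstrap,
    fit_count_model,
    fit_lmm,
    lrt,
    summarize_residual_nectar,
    wastage_ratio,
)


def _cell_frame(y, **labels):
    base = {
        "year": "2021", "site": "S1", "day": "D1", "period": "T1",
        "location": "edge", "treatment": "accessible",
    }
    base.update(labels)
    n = len(y)
    out = {k: (v if isinstance(v, (list, np.ndarray, pd.Series)) else [v] * n)
           for k, v in base.items()}
    out["mean_rate"] = y
    return pd.DataFrame(out)


class TestAggregateMeans:
    def test_cell_mean_and_single_sample_cells(self):
        df = pd.DataFrame(
            {
                "year": [2021] * 3, "site": ["S1"] * 3, "day": ["D1"] * 3,
                "period": ["T1", "T1", "T2"], "location": ["edge"] * 3,
                "treatment": ["accessible"] * 3,
                "sugar_rate_ug_h": [40.0, 60.0, 33.0],
            }
        )
        agg = aggregate_means(df)
        assert len(agg) == 2
        t1 = agg[agg["period"] == "T1"]
        assert t1["mean_rate"].iloc[0] == pytest.approx(50.0)
        assert t1["n"].iloc[0] == 2
        assert agg[agg["period"] == "T2"]["mean_rate"].iloc[0] == pytest.approx(33.0)

    def test_weighted_cell_means_conserve_grand_mean(self, nectar_rates):
        agg = aggregate_means(nectar_rates)
        weighted = (agg["mean_rate"] * agg["n"]).sum() / agg["n"].sum()
        assert weighted == pytest.approx(nectar_rates["sugar_rate_ug_h"].mean())

    def test_missing_design_label_rejected(self):
        df = pd.DataFrame(
            {
                "year": [2021], "site": ["S1"], "day": [None], "period": ["T1"],
                "location": ["edge"], "treatment": ["accessible"],
                "sugar_rate_ug_h": [1.0],
            }
        )
        with pytest.raises(FitError):
            aggregate_means(df)


class TestLmm:
    def test_no_group_variability_reduces_to_ols(self, rng):
        """When between-year/site variance is zero the GLS fixed effects
        collapse to ordinary least squares."""
        n = 40
        df = _cell_frame(
            rng.normal(10, 1, n),
            treatment=list(np.tile(["accessible", "inaccessible"], n // 2)),
            year=["2021"] * n, site=["S1"] * n,
            day=[f"D{i}" for i in range(n)],
        )
        fit = fit_lmm(df, fixed=("treatment",), random=("year", "site_in_year"))
        X = np.column_stack(
            [np.ones(n), (df["treatment"] == "inaccessible").to_numpy(float)]
        )
        beta_ols, *_ = np.linalg.lstsq(X, df["mean_rate"].to_numpy(), rcond=None)
        assert np.max(np.abs(fit.beta - beta_ols)) < 1e-8

    def test_reml_matches_anova_closed_form(self, rng):
        """Balanced one-way layout: REML variance components equal the
        classical expected-mean-squares estimator."""
        k, m = 4, 5
        groups = np.repeat([f"g{i}" for i in range(k)], m)
        effects = dict(zip(sorted(set(groups)), rng.normal(0, 2, k)))
        y = np.array([10 + effects[g] for g in groups]) + rng.normal(0, 1, k * m)
        df = _cell_frame(y, year=list(groups), day=list(groups))
        fit = fit_lmm(df, fixed=(), random=("year",))
        ybar = pd.Series(y).groupby(pd.Series(groups)).mean()
        msa = m * ((ybar - y.mean()) ** 2).sum() / (k - 1)
        mse = ((y - np.repeat(ybar.to_numpy(), m)) ** 2).sum() / (k * (m - 1))
        assert fit.varcomps["year"] == pytest.approx((msa - mse) / m, abs=1e-6)
        assert fit.sigma2 == pytest.approx(mse, abs=1e-6)

    def test_reml_matches_statsmodels_reference(self, rng):
        """Cross-validation of fixed effects and variance components against
        an established mixed-model implementation, to 3 significant figures."""
        smf = pytest.importorskip("statsmodels.formula.api")
        n_groups, m = 8, 6
        groups = np.repeat([f"g{i}" for i in range(n_groups)], m)
        eff = dict(zip(sorted(set(groups)), rng.normal(0, 1.5, n_groups)))
        trt = np.tile(["accessible", "inaccessible"], n_groups * m // 2)
        y = (
            np.array([5 + eff[g] for g in groups])
            + 2.0 * (trt == "inaccessible")
            + rng.normal(0, 1, n_groups * m)
        )
        df = _cell_frame(y, year=list(groups), day=list(groups), treatment=list(trt))
        fit = fit_lmm(df, fixed=("treatment",), random=("year",))
        ref = smf.mixedlm("mean_rate ~ treatment", df, groups=df["year"]).fit(reml=True)
        for own, theirs in zip(fit.beta, ref.fe_params.to_numpy()):
            assert own == pytest.approx(theirs, rel=1e-3)
        assert fit.varcomps["year"] == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=1e-3
        )
        assert fit.sigma2 == pytest.approx(float(ref.scale), rel=1e-3)

    def test_boundary_variance_reported_as_zero(self, rng):
        # groups with no real effect: REML may sit at the zero boundary
        n = 60
        df = _cell_frame(
            rng.normal(0, 1, n),
            treatment=list(np.tile(["accessible", "inaccessible"], n // 2)),
            year=list(np.repeat(["2021", "2023"], n // 2)),
            day=[f"D{i}" for i in range(n)],
        )
        fit = fit_lmm(df, fixed=("treatment",), random=("year",))
        assert fit.varcomps["year"] >= 0.0

    def test_single_level_fixed_factor_rejected(self):
        df = _cell_frame([1.0, 2.0])
        with pytest.raises(FitError):
            fit_lmm(df, fixed=("treatment",))

    def test_emmeans_recover_cell_means_in_balanced_design(self, rng):
        trt = np.tile(["accessible", "inaccessible"], 20)
        loc = np.repeat(["edge", "interior"], 20)
        y = 10 + 3 * (trt == "inaccessible") + 1 * (loc == "interior") + rng.normal(0, 0.1, 40)
        df = _cell_frame(y, treatment=list(trt), location=list(loc),
                         day=[f"D{i}" for i in range(40)])
        fit = fit_lmm(df, fixed=("treatment", "location"), random=())
        emm = fit.emmeans("treatment").set_index("treatment")["emmean"]
        by_cell = pd.DataFrame({"y": y, "t": trt, "l": loc}).groupby(["t", "l"])["y"].mean()
        assert emm["accessible"] == pytest.approx(by_cell["accessible"].mean(), abs=0.05)
        assert emm["inaccessible"] == pytest.approx(by_cell["inaccessible"].mean(), abs=0.05)


class TestCountModel:
    def test_null_effect_coefficient_near_zero(self, rng):
        y = rng.poisson(20, 200)
        df = pd.DataFrame({"stage": np.tile(["begin", "end"], 100), "count": y})
        fit = fit_count_model(df, fixed=("stage",))
        assert abs(fit.beta[1]) < 0.15

    def test_poisson_data_poisson_limit(self, rng):
        """On Poisson-generated counts the NB dispersion collapses and the
        fitted means match a Poisson GLM oracle."""
        sm = pytest.importorskip("statsmodels.api")
        stage = np.repeat(["begin", "end"], 150)
        mu = np.where(stage == "begin", 30.0, 6.0)
        y = rng.poisson(mu)
        df = pd.DataFrame({"stage": stage, "count": y})
        fit = fit_count_model(df, fixed=("stage",))
        assert fit.dispersion < 0.02  # var ~ mu: NB alpha at the boundary
        X = np.column_stack([np.ones(300), (stage == "end").astype(float)])
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.max(np.abs(fit.beta - ref.params)) < 1e-4

    def test_negbin_matches_statsmodels_mle(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        stage = np.repeat(["begin", "end"], 150)
        mu = np.where(stage == "begin", 167.0, 32.0)
        size = 2.0
        y = rng.negative_binomial(size, size / (size + mu))
        df = pd.DataFrame({"stage": stage, "count": y})
        fit = fit_count_model(df, fixed=("stage",))
        X = np.column_stack([np.ones(300), (stage == "end").astype(float)])
        ref = sm.NegativeBinomial(y, X).fit(disp=0)
        assert np.max(np.abs(fit.beta - ref.params[:2])) < 1e-4
        assert fit.dispersion == pytest.approx(ref.params[2], rel=1e-3)

    def test_quasipoisson_dispersion_scales_se(self, rng):
        stage = np.repeat(["edge", "interior"], 200)
        mu = np.where(stage == "edge", 1.31, 0.71)
        size = 0.8
        y = rng.negative_binomial(size, size / (size + mu))
        df = pd.DataFrame({"location": stage, "count": y})
        fit = fit_count_model(df, fixed=("location",), family="quasipoisson")
        assert fit.dispersion > 1.0  # overdispersed relative to Poisson
        assert fit.loglik is None

    def test_all_zero_level_is_boundary_error(self):
        df = pd.DataFrame({"stage": ["begin"] * 3 + ["end"] * 3,
                           "count": [5, 3, 4, 0, 0, 0]})
        with pytest.raises(FitError, match="all-zero"):
            fit_count_model(df, fixed=("stage",))


class TestLrt:
    def test_identical_models_statistic_zero(self, rng):
        df = _cell_frame(
            rng.normal(0, 1, 30),
            treatment=list(np.tile(["accessible", "inaccessible"], 15)),
            day=[f"D{i}" for i in range(30)],
        )
        fit = fit_lmm(df, fixed=("treatment",), random=(), reml=False)
        stat, dfree, p = lrt(fit, fit)
        assert stat == 0.0 and p == 1.0

    def test_gaussian_closed_form(self, rng):
        """Fixed-effects-only Gaussian LRT equals n*log(RSS_r/RSS_f)."""
        n = 80
        trt = np.tile(["accessible", "inaccessible"], n // 2)
        loc = np.repeat(["edge", "interior"], n // 2)
        y = rng.normal(10, 2, n) + 0.5 * (loc == "interior")
        df = _cell_frame(y, treatment=list(trt), location=list(loc),
                         day=[f"D{i}" for i in range(n)])
        full = fit_lmm(df, fixed=("treatment", "location"), random=(), reml=False)
        red = fit_lmm(df, fixed=("treatment",), random=(), reml=False)
        stat, dfree, p = lrt(full, red)
        def rss(terms):
            cols = [np.ones(n)]
            for t in terms:
                lv = sorted(df[t].unique())[1:]
                cols += [(df[t] == l).to_numpy(float) for l in lv]
            X = np.column_stack(cols)
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ b
            return float(r @ r)
        oracle = n * np.log(rss(["treatment"]) / rss(["treatment", "location"]))
        assert stat == pytest.approx(oracle, abs=1e-8)
        assert dfree == 1

    def test_reml_fits_rejected(self, rng):
        df = _cell_frame(
            rng.normal(0, 1, 20),
            treatment=list(np.tile(["accessible", "inaccessible"], 10)),
            day=[f"D{i}" for i in range(20)],
        )
        full = fit_lmm(df, fixed=("treatment",), random=(), reml=True)
        red = fit_lmm(df, fixed=(), random=(), reml=True)
        with pytest.raises(FitError, match="ML"):
            lrt(full, red)

    def test_affine_invariance_of_gaussian_lrt(self, rng):
        n = 60
        trt = np.tile(["accessible", "inaccessible"], n // 2)
        y = rng.normal(5, 1, n)
        def stat_for(yy):
            df = _cell_frame(yy, treatment=list(trt), day=[f"D{i}" for i in range(n)])
            full = fit_lmm(df, fixed=("treatment",), random=(), reml=False)
            red = fit_lmm(df, fixed=(), random=(), reml=False)
            return lrt(full, red)[0]
        assert stat_for(3.7 * y + 11.0) == pytest.approx(stat_for(y), abs=1e-7)


class TestWastageRatio:
    def test_printed_marginal_means(self):
        assert wastage_ratio(28.2, 40.8).rounded() == 69
        assert wastage_ratio(32.0, 167.0, comparison="end/begin").rounded() == 19

    def test_equal_means_full_wastage(self):
        assert wastage_ratio(5.0, 5.0).percent == pytest.approx(100.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(EstimateError):
            wastage_ratio(1.0, 0.0)

    @given(
        hst.floats(min_value=0.01, max_value=1e3),
        hst.floats(min_value=0.01, max_value=1e3),
        hst.floats(min_value=0.01, max_value=1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, a, b, c):
        assert wastage_ratio(c * a, c * b).percent == pytest.approx(
            wastage_ratio(a, b).percent, rel=1e-9
        )


class TestClusterBootstrap:
    @staticmethod
    def _mean(df):
        return df["x"].mean()

    def test_constant_data_zero_width_ci(self):
        df = pd.DataFrame({"day": list("abcdef"), "x": 3.0})
        res = cluster_bootstrap(df, self._mean, cluster="day", B=50, seed=1)
        assert res["ci_low"] == res["ci_high"] == res["point"] == 3.0

    def test_seed_determinism(self, rng):
        df = pd.DataFrame({"day": np.repeat(list("abcdefgh"), 4), "x": rng.normal(size=32)})
        r1 = cluster_bootstrap(df, self._mean, cluster="day", B=100, seed=9)
        r2 = cluster_bootstrap(df, self._mean, cluster="day", B=100, seed=9)
        assert (r1["ci_low"], r1["ci_high"]) == (r2["ci_low"], r2["ci_high"])

    def test_ci_narrows_with_more_clusters(self, rng):
        widths = []
        for n_clusters in (6, 48):
            df = pd.DataFrame(
                {
                    "day": np.repeat([f"d{i}" for i in range(n_clusters)], 3),
                    "x": rng.normal(0, 1, 3 * n_clusters),
                }
            )
            res = cluster_bootstrap(df, self._mean, cluster="day", B=200, seed=2)
            widths.append(res["ci_high"] - res["ci_low"])
        assert widths[1] < widths[0]

    def test_failed_replicates_dropped_and_counted(self):
        df = pd.DataFrame({"day": list("aabb"), "x": [1.0, 2.0, 3.0, 4.0]})

        def fragile(d):
            if set(d["day"].str[0]) == {"a"}:
                raise ValueError("degenerate resample")
            return d["x"].mean()

        with pytest.warns(UserWarning, match="dropped"):
            res = cluster_bootstrap(df, fragile, cluster="day", B=100, seed=0)
        assert res["n_failed"] > 0
        assert len(res["replicates"]) == 100 - res["n_failed"]


class TestResidualNectar:
    def test_mixed_zeros(self):
        res = summarize_residual_nectar([0.0, 0.0, 0.03])
        assert res["proportion_zero"] == pytest.approx(2 / 3)
        assert res["mean_volume_uL"] == pytest.approx(0.01)

    def test_all_zero_and_no_zero(self):
        assert summarize_residual_nectar([0, 0])["proportion_zero"] == 1.0
        res = summarize_residual_nectar([0.02, 0.04])
        assert res["proportion_zero"] == 0.0
        assert res["mean_volume_uL"] == pytest.approx(0.03)

    def test_empty_input_absent(self):
        res = summarize_residual_nectar([])
        assert res["proportion_zero"] is None and res["mean_volume_uL"] is None
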