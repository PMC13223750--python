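import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import statsmodels.api as sm

from kynpath.stats import (
    bh_adjust,
    fit_activity_lmm,
    impute_activity_log_decline,
    spearman_with_fdr,
    timepoint_contrasts,
)
from kynpath.synthetic import SyntheticConfig, activity_zscore, generate_cohort


class TestBHAdjust:
    def test_worked_example(self):
        # cumulative-minimum oracle: sorted p * m / rank, then min from the right
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        want = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(want)

    def test_adjusted_geq_raw_and_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=25)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_idempotent_on_identical_values(self):
        p = np.full(6, 0.2)
        once = bh_adjust(p)
        assert bh_adjust(once) == pytest.approx(once)

    def test_nan_propagates(self):
        adj = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(adj[1]) and np.isfinite(adj[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _mini_cohort(rows):
    df = pd.DataFrame(
        rows, columns=["patient_id", "diagnosis", "week", "activity", "observed_activity"]
    )
    df["sex"] = 0
    df["remitter"] = False
    df.index = [f"{p}_w{w:02d}" for p, w in zip(df["patient_id"], df["week"])]
    return df


class TestLogDeclineImputation:
    def test_two_point_exact_fit(self):
        a, b = 10.0, 2.0
        df = _mini_cohort(
            [
                ["P0", "UC", 0, a, True],
                ["P0", "UC", 2, np.nan, False],
                ["P0", "UC", 14, a - b * np.log(15), True],
            ]
        )
        out = impute_activity_log_decline(df)
        assert out.loc["P0_w02", "activity"] == pytest.approx(a - b * np.log(3), abs=1e-9)

    def test_constant_scores_stay_constant(self):
        df = _mini_cohort(
            [
                ["P0", "CD", 0, 7.0, True],
                ["P0", "CD", 2, np.nan, False],
                ["P0", "CD", 14, 7.0, True],
            ]
        )
        out = impute_activity_log_decline(df)
        assert out.loc["P0_w02", "activity"] == pytest.approx(7.0)

    def test_all_observed_identity(self, small_cohort):
        pd.testing.assert_frame_equal(impute_activity_log_decline(small_cohort), small_cohort)

    def test_single_observation_carried(self):
        df = _mini_cohort(
            [
                ["P0", "UC", 0, 9.0, True],
                ["P0", "UC", 14, np.nan, False],
            ]
        )
        out = impute_activity_log_decline(df)
        assert out.loc["P0_w14", "activity"] == 9.0

    def test_observed_values_never_altered(self):
        cfg = SyntheticConfig(n_patients=20, frac_missing_activity=0.3, seed=21)
        cohort = generate_cohort(cfg)
        out = impute_activity_log_decline(cohort)
        obs = cohort["observed_activity"]
        pd.testing.assert_series_equal(out.loc[obs, "activity"], cohort.loc[obs, "activity"])

    def test_clipped_to_scale_range(self):
        # steep decline extrapolates below zero at week 52 -> clipped to 0
        df = _mini_cohort(
            [
                ["P0", "UC", 0, 12.0, True],
                ["P0", "UC", 2, 12.0 - 5 * np.log(3), True],
                ["P0", "UC", 52, np.nan, False],
            ]
        )
        out = impute_activity_log_decline(df)
        assert out.loc["P0_w52", "activity"] == 0.0

    def test_no_observation_rejected_with_ids(self):
        df = _mini_cohort(
            [
                ["P0", "UC", 0, np.nan, False],
                ["P0", "UC", 14, np.nan, False],
                ["P1", "UC", 0, 5.0, True],
                ["P1", "UC", 14, 4.0, True],
            ]
        )
        with pytest.raises(ValueError, match="P0"):
            impute_activity_log_decline(df)


@pytest.fixture(scope="module")
def lmm_cohort():
    return generate_cohort(SyntheticConfig(n_patients=50, weeks=(0, 2, 6, 14), seed=22))


class TestFitActivityLMM:
    def test_slope_recovery(self, lmm_cohort):
        rng = np.random.default_rng(23)
        z = activity_zscore(lmm_cohort).to_numpy()
        pid = lmm_cohort["patient_id"]
        intercepts = pd.Series(rng.normal(0, 1, pid.nunique()), index=pid.unique())
        y = 0.5 * z + intercepts[pid].to_numpy() + rng.normal(0, 0.1, len(z))
        resp = pd.DataFrame({"y": y}, index=lmm_cohort.index)
        res = fit_activity_lmm(resp, lmm_cohort)
        row = res[(res["response"] == "y") & (res["term"] == "activity_z")].iloc[0]
        assert row["converged"]
        assert abs(row["estimate"] - 0.5) < 2 * row["se"]

    def test_ols_equivalence_zero_random_variance(self, lmm_cohort):
        rng = np.random.default_rng(24)
        z = activity_zscore(lmm_cohort).to_numpy()
        sex = lmm_cohort["sex"].to_numpy(dtype=float)
        y = 0.3 + 0.5 * z - 0.2 * sex + 0.1 * sex * z + rng.normal(0, 0.5, len(z))
        resp = pd.DataFrame({"y": y}, index=lmm_cohort.index)
        res = fit_activity_lmm(resp, lmm_cohort).set_index("term")
        X = np.column_stack([np.ones_like(z), sex, z, sex * z])
        ols = sm.OLS(y, X).fit()
        for i, term in enumerate(["Intercept", "sex", "activity_z", "sex:activity_z"]):
            assert res.loc[term, "estimate"] == pytest.approx(ols.params[i], abs=1e-3)

    def test_t_equals_estimate_over_se(self, lmm_cohort):
        from kynpath.synthetic import generate_expression

        cfg = SyntheticConfig(n_patients=50, weeks=(0, 2, 6, 14), seed=22)
        resp = np.log(generate_expression(lmm_cohort, cfg)[["IDO1", "QPRT"]])
        res = fit_activity_lmm(resp, lmm_cohort)
        ok = res["se"] > 0
        assert np.allclose(res.loc[ok, "t"], res.loc[ok, "estimate"] / res.loc[ok, "se"], atol=1e-9)

    def test_p_adj_geq_p(self, lmm_cohort):
        rng = np.random.default_rng(25)
        resp = pd.DataFrame(
            rng.normal(size=(len(lmm_cohort), 5)), index=lmm_cohort.index,
            columns=[f"r{i}" for i in range(5)],
        )
        res = fit_activity_lmm(resp, lmm_cohort)
        ok = res["p"].notna()
        assert (res.loc[ok, "p_adj"] >= res.loc[ok, "p"] - 1e-15).all()

    def test_degenerate_column_flagged_not_raised(self, lmm_cohort):
        resp = pd.DataFrame(
            {"allnan": np.nan, "ok": np.arange(len(lmm_cohort), dtype=float)},
            index=lmm_cohort.index,
        )
        res = fit_activity_lmm(resp, lmm_cohort)
        bad = res[res["response"] == "allnan"]
        assert (~bad["converged"]).all() and bad["estimate"].isna().all()

    def test_series_predictor(self, lmm_cohort):
        rng = np.random.default_rng(26)
        kyn_trp = pd.Series(rng.lognormal(0, 0.3, len(lmm_cohort)), index=lmm_cohort.index, name="Kyn:Trp")
        resp = pd.DataFrame({"y": rng.normal(size=len(lmm_cohort))}, index=lmm_cohort.index)
        res = fit_activity_lmm(resp, lmm_cohort, predictor=kyn_trp)
        assert set(res["term"]) == {"Intercept", "sex", "Kyn:Trp", "sex:Kyn:Trp"}

    def test_covariates_add_terms(self, lmm_cohort):
        rng = np.random.default_rng(27)
        resp = pd.DataFrame({"y": rng.normal(size=len(lmm_cohort))}, index=lmm_cohort.index)
        res = fit_activity_lmm(resp, lmm_cohort, covariates=("age", "bmi", "diagnosis"))
        assert {"age", "bmi", "diagnosis[CD]"} <= set(res["term"])


class TestTimepointContrasts:
    def _cohort_with_group_effect(self, delta, noise_sd, seed, n=40):
        cfg = SyntheticConfig(n_patients=n, weeks=(0, 2, 6, 14), frac_remitters=0.5, seed=seed)
        cohort = generate_cohort(cfg)
        rng = np.random.default_rng(seed + 1)
        pid = cohort["patient_id"]
        intercepts = pd.Series(rng.normal(0, 0.3, pid.nunique()), index=pid.unique())
        y = (
            delta * cohort["remitter"].astype(float)
            + intercepts[pid].to_numpy()
            + rng.normal(0, noise_sd, len(cohort))
        )
        return cohort, pd.Series(y, index=cohort.index, name="resp")

    def test_planted_difference_recovered(self):
        cohort, y = self._cohort_with_group_effect(1.0, 0.2, seed=28)
        res = timepoint_contrasts(y, cohort)
        assert len(res) == 4
        assert ((res["estimate"] - 1.0).abs() < 0.2).all()

    def test_identical_groups_near_zero(self):
        cohort, y = self._cohort_with_group_effect(0.0, 0.1, seed=29)
        res = timepoint_contrasts(y, cohort)
        assert (res["estimate"].abs() < 0.2).all()

    def test_permuted_labels_lose_effect(self):
        sig = 0
        total = 0
        for s in range(10):
            cohort, y = self._cohort_with_group_effect(1.0, 0.5, seed=300 + s)
            rng = np.random.default_rng(600 + s)
            labels = cohort.groupby("patient_id")["remitter"].first()
            permuted = pd.Series(
                rng.permutation(labels.to_numpy()), index=labels.index
            )
            shuffled = cohort.assign(remitter=permuted[cohort["patient_id"]].to_numpy())
            res = timepoint_contrasts(y, shuffled)
            sig += (res["p"] < 0.05).sum()
            total += res["p"].notna().sum()
        assert sig / total < 0.2

    def test_single_group_week_is_nan(self):
        cohort, y = self._cohort_with_group_effect(1.0, 0.2, seed=31)
        drop = (cohort["week"] == 6) & ~cohort["remitter"]
        res = timepoint_contrasts(y[~drop], cohort.loc[~drop])
        row = res[res["week"] == 6].iloc[0]
        assert np.isnan(row["estimate"]) and np.isnan(row["p"])
        assert res[res["week"] != 6]["estimate"].notna().all()


class TestSpearman:
    def test_perfect_monotone(self):
        f = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        res = spearman_with_fdr(f, pd.Series([1.0, 2.0, 3.0]))
        assert res["rho"][0] == pytest.approx(1.0)

    def test_reversed(self):
        f = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        res = spearman_with_fdr(f, pd.Series([3.0, 2.0, 1.0]))
        assert res["rho"][0] == pytest.approx(-1.0)

    def test_ties_equal_pearson_on_midranks(self):
        rng = np.random.default_rng(32)
        x = rng.integers(0, 5, 30).astype(float)  # heavy ties
        y = rng.integers(0, 5, 30).astype(float)
        res = spearman_with_fdr(pd.DataFrame({"x": x}), pd.Series(y))
        want = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert res["rho"][0] == pytest.approx(want)

    def test_pairwise_complete_and_min_pairs(self):
        f = pd.DataFrame({"short": [1.0, 2.0, np.nan, np.nan], "ok": [1.0, 2.0, 3.0, 4.0]})
        res = spearman_with_fdr(f, pd.Series([1.0, 2.0, 3.0, np.nan])).set_index("feature")
        assert np.isnan(res.loc["short", "rho"]) and res.loc["short", "n"] == 2
        assert res.loc["ok", "n"] == 3

    def test_bh_across_features(self):
        rng = np.random.default_rng(33)
        f = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        res = spearman_with_fdr(f, pd.Series(rng.normal(size=20)))
        assert (res["p_adj"].dropna() >= res["p"].dropna() - 1e-15).all()
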