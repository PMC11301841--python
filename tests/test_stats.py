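import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from choroquant import (
    CohortSimConfig,
    age_stratified_table,
    apply_exclusions,
    compare_groups,
    fit_dca_logistic,
    fit_md_linear,
    roc_cutoff,
    simulate_cohort,
    youden_index,
)
from choroquant.stats import delong_se, roc_auc

from oracles import brute_force_auc


class TestExclusions:
    def test_no_flags_is_identity(self, default_cohort):
        df, _ = default_cohort
        kept, ledger = apply_exclusions(df)
        pd.testing.assert_frame_equal(kept, df)
        assert ledger["n_removed"] == 0

    def test_all_flagged_empties_table(self, default_cohort):
        df, _ = default_cohort
        df = df.copy()
        df["excl_choroiditis"] = True
        kept, ledger = apply_exclusions(df)
        assert kept.empty
        assert ledger["n_removed"] == len(df)
        assert ledger["by_reason"]["choroiditis"] == len(df)

    def test_ledger_counts_sum_to_removals(self, default_cohort):
        df, _ = default_cohort
        df = df.copy()
        df.loc[df.index[:7], "excl_PCV"] = True
        df.loc[df.index[5:12], "excl_choroiditis"] = True  # overlap rows 5,6
        kept, ledger = apply_exclusions(df)
        assert ledger["n_removed"] == 12
        assert ledger["n_kept"] == len(df) - 12
        assert ledger["by_reason"] == {
            "choroiditis": 7, "PCV": 7, "severe_MM_or_plus": 0,
            "FCE_or_PICC": 0, "long_standing_RD": 0,
        }
        side_total = sum(ledger["by_side"].values())
        assert side_total == ledger["n_removed"]


class TestCompareGroups:
    def test_matches_ols_with_independent_eyes(self, default_cohort):
        # one eye per subject, no adjusters: GEE point estimates = OLS
        df, _ = default_cohort
        one_eye = df[df["eye"] == "OD"]
        gc = compare_groups(one_eye, "ChT_V", adjusters=())
        X = pd.get_dummies(one_eye["category"], prefix="g", dtype=float).drop(columns="g_C0")
        ols = sm.OLS(one_eye["ChT_V"], sm.add_constant(X)).fit()
        est = gc.contrasts.set_index("pair")["estimate"]
        assert est["C1-C0"] == pytest.approx(ols.params["g_C1"], rel=1e-6)
        assert est["C2-C0"] == pytest.approx(ols.params["g_C2"], rel=1e-6)
        assert est["C2-C1"] == pytest.approx(
            ols.params["g_C2"] - ols.params["g_C1"], rel=1e-6
        )

    def test_bonferroni_arithmetic(self, default_cohort):
        df, _ = default_cohort
        gc = compare_groups(df, "ChT_V")
        for _, row in gc.contrasts.iterrows():
            assert row["p_adj"] == pytest.approx(min(1.0, 3 * row["p_raw"]))
            assert row["p_adj"] >= row["p_raw"]

    def test_singular_design_named(self, default_cohort):
        df, _ = default_cohort
        df = df.copy()
        df["age_copy"] = df["age"]
        with pytest.raises(ValueError, match="singular"):
            compare_groups(df, "ChT_V", adjusters=("age", "age_copy"))

    def test_requires_two_groups(self, default_cohort):
        df, _ = default_cohort
        with pytest.raises(ValueError, match="two groups"):
            compare_groups(df[df["category"] == "C1"], "ChT_V")


class TestDcaLogistic:
    def test_or_invariant_to_predictor_rescaling(self, default_cohort):
        df, _ = default_cohort
        df = df.copy()
        r1 = fit_dca_logistic(df, "LA_N2")
        df["LA_N2"] = df["LA_N2"] * 10.0
        r2 = fit_dca_logistic(df, "LA_N2")
        or1 = r1.table.set_index("term").loc["LA_N2", "OR"]
        or2 = r2.table.set_index("term").loc["LA_N2", "OR"]
        assert or2 == pytest.approx(or1, rel=1e-8)

    def test_perfect_separation_is_explicit_error(self):
        n = 60
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "dca": [False] * (n // 2) + [True] * (n // 2),
                "x": np.r_[rng.uniform(0, 1, n // 2), rng.uniform(2, 3, n // 2)],
                "age": rng.uniform(20, 60, n),
                "AL": rng.uniform(25, 29, n),
                "gender": ["M", "F"] * (n // 2),
            }
        )
        with pytest.raises(ValueError, match="separation"):
            fit_dca_logistic(df, "x")

    def test_one_class_outcome_rejected(self, default_cohort):
        df, _ = default_cohort
        sub = df[~df["dca"]]
        with pytest.raises(ValueError, match="classes"):
            fit_dca_logistic(sub, "LA_N2")

    def test_protective_predictor_has_or_below_one(self, default_cohort):
        df, _ = default_cohort
        row = fit_dca_logistic(df, "ChT_V").table.set_index("term").loc["ChT_V"]
        assert row["OR"] < 1.0
        assert row["OR_CI_low"] < row["OR"] < row["OR_CI_high"]


class TestMdLinear:
    def test_location_shift_changes_only_intercept(self, default_cohort):
        df, _ = default_cohort
        r1 = fit_md_linear(df)
        df2 = df.copy()
        df2["MD"] = df2["MD"] + 5.0
        r2 = fit_md_linear(df2)
        t1 = r1.table.set_index("term")
        t2 = r2.table.set_index("term")
        assert t2.loc["const", "B"] == pytest.approx(t1.loc["const", "B"] + 5.0, rel=1e-9)
        for term in ("age", "height", "AL", "corneal_curvature", "LA_V"):
            assert t2.loc[term, "B"] == pytest.approx(t1.loc[term, "B"], rel=1e-9)

    def test_subsets_partition_sample(self, default_cohort):
        df, _ = default_cohort
        n_all = fit_md_linear(df, subset="all").n
        n_non = fit_md_linear(df, subset="non_pm").n
        n_pm = fit_md_linear(df, subset="pm").n
        assert n_non + n_pm == n_all

    def test_too_few_rows_rejected(self, default_cohort):
        df, _ = default_cohort
        with pytest.raises(ValueError, match="too few"):
            fit_md_linear(df.head(6))

    def test_standardized_beta_scale(self, default_cohort):
        df, _ = default_cohort
        t = fit_md_linear(df).table.set_index("term")
        b = t.loc["LA_V", "B"]
        beta = t.loc["LA_V", "beta"]
        sub = df[df["vf_reliable"]]
        expect = b * sub["LA_V"].std(ddof=0) / sub["MD"].std(ddof=0)
        assert beta == pytest.approx(expect, rel=1e-6)


class TestROC:
    def test_four_point_worked_example(self):
        r = roc_cutoff(
            [0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], predictor="x", orientation="higher"
        )
        assert r.auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        v = rng.normal(size=n).round(1)  # rounding forces ties
        y = rng.uniform(size=n) < 0.4
        if y.sum() == 0 or (~y).sum() == 0:
            y[:2] = [True, False]
        assert roc_auc(v, y) == pytest.approx(brute_force_auc(v, y), abs=1e-12)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        v = rng.normal(size=300)
        y = rng.uniform(size=300) < 0.3
        assert roc_auc(v, y) == pytest.approx(roc_auc_score(y, v), abs=1e-12)

    def test_perfect_separation(self):
        # all diseased below all healthy, lower => disease
        v = np.r_[np.linspace(0, 1, 20), np.linspace(2, 3, 30)]
        y = np.r_[np.ones(20, bool), np.zeros(30, bool)]
        r = roc_cutoff(v, y)
        assert r.orientation == "lower"
        assert r.auc == 1.0
        assert r.youden == pytest.approx(1.0)
        assert r.sensitivity_pct == 100.0 and r.specificity_pct == 100.0

    def test_youden_identity_and_cutoff_range(self, default_cohort):
        df, _ = default_cohort
        for col in ("ChT_V", "LA_N2"):
            r = roc_cutoff(df[col], df["dca"], predictor=col)
            assert r.youden == pytest.approx(
                youden_index(r.sensitivity_pct, r.specificity_pct), abs=1e-12
            )
            assert df[col].min() < r.cutoff < df[col].max()
            assert r.orientation == "lower"
            assert 0.5 <= r.auc <= 1.0

    def test_one_class_stratum_rejected(self, default_cohort):
        df, _ = default_cohort
        with pytest.raises(ValueError, match="single outcome class"):
            roc_cutoff(df["ChT_V"], np.zeros(len(df), bool))

    def test_delong_matches_r_proc(self, tmp_path):
        rng = np.random.default_rng(7)
        v = np.r_[rng.normal(0, 1, 40), rng.normal(1, 1, 25)]
        y = np.r_[np.zeros(40, int), np.ones(25, int)]
        csv = tmp_path / "roc.csv"
        pd.DataFrame({"value": v, "label": y}).to_csv(csv, index=False)
        script = (
            "suppressMessages(library(pROC));"
            f"d <- read.csv('{csv}');"
            "r <- roc(d$label, d$value, direction='<', levels=c(0,1), quiet=TRUE);"
            "cat(sprintf('%.12f %.12f', as.numeric(auc(r)), sqrt(var(r))))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_auc, r_se = map(float, out.stdout.split())
        assert roc_auc(v, y.astype(bool)) == pytest.approx(r_auc, abs=1e-9)
        assert delong_se(v, y.astype(bool)) == pytest.approx(r_se, rel=1e-6)


class TestAgeStratified:
    def test_equals_direct_subset_calls(self, default_cohort):
        df, _ = default_cohort
        table = age_stratified_table(df, predictors=("ChT_V",))
        row = table[(table.stratum == "30<Age<=40") & (table.predictor == "ChT_V")].iloc[0]
        sub = df[(df.age > 30) & (df.age <= 40)]
        direct = roc_cutoff(sub["ChT_V"], sub["dca"], predictor="ChT_V")
        assert row["auc"] == pytest.approx(direct.auc, abs=1e-12)
        assert row["cutoff"] == pytest.approx(direct.cutoff, abs=1e-12)

    def test_missing_strata_reported_not_raised(self, default_cohort):
        df, _ = default_cohort
        narrow = df[(df.age > 30) & (df.age <= 40)]
        table = age_stratified_table(narrow, predictors=("ChT_V",))
        assert len(table) == 5  # All + 4 bands, none dropped
        by = table.set_index("stratum")
        assert np.isfinite(by.loc["All", "auc"])
        assert np.isfinite(by.loc["30<Age<=40", "auc"])
        assert np.isnan(by.loc["50<Age<=60", "auc"])

    def test_effect_shift_gives_high_auc_everywhere(self):
        # C2 eyes ~60 um thinner in every stratum: AUC > 0.8 throughout
        df, _ = simulate_cohort(CohortSimConfig(n_subjects=1500, seed=21))
        table = age_stratified_table(df, predictors=("ChT_V",))
        assert (table["auc"] > 0.8).all()
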