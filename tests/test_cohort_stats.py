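"""Cohort filtering, OLS with covariates, LRT, Bonferroni, Welch tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from shapeasym import (
    CohortSimSpec,
    apply_cohort_filters,
    bonferroni,
    cohort_summary,
    fit_asymmetry_model,
    is_significant,
    lrt_quadratic_age,
    simulate_cohort,
    welch_ttest,
)
from shapeasym.cohort_stats import _design_matrix, format_summary


def small_cohort(n=40, seed=0, n_sites=2, **kw):
    return simulate_cohort(CohortSimSpec(n=n, seed=seed, n_sites=n_sites, **kw))


class TestCohortFilters:
    def test_age_boundary(self):
        df = small_cohort(n=60, seed=1)
        df.loc[0, "age"] = 36.0
        df.loc[1, "age"] = 34.6
        kept, excl = apply_cohort_filters(df)
        assert df.loc[0, "subject_id"] in set(excl["subject_id"])
        assert excl.set_index("subject_id").loc[df.loc[0, "subject_id"], "rule"] == "age"
        assert df.loc[1, "subject_id"] in set(kept["subject_id"])

    def test_fsiq_outlier_excluded(self):
        df = small_cohort(n=60, seed=2)
        sd = df["fsiq"].std()
        df.loc[3, "fsiq"] = df["fsiq"].mean() + 10 * sd
        kept, excl = apply_cohort_filters(df)
        rules = excl.set_index("subject_id")["rule"]
        assert rules.get(df.loc[3, "subject_id"]) == "fsiq"

    def test_fsiq_mean_sd_from_prefilter_sample(self):
        """The outlier band is anchored on the pre-filter mean/SD: a borderline
        value just inside 2 SD of the original sample is retained even though
        removing the gross outlier would shift the post-filter band."""
        df = small_cohort(n=200, seed=3)
        mean, sd = df["fsiq"].mean(), df["fsiq"].std()
        df.loc[0, "fsiq"] = mean + 1.95 * sd
        kept, _ = apply_cohort_filters(df)
        assert df.loc[0, "subject_id"] in set(kept["subject_id"])

    def test_poor_quality_and_missing_fsiq(self):
        df = small_cohort(n=30, seed=4)
        df.loc[0, "quality_flag"] = "poor"
        df.loc[1, "fsiq"] = np.nan
        kept, excl = apply_cohort_filters(df)
        rules = excl.set_index("subject_id")["rule"]
        assert rules.get(df.loc[0, "subject_id"]) == "quality"
        assert rules.get(df.loc[1, "subject_id"]) == "fsiq_missing"
        assert len(kept) <= 28

    def test_empty_cohort_raises(self):
        df = small_cohort(n=5, seed=5)
        df["age"] = 50.0
        with pytest.raises(ValueError, match="empty"):
            apply_cohort_filters(df)


class TestFitAsymmetryModel:
    def test_agrees_with_normal_equations_oracle(self):
        """β from the fit matches a brute-force (XᵀX)⁻¹Xᵀy solve to 1e-8."""
        df = small_cohort(n=50, seed=7, beta_diagnosis=-0.4, beta_sex=-0.3)
        X = _design_matrix(df)
        y = df["hippocampus_shape"].to_numpy()
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        report = fit_asymmetry_model(df, "hippocampus_shape")
        for i, col in enumerate(X.columns):
            if col in report.terms:
                assert report.terms[col].beta == pytest.approx(
                    beta_oracle[i], abs=1e-8
                )

    def test_constant_outcome_degenerate(self):
        df = small_cohort(n=50, seed=8)
        df["hippocampus_shape"] = 3.14
        report = fit_asymmetry_model(df, "hippocampus_shape")
        for term in report.terms.values():
            assert abs(term.beta) < 1e-8
        assert report.r_squared == pytest.approx(0.0, abs=1e-8)

    def test_sign_convention_asd_larger_gives_negative_beta(self):
        """ASD mean > controls ⇒ negative diagnosis β (control = 1 coding);
        same convention for sex (female = 1, males larger ⇒ negative β)."""
        df = small_cohort(n=2000, seed=9, beta_diagnosis=-0.4, beta_sex=-0.3)
        assert (
            df[df.diagnosis == "ASD"]["hippocampus_shape"].mean()
            > df[df.diagnosis == "control"]["hippocampus_shape"].mean()
        )
        report = fit_asymmetry_model(df, "hippocampus_shape")
        assert report.terms["diagnosis"].beta < 0
        assert report.terms["sex"].beta < 0

    def test_beta_coverage(self):
        """The 95% CI for the diagnosis β covers the generating value −0.4 in
        at least 90 of 100 replicate cohorts (n = 2000)."""
        from scipy import stats as sps

        hits = 0
        for rep in range(100):
            df = simulate_cohort(
                CohortSimSpec(n=2000, beta_diagnosis=-0.4, seed=1000 + rep,
                              outcomes=("hippocampus_shape",)))
            report = fit_asymmetry_model(df, "hippocampus_shape")
            tr = report.terms["diagnosis"]
            se = tr.beta / tr.t
            crit = sps.t.ppf(0.975, report.df_resid)
            if abs(tr.beta - (-0.4)) <= crit * abs(se):
                hits += 1
        assert hits >= 90

    def test_rank_deficiency_names_collinear_terms(self):
        df = small_cohort(n=60, seed=10)
        # a site perfectly confounded with diagnosis
        df["site"] = np.where(df.diagnosis == "ASD", "siteA", "siteB")
        with pytest.raises(ValueError, match="collinear"):
            fit_asymmetry_model(df, "hippocampus_shape")

    def test_too_few_per_group(self):
        df = small_cohort(n=40, seed=11)
        df["diagnosis"] = "ASD"
        with pytest.raises(ValueError, match="diagnosis"):
            fit_asymmetry_model(df, "hippocampus_shape")

    def test_site_joint_test_reported(self):
        df = small_cohort(n=200, seed=12, n_sites=4)
        report = fit_asymmetry_model(df, "hippocampus_shape")
        assert report.site_joint_f is not None
        assert 0.0 <= report.site_joint_p <= 1.0
        assert "site[site02]" not in report.terms  # sites not reported per-term

    def test_interactions_optional(self):
        df = small_cohort(n=300, seed=13)
        report = fit_asymmetry_model(
            df, "hippocampus_shape", interactions=("diagnosis:sex",)
        )
        assert "diagnosis:sex" in report.terms


class TestLrtQuadraticAge:
    def test_power_under_strong_quadratic(self):
        df = simulate_cohort(
            CohortSimSpec(n=2000, beta_age_sq=0.05, seed=21,
                          outcomes=("hippocampus_shape",)))
        stat, p = lrt_quadratic_age(df, "hippocampus_shape")
        assert stat > 10
        assert p < 0.001

    def test_null_keeps_high_p_typically(self):
        df = simulate_cohort(
            CohortSimSpec(n=1000, beta_age=0.02, seed=22,
                          outcomes=("hippocampus_shape",)))
        stat, p = lrt_quadratic_age(df, "hippocampus_shape")
        assert stat >= 0

    def test_zero_variance_age_rejected(self):
        df = small_cohort(n=40, seed=23)
        df["age"] = 20.0
        with pytest.raises(ValueError, match="age"):
            lrt_quadratic_age(df, "hippocampus_shape")


class TestBonferroni:
    def test_threshold_arithmetic(self):
        assert bonferroni(0.05, 6) == pytest.approx(0.05 / 6, abs=0)
        assert bonferroni(0.05, 1) == 0.05

    def test_flagging(self):
        assert is_significant(0.006, alpha=0.05, m=6)
        assert not is_significant(0.03, alpha=0.05, m=6)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)


class TestWelch:
    def test_closed_form_example(self):
        t, df, p = welch_ttest([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247448, abs=1e-6)
        assert df == pytest.approx(4.0, abs=1e-10)
        assert p == pytest.approx(0.2878641, abs=1e-6)

    def test_identical_groups(self):
        t, _, p = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 2, 15)
        t1, df1, p1 = welch_ttest(a, b)
        t2, df2, p2 = welch_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert df1 == pytest.approx(df2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            welch_ttest([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_ttest([2.0, 2.0], [3.0, 3.0])


class TestCohortSummary:
    def test_two_subject_toy_exact(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "diagnosis": ["ASD", "ASD"],
                "sex": ["male", "female"],
                "age": [10.0, 20.0],
                "fsiq": [100.0, 110.0],
                "icv": [1.0e6, 1.2e6],
                "site": ["s1", "s1"],
                "hippocampus_shape": [1.0, 3.0],
            }
        )
        summary = cohort_summary(df)
        assert summary[("ASD", "count")]["n"] == 2
        assert summary[("ASD", "mean")]["age"] == 15.0
        assert summary[("ASD", "sd")]["age"] == pytest.approx(np.sqrt(50))
        assert summary[("ASD", "mean")]["hippocampus_shape"] == 2.0
        assert "Variable" in format_summary(summary)

    def test_single_group_single_column(self):
        df = small_cohort(n=20, seed=30)
        df["diagnosis"] = "control"
        summary = cohort_summary(df)
        assert list(summary.columns.get_level_values(0).unique()) == ["control"]

    def test_simulated_means_within_3se(self):
        spec = CohortSimSpec(n=2000, seed=31)
        df = simulate_cohort(spec)
        summary = cohort_summary(df)
        for group in ("ASD", "control"):
            n = summary[(group, "count")]["n"]
            got = summary[(group, "mean")]["fsiq"]
            se = spec.fsiq_sd / np.sqrt(n)
            assert abs(got - spec.fsiq_mean) < 3 * se
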