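"""Cohort-level statistics for asymmetry outcomes.

Covers the full analysis protocol: sample filtering (age cap, FSIQ
outliers, poor-quality scans), per-outcome ordinary least squares with
diagnosis and sex as predictors and age, scanning site, intracranial
volume (ICV) and full-scale IQ (FSIQ) as covariates, a likelihood-ratio
test for a quadratic age term, Bonferroni correction across outcomes,
Welch two-sample t-tests for subgroup contrasts, and demographic summary
tables.

Coding conventions (chosen to reproduce the reported sign semantics):
the diagnosis indicator is 1 for controls and 0 for ASD, so a negative β
means ASD > controls; the sex indicator is 1 for female and 0 for male,
so a negative β means males > females. Site enters as dummy variables
with the alphabetically first site as reference; site terms are reported
jointly, not individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "OUTCOME_COLUMNS",
    "TermResult",
    "ModelReport",
    "apply_cohort_filters",
    "fit_asymmetry_model",
    "lrt_quadratic_age",
    "bonferroni",
    "is_significant",
    "welch_ttest",
    "cohort_summary",
]

#: the six asymmetry outcomes: 3 structures × {shape, volumetric}
OUTCOME_COLUMNS: tuple[str, ...] = (
    "amygdala_shape",
    "amygdala_volumetric",
    "hippocampus_shape",
    "hippocampus_volumetric",
    "lateral_ventricle_shape",
    "lateral_ventricle_volumetric",
)

#: Bonferroni family size for the headline analysis (3 structures × 2 measures)
DEFAULT_N_TESTS = 6


def apply_cohort_filters(
    records: pd.DataFrame,
    fsiq_sd_limit: float = 2.0,
    age_max: float = 35.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the sample-selection filters; return (kept, exclusion log).

    Exclusions, each logged with its rule:

    * ``age``     — age strictly greater than ``age_max`` years;
    * ``quality`` — scans flagged ``poor``;
    * ``fsiq_missing`` — FSIQ not recorded;
    * ``fsiq``    — FSIQ farther than ``fsiq_sd_limit`` standard deviations
      from the pre-filter sample mean (mean/SD over all records with FSIQ).

    Raises if nothing survives.
    """
    df = records.copy()
    reasons: list[dict] = []

    fsiq = pd.to_numeric(df["fsiq"], errors="coerce")
    mean, sd = fsiq.mean(), fsiq.std()

    def _log(mask: pd.Series, rule: str) -> None:
        for sid in df.loc[mask, "subject_id"]:
            reasons.append({"subject_id": sid, "rule": rule})

    missing = fsiq.isna()
    _log(missing, "fsiq_missing")
    age_bad = df["age"] > age_max
    _log(age_bad & ~missing, "age")
    qual_bad = df.get("quality_flag", pd.Series("ok", index=df.index)) == "poor"
    _log(qual_bad & ~missing & ~age_bad, "quality")
    fsiq_bad = (fsiq - mean).abs() > fsiq_sd_limit * sd
    fsiq_bad = fsiq_bad.fillna(False)
    _log(fsiq_bad & ~missing & ~age_bad & ~qual_bad, "fsiq")

    drop = missing | age_bad | qual_bad | fsiq_bad
    kept = df.loc[~drop].reset_index(drop=True)
    if kept.empty:
        raise ValueError("all subjects excluded; empty cohort")
    return kept, pd.DataFrame(reasons, columns=["subject_id", "rule"])


@dataclass
class TermResult:
    beta: float
    t: float
    p: float
    bonferroni_significant: bool = False


@dataclass
class ModelReport:
    """OLS fit of one asymmetry outcome on the covariate design."""

    outcome: str
    terms: dict[str, TermResult]
    r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n: int
    site_joint_f: float | None = None
    site_joint_p: float | None = None
    n_tests: int = DEFAULT_N_TESTS

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "outcome": self.outcome,
                "term": name,
                "beta": tr.beta,
                "t": tr.t,
                "p": tr.p,
                "bonferroni_significant": tr.bonferroni_significant,
            }
            for name, tr in self.terms.items()
        ]
        return pd.DataFrame(rows)


def _design_matrix(
    cohort: pd.DataFrame,
    interactions: tuple[str, ...] = (),
    quadratic_age: bool = False,
) -> pd.DataFrame:
    """Build the regression design (no patsy; column order is fixed).

    diagnosis: 1 = control, 0 = ASD. sex: 1 = female, 0 = male.
    Site dummies drop the alphabetically first level as reference.
    The optional age² column uses centered age for conditioning only —
    the fitted values (hence the LRT) are unchanged by centering.
    """
    dx = (cohort["diagnosis"].astype(str) == "control").astype(float)
    sex = (cohort["sex"].astype(str) == "female").astype(float)
    X = pd.DataFrame(
        {
            "const": 1.0,
            "diagnosis": dx,
            "sex": sex,
            "age": cohort["age"].astype(float),
        },
        index=cohort.index,
    )
    sites = sorted(cohort["site"].astype(str).unique())
    for s in sites[1:]:
        X[f"site[{s}]"] = (cohort["site"].astype(str) == s).astype(float)
    X["icv"] = cohort["icv"].astype(float)
    X["fsiq"] = cohort["fsiq"].astype(float)
    if quadratic_age:
        age_c = X["age"] - X["age"].mean()
        X["age_sq"] = age_c**2
    for inter in interactions:
        a, b = inter.split(":")
        X[inter] = X[a] * X[b]
    return X


def _check_design(cohort: pd.DataFrame, X: pd.DataFrame) -> None:
    counts = cohort.groupby("diagnosis").size()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 subjects in each diagnosis group")
    site_counts = cohort.groupby("site").size()
    if site_counts.min() < 2:
        thin = site_counts[site_counts < 2].index.tolist()
        raise ValueError(f"site level(s) with < 2 subjects: {thin}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the culprits: columns whose removal restores full rank
        culprits = []
        for col in X.columns:
            sub = X.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(sub) == rank:
                culprits.append(col)
        raise ValueError(f"design is rank deficient; collinear terms: {culprits}")


def fit_asymmetry_model(
    cohort: pd.DataFrame,
    outcome: str,
    interactions: tuple[str, ...] = (),
    n_tests: int = DEFAULT_N_TESTS,
    alpha: float = 0.05,
) -> ModelReport:
    """OLS of one asymmetry outcome on diagnosis, sex, age, site, ICV, FSIQ.

    Returns per-term β, t and two-sided p (site dummies summarized by a
    joint F-test), model R², F and degrees of freedom, and a Bonferroni
    significance flag per term at family size ``n_tests``.
    """
    X = _design_matrix(cohort, interactions=interactions)
    _check_design(cohort, X)
    y = cohort[outcome].astype(float)
    res = sm.OLS(y, X).fit()

    site_cols = [c for c in X.columns if c.startswith("site[")]
    report_terms = ["diagnosis", "sex", "age", "icv", "fsiq", *interactions]
    threshold = bonferroni(alpha=alpha, m=n_tests)
    terms = {
        name: TermResult(
            beta=float(res.params[name]),
            t=float(res.tvalues[name]),
            p=float(res.pvalues[name]),
            bonferroni_significant=bool(res.pvalues[name] < threshold),
        )
        for name in report_terms
    }
    site_f = site_p = None
    if site_cols:
        contrast = np.zeros((len(site_cols), X.shape[1]))
        for i, c in enumerate(site_cols):
            contrast[i, X.columns.get_loc(c)] = 1.0
        ftest = res.f_test(contrast)
        site_f, site_p = float(ftest.fvalue), float(ftest.pvalue)
    # constant outcome: zero total sum of squares makes R² undefined; report 0
    r2 = float(res.rsquared) if np.ptp(y.to_numpy()) > 0 else 0.0
    return ModelReport(
        outcome=outcome,
        terms=terms,
        r_squared=r2,
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        n=int(res.nobs),
        site_joint_f=site_f,
        site_joint_p=site_p,
        n_tests=n_tests,
    )


def lrt_quadratic_age(
    cohort: pd.DataFrame,
    outcome: str,
    interactions: tuple[str, ...] = (),
) -> tuple[float, float]:
    """Likelihood-ratio test: linear-age model vs the same model + age².

    Returns (2·Δloglik, p) with p from χ²(1). Used to decide whether a
    non-linear aging effect is needed; a high p keeps the linear term.
    """
    if cohort["age"].astype(float).std() == 0:
        raise ValueError("age has zero variance; quadratic term undefined")
    y = cohort[outcome].astype(float)
    X0 = _design_matrix(cohort, interactions=interactions)
    _check_design(cohort, X0)
    X1 = _design_matrix(cohort, interactions=interactions, quadratic_age=True)
    ll0 = sm.OLS(y, X0).fit().llf
    ll1 = sm.OLS(y, X1).fit().llf
    stat = float(2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(max(stat, 0.0), df=1))
    return stat, p


def bonferroni(alpha: float = 0.05, m: int = DEFAULT_N_TESTS) -> float:
    """Adjusted per-test significance threshold α/m."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def is_significant(p: float, alpha: float = 0.05, m: int = DEFAULT_N_TESTS) -> bool:
    """Bonferroni-corrected significance: p < α/m."""
    return p < bonferroni(alpha=alpha, m=m)


def welch_ttest(group_a, group_b) -> tuple[float, float, float]:
    """Welch's two-sample t-test (Satterthwaite df); returns (t, df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-diagnosis demographics and outcome summary (mean ± SD layout).

    Rows are variables, columns a MultiIndex (group, statistic); counts
    for n and sex, mean/sd for age, FSIQ, ICV and every asymmetry outcome
    present in the table.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    numeric = ["age", "fsiq", "icv"] + [c for c in OUTCOME_COLUMNS if c in cohort]
    blocks: dict[str, pd.DataFrame] = {}
    for group, sub in cohort.groupby("diagnosis"):
        rows: dict[str, dict[str, float]] = {
            "n": {"count": float(len(sub))},
            "n_male": {"count": float((sub["sex"] == "male").sum())},
            "n_female": {"count": float((sub["sex"] == "female").sum())},
        }
        for var in numeric:
            vals = sub[var].astype(float)
            rows[var] = {"mean": vals.mean(), "sd": vals.std()}
        blocks[str(group)] = pd.DataFrame(rows).T
    out = pd.concat(blocks, axis=1)
    out.columns.names = ["diagnosis", "stat"]
    return out


def format_summary(summary: pd.DataFrame, digits: int = 2) -> str:
    """Render a cohort summary as a Markdown table of `mean ± SD` cells."""
    groups = summary.columns.get_level_values(0).unique()
    lines = ["| Variable | " + " | ".join(groups) + " |",
             "|---" * (len(groups) + 1) + "|"]
    for var in summary.index:
        cells = []
        for g in groups:
            block = summary[g].loc[var]
            if not np.isnan(block.get("count", np.nan)):
                cells.append(f"{block['count']:.0f}")
            else:
                cells.append(f"{block['mean']:.{digits}f} ± {block['sd']:.{digits}f}")
        lines.append("| " + var + " | " + " | ".join(cells) + " |")
    return "\n".join(lines)
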