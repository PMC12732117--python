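"""Cohort-level statistics: visit summaries, paired comparisons,
CI-stratified contrasts, correlation, and regression with 95% bands.

Works on any tidy cohort table with columns ``implant_id, visit_months,
ci, mbl_mm`` (as produced by :func:`corticalization.synthetic.generate_cohort`
or assembled from measured data).

Test choice is normality-gated: a parametric test (paired/two-sample t) is
used when Shapiro-Wilk accepts normality at alpha = 0.05 for both samples,
otherwise the rank analogue (Wilcoxon signed-rank / Mann-Whitney U).  Each
test is reported at its own p-value; an optional Holm correction over a
report's p-values is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .changepoint import ChangepointMBLModel, ChangepointMBLResults

__all__ = [
    "TestResult",
    "summarize_visits",
    "compare_timepoints",
    "stratified_contrast",
    "correlate",
    "regress_mbl_on_ci",
    "RegressionBands",
    "full_report",
]

_SHAPIRO_ALPHA = 0.05
_SHAPIRO_MAX_N = 4999  # scipy's Shapiro-Wilk is defined up to n=5000


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    test_name: str  # which branch fired
    n: int
    detail: dict = field(default_factory=dict)


def _is_normal(x: np.ndarray) -> bool:
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return False
    if x.size > _SHAPIRO_MAX_N:
        x = x[:: x.size // _SHAPIRO_MAX_N + 1]
    return stats.shapiro(x).pvalue >= _SHAPIRO_ALPHA


def summarize_visits(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and n of CI and MBL per visit (the summary-table surface)."""
    req = {"visit_months", "ci", "mbl_mm"}
    if not req <= set(cohort.columns):
        raise ValueError(f"cohort table must have columns {sorted(req)}")
    if cohort.empty:
        raise ValueError("empty cohort")
    rows = []
    for visit, grp in cohort.groupby("visit_months"):
        if len(grp) < 2:
            raise ValueError(f"visit {visit} has fewer than 2 implants")
        rows.append(
            {
                "visit_months": visit,
                "n": len(grp),
                "ci_mean": grp["ci"].mean(),
                "ci_sd": grp["ci"].std(ddof=1),
                "mbl_mean": grp["mbl_mm"].mean(),
                "mbl_sd": grp["mbl_mm"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows).sort_values("visit_months").reset_index(drop=True)


def compare_timepoints(
    cohort: pd.DataFrame,
    metric: str,
    visit_a: int = 3,
    visit_b: int = 60,
) -> TestResult:
    """Paired comparison of a metric between two visits.

    Pairs implants present at both visits.  Branches: paired t-test when
    both samples pass the normality gate, else Wilcoxon signed-rank.
    Identical samples (all differences zero) short-circuit to p = 1 — there
    is no evidence of change and neither test statistic is defined.
    """
    col = {"ci": "ci", "mbl": "mbl_mm"}.get(metric, metric)
    a = cohort[cohort["visit_months"] == visit_a].set_index("implant_id")[col]
    b = cohort[cohort["visit_months"] == visit_b].set_index("implant_id")[col]
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired observations")
    x, y = a.loc[common].to_numpy(float), b.loc[common].to_numpy(float)
    diff = y - x
    if np.all(diff == 0):
        return TestResult(0.0, 1.0, "identical-samples", len(common))
    if _is_normal(x) and _is_normal(y):
        st = stats.ttest_rel(x, y)
        return TestResult(float(st.statistic), float(st.pvalue), "paired-t", len(common))
    st = stats.wilcoxon(x, y)
    return TestResult(float(st.statistic), float(st.pvalue), "wilcoxon-signed-rank", len(common))


def stratified_contrast(
    cohort: pd.DataFrame,
    low_cut: float = 300.0,
    high_cut: float = 500.0,
    ci_visit: int = 3,
    outcome_visit: int = 60,
) -> TestResult:
    """Compare 60-month MBL between low-CI and high-CI implants.

    Strata are 3-month CI < ``low_cut`` versus > ``high_cut``; implants
    with CI in between are dropped (the published two-group comparison).
    The two-sample test is normality-gated: Welch t when both strata look
    normal, Mann-Whitney U otherwise.
    """
    ci = cohort[cohort["visit_months"] == ci_visit].set_index("implant_id")["ci"]
    mbl = cohort[cohort["visit_months"] == outcome_visit].set_index("implant_id")["mbl_mm"]
    common = ci.index.intersection(mbl.index)
    ci, mbl = ci.loc[common], mbl.loc[common]
    low = mbl[ci < low_cut].to_numpy(float)
    high = mbl[ci > high_cut].to_numpy(float)
    if low.size == 0 or high.size == 0:
        raise ValueError("one of the CI strata is empty")
    detail = {
        "low_n": int(low.size),
        "low_mean": float(low.mean()),
        "low_sd": float(low.std(ddof=1)) if low.size > 1 else np.nan,
        "high_n": int(high.size),
        "high_mean": float(high.mean()),
        "high_sd": float(high.std(ddof=1)) if high.size > 1 else np.nan,
    }
    if _is_normal(low) and _is_normal(high):
        st = stats.ttest_ind(low, high, equal_var=False)
        name = "welch-t"
    else:
        st = stats.mannwhitneyu(low, high, alternative="two-sided")
        name = "mann-whitney-u"
    return TestResult(float(st.statistic), float(st.pvalue), name,
                      low.size + high.size, detail)


def correlate(
    cohort: pd.DataFrame,
    x: tuple[str, int],
    y: tuple[str, int],
    method: str = "spearman",
) -> TestResult:
    """Correlation between two (metric, visit) series paired by implant.

    ``x``/``y`` are (metric, visit_months) pairs, e.g. ``("ci", 3)`` and
    ``("mbl", 60)``.  Spearman by default — the CI and MBL distributions
    are right-skewed; Pearson available.
    """
    cols = {"ci": "ci", "mbl": "mbl_mm"}
    a = cohort[cohort["visit_months"] == x[1]].set_index("implant_id")[cols.get(x[0], x[0])]
    b = cohort[cohort["visit_months"] == y[1]].set_index("implant_id")[cols.get(y[0], y[0])]
    common = a.index.intersection(b.index)
    xa, yb = a.loc[common].to_numpy(float), b.loc[common].to_numpy(float)
    if method == "spearman":
        st = stats.spearmanr(xa, yb)
    elif method == "pearson":
        st = stats.pearsonr(xa, yb)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return TestResult(float(st.statistic), float(st.pvalue), f"{method}-correlation",
                      len(common))


@dataclass
class RegressionBands:
    """OLS fit of MBL on CI with pointwise 95% confidence/prediction bands."""

    slope: float
    intercept: float
    slope_conf_int: tuple[float, float]
    pvalue: float
    grid: np.ndarray  # CI values of the band evaluation grid
    fitted: np.ndarray
    conf_lower: np.ndarray
    conf_upper: np.ndarray
    pred_lower: np.ndarray
    pred_upper: np.ndarray
    nobs: int

    def summary(self) -> str:
        lo, hi = self.slope_conf_int
        return (
            "OLS: MBL ~ CI\n"
            f"  n: {self.nobs}  slope: {self.slope:.5f} "
            f"[{lo:.5f}, {hi:.5f}]  p: {self.pvalue:.3g}\n"
            f"  intercept: {self.intercept:.4f}"
        )


def regress_mbl_on_ci(
    cohort: pd.DataFrame,
    visit: int = 60,
    n_grid: int = 50,
    alpha: float = 0.05,
) -> RegressionBands:
    """Least-squares MBL-on-CI fit at one visit with 95% bands.

    The confidence band bounds the conditional mean, the prediction band a
    new observation; the latter contains the former pointwise.
    """
    sub = cohort[cohort["visit_months"] == visit]
    x = sub["ci"].to_numpy(float)
    y = sub["mbl_mm"].to_numpy(float)
    if x.size < 10:
        raise ValueError("regression needs at least 10 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in CI")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), n_grid)
    pred = fit.get_prediction(sm.add_constant(grid))
    frame = pred.summary_frame(alpha=alpha)
    ci_lo, ci_hi = fit.conf_int(alpha=alpha)[1]
    return RegressionBands(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_conf_int=(float(ci_lo), float(ci_hi)),
        pvalue=float(fit.pvalues[1]),
        grid=grid,
        fitted=frame["mean"].to_numpy(),
        conf_lower=frame["mean_ci_lower"].to_numpy(),
        conf_upper=frame["mean_ci_upper"].to_numpy(),
        pred_lower=frame["obs_ci_lower"].to_numpy(),
        pred_upper=frame["obs_ci_upper"].to_numpy(),
        nobs=int(fit.nobs),
    )


def full_report(cohort: pd.DataFrame, holm: bool = False) -> dict:
    """The complete statistical surface of one cohort table.

    Visit summaries, 3-vs-60-month paired comparisons of CI and MBL, the
    CI-stratified MBL contrast, CI3-CI60 and CI-MBL correlations, the
    linear MBL-on-CI60 fit with bands, and the censored changepoint fit of
    MBL60 on CI3.  ``holm=True`` applies a Holm step-down correction across
    the report's p-values.
    """
    summary = summarize_visits(cohort)
    tests: dict[str, TestResult] = {
        "ci_3_vs_60": compare_timepoints(cohort, "ci"),
        "mbl_3_vs_60": compare_timepoints(cohort, "mbl"),
        "mbl60_low_vs_high_ci3": stratified_contrast(cohort),
        "ci3_vs_ci60_correlation": correlate(cohort, ("ci", 3), ("ci", 60)),
        "ci60_vs_mbl60_correlation": correlate(cohort, ("ci", 60), ("mbl", 60)),
    }
    pvals = {k: t.pvalue for k, t in tests.items()}
    if holm:
        order = sorted(pvals, key=pvals.get)
        m = len(order)
        adj, running = {}, 0.0
        for rank, k in enumerate(order):
            running = max(running, min(1.0, (m - rank) * pvals[k]))
            adj[k] = running
        pvals = adj
    bands = regress_mbl_on_ci(cohort, visit=60)
    hinge: ChangepointMBLResults = ChangepointMBLModel.from_cohort(cohort).fit()
    return {
        "visit_summary": summary,
        "tests": tests,
        "pvalues": pvals,
        "holm_corrected": holm,
        "regression": bands,
        "changepoint_fit": hinge,
    }
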