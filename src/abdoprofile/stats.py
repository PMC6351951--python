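"""The study's statistical workflow as deterministic, testable operations.

Normality screening (Lilliefors-corrected KS + Shapiro-Wilk), one-sample t
confidence intervals, Levene-gated independent t-tests (pooled variance when
Levene p > 0.05, Welch otherwise), Pearson and residualization-based partial
correlations, simple linear regression with a t-based 95% slope CI, and
power analysis for the correlation test via the Fisher z approximation.

``run_study_analysis`` assembles these into a report mirroring the study's
table layout on any cohort of patient records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .errors import CollinearityError, DomainError

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "TTestResult",
    "CohortStatsReport",
    "pearson",
    "partial_correlation",
    "one_sample_ci",
    "independent_t_test",
    "linear_regression",
    "power_correlation",
    "min_detectable_correlation",
    "normality_tests",
    "run_study_analysis",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int

    @property
    def r_squared(self) -> float:
        return self.r * self.r


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    p_value: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    mean_diff: float
    se_diff: float
    p_value: float
    levene_p: float
    equal_var_assumed: bool
    n1: int
    n2: int


def _as_vector(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} contains non-finite values")
    return arr


def _r_p_value(r: float, df: int) -> float:
    """Two-sided p for a correlation via the t transform with df degrees of freedom."""
    if df <= 0:
        return math.nan
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    return 2.0 * sps.t.sf(abs(t), df)


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-transform p-value."""
    x, y = _as_vector(x, "x"), _as_vector(y, "y")
    if len(x) != len(y):
        raise DomainError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise DomainError("need at least 3 paired observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DomainError("correlation undefined for a zero-variance vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(r=r, p_value=_r_p_value(r, n - 2), n=n)


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(x, y, controls) -> CorrelationResult:
    """Correlation of x and y after removing linear effects of the controls.

    Residualizes both variables on ``[1, controls]``; the p-value uses
    ``df = n - 2 - k`` for k control columns.  With no controls this reduces
    exactly to :func:`pearson`.
    """
    x, y = _as_vector(x, "x"), _as_vector(y, "y")
    n = len(x)
    if len(y) != n:
        raise DomainError("x and y must have equal length")
    c = np.asarray(controls, dtype=float)
    if c.size == 0:
        return pearson(x, y)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != n:
        raise DomainError("controls must have one row per observation")
    k = c.shape[1]
    if n <= k + 2:
        raise DomainError(f"need n > {k + 2} observations for {k} controls")
    design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("control matrix is rank deficient")
    rx, ry = _residualize(x, design), _residualize(y, design)
    if np.ptp(rx) < 1e-300 or np.ptp(ry) < 1e-300:
        raise DomainError("a variable is fully explained by the controls")
    r = float(np.corrcoef(rx, ry)[0, 1])
    return CorrelationResult(r=r, p_value=_r_p_value(r, n - 2 - k), n=n)


def one_sample_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """t-based symmetric confidence interval for the mean."""
    v = _as_vector(values, "values")
    n = len(v)
    if n < 2:
        raise DomainError("need at least 2 values for a confidence interval")
    if not 0.0 < level < 1.0:
        raise DomainError("confidence level must be in (0, 1)")
    mean = float(np.mean(v))
    se = float(np.std(v, ddof=1)) / math.sqrt(n)
    half = sps.t.ppf(0.5 + level / 2.0, n - 1) * se
    return mean, mean - half, mean + half


def independent_t_test(g1, g2) -> TTestResult:
    """Independent-samples t-test gated on Levene's variance test.

    ``mean_diff = mean(g1) - mean(g2)``.  Pooled-variance t when the Levene
    test (mean-centered) gives p > 0.05, Welch otherwise.
    """
    a, b = _as_vector(g1, "g1"), _as_vector(g2, "g2")
    if len(a) < 2 or len(b) < 2:
        raise DomainError("each group needs at least 2 observations")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0 and np.mean(a) == np.mean(b):
        # identical constant groups: difference is exactly zero, no variance
        return TTestResult(0.0, 0.0, 1.0, 1.0, True, len(a), len(b))
    _, levene_p = sps.levene(a, b, center="mean")
    equal_var = bool(levene_p > 0.05)
    t_stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
    mean_diff = float(np.mean(a) - np.mean(b))
    se = abs(mean_diff / t_stat) if t_stat != 0.0 else _pooled_se(a, b, equal_var)
    return TTestResult(
        mean_diff=mean_diff,
        se_diff=float(se),
        p_value=float(p),
        levene_p=float(levene_p),
        equal_var_assumed=equal_var,
        n1=len(a),
        n2=len(b),
    )


def _pooled_se(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    n1, n2 = len(a), len(b)
    v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)
    if equal_var:
        sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        return math.sqrt(sp * (1.0 / n1 + 1.0 / n2))
    return math.sqrt(v1 / n1 + v2 / n2)


def linear_regression(x, y, level: float = 0.95) -> RegressionResult:
    """Simple least-squares regression with a t-based slope CI."""
    x, y = _as_vector(x, "x"), _as_vector(y, "y")
    n = len(x)
    if len(y) != n:
        raise DomainError("x and y must have equal length")
    if n < 3:
        raise DomainError("need at least 3 observations")
    if np.ptp(x) == 0.0:
        raise DomainError("zero predictor variance")
    res = sps.linregress(x, y)
    half = sps.t.ppf(0.5 + level / 2.0, n - 2) * res.stderr
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci_low=float(res.slope - half),
        slope_ci_high=float(res.slope + half),
        p_value=float(res.pvalue),
        n=n,
    )


def power_correlation(n: int, rho: float, alpha: float = 0.05) -> float:
    """Two-sided power of the Pearson significance test, Fisher z approximation.

    power = Phi(sqrt(n-3)|atanh(rho)| - z_{1-a/2}) + Phi(-sqrt(n-3)|atanh(rho)| - z_{1-a/2})
    """
    if n < 4:
        raise DomainError("need n >= 4")
    if not 0.0 <= rho < 1.0:
        raise DomainError("rho must be in [0, 1)")
    if not 0.0 < alpha < 1.0:
        raise DomainError("alpha must be in (0, 1)")
    z_crit = sps.norm.ppf(1.0 - alpha / 2.0)
    shift = math.sqrt(n - 3) * math.atanh(rho)
    return float(sps.norm.cdf(shift - z_crit) + sps.norm.cdf(-shift - z_crit))


def min_detectable_correlation(n: int, power: float, alpha: float = 0.05) -> float:
    """Smallest true correlation reaching the requested power, by bisection."""
    if not 0.0 < power < 1.0:
        raise DomainError("power must be in (0, 1)")
    if power <= power_correlation(n, 0.0, alpha):
        raise DomainError("requested power not above the test size; no root in (0, 1)")
    lo, hi = 0.0, 1.0 - 1e-12
    if power_correlation(n, hi, alpha) < power:
        raise DomainError("requested power unreachable for this n")
    while hi - lo > 1e-9:
        mid = 0.5 * (lo + hi)
        if power_correlation(n, mid, alpha) < power:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def normality_tests(values) -> tuple[float, float]:
    """(Lilliefors-KS p, Shapiro-Wilk p) against a fitted normal."""
    v = _as_vector(values, "values")
    if len(v) < 4:
        raise DomainError("need at least 4 values for normality testing")
    if np.ptp(v) == 0.0:
        raise DomainError("normality undefined for a constant vector")
    _, ks_p = lilliefors(v, dist="norm")
    _, sw_p = sps.shapiro(v)
    return float(ks_p), float(sw_p)


# ---------------------------------------------------------------------------
# Whole-study report
# ---------------------------------------------------------------------------

_CORR_VARS = ("wc", "bmi", "k2", "inf_arc", "area2", "vlow")
_CORR_LABELS = {"wc": "WC", "bmi": "BMI", "k2": "K2", "inf_arc": "InfArc",
                "area2": "Area2", "vlow": "Vol.InfArc"}
_TARGETS = ("rhd", "lhd", "shd")
_PARTIAL_VARS = ("inf_arc", "area2", "vlow")


@dataclass
class CohortStatsReport:
    """Correlation / partial-correlation / regression / t-test summaries."""

    correlations: pd.DataFrame
    partial_correlations: pd.DataFrame
    regression: RegressionResult | None
    profile_ttests: pd.DataFrame
    steatosis_ttests: pd.DataFrame
    n: int

    def summary(self) -> str:
        lines = [f"Cohort analysis (n = {self.n})", ""]
        lines.append("Pearson correlations vs ultrasound diameters:")
        lines.append(self.correlations.to_string(index=False))
        lines.append("")
        lines.append("Partial correlations vs SHD (controls: sex, height, weight):")
        lines.append(self.partial_correlations.to_string(index=False))
        lines.append("")
        if self.regression is not None:
            r = self.regression
            lines.append(
                f"Regression SHD ~ InfArc: slope B = {r.slope:.3f} "
                f"(95% CI {r.slope_ci_low:.3f}; {r.slope_ci_high:.3f}), p = {r.p_value:.3g}"
            )
        lines.append("")
        lines.append("SHD mean differences by profile type (rest minus group):")
        lines.append(self.profile_ttests.to_string(index=False))
        lines.append("")
        lines.append("Liver-diameter differences by steatosis type (non minus steatosic):")
        lines.append(self.steatosis_ttests.to_string(index=False))
        return "\n".join(lines)

    def to_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.partial_correlations.to_csv(out / "partial_correlations.csv", index=False)
        self.profile_ttests.to_csv(out / "profile_ttests.csv", index=False)
        self.steatosis_ttests.to_csv(out / "steatosis_ttests.csv", index=False)
        if self.regression is not None:
            pd.DataFrame([self.regression.__dict__]).to_csv(
                out / "regression.csv", index=False
            )
        (out / "summary.txt").write_text(self.summary(), encoding="utf-8")


def _cohort_frame(cohort) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        row = {
            "patient_id": rec.patient_id,
            "sex_male": None if rec.sex is None else float(rec.sex == "M"),
            "height": rec.height,
            "weight": rec.weight,
            "bmi": rec.bmi,
            "wc": rec.wc,
            "rhd": rec.rhd,
            "lhd": rec.lhd,
            "shd": rec.shd,
        }
        if rec.metrics is not None:
            row.update(k2=rec.metrics.k2, inf_arc=rec.metrics.inf_arc,
                       area2=rec.metrics.area2, vlow=rec.metrics.vlow)
        if rec.classification is not None:
            row.update(
                criterion1=rec.classification.criterion1,
                criterion2=rec.classification.criterion2,
                type_a=rec.classification.type_a,
                type_b=rec.classification.type_b,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("patient_id", kind="stable").reset_index(drop=True)


def run_study_analysis(cohort) -> CohortStatsReport:
    """Fill the whole report for a cohort of patient records.

    Cells that cannot be computed (insufficient n, degenerate groups) are
    flagged with ``insufficient_n = True`` and NaN statistics.  The result is
    invariant to the order of the input records.
    """
    if not cohort:
        raise DomainError("empty cohort")
    df = _cohort_frame(cohort)

    corr_rows = []
    for var in _CORR_VARS:
        for target in _TARGETS:
            sub = df[[var, target]].dropna() if var in df and target in df else pd.DataFrame()
            row = {"variable": _CORR_LABELS[var], "target": target.upper(),
                   "r": math.nan, "r_squared": math.nan, "p_value": math.nan,
                   "n": len(sub), "insufficient_n": False}
            try:
                res = pearson(sub[var], sub[target])
                row.update(r=res.r, r_squared=res.r_squared, p_value=res.p_value, n=res.n)
            except (DomainError, KeyError):
                row["insufficient_n"] = True
            corr_rows.append(row)
    correlations = pd.DataFrame(corr_rows)

    partial_rows = []
    ctrl_cols = ["sex_male", "height", "weight"]
    for var in _PARTIAL_VARS:
        cols = [var, "shd"] + ctrl_cols
        sub = df[cols].dropna() if all(c in df for c in cols) else pd.DataFrame()
        row = {"variable": _CORR_LABELS[var], "target": "SHD",
               "r": math.nan, "p_value": math.nan, "n": len(sub),
               "insufficient_n": False}
        try:
            res = partial_correlation(sub[var], sub["shd"], sub[ctrl_cols].to_numpy())
            row.update(r=res.r, p_value=res.p_value, n=res.n)
        except (DomainError, KeyError, CollinearityError):
            row["insufficient_n"] = True
        partial_rows.append(row)
    partial_correlations = pd.DataFrame(partial_rows)

    regression = None
    if "inf_arc" in df and "shd" in df:
        sub = df[["inf_arc", "shd"]].dropna()
        try:
            regression = linear_regression(sub["inf_arc"], sub["shd"])
        except DomainError:
            regression = None

    def _col_mask(col: str, value: str) -> pd.Series:
        if col in df:
            return df[col] == value
        return pd.Series(False, index=df.index)

    profile_groups = {
        "RP": _col_mask("criterion1", "RP"),
        "FP": _col_mask("criterion1", "FP"),
        "FTP": _col_mask("criterion2", "FTP"),
        "PP": _col_mask("criterion2", "PP"),
    }
    prof_rows = []
    for label, mask in profile_groups.items():
        in_g = df.loc[mask & df["shd"].notna(), "shd"]
        out_g = df.loc[~mask & df["shd"].notna(), "shd"]
        row = {"profile": label, "n_group": len(in_g), "n_rest": len(out_g),
               "mean_diff_rest_minus_group": math.nan, "p_value": math.nan,
               "levene_p": math.nan, "equal_var_assumed": None,
               "insufficient_n": False}
        try:
            res = independent_t_test(out_g, in_g)
            row.update(
                mean_diff_rest_minus_group=res.mean_diff,
                p_value=res.p_value,
                levene_p=res.levene_p,
                equal_var_assumed=res.equal_var_assumed,
            )
        except DomainError:
            row["insufficient_n"] = True
        prof_rows.append(row)
    profile_ttests = pd.DataFrame(prof_rows)

    stea_rows = []
    for cat in ("type_a", "type_b"):
        for measure in _TARGETS:
            if cat not in df or measure not in df:
                continue
            stea = df.loc[(df[cat] == "steatosic") & df[measure].notna(), measure]
            non = df.loc[(df[cat] == "non_steatosic") & df[measure].notna(), measure]
            row = {"category": cat, "measure": measure.upper(),
                   "n_steatosic": len(stea), "n_non_steatosic": len(non),
                   "mean_diff_non_minus_steatosic": math.nan, "p_value": math.nan,
                   "levene_p": math.nan, "equal_var_assumed": None,
                   "insufficient_n": False}
            try:
                res = independent_t_test(non, stea)
                row.update(
                    mean_diff_non_minus_steatosic=res.mean_diff,
                    p_value=res.p_value,
                    levene_p=res.levene_p,
                    equal_var_assumed=res.equal_var_assumed,
                )
            except DomainError:
                row["insufficient_n"] = True
            stea_rows.append(row)
    steatosis_ttests = pd.DataFrame(stea_rows)

    return CohortStatsReport(
        correlations=correlations,
        partial_correlations=partial_correlations,
        regression=regression,
        profile_ttests=profile_ttests,
        steatosis_ttests=steatosis_ttests,
        n=len(df),
    )
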