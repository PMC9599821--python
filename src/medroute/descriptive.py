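"""Descriptive layer: cross-tabulations by exposure status, Wald odds
ratios with 95% CIs, chi-squared association tests, and the per-decade age
odds ratio from a univariable logistic regression.

Odds ratios are computed on complete cases: a missing level (e.g. missing
diagnostic route) is tabulated as its own row but excluded from OR and
chi-squared computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats.contingency import expected_freq

from .errors import ConfigurationError, ConvergenceError
from .synthetic_cohort import Cohort

Z_975 = float(stats.norm.ppf(0.975))  # 1.959964...


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts with the orientation

        a = exposed & event      b = exposed & non-event
        c = unexposed & event    d = unexposed & non-event
    """

    a: int
    b: int
    c: int
    d: int
    exposure_label: str = "exposed"
    event_label: str = "event"

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"cell {name} must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ConfigurationError("contingency table total must be positive")

    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class OREstimate:
    or_: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_ <= self.ci_high):
            raise ConfigurationError("CI must bracket the odds ratio")


@dataclass(frozen=True)
class CrossTab:
    """Counts (levels x exposure) with within-exposure-column percentages.

    ``missing_counts`` holds the separately tabulated missing row (or None);
    percentages are computed over non-missing rows only.
    """

    counts: pd.DataFrame
    percent: pd.DataFrame
    missing_counts: pd.Series | None
    variable: str
    exposure: str


def crosstab(cohort: Cohort, variable: str, exposure: str = "comorbidity") -> CrossTab:
    """Tabulate ``variable`` against ``exposure``, missing values as a
    separate row excluded from the percentage base."""
    df = cohort.df
    for col in (variable, exposure):
        if col not in df.columns:
            raise ConfigurationError(f"unknown cohort column: {col!r}")
    if len(df) == 0:
        raise ConfigurationError("cohort is empty")

    var = df[variable]
    missing_mask = var.isna()
    observed = df.loc[~missing_mask]
    counts = pd.crosstab(observed[variable], observed[exposure])
    percent = 100.0 * counts / counts.sum(axis=0)

    missing_counts = None
    if missing_mask.any():
        missing_counts = df.loc[missing_mask].groupby(exposure, observed=True).size()
        missing_counts = missing_counts.reindex(counts.columns, fill_value=0)

    return CrossTab(counts=counts, percent=percent, missing_counts=missing_counts,
                    variable=variable, exposure=exposure)


def table2x2(ct: CrossTab, event_level, exposure_level=1,
             ref_event_level=None, ref_exposure_level=0) -> ContingencyTable2x2:
    """Collapse a CrossTab to a 2x2 with the documented orientation."""
    counts = ct.counts
    event_rows = counts.index.tolist()
    if ref_event_level is None:
        others = [lv for lv in event_rows if lv != event_level]
        if len(others) != 1:
            raise ConfigurationError("ref_event_level required for tables with >2 levels")
        ref_event_level = others[0]
    return ContingencyTable2x2(
        a=int(counts.loc[event_level, exposure_level]),
        b=int(counts.loc[ref_event_level, exposure_level]),
        c=int(counts.loc[event_level, ref_exposure_level]),
        d=int(counts.loc[ref_event_level, ref_exposure_level]),
        exposure_label=f"{ct.exposure}={exposure_level}",
        event_label=f"{ct.variable}={event_level}",
    )


def odds_ratio_wald(table: ContingencyTable2x2, alpha_level: float = 0.05,
                    continuity_correction: bool = False) -> OREstimate:
    """Cross-product OR with a Wald CI and the Wald z-test p-value."""
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if continuity_correction and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        raise ConfigurationError(
            "2x2 table has a zero cell; pass continuity_correction=True to add 0.5"
        )
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(stats.norm.ppf(1.0 - alpha_level / 2.0))
    p = 2.0 * float(stats.norm.sf(abs(log_or / se)))
    return OREstimate(
        or_=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        p_value=p,
        method="wald",
    )


def chi2_test(counts) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction on a k x 2 table."""
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2:
        raise ConfigurationError("chi2_test expects a 2-dimensional count table")
    if np.any(expected_freq(obs) == 0):
        raise ConfigurationError("chi-squared test undefined: an expected cell count is 0")
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.statistic), float(res.pvalue)


def age_or_per_decade(cohort: Cohort, exposure: str = "comorbidity") -> OREstimate:
    """OR per 10-year age increase from a univariable logistic regression."""
    df = cohort.df
    if df["age"].nunique() < 2:
        raise ConfigurationError("age odds ratio undefined: all patients the same age")
    y = df[exposure].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ConfigurationError("both exposure levels must be present")
    X = sm.add_constant(df["age"].to_numpy(dtype=float) / 10.0)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=False, maxiter=100)
    except Exception as exc:  # statsmodels raises PerfectSeparation variants
        raise ConvergenceError(f"age logistic regression failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError("age logistic regression did not converge")
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    return OREstimate(
        or_=float(np.exp(coef)),
        ci_low=float(np.exp(coef - Z_975 * se)),
        ci_high=float(np.exp(coef + Z_975 * se)),
        p_value=float(fit.pvalues[1]),
        method="logistic",
    )


def deprivation_ors(cohort: Cohort, exposure: str = "comorbidity") -> dict[int, OREstimate]:
    """Per-quintile ORs of exposure against quintile 1 (least deprived)."""
    ct = crosstab(cohort, "deprivation", exposure)
    counts = ct.counts
    out: dict[int, OREstimate] = {}
    for level in counts.index:
        if level == 1:
            continue
        tab = ContingencyTable2x2(
            a=int(counts.loc[level, 1]), b=int(counts.loc[1, 1]),
            c=int(counts.loc[level, 0]), d=int(counts.loc[1, 0]),
            exposure_label=f"{exposure}=1", event_label=f"deprivation={level}",
        )
        out[int(level)] = odds_ratio_wald(tab)
    return out


def table_one(cohort: Cohort, exposure: str = "comorbidity") -> pd.DataFrame:
    """Assemble a Table-1-style frame: counts, column %, OR (CI), p-value."""
    rows: list[dict] = []

    def _fmt_or(est: OREstimate | None) -> tuple[float, float, float, float]:
        if est is None:
            return (np.nan, np.nan, np.nan, np.nan)
        return (est.or_, est.ci_low, est.ci_high, est.p_value)

    age_est = age_or_per_decade(cohort, exposure)
    df = cohort.df
    for a_level, name in ((0, "unexposed"), (1, "exposed")):
        sub = df.loc[df[exposure] == a_level, "age"]
        rows.append({"variable": "age", "level": f"mean_sd_{name}",
                     "count": float(sub.mean()), "percent": float(sub.std())})
    o, lo, hi, p = _fmt_or(age_est)
    rows.append({"variable": "age", "level": "per_decade", "or": o,
                 "ci_low": lo, "ci_high": hi, "p_value": p})

    for variable in ("sex", "deprivation", "route", "ethnicity"):
        ct = crosstab(cohort, variable, exposure)
        chi_stat, chi_p = chi2_test(ct.counts.to_numpy())
        ref = ct.counts.index[0]
        for level in ct.counts.index:
            est = None
            if level != ref:
                tab = ContingencyTable2x2(
                    a=int(ct.counts.loc[level, 1]), b=int(ct.counts.loc[ref, 1]),
                    c=int(ct.counts.loc[level, 0]), d=int(ct.counts.loc[ref, 0]),
                )
                est = odds_ratio_wald(tab)
            o, lo, hi, p = _fmt_or(est)
            rows.append({
                "variable": variable, "level": str(level),
                "count": int(ct.counts.loc[level].sum()),
                "count_unexposed": int(ct.counts.loc[level, 0]),
                "count_exposed": int(ct.counts.loc[level, 1]),
                "percent_unexposed": float(ct.percent.loc[level, 0]),
                "percent_exposed": float(ct.percent.loc[level, 1]),
                "or": o, "ci_low": lo, "ci_high": hi, "p_value": p,
                "chi2_p": chi_p,
            })
        if ct.missing_counts is not None:
            rows.append({
                "variable": variable, "level": "missing",
                "count": int(ct.missing_counts.sum()),
                "count_unexposed": int(ct.missing_counts.get(0, 0)),
                "count_exposed": int(ct.missing_counts.get(1, 0)),
            })
    return pd.DataFrame(rows)
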