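"""Net survival on a monthly grid: an inverse-expected-survival-weighted
excess-hazard estimator plus a plain Kaplan-Meier used as its oracle in the
zero-background-mortality limit.

Discretization conventions (stated because they define the estimators):

* deaths are placed at month-end: a death at time t contributes to month
  ceil(t); censoring at time t keeps the patient at risk through month
  floor(t);
* attained age and calendar year advance in integer years via the floor
  convention: during month u the patient is age + (u-1)//12 years old;
* the net-survival curve is built in product-limit form,
  S(u) = prod_{v<=u} (1 - dLambda_E(v)), so that with a zero life table it
  reduces to the Kaplan-Meier estimator exactly (not just asymptotically).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .synthetic_cohort import Cohort, LifeTable


@dataclass(frozen=True)
class SurvivalCurve:
    """Survival estimate on a strictly increasing month grid starting at 0."""

    times: np.ndarray
    estimate: np.ndarray
    variance: np.ndarray
    at_risk: np.ndarray
    method: str = "kaplan_meier"

    def __post_init__(self) -> None:
        if self.times[0] != 0 or self.estimate[0] != 1.0 or self.variance[0] != 0.0:
            raise ConfigurationError("curve must start at (t=0, S=1, var=0)")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("time grid must be strictly increasing")

    def at(self, t: float) -> float:
        """Step-function evaluation at time t (last estimate at or before t)."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.estimate[idx])


def _event_layout(cohort: Cohort, horizon: int) -> tuple[np.ndarray, np.ndarray]:
    """(event_month, last_at_risk_month) per patient on the monthly grid."""
    fu = cohort.df["follow_up_months"].to_numpy(dtype=float)
    dead = cohort.df["dead"].to_numpy(dtype=int).astype(bool)
    event_month = np.where(dead, np.ceil(fu), np.inf)
    event_month = np.maximum(event_month, 1)  # a death at t=0 counts in month 1
    last_at_risk = np.where(dead, event_month, np.floor(fu))
    return event_month, np.minimum(last_at_risk, horizon)


def expected_hazard(patient, lifetable: LifeTable, t: float) -> float:
    """Per-month expected hazard for one patient at t months since diagnosis.

    ``patient`` is any mapping with keys age, sex, diagnosis_year (a cohort
    row, a dict, or a PatientRecord's __dict__ works).
    """
    if hasattr(patient, "age"):  # PatientRecord / namedtuple
        age, sex, year = patient.age, patient.sex, patient.diagnosis_year
    else:
        age, sex, year = patient["age"], patient["sex"], patient["diagnosis_year"]
    offset = int(np.floor(t / 12.0))
    return lifetable.rate(int(age) + offset, sex, int(year) + offset) / 12.0


def _monthly_expected_hazards(cohort: Cohort, lifetable: LifeTable, horizon: int) -> np.ndarray:
    """(n, horizon) matrix of per-month expected hazards; column u-1 is month u."""
    df = cohort.df
    age = df["age"].to_numpy(dtype=int)
    year = df["diagnosis_year"].to_numpy(dtype=int)
    sex = df["sex"].to_numpy()
    out = np.empty((len(df), horizon), dtype=float)
    for offset in range(horizon // 12 + 1):
        months = range(offset * 12, min((offset + 1) * 12, horizon))
        cols = list(months)
        if not cols:
            continue
        rates = lifetable.rates(age + offset, sex, year + offset) / 12.0
        out[:, cols] = rates[:, None]
    return out


def kaplan_meier(cohort: Cohort, grid=None) -> SurvivalCurve:
    """Product-limit estimator on the monthly grid with Greenwood variance."""
    horizon = int(np.ceil(cohort.df["follow_up_months"].max())) if grid is None else int(max(grid))
    event_month, last_at_risk = _event_layout(cohort, horizon)

    times = [0.0]
    est = [1.0]
    var = [0.0]
    n_risk = [len(cohort)]
    s = 1.0
    greenwood = 0.0
    for u in range(1, horizon + 1):
        at_risk = int(np.sum(last_at_risk >= u))
        if at_risk == 0:
            warnings.warn(f"risk set empty at month {u}; curve truncated", stacklevel=2)
            break
        d = int(np.sum(event_month == u))
        s *= 1.0 - d / at_risk
        if d > 0 and at_risk > d:
            greenwood += d / (at_risk * (at_risk - d))
        elif d == at_risk:
            greenwood = np.inf
        times.append(float(u))
        est.append(s)
        var.append(s * s * greenwood if np.isfinite(greenwood) else 0.0)
        n_risk.append(at_risk)

    curve = SurvivalCurve(
        times=np.asarray(times), estimate=np.asarray(est),
        variance=np.asarray(var), at_risk=np.asarray(n_risk), method="kaplan_meier",
    )
    return _subset(curve, grid)


def pohar_perme(cohort: Cohort, lifetable: LifeTable, grid=None) -> SurvivalCurve:
    """Inverse-expected-survival-weighted net survival.

    Each patient carries weight w_i(u) = 1 / S*_i(u), where S*_i(u) is the
    cumulative expected survival through month u from the life table. The
    excess-hazard increment at month u is

        dLambda_E(u) = [sum_i w_i dN_i(u) - sum_i w_i Y_i(u) lambda*_i(u)]
                       / sum_i w_i Y_i(u)

    and the curve is the product-limit transform of those increments, with
    variance from the weighted counting-process estimator
    sum_i w_i^2 dN_i(u) / (sum_i w_i Y_i(u))^2, scaled by S(u)^2.
    """
    horizon = int(np.ceil(cohort.df["follow_up_months"].max())) if grid is None else int(max(grid))
    event_month, last_at_risk = _event_layout(cohort, horizon)
    haz = _monthly_expected_hazards(cohort, lifetable, horizon)
    cum_expected = np.cumsum(haz, axis=1)  # H*_i through end of month u

    times = [0.0]
    est = [1.0]
    var = [0.0]
    n_risk = [len(cohort)]
    s = 1.0
    cumvar = 0.0
    for u in range(1, horizon + 1):
        at_risk = last_at_risk >= u
        n_at_risk = int(at_risk.sum())
        if n_at_risk == 0:
            warnings.warn(f"risk set empty at month {u}; curve truncated", stacklevel=2)
            break
        w = np.exp(cum_expected[:, u - 1])          # 1 / S*_i(u)
        died = event_month == u
        denom = float(np.sum(w[at_risk]))
        num_deaths = float(np.sum(w[died]))
        num_expected = float(np.sum(w[at_risk] * haz[at_risk, u - 1]))
        d_lambda = (num_deaths - num_expected) / denom
        s *= 1.0 - d_lambda
        cumvar += float(np.sum(w[died] ** 2)) / denom**2
        times.append(float(u))
        est.append(s)
        var.append(s * s * cumvar)
        n_risk.append(n_at_risk)

    curve = SurvivalCurve(
        times=np.asarray(times), estimate=np.asarray(est),
        variance=np.asarray(var), at_risk=np.asarray(n_risk), method="pohar_perme",
    )
    return _subset(curve, grid)


def _subset(curve: SurvivalCurve, grid) -> SurvivalCurve:
    if grid is None:
        return curve
    wanted = np.concatenate([[0.0], np.asarray(sorted(grid), dtype=float)])
    mask = np.isin(curve.times, wanted)
    return SurvivalCurve(
        times=curve.times[mask], estimate=curve.estimate[mask],
        variance=curve.variance[mask], at_risk=curve.at_risk[mask], method=curve.method,
    )


def net_survival_by(cohort: Cohort, lifetable: LifeTable, by: str,
                    times=(12, 36, 60)) -> pd.DataFrame:
    """Stratified net-survival estimates (one row per stratum x time)."""
    df = cohort.df
    if by not in df.columns:
        raise ConfigurationError(f"unknown stratification column: {by!r}")
    rows = []
    strata = df[by].dropna().unique()
    for stratum in sorted(strata):
        sub = Cohort(df=df[df[by] == stratum].reset_index(drop=True),
                     label=f"{cohort.label}:{by}={stratum}")
        curve = pohar_perme(sub, lifetable, grid=list(times))
        for t in times:
            idx = int(np.searchsorted(curve.times, t))
            if idx >= len(curve.times) or curve.times[idx] != t:
                continue
            rows.append({
                "stratum": stratum, "time_months": t,
                "net_survival": curve.estimate[idx],
                "variance": curve.variance[idx],
                "n": len(sub),
            })
    return pd.DataFrame(rows)
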