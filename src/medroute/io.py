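"""CSV/YAML input-output with strict validation.

Cohort CSV contract (header required, in this order):

    patient_id,age,sex,deprivation,ethnicity,comorbidity,route,follow_up_months,dead,diagnosis_year

Categorical dictionaries: sex in {male, female}; ethnicity in {white, other};
route in {elective, emergency} or empty (missing); deprivation in 1..5
(1 = least deprived); comorbidity and dead in {0, 1}; age in 45..99.

Life-table CSV: age,sex,year,rate with rate >= 0 per person-year.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from ._design import ETHNICITY_LEVELS, ROUTE_LEVELS, SEX_LEVELS
from .errors import CohortValidationError, ConfigurationError
from .synthetic_cohort import (
    COHORT_COLUMNS,
    Cohort,
    ConfounderConfig,
    LifeTable,
    ScenarioSpec,
)

AGE_RANGE = (45, 99)


def _bad_rows(mask: pd.Series, df: pd.DataFrame, what: str) -> str:
    lines = (df.index[mask] + 2).tolist()[:10]  # +2: header plus 1-based lines
    return f"{what} at line(s) {lines}"


def validate_cohort_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate levels and ranges; raises CohortValidationError with line numbers."""
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"cohort file missing columns: {missing_cols}")
    if len(df) == 0:
        raise CohortValidationError("cohort file contains no rows")
    problems = []
    age = pd.to_numeric(df["age"], errors="coerce")
    bad = age.isna() | (age < AGE_RANGE[0]) | (age > AGE_RANGE[1])
    if bad.any():
        problems.append(_bad_rows(bad, df, f"age outside {AGE_RANGE}"))
    for col, levels in (("sex", SEX_LEVELS), ("ethnicity", ETHNICITY_LEVELS)):
        bad = ~df[col].isin(levels)
        if bad.any():
            offending = sorted(df.loc[bad, col].astype(str).unique())
            problems.append(_bad_rows(bad, df, f"unknown {col} level(s) {offending}"))
    bad = ~df["route"].isin(ROUTE_LEVELS) & df["route"].notna()
    if bad.any():
        offending = sorted(df.loc[bad, "route"].astype(str).unique())
        problems.append(_bad_rows(bad, df, f"unknown route level(s) {offending}"))
    dep = pd.to_numeric(df["deprivation"], errors="coerce")
    bad = dep.isna() | ~dep.isin([1, 2, 3, 4, 5])
    if bad.any():
        problems.append(_bad_rows(bad, df, "deprivation outside 1..5"))
    for col in ("comorbidity", "dead"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~vals.isin([0, 1])
        if bad.any():
            problems.append(_bad_rows(bad, df, f"{col} not in {{0,1}}"))
    fu = pd.to_numeric(df["follow_up_months"], errors="coerce")
    bad = fu.isna() | (fu < 0)
    if bad.any():
        problems.append(_bad_rows(bad, df, "follow_up_months negative or malformed"))
    if problems:
        raise CohortValidationError("; ".join(problems))

    out = df.copy()
    out["age"] = age.astype(int)
    out["deprivation"] = dep.astype(int)
    out["comorbidity"] = pd.to_numeric(out["comorbidity"]).astype(int)
    out["dead"] = pd.to_numeric(out["dead"]).astype(int)
    out["follow_up_months"] = fu.astype(float)
    out["diagnosis_year"] = pd.to_numeric(out["diagnosis_year"]).astype(int)
    out["route"] = out["route"].where(out["route"].notna(), None).astype(object)
    return out[list(COHORT_COLUMNS)]


def read_cohort(path: str | Path, label: str | None = None) -> Cohort:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"route": "object", "sex": "object", "ethnicity": "object"})
    except pd.errors.EmptyDataError:
        raise CohortValidationError(f"cohort file is empty: {path}") from None
    return Cohort(df=validate_cohort_frame(df), label=label or path.stem)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    df = cohort.df.copy()
    df["route"] = df["route"].fillna("")  # missing route -> empty field
    df.to_csv(path, index=False, float_format="%.6f")


def read_life_table(path: str | Path) -> LifeTable:
    df = pd.read_csv(path)
    required = {"age", "sex", "year", "rate"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"life table must have columns {sorted(required)}")
    return LifeTable(df)


def write_life_table(table: LifeTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def load_scenario(path: str | Path) -> ScenarioSpec:
    """Read a ScenarioSpec from a YAML (or JSON-style) config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return scenario_from_dict(raw)


def scenario_from_dict(raw: dict) -> ScenarioSpec:
    if not isinstance(raw, dict):
        raise ConfigurationError("scenario config must be a mapping")
    if "seed" not in raw:
        raise ConfigurationError("scenario config must set a seed")
    raw = dict(raw)
    conf_raw = raw.pop("confounders", {})
    conf = ConfounderConfig(**{
        k: tuple(v) if isinstance(v, list) else v for k, v in conf_raw.items()
    })
    theta = {int(k): tuple(v) for k, v in raw.pop("theta", {}).items()}
    spec = ScenarioSpec(
        n_patients=int(raw.pop("n_patients")),
        seed=int(raw.pop("seed")),
        confounders=conf,
        alpha=tuple(raw.pop("alpha", ())),
        gamma=tuple(raw.pop("gamma", ())),
        theta=theta,
        **{k: raw[k] for k in ("missing_route_prob", "admin_censor_month",
                               "diagnosis_year", "label") if k in raw},
    )
    spec.validate()
    return spec


def dump_scenario(spec: ScenarioSpec, path: str | Path) -> None:
    data = {
        "n_patients": spec.n_patients,
        "seed": spec.seed,
        "confounders": {
            "age_mean": spec.confounders.age_mean,
            "age_sd": spec.confounders.age_sd,
            "age_min": spec.confounders.age_min,
            "age_max": spec.confounders.age_max,
            "p_female": spec.confounders.p_female,
            "deprivation_probs": list(spec.confounders.deprivation_probs),
            "p_ethnicity_other": spec.confounders.p_ethnicity_other,
        },
        "alpha": list(spec.alpha),
        "gamma": list(spec.gamma),
        "theta": {int(w): list(v) for w, v in spec.theta.items()},
        "missing_route_prob": spec.missing_route_prob,
        "admin_censor_month": spec.admin_censor_month,
        "diagnosis_year": spec.diagnosis_year,
        "label": spec.label,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
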