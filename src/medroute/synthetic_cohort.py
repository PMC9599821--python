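"""Registry-like cohort simulator and its exact ground-truth oracle.

The generating process follows the causal ordering

    confounders C  ->  exposure A (comorbidity)  ->  mediator M (route)
                   ->  sequential window deaths Y_w,

with every linear predictor on the shared confounder design of
:mod:`medroute._design`. Because the confounders live on a finite grid
(integer ages 45-99 x sex x deprivation quintile x ethnicity), the natural
effects implied by a :class:`ScenarioSpec` can be computed by exact
enumeration rather than simulation; :func:`true_natural_effects` is the
oracle every downstream estimator is tested against.

Coefficient vector layouts (all on the logit scale):

    alpha   : [intercept, *C]                 -> P(A=1 | C)
    gamma   : [intercept, a, *C]              -> P(M=1 | A, C)
    theta_w : [intercept, a, m, a*m, *C]      -> P(death in w | A, M, C, at risk)

where ``*C`` is the 7-term design (age_dec, female, dep2..dep5, eth_other).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from ._design import N_CONFOUNDER_TERMS, confounder_matrix_from_grid
from .errors import ConfigurationError, LifeTableCoverageError

#: default conditional-outcome windows, months since diagnosis (half-open (lo, hi])
DEFAULT_WINDOWS: dict[int, tuple[float, float]] = {1: (0.0, 12.0), 2: (12.0, 36.0), 3: (36.0, 60.0)}

ALPHA_LEN = 1 + N_CONFOUNDER_TERMS   # intercept + C
GAMMA_LEN = 2 + N_CONFOUNDER_TERMS   # intercept + a + C
THETA_LEN = 4 + N_CONFOUNDER_TERMS   # intercept + a + m + a*m + C


# ---------------------------------------------------------------------------
# scenario specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfounderConfig:
    """Marginal confounder distribution (components drawn independently).

    Age is a normal(age_mean, age_sd) discretized to the integer grid
    [age_min, age_max]; the grid keeps the enumeration oracle exact.
    """

    age_mean: float = 71.0
    age_sd: float = 11.0
    age_min: int = 45
    age_max: int = 99
    p_female: float = 0.465
    deprivation_probs: tuple[float, ...] = (0.215, 0.228, 0.210, 0.195, 0.152)
    p_ethnicity_other: float = 0.10

    def validate(self) -> None:
        if not (self.age_min < self.age_max):
            raise ConfigurationError("confounder_config.age_min must be < age_max")
        if self.age_sd <= 0:
            raise ConfigurationError("confounder_config.age_sd must be positive")
        for name, p in (("p_female", self.p_female), ("p_ethnicity_other", self.p_ethnicity_other)):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"confounder_config.{name} must be in [0, 1]")
        probs = np.asarray(self.deprivation_probs, dtype=float)
        if probs.shape != (5,):
            raise ConfigurationError("confounder_config.deprivation_probs must have 5 entries")
        if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ConfigurationError("confounder_config.deprivation_probs must be a probability vector")

    def age_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer ages and their (renormalized) discretized-normal probabilities."""
        ages = np.arange(self.age_min, self.age_max + 1)
        upper = norm.cdf((ages + 0.5 - self.age_mean) / self.age_sd)
        lower = norm.cdf((ages - 0.5 - self.age_mean) / self.age_sd)
        p = upper - lower
        return ages, p / p.sum()


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete parameterization of the synthetic generating process."""

    n_patients: int
    seed: int
    confounders: ConfounderConfig = field(default_factory=ConfounderConfig)
    alpha: tuple[float, ...] = ()
    gamma: tuple[float, ...] = ()
    theta: Mapping[int, tuple[float, ...]] = field(default_factory=dict)
    missing_route_prob: float = 0.058
    admin_censor_month: float = 60.0
    diagnosis_year: int = 2010
    label: str = "synthetic"

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        self.confounders.validate()
        if len(self.alpha) != ALPHA_LEN:
            raise ConfigurationError(f"alpha must have length {ALPHA_LEN}, got {len(self.alpha)}")
        if len(self.gamma) != GAMMA_LEN:
            raise ConfigurationError(f"gamma must have length {GAMMA_LEN}, got {len(self.gamma)}")
        if set(self.theta.keys()) != {1, 2, 3}:
            raise ConfigurationError("theta must provide coefficient vectors for windows 1, 2 and 3")
        for w, vec in self.theta.items():
            if len(vec) != THETA_LEN:
                raise ConfigurationError(f"theta[{w}] must have length {THETA_LEN}, got {len(vec)}")
        if not 0.0 <= self.missing_route_prob < 1.0:
            raise ConfigurationError("missing_route_prob must be in [0, 1)")
        if self.admin_censor_month <= 0:
            raise ConfigurationError("admin_censor_month must be positive")

    def windows(self) -> dict[int, tuple[float, float]]:
        scale = self.admin_censor_month / 60.0
        return {w: (lo * scale, hi * scale) for w, (lo, hi) in DEFAULT_WINDOWS.items()}


def default_scenario(n_patients: int = 20_000, seed: int = 0, **overrides) -> ScenarioSpec:
    """A DLBCL-flavoured default: ~11% exposure prevalence, ~1/3 emergency
    route, a clear route -> early-death effect that fades in later windows."""
    spec = ScenarioSpec(
        n_patients=n_patients,
        seed=seed,
        alpha=(-2.45, 0.30, -0.13, 0.13, 0.21, 0.35, 0.49, 0.00),
        gamma=(-0.95, 0.35, 0.25, 0.05, 0.08, 0.15, 0.22, 0.30, 0.10),
        theta={
            1: (-1.60, 0.28, 0.85, 0.05, 0.45, -0.05, 0.05, 0.10, 0.15, 0.20, 0.05),
            2: (-1.20, 0.30, 0.35, 0.02, 0.40, -0.05, 0.05, 0.08, 0.12, 0.16, 0.05),
            3: (-1.40, 0.35, 0.15, 0.00, 0.40, -0.05, 0.04, 0.06, 0.10, 0.14, 0.04),
        },
    )
    return replace(spec, **overrides) if overrides else spec


def null_mediation_scenario(n_patients: int = 20_000, seed: int = 0) -> ScenarioSpec:
    """Default scenario with the exposure's effect on the mediator removed,
    so the true NIE equals 1 in every window."""
    spec = default_scenario(n_patients, seed)
    gamma = list(spec.gamma)
    gamma[1] = 0.0
    return replace(spec, gamma=tuple(gamma))


# ---------------------------------------------------------------------------
# patient-level generation
# ---------------------------------------------------------------------------

#: documented cohort column order (see io module for the CSV contract)
COHORT_COLUMNS = (
    "patient_id", "age", "sex", "deprivation", "ethnicity",
    "comorbidity", "route", "follow_up_months", "dead", "diagnosis_year",
)


@dataclass(frozen=True)
class PatientRecord:
    """One registry row. The DataFrame in :class:`Cohort` is the bulk
    representation; this dataclass is the per-row view used at the edges."""

    patient_id: int
    age: int
    sex: str
    deprivation: int
    ethnicity: str
    comorbidity: int
    route: str | None
    follow_up_months: float
    dead: int
    diagnosis_year: int


@dataclass
class Cohort:
    """An ordered patient table plus a label (e.g. disease subtype)."""

    df: pd.DataFrame
    label: str = "cohort"

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise ConfigurationError("cohort must be non-empty")
        if self.df["patient_id"].duplicated().any():
            raise ConfigurationError("cohort patient_ids must be unique")

    def __len__(self) -> int:
        return len(self.df)

    def records(self):
        for row in self.df.itertuples(index=False):
            yield PatientRecord(
                patient_id=row.patient_id, age=row.age, sex=row.sex,
                deprivation=row.deprivation, ethnicity=row.ethnicity,
                comorbidity=row.comorbidity,
                route=None if pd.isna(row.route) else row.route,
                follow_up_months=row.follow_up_months, dead=row.dead,
                diagnosis_year=row.diagnosis_year,
            )


def _draw_confounders(cfg: ConfounderConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    ages, p_age = cfg.age_grid()
    age = rng.choice(ages, size=n, p=p_age)
    female = rng.random(n) < cfg.p_female
    dep = rng.choice(np.arange(1, 6), size=n, p=np.asarray(cfg.deprivation_probs))
    eth_other = rng.random(n) < cfg.p_ethnicity_other
    return pd.DataFrame({
        "age": age.astype(int),
        "sex": np.where(female, "female", "male"),
        "deprivation": dep.astype(int),
        "ethnicity": np.where(eth_other, "other", "white"),
    })


def generate_cohort(spec: ScenarioSpec) -> Cohort:
    """Draw one cohort from the generating process. Bit-reproducible for a
    fixed ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    df = _draw_confounders(spec.confounders, n, rng)
    C = confounder_matrix_from_grid(
        df["age"].to_numpy(float),
        (df["sex"] == "female").to_numpy(float),
        df["deprivation"].to_numpy(int),
        (df["ethnicity"] == "other").to_numpy(float),
    )

    alpha = np.asarray(spec.alpha)
    a = (rng.random(n) < expit(alpha[0] + C @ alpha[1:])).astype(int)

    gamma = np.asarray(spec.gamma)
    m = (rng.random(n) < expit(gamma[0] + gamma[1] * a + C @ gamma[2:])).astype(int)

    windows = spec.windows()
    alive = np.ones(n, dtype=bool)
    follow_up = np.full(n, spec.admin_censor_month, dtype=float)
    dead = np.zeros(n, dtype=int)
    for w in (1, 2, 3):
        theta = np.asarray(spec.theta[w])
        eta = theta[0] + theta[1] * a + theta[2] * m + theta[3] * a * m + C @ theta[4:]
        dies = alive & (rng.random(n) < expit(eta))
        lo, hi = windows[w]
        # uniform placement within the fatal window; timing only matters to
        # the survival layer, the mediation layer sees window indicators
        follow_up[dies] = lo + rng.random(int(dies.sum())) * (hi - lo)
        dead[dies] = 1
        alive &= ~dies

    route = np.where(m == 1, "emergency", "elective").astype(object)
    missing = rng.random(n) < spec.missing_route_prob
    route[missing] = None

    out = pd.DataFrame({
        "patient_id": np.arange(1, n + 1),
        "age": df["age"],
        "sex": df["sex"],
        "deprivation": df["deprivation"],
        "ethnicity": df["ethnicity"],
        "comorbidity": a,
        "route": route,
        "follow_up_months": follow_up,
        "dead": dead,
        "diagnosis_year": spec.diagnosis_year,
    }, columns=list(COHORT_COLUMNS))
    return Cohort(df=out, label=spec.label)


# ---------------------------------------------------------------------------
# exact enumeration oracle
# ---------------------------------------------------------------------------

def _confounder_grid(cfg: ConfounderConfig) -> tuple[np.ndarray, np.ndarray]:
    """All confounder cells with their joint probabilities.

    Returns (C, p): C is (k, 7) design rows, p the cell probabilities
    (product of independent marginals)."""
    ages, p_age = cfg.age_grid()
    sexes = np.array([0.0, 1.0])                       # female indicator
    p_sex = np.array([1.0 - cfg.p_female, cfg.p_female])
    deps = np.arange(1, 6)
    p_dep = np.asarray(cfg.deprivation_probs, dtype=float)
    eths = np.array([0.0, 1.0])                        # other-ethnicity indicator
    p_eth = np.array([1.0 - cfg.p_ethnicity_other, cfg.p_ethnicity_other])

    A, S, D, E = np.meshgrid(ages, sexes, deps, eths, indexing="ij")
    PA, PS, PD, PE = np.meshgrid(p_age, p_sex, p_dep, p_eth, indexing="ij")
    C = confounder_matrix_from_grid(A.ravel().astype(float), S.ravel(), D.ravel(), E.ravel())
    p = (PA * PS * PD * PE).ravel()
    return C, p


@dataclass(frozen=True)
class TrueNaturalEffects:
    """Exact natural effects implied by a ScenarioSpec for one window."""

    window: int
    tce_or: float
    nde_or: float
    nie_or: float
    pm: float
    risks: dict[tuple[int, int], float]   # (a, a_star) -> P(Y_{a, M_{a*}} = 1)


def _window_risks(spec: ScenarioSpec, C: np.ndarray, window: int) -> dict[tuple[int, int], np.ndarray]:
    """P(death in `window` | a, m, C, at risk) for all (a, m), per grid cell."""
    theta = np.asarray(spec.theta[window])
    base = C @ theta[4:]
    return {
        (a, m): expit(theta[0] + theta[1] * a + theta[2] * m + theta[3] * a * m + base)
        for a in (0, 1) for m in (0, 1)
    }


def true_natural_effects(spec: ScenarioSpec, window: int = 1) -> TrueNaturalEffects:
    """Exact TCE/NDE/NIE odds ratios (and PM) for one conditional window.

    The confounder distribution used for windows 2 and 3 is re-weighted by
    the exact probability of surviving all earlier windows given C under the
    observational law — the same at-risk population an analyst conditions on.
    The counterfactual mediator law P(M | a*, C) is the generating one.
    """
    spec.validate()
    if window not in (1, 2, 3):
        raise ConfigurationError("window must be 1, 2 or 3")

    C, p_c = _confounder_grid(spec.confounders)

    alpha = np.asarray(spec.alpha)
    p_a1 = expit(alpha[0] + C @ alpha[1:])
    gamma = np.asarray(spec.gamma)
    p_m1 = {a: expit(gamma[0] + gamma[1] * a + C @ gamma[2:]) for a in (0, 1)}

    # observational survival to the window start, per confounder cell
    surv = np.ones(len(C))
    if window > 1:
        s_am = {(a, m): np.ones(len(C)) for a in (0, 1) for m in (0, 1)}
        for w in range(1, window):
            r = _window_risks(spec, C, w)
            for key in s_am:
                s_am[key] = s_am[key] * (1.0 - r[key])
        surv = np.zeros(len(C))
        for a in (0, 1):
            p_a = p_a1 if a == 1 else 1.0 - p_a1
            for m in (0, 1):
                p_m = p_m1[a] if m == 1 else 1.0 - p_m1[a]
                surv += p_a * p_m * s_am[(a, m)]

    weights = p_c * surv
    weights = weights / weights.sum()

    risk_w = _window_risks(spec, C, window)

    def nested_risk(a: int, a_star: int) -> float:
        per_cell = p_m1[a_star] * risk_w[(a, 1)] + (1.0 - p_m1[a_star]) * risk_w[(a, 0)]
        return float(weights @ per_cell)

    risks = {(a, s): nested_risk(a, s) for (a, s) in ((1, 1), (1, 0), (0, 0))}
    odds = {k: v / (1.0 - v) for k, v in risks.items()}
    tce = odds[(1, 1)] / odds[(0, 0)]
    nde = odds[(1, 0)] / odds[(0, 0)]
    nie = odds[(1, 1)] / odds[(1, 0)]
    pm = nde * (nie - 1.0) / (nde * nie - 1.0) if abs(nde * nie - 1.0) > 1e-12 else float("nan")
    return TrueNaturalEffects(window=window, tce_or=tce, nde_or=nde, nie_or=nie, pm=pm, risks=risks)


def true_marginals(spec: ScenarioSpec) -> dict[str, float]:
    """Exact marginal P(A=1), P(M=1) and P(death in window 1) under the spec."""
    spec.validate()
    C, p_c = _confounder_grid(spec.confounders)
    alpha = np.asarray(spec.alpha)
    p_a1 = expit(alpha[0] + C @ alpha[1:])
    gamma = np.asarray(spec.gamma)
    p_m1 = {a: expit(gamma[0] + gamma[1] * a + C @ gamma[2:]) for a in (0, 1)}
    risk1 = _window_risks(spec, C, 1)

    p_m = (1.0 - p_a1) * p_m1[0] + p_a1 * p_m1[1]
    p_y1 = np.zeros(len(C))
    for a in (0, 1):
        pa = p_a1 if a == 1 else 1.0 - p_a1
        for m in (0, 1):
            pm_ = p_m1[a] if m == 1 else 1.0 - p_m1[a]
            p_y1 += pa * pm_ * risk1[(a, m)]
    return {
        "p_exposure": float(p_c @ p_a1),
        "p_mediator": float(p_c @ p_m),
        "p_death_window1": float(p_c @ p_y1),
    }


# ---------------------------------------------------------------------------
# life tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GompertzLifeTableConfig:
    """Background mortality rate(age) = b * exp(c * age), per person-year,
    optionally scaled for males, on an (age, sex, year) grid."""

    b: float = 1e-4
    c: float = 0.09
    male_factor: float = 1.0
    age_min: int = 45
    age_max: int = 104          # must cover oldest diagnosis age + follow-up
    year_min: int = 2010
    year_max: int = 2015

    def validate(self) -> None:
        if self.b < 0:
            raise ConfigurationError("life-table rate parameter b must be >= 0")
        if self.male_factor < 0:
            raise ConfigurationError("life-table male_factor must be >= 0")
        if self.age_min > self.age_max or self.year_min > self.year_max:
            raise ConfigurationError("life-table grid bounds are inverted")


class LifeTable:
    """Expected (background) mortality rates indexed by (age, sex, year)."""

    def __init__(self, df: pd.DataFrame):
        required = {"age", "sex", "year", "rate"}
        if not required.issubset(df.columns):
            raise ConfigurationError(f"life table must have columns {sorted(required)}")
        if (df["rate"] < 0).any():
            raise ConfigurationError("life-table rates must be non-negative")
        self.df = df.reset_index(drop=True)
        self._lookup = {
            (int(r.age), r.sex, int(r.year)): float(r.rate)
            for r in df.itertuples(index=False)
        }

    def rate(self, age: int, sex: str, year: int) -> float:
        """Expected deaths per person-year for one cell."""
        try:
            return self._lookup[(int(age), sex, int(year))]
        except KeyError:
            raise LifeTableCoverageError(
                f"life table has no entry for (age={age}, sex={sex}, year={year})"
            ) from None

    def rates(self, ages: np.ndarray, sexes: np.ndarray, years: np.ndarray) -> np.ndarray:
        out = np.empty(len(ages), dtype=float)
        for i, (a, s, y) in enumerate(zip(ages, sexes, years)):
            out[i] = self.rate(int(a), s, int(y))
        return out

    def covers(self, ages: Sequence[int], sexes: Sequence[str], years: Sequence[int]) -> bool:
        return all((int(a), s, int(y)) in self._lookup for a, s, y in zip(ages, sexes, years))


def generate_life_table(config: GompertzLifeTableConfig) -> LifeTable:
    """Build a complete LifeTable on the configured grid from the Gompertz form."""
    config.validate()
    ages = np.arange(config.age_min, config.age_max + 1)
    years = np.arange(config.year_min, config.year_max + 1)
    rows = []
    for sex, factor in (("male", config.male_factor), ("female", 1.0)):
        base = config.b * np.exp(config.c * ages) * factor
        for year in years:
            rows.append(pd.DataFrame({"age": ages, "sex": sex, "year": year, "rate": base}))
    return LifeTable(pd.concat(rows, ignore_index=True))


def life_table_for_cohort(cohort: Cohort, config: GompertzLifeTableConfig | None = None,
                          follow_up_years: int = 5) -> LifeTable:
    """A life table guaranteed to cover every (age, sex, year) the cohort can
    reach during follow-up."""
    df = cohort.df
    cfg = config or GompertzLifeTableConfig()
    cfg = GompertzLifeTableConfig(
        b=cfg.b, c=cfg.c, male_factor=cfg.male_factor,
        age_min=min(cfg.age_min, int(df["age"].min())),
        age_max=max(cfg.age_max, int(df["age"].max()) + follow_up_years),
        year_min=min(cfg.year_min, int(df["diagnosis_year"].min())),
        year_max=max(cfg.year_max, int(df["diagnosis_year"].max()) + follow_up_years),
    )
    return generate_life_table(cfg)
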