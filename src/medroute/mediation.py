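"""Natural-effects mediation analysis by Monte Carlo g-computation.

Pipeline per conditional window: restrict to patients alive at the window
start, stochastically impute missing mediator values once, fit logistic
mediator and outcome models, simulate the three nested counterfactual risks
P(Y_{a, M_{a*}} = 1) for (a, a*) in {(1,1), (1,0), (0,0)}, and form marginal
odds ratios

    TCE = odds(1,1) / odds(0,0)
    NDE = odds(1,0) / odds(0,0)      (mediator held at its a*=0 law)
    NIE = odds(1,1) / odds(1,0)      (exposure held at a=1)

so that TCE = NDE * NIE holds as an algebraic identity of the construction.
The proportion mediated on the odds-ratio scale is
PM = OR_NDE (OR_NIE - 1) / (OR_NDE OR_NIE - 1). Confidence intervals are
percentile bootstrap with full re-estimation (imputation included) per
replicate.

All randomness flows from a single master seed through
numpy.random.SeedSequence.spawn in the fixed order (imputation, g-comp
draws, bootstrap); replicate b uses the b-th child of the bootstrap stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit

from ._design import confounder_matrix
from ._logit import LogitFit, fit_logit
from .errors import (
    ConfigurationError,
    ConvergenceError,
    UndefinedProportionMediatedError,
)
from .synthetic_cohort import DEFAULT_WINDOWS, Cohort

CONTRASTS = ((1, 1), (1, 0), (0, 0))


# ---------------------------------------------------------------------------
# conditional window outcomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionalOutcome:
    """Binary death indicator for one window among patients at risk.

    ``at_risk`` and ``y`` are aligned to the source cohort rows; ``y`` is
    NaN where the patient was not alive at the window start.
    """

    window: int
    bounds: tuple[float, float]
    at_risk: np.ndarray
    y: np.ndarray

    @property
    def n_at_risk(self) -> int:
        return int(self.at_risk.sum())

    @property
    def n_events(self) -> int:
        return int(np.nansum(self.y))


def make_conditional_outcome(cohort: Cohort, window: int,
                             windows: Mapping[int, tuple[float, float]] | None = None
                             ) -> ConditionalOutcome:
    """Death-within-window indicator with half-open (lo, hi] bounds."""
    bounds = (windows or DEFAULT_WINDOWS).get(window)
    if bounds is None:
        raise ConfigurationError(f"unknown window index: {window}")
    lo, hi = bounds
    if not lo < hi:
        raise ConfigurationError(f"window bounds must be increasing, got ({lo}, {hi})")
    fu = cohort.df["follow_up_months"].to_numpy(dtype=float)
    dead = cohort.df["dead"].to_numpy(dtype=int).astype(bool)
    # alive at window start: death time beyond lo, or never died
    at_risk = ~dead | (fu > lo)
    y = np.full(len(fu), np.nan)
    y[at_risk] = (dead & (fu > lo) & (fu <= hi))[at_risk].astype(float)
    return ConditionalOutcome(window=window, bounds=(lo, hi), at_risk=at_risk, y=y)


# ---------------------------------------------------------------------------
# component models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediatorModel:
    """logit P(M=1 | A, C); design [1, a, C]."""

    fit: LogitFit

    def prob(self, a: float, C: np.ndarray) -> np.ndarray:
        coef = self.fit.coef
        return expit(coef[0] + coef[1] * a + C @ coef[2:])


@dataclass(frozen=True)
class OutcomeModel:
    """logit P(Y=1 | A, M, A*M, C); design [1, a, m, a*m, C]."""

    fit: LogitFit

    def prob(self, a: float, m: np.ndarray, C: np.ndarray) -> np.ndarray:
        coef = self.fit.coef
        return expit(coef[0] + coef[1] * a + coef[2] * m + coef[3] * a * m + C @ coef[4:])


def fit_mediator_model(a: np.ndarray, m: np.ndarray, C: np.ndarray,
                       start: np.ndarray | None = None) -> MediatorModel:
    X = np.column_stack([np.ones(len(a)), a, C])
    return MediatorModel(fit=fit_logit(X, m, start=start))


def fit_outcome_model(a: np.ndarray, m: np.ndarray, y: np.ndarray, C: np.ndarray,
                      start: np.ndarray | None = None) -> OutcomeModel:
    X = np.column_stack([np.ones(len(a)), a, m, a * m, C])
    return OutcomeModel(fit=fit_logit(X, y, start=start))


def _impute_with_coef(a: np.ndarray, m: np.ndarray, C: np.ndarray, y: np.ndarray,
                      rng: np.random.Generator, start: np.ndarray | None = None
                      ) -> tuple[np.ndarray, int, np.ndarray | None]:
    missing = np.isnan(m)
    n_missing = int(missing.sum())
    if n_missing == 0:
        return m.copy(), 0, None
    complete = ~missing
    if not complete.any():
        raise ConfigurationError("cannot impute: every mediator value is missing")
    X = np.column_stack([np.ones(len(a)), a, C, y])
    fit = fit_logit(X[complete], m[complete], start=start)
    p = expit(X[missing] @ fit.coef)
    out = m.copy()
    out[missing] = (rng.random(n_missing) < p).astype(float)
    return out, n_missing, fit.coef


def impute_missing_mediator(a: np.ndarray, m: np.ndarray, C: np.ndarray, y: np.ndarray,
                            rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Single stochastic imputation of missing mediator values.

    The imputation model is logistic M ~ A + C + Y fitted on complete cases;
    every variable participates. Each missing value is replaced by one
    Bernoulli draw from its fitted probability.
    """
    out, n_missing, _ = _impute_with_coef(a, m, C, y, rng)
    return out, n_missing


# ---------------------------------------------------------------------------
# g-computation
# ---------------------------------------------------------------------------

def gcomp_counterfactual_risk(mm: MediatorModel, om: OutcomeModel, C: np.ndarray,
                              a: int, a_star: int, mc_draws: int = 50,
                              seed: int | np.random.SeedSequence | None = None,
                              exact: bool = False) -> float:
    """Marginal nested counterfactual risk P(Y_{a, M_{a*}} = 1).

    For each subject the mediator is drawn ``mc_draws`` times from its law
    under exposure ``a_star`` and the outcome model is evaluated at exposure
    ``a``; the estimate averages over draws and subjects. ``exact=True``
    replaces sampling with the closed-form average over the two mediator
    values (no Monte Carlo error).
    """
    p_m = mm.prob(a_star, C)
    if exact:
        risk = p_m * om.prob(a, np.ones(len(C)), C) + (1.0 - p_m) * om.prob(a, np.zeros(len(C)), C)
        return float(risk.mean())
    if mc_draws < 1:
        raise ConfigurationError("mc_draws must be >= 1")
    rng = np.random.default_rng(seed)
    risk1 = om.prob(a, np.ones(len(C)), C)
    risk0 = om.prob(a, np.zeros(len(C)), C)
    total = 0.0
    for _ in range(mc_draws):
        m_draw = rng.random(len(C)) < p_m
        total += float(np.where(m_draw, risk1, risk0).mean())
    return total / mc_draws


def proportion_mediated(nde_or: float, nie_or: float, tol: float = 1e-9) -> float:
    """PM = OR_NDE (OR_NIE - 1) / (OR_NDE OR_NIE - 1) on the OR scale."""
    if nde_or <= 0 or nie_or <= 0:
        raise ConfigurationError("odds ratios must be positive")
    denom = nde_or * nie_or - 1.0
    if abs(denom) < tol:
        raise UndefinedProportionMediatedError(
            "proportion mediated undefined: total effect odds ratio is 1"
        )
    return nde_or * (nie_or - 1.0) / denom


# ---------------------------------------------------------------------------
# closed-form conditional effects from the natural-effect model coefficients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NaturalEffectModelCoefficients:
    """Coefficients of logit E[Y_{a, M_{a*}} | C] =
    b0 + b1 a + b2 a* + b3'C + b4 a a* + b5'(a C) + b6'(a* C)."""

    b0: float
    b1: float
    b2: float
    b3: np.ndarray
    b4: float
    b5: np.ndarray
    b6: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.b3) == len(self.b5) == len(self.b6)):
            raise ConfigurationError("b3, b5 and b6 must share the confounder dimension")


def _check_levels(a: int, a_star: int) -> None:
    if a not in (0, 1) or a_star not in (0, 1):
        raise ConfigurationError("exposure levels must be binary (0 or 1)")


def nde_or_closed_form(coef: NaturalEffectModelCoefficients, a: int, a_star: int,
                       C: np.ndarray) -> float:
    """Conditional NDE odds ratio: exp[(b1 + b4 a* + b5'C)(a - a*)]."""
    _check_levels(a, a_star)
    C = np.asarray(C, dtype=float)
    if C.shape != coef.b3.shape:
        raise ConfigurationError("confounder vector has wrong dimension")
    return float(np.exp((coef.b1 + coef.b4 * a_star + coef.b5 @ C) * (a - a_star)))


def nie_or_closed_form(coef: NaturalEffectModelCoefficients, a: int, a_star: int,
                       C: np.ndarray) -> float:
    """Conditional NIE odds ratio: exp[(b2 + b4 a + b6'C)(a - a*)]."""
    _check_levels(a, a_star)
    C = np.asarray(C, dtype=float)
    if C.shape != coef.b3.shape:
        raise ConfigurationError("confounder vector has wrong dimension")
    return float(np.exp((coef.b2 + coef.b4 * a + coef.b6 @ C) * (a - a_star)))


# ---------------------------------------------------------------------------
# full estimator with bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediationConfig:
    seed: int = 0
    mc_draws: int = 50
    n_bootstrap: int = 1000
    method: str = "montecarlo"        # or "exact" (closed-form mediator averaging)
    min_events: int = 10
    max_replicate_failure_frac: float = 0.05
    windows: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS))

    def validate(self) -> None:
        if self.method not in ("montecarlo", "exact"):
            raise ConfigurationError("method must be 'montecarlo' or 'exact'")
        if self.method == "montecarlo" and self.mc_draws < 1:
            raise ConfigurationError("mc_draws must be >= 1")
        if self.n_bootstrap is not None and self.n_bootstrap < 2:
            raise ConfigurationError("n_bootstrap must be >= 2 (or None to skip)")


@dataclass(frozen=True)
class NaturalEffects:
    """Point estimates and percentile bootstrap intervals for one window."""

    window: int
    tce_or: float
    nde_or: float
    nie_or: float
    pm: float
    ci: dict[str, tuple[float, float]]
    n_at_risk: int
    n_events: int
    n_imputed: int
    estimator: str
    mc_draws: int
    n_bootstrap: int
    n_replicate_failures: int
    seed: int

    def as_dict(self) -> dict:
        out = {
            "window": self.window, "tce_or": self.tce_or, "nde_or": self.nde_or,
            "nie_or": self.nie_or, "pm": self.pm, "n_at_risk": self.n_at_risk,
            "n_events": self.n_events, "n_imputed": self.n_imputed,
            "estimator": self.estimator, "mc_draws": self.mc_draws,
            "n_bootstrap": self.n_bootstrap,
            "n_replicate_failures": self.n_replicate_failures, "seed": self.seed,
        }
        for key, (lo, hi) in self.ci.items():
            out[f"{key}_ci_low"] = lo
            out[f"{key}_ci_high"] = hi
        return out


def _point_estimate(a: np.ndarray, m: np.ndarray, C: np.ndarray, y: np.ndarray,
                    config: MediationConfig,
                    impute_ss: np.random.SeedSequence,
                    gcomp_ss: np.random.SeedSequence,
                    starts: dict | None = None) -> dict:
    """One full pass: impute -> fit -> g-compute -> effect ratios.

    ``starts`` optionally warm-starts each model fit (bootstrap resamples
    converge in 2-3 Newton steps from the full-data coefficients).
    """
    starts = starts or {}
    m_complete, n_imputed, impute_coef = _impute_with_coef(
        a, m, C, y, np.random.default_rng(impute_ss), start=starts.get("impute"))
    mm = fit_mediator_model(a, m_complete, C, start=starts.get("mediator"))
    om = fit_outcome_model(a, m_complete, y, C, start=starts.get("outcome"))
    exact = config.method == "exact"
    risk_seeds = gcomp_ss.spawn(len(CONTRASTS))
    risks = {
        contrast: gcomp_counterfactual_risk(
            mm, om, C, contrast[0], contrast[1],
            mc_draws=config.mc_draws, seed=ss, exact=exact)
        for contrast, ss in zip(CONTRASTS, risk_seeds)
    }
    odds = {k: v / (1.0 - v) for k, v in risks.items()}
    tce = odds[(1, 1)] / odds[(0, 0)]
    nde = odds[(1, 0)] / odds[(0, 0)]
    nie = odds[(1, 1)] / odds[(1, 0)]
    try:
        pm = proportion_mediated(nde, nie)
    except UndefinedProportionMediatedError:
        pm = float("nan")
    return {"tce": tce, "nde": nde, "nie": nie, "pm": pm, "n_imputed": n_imputed,
            "coefs": {"impute": impute_coef, "mediator": mm.fit.coef,
                      "outcome": om.fit.coef}}


def bootstrap_natural_effects(a: np.ndarray, m: np.ndarray, C: np.ndarray, y: np.ndarray,
                              config: MediationConfig,
                              boot_ss: np.random.SeedSequence,
                              alpha_level: float = 0.05,
                              starts: dict | None = None) -> tuple[dict, int]:
    """Percentile bootstrap over patients with full re-estimation.

    Returns ({effect: (low, high)}, n_failed). Replicates whose model fits
    fail are dropped; more than ``max_replicate_failure_frac`` failures is an
    error.
    """
    if config.n_bootstrap < 2:
        raise ConfigurationError("n_bootstrap must be >= 2")
    n = len(a)
    draws: dict[str, list[float]] = {k: [] for k in ("tce", "nde", "nie", "pm")}
    n_failed = 0
    for rep_ss in boot_ss.spawn(config.n_bootstrap):
        resample_ss, impute_ss, gcomp_ss = rep_ss.spawn(3)
        idx = np.random.default_rng(resample_ss).integers(0, n, size=n)
        try:
            est = _point_estimate(a[idx], m[idx], C[idx], y[idx],
                                  config, impute_ss, gcomp_ss, starts=starts)
        except (ConvergenceError, ConfigurationError):
            n_failed += 1
            continue
        for k in draws:
            draws[k].append(est[k])
    if n_failed > config.max_replicate_failure_frac * config.n_bootstrap:
        raise ConvergenceError(
            f"{n_failed}/{config.n_bootstrap} bootstrap replicates failed to converge"
        )
    lo_q, hi_q = 100 * alpha_level / 2, 100 * (1 - alpha_level / 2)
    ci = {}
    for k, vals in draws.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        ci[k] = (float(np.percentile(arr, lo_q)), float(np.percentile(arr, hi_q)))
    return ci, n_failed


def estimate_natural_effects(cohort: Cohort, window: int,
                             config: MediationConfig | None = None) -> NaturalEffects:
    """Estimate TCE/NDE/NIE/PM for one conditional window with bootstrap CIs.

    Set ``config.n_bootstrap`` to None for point estimates only.
    """
    config = config or MediationConfig()
    config.validate()
    co = make_conditional_outcome(cohort, window, config.windows)
    if co.n_events < config.min_events:
        raise ConfigurationError(
            f"window {window} has {co.n_events} events, fewer than the "
            f"configured minimum of {config.min_events}; refusing to fit"
        )
    df = cohort.df.loc[co.at_risk]
    a = df["comorbidity"].to_numpy(dtype=float)
    m = np.where(df["route"].isna(), np.nan,
                 (df["route"] == "emergency").astype(float))
    C = confounder_matrix(df)
    y = co.y[co.at_risk]

    master = np.random.SeedSequence(config.seed)
    impute_ss, gcomp_ss, boot_ss = master.spawn(3)
    point = _point_estimate(a, m, C, y, config, impute_ss, gcomp_ss)

    ci: dict[str, tuple[float, float]] = {}
    n_failed = 0
    if config.n_bootstrap is not None:
        ci, n_failed = bootstrap_natural_effects(a, m, C, y, config, boot_ss,
                                                 starts=point["coefs"])

    return NaturalEffects(
        window=window,
        tce_or=point["tce"], nde_or=point["nde"], nie_or=point["nie"], pm=point["pm"],
        ci=ci, n_at_risk=co.n_at_risk, n_events=co.n_events,
        n_imputed=point["n_imputed"],
        estimator="gcomp" if config.method == "montecarlo" else "gcomp_exact",
        mc_draws=config.mc_draws,
        n_bootstrap=config.n_bootstrap or 0,
        n_replicate_failures=n_failed,
        seed=config.seed,
    )
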