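"""Shared covariate encoding.

Every model in the package (generating process, mediator, outcome,
imputation) uses the same baseline-covariate design so that the exact
enumeration oracle and the fitted estimators live on a common scale:

    age_dec   (age_years - 70) / 10           linear, per decade
    female    1 if sex == "female"
    dep2..dep5 indicator contrasts against quintile 1 (least deprived)
    eth_other 1 if ethnicity == "other"
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AGE_CENTER = 70.0

CONFOUNDER_TERMS = ("age_dec", "female", "dep2", "dep3", "dep4", "dep5", "eth_other")
N_CONFOUNDER_TERMS = len(CONFOUNDER_TERMS)

SEX_LEVELS = ("male", "female")
ETHNICITY_LEVELS = ("white", "other")
ROUTE_LEVELS = ("elective", "emergency")
DEPRIVATION_LEVELS = (1, 2, 3, 4, 5)


def confounder_matrix(df: pd.DataFrame) -> np.ndarray:
    """Encode the baseline confounders of a cohort frame as an (n, 7) array."""
    n = len(df)
    X = np.empty((n, N_CONFOUNDER_TERMS), dtype=float)
    X[:, 0] = (df["age"].to_numpy(dtype=float) - AGE_CENTER) / 10.0
    X[:, 1] = (df["sex"].to_numpy() == "female").astype(float)
    dep = df["deprivation"].to_numpy(dtype=int)
    for j, level in enumerate((2, 3, 4, 5)):
        X[:, 2 + j] = (dep == level).astype(float)
    X[:, 6] = (df["ethnicity"].to_numpy() == "other").astype(float)
    return X


def confounder_matrix_from_grid(
    age: np.ndarray, female: np.ndarray, dep: np.ndarray, eth_other: np.ndarray
) -> np.ndarray:
    """Same encoding, but from raw component arrays (used by the enumeration grid)."""
    X = np.empty((len(age), N_CONFOUNDER_TERMS), dtype=float)
    X[:, 0] = (age - AGE_CENTER) / 10.0
    X[:, 1] = female
    for j, level in enumerate((2, 3, 4, 5)):
        X[:, 2 + j] = (dep == level).astype(float)
    X[:, 6] = eth_other
    return X
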