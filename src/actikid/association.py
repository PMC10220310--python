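"""Association analysis: screening, standardized regression, HRQoL model.

Workflow mirrored here: (i) univariate Spearman rank correlations between
each candidate factor and the activity outcome, carried forward at the
liberal p <= 0.2 criterion to limit false negatives; (ii) per-parent-action
two-predictor models adjusting for mobility capacity; (iii) a multivariable
ordinary-least-squares model on listwise-complete rows with every variable
standardized to unit variance, reporting standardized coefficients with 95%
CIs, structural coefficients (squared correlation between a predictor and
the fitted outcome), and the design-matrix condition number as a
multicollinearity diagnostic; (iv) a pre-specified model for health-related
quality of life (PedsQL total = mean of contributing item scores, 0-4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

PARENT_ACTION_COLUMNS = [f"parent_action_{i}" for i in range(1, 20)]

#: candidate explanatory factors screened for the activity models
DEFAULT_CANDIDATES = [
    "age_months",
    "sex",
    "imd_decile",
    "pathway",
    "mobility",
    "social_cognitive",
    "carer_work_hours",
    "time_to_outdoors",
    "max_daily_temp",
    *PARENT_ACTION_COLUMNS,
]

#: pre-specified predictors of the HRQoL model (no screening)
HRQOL_PREDICTORS = [
    "age_months",
    "imd_decile",
    "mobility",
    "social_cognitive",
    "pathway",
    "prop_active",
]


class AssociationError(ValueError):
    pass


class CollinearityWarning(UserWarning):
    pass


@dataclass
class RegressionResult:
    outcome: str
    n_used: int
    r_squared: float
    adj_r_squared: float
    condition_number: float
    table: pd.DataFrame  # index term: beta, ci_low, ci_high, p, rs2
    warnings: list = field(default_factory=list)

    def to_tidy(self) -> pd.DataFrame:
        df = self.table.reset_index(names="term")
        df.insert(0, "outcome", self.outcome)
        return df


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


def spearman_screen(
    table: pd.DataFrame,
    outcome: str,
    candidates: list[str] | None = None,
    alpha: float = 0.2,
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Spearman rank correlation of each candidate with the outcome on
    pairwise-complete rows; candidates with p <= alpha are selected.

    p-values use the t approximation for n > 20 and a seeded Monte-Carlo
    permutation test for n <= 20. Constant candidates are excluded with a
    warning.
    """
    if outcome not in table.columns:
        raise AssociationError(f"outcome {outcome!r} not in table")
    if candidates is None:
        candidates = [c for c in DEFAULT_CANDIDATES if c in table.columns]
    rng = np.random.default_rng(seed)
    rows = []
    for cov in candidates:
        pair = table[[outcome, cov]].dropna()
        n = len(pair)
        if n < 3:
            raise AssociationError(f"fewer than 3 complete pairs for {cov!r}")
        x = pair[cov].to_numpy(dtype=float)
        y = pair[outcome].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"constant column {cov!r} excluded from screen", UserWarning)
            continue
        rho, p = stats.spearmanr(x, y)
        if n <= 20:
            p = _permutation_p(x, y, rho, n_permutations, rng)
        rows.append({"term": cov, "rho": rho, "p": p, "n": n, "selected": p <= alpha})
    return pd.DataFrame(
        rows, columns=["term", "rho", "p", "n", "selected"]
    ).set_index("term")


def _permutation_p(x, y, rho_obs, n_permutations, rng):
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    hits = 0
    for _ in range(n_permutations):
        rho = np.corrcoef(rx, rng.permutation(ry))[0, 1]
        if abs(rho) >= abs(rho_obs) - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# Standardization and OLS
# ---------------------------------------------------------------------------


def standardize(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Scale each listed variable to zero mean and unit (sample) variance on
    its non-missing rows. Categorical 0/1 codes are standardized like any
    numeric column, matching the standardized-coefficient convention."""
    out = table.copy()
    for v in variables:
        col = pd.to_numeric(out[v], errors="coerce")
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise AssociationError(f"variable {v!r} has zero variance")
        out[v] = (col - col.mean()) / sd
    return out


def fit_multivariable(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    min_rows: int | None = None,
) -> RegressionResult:
    """OLS of the standardized outcome on standardized predictors,
    listwise-complete rows only.

    Standardization is performed on the analysis (complete-case) sample.
    Reports standardized betas with 95% CIs and p-values, R2 and adjusted
    R2, each predictor's structural coefficient r_s^2 (squared Pearson
    correlation with the fitted values), and the condition number of the
    standardized design matrix (largest/smallest singular value, intercept
    excluded).
    """
    missing = [c for c in [outcome, *predictors] if c not in table.columns]
    if missing:
        raise AssociationError(f"columns not in table: {missing}")
    data = table[[outcome, *predictors]].apply(pd.to_numeric, errors="coerce").dropna()
    n = len(data)
    need = max(len(predictors) + 2, min_rows or 0)
    if n < need:
        raise AssociationError(f"only {n} complete rows; need at least {need}")
    _check_rank(data[predictors])
    data = standardize(data, [outcome, *predictors])
    y = data[outcome].to_numpy()
    X = data[predictors].to_numpy()
    sv = np.linalg.svd(X, compute_uv=False)
    cond = float(sv[0] / sv[-1])
    model = sm.OLS(y, sm.add_constant(X)).fit()
    ci = model.conf_int(alpha=0.05)
    fitted = model.fittedvalues
    notes = []
    rs2 = []
    for j in range(X.shape[1]):
        r = np.corrcoef(X[:, j], fitted)[0, 1] if np.std(fitted) > 0 else np.nan
        rs2.append(r**2)
    tab = pd.DataFrame(
        {
            "beta": model.params[1:],
            "ci_low": ci[1:, 0],
            "ci_high": ci[1:, 1],
            "p": model.pvalues[1:],
            "rs2": rs2,
        },
        index=predictors,
    )
    corr = np.corrcoef(X, rowvar=False) if X.shape[1] > 1 else np.ones((1, 1))
    if X.shape[1] > 1 and np.any(np.abs(corr - np.eye(len(predictors))) > 0.99):
        notes.append("near-perfect collinearity between predictors")
        warnings.warn(
            f"{outcome}: near-perfect collinearity among predictors; "
            "coefficient split is unstable",
            CollinearityWarning,
        )
    return RegressionResult(
        outcome=outcome,
        n_used=n,
        r_squared=float(model.rsquared),
        adj_r_squared=float(model.rsquared_adj),
        condition_number=cond,
        table=tab,
        warnings=notes,
    )


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    arr = arr - arr.mean(axis=0)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the aliased columns: those whose removal restores full rank
        aliased = []
        for j, col in enumerate(X.columns):
            rest = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(rest) == rank:
                aliased.append(col)
        raise AssociationError(f"rank-deficient design; aliased predictors: {aliased}")


def parent_action_model(
    table: pd.DataFrame, outcome: str, action: str
) -> RegressionResult:
    """Two-predictor standardized model of the outcome on one parent-action
    item plus mobility capacity (to allow parent actions to depend on the
    child's capacity). The action's p-value feeds the screening criterion."""
    res = fit_multivariable(table, outcome, [action, "mobility"], min_rows=10)
    return res


# ---------------------------------------------------------------------------
# HRQoL
# ---------------------------------------------------------------------------


def pedsql_total(items: np.ndarray, min_answered: float = 0.5) -> float:
    """PedsQL total score: mean of the non-missing item scores (each 0-4).

    Returns NaN with a warning when fewer than ``min_answered`` of the items
    were answered.
    """
    items = np.asarray(items, dtype=float)
    answered = np.isfinite(items)
    if answered.sum() < min_answered * items.size or answered.sum() == 0:
        warnings.warn(
            f"only {int(answered.sum())}/{items.size} items answered; total set missing",
            UserWarning,
        )
        return float("nan")
    total = float(items[answered].mean())
    if not 0.0 <= total <= 4.0:
        raise AssociationError("item scores must lie in [0, 4]")
    return total


def hrqol_model(table: pd.DataFrame, min_children: int = 20) -> RegressionResult:
    """Pre-specified model of the PedsQL total on the key child
    characteristics (age, IMD, mobility, social-cognitive capacity,
    recruitment pathway) plus total time active; no screening step."""
    avail = table["pedsql_total"].notna().sum() if "pedsql_total" in table else 0
    if avail < min_children:
        raise AssociationError(
            f"need pedsql_total for at least {min_children} children, have {avail}"
        )
    return fit_multivariable(table, "pedsql_total", HRQOL_PREDICTORS)
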