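"""Missing-outcome handling: stochastic-regression imputation, Rubin pooling
and MCAR diagnostics.

Missing outcome data (MOD) arise when a participant records zero qualifying
purchases in a period, or withdraws before it.  Missing cells are filled by
stochastic regression: an OLS fit of the observed outcome on the two
allocation stratifiers (sex, dependent children) within the same period, plus
a normal residual draw.  The primary outcome uses multiple imputation pooled
by Rubin's rules; secondary outcomes use a single stochastic fill.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ImputationSpec",
    "impute_stochastic_regression",
    "pool_rubin",
    "PooledEstimate",
    "mcar_diagnostics",
]


@dataclass(frozen=True)
class ImputationSpec:
    """Settings of one imputation run.

    ``method`` is ``"multiple"`` (m independent stochastic fills) or
    ``"single"`` (one fill).  The default predictors are the allocation
    stratifiers, which are never missing by design; ``"group"`` may be added
    — imputation theory requires every analysis-model variable in the
    imputation model for the pooled inference to be well calibrated, and
    omitting group at high missingness shrinks the group effect toward zero
    while overstating its pooled variance.

    ``proper=True`` (the default) draws the regression coefficients and
    residual variance from their posterior for every copy before drawing the
    residuals — the standard Bayesian form of stochastic-regression
    imputation, required for Rubin's pooled variance to account for
    estimation uncertainty in the fill model.  ``proper=False`` keeps the
    coefficients fixed at their estimates (fill = fitted value + N(0,
    residual SD) exactly).
    """

    method: str = "multiple"
    m: int = 20
    predictors: tuple[str, ...] = ("sex", "dependents")
    seed: int = 0
    proper: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("multiple", "single"):
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.method == "multiple" and self.m < 2:
            raise ValueError("multiple imputation requires m >= 2")

    @property
    def n_copies(self) -> int:
        return self.m if self.method == "multiple" else 1


def _design_matrix(df: pd.DataFrame, predictors: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Intercept + 0/1 predictor columns; drops collinear columns with a warning."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for p in predictors:
        v = df[p].to_numpy(dtype=float)
        cols.append(v)
        names.append(p)
    X = np.column_stack(cols)
    # graceful degradation: drop constant/collinear predictors
    while np.linalg.matrix_rank(X) < X.shape[1]:
        for j in range(X.shape[1] - 1, 0, -1):
            rest = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(X):
                warnings.warn(
                    f"imputation predictor {names[j]!r} is collinear; dropped", stacklevel=3
                )
                X = rest
                del names[j]
                break
    return X, names


def impute_stochastic_regression(
    outcomes: pd.DataFrame,
    roster: pd.DataFrame,
    column: str,
    period: str,
    spec: ImputationSpec,
    clip: tuple[float | None, float | None] = (None, None),
) -> list[pd.DataFrame]:
    """Fill the missing cells of one outcome column within one period.

    Fits OLS of the observed values on the spec's predictors (coded 0/1 from
    the roster: female=1, dependents=1) using all observations within the
    period, then replaces each missing cell with fitted value + N(0, residual
    SD); under ``spec.proper`` the coefficients and residual SD are drawn
    from their posterior afresh for each copy.  Returns ``spec.n_copies`` data frames — the rows of that period with
    the column filled and a boolean ``<column>_imputed`` provenance flag.
    Observed cells are never modified.  ``clip`` bounds out-of-range draws
    (e.g. (0, 1) for the healthiness score).
    """
    rows = outcomes[outcomes["period"] == period].copy()
    if rows.empty:
        raise ValueError(f"no outcome rows for period {period!r}")
    covars = _roster_codes(roster)
    rows = rows.merge(covars, left_on="participant_id", right_index=True, how="left")

    observed = rows[column].notna().to_numpy()
    if not observed.any():
        raise ValueError(f"cannot impute {column!r} in {period}: zero observed values")

    y = rows.loc[observed, column].to_numpy(dtype=float)
    X_obs, names = _design_matrix(rows[observed], spec.predictors)
    beta, *_ = np.linalg.lstsq(X_obs, y, rcond=None)
    resid = y - X_obs @ beta
    sse = float(resid @ resid)
    dof = max(len(y) - X_obs.shape[1], 1)
    resid_sd = float(np.sqrt(sse / dof))
    xtx_inv = np.linalg.pinv(X_obs.T @ X_obs)
    chol = np.linalg.cholesky(xtx_inv + 1e-12 * np.eye(len(beta)))

    X_mis = np.column_stack(
        [np.ones(int((~observed).sum()))]
        + [rows.loc[~observed, n].to_numpy(dtype=float) for n in names[1:]]
    )

    out_cols = [c for c in outcomes.columns]
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_copies)
    copies = []
    lo, hi = clip
    for ss in streams:
        rng = np.random.default_rng(ss)
        if spec.proper and resid_sd > 0:
            sigma = float(np.sqrt(sse / rng.chisquare(dof)))
            beta_k = beta + sigma * (chol @ rng.standard_normal(len(beta)))
        else:
            sigma = resid_sd
            beta_k = beta
        fills = X_mis @ beta_k + rng.normal(0.0, sigma, size=len(X_mis))
        if lo is not None or hi is not None:
            fills = np.clip(fills, lo, hi)
        copy = rows[out_cols].copy()
        copy.loc[~observed, column] = fills
        copy[f"{column}_imputed"] = ~observed
        copies.append(copy)
    return copies


def _roster_codes(roster: pd.DataFrame) -> pd.DataFrame:
    """0/1 codings indexed by participant id (female=1, dependents yes=1,
    intervention=1)."""
    idx = roster.set_index("id")
    sex = idx["sex"]
    dep = idx["dependents"]
    codes = pd.DataFrame(
        {
            "sex": np.where(sex.astype(str).str.lower().isin(["female", "f", "1"]), 1.0, 0.0),
            "dependents": np.where(dep.astype(str).str.lower().isin(["yes", "y", "1"]), 1.0, 0.0),
        },
        index=idx.index,
    )
    if "group" in idx.columns:
        codes["group"] = np.where(idx["group"].astype(str) == "intervention", 1.0, 0.0)
    return codes


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin-pooled estimate across m imputed copies."""

    estimate: float
    se: float
    df: float
    t: float
    p: float
    within: float
    between: float
    m: int


def pool_rubin(
    estimates, variances, dfcom: float | None = None
) -> PooledEstimate:
    """Pool per-copy estimates and variances by Rubin's rules.

    Total variance = mean within-variance + (1 + 1/m) × between-variance;
    degrees of freedom by the Barnard–Rubin small-sample formula when the
    complete-data df (``dfcom``) is given, else the classical large-sample
    Rubin df.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling requires at least 2 imputed copies")
    qbar = float(q.mean())
    within = float(u.mean())
    between = float(np.var(q, ddof=1))
    total = within + (1 + 1 / m) * between

    if total <= 0:
        return PooledEstimate(qbar, 0.0, float("inf"), float("inf"), 0.0, within, between, m)
    lam = (1 + 1 / m) * between / total
    if lam <= 0:
        df = (
            (dfcom + 1) / (dfcom + 3) * dfcom if dfcom is not None else float("inf")
        )
    else:
        df_old = (m - 1) / lam**2
        if dfcom is not None:
            df_obs = (dfcom + 1) / (dfcom + 3) * dfcom * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
    se = float(np.sqrt(total))
    t = qbar / se if se > 0 else float("inf")
    if np.isinf(df):
        p = float(2 * sps.norm.sf(abs(t)))
    else:
        p = float(2 * sps.t.sf(abs(t), df))
    return PooledEstimate(qbar, se, float(df), float(t), p, within, between, m)


def mcar_diagnostics(
    outcomes: pd.DataFrame,
    roster: pd.DataFrame,
    column: str = "healthiness",
    correction: bool = False,
) -> dict[str, dict]:
    """Chi-square tests of "any missing outcome across the 3 periods" against
    each allocation stratifier.

    A small p-value indicates missingness associated with the stratifier
    (evidence against MCAR with respect to it).  No Yates correction by
    default, configurable via ``correction``.
    """
    miss = (
        outcomes.assign(miss=outcomes[column].isna())
        .groupby("participant_id")["miss"]
        .any()
    )
    covars = _roster_codes(roster)
    results = {}
    for strat in ("sex", "dependents"):
        table = pd.crosstab(covars[strat].reindex(miss.index), miss)
        if table.shape != (2, 2):
            results[strat] = {"statistic": 0.0, "df": 0, "p": 1.0, "table": table.to_numpy().tolist()}
            continue
        chi2, p, df, _ = sps.chi2_contingency(table.to_numpy(), correction=correction)
        results[strat] = {
            "statistic": float(chi2),
            "df": int(df),
            "p": float(p),
            "table": table.to_numpy().tolist(),
        }
    return results
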