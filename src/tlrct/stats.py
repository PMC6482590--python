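"""Effect estimation for the two-arm trial.

The primary model is the baseline-adjusted ANCOVA of Vickers & Altman: the
follow-up outcome regressed on the two allocation stratifiers, the baseline
outcome and allocation group; the group coefficient is the treatment effect.
Codings throughout: female = 1, dependents = 1, intervention = 1, so a
positive group effect means the intervention arm is healthier.

Non-normal outcomes route to an unadjusted Mann-Whitney U test (exact
permutation enumeration for small samples, tie-corrected normal approximation
otherwise).  Allocation itself is stratified permuted-block randomization.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AncovaFit",
    "TestResult",
    "ancova_group_effect",
    "mann_whitney",
    "subgroup_ancova",
    "interaction_test",
    "block_randomize",
    "normality_gate",
]


@dataclass(frozen=True)
class AncovaFit:
    """An OLS fit of the baseline-adjusted group-effect model."""

    terms: tuple[str, ...]
    coef: dict
    se: dict
    t: dict
    p: dict
    resid_sd: float
    n: int
    df_resid: int

    @property
    def group_effect(self) -> float:
        return self.coef["group"]

    @property
    def group_p(self) -> float:
        return self.p["group"]


@dataclass(frozen=True)
class TestResult:
    """A single hypothesis-test result."""

    statistic: float
    name: str  # one of "U", "X2", "t"
    p: float
    df: float | None = None
    adjusted: bool = False


def _ols(X: np.ndarray, y: np.ndarray, terms: list[str]) -> AncovaFit:
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"need n >= {k + 1} observations for {k} parameters, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the collinear columns via the QR diagonal
        _, R = np.linalg.qr(X)
        bad = [terms[j] for j in range(k) if abs(R[j, j]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad or terms}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n - k
    sigma2 = float(resid @ resid) / df_resid
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
    pvals = 2 * sps.t.sf(np.abs(tvals), df_resid)
    return AncovaFit(
        terms=tuple(terms),
        coef=dict(zip(terms, beta.astype(float))),
        se=dict(zip(terms, se.astype(float))),
        t=dict(zip(terms, tvals.astype(float))),
        p=dict(zip(terms, pvals.astype(float))),
        resid_sd=float(np.sqrt(sigma2)),
        n=n,
        df_resid=df_resid,
    )


def ancova_group_effect(
    outcome,
    sex,
    dependents,
    group,
    baseline=None,
) -> AncovaFit:
    """Fit ``outcome = b0 + b1·sex + b2·dependents + b3·baseline + b4·group``.

    ``baseline`` may be omitted (e.g. for the first trial period, which has
    nothing earlier to adjust for).  All covariates are numeric 0/1 codes; no
    cell may be missing — run after imputation or on complete cases.
    """
    y = np.asarray(outcome, dtype=float)
    cols = [np.ones(len(y)), np.asarray(sex, float), np.asarray(dependents, float)]
    terms = ["intercept", "sex", "dependents"]
    if baseline is not None:
        cols.append(np.asarray(baseline, float))
        terms.append("baseline")
    cols.append(np.asarray(group, float))
    terms.append("group")
    X = np.column_stack(cols)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing cells in the ANCOVA inputs; impute or subset first")
    return _ols(X, y, terms)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of sample x: rank-sum formula, ties shared (equivalent to pairwise
    wins + half-ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)


def mann_whitney(x, y, exact_max_n: int = 8) -> TestResult:
    """Two-sided Mann-Whitney U test (unadjusted).

    When both samples have at most ``exact_max_n`` observations the p-value is
    computed by exhaustive enumeration of group relabelings (exact even with
    ties); otherwise a tie-corrected normal approximation with continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if n1 <= exact_max_n and n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        obs_dev = abs(u - mu)
        hits = 0
        total = 0
        idx = range(n1 + n2)
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                hits += 1
        p = hits / total
        return TestResult(statistic=u, name="U", p=float(p))

    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(statistic=u, name="U", p=1.0)
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    p = float(2 * sps.norm.sf(max(z, 0.0)))
    return TestResult(statistic=u, name="U", p=min(p, 1.0))


def subgroup_ancova(
    data: pd.DataFrame, ses_column: str = "ses_high"
) -> dict[str, AncovaFit | None]:
    """One ANCOVA per socioeconomic stratum (NS-SEC 1–2 vs 3–5).

    ``data`` needs columns outcome, baseline, sex, dependents, group and a 0/1
    ``ses_column`` (1 = NS-SEC 1–2); rows with missing SES are excluded.
    Empty strata are skipped with a warning and reported as None.
    """
    out: dict[str, AncovaFit | None] = {}
    usable = data[data[ses_column].notna()]
    for label, flag in (("nssec_1_2", 1), ("nssec_3_5", 0)):
        sub = usable[usable[ses_column] == flag]
        if sub.empty:
            warnings.warn(f"SES stratum {label} is empty; skipped", stacklevel=2)
            out[label] = None
            continue
        out[label] = ancova_group_effect(
            sub["outcome"], sub["sex"], sub["dependents"], sub["group"], sub["baseline"]
        )
    return out


def interaction_test(data: pd.DataFrame, ses_column: str = "ses_high") -> TestResult:
    """t-test of the group × SES interaction added to the ANCOVA."""
    usable = data[data[ses_column].notna()]
    y = usable["outcome"].to_numpy(dtype=float)
    ses = usable[ses_column].to_numpy(dtype=float)
    group = usable["group"].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(y)),
            usable["sex"].to_numpy(dtype=float),
            usable["dependents"].to_numpy(dtype=float),
            usable["baseline"].to_numpy(dtype=float),
            group,
            ses,
            group * ses,
        ]
    )
    terms = ["intercept", "sex", "dependents", "baseline", "group", "ses", "group_x_ses"]
    fit = _ols(X, y, terms)
    return TestResult(
        statistic=fit.t["group_x_ses"],
        name="t",
        p=fit.p["group_x_ses"],
        df=fit.df_resid,
        adjusted=True,
    )


def block_randomize(
    roster: pd.DataFrame, block_size: int = 4, seed: int = 0
) -> pd.Series:
    """Stratified permuted-block allocation to intervention/control.

    Strata are the four sex × dependents cells.  Within each stratum,
    participants (in sorted-id order, so the result is invariant to roster row
    order) are assigned from consecutive randomly permuted blocks containing
    ``block_size/2`` of each arm; any complete block is exactly balanced.
    """
    if block_size % 2 != 0 or block_size <= 0:
        raise ValueError("block_size must be a positive even number")
    strata = sorted(
        roster.groupby(
            [roster["sex"].astype(str), roster["dependents"].astype(str)]
        ).groups.items()
    )
    assignment = pd.Series(index=roster["id"].to_numpy(), dtype="object", name="group")
    half = block_size // 2
    for s_idx, (_, row_idx) in enumerate(strata):
        ids = sorted(roster.loc[row_idx, "id"])
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(s_idx,)))
        labels = []
        while len(labels) < len(ids):
            block = np.array(["intervention"] * half + ["control"] * half)
            rng.shuffle(block)
            labels.extend(block)
        assignment.loc[ids] = labels[: len(ids)]
    return assignment


def normality_gate(values, alpha: float = 0.05) -> str:
    """Route an outcome to ANCOVA ("normal") or Mann-Whitney ("non_normal")
    by a Shapiro–Wilk test at ``alpha``; degenerate inputs are non-normal."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 3:
        warnings.warn("fewer than 3 values; treating as non-normal", stacklevel=2)
        return "non_normal"
    if np.ptp(arr) == 0:
        warnings.warn("constant values; treating as non-normal", stacklevel=2)
        return "non_normal"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = sps.shapiro(arr if arr.size <= 5000 else arr[:5000])
    return "normal" if p > alpha else "non_normal"
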