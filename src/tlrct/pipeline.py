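"""End-to-end analysis orchestration: validation, aggregation, imputation,
effect estimation and report assembly.

`analyze_trial` is the pure in-memory pipeline; `run_analysis` wraps it with
file I/O (CSV inputs, CSV/JSON/plain-text outputs).  With a fixed seed the
machine-readable outputs are byte-identical across runs.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imputation as imp
from . import stats as st
from .labeling import label_catalog
from .ledger import (
    OUTCOME_PERIODS,
    SECONDARY_OUTCOMES,
    StudyCalendar,
    build_outcome_table,
    filter_scope,
    truncate_at_withdrawal,
)
from .scoring import score_catalog

__all__ = ["RunConfig", "ValidationReport", "validate_inputs", "analyze_trial", "run_analysis"]

log = logging.getLogger("tlrct")

CATALOG_COLUMNS = [
    "product_id", "category", "own_brand", "fat_100g", "satfat_100g",
    "sugars_100g", "salt_100g", "pack_weight_g", "price",
]
ROSTER_COLUMNS = ["id", "sex", "dependents", "nssec", "group", "withdrawal_date",
                  "q_t0", "q_t1", "q_t2"]
TRANSACTION_COLUMNS = ["participant_id", "date", "product_id", "quantity", "spend"]


@dataclass(frozen=True)
class RunConfig:
    """Settings of one analysis run."""

    catalog_path: str
    roster_path: str
    transactions_path: str
    calendar_start: dt.date = dt.date(2014, 11, 11)
    m_imputations: int = 20
    seed: int = 0
    alpha: float = 0.05
    subgroups: bool = True
    interaction: bool = True
    #: force a route per secondary outcome: {"spend_total": "mann_whitney", ...}
    normality_overrides: dict = field(default_factory=dict)
    outdir: str = "results"


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    issues: tuple[str, ...]


def validate_inputs(
    catalog: pd.DataFrame, roster: pd.DataFrame, transactions: pd.DataFrame
) -> ValidationReport:
    """Schema and referential-integrity checks; returns itemized issues."""
    issues: list[str] = []
    for name, df, cols in (
        ("catalog", catalog, CATALOG_COLUMNS),
        ("roster", roster, ROSTER_COLUMNS),
        ("transactions", transactions, TRANSACTION_COLUMNS),
    ):
        for c in cols:
            if c not in df.columns:
                issues.append(f"{name}: missing required column {c!r}")
    if issues:
        return ValidationReport(False, tuple(issues))

    for col in ("fat_100g", "satfat_100g", "sugars_100g", "salt_100g", "pack_weight_g", "price"):
        bad = catalog.index[catalog[col].astype(float) < 0].tolist()
        if bad:
            issues.append(f"catalog: negative {col} at rows {bad[:10]}")
    if catalog["product_id"].duplicated().any():
        dup = catalog["product_id"][catalog["product_id"].duplicated()].tolist()
        issues.append(f"catalog: duplicated product ids {dup[:10]}")
    if roster["id"].duplicated().any():
        issues.append("roster: duplicated participant ids")
    bad_group = roster.index[~roster["group"].isin(["intervention", "control"])].tolist()
    if bad_group:
        issues.append(f"roster: invalid group at rows {bad_group[:10]}")

    dates = pd.to_datetime(transactions["date"], errors="coerce")
    bad_dates = transactions.index[dates.isna()].tolist()
    if bad_dates:
        issues.append(f"transactions: unparsable dates at rows {bad_dates[:10]}")
    if (transactions["quantity"].astype(float) < 1).any():
        rows = transactions.index[transactions["quantity"].astype(float) < 1].tolist()
        issues.append(f"transactions: quantity < 1 at rows {rows[:10]}")
    if (transactions["spend"].astype(float) < 0).any():
        rows = transactions.index[transactions["spend"].astype(float) < 0].tolist()
        issues.append(f"transactions: negative spend at rows {rows[:10]}")

    unknown_products = sorted(set(transactions["product_id"]) - set(catalog["product_id"]))
    if unknown_products:
        issues.append(f"transactions: unknown product ids {unknown_products[:10]}")
    unknown_participants = sorted(set(transactions["participant_id"]) - set(roster["id"]))
    if unknown_participants:
        issues.append(f"transactions: unknown participant ids {unknown_participants[:10]}")
    return ValidationReport(not issues, tuple(issues))


def _roster_frame(roster: pd.DataFrame) -> pd.DataFrame:
    """Numeric codings indexed by id: sex (female=1), dependents (yes=1),
    group (intervention=1), ses_high (NS-SEC 1-2 = 1, 3-5 = 0, else NA)."""
    codes = imp._roster_codes(roster)
    idx = roster.set_index("id")
    codes["group"] = np.where(idx["group"].astype(str) == "intervention", 1.0, 0.0)
    nssec = pd.to_numeric(idx["nssec"], errors="coerce")
    codes["ses_high"] = np.where(
        nssec.isin([1, 2]), 1.0, np.where(nssec.isin([3, 4, 5]), 0.0, np.nan)
    )
    return codes


def _arm_means(values: pd.Series, group: pd.Series) -> dict:
    out = {}
    for arm, flag in (("control", 0.0), ("intervention", 1.0)):
        v = values[group == flag].dropna().to_numpy(dtype=float)
        out[arm] = {
            "n": int(v.size),
            "mean": float(v.mean()) if v.size else None,
            "se": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else None,
        }
    return out


def _wide(outcomes: pd.DataFrame, column: str) -> pd.DataFrame:
    return outcomes.pivot(index="participant_id", columns="period", values=column)


def analyze_trial(
    catalog: pd.DataFrame,
    roster: pd.DataFrame,
    transactions: pd.DataFrame,
    calendar: StudyCalendar,
    m: int = 20,
    seed: int = 0,
    alpha: float = 0.05,
    subgroups: bool = True,
    interaction: bool = True,
    normality_overrides: dict | None = None,
    secondaries: bool = True,
    mi_predictors: tuple[str, ...] = ("sex", "dependents", "group"),
) -> tuple[dict, pd.DataFrame]:
    """Run the full analysis; returns (results dict, outcome table).

    Primary outcome: multiple imputation (m stochastic-regression fills per
    period, paired across periods) feeding the baseline-adjusted ANCOVA,
    pooled by Rubin's rules; at baseline the model has no earlier measure to
    adjust for.  Secondary outcomes: single imputation, then ANCOVA or
    Mann-Whitney per the normality gate.  A complete-case sensitivity
    analysis restricts to participants with observed purchases in both
    baseline and the analysis period.

    ``mi_predictors`` sets the imputation-model covariates.  The default adds
    allocation group to the two stratifiers: with group omitted, fills are
    independent of allocation, which biases the pooled group effect toward
    zero and makes its Rubin variance badly conservative at high missingness
    (uncongenial imputation).  Pass ``("sex", "dependents")`` to reproduce the
    stratifier-only scheme.
    """
    normality_overrides = normality_overrides or {}
    scored = score_catalog(label_catalog(catalog))

    tx = truncate_at_withdrawal(transactions, roster)
    _, filter_counts = filter_scope(tx, scored)
    outcomes = build_outcome_table(roster, transactions, scored, calendar)
    codes = _roster_frame(roster)

    reasons = {
        p: outcomes[outcomes["period"] == p]["missing_reason"].value_counts().to_dict()
        for p in OUTCOME_PERIODS
    }

    # --- primary outcome under multiple imputation
    seeds = np.random.SeedSequence(seed).generate_state(len(OUTCOME_PERIODS) + 1)
    copies_by_period: dict[str, list[pd.DataFrame]] = {}
    for k, period in enumerate(OUTCOME_PERIODS):
        spec = imp.ImputationSpec(
            method="multiple", m=m, seed=int(seeds[k] % (2**31)), predictors=mi_predictors
        )
        copies_by_period[period] = imp.impute_stochastic_regression(
            outcomes, roster, "healthiness", period, spec, clip=(0.0, 1.0)
        )

    def _aligned(copy: pd.DataFrame) -> pd.Series:
        return copy.set_index("participant_id")["healthiness"].reindex(codes.index)

    primary = {}
    for period in OUTCOME_PERIODS:
        ests, variances = [], []
        for k in range(m):
            y = _aligned(copies_by_period[period][k])
            base = _aligned(copies_by_period["T-1"][k]) if period != "T-1" else None
            fit = st.ancova_group_effect(
                y, codes["sex"], codes["dependents"], codes["group"], base
            )
            ests.append(fit.group_effect)
            variances.append(fit.se["group"] ** 2)
        dfcom = len(codes) - (5 if period != "T-1" else 4)
        pooled = imp.pool_rubin(ests, variances, dfcom=dfcom)
        observed = outcomes[outcomes["period"] == period].set_index("participant_id")[
            "healthiness"
        ].reindex(codes.index)
        primary[period] = {
            "arm_means_observed": _arm_means(observed, codes["group"]),
            "effect": {
                "estimate": pooled.estimate,
                "se": pooled.se,
                "df": pooled.df,
                "p": pooled.p,
                "m": pooled.m,
            },
        }

    # --- complete-case sensitivity analysis
    wide = _wide(outcomes, "healthiness")
    complete_case = {}
    for period in ("T1", "T2"):
        cc = wide[["T-1", period]].dropna()
        sub = codes.loc[cc.index]
        fit = st.ancova_group_effect(
            cc[period], sub["sex"], sub["dependents"], sub["group"], cc["T-1"]
        )
        complete_case[period] = {
            "n": int(len(cc)),
            "estimate": fit.group_effect,
            "se": fit.se["group"],
            "p": fit.group_p,
        }

    # --- MOD diagnostics
    mod = imp.mcar_diagnostics(outcomes, roster)

    results: dict = {
        "n_participants": int(len(roster)),
        "filter_counts": filter_counts,
        "missingness": reasons,
        "mod_diagnostics": mod,
        "primary": primary,
        "primary_complete_case": complete_case,
    }

    # --- secondary outcomes (single imputation; gate to ANCOVA or MW)
    if secondaries:
        secondary: dict = {}
        for j, col in enumerate(SECONDARY_OUTCOMES):
            secondary[col] = {}
            single_fills = {}
            for k, period in enumerate(OUTCOME_PERIODS):
                spec = imp.ImputationSpec(
                    method="single",
                    seed=int((seeds[-1] + 1000 * j + k) % (2**31)),
                    predictors=mi_predictors,
                )
                single_fills[period] = imp.impute_stochastic_regression(
                    outcomes, roster, col, period, spec, clip=(0.0, None)
                )[0]
            for period in OUTCOME_PERIODS:
                y = single_fills[period].set_index("participant_id")[col].reindex(codes.index)
                route = normality_overrides.get(
                    col, "ancova" if st.normality_gate(y, alpha) == "normal" else "mann_whitney"
                )
                entry: dict = {
                    "route": route,
                    "arm_means": _arm_means(y, codes["group"]),
                }
                if route == "ancova" and period != "T-1":
                    base = (
                        single_fills["T-1"].set_index("participant_id")[col].reindex(codes.index)
                    )
                    fit = st.ancova_group_effect(
                        y, codes["sex"], codes["dependents"], codes["group"], base
                    )
                    entry["effect"] = {
                        "estimate": fit.group_effect, "se": fit.se["group"], "p": fit.group_p,
                    }
                else:
                    res = st.mann_whitney(
                        y[codes["group"] == 1.0].dropna(), y[codes["group"] == 0.0].dropna()
                    )
                    entry["route"] = "mann_whitney"
                    entry["effect"] = {"U": res.statistic, "p": res.p}
                secondary[col][period] = entry
        results["secondary"] = secondary

    # --- SES subgroup and interaction analyses on the primary outcome
    if subgroups or interaction:
        sub_results: dict = {}
        int_results: dict = {}
        for period in ("T1", "T2"):
            per_stratum: dict = {"nssec_1_2": [], "nssec_3_5": []}
            int_est, int_var = [], []
            for k in range(m):
                data = pd.DataFrame(
                    {
                        "outcome": _aligned(copies_by_period[period][k]),
                        "baseline": _aligned(copies_by_period["T-1"][k]),
                        "sex": codes["sex"],
                        "dependents": codes["dependents"],
                        "group": codes["group"],
                        "ses_high": codes["ses_high"],
                    }
                )
                if subgroups:
                    fits = st.subgroup_ancova(data)
                    for name, fit in fits.items():
                        if fit is not None:
                            per_stratum[name].append((fit.group_effect, fit.se["group"] ** 2))
                if interaction:
                    usable = data[data["ses_high"].notna()]
                    coef, se = _interaction_coef(usable)
                    int_est.append(coef)
                    int_var.append(se**2)
            if subgroups:
                sub_results[period] = {}
                for name, pairs in per_stratum.items():
                    if not pairs:
                        sub_results[period][name] = None
                        continue
                    pooled = imp.pool_rubin([e for e, _ in pairs], [v for _, v in pairs])
                    sub_results[period][name] = {
                        "estimate": pooled.estimate, "se": pooled.se, "p": pooled.p,
                    }
            if interaction:
                pooled = imp.pool_rubin(int_est, int_var)
                int_results[period] = {
                    "estimate": pooled.estimate, "se": pooled.se, "p": pooled.p,
                }
        if subgroups:
            results["subgroups"] = sub_results
        if interaction:
            results["interaction"] = int_results

    return results, outcomes


def _interaction_coef(usable: pd.DataFrame) -> tuple[float, float]:
    """Coefficient and SE of group × SES in the augmented ANCOVA."""
    y = usable["outcome"].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(y)),
            usable["sex"], usable["dependents"], usable["baseline"],
            usable["group"], usable["ses_high"],
            usable["group"].to_numpy() * usable["ses_high"].to_numpy(),
        ]
    )
    terms = ["intercept", "sex", "dependents", "baseline", "group", "ses", "group_x_ses"]
    full = st._ols(X.astype(float), y, terms)
    return full.coef["group_x_ses"], full.se["group_x_ses"]


def _render_report(results: dict) -> str:
    """Plain-text report mirroring the per-arm mean (SE) / p layout."""
    lines = [
        "Trial analysis report",
        "=" * 60,
        f"participants: {results['n_participants']}",
        "",
        "Scope filter (in-period transactions): "
        + ", ".join(f"{k}={v}" for k, v in results["filter_counts"].items()),
        "",
        "Primary outcome: label healthiness of own-brand ready meals & pizzas",
        f"{'period':>8} {'control mean (SE)':>22} {'intervention mean (SE)':>24} "
        f"{'effect':>9} {'p':>7}",
    ]
    for period, entry in results["primary"].items():
        am = entry["arm_means_observed"]

        def fmt(arm):
            m_, s = am[arm]["mean"], am[arm]["se"]
            return f"{m_:.3f} ({s:.3f})" if m_ is not None and s is not None else "--"

        eff = entry["effect"]
        lines.append(
            f"{period:>8} {fmt('control'):>22} {fmt('intervention'):>24} "
            f"{eff['estimate']:>9.4f} {eff['p']:>7.3f}"
        )
    lines.append("")
    lines.append("Complete-case sensitivity (observed baseline and period):")
    for period, entry in results["primary_complete_case"].items():
        lines.append(
            f"{period:>8} n={entry['n']:<5} effect={entry['estimate']:.4f} "
            f"(SE {entry['se']:.4f}) p={entry['p']:.3f}"
        )
    lines.append("")
    lines.append("Missing-data (MOD) chi-square diagnostics:")
    for strat, r in results["mod_diagnostics"].items():
        lines.append(f"  {strat}: X2={r['statistic']:.3f} df={r['df']} p={r['p']:.3f}")
    if "secondary" in results:
        lines.append("")
        lines.append("Secondary outcomes (single imputation):")
        for col, periods in results["secondary"].items():
            for period, entry in periods.items():
                eff = entry["effect"]
                p = eff.get("p")
                lines.append(f"  {col:>14} {period:>4} route={entry['route']:<13} p={p:.3f}")
    return "\n".join(lines) + "\n"


def load_inputs(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    catalog = pd.read_csv(config.catalog_path)
    roster = pd.read_csv(config.roster_path, dtype={"nssec": "string"})
    transactions = pd.read_csv(config.transactions_path, parse_dates=["date"])
    return catalog, roster, transactions


def run_analysis(config: RunConfig) -> dict:
    """Validate inputs, run the pipeline and write the report bundle.

    Writes ``outcomes.csv``, ``results.json`` and ``report.txt`` under
    ``config.outdir``.  Nothing is written if validation or analysis fails.
    """
    catalog, roster, transactions = load_inputs(config)
    report = validate_inputs(catalog, roster, transactions)
    if not report.ok:
        raise ValueError("input validation failed:\n" + "\n".join(report.issues))

    calendar = StudyCalendar(start=config.calendar_start)
    results, outcomes = analyze_trial(
        catalog, roster, transactions, calendar,
        m=config.m_imputations, seed=config.seed, alpha=config.alpha,
        subgroups=config.subgroups, interaction=config.interaction,
        normality_overrides=config.normality_overrides,
    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outcomes.to_csv(outdir / "outcomes.csv", index=False)
    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (outdir / "report.txt").write_text(_render_report(results))
    log.info("analysis written to %s", outdir)
    return results
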