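"""Trial data model and loyalty-card transaction aggregation.

The trial calendar is five contiguous periods: a 26-week baseline of
historical shopping data (T-1), 4 weeks of recruitment (T0), a 10-week data
processing gap, 6 weeks of intervention (T1) and 12 weeks of washout follow-up
(T2).  Outcomes are measured at T-1, T1 and T2 only.

The analysed scope for the primary outcome is own-brand ready meals and
pizzas that carry a complete traffic-light label; secondary spend outcomes
(fruit & vegetables, total spend) are computed over the full ledger.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OUTCOME_PERIODS",
    "SCOPE_CATEGORIES",
    "StudyCalendar",
    "assign_period",
    "filter_scope",
    "truncate_at_withdrawal",
    "aggregate_outcomes",
    "build_outcome_table",
    "OUTCOME_COLUMNS",
    "SECONDARY_OUTCOMES",
]

#: periods for which outcomes are computed, in calendar order
OUTCOME_PERIODS = ("T-1", "T1", "T2")

#: product categories eligible for the primary outcome
SCOPE_CATEGORIES = frozenset({"ready_meal", "pizza"})

#: outcome-table value columns (per participant × period)
OUTCOME_COLUMNS = [
    "healthiness",
    "items_per_week",
    "spend_rmp",
    "fat_g",
    "satfat_g",
    "sugars_g",
    "salt_g",
    "spend_fv",
    "spend_total",
]

#: secondary outcomes (everything except the primary healthiness score)
SECONDARY_OUTCOMES = [c for c in OUTCOME_COLUMNS if c != "healthiness"]


@dataclass(frozen=True)
class StudyCalendar:
    """Start date and period durations (weeks) of the trial.

    Periods run contiguously in the order baseline (T-1), recruitment (T0),
    processing gap, intervention (T1), washout (T2); intervals are half-open
    ``[start, end)``.
    """

    start: dt.date
    weeks_baseline: int = 26
    weeks_recruitment: int = 4
    weeks_gap: int = 10
    weeks_intervention: int = 6
    weeks_washout: int = 12

    def __post_init__(self) -> None:
        for name in (
            "weeks_baseline",
            "weeks_recruitment",
            "weeks_gap",
            "weeks_intervention",
            "weeks_washout",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive number of weeks")

    def _edges(self) -> dict[str, tuple[dt.date, dt.date]]:
        t = self.start
        out = {}
        for name, weeks in (
            ("T-1", self.weeks_baseline),
            ("T0", self.weeks_recruitment),
            ("gap", self.weeks_gap),
            ("T1", self.weeks_intervention),
            ("T2", self.weeks_washout),
        ):
            end = t + dt.timedelta(weeks=weeks)
            out[name] = (t, end)
            t = end
        return out

    def period_bounds(self, period: str) -> tuple[dt.date, dt.date]:
        """Half-open ``[start, end)`` bounds of a named period."""
        edges = self._edges()
        if period not in edges:
            raise ValueError(f"unknown period {period!r}")
        return edges[period]

    def period_weeks(self, period: str) -> float:
        start, end = self.period_bounds(period)
        return (end - start).days / 7.0

    @property
    def end(self) -> dt.date:
        return self.period_bounds("T2")[1]


def assign_period(date: dt.date, calendar: StudyCalendar) -> str | None:
    """Name of the outcome period containing ``date``; None for T0, the gap
    and anything outside the calendar."""
    for period in OUTCOME_PERIODS:
        start, end = calendar.period_bounds(period)
        if start <= date < end:
            return period
    return None


def _assign_period_series(dates: pd.Series, calendar: StudyCalendar) -> pd.Series:
    """Vectorized :func:`assign_period` over a datetime series."""
    out = pd.Series(pd.NA, index=dates.index, dtype="object")
    d = pd.to_datetime(dates)
    for period in OUTCOME_PERIODS:
        start, end = calendar.period_bounds(period)
        mask = (d >= pd.Timestamp(start)) & (d < pd.Timestamp(end))
        out[mask] = period
    return out


def filter_scope(
    transactions: pd.DataFrame, catalog: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Restrict transactions to the primary-outcome scope.

    Keeps transactions whose product is a ready meal or pizza, own-brand, and
    carries a complete traffic-light label (all four nutrients present).
    Returns the kept rows and a ``{reason: count}`` accounting of drops; the
    counts plus the kept rows always sum to the input row count.

    Raises ``ValueError`` listing offending ids if any transaction references
    a product absent from the catalog.
    """
    cat = catalog.set_index("product_id")
    unknown = set(transactions["product_id"]) - set(cat.index)
    if unknown:
        raise ValueError(f"transactions reference unknown product ids: {sorted(unknown)[:20]}")

    category = cat["category"].reindex(transactions["product_id"]).to_numpy()
    own = cat["own_brand"].reindex(transactions["product_id"]).to_numpy(dtype=float) > 0
    nutrient_cols = ["fat_100g", "satfat_100g", "sugars_100g", "salt_100g"]
    labelable = (
        cat[nutrient_cols].notna().all(axis=1).reindex(transactions["product_id"]).to_numpy()
    )

    in_category = np.isin(category, list(SCOPE_CATEGORIES))
    kept_mask = in_category & own & labelable
    counts = {
        "kept": int(kept_mask.sum()),
        "out_of_category": int((~in_category).sum()),
        "branded": int((in_category & ~own).sum()),
        "unlabelable": int((in_category & own & ~labelable).sum()),
    }
    return transactions[kept_mask].copy(), counts


def truncate_at_withdrawal(
    transactions: pd.DataFrame, roster: pd.DataFrame
) -> pd.DataFrame:
    """Drop each participant's transactions on or after their withdrawal date.

    Participants without a withdrawal date are untouched.
    """
    wd = roster.set_index("id")["withdrawal_date"]
    wd = pd.to_datetime(wd, errors="coerce")
    tx_wd = wd.reindex(transactions["participant_id"]).to_numpy()
    dates = pd.to_datetime(transactions["date"]).to_numpy()
    keep = pd.isna(tx_wd) | (dates < tx_wd)
    return transactions[keep].copy()


def _withdrawn_before(roster: pd.DataFrame, period_start: dt.date) -> pd.Series:
    """Boolean per participant id: withdrew strictly before the period start."""
    wd = pd.to_datetime(roster.set_index("id")["withdrawal_date"], errors="coerce")
    return wd.notna() & (wd <= pd.Timestamp(period_start))


def build_outcome_table(
    roster: pd.DataFrame,
    transactions: pd.DataFrame,
    scored_catalog: pd.DataFrame,
    calendar: StudyCalendar,
    fv_categories: frozenset[str] = frozenset({"fruit_veg"}),
) -> pd.DataFrame:
    """Aggregate per-participant per-period outcomes into a tidy table.

    ``scored_catalog`` must carry the label colours and ``score`` column (see
    ``label_catalog`` / ``score_catalog``).  One row per participant × outcome
    period with the columns of :data:`OUTCOME_COLUMNS` plus ``missing_reason``
    (``observed`` / ``zero_purchases`` / ``withdrawal``).

    Rules: the healthiness of a period is the quantity-weighted mean score of
    in-scope purchases (MISSING when there are none); per-week rates divide by
    the nominal period length; nutrient grams use the whole pack weight;
    fruit & veg and total spend run over the full ledger.  Withdrawal before a
    period start blanks the whole row for that period.
    """
    tx = truncate_at_withdrawal(transactions, roster)
    tx = tx.copy()
    tx["period"] = _assign_period_series(tx["date"], calendar)
    tx = tx[tx["period"].notna()]

    cat = scored_catalog.set_index("product_id")
    pid = tx["product_id"]
    category = cat["category"].reindex(pid).to_numpy()
    own = cat["own_brand"].reindex(pid).to_numpy(dtype=float) > 0
    score = cat["score"].reindex(pid).to_numpy(dtype=float)
    pack = cat["pack_weight_g"].reindex(pid).to_numpy(dtype=float)
    qty = tx["quantity"].to_numpy(dtype=float)
    spend = tx["spend"].to_numpy(dtype=float)

    in_scope = np.isin(category, list(SCOPE_CATEGORIES)) & own & ~np.isnan(score)
    is_fv = np.isin(category, list(fv_categories))

    agg = pd.DataFrame(
        {
            "participant_id": tx["participant_id"].to_numpy(),
            "period": tx["period"].to_numpy(),
            "scope_qty": np.where(in_scope, qty, 0.0),
            "scope_score_qty": np.where(in_scope, score * qty, 0.0),
            "scope_spend": np.where(in_scope, spend, 0.0),
            "spend_fv": np.where(is_fv, spend, 0.0),
            "spend_total": spend,
        }
    )
    for nutrient, col in (
        ("fat_g", "fat_100g"),
        ("satfat_g", "satfat_100g"),
        ("sugars_g", "sugars_100g"),
        ("salt_g", "salt_100g"),
    ):
        per100 = cat[col].reindex(pid).to_numpy(dtype=float)
        agg[nutrient] = np.where(in_scope, per100 * pack / 100.0 * qty, 0.0)

    sums = agg.groupby(["participant_id", "period"], sort=False).sum()

    grid = pd.MultiIndex.from_product(
        [roster["id"], OUTCOME_PERIODS], names=["participant_id", "period"]
    )
    sums = sums.reindex(grid, fill_value=0.0).reset_index()

    weeks = sums["period"].map({p: calendar.period_weeks(p) for p in OUTCOME_PERIODS})
    if (weeks <= 0).any():
        raise ValueError("period of zero length in calendar")
    scope_qty = sums["scope_qty"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        healthiness = np.where(
            scope_qty > 0, sums["scope_score_qty"] / np.where(scope_qty > 0, scope_qty, 1), np.nan
        )

    out = pd.DataFrame(
        {
            "participant_id": sums["participant_id"],
            "period": sums["period"],
            "healthiness": healthiness,
            "items_per_week": scope_qty / weeks,
            "spend_rmp": sums["scope_spend"] / weeks,
            "fat_g": sums["fat_g"] / weeks,
            "satfat_g": sums["satfat_g"] / weeks,
            "sugars_g": sums["sugars_g"] / weeks,
            "salt_g": sums["salt_g"] / weeks,
            "spend_fv": sums["spend_fv"] / weeks,
            "spend_total": sums["spend_total"] / weeks,
        }
    )

    reason = np.where(scope_qty > 0, "observed", "zero_purchases")
    for period in OUTCOME_PERIODS:
        start, _ = calendar.period_bounds(period)
        withdrawn = _withdrawn_before(roster, start)
        gone = out["participant_id"].map(withdrawn).fillna(False).to_numpy(dtype=bool)
        mask = (out["period"] == period).to_numpy() & gone
        reason = np.where(mask, "withdrawal", reason)
        out.loc[mask, OUTCOME_COLUMNS] = np.nan
    out["missing_reason"] = reason
    return out


def aggregate_outcomes(
    participant_id,
    period: str,
    transactions: pd.DataFrame,
    scored_catalog: pd.DataFrame,
    calendar: StudyCalendar,
    roster: pd.DataFrame | None = None,
) -> pd.Series:
    """One participant × period outcome row (see :func:`build_outcome_table`).

    Convenience wrapper used in tests and interactive work; the table builder
    is the vectorized equivalent.
    """
    if roster is None:
        roster = pd.DataFrame(
            {"id": [participant_id], "withdrawal_date": [pd.NaT]}
        )
    table = build_outcome_table(
        roster[roster["id"] == participant_id],
        transactions[transactions["participant_id"] == participant_id],
        scored_catalog,
        calendar,
    )
    row = table[(table["participant_id"] == participant_id) & (table["period"] == period)]
    if row.empty:
        raise ValueError(f"participant {participant_id!r} not found")
    return row.iloc[0]
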