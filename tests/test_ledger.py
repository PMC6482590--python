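"""Calendar assignment, scope filtering and outcome aggregation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from tlrct.labeling import label_catalog
from tlrct.ledger import (
    OUTCOME_PERIODS,
    StudyCalendar,
    aggregate_outcomes,
    assign_period,
    build_outcome_table,
    filter_scope,
    truncate_at_withdrawal,
)
from tlrct.scoring import score_catalog

CAL = StudyCalendar(dt.date(2014, 11, 11))


def _catalog(rows):
    base = {
        "product_id": [], "category": [], "own_brand": [], "fat_100g": [],
        "satfat_100g": [], "sugars_100g": [], "salt_100g": [], "pack_weight_g": [],
        "price": [],
    }
    for r in rows:
        for k in base:
            base[k].append(r.get(k))
    return score_catalog(label_catalog(pd.DataFrame(base)))


# all-green product scores 1.0; all-red scores 0.0
GREEN_MEAL = dict(product_id="g", category="ready_meal", own_brand=1, fat_100g=1.0,
                  satfat_100g=0.5, sugars_100g=2.0, salt_100g=0.1, pack_weight_g=400.0,
                  price=3.0)
RED_MEAL = dict(product_id="r", category="ready_meal", own_brand=1, fat_100g=25.0,
                satfat_100g=10.0, sugars_100g=30.0, salt_100g=3.0, pack_weight_g=400.0,
                price=2.0)


def test_calendar_periods_contiguous_and_correct_lengths():
    edges = [CAL.period_bounds(p) for p in ("T-1", "T0", "gap", "T1", "T2")]
    weeks = [26, 4, 10, 6, 12]
    for (start, end), w in zip(edges, weeks):
        assert (end - start).days == w * 7
    for (_, end), (start, _) in zip(edges, edges[1:]):
        assert end == start
    assert CAL.end - CAL.start == dt.timedelta(weeks=58)


def test_assign_period_boundaries():
    assert assign_period(CAL.start, CAL) == "T-1"
    t0_start = CAL.period_bounds("T0")[0]
    assert assign_period(t0_start - dt.timedelta(days=1), CAL) == "T-1"
    assert assign_period(t0_start, CAL) is None  # T0 is not an outcome period
    assert assign_period(CAL.start - dt.timedelta(days=1), CAL) is None
    t1_start, t1_end = CAL.period_bounds("T1")
    assert assign_period(t1_start, CAL) == "T1"
    assert assign_period(t1_end - dt.timedelta(days=1), CAL) == "T1"
    assert assign_period(t1_end, CAL) == "T2"
    assert assign_period(CAL.end, CAL) is None


def test_calendar_validation():
    with pytest.raises(ValueError):
        StudyCalendar(dt.date(2014, 11, 11), weeks_intervention=0)
    with pytest.raises(ValueError):
        CAL.period_bounds("T9")


def test_filter_scope_reasons_and_accounting():
    catalog = _catalog(
        [
            GREEN_MEAL,
            dict(RED_MEAL, product_id="branded_pizza", category="pizza", own_brand=0),
            dict(GREEN_MEAL, product_id="nosalt", salt_100g=None),
            dict(product_id="veg", category="fruit_veg", own_brand=1, pack_weight_g=100.0,
                 price=1.0),
        ]
    )
    tx = pd.DataFrame(
        {
            "participant_id": ["p1"] * 4,
            "date": ["2015-09-01"] * 4,
            "product_id": ["g", "branded_pizza", "nosalt", "veg"],
            "quantity": [1, 1, 1, 1],
            "spend": [3.0, 2.0, 3.0, 1.0],
        }
    )
    kept, counts = filter_scope(tx, catalog)
    assert kept["product_id"].tolist() == ["g"]
    assert counts == {"kept": 1, "out_of_category": 1, "branded": 1, "unlabelable": 1}
    assert sum(counts.values()) == len(tx)

    with pytest.raises(ValueError, match="ghost"):
        filter_scope(tx.assign(product_id=["g", "ghost", "nosalt", "veg"]), catalog)


def test_aggregation_arithmetic():
    """2 purchases of a score-1 product + 1 of a score-0 product over T1."""
    catalog = _catalog([GREEN_MEAL, RED_MEAL])
    t1_start = CAL.period_bounds("T1")[0]
    tx = pd.DataFrame(
        {
            "participant_id": ["p1"] * 3,
            "date": [t1_start, t1_start + dt.timedelta(days=3), t1_start + dt.timedelta(days=9)],
            "product_id": ["g", "g", "r"],
            "quantity": [1, 1, 1],
            "spend": [3.0, 3.0, 2.0],
        }
    )
    row = aggregate_outcomes("p1", "T1", tx, catalog, CAL)
    assert row["healthiness"] == pytest.approx(2 / 3)
    assert row["items_per_week"] == pytest.approx(3 / 6)  # 0.5
    assert row["spend_rmp"] == pytest.approx(8.0 / 6)
    assert row["spend_total"] == pytest.approx(8.0 / 6)
    assert row["missing_reason"] == "observed"


def test_nutrient_grams_per_week():
    """qty 2 of a 400 g meal at 10 g fat/100 g over a 4-week period -> 20 g/wk."""
    cal = StudyCalendar(dt.date(2014, 11, 11), weeks_intervention=4)
    catalog = _catalog([dict(GREEN_MEAL, fat_100g=10.0, satfat_100g=3.0)])
    t1_start = cal.period_bounds("T1")[0]
    tx = pd.DataFrame(
        {
            "participant_id": ["p1"],
            "date": [t1_start],
            "product_id": ["g"],
            "quantity": [2],
            "spend": [6.0],
        }
    )
    row = aggregate_outcomes("p1", "T1", tx, catalog, cal)
    assert row["fat_g"] == pytest.approx(10.0 * 400 / 100 * 2 / 4)  # 20 g/week
    assert row["satfat_g"] == pytest.approx(3.0 * 400 / 100 * 2 / 4)


def test_zero_purchases_missing_healthiness_but_zero_items():
    catalog = _catalog([GREEN_MEAL])
    tx = pd.DataFrame(columns=["participant_id", "date", "product_id", "quantity", "spend"])
    row = aggregate_outcomes("p1", "T1", tx, catalog, CAL)
    assert np.isnan(row["healthiness"])
    assert row["items_per_week"] == 0.0
    assert row["missing_reason"] == "zero_purchases"


def test_withdrawal_truncation():
    catalog = _catalog([GREEN_MEAL])
    t1_start = CAL.period_bounds("T1")[0]
    roster = pd.DataFrame(
        {
            "id": ["early", "mid", "stays"],
            "withdrawal_date": [CAL.period_bounds("T0")[0], t1_start + dt.timedelta(days=7), None],
        }
    )
    tx = pd.DataFrame(
        {
            "participant_id": ["early", "mid", "mid", "stays"],
            "date": [t1_start, t1_start + dt.timedelta(days=2), t1_start + dt.timedelta(days=10),
                     t1_start],
            "product_id": ["g"] * 4,
            "quantity": [1, 1, 1, 1],
            "spend": [3.0] * 4,
        }
    )
    kept = truncate_at_withdrawal(tx, roster)
    # early: everything gone; mid: only the pre-withdrawal purchase survives
    assert kept["participant_id"].tolist() == ["mid", "stays"]

    table = build_outcome_table(roster, tx, catalog, CAL).set_index(["participant_id", "period"])
    assert table.loc[("early", "T1"), "missing_reason"] == "withdrawal"
    assert np.isnan(table.loc[("early", "T1"), "healthiness"])
    assert table.loc[("mid", "T1"), "missing_reason"] == "observed"
    assert table.loc[("mid", "T1"), "items_per_week"] == pytest.approx(1 / 6)
    assert table.loc[("stays", "T1"), "missing_reason"] == "observed"


def test_outcome_table_invariants_on_synthetic_trial(small_trial, small_config):
    scored = score_catalog(label_catalog(small_trial.catalog.drop(
        columns=[c for c in small_trial.catalog.columns if c.endswith("_color")
                 or c.endswith("_intended") or c in ("score", "labelable")])))
    table = build_outcome_table(
        small_trial.roster, small_trial.transactions, scored, small_config.calendar
    )
    present = table["healthiness"].dropna()
    assert ((present >= 0) & (present <= 1)).all()
    ok = table["missing_reason"] == "observed"
    assert (table.loc[ok, "spend_fv"] <= table.loc[ok, "spend_total"] + 1e-9).all()
    # missingness flag agrees with a brute-force count of in-scope purchases
    kept, _ = filter_scope(
        truncate_at_withdrawal(small_trial.transactions, small_trial.roster), scored
    )
    kept = kept.copy()
    kept["period"] = [
        (lambda p: p if p else "none")(assign_period(d.date(), small_config.calendar))
        for d in pd.to_datetime(kept["date"])
    ]
    brute = kept.groupby(["participant_id", "period"])["quantity"].sum()
    for _, row in table.iterrows():
        n_scope = brute.get((row["participant_id"], row["period"]), 0)
        if row["missing_reason"] == "observed":
            assert n_scope > 0
        else:
            assert n_scope == 0


def test_aggregation_additivity():
    """Splitting transactions into batches and recombining matches the whole."""
    catalog = _catalog([GREEN_MEAL, RED_MEAL])
    t1 = CAL.period_bounds("T1")[0]
    rng = np.random.default_rng(5)
    tx = pd.DataFrame(
        {
            "participant_id": ["p1"] * 10,
            "date": [t1 + dt.timedelta(days=int(d)) for d in rng.integers(0, 40, 10)],
            "product_id": rng.choice(["g", "r"], 10),
            "quantity": rng.integers(1, 4, 10),
            "spend": np.round(rng.uniform(1, 5, 10), 2),
        }
    )
    whole = aggregate_outcomes("p1", "T1", tx, catalog, CAL)
    a = aggregate_outcomes("p1", "T1", tx.iloc[:4], catalog, CAL)
    b = aggregate_outcomes("p1", "T1", tx.iloc[4:], catalog, CAL)
    for col in ("items_per_week", "spend_rmp", "fat_g", "spend_total"):
        assert a[col] + b[col] == pytest.approx(whole[col])
    # weighted-mean healthiness recombines by item weights
    wa, wb = a["items_per_week"], b["items_per_week"]
    assert (a["healthiness"] * wa + b["healthiness"] * wb) / (wa + wb) == pytest.approx(
        whole["healthiness"]
    )
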