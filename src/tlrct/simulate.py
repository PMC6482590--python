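"""Synthetic loyalty-card trial generator.

Generates complete, internally consistent trials — product catalog,
participant roster, transaction ledger and a ground-truth record — with the
statistical structure the analysis pipeline assumes, so every stage is
testable without any external data:

* catalog: per-product target scores drawn from a [0,1]-truncated normal
  whose post-truncation moments are matched to the configured mean/SD
  (0.63 / 0.21 by default), inverted to the nearest feasible four-light
  colour pattern, then nutrient values sampled inside each colour's band so
  the labeling engine reproduces the intended pattern exactly;
* roster: demographics at the trial's observed proportions, allocation by
  stratified permuted-block randomization, a configurable number of
  withdrawals during recruitment, and questionnaire-completion flags hitting
  both the marginal completion rates and the joint complete-data rate;
* purchases: per participant × period zero-purchase indicators (missingness
  is MCAR by construction), Poisson purchase counts, and product choice by a
  per-participant softmax tilt over product scores.  The intervention arm's
  tilt is shifted during intervention and washout so the expected purchased
  healthiness difference equals the injected effect δ (calibrated by
  bisection against the realized catalog).
"""

from __future__ import annotations

import datetime as dt
import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .labeling import LABEL_NUTRIENTS, Color, DEFAULT_THRESHOLDS, ThresholdTable, label_catalog
from .ledger import OUTCOME_PERIODS, StudyCalendar
from .scoring import CANONICAL_WEIGHTS, ScoreWeights, score_catalog
from .stats import block_randomize

__all__ = ["SimulationConfig", "SyntheticTrial", "generate_catalog", "generate_roster",
           "generate_purchases", "generate_trial"]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic trial; defaults are the study conditions."""

    seed: int = 0
    # roster
    n_participants: int = 496
    prop_female: float = 333 / 496
    prop_dependents: float = 160 / 496
    #: NS-SEC classes 1..5 (remainder is undisclosed/missing)
    nssec_probs: tuple[float, ...] = (0.554, 0.050, 0.067, 0.036, 0.083)
    n_withdrawals: int = 3
    block_size: int = 4
    #: joint rate of "completed all questionnaires and full purchase data"
    q_complete_rate: float = 208 / 496
    #: marginal completion rates of the T0/T1/T2 questionnaires
    q_rates: tuple[float, float, float] = (394 / 496, 270 / 496, 313 / 496)
    # catalog
    catalog_size: int = 438
    own_brand_frac: float = 317 / 438
    prop_pizza: float = 0.4
    n_fruit_veg: int = 40
    n_other: int = 120
    score_mean: float = 0.63
    score_sd: float = 0.21
    pack_range: tuple[float, float] = (250.0, 550.0)
    price_range: tuple[float, float] = (1.5, 6.0)
    # purchase process
    calendar: StudyCalendar = field(default_factory=lambda: StudyCalendar(dt.date(2014, 11, 11)))
    items_per_week: float = 0.35
    zero_purchase_probs: tuple[float, float, float] = (0.224, 0.520, 0.395)
    own_brand_purchase_share: float = 8263 / 10416
    target_baseline_score: float = 0.57
    tilt_sd: float = 3.0
    delta: float = 0.0
    fv_items_per_week: float = 1.5
    other_items_per_week: float = 6.0
    include_filler: bool = True

    def __post_init__(self) -> None:
        probs = (
            self.prop_female,
            self.prop_dependents,
            self.own_brand_frac,
            self.own_brand_purchase_share,
            self.q_complete_rate,
            *self.q_rates,
            *self.zero_purchase_probs,
            *self.nssec_probs,
        )
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not -1 <= self.delta <= 1:
            raise ValueError("delta must lie in [-1, 1]")
        if self.catalog_size < 2:
            raise ValueError("catalog_size must be at least 2")


@dataclass(frozen=True)
class SyntheticTrial:
    """A generated trial plus the latent truth needed to score estimators."""

    catalog: pd.DataFrame
    roster: pd.DataFrame
    transactions: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# catalog generation


@lru_cache(maxsize=16)
def _truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Latent (mu, sigma) of a [0,1]-truncated normal whose post-truncation
    mean and SD equal the targets (moment matching)."""

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (0 - mu) / sigma, (1 - mu) / sigma
        m, v = sps.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.fsolve(moments, x0=[mean, np.log(sd)], full_output=False)
    mu, sigma = float(sol[0]), float(np.exp(sol[1]))
    resid = moments([sol[0], sol[1]])
    if abs(resid[0]) > 1e-6 or abs(resid[1]) > 1e-6:
        raise ValueError(
            f"cannot match truncated-normal moments mean={mean}, sd={sd} "
            f"(residuals {resid})"
        )
    return mu, sigma


@lru_cache(maxsize=4)
def _feasible_patterns(weights: ScoreWeights = CANONICAL_WEIGHTS):
    """All four-colour patterns achievable by a real food, with their scores.

    (fat=GREEN, saturates=RED) is excluded: red saturates exceed 5 g which
    forces total fat above the 3 g green bound.  Every achievable score
    retains at least one feasible pattern because the score is permutation
    invariant across slots.
    """
    patterns = []
    for combo in itertools.product(list(Color), repeat=4):
        fat_c, sat_c, _, _ = combo
        if fat_c == Color.GREEN and sat_c == Color.RED:
            continue
        score = sum(weights.points(c) for c in combo)
        patterns.append((combo, score))
    combos = [c for c, _ in patterns]
    scores = np.array([s for _, s in patterns])
    return combos, scores


def _nearest_pattern(target: float, rng: np.random.Generator,
                     weights: ScoreWeights = CANONICAL_WEIGHTS):
    combos, scores = _feasible_patterns(weights)
    dist = np.abs(scores - target)
    candidates = np.flatnonzero(dist <= dist.min() + 1e-9)
    return combos[int(rng.choice(candidates))]


def _sample_band(nutrient: str, color: Color, portion: float, rng: np.random.Generator,
                 thresholds: ThresholdTable = DEFAULT_THRESHOLDS) -> float:
    """Uniform draw inside the colour's per-100g band, capped so the
    per-portion override cannot overturn an intended green/amber light."""
    b = thresholds.bands(nutrient)
    cap = np.inf
    if portion > thresholds.portion_override_threshold_g:
        cap = b.portion_red * 100.0 / portion
    if color == Color.GREEN:
        lo, hi = 0.0, min(b.green_max, cap)
    elif color == Color.AMBER:
        lo, hi = b.green_max, min(b.amber_max, cap)
    else:
        lo, hi = b.amber_max, 2.0 * b.amber_max
    if hi <= lo:
        raise ValueError(
            f"infeasible band for {nutrient} {color.name} at portion {portion:.0f} g"
        )
    return float(rng.uniform(lo, hi))


def _sample_nutrients(pattern, portion: float, rng: np.random.Generator,
                      max_tries: int = 1000) -> dict[str, float]:
    """Draw the four nutrient values for a colour pattern, rejecting draws
    that violate saturates <= fat."""
    fat_c, sat_c, sugars_c, salt_c = pattern
    for _ in range(max_tries):
        fat = _sample_band("fat", fat_c, portion, rng)
        sat = _sample_band("saturates", sat_c, portion, rng)
        if sat <= fat:
            return {
                "fat": fat,
                "saturates": sat,
                "sugars": _sample_band("sugars", sugars_c, portion, rng),
                "salt": _sample_band("salt", salt_c, portion, rng),
            }
    raise ValueError(f"rejection limit reached sampling nutrients for pattern {pattern}")


def generate_catalog(config: SimulationConfig, rng: np.random.Generator | None = None
                     ) -> pd.DataFrame:
    """Generate a labelled, scored product catalog.

    In-scope products (ready meals and pizzas) carry nutrients constructed to
    reproduce their intended colour pattern under the labeling engine; the
    own-brand count is exactly ``round(own_brand_frac × catalog_size)``.
    Filler products (fruit & veg, other groceries) carry no label nutrients
    and exist for the secondary spend outcomes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.catalog_size
    mu, sigma = _truncnorm_params(config.score_mean, config.score_sd)
    a, b = (0 - mu) / sigma, (1 - mu) / sigma
    targets = sps.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)

    packs = np.round(rng.uniform(*config.pack_range, size=n), 0)
    # single-serve up to 300 g, else two portions; portions stay <= 300 g so
    # every amber band survives the per-portion cap (see _sample_band)
    portions = np.where(packs <= 300.0, packs, np.round(packs / 2.0, 0))

    records = []
    for i in range(n):
        pattern = _nearest_pattern(float(targets[i]), rng)
        nutrients = _sample_nutrients(pattern, float(portions[i]), rng)
        records.append(
            {
                **{f"{k}_intended": c.name.lower() for k, c in zip(LABEL_NUTRIENTS, pattern)},
                **nutrients,
            }
        )
    rec = pd.DataFrame(records)

    n_own = int(round(config.own_brand_frac * n))
    own = np.zeros(n, dtype=int)
    own[rng.permutation(n)[:n_own]] = 1
    category = np.where(rng.random(n) < config.prop_pizza, "pizza", "ready_meal")

    catalog = pd.DataFrame(
        {
            "product_id": [f"P{i:04d}" for i in range(n)],
            "category": category,
            "own_brand": own,
            "fat_100g": rec["fat"],
            "satfat_100g": rec["saturates"],
            "sugars_100g": rec["sugars"],
            "salt_100g": rec["salt"],
            "pack_weight_g": packs,
            "portion_weight_g": portions,
            "price": np.round(rng.uniform(*config.price_range, size=n), 2),
            "fat_intended": rec["fat_intended"],
            "saturates_intended": rec["saturates_intended"],
            "sugars_intended": rec["sugars_intended"],
            "salt_intended": rec["salt_intended"],
        }
    )

    fillers = []
    for cat_name, count in (("fruit_veg", config.n_fruit_veg), ("other", config.n_other)):
        for j in range(count):
            fillers.append(
                {
                    "product_id": f"F{cat_name[0].upper()}{j:04d}",
                    "category": cat_name,
                    "own_brand": int(rng.random() < 0.5),
                    "pack_weight_g": float(np.round(rng.uniform(100, 1000), 0)),
                    "portion_weight_g": np.nan,
                    "price": float(np.round(rng.uniform(0.5, 4.0), 2)),
                }
            )
    if fillers:
        catalog = pd.concat([catalog, pd.DataFrame(fillers)], ignore_index=True)

    catalog = label_catalog(catalog)
    catalog = score_catalog(catalog)
    return catalog


# ---------------------------------------------------------------------------
# roster generation


def _questionnaire_flags(ids: list, withdrawn: set, config: SimulationConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Completion flags hitting the marginal rates and joint complete rate.

    A core group of exactly round(q_complete_rate × n) non-withdrawn
    participants completes everything; the per-questionnaire shortfall to the
    marginal targets is made up from the remaining participants, arranged so
    nobody outside the core completes all three (the T1 top-up nests inside
    the T0 top-up, and the T2 top-up is disjoint from the T1 top-up).
    """
    n = len(ids)
    eligible = [i for i in ids if i not in withdrawn]
    n_complete = min(int(round(config.q_complete_rate * n)), len(eligible))
    order = list(rng.permutation(eligible))
    core = set(order[:n_complete])
    pool = [i for i in order[n_complete:]]

    flags = {q: set(core) for q in ("q_t0", "q_t1", "q_t2")}
    extras = [max(int(round(r * n)) - n_complete, 0) for r in config.q_rates]
    e0, e1, e2 = (min(e, len(pool)) for e in extras)
    flags["q_t0"].update(pool[:e0])
    flags["q_t1"].update(pool[:e1])        # nested in the T0 top-up
    flags["q_t2"].update(pool[len(pool) - e2:])  # disjoint from the T1 top-up
    return pd.DataFrame(
        {q: [i in members for i in ids] for q, members in flags.items()},
        index=ids,
    )


def generate_roster(config: SimulationConfig, rng: np.random.Generator | None = None
                    ) -> pd.DataFrame:
    """Generate the participant roster with block-randomized allocation."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_participants
    ids = [f"S{i:04d}" for i in range(n)]
    sex = np.where(rng.random(n) < config.prop_female, "female", "male")
    dependents = np.where(rng.random(n) < config.prop_dependents, "yes", "no")

    p_missing = 1.0 - sum(config.nssec_probs)
    nssec_draw = rng.choice(
        np.arange(6), size=n, p=list(config.nssec_probs) + [p_missing]
    )
    nssec = pd.array([str(k + 1) if k < 5 else pd.NA for k in nssec_draw], dtype="string")

    roster = pd.DataFrame({"id": ids, "sex": sex, "dependents": dependents, "nssec": nssec})
    alloc_seed = int(rng.integers(0, 2**31 - 1))
    roster["group"] = block_randomize(roster, config.block_size, alloc_seed).loc[ids].to_numpy()

    t0_start, t0_end = config.calendar.period_bounds("T0")
    t0_days = (t0_end - t0_start).days
    withdrawn_idx = rng.choice(n, size=min(config.n_withdrawals, n), replace=False)
    wd = pd.array([pd.NaT] * n, dtype="object")
    for i in withdrawn_idx:
        wd[i] = t0_start + dt.timedelta(days=int(rng.integers(0, t0_days)))
    roster["withdrawal_date"] = wd

    qflags = _questionnaire_flags(ids, {ids[i] for i in withdrawn_idx}, config, rng)
    for q in ("q_t0", "q_t1", "q_t2"):
        roster[q] = qflags[q].to_numpy().astype(int)
    return roster


# ---------------------------------------------------------------------------
# purchase generation


def _softmax_mean_score(scores: np.ndarray, tilt) -> np.ndarray:
    """Expected purchased score under a softmax tilt over product scores."""
    tilt = np.atleast_1d(np.asarray(tilt, dtype=float))
    z = tilt[:, None] * scores[None, :]
    z -= z.max(axis=1, keepdims=True)
    w = np.exp(z)
    return (w * scores[None, :]).sum(axis=1) / w.sum(axis=1)


def _solve_base_tilt(scores: np.ndarray, target: float) -> float:
    lo, hi = -200.0, 200.0
    if not (scores.min() < target < scores.max()):
        raise ValueError(
            f"target purchased score {target} outside the catalog score range "
            f"[{scores.min():.3f}, {scores.max():.3f}]"
        )
    return float(optimize.brentq(lambda t: _softmax_mean_score(scores, t)[0] - target, lo, hi))


def _calibrate_shift(scores: np.ndarray, tilts: np.ndarray, delta: float) -> float:
    """Tilt shift making the mean expected-score lift equal delta (bisection)."""
    if delta == 0:
        return 0.0
    base = _softmax_mean_score(scores, tilts)

    def lift(shift):
        return float(np.mean(_softmax_mean_score(scores, tilts + shift) - base))

    max_lift = float(np.mean(scores.max() - base))
    min_lift = float(np.mean(scores.min() - base))
    if not (min_lift < delta < max_lift):
        raise ValueError(
            f"injected effect delta={delta} unreachable: attainable range "
            f"({min_lift:.3f}, {max_lift:.3f}) for this catalog"
        )
    return float(optimize.brentq(lambda s: lift(s) - delta, -400.0, 400.0, xtol=1e-10))


def generate_purchases(
    roster: pd.DataFrame,
    catalog: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate the transaction ledger; returns (transactions, truth record).

    Missingness is MCAR: each participant × period is a zero-purchaser with
    the period's configured probability, independently of everything else.
    Non-zero purchasers draw ``max(1, Poisson(items_per_week × weeks))``
    ready-meal/pizza purchases; each purchase is own-brand with the configured
    share, and own-brand product choice follows the participant's softmax
    tilt (shifted by the calibrated amount for the intervention arm during T1
    and T2).  Filler purchases (fruit & veg, other) feed secondary outcomes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cal = config.calendar
    n = len(roster)

    scope = catalog[
        catalog["category"].isin(["ready_meal", "pizza"]) & catalog["score"].notna()
    ]
    own_products = scope[scope["own_brand"] == 1]
    branded_products = scope[scope["own_brand"] == 0]
    s_own = own_products["score"].to_numpy(dtype=float)
    own_ids = own_products["product_id"].to_numpy()
    own_prices = own_products["price"].to_numpy(dtype=float)

    base_tilt = _solve_base_tilt(s_own, config.target_baseline_score)
    tilts = base_tilt + rng.normal(0.0, config.tilt_sd, size=n)
    shift = _calibrate_shift(s_own, tilts, config.delta)
    is_intervention = (roster["group"] == "intervention").to_numpy()
    pid = roster["id"].to_numpy()

    frames = []
    for period, p_zero in zip(OUTCOME_PERIODS, config.zero_purchase_probs):
        start, end = cal.period_bounds(period)
        weeks = cal.period_weeks(period)
        days = (end - start).days

        zero = rng.random(n) < p_zero
        counts = np.maximum(rng.poisson(config.items_per_week * weeks, size=n), 1)
        counts[zero] = 0
        idx = np.repeat(np.arange(n), counts)
        total = len(idx)
        if total:
            own_flag = rng.random(total) < config.own_brand_purchase_share
            eff_tilt = tilts[idx].copy()
            if period != "T-1":
                eff_tilt[is_intervention[idx]] += shift
            product = np.empty(total, dtype=object)
            price = np.empty(total)
            n_own_items = int(own_flag.sum())
            if n_own_items:
                logits = eff_tilt[own_flag, None] * s_own[None, :]
                logits += rng.gumbel(size=(n_own_items, len(s_own)))
                choice = logits.argmax(axis=1)
                product[own_flag] = own_ids[choice]
                price[own_flag] = own_prices[choice]
            n_br = total - n_own_items
            if n_br:
                if len(branded_products) == 0:
                    raise ValueError("no branded scope products to purchase")
                j = rng.integers(0, len(branded_products), size=n_br)
                product[~own_flag] = branded_products["product_id"].to_numpy()[j]
                price[~own_flag] = branded_products["price"].to_numpy(dtype=float)[j]
            dates = pd.Timestamp(start) + pd.to_timedelta(
                rng.integers(0, days, size=total), unit="D"
            )
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid[idx],
                        "date": dates,
                        "product_id": product,
                        "quantity": 1,
                        "spend": np.round(price, 2),
                    }
                )
            )

        if config.include_filler:
            for cat_name, rate in (
                ("fruit_veg", config.fv_items_per_week),
                ("other", config.other_items_per_week),
            ):
                pool = catalog[catalog["category"] == cat_name]
                if pool.empty:
                    continue
                c = rng.poisson(rate * weeks, size=n)
                fidx = np.repeat(np.arange(n), c)
                if not len(fidx):
                    continue
                j = rng.integers(0, len(pool), size=len(fidx))
                fdates = pd.Timestamp(start) + pd.to_timedelta(
                    rng.integers(0, days, size=len(fidx)), unit="D"
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "participant_id": pid[fidx],
                            "date": fdates,
                            "product_id": pool["product_id"].to_numpy()[j],
                            "quantity": 1,
                            "spend": pool["price"].to_numpy(dtype=float)[j],
                        }
                    )
                )

    tx = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["participant_id", "date", "product_id", "quantity", "spend"]
    )
    tx = tx.sort_values(["participant_id", "date", "product_id"], kind="stable").reset_index(
        drop=True
    )
    truth = {
        "delta": config.delta,
        "tilt_shift": shift,
        "base_tilt": base_tilt,
        "tilts": dict(zip(pid, tilts.tolist())),
        "expected_score_lift": float(
            np.mean(_softmax_mean_score(s_own, tilts + shift) - _softmax_mean_score(s_own, tilts))
        ),
    }
    return tx, truth


def generate_trial(config: SimulationConfig) -> SyntheticTrial:
    """Compose catalog, roster and purchases into a full synthetic trial.

    Transactions are truncated at each participant's withdrawal date, as the
    real loyalty-card extract would be.  Two calls with the same config are
    byte-identical.
    """
    rng = np.random.default_rng(config.seed)
    catalog = generate_catalog(config, rng)
    roster = generate_roster(config, rng)
    transactions, truth = generate_purchases(roster, catalog, config, rng)

    from .ledger import truncate_at_withdrawal

    transactions = truncate_at_withdrawal(transactions, roster)
    return SyntheticTrial(catalog=catalog, roster=roster, transactions=transactions, truth=truth)
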