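"""ANCOVA, Mann-Whitney, allocation and routing against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
import statsmodels.api as sm

from tlrct.stats import (
    ancova_group_effect,
    block_randomize,
    interaction_test,
    mann_whitney,
    normality_gate,
    subgroup_ancova,
)


def _random_design(rng, n):
    sex = rng.integers(0, 2, n).astype(float)
    dep = rng.integers(0, 2, n).astype(float)
    group = np.array([0.0, 1.0] * (n // 2) + [0.0] * (n % 2))
    baseline = rng.normal(0.6, 0.2, n)
    y = 0.1 + 0.05 * sex - 0.02 * dep + 0.7 * baseline + 0.04 * group + rng.normal(0, 0.1, n)
    return y, sex, dep, group, baseline


def test_ancova_matches_statsmodels_and_normal_equations():
    """Coefficients, SEs and p-values agree with two independent solvers."""
    rng = np.random.default_rng(123)
    for _ in range(100):
        n = int(rng.integers(10, 40))
        y, sex, dep, group, baseline = _random_design(rng, n)
        fit = ancova_group_effect(y, sex, dep, group, baseline)
        X = np.column_stack([np.ones(n), sex, dep, baseline, group])
        # brute-force normal equations
        beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
        ours = np.array([fit.coef[t] for t in fit.terms])
        assert np.allclose(ours, beta_ne, rtol=1e-10, atol=1e-12)
        # statsmodels oracle for the inference
        sm_fit = sm.OLS(y, X).fit()
        assert np.allclose(ours, sm_fit.params, rtol=1e-8)
        assert np.allclose([fit.se[t] for t in fit.terms], sm_fit.bse, rtol=1e-8)
        assert fit.p["group"] == pytest.approx(sm_fit.pvalues[4], rel=1e-6, abs=1e-12)


def test_ancova_exact_interpolation():
    """Outcome identical to baseline -> baseline coefficient 1, group effect 0."""
    rng = np.random.default_rng(1)
    n = 24
    baseline = rng.normal(0.5, 0.2, n)
    sex = rng.integers(0, 2, n).astype(float)
    dep = rng.integers(0, 2, n).astype(float)
    group = np.tile([0.0, 1.0], n // 2)
    fit = ancova_group_effect(baseline, sex, dep, group, baseline)
    assert fit.coef["baseline"] == pytest.approx(1.0, abs=1e-10)
    assert fit.coef["group"] == pytest.approx(0.0, abs=1e-10)
    assert fit.resid_sd == pytest.approx(0.0, abs=1e-8)


def test_ancova_rank_deficiency_reported():
    n = 20
    y = np.random.default_rng(2).normal(size=n)
    const = np.ones(n)
    with pytest.raises(ValueError, match="rank deficient"):
        ancova_group_effect(y, const, const, np.tile([0.0, 1.0], n // 2), None)


def test_ancova_rejects_missing_cells():
    y = np.array([0.5, np.nan, 0.4, 0.6, 0.2, 0.7])
    z = np.zeros(6)
    with pytest.raises(ValueError, match="missing"):
        ancova_group_effect(y, z, z, np.tile([0.0, 1.0], 3), None)


def _u_bruteforce(x, y):
    """Pairwise-wins oracle: wins + half ties of x over y."""
    return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)


@pytest.mark.parametrize("seed", range(12))
def test_mann_whitney_u_matches_pairwise_enumeration(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(1, 9, 2)
    x = rng.integers(0, 6, n1).astype(float)  # integer values force ties
    y = rng.integers(0, 6, n2).astype(float)
    res = mann_whitney(x, y)
    assert res.statistic == pytest.approx(_u_bruteforce(x, y))


def test_mann_whitney_examples():
    assert mann_whitney([1, 2], [3, 4]).statistic == 0.0
    assert mann_whitney([1, 3], [2, 4]).statistic == 1.0
    res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(4.5)  # n^2 / 2
    assert res.p == pytest.approx(1.0)


def test_mann_whitney_exact_p_matches_scipy():
    """On tie-free small samples the enumeration equals scipy's exact test."""
    rng = np.random.default_rng(9)
    for _ in range(10):
        n1, n2 = rng.integers(2, 8, 2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2) + rng.uniform(-1, 1)
        ours = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)


def test_mann_whitney_asymptotic_matches_scipy():
    rng = np.random.default_rng(10)
    x = rng.integers(0, 10, 30).astype(float)
    y = rng.integers(0, 12, 25).astype(float)
    ours = mann_whitney(x, y)
    ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert ours.p == pytest.approx(ref.pvalue, rel=1e-8)
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


def _strata_data(n, effect_high, effect_low, seed=3):
    rng = np.random.default_rng(seed)
    ses = np.tile([1.0, 0.0], n // 2)
    group = np.repeat([0.0, 1.0], n // 2)[rng.permutation(n)]
    baseline = rng.normal(0.6, 0.15, n)
    y = baseline + np.where(ses == 1, effect_high, effect_low) * group
    return pd.DataFrame(
        {
            "outcome": y,
            "baseline": baseline,
            "sex": rng.integers(0, 2, n).astype(float),
            "dependents": rng.integers(0, 2, n).astype(float),
            "group": group,
            "ses_high": ses,
        }
    )


def test_subgroup_ancova_recovers_stratum_effects():
    data = _strata_data(200, effect_high=0.0, effect_low=0.1)
    fits = subgroup_ancova(data)
    assert fits["nssec_1_2"].group_effect == pytest.approx(0.0, abs=1e-10)
    assert fits["nssec_3_5"].group_effect == pytest.approx(0.1, abs=1e-10)


def test_subgroup_empty_stratum_warns():
    data = _strata_data(100, 0.05, 0.05)
    data["ses_high"] = 1.0
    with pytest.warns(UserWarning, match="empty"):
        fits = subgroup_ancova(data)
    assert fits["nssec_3_5"] is None
    assert fits["nssec_1_2"] is not None


def test_interaction_recovered_and_degenerate_ses_rejected():
    data = _strata_data(300, effect_high=0.15, effect_low=0.0, seed=4)
    res = interaction_test(data)
    # noiseless construction: group x ses coefficient is exactly 0.15
    assert res.name == "t"
    assert res.p < 1e-10
    data["ses_high"] = 1.0
    with pytest.raises(ValueError, match="rank deficient"):
        interaction_test(data)


def test_block_randomization_balance_and_determinism():
    roster = pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(8)],
            "sex": ["female"] * 8,
            "dependents": ["no"] * 8,
        }
    )
    a = block_randomize(roster, block_size=4, seed=5)
    assert (a == "intervention").sum() == 4
    b = block_randomize(roster, block_size=4, seed=5)
    assert a.equals(b)
    shuffled = roster.sample(frac=1, random_state=1)
    c = block_randomize(shuffled, block_size=4, seed=5)
    assert a.sort_index().equals(c.sort_index())
    with pytest.raises(ValueError):
        block_randomize(roster, block_size=3, seed=5)


def test_block_randomization_stratum_imbalance_bounded():
    rng = np.random.default_rng(6)
    n = 2000
    roster = pd.DataFrame(
        {
            "id": [f"p{i:05d}" for i in range(n)],
            "sex": rng.choice(["male", "female"], n),
            "dependents": rng.choice(["yes", "no"], n),
        }
    )
    alloc = block_randomize(roster, block_size=4, seed=7)
    merged = roster.set_index("id").join(alloc)
    for _, g in merged.groupby(["sex", "dependents"]):
        imbalance = abs((g["group"] == "intervention").sum() - (g["group"] == "control").sum())
        assert imbalance <= 2  # block_size / 2


def test_normality_gate_routes():
    rng = np.random.default_rng(11)
    assert normality_gate(rng.normal(5, 1, 500)) == "normal"
    zero_inflated = np.concatenate([np.zeros(300), rng.exponential(2, 200)])
    assert normality_gate(zero_inflated) == "non_normal"
    with pytest.warns(UserWarning):
        assert normality_gate([1.0, 1.0, 1.0, 1.0]) == "non_normal"
    with pytest.warns(UserWarning):
        assert normality_gate([1.0, 2.0]) == "non_normal"


def test_null_ancova_pvalues_uniform():
    """Under the null on Gaussian data the group p-value is ~ Uniform(0,1)."""
    rng = np.random.default_rng(12)
    ps = []
    for _ in range(500):
        n = 60
        y, sex, dep, group, baseline = _random_design(rng, n)
        y = y - 0.04 * group  # remove the injected effect
        ps.append(ancova_group_effect(y, sex, dep, group, baseline).group_p)
    assert sps.kstest(ps, "uniform").pvalue > 1e-3
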