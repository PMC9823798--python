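"""Nonparametric tests against independent enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as ss

from neoqeeg.cohort_stats import (
    ComparisonPlan,
    kruskal,
    ranksum,
    run_planned_analyses,
    spearman,
)


# --------------------------------------------------------------------------
# independent oracles (pure enumeration, no shared code with the package)


def oracle_spearman_p(x, y):
    """Two-sided permutation p for Spearman by full enumeration."""
    rx = ss.rankdata(x)
    ry = ss.rankdata(y)

    def rho(a, b):
        return np.corrcoef(a, b)[0, 1]

    obs = abs(rho(rx, ry))
    count = total = 0
    for perm in itertools.permutations(ry):
        if abs(rho(rx, np.array(perm))) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def oracle_ranksum_p(a, b):
    """Two-sided exact rank-sum p by enumerating group assignments."""
    pooled = np.concatenate([a, b])
    ranks = ss.rankdata(pooled)
    na, n = len(a), len(pooled)
    mean_w = na * (n + 1) / 2
    w_obs = ranks[:na].sum()
    d = abs(w_obs - mean_w) - 1e-9
    hits = total = 0
    for combo in itertools.combinations(range(n), na):
        if abs(ranks[list(combo)].sum() - mean_w) >= d:
            hits += 1
        total += 1
    return hits / total


# --------------------------------------------------------------------------
# Spearman


def test_spearman_perfect_antimonotone():
    r = spearman([1, 2, 3, 4, 5, 6], [10, 8, 7, 5, 3, 1])
    assert r.statistic == pytest.approx(-1.0)
    assert r.p_value == pytest.approx(2 / 720)  # only the two extreme orderings


def test_spearman_rank_formula_example():
    x = np.array([1, 2, 3, 4, 5])
    y = np.array([2, 1, 4, 3, 5])
    r = spearman(x, y)
    d2 = ((ss.rankdata(x) - ss.rankdata(y)) ** 2).sum()
    assert r.statistic == pytest.approx(1 - 6 * d2 / (5 * 24))  # = 0.8
    assert r.p_value == pytest.approx(oracle_spearman_p(x, y))


@pytest.mark.parametrize("seed", range(6))
def test_spearman_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 8))
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    if seed % 2:  # exercise ties
        x = np.round(x)
    r = spearman(x, y)
    assert r.statistic == pytest.approx(ss.spearmanr(x, y).statistic)
    assert r.p_value == pytest.approx(oracle_spearman_p(x, y))


def test_spearman_listwise_deletion_and_gates():
    r = spearman([1, 2, np.nan, 4], [2, 4, 5, np.nan])
    assert r.n == 2 and not r.computed
    flat = spearman([1, 1, 1, 1], [1, 2, 3, 4])
    assert not flat.computed and "variance" in flat.note


def test_spearman_monte_carlo_regime_close_to_asymptotic():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=11), rng.normal(size=11)
    r = spearman(x, y)
    assert 0 <= r.p_value <= 1
    assert abs(r.p_value - ss.spearmanr(x, y).pvalue) < 0.08


# --------------------------------------------------------------------------
# rank sum


def test_ranksum_identical_groups_p_one():
    r = ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.p_value == pytest.approx(1.0)


def test_ranksum_fully_separated_minimal_p():
    r = ranksum([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
    assert r.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments


@pytest.mark.parametrize("seed", range(6))
def test_ranksum_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
    a = rng.normal(size=na)
    b = rng.normal(size=nb) + rng.normal()
    if seed % 2:
        a, b = np.round(a * 2) / 2, np.round(b * 2) / 2
    r = ranksum(a, b)
    assert r.p_value == pytest.approx(oracle_ranksum_p(a, b))


def test_ranksum_empty_group_fatal():
    with pytest.raises(ValueError):
        ranksum([], [1.0, 2.0])


# --------------------------------------------------------------------------
# Kruskal-Wallis


def test_kruskal_hand_formula():
    r = kruskal([[1, 2], [3, 4], [5, 6]])
    # ranks 1..6, group mean ranks 1.5 / 3.5 / 5.5:
    # H = 12 / (6*7) * sum(n_i (Rbar_i - 3.5)^2) = 32/7
    assert r.statistic == pytest.approx(12 / 42 * (2 * 4 + 0 + 2 * 4))
    assert r.p_value == pytest.approx(ss.chi2.sf(r.statistic, 2))


def test_kruskal_two_groups_agrees_with_ranksum_asymptotics():
    rng = np.random.default_rng(1)
    a = rng.normal(size=15)
    b = rng.normal(size=15) + 0.8
    kw = kruskal([a, b])
    rs = float(ss.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    assert kw.p_value == pytest.approx(rs, rel=0.10)


def test_kruskal_group_handling():
    with pytest.warns(UserWarning, match="empty"):
        r = kruskal([[1.0, 2.0], [], [3.0, 4.0]])
    assert r.n == 4
    with pytest.raises(ValueError):
        with pytest.warns(UserWarning, match="empty"):
            kruskal([[1.0, 2.0], []])


# --------------------------------------------------------------------------
# the planned analysis runner


def _short_term_table(n, rng, effect=-0.5):
    import pandas as pd

    rows = []
    for i in range(n):
        base = rng.uniform(20, 120)
        for feature, derivs in (
            ("rEEG", ("P3-P4", "F3-F4", "F3", "F4", "P3", "P4")),
            ("ASI", ("interhemispheric", "intra_left", "intra_right", "frontal")),
        ):
            for d in derivs:
                delta = effect * base / 120 * rng.uniform(0.5, 1.5)
                rows.append({"subject_id": f"s{i}", "feature": feature, "derivation": d,
                             "baseline_median": base, "post_median": base + delta,
                             "delta": delta, "n_epochs_baseline": 4, "n_epochs_post": 4})
    return pd.DataFrame(rows)


def _clinical_table(n, rng):
    import pandas as pd

    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "gestational_age_days": rng.integers(189, 295, n),
        "fentanyl": rng.integers(0, 2, n),
        "diagnosis_group": rng.integers(0, 4, n),
    })


def test_planned_analyses_emit_exactly_the_plan():
    rng = np.random.default_rng(5)
    table = _short_term_table(21, rng)
    clin = _clinical_table(21, rng)
    stats, scatter = run_planned_analyses(table, clin)
    plan = ComparisonPlan()
    n_delta = len(plan.reeg_targets) + len(plan.asi_targets)
    # delta-vs-baseline + pre-vs-post per target, 3 clinical tests per primary
    assert len(stats) == 2 * n_delta + 3 * len(plan.primary)
    assert set(stats.loc[stats["computed"], "test"]) <= {
        "spearman", "wilcoxon_ranksum", "kruskal_wallis"
    }
    assert (stats["family_size"] == stats["computed"].sum()).all()
    assert set(scatter.columns) == {"subject_id", "feature", "derivation", "baseline", "delta"}
    # strong negative baseline-proportional effect is recovered
    delta_rows = stats[stats["comparison"].str.startswith("delta_vs_baseline")]
    assert (delta_rows["statistic"] < 0).all()


def test_planned_analyses_single_subject_not_computed():
    rng = np.random.default_rng(6)
    stats, scatter = run_planned_analyses(_short_term_table(1, rng), _clinical_table(1, rng))
    assert not stats["computed"].any()
    assert len(stats) > 0  # reported, never silently skipped
    assert scatter.empty
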