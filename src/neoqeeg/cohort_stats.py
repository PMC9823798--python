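"""Nonparametric cohort statistics over the short-term drug-effect table.

The inferential layer is deliberately small and declared a priori:
Spearman rank correlations for delta-vs-baseline and gestational-age
questions, Wilcoxon rank-sum for two-group contrasts (pre vs post,
fentanyl vs no fentanyl), Kruskal-Wallis across diagnosis groups. No
multiple-testing correction is applied — the comparison family is
minimised up front instead — but every result row records the family
size so users can correct post hoc. All tests are two-sided.

Exact null distributions are used where enumeration is feasible:
Spearman p-values by exhaustive permutation for n <= 8 and seeded
Monte-Carlo permutation for n <= 12; rank-sum p-values from the exact
distribution up to a combined n of 20 (by direct enumeration when ties
are present). Larger samples use the standard asymptotic
approximations with tie corrections.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as ss

SPEARMAN_EXHAUSTIVE_N = 8
SPEARMAN_MONTE_CARLO_N = 12
SPEARMAN_MC_SAMPLES = 20000
RANKSUM_EXACT_N = 20


@dataclass
class StatResult:
    test: str                  # spearman | wilcoxon_ranksum | kruskal_wallis
    comparison: str
    statistic: float           # rho, U, or H
    p_value: float
    n: int
    computed: bool = True
    note: str = ""


def _pairwise_complete(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x, y, comparison: str = "", rng_seed: int = 0) -> StatResult:
    """Spearman rank correlation with a permutation-exact small-sample p.

    Missing pairs are dropped listwise; ties get average ranks. For
    n <= 8 the two-sided p comes from all n! permutations; for n <= 12
    from a seeded Monte-Carlo permutation null; otherwise from the
    t-distribution approximation.
    """
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 3:
        return StatResult("spearman", comparison, np.nan, np.nan, n, False, "n < 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult(
            "spearman", comparison, np.nan, np.nan, n, False, "zero variance"
        )
    rx = ss.rankdata(x)
    ry = ss.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    tol = 1e-12
    if n <= SPEARMAN_EXHAUSTIVE_N:
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - tol))
    elif n <= SPEARMAN_MONTE_CARLO_N:
        rng = np.random.default_rng(rng_seed)
        idx = np.argsort(rng.random((SPEARMAN_MC_SAMPLES, n)), axis=1)
        rhos = (ryc[idx] @ rxc) / denom
        hits = int(np.sum(np.abs(rhos) >= abs(rho) - tol))
        p = (1 + hits) / (1 + SPEARMAN_MC_SAMPLES)
    else:
        p = float(ss.spearmanr(x, y).pvalue)
    return StatResult("spearman", comparison, rho, min(p, 1.0), n)


def _ranksum_enumerate(ranks: np.ndarray, na: int) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    n = ranks.size
    w_obs = float(ranks[:na].sum())
    mean_w = na * (n + 1) / 2.0
    d_obs = abs(w_obs - mean_w) - 1e-9
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), na):
        w = ranks[list(combo)].sum()
        if abs(w - mean_w) >= d_obs:
            count += 1
        total += 1
    return w_obs, count / total


def ranksum(group_a, group_b, comparison: str = "") -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact for combined n <= 20 (enumeration handles ties); otherwise
    the normal approximation with tie correction and continuity.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("ranksum requires two non-empty groups")
    if a.size < 2 or b.size < 2:
        return StatResult(
            "wilcoxon_ranksum", comparison, np.nan, np.nan, a.size + b.size, False,
            "group n < 2",
        )
    n = a.size + b.size
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < n
    u_stat = float(ss.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic)
    if n <= RANKSUM_EXACT_N:
        if has_ties:
            ranks = ss.rankdata(pooled)
            _, p = _ranksum_enumerate(ranks, a.size)
        else:
            p = float(ss.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    else:
        p = float(ss.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    return StatResult("wilcoxon_ranksum", comparison, u_stat, min(p, 1.0), n)


def kruskal(groups, comparison: str = "") -> StatResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square p, k-1 df)."""
    cleaned = []
    for g in groups:
        g = np.asarray(g, float)
        g = g[np.isfinite(g)]
        if g.size == 0:
            warnings.warn("dropping empty group from Kruskal-Wallis", stacklevel=2)
            continue
        cleaned.append(g)
    if len(cleaned) < 2:
        raise ValueError("Kruskal-Wallis requires >= 2 non-empty groups")
    h, p = ss.kruskal(*cleaned)
    n = int(sum(g.size for g in cleaned))
    return StatResult("kruskal_wallis", comparison, float(h), float(p), n)


# ---------------------------------------------------------------------------
# the a-priori comparison plan


@dataclass
class ComparisonPlan:
    """The fixed, physiologically-motivated comparison set.

    rEEG targets global activity (biparietal and interfrontal bipolar
    derivations plus the four referential channels); ASI targets the
    interhemispheric, the two intrahemispheric, and the frontal channel
    pairs. The plan is declared before any testing.
    """

    reeg_targets: tuple[str, ...] = ("P3-P4", "F3-F4", "F3", "F4", "P3", "P4")
    asi_targets: tuple[str, ...] = (
        "interhemispheric",
        "intra_left",
        "intra_right",
        "frontal",
    )
    # primary derivations used for the clinical-factor analyses
    primary: dict = field(
        default_factory=lambda: {"rEEG": "P3-P4", "ASI": "interhemispheric"}
    )
    min_subjects: int = 5

    def targets(self, feature: str) -> tuple[str, ...]:
        return self.reeg_targets if feature == "rEEG" else self.asi_targets


def run_planned_analyses(
    short_term_table: pd.DataFrame,
    clinical_table: pd.DataFrame | None = None,
    plan: ComparisonPlan | None = None,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run exactly the planned comparisons on the per-subject results.

    ``short_term_table`` is the tidy pre/post summary (columns
    subject_id, feature, derivation, baseline_median, post_median,
    delta). Returns (stats table, scatter data). Comparisons whose
    sample is too small are reported as not-computed, never skipped.
    """
    plan = plan or ComparisonPlan()
    rows: list[StatResult] = []
    scatter_rows = []

    def subset(feature: str, derivation: str) -> pd.DataFrame:
        sel = short_term_table[
            (short_term_table["feature"] == feature)
            & (short_term_table["derivation"] == derivation)
        ]
        return sel.dropna(subset=["baseline_median", "post_median"])

    for feature in ("rEEG", "ASI"):
        for target in plan.targets(feature):
            sub = subset(feature, target)
            label = f"{feature} {target}"
            if len(sub) < plan.min_subjects:
                rows.append(
                    StatResult("spearman", f"delta_vs_baseline {label}", np.nan, np.nan,
                               len(sub), False, "insufficient subjects")
                )
                rows.append(
                    StatResult("wilcoxon_ranksum", f"pre_vs_post {label}", np.nan, np.nan,
                               len(sub), False, "insufficient subjects")
                )
                continue
            rows.append(
                spearman(sub["baseline_median"], sub["delta"],
                         f"delta_vs_baseline {label}", rng_seed=rng_seed)
            )
            rows.append(
                ranksum(sub["baseline_median"], sub["post_median"], f"pre_vs_post {label}")
            )
            for _, r in sub.iterrows():
                scatter_rows.append(
                    {"subject_id": r["subject_id"], "feature": feature,
                     "derivation": target, "baseline": r["baseline_median"],
                     "delta": r["delta"]}
                )

    if clinical_table is not None:
        clin = clinical_table.copy()
        clin["subject_id"] = clin["subject_id"].astype(str)
        for feature, derivation in plan.primary.items():
            sub = subset(feature, derivation).copy()
            sub["subject_id"] = sub["subject_id"].astype(str)
            merged = sub.merge(clin, on="subject_id", how="inner")
            label = f"{feature} {derivation}"
            if len(merged) < plan.min_subjects:
                for test, name in (
                    ("spearman", "ga_vs_baseline"),
                    ("wilcoxon_ranksum", "fentanyl_vs_baseline"),
                    ("kruskal_wallis", "diagnosis_vs_baseline"),
                ):
                    rows.append(StatResult(test, f"{name} {label}", np.nan, np.nan,
                                           len(merged), False, "insufficient subjects"))
                continue
            rows.append(
                spearman(merged["gestational_age_days"], merged["baseline_median"],
                         f"ga_vs_baseline {label}", rng_seed=rng_seed)
            )
            fent = merged["fentanyl"].astype(int) == 1
            if fent.sum() >= 2 and (~fent).sum() >= 2:
                rows.append(
                    ranksum(merged.loc[~fent, "baseline_median"],
                            merged.loc[fent, "baseline_median"],
                            f"fentanyl_vs_baseline {label}")
                )
            else:
                rows.append(StatResult("wilcoxon_ranksum", f"fentanyl_vs_baseline {label}",
                                       np.nan, np.nan, len(merged), False,
                                       "a fentanyl group has n < 2"))
            groups = [g["baseline_median"].values
                      for _, g in merged.groupby("diagnosis_group")]
            if sum(len(g) > 0 for g in groups) >= 2:
                rows.append(kruskal(groups, f"diagnosis_vs_baseline {label}"))
            else:
                rows.append(StatResult("kruskal_wallis", f"diagnosis_vs_baseline {label}",
                                       np.nan, np.nan, len(merged), False,
                                       "fewer than 2 diagnosis groups"))

    stats = pd.DataFrame(
        [
            {"comparison": r.comparison, "test": r.test, "statistic": r.statistic,
             "p_value": r.p_value, "n": r.n, "computed": r.computed, "note": r.note}
            for r in rows
        ]
    )
    stats["family_size"] = int(stats["computed"].sum())
    return stats, pd.DataFrame(scatter_rows)
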