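"""Nonparametric testing toolkit shared by all analysis stages.

Survey-style and fitness data in this pipeline are heavily tied and rarely
normal, so every test here is rank-based with mid-rank tie handling and
tie-corrected variances:

* Friedman rank-sum test on unreplicated blocked data (participants x
  timepoints) followed, when significant, by Conover all-pairs post-hoc
  comparisons with Benjamini-Hochberg adjustment.
* Kruskal-Wallis with Dunn's all-pairs z comparisons (BH adjusted).
* Wilcoxon rank-sum (Mann-Whitney) with continuity correction.
* Two-sample Kolmogorov-Smirnov and Pearson chi-square.
* Pearson correlation.
* A seeded permutation surrogate for the group x time interaction in a
  two-group, three-repeated-measures design.

Multiple-testing adjustments (Benjamini-Hochberg step-up, Holm step-down)
are delegated to statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    method: str
    statistic: float
    p: float
    adjusted_p: Optional[float] = None
    pairwise: Optional[pd.DataFrame] = None
    letters: Optional[dict] = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# multiple-testing adjustments


def _check_p(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.size and ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return arr


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    arr = _check_p(p)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def holm_adjust(p: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (input order preserved)."""
    arr = _check_p(p)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="holm")[1]


# ---------------------------------------------------------------------------
# compact letter display


def compact_letters(
    items: Sequence, pair_p: dict, alpha: float = 0.05
) -> dict:
    """Greedy insert-absorb compact-letter display.

    Items that are *not* significantly different (adjusted p > alpha) share
    at least one letter; significantly different items never share a letter.
    """
    items = list(items)
    sig = {
        frozenset(pair): p <= alpha
        for pair, p in pair_p.items()
    }
    groups: list[set] = [set(items)]
    for a_idx in range(len(items)):
        for b_idx in range(a_idx + 1, len(items)):
            a, b = items[a_idx], items[b_idx]
            if not sig.get(frozenset((a, b)), False):
                continue
            for grp in list(groups):
                if a in grp and b in grp:
                    groups.remove(grp)
                    g1, g2 = grp - {a}, grp - {b}
                    for g in (g1, g2):
                        if g and not any(g <= other for other in groups):
                            groups.append(g)
    groups = [g for g in groups if g]
    letters = {item: "" for item in items}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, grp in zip(alphabet, groups):
        for item in grp:
            letters[item] += letter
    return letters


# ---------------------------------------------------------------------------
# Friedman + Conover


def friedman_conover(
    data,
    alpha: float = 0.05,
    condition_names: Optional[Sequence] = None,
) -> TestResult:
    """Friedman test on a complete blocks x conditions matrix with, when
    significant, Conover all-pairs post-hoc comparisons (BH adjusted).

    Uses the tie-corrected chi-square form on within-block mid-ranks; the
    pairwise statistic follows the Conover-Iman t on rank sums with
    (n-1)(k-1) degrees of freedom.
    """
    mat = np.asarray(data, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need a blocks x conditions matrix, at least 2x2")
    if np.isnan(mat).any():
        raise ValueError("incomplete blocks are not allowed (no imputation)")
    n, k = mat.shape
    if condition_names is None:
        condition_names = list(range(k))
    ranks = sps.rankdata(mat, axis=1)
    rank_sums = ranks.sum(axis=0)
    a1 = float((ranks**2).sum())
    c1 = n * k * (k + 1) ** 2 / 4.0
    denom = a1 - c1
    if denom <= 0:  # every block fully tied
        return TestResult("friedman", 0.0, 1.0)
    stat = (k - 1) * float(((rank_sums - n * (k + 1) / 2.0) ** 2).sum()) / denom
    p = float(sps.chi2.sf(stat, k - 1))
    result = TestResult("friedman", stat, p)
    if p <= alpha:
        b1 = float((rank_sums**2).sum()) / n
        df = (n - 1) * (k - 1)
        se2 = 2.0 * n * (a1 - b1) / df
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                diff = abs(rank_sums[i] - rank_sums[j])
                if se2 <= 0:
                    t = np.inf if diff > 0 else 0.0
                else:
                    t = diff / np.sqrt(se2)
                pij = float(2.0 * sps.t.sf(t, df)) if np.isfinite(t) else 0.0
                rows.append(
                    (condition_names[i], condition_names[j], float(t), min(pij, 1.0))
                )
        pairwise = pd.DataFrame(
            rows, columns=["condition_a", "condition_b", "statistic", "p"]
        )
        pairwise["adjusted_p"] = bh_adjust(pairwise["p"])
        result.pairwise = pairwise
        result.letters = compact_letters(
            condition_names,
            {
                (r.condition_a, r.condition_b): r.adjusted_p
                for r in pairwise.itertuples()
            },
            alpha=alpha,
        )
    return result


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn


def kruskal_dunn(values, groups, alpha: float = 0.05) -> TestResult:
    """Kruskal-Wallis H (tie corrected) with Dunn all-pairs z post hoc.

    Dunn's z uses global mid-ranks, the tie correction
    sum(t^3 - t) / (12 (N - 1)), and BH adjustment across pairs.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    if np.all(values == values[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)
    result = TestResult("kruskal", float(h), float(p))

    n_total = len(values)
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            if se == 0:
                z = 0.0
            else:
                z = (mean_ranks[a] - mean_ranks[b]) / se
            pij = float(2.0 * sps.norm.sf(abs(z)))
            rows.append((a, b, float(z), min(pij, 1.0)))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p"])
    pairwise["adjusted_p"] = bh_adjust(pairwise["p"])
    result.pairwise = pairwise
    result.letters = compact_letters(
        list(labels),
        {(r.group_a, r.group_b): r.adjusted_p for r in pairwise.itertuples()},
        alpha=alpha,
    )
    return result


# ---------------------------------------------------------------------------
# two-sample tests


def wilcoxon_cc(x, y) -> TestResult:
    """Wilcoxon rank-sum test, normal approximation with continuity
    correction and tie-corrected variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    stat, p = sps.mannwhitneyu(
        x, y, use_continuity=True, alternative="two-sided", method="asymptotic"
    )
    return TestResult("wilcoxon-rank-sum-cc", float(stat), float(p))


def pearson_r(a, b) -> TestResult:
    """Pearson product-moment correlation with two-sided t-distribution p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(a, b)
    return TestResult("pearson", float(r), float(p))


def ks_test(a, b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return TestResult("ks", float(res.statistic), float(res.pvalue))


def chi2_test(table, correction: bool = False) -> TestResult:
    """Pearson chi-square test on an r x c contingency table.

    Yates continuity correction is off by default; a warning is emitted when
    any expected count falls below 5.
    """
    table = np.asarray(table, dtype=float)
    stat, p, dof, expected = sps.chi2_contingency(table, correction=correction)
    if (expected < 5).any():
        warnings.warn(
            "chi-square approximation unreliable: expected count < 5",
            stacklevel=2,
        )
    return TestResult("chi2", float(stat), float(p), extra={"dof": int(dof)})


# ---------------------------------------------------------------------------
# group x time interaction (permutation surrogate)


def group_time_interaction_perm(
    values,
    group,
    time,
    participant,
    n_perm: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Permutation test for a group x time interaction with repeated measures.

    Observations are rank-transformed globally (mid-ranks); each
    participant's mean rank is removed so only the within-subject trajectory
    shape remains; the statistic is the sum over timepoints of the squared
    difference of group mean centered ranks.  The null distribution permutes
    group labels across participants.  The empirical p uses the add-one
    convention (1 + #perm >= obs) / (1 + n_perm), so it is never exactly 0.
    """
    frame = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "group": np.asarray(group),
            "time": np.asarray(time),
            "participant": np.asarray(participant),
        }
    )
    group_labels = pd.unique(frame["group"])
    if len(group_labels) != 2:
        raise ValueError("exactly two groups are required")
    frame["rank"] = sps.rankdata(frame["value"])
    wide = frame.pivot_table(
        index="participant", columns="time", values="rank", aggfunc="first"
    )
    if wide.isna().any().any():
        raise ValueError("complete cases required: every participant needs "
                         "every timepoint")
    centered = wide.sub(wide.mean(axis=1), axis=0).to_numpy()
    part_group = frame.drop_duplicates("participant").set_index("participant")[
        "group"
    ]
    is_a = (part_group.loc[wide.index] == group_labels[0]).to_numpy()

    def statistic(mask: np.ndarray) -> float:
        mean_a = centered[mask].mean(axis=0)
        mean_b = centered[~mask].mean(axis=0)
        return float(((mean_a - mean_b) ** 2).sum())

    observed = statistic(is_a)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        exceed += statistic(rng.permutation(is_a)) >= observed
    p = (1.0 + exceed) / (1.0 + n_perm)
    return TestResult(
        "group-time-interaction-perm", observed, float(p),
        extra={"n_perm": n_perm},
    )
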