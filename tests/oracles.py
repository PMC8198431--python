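"""Independent brute-force oracles for the rank statistics.

These deliberately re-derive each statistic from first principles (direct
rank arithmetic, exhaustive pair counting, permutation nulls) without
touching the package's implementations, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2, mannwhitneyu, rankdata, t as t_dist


def kw_brute(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H from the textbook rank formula with tie correction."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if correction == 0:
        return 0.0, 1.0
    h /= correction
    return h, float(chi2.sf(h, df=len(groups) - 1))


def conover_perm_p(
    groups: dict[str, np.ndarray],
    pair: tuple[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the Conover pairwise statistic.

    Recomputes the full statistic (pooled ranks, tie-corrected variance,
    H-dependent scaling) on every label permutation; the returned two-sided
    p is the fraction of permutations with |t| at least as extreme.
    """

    def conover_t(values: np.ndarray, labels: np.ndarray) -> float:
        n = len(values)
        ks = np.unique(labels)
        ranks = rankdata(values)
        h, _ = kw_brute([values[labels == g] for g in ks])
        s2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
        a, b = pair
        na, nb = (labels == a).sum(), (labels == b).sum()
        var = s2 * (n - 1 - h) / (n - len(ks)) * (1.0 / na + 1.0 / nb)
        if var <= 0:
            return 0.0
        return (ranks[labels == a].mean() - ranks[labels == b].mean()) / np.sqrt(var)

    labels = np.concatenate([[g] * len(v) for g, v in groups.items()])
    values = np.concatenate(list(groups.values()))
    t_obs = abs(conover_t(values, labels))
    rng = np.random.default_rng(seed)
    hits = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if abs(conover_t(values, lab)) >= t_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def jt_brute(groups: list[np.ndarray]) -> float:
    """JT statistic as the sum of pairwise Mann-Whitney U counts (ties 1/2)."""
    total = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            u = mannwhitneyu(groups[j], groups[i], alternative="two-sided",
                             method="asymptotic").statistic
            total += float(u)
    return total


def bh_brute(p: np.ndarray) -> np.ndarray:
    """BH adjusted values from the definition: min over j>=i of m*p(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj
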