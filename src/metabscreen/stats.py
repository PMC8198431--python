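"""Univariate cross-cohort battery on quantitative analytes and class sums.

Per analyte: tie-corrected Kruskal–Wallis H with its eta-squared effect
size, Conover–Iman pairwise posthoc tests on the pooled ranks (effect size:
the t statistic standardized by the square root of the compared pair's
size, Pallant's r), a Jonckheere–Terpstra trend test across the ordered
screening groups (Ctr < LN < LC), Benjamini–Hochberg FDR across analytes,
and — when the two cohorts are analysed separately — a Lancaster-weighted
combination of the per-cohort Kruskal–Wallis p-values with cohort-size
degrees of freedom.  Low-abundance (mostly censored) analytes are tested
as presence/absence via a chi-square independence test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import (
    BELOW_LOD,
    CLASS_ORDER,
    GROUPS,
    LIPID_CLASSES,
    LOD_REPLACED,
    MISSING_CALIBRANT,
    MeasurementMatrix,
    PanelRegistry,
)
from .preprocess import AnalytePartition

PAIRS = (("Ctr", "LN"), ("Ctr", "LC"), ("LN", "LC"))


# ---------------------------------------------------------------------------
# Elementary tests


def kruskal_wallis(values: Sequence[np.ndarray] | Iterable[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square (k-1 d.f.) p-value.

    The degenerate all-tied input is defined as (H, p) = (0, 1).
    """
    groups = [np.asarray(g, dtype=float) for g in values]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def eta_squared_kw(h: float, k: int, n: int) -> float:
    """Effect size for Kruskal–Wallis: (H - k + 1) / (n - k)."""
    if n <= k:
        raise ValueError("need more observations than groups")
    return (h - k + 1) / (n - k)


def conover_posthoc(
    values: Mapping[str, np.ndarray], h: float | None = None
) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Conover–Iman pairwise tests on the pooled Kruskal–Wallis ranks.

    Returns per pair (t, two-sided p from Student t with n-k d.f., r) where
    r = |t| / sqrt(n_i + n_j) is the Pallant-style standardized effect size.
    """
    names = list(values)
    groups = [np.asarray(values[g], dtype=float) for g in names]
    sizes = np.array([len(g) for g in groups])
    if (sizes == 0).any():
        raise ValueError("empty group")
    n, k = int(sizes.sum()), len(groups)
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum(sizes)
    rank_groups = np.split(ranks, bounds[:-1])
    mean_ranks = np.array([rg.mean() for rg in rank_groups])
    if h is None:
        h, _ = kruskal_wallis(groups)
    # pooled rank variance with tie correction (vanishes when all tied)
    s2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    out: dict[tuple[str, str], tuple[float, float, float]] = {}
    for (i, a), (j, b) in combinations(enumerate(names), 2):
        denom_var = s2 * (n - 1 - h) / (n - k) * (1.0 / sizes[i] + 1.0 / sizes[j])
        if denom_var <= 0:
            t = 0.0
        else:
            t = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(denom_var)
        p = 2.0 * sps.t.sf(abs(t), df=n - k)
        r = abs(t) / math.sqrt(sizes[i] + sizes[j])
        out[(a, b)] = (float(t), float(min(p, 1.0)), float(r))
    return out


def jonckheere_terpstra(
    values: Sequence[np.ndarray], alternative: str = "two-sided"
) -> tuple[float, float, float]:
    """Jonckheere–Terpstra trend test for ordered groups.

    ``values`` must be given in the hypothesised order.  Returns
    (JT, z, p) with JT the sum of between-group Mann–Whitney counts (ties
    counted 1/2), z from the tie-adjusted normal approximation.
    """
    groups = [np.asarray(g, dtype=float) for g in values if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 nonempty groups")
    sizes = np.array([len(g) for g in groups])
    n = int(sizes.sum())
    jt = 0.0
    for gi, gj in combinations(groups, 2):
        diff = gj[None, :] - gi[:, None]
        jt += float((diff > 0).sum() + 0.5 * (diff == 0).sum())
    mean_jt = (n**2 - np.sum(sizes**2)) / 4.0
    pooled = np.concatenate(groups)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    ni = sizes.astype(float)
    term1 = (
        n * (n - 1) * (2 * n + 5)
        - np.sum(ni * (ni - 1) * (2 * ni + 5))
        - np.sum(t * (t - 1) * (2 * t + 5))
    ) / 72.0
    term2 = (
        np.sum(ni * (ni - 1) * (ni - 2)) * np.sum(t * (t - 1) * (t - 2))
    ) / (36.0 * n * (n - 1) * (n - 2))
    term3 = (np.sum(ni * (ni - 1)) * np.sum(t * (t - 1))) / (8.0 * n * (n - 1))
    var_jt = term1 + term2 + term3
    if var_jt <= 0:
        return jt, 0.0, 1.0
    z = (jt - mean_jt) / math.sqrt(var_jt)
    if alternative == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif alternative == "increasing":
        p = float(sps.norm.sf(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(jt), float(z), float(min(p, 1.0))


def lancaster_combine(
    p_values: Sequence[float], weights: Sequence[float]
) -> float:
    """Lancaster's weighted p-value combination via chi-square quantiles.

    Each p_i maps to the upper-tail chi-square quantile with w_i degrees of
    freedom; the sum is referred to chi-square with sum(w_i) d.f.  With all
    weights equal to 2 this is exactly Fisher's method.  Zero p-values are
    clamped to machine epsilon to keep quantiles finite.
    """
    p = np.asarray(p_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape:
        raise ValueError("p_values and weights must have equal length")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    p = np.clip(p, np.finfo(float).eps, 1.0)
    t = np.sum(sps.chi2.isf(p, df=w))
    return float(sps.chi2.sf(t, df=w.sum()))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def chi_square_presence(
    presence: np.ndarray,
    groups: np.ndarray,
    n_permutations: int = 9999,
    seed: int = 0,
) -> tuple[float, float, str]:
    """Chi-square independence test of presence/absence status across groups.

    Builds the 2 x k contingency table of detected vs censored counts.  When
    any expected count falls below 5 the asymptotic chi-square is replaced
    by Fisher's exact test (2 x 2) or a seeded Monte-Carlo permutation
    chi-square (k > 2).  Returns (statistic, p, method).
    """
    presence = np.asarray(presence, dtype=bool)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    table = np.array(
        [
            [(presence & (groups == g)).sum() for g in levels],
            [(~presence & (groups == g)).sum() for g in levels],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any():
        raise ValueError("a group has zero samples")
    # degenerate margins: identical status everywhere -> no information
    if (table.sum(axis=1) == 0).any():
        return 0.0, 1.0, "degenerate"
    chi2, p, _, expected = sps.chi2_contingency(table, correction=False)
    if (expected >= 5).all():
        return float(chi2), float(p), "chi2"
    if len(levels) == 2:
        _, p_exact = sps.fisher_exact(table.astype(int))
        return float(chi2), float(p_exact), "fisher_exact"
    rng = np.random.default_rng(seed)
    perm = presence.copy()
    count = 0
    for _ in range(n_permutations):
        rng.shuffle(perm)
        t = np.array(
            [
                [(perm & (groups == g)).sum() for g in levels],
                [(~perm & (groups == g)).sum() for g in levels],
            ],
            dtype=float,
        )
        stat, _, _, _ = sps.chi2_contingency(t, correction=False)
        if stat >= chi2 - 1e-12:
            count += 1
    p_mc = (count + 1) / (n_permutations + 1)
    return float(chi2), float(p_mc), "permutation"


# ---------------------------------------------------------------------------
# Effect-size magnitude labels

# conventional cut-offs; eta-squared: negligible/small/medium/large at
# 0.01/0.06/0.14, r at 0.1/0.3/0.5
_ETA_CUTS = (0.01, 0.06, 0.14)
_R_CUTS = (0.1, 0.3, 0.5)
_LABELS = ("N", "S", "M", "L")


def effect_magnitude(value: float, kind: str = "r") -> str:
    if value < 0:
        raise ValueError("effect size must be nonnegative")
    cuts = {"eta_sq": _ETA_CUTS, "r": _R_CUTS}[kind]
    idx = int(np.searchsorted(cuts, value, side="right"))
    return _LABELS[idx]


# ---------------------------------------------------------------------------
# Class aggregates


def aggregate_classes(
    matrix: MeasurementMatrix, registry: PanelRegistry | None = None
) -> pd.DataFrame:
    """Per-sample summed concentration per analyte class, plus total lipids.

    Requires the linear micromolar scale (sums of log-values are
    meaningless); run after imputation/replacement, before log2.
    """
    if matrix.scale != "linear":
        raise ValueError("class aggregation requires the linear scale")
    registry = registry if registry is not None else matrix.registry
    cols = {}
    for c in CLASS_ORDER:
        ids = [a for a in registry.ids_of_class(c) if a in matrix.values.columns]
        cols[c] = matrix.values[ids].sum(axis=1) if ids else pd.Series(
            0.0, index=matrix.values.index
        )
    agg = pd.DataFrame(cols)
    agg["total_lipids"] = agg[[c for c in CLASS_ORDER if c in LIPID_CLASSES]].sum(axis=1)
    return agg


# ---------------------------------------------------------------------------
# The battery


def _analyte_row(vals: np.ndarray, group_arr: np.ndarray) -> dict:
    by_group = {g: vals[group_arr == g] for g in GROUPS}
    h, p = kruskal_wallis([by_group[g] for g in GROUPS])
    n, k = len(vals), len(GROUPS)
    eta = eta_squared_kw(h, k, n)
    row = {
        "n": n,
        "H": h,
        "p_kw": p,
        "eta_sq": eta,
        "eta_label": effect_magnitude(max(eta, 0.0), "eta_sq"),
    }
    pairs = conover_posthoc(by_group, h=h)
    for a, b in PAIRS:
        t, pc, r = pairs[(a, b)]
        tag = f"{a.lower()}_{b.lower()}"
        row[f"conover_t_{tag}"] = t
        row[f"conover_p_{tag}"] = pc
        row[f"r_{tag}"] = r
        row[f"r_label_{tag}"] = effect_magnitude(r, "r")
    _, z, pjt = jonckheere_terpstra([by_group[g] for g in GROUPS])
    row["jt_z"] = z
    row["p_jt"] = pjt
    med = {g: float(np.median(by_group[g])) for g in GROUPS}
    row["delta_lc_ctr"] = med["LC"] - med["Ctr"]
    row["direction_lc"] = int(np.sign(row["delta_lc_ctr"]))
    return row


def _battery_frame(
    matrix: MeasurementMatrix, analytes: list[str], alpha: float
) -> pd.DataFrame:
    group_arr = matrix.samples["group"].to_numpy()
    rows = {}
    vals_all = matrix.values
    for a in analytes:
        rows[a] = _analyte_row(vals_all[a].to_numpy(), group_arr)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "analyte_id"
    df.insert(0, "analyte_class",
              [matrix.registry.class_of(a) for a in df.index])
    df["p_kw_fdr"] = bh_fdr(df["p_kw"].to_numpy())
    df["significant"] = df["p_kw_fdr"] < alpha
    for a, b in PAIRS:
        tag = f"{a.lower()}_{b.lower()}"
        df[f"sig_{tag}"] = df["significant"] & (df[f"conover_p_{tag}"] < alpha)
    return df


@dataclass
class BatteryResult:
    """Outputs of the univariate battery in one or both analysis modes."""

    pooled: pd.DataFrame | None = None
    per_cohort: dict[str, pd.DataFrame] | None = None
    combined: pd.DataFrame | None = None
    concordance: pd.DataFrame | None = None
    presence: pd.DataFrame | None = None


def presence_battery(
    raw_matrix: MeasurementMatrix,
    binary_analytes: list[str],
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Presence/absence chi-square battery on the low-abundance analytes.

    Presence means the cell was detected and quantified; below-LOD cells
    (whether or not later replaced) count as absent; calibrant-failure
    cells are left out of the table.
    """
    codes = raw_matrix.codes
    group_arr = raw_matrix.samples["group"].to_numpy()
    rows = {}
    for a in binary_analytes:
        ca = codes[a].to_numpy()
        usable = ca != MISSING_CALIBRANT
        presence = ~np.isin(ca, (BELOW_LOD, LOD_REPLACED))
        stat, p, method = chi_square_presence(
            presence[usable], group_arr[usable], seed=seed
        )
        rows[a] = {"chi2": stat, "p": p, "method": method}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "analyte_id"
    if len(df):
        df["p_fdr"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["p_fdr"] < alpha
    return df


def lancaster_weights(sizes: Mapping[str, int]) -> dict[str, float]:
    """Cohort-size weights rescaled to mean 2 (equal sizes reduce to Fisher)."""
    mean_n = float(np.mean(list(sizes.values())))
    return {c: 2.0 * n / mean_n for c, n in sizes.items()}


def run_battery(
    matrix: MeasurementMatrix,
    partition: AnalytePartition,
    mode: str = "pooled",
    alpha: float = 0.05,
) -> BatteryResult:
    """Run the univariate battery on the quantitative analytes.

    mode="pooled": both cohorts together.  mode="per_cohort": one table per
    cohort plus a Lancaster-combined table (cohort-size weights) and the
    cross-cohort concordance list — an analyte is "common" only when
    FDR-significant with the same LC-vs-Ctr direction in both cohorts.
    """
    if mode not in ("pooled", "per_cohort"):
        raise ValueError(f"invalid mode {mode!r}")
    analytes = [a for a in partition.quantitative if a in matrix.values.columns]
    result = BatteryResult()
    if mode == "pooled":
        result.pooled = _battery_frame(matrix, analytes, alpha)
        return result

    cohorts = list(dict.fromkeys(matrix.samples["cohort"]))
    per_cohort: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    for cohort in cohorts:
        sub = matrix.subset_samples(
            matrix.samples.index[matrix.samples["cohort"] == cohort]
        )
        per_cohort[cohort] = _battery_frame(sub, analytes, alpha)
        sizes[cohort] = len(sub.sample_ids)
    result.per_cohort = per_cohort

    weights = lancaster_weights(sizes)
    combined = pd.DataFrame(index=per_cohort[cohorts[0]].index)
    combined["analyte_class"] = per_cohort[cohorts[0]]["analyte_class"]
    for cohort in cohorts:
        combined[f"p_kw_{cohort}"] = per_cohort[cohort]["p_kw"]
        combined[f"weight_{cohort}"] = weights[cohort]
    combined["p_lancaster"] = [
        lancaster_combine(
            [per_cohort[c].loc[a, "p_kw"] for c in cohorts],
            [weights[c] for c in cohorts],
        )
        for a in combined.index
    ]
    combined["p_lancaster_fdr"] = bh_fdr(combined["p_lancaster"].to_numpy())
    result.combined = combined

    conc = pd.DataFrame(index=combined.index)
    conc["analyte_class"] = combined["analyte_class"]
    for cohort in cohorts:
        conc[f"significant_{cohort}"] = per_cohort[cohort]["significant"]
        conc[f"direction_{cohort}"] = per_cohort[cohort]["direction_lc"]
    sig_all = np.logical_and.reduce(
        [conc[f"significant_{c}"].to_numpy() for c in cohorts]
    )
    same_dir = np.logical_and.reduce(
        [
            conc[f"direction_{c}"].to_numpy() == conc[f"direction_{cohorts[0]}"].to_numpy()
            for c in cohorts
        ]
    ) & (conc[f"direction_{cohorts[0]}"].to_numpy() != 0)
    conc["common"] = sig_all & same_dir
    result.concordance = conc
    return result


def class_level_tests(
    linear_matrix: MeasurementMatrix, alpha: float = 0.05
) -> pd.DataFrame:
    """Kruskal–Wallis battery on the per-class aggregate concentrations."""
    agg = aggregate_classes(linear_matrix)
    group_arr = linear_matrix.samples["group"].to_numpy()
    rows = {}
    for c in agg.columns:
        rows[c] = _analyte_row(agg[c].to_numpy(), group_arr)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "metabolite_class"
    df["p_kw_fdr"] = bh_fdr(df["p_kw"].to_numpy())
    df["significant"] = df["p_kw_fdr"] < alpha
    return df
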