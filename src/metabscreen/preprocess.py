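"""Normalization chain for plate-acquired targeted-metabolomics tables.

Fixed order: missingness profiling -> analyte partition (quantitative /
presence-absence / excluded) -> kNN imputation of calibrant failures ->
truncated-normal replacement of below-LOD zeros -> log2 transform ->
empirical-Bayes batch correction with the 96-well plate as the batch.
A 2-D UMAP embedding is provided for dataset-structure visualization only.

The batch correction is the standard parametric location/scale model:
per-analyte standardization, normal / inverse-gamma method-of-moments
priors across analytes within each batch, shrunken per-batch additive
(gamma) and multiplicative (delta) estimates, then back-transformation
restoring the grand mean and pooled variance.  The fitted parameters are
exposed so held-out samples can be adjusted without refitting, which is
what the leakage-guarded classifier mode requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .core import (
    BELOW_LOD,
    IMPUTED,
    LOD_REPLACED,
    MISSING_CALIBRANT,
    OBSERVED,
    MeasurementMatrix,
    PlateLimits,
)

# ---------------------------------------------------------------------------
# Missingness accounting and the analyte partition


@dataclass
class MissingnessProfile:
    """Per-stratum fractions of each missingness mechanism, per analyte.

    Rows are (cohort, group) strata — or pooled groups when
    ``pooled_groups`` — columns are analytes.
    """

    frac_calibrant: pd.DataFrame
    frac_below_lod: pd.DataFrame
    pooled_groups: bool = False


def profile_missingness(
    matrix: MeasurementMatrix, pooled_groups: bool = False
) -> MissingnessProfile:
    if matrix.values.empty:
        raise ValueError("empty matrix")
    keys = ["group"] if pooled_groups else ["cohort", "group"]
    strata = matrix.samples.groupby(keys, sort=True).groups
    cal_rows, lod_rows, index = [], [], []
    codes = matrix.codes
    for key, ids in strata.items():
        sub = codes.loc[ids]
        cal_rows.append((sub == MISSING_CALIBRANT).mean(axis=0))
        lod_rows.append((sub == BELOW_LOD).mean(axis=0))
        index.append(key)
    idx = pd.Index(index, name="group") if pooled_groups else pd.MultiIndex.from_tuples(
        index, names=["cohort", "group"]
    )
    return MissingnessProfile(
        frac_calibrant=pd.DataFrame(cal_rows, index=idx),
        frac_below_lod=pd.DataFrame(lod_rows, index=idx),
        pooled_groups=pooled_groups,
    )


@dataclass
class AnalytePartition:
    """Disjoint analyte sets: quantitative, presence/absence, excluded."""

    quantitative: list[str]
    binary: list[str]
    excluded: list[str]

    def __post_init__(self) -> None:
        sets = [set(self.quantitative), set(self.binary), set(self.excluded)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("partition sets must be disjoint")

    @property
    def retained(self) -> list[str]:
        return self.quantitative + self.binary

    def as_frame(self) -> pd.DataFrame:
        rows = [(a, "quantitative") for a in self.quantitative]
        rows += [(a, "binary") for a in self.binary]
        rows += [(a, "excluded") for a in self.excluded]
        return pd.DataFrame(rows, columns=["analyte_id", "partition"])


def partition_analytes(
    profile: MissingnessProfile,
    calibrant_tol: float = 0.10,
    lod_tol: float = 0.50,
) -> AnalytePartition:
    """Apply the 10% / 50% per-group missingness rules.

    An analyte whose calibrant-failure fraction exceeds ``calibrant_tol`` in
    any stratum is excluded outright; otherwise, if its below-LOD fraction
    exceeds ``lod_tol`` in any stratum it is analysed as presence/absence
    only; the rest are quantitative.
    """
    for tol in (calibrant_tol, lod_tol):
        if not 0.0 <= tol <= 1.0:
            raise ValueError("tolerances must be in [0, 1]")
    excluded_mask = (profile.frac_calibrant > calibrant_tol).any(axis=0)
    binary_mask = (profile.frac_below_lod > lod_tol).any(axis=0) & ~excluded_mask
    analytes = profile.frac_calibrant.columns
    excluded = [a for a in analytes if excluded_mask[a]]
    binary = [a for a in analytes if binary_mask[a]]
    quantitative = [a for a in analytes if not excluded_mask[a] and not binary_mask[a]]
    return AnalytePartition(quantitative, binary, excluded)


# ---------------------------------------------------------------------------
# kNN imputation of calibrant failures


def _correlation_to_donors(
    target_log2: np.ndarray,
    donor_log2: np.ndarray,
    min_shared: int,
) -> np.ndarray:
    """1 - Pearson correlation between a sample and each donor row.

    Correlations use analytes detected in both profiles (log2 scale);
    donors sharing fewer than ``min_shared`` analytes get distance inf.
    """
    dists = np.full(donor_log2.shape[0], np.inf)
    t_ok = np.isfinite(target_log2)
    for i, row in enumerate(donor_log2):
        shared = t_ok & np.isfinite(row)
        if shared.sum() < min_shared:
            continue
        x, y = target_log2[shared], row[shared]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        dists[i] = 1.0 - r
    return dists


def impute_calibrant_knn(
    matrix: MeasurementMatrix,
    k: int = 3,
    min_shared: int = 10,
    fallback_log: list | None = None,
) -> MeasurementMatrix:
    """Fill calibrant-failure cells from the k nearest same-group, same-plate donors.

    Distance is one minus the Pearson correlation of detected log2 profiles;
    each missing cell gets the mean concentration of the ``k`` nearest donor
    samples with that analyte detected.  When fewer than ``k`` eligible
    donors exist on the plate, the pool widens to the same cohort+group
    across plates, then to the stratum median; every fallback is logged.
    """
    if matrix.scale != "linear":
        raise ValueError("imputation operates on the linear scale")
    out = matrix.copy()
    values = out.values
    codes = out.codes
    log = fallback_log if fallback_log is not None else []

    vals_arr = values.to_numpy()
    pos = (codes.to_numpy() == OBSERVED) & np.isfinite(vals_arr) & (vals_arr > 0)
    log2_vals = np.full(vals_arr.shape, np.nan)
    log2_vals[pos] = np.log2(vals_arr[pos])
    log2_df = pd.DataFrame(log2_vals, index=values.index, columns=values.columns)

    samples = out.samples
    missing_cells = codes.to_numpy() == MISSING_CALIBRANT
    rows_with_missing = values.index[missing_cells.any(axis=1)]

    for sid in rows_with_missing:
        meta = samples.loc[sid]
        plate_pool = samples.index[
            (samples["cohort"] == meta["cohort"])
            & (samples["group"] == meta["group"])
            & (samples["plate_id"] == meta["plate_id"])
            & (samples.index != sid)
        ]
        group_pool = samples.index[
            (samples["cohort"] == meta["cohort"])
            & (samples["group"] == meta["group"])
            & (samples.index != sid)
        ]
        target = log2_df.loc[sid].to_numpy()
        dist_plate = _correlation_to_donors(
            target, log2_df.loc[plate_pool].to_numpy(), min_shared
        )
        dist_group: np.ndarray | None = None
        miss_analytes = codes.columns[codes.loc[sid].to_numpy() == MISSING_CALIBRANT]
        for analyte in miss_analytes:
            donor_vals = values.loc[plate_pool, analyte].to_numpy()
            donor_ok = (codes.loc[plate_pool, analyte].to_numpy() == OBSERVED) & np.isfinite(
                dist_plate
            )
            if donor_ok.sum() >= k:
                order = np.argsort(dist_plate[donor_ok], kind="stable")[:k]
                fill = float(donor_vals[donor_ok][order].mean())
            else:
                if dist_group is None:
                    dist_group = _correlation_to_donors(
                        target, log2_df.loc[group_pool].to_numpy(), min_shared
                    )
                gdonor_vals = values.loc[group_pool, analyte].to_numpy()
                gdonor_ok = (
                    codes.loc[group_pool, analyte].to_numpy() == OBSERVED
                ) & np.isfinite(dist_group)
                if gdonor_ok.sum() >= k:
                    order = np.argsort(dist_group[gdonor_ok], kind="stable")[:k]
                    fill = float(gdonor_vals[gdonor_ok][order].mean())
                    log.append(("cross_plate", sid, analyte))
                else:
                    obs = gdonor_vals[codes.loc[group_pool, analyte].to_numpy() == OBSERVED]
                    if len(obs) == 0:
                        obs_all = values[analyte].to_numpy()[
                            codes[analyte].to_numpy() == OBSERVED
                        ]
                        if len(obs_all) == 0:
                            raise ValueError(
                                f"no observed values at all for analyte {analyte!r}"
                            )
                        fill = float(np.median(obs_all))
                        log.append(("global_median", sid, analyte))
                    else:
                        fill = float(np.median(obs))
                        log.append(("group_median", sid, analyte))
            values.loc[sid, analyte] = fill
            codes.loc[sid, analyte] = IMPUTED
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Below-LOD replacement, log2


def replace_below_lod(
    matrix: MeasurementMatrix,
    limits: PlateLimits,
    seed: int,
    mean_frac: float = 0.5,
    sd_frac: float = 0.25,
) -> MeasurementMatrix:
    """Replace below-LOD zeros by truncated-normal draws on [0, LOD].

    Each censored cell receives an independent draw from
    Normal(mean_frac * LOD, sd_frac * LOD) truncated to [0, LOD], where LOD
    is the limit of the cell's plate for that analyte.  Defaults centre the
    mass mid-interval with negligible boundary pile-up.
    """
    out = matrix.copy()
    codes_arr = out.codes.to_numpy()
    mask = codes_arr == BELOW_LOD
    if not mask.any():
        return out
    plate_ids = list(dict.fromkeys(out.samples["plate_id"]))
    lod_wide = limits.as_matrix(plate_ids, out.analyte_ids)
    plate_of = out.samples["plate_id"].to_numpy()
    lod_cells = lod_wide.loc[plate_of].to_numpy()
    lod_flat = lod_cells[mask]
    if np.isnan(lod_flat).any():
        i, j = np.argwhere(mask & np.isnan(lod_cells))[0]
        raise KeyError(
            f"no LOD for plate {plate_of[i]!r}, analyte {out.analyte_ids[j]!r}"
        )
    a = (0.0 - mean_frac) / sd_frac
    b = (1.0 - mean_frac) / sd_frac
    rng = np.random.default_rng(seed)
    draws_unit = truncnorm.rvs(a, b, loc=mean_frac, scale=sd_frac,
                               size=lod_flat.size, random_state=rng)
    vals = out.values.to_numpy()
    vals[mask] = lod_flat * draws_unit
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    codes_arr[mask] = LOD_REPLACED
    out.codes = pd.DataFrame(codes_arr, index=out.codes.index, columns=out.codes.columns)
    out.validate()
    return out


def log2_transform(matrix: MeasurementMatrix) -> MeasurementMatrix:
    """Elementwise log2; requires every cell strictly positive."""
    if matrix.scale != "linear":
        raise ValueError("matrix already transformed")
    vals = matrix.values.to_numpy()
    bad = ~(vals > 0) | ~np.isfinite(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"nonpositive or missing value at sample {matrix.sample_ids[i]!r}, "
            f"analyte {matrix.analyte_ids[j]!r}; impute and replace first"
        )
    out = matrix.copy()
    out.values = pd.DataFrame(
        np.log2(vals), index=matrix.values.index, columns=matrix.values.columns
    )
    out.scale = "log2"
    return out


# ---------------------------------------------------------------------------
# Empirical-Bayes batch correction (parametric location/scale model)


@dataclass
class CombatModel:
    """Fitted batch-correction parameters, applicable to held-out samples."""

    stand_mean: pd.Series          # per-analyte grand mean
    var_pooled: pd.Series          # per-analyte pooled within-batch variance
    gamma_star: pd.DataFrame       # batches x analytes, shrunken additive shifts
    delta_star: pd.DataFrame       # batches x analytes, shrunken scale factors

    def transform(self, values: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
        unknown = set(batches.unique()) - set(self.gamma_star.index)
        if unknown:
            raise KeyError(f"batches not seen at fit time: {sorted(unknown)}")
        sd = np.sqrt(self.var_pooled.to_numpy())[None, :]
        z = (values.to_numpy() - self.stand_mean.to_numpy()[None, :]) / sd
        g = self.gamma_star.loc[batches].to_numpy()
        d = self.delta_star.loc[batches].to_numpy()
        adj = (z - g) / np.sqrt(d)
        out = adj * sd + self.stand_mean.to_numpy()[None, :]
        return pd.DataFrame(out, index=values.index, columns=values.columns)


def _it_solve(
    s_data: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
    g_bar: float, t2: float, a_prior: float, b_prior: float,
    conv: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the coupled posterior equations for one batch."""
    n = s_data.shape[0]
    g_new, d_new = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_old, d_old = g_new.copy(), d_new.copy()
        g_new = (n * t2 * g_hat + d_new * g_bar) / (n * t2 + d_new)
        sse = ((s_data - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sse + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
    return g_new, d_new


def combat_fit(values: pd.DataFrame, batches: pd.Series) -> CombatModel:
    """Fit the parametric empirical-Bayes batch model on log2 data."""
    batches = batches.loc[values.index]
    levels = list(dict.fromkeys(batches))
    counts = batches.value_counts()
    if (counts < 2).any():
        bad = counts.index[counts < 2][0]
        raise ValueError(f"batch {bad!r} has fewer than 2 samples")
    X = values.to_numpy()
    n_total = X.shape[0]
    batch_means = np.vstack([X[(batches == b).to_numpy()].mean(axis=0) for b in levels])
    weights = np.array([counts[b] / n_total for b in levels])
    grand_mean = weights @ batch_means
    resid = X - batch_means[[levels.index(b) for b in batches]]
    var_pooled = (resid**2).mean(axis=0)
    if (var_pooled <= 0).any():
        j = int(np.argmin(var_pooled))
        raise ValueError(f"analyte {values.columns[j]!r} has zero within-batch variance")

    s_data = (X - grand_mean[None, :]) / np.sqrt(var_pooled)[None, :]
    gamma_star = np.empty_like(batch_means)
    delta_star = np.empty_like(batch_means)
    for i, b in enumerate(levels):
        rows = s_data[(batches == b).to_numpy()]
        g_hat = rows.mean(axis=0)
        d_hat = rows.var(axis=0, ddof=1)
        g_bar, t2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
        m, s2 = float(d_hat.mean()), float(d_hat.var(ddof=1))
        if s2 <= 0 or t2 <= 0:
            # degenerate prior (e.g. very few analytes): no shrinkage
            gamma_star[i], delta_star[i] = g_hat, np.maximum(d_hat, 1e-12)
            continue
        a_prior = (2.0 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        gamma_star[i], delta_star[i] = _it_solve(
            rows, g_hat, d_hat, g_bar, t2, a_prior, b_prior
        )
    return CombatModel(
        stand_mean=pd.Series(grand_mean, index=values.columns),
        var_pooled=pd.Series(var_pooled, index=values.columns),
        gamma_star=pd.DataFrame(gamma_star, index=pd.Index(levels, name="batch"),
                                columns=values.columns),
        delta_star=pd.DataFrame(delta_star, index=pd.Index(levels, name="batch"),
                                columns=values.columns),
    )


def batch_correct_eb(
    matrix: MeasurementMatrix, batch_key: str = "plate_id"
) -> tuple[MeasurementMatrix, CombatModel | None]:
    """Adjust per-plate location/scale effects on a log2 matrix."""
    if matrix.scale != "log2":
        raise ValueError("batch correction expects a log2-transformed matrix")
    batches = matrix.samples[batch_key]
    if batches.nunique() == 1:
        return matrix.copy(), None
    model = combat_fit(matrix.values, batches)
    corrected = model.transform(matrix.values, batches)
    out = matrix.with_values(corrected)
    return out, model


# ---------------------------------------------------------------------------
# 2-D embedding (visualization only)


def embed_2d(
    matrix: MeasurementMatrix,
    seed: int,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """UMAP embedding of samples; deterministic given ``seed``."""
    if len(matrix.sample_ids) <= n_neighbors:
        raise ValueError("fewer samples than the neighborhood size")
    import umap  # deferred: heavy import

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
        random_state=int(seed) % (2**31),
    )
    coords = reducer.fit_transform(matrix.values.to_numpy())
    return pd.DataFrame(coords, index=matrix.values.index, columns=["x", "y"])


# ---------------------------------------------------------------------------
# Full chain


@dataclass
class PreprocessResult:
    """Corrected matrix plus everything needed to replay or extend the fit."""

    matrix: MeasurementMatrix          # log2, batch-corrected, retained analytes
    partition: AnalytePartition
    profile: MissingnessProfile
    combat: CombatModel | None
    limits: PlateLimits
    fallbacks: list = field(default_factory=list)
    params: dict = field(default_factory=dict)
    _fit_linear: MeasurementMatrix | None = None  # post-imputation donor pool

    def transform(self, held_out: MeasurementMatrix, seed: int) -> MeasurementMatrix:
        """Preprocess held-out samples using only fit-time statistics.

        Calibrant gaps are filled from fit-set donors (same cohort, group
        and plate), below-LOD zeros are replaced from the plate limits,
        and the fitted batch parameters are applied — the held-out samples
        never influence any estimate.
        """
        ids = self.partition.retained
        sub = held_out.subset_analytes([a for a in ids if a in held_out.values.columns])
        fit = self._fit_linear
        if fit is None:
            raise ValueError("fit donor pool not retained")
        combined = MeasurementMatrix(
            samples=pd.concat([fit.samples, sub.samples]),
            values=pd.concat([fit.values, sub.values]),
            codes=pd.concat([fit.codes, sub.codes]),
            registry=sub.registry,
        )
        # impute only the held-out cells; donors restricted to observed cells,
        # which include the fit set (held-out calibrant cells are NaN anyway)
        imputed = impute_calibrant_knn(
            combined, k=self.params.get("knn_k", 3),
            min_shared=self.params.get("min_shared", 10),
        ).subset_samples(sub.sample_ids)
        replaced = replace_below_lod(
            imputed, self.limits, seed,
            self.params.get("lod_mean_frac", 0.5), self.params.get("lod_sd_frac", 0.25),
        )
        logged = log2_transform(replaced)
        if self.combat is not None:
            corrected = self.combat.transform(
                logged.values, logged.samples["plate_id"]
            )
            logged = logged.with_values(corrected)
        return logged


def preprocess(
    matrix: MeasurementMatrix,
    limits: PlateLimits,
    seed: int,
    calibrant_tol: float = 0.10,
    lod_tol: float = 0.50,
    knn_k: int = 3,
    min_shared: int = 10,
    lod_mean_frac: float = 0.5,
    lod_sd_frac: float = 0.25,
    pooled_groups: bool = False,
    batch_key: str = "plate_id",
) -> PreprocessResult:
    """Run the full normalization chain on a raw linear-scale matrix."""
    profile = profile_missingness(matrix, pooled_groups=pooled_groups)
    partition = partition_analytes(profile, calibrant_tol, lod_tol)
    retained = matrix.subset_analytes(partition.retained)
    fallbacks: list = []
    imputed = impute_calibrant_knn(retained, k=knn_k, min_shared=min_shared,
                                   fallback_log=fallbacks)
    replaced = replace_below_lod(imputed, limits, seed, lod_mean_frac, lod_sd_frac)
    logged = log2_transform(replaced)
    corrected, combat = batch_correct_eb(logged, batch_key=batch_key)
    return PreprocessResult(
        matrix=corrected,
        partition=partition,
        profile=profile,
        combat=combat,
        limits=limits,
        fallbacks=fallbacks,
        params=dict(
            calibrant_tol=calibrant_tol, lod_tol=lod_tol, knn_k=knn_k,
            min_shared=min_shared, lod_mean_frac=lod_mean_frac,
            lod_sd_frac=lod_sd_frac, pooled_groups=pooled_groups,
            batch_key=batch_key, seed=seed,
        ),
        _fit_linear=imputed,
    )
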