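"""Synthetic two-cohort serum-metabolome generator with planted ground truth.

Emulates the statistical structure the downstream analysis assumes: a large
test cohort (MOLTEST-like, 123 samples per group) and a small validation
cohort (SMAC-like, 31 per group), each with three screening groups (Ctr /
LN / LC); class-structured log-normal lipid abundances dominated by
cholesteryl esters; per-sample metabolic heterogeneity (global dilution and
lipid-class factors); plate-wise batch effects (additive shift plus
multiplicative scale on the log2 scale, the model the empirical-Bayes
correction removes); and both missingness mechanisms — censoring below a
plate-specific LOD and independent calibrant failures.

Group effects are planted as log2 fold changes per analyte, optionally
scoped to one cohort, so cross-cohort concordance behaviour can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core
from .core import (
    BELOW_LOD,
    GROUPS,
    MISSING_CALIBRANT,
    OBSERVED,
    MeasurementMatrix,
    PanelRegistry,
    PlateLimits,
    default_panel,
)

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class EffectSpec:
    """A planted group effect for one analyte (log2 fold changes vs Ctr)."""

    analyte_id: str
    lfc_lc: float
    lfc_ln: float = 0.0
    cohort_scope: str = "both"  # both | MOLTEST_only | SMAC_only

    def __post_init__(self) -> None:
        if self.cohort_scope not in ("both", "MOLTEST_only", "SMAC_only"):
            raise ValueError(f"bad cohort_scope {self.cohort_scope!r}")
        if not (np.isfinite(self.lfc_lc) and np.isfinite(self.lfc_ln)):
            raise ValueError("fold changes must be finite")

    def applies_to(self, cohort: str) -> bool:
        return self.cohort_scope == "both" or self.cohort_scope == f"{cohort}_only"


@dataclass(frozen=True)
class ClassAbundance:
    """Hyperparameters of per-analyte baseline means within a class (log2 uM)."""

    mean_log2: float
    sd_log2: float


# Per-analyte expected concentrations chosen so that, in aggregate, cholesteryl
# esters carry ~55% of total lipid mass, choline phospholipids ~25% and
# glycerides ~14% — the composition of detected serum lipids the analysis is
# built around.  mean_log2 is the class mean of per-analyte baseline log2
# concentrations; the log-normal mean-correction (~0.43 log2 units for the
# default dispersions) is already folded in.
DEFAULT_CLASS_ABUNDANCE: dict[str, ClassAbundance] = {
    core.AMINO_ACID: ClassAbundance(6.21, 0.8),
    core.BIOGENIC_AMINE: ClassAbundance(-0.94, 0.8),
    core.ACYLCARNITINE: ClassAbundance(-0.58, 0.8),
    core.LYSOPHOSPHATIDYLCHOLINE: ClassAbundance(2.57, 0.8),
    core.PHOSPHATIDYLCHOLINE: ClassAbundance(2.36, 0.8),
    core.DIGLYCERIDE: ClassAbundance(2.22, 0.8),
    core.TRIGLYCERIDE: ClassAbundance(3.48, 0.8),
    core.SPHINGOLIPID: ClassAbundance(2.38, 0.8),
    core.CHOLESTERYL_ESTER: ClassAbundance(7.31, 0.7),
    core.HEXOSE: ClassAbundance(12.2, 0.0),
}

DEFAULT_GROUP_SIZES: dict[str, dict[str, int]] = {
    "MOLTEST": {"Ctr": 123, "LN": 123, "LC": 123},
    "SMAC": {"Ctr": 31, "LN": 31, "LC": 31},
}


@dataclass
class CohortSpec:
    """Full parameterisation of one simulated two-cohort dataset.

    All effect and noise parameters live on the log2 scale.  ``lod_quantile``
    is the quantile of an analyte's baseline distribution used as the plate
    LOD (so it is, by construction, the expected censoring fraction); when
    ``lod_quantile_beta`` is set, per-analyte quantiles are drawn from that
    Beta distribution instead, and a ``low_abundance_fraction`` of analytes
    gets a high quantile so they fall below the LOD in most samples (the
    compounds that end up in the presence/absence analysis).
    """

    group_sizes: dict[str, dict[str, int]] = field(
        default_factory=lambda: {c: dict(g) for c, g in DEFAULT_GROUP_SIZES.items()}
    )
    plate_size: int = 96
    class_abundance: dict[str, ClassAbundance] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_ABUNDANCE)
    )
    noise_sd_range: tuple[float, float] = (0.35, 0.65)
    sample_shift_sd: float = 0.3
    class_factor_sd: float = 0.5
    cohort_shift_sd: float = 0.25
    batch_shift_sd: float = 0.3
    batch_scale_log_sd: float = 0.15
    lod_quantile: float = 0.02
    lod_quantile_beta: tuple[float, float] | None = None
    low_abundance_fraction: float = 0.0
    low_abundance_quantile_range: tuple[float, float] = (0.55, 0.9)
    lod_plate_jitter_sd: float = 0.05
    calibrant_missing_rate: float = 0.005
    calibrant_fail_fraction: float = 0.0
    calibrant_fail_rate: float = 0.2
    effects: list[EffectSpec] = field(default_factory=list)
    confounded_plates: bool = False
    seed: int = 0

    def validate(self, registry: PanelRegistry) -> None:
        for cohort, sizes in self.group_sizes.items():
            for group, n in sizes.items():
                if group not in GROUPS:
                    raise ValueError(f"unknown group {group!r}")
                if n < 1:
                    raise ValueError(f"group size must be >= 1 ({cohort}/{group})")
        for rate in (self.calibrant_missing_rate, self.calibrant_fail_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("calibrant rates must be in [0, 1)")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ValueError("lod_quantile must be in [0, 1)")
        if not 0.0 <= self.low_abundance_fraction < 1.0:
            raise ValueError("low_abundance_fraction must be in [0, 1)")
        if self.plate_size < 2:
            raise ValueError("plate_size must be >= 2")
        for eff in self.effects:
            if eff.analyte_id not in registry:
                raise ValueError(f"effect analyte {eff.analyte_id!r} not in registry")


@dataclass
class GroundTruth:
    """Planted parameters of a simulated dataset, for recovery testing."""

    analytes: pd.DataFrame   # per-analyte baseline/noise/LOD/differential status
    plates: pd.DataFrame     # per-plate cohort, additive gamma, scale delta
    censored: pd.DataFrame   # bool, below-LOD before calibrant masking
    calibrant_mask: pd.DataFrame  # bool, calibrant-failure cells
    effects: list[EffectSpec]

    def differential_ids(self, scope: str | None = None) -> list[str]:
        sub = self.analytes[self.analytes["is_differential"]]
        if scope is not None:
            sub = sub[sub["cohort_scope"] == scope]
        return list(sub.index)


def _assign_samples(spec: CohortSpec) -> pd.DataFrame:
    """Sample metadata with interleaved group order and sequential plate fill."""
    rows = []
    for cohort in ("MOLTEST", "SMAC"):
        if cohort not in spec.group_sizes:
            continue
        sizes = spec.group_sizes[cohort]
        order: list[str] = []
        if spec.confounded_plates:
            for g in GROUPS:
                order.extend([g] * sizes.get(g, 0))
        else:
            counters = {g: 0 for g in GROUPS}
            while any(counters[g] < sizes.get(g, 0) for g in GROUPS):
                for g in GROUPS:
                    if counters[g] < sizes.get(g, 0):
                        order.append(g)
                        counters[g] += 1
        for i, g in enumerate(order):
            plate = f"{cohort}-P{i // spec.plate_size + 1}"
            rows.append(
                {
                    "sample_id": f"{cohort}_{i:04d}",
                    "cohort": cohort,
                    "group": g,
                    "plate_id": plate,
                }
            )
    samples = pd.DataFrame(rows).set_index("sample_id")
    return samples


def _sample_covariates(samples: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Age / sex / pack-years drawn to resemble a heavy-smoker screening cohort."""
    n = len(samples)
    samples = samples.copy()
    samples["age"] = np.clip(rng.normal(66, 6, n).round(), 50, 85).astype(int)
    samples["sex"] = np.where(rng.random(n) < 0.42, "F", "M")
    samples["pack_years"] = np.clip(rng.normal(46, 15, n).round(), 10, 140).astype(int)
    return samples


def generate(
    spec: CohortSpec, registry: PanelRegistry | None = None
) -> tuple[MeasurementMatrix, PlateLimits, GroundTruth]:
    """Simulate one two-cohort dataset.

    Draw order is fixed, so results are fully reproducible given
    ``spec.seed``; all randomness flows from a single generator.
    """
    registry = registry if registry is not None else default_panel()
    spec.validate(registry)
    rng = np.random.default_rng(spec.seed)

    samples = _assign_samples(spec)
    samples = _sample_covariates(samples, rng)
    analyte_ids = registry.ids
    n_samples, n_analytes = len(samples), len(analyte_ids)
    classes = np.array([registry.class_of(a) for a in analyte_ids])

    # --- per-analyte baselines -------------------------------------------
    mu = np.empty(n_analytes)
    for j, a_class in enumerate(classes):
        ab = spec.class_abundance[a_class]
        mu[j] = ab.mean_log2 + ab.sd_log2 * rng.standard_normal()
    sigma = rng.uniform(*spec.noise_sd_range, n_analytes)
    cohort_offset = {
        "MOLTEST": np.zeros(n_analytes),
        "SMAC": rng.normal(0.0, spec.cohort_shift_sd, n_analytes),
    }

    # --- per-analyte LOD quantiles ---------------------------------------
    if spec.lod_quantile_beta is not None:
        a, b = spec.lod_quantile_beta
        quantiles = np.clip(rng.beta(a, b, n_analytes), 0.0, 0.45)
    else:
        quantiles = np.full(n_analytes, spec.lod_quantile)
    low_mask = rng.random(n_analytes) < spec.low_abundance_fraction
    quantiles[low_mask] = rng.uniform(
        *spec.low_abundance_quantile_range, int(low_mask.sum())
    )

    # --- per-analyte calibrant-failure rates ------------------------------
    cal_rate = np.full(n_analytes, spec.calibrant_missing_rate)
    fail_mask = rng.random(n_analytes) < spec.calibrant_fail_fraction
    cal_rate[fail_mask] = spec.calibrant_fail_rate

    # --- plates -----------------------------------------------------------
    plate_ids = list(dict.fromkeys(samples["plate_id"]))
    gamma = rng.normal(0.0, spec.batch_shift_sd, len(plate_ids))
    delta = np.exp(rng.normal(0.0, spec.batch_scale_log_sd, len(plate_ids)))
    plates = pd.DataFrame(
        {
            "cohort": [p.split("-")[0] for p in plate_ids],
            "gamma": gamma,
            "delta": delta,
        },
        index=pd.Index(plate_ids, name="plate_id"),
    )

    # --- per-sample heterogeneity ----------------------------------------
    g_s = rng.normal(0.0, spec.sample_shift_sd, n_samples)
    class_list = list(core.CLASS_ORDER)
    class_idx = np.array([class_list.index(c) for c in classes])
    class_factors = rng.normal(0.0, spec.class_factor_sd, (n_samples, len(class_list)))

    # --- planted group effects -------------------------------------------
    effect_shift = np.zeros((n_samples, n_analytes))
    group_arr = samples["group"].to_numpy()
    cohort_arr = samples["cohort"].to_numpy()
    col_of = {a: j for j, a in enumerate(analyte_ids)}
    for eff in spec.effects:
        j = col_of[eff.analyte_id]
        in_scope = np.array([eff.applies_to(c) for c in cohort_arr])
        effect_shift[in_scope & (group_arr == "LC"), j] += eff.lfc_lc
        effect_shift[in_scope & (group_arr == "LN"), j] += eff.lfc_ln

    # --- assemble log2 concentrations ------------------------------------
    plate_of = samples["plate_id"].to_numpy()
    p_idx = np.array([plate_ids.index(p) for p in plate_of])
    noise = rng.standard_normal((n_samples, n_analytes)) * sigma[None, :]
    base = (
        mu[None, :]
        + np.stack([cohort_offset[c] for c in cohort_arr])
        + g_s[:, None]
        + class_factors[:, class_idx]
        + effect_shift
    )
    log2_vals = base + gamma[p_idx][:, None] + delta[p_idx][:, None] * noise
    linear = np.exp2(log2_vals)

    # --- plate LODs and censoring ----------------------------------------
    from scipy.stats import norm

    base_sd = np.sqrt(sigma**2 + spec.sample_shift_sd**2 + spec.class_factor_sd**2)
    z_q = norm.ppf(np.clip(quantiles, 1e-12, 1 - 1e-12))
    lod_records = []
    lod_log2 = np.empty((len(plate_ids), n_analytes))
    for i, p in enumerate(plate_ids):
        jitter = rng.normal(0.0, spec.lod_plate_jitter_sd, n_analytes)
        lod_log2[i] = mu + cohort_offset[plates.loc[p, "cohort"]] + z_q * base_sd + jitter
        for j, a in enumerate(analyte_ids):
            lod_records.append((p, a, float(np.exp2(lod_log2[i, j]))))
    limits = PlateLimits.from_records(lod_records)

    lod_per_cell = np.exp2(lod_log2[p_idx])
    censored = linear < lod_per_cell
    values = np.where(censored, 0.0, linear)
    codes = np.where(censored, BELOW_LOD, OBSERVED)

    # --- calibrant failures (override censoring) --------------------------
    cal_mask = rng.random((n_samples, n_analytes)) < cal_rate[None, :]
    values = np.where(cal_mask, np.nan, values)
    codes = np.where(cal_mask, MISSING_CALIBRANT, codes)

    values_df = pd.DataFrame(values, index=samples.index, columns=analyte_ids)
    codes_df = pd.DataFrame(codes, index=samples.index, columns=analyte_ids)
    matrix = MeasurementMatrix(samples=samples, values=values_df, codes=codes_df,
                               registry=registry)

    # --- ground truth ------------------------------------------------------
    eff_by_analyte: dict[str, EffectSpec] = {}
    scope_of: dict[str, str] = {}
    for eff in spec.effects:
        if eff.analyte_id in eff_by_analyte:
            # two cohort-scoped specs for one analyte (opposite-sign pattern)
            scope_of[eff.analyte_id] = "cohort_dependent"
        else:
            eff_by_analyte[eff.analyte_id] = eff
            scope_of[eff.analyte_id] = eff.cohort_scope
    truth_analytes = pd.DataFrame(
        {
            "analyte_class": classes,
            "baseline_log2": mu,
            "noise_sd": sigma,
            "lod_quantile": quantiles,
            "calibrant_rate": cal_rate,
            "is_differential": [a in eff_by_analyte for a in analyte_ids],
            "lfc_lc": [eff_by_analyte[a].lfc_lc if a in eff_by_analyte else 0.0
                       for a in analyte_ids],
            "lfc_ln": [eff_by_analyte[a].lfc_ln if a in eff_by_analyte else 0.0
                       for a in analyte_ids],
            "cohort_scope": [scope_of.get(a, "") for a in analyte_ids],
        },
        index=pd.Index(analyte_ids, name="analyte_id"),
    )
    truth = GroundTruth(
        analytes=truth_analytes,
        plates=plates,
        censored=pd.DataFrame(censored, index=samples.index, columns=analyte_ids),
        calibrant_mask=pd.DataFrame(cal_mask, index=samples.index, columns=analyte_ids),
        effects=list(spec.effects),
    )
    return matrix, limits, truth


def spec_from_yaml(path) -> CohortSpec:
    """Load a CohortSpec from YAML.

    Scalar fields map directly; ``class_abundance`` entries are
    ``{class: [mean_log2, sd_log2]}`` and ``effects`` entries are mappings
    with the EffectSpec fields.  Omitted fields keep their defaults.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    from dataclasses import fields as dc_fields

    known = {f.name for f in dc_fields(CohortSpec)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown spec keys: {sorted(unknown)}")
    if "class_abundance" in data:
        data["class_abundance"] = {
            c: ClassAbundance(*v) for c, v in data["class_abundance"].items()
        }
    if "effects" in data:
        data["effects"] = [EffectSpec(**e) for e in data["effects"]]
    for key in ("noise_sd_range", "low_abundance_quantile_range",
                "lod_quantile_beta"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return CohortSpec(**data)


def default_paper_like_spec(seed: int = 0) -> CohortSpec:
    """The study-like default scenario.

    Two cohorts at the study's group sizes, ~6% of analytes failing the
    calibrant in a fifth of cells, ~30% of analytes low-abundance (mostly
    censored), and planted effects: four lipids reduced in lung cancer in
    both cohorts (the concordant set), plus cohort-specific effects
    including a triglyceride and an amino acid whose LC shifts have opposite
    signs in the two cohorts.
    """
    effects = [
        EffectSpec("LPC(18:0)", lfc_lc=-0.8),
        EffectSpec("PC(32:3)", lfc_lc=-0.7),
        EffectSpec("DG(39:0)", lfc_lc=-0.7),
        EffectSpec("CE(20:5)", lfc_lc=-0.8, lfc_ln=-0.1),
        EffectSpec("TG(52:4)", lfc_lc=-0.6, cohort_scope="MOLTEST_only"),
        EffectSpec("TG(52:4)", lfc_lc=0.6, cohort_scope="SMAC_only"),
        EffectSpec("Asn", lfc_lc=-0.6, cohort_scope="MOLTEST_only"),
        EffectSpec("Asn", lfc_lc=0.6, cohort_scope="SMAC_only"),
        EffectSpec("PC(38:6)", lfc_lc=-0.5, cohort_scope="MOLTEST_only"),
        EffectSpec("PC(40:6)", lfc_lc=-0.5, cohort_scope="MOLTEST_only"),
        EffectSpec("SM(38:1)", lfc_lc=-0.5, cohort_scope="MOLTEST_only"),
        EffectSpec("CE(22:6)", lfc_lc=-0.5, cohort_scope="SMAC_only"),
    ]
    return CohortSpec(
        lod_quantile_beta=(0.2, 10.0),
        low_abundance_fraction=0.30,
        calibrant_fail_fraction=0.06,
        effects=effects,
        seed=seed,
    )
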