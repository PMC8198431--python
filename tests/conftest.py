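import numpy as np
import pandas as pd
import pytest

from metabscreen import core
from metabscreen.core import MeasurementMatrix, default_panel
from metabscreen.preprocess import preprocess
from metabscreen.synthetic import CohortSpec, EffectSpec, default_paper_like_spec, generate


@pytest.fixture(scope="session")
def registry():
    return default_panel()


def small_spec(seed: int = 7, effects=None) -> CohortSpec:
    """Reduced two-cohort scenario for fast unit tests."""
    if effects is None:
        # effects sized for adequate rank-test power at the reduced n
        effects = [
            EffectSpec("LPC(18:0)", lfc_lc=-2.0),
            EffectSpec("CE(20:5)", lfc_lc=-2.0),
            EffectSpec("TG(52:4)", lfc_lc=-1.2, cohort_scope="MOLTEST_only"),
            EffectSpec("TG(52:4)", lfc_lc=1.2, cohort_scope="SMAC_only"),
        ]
    return CohortSpec(
        group_sizes={
            "MOLTEST": {"Ctr": 30, "LN": 30, "LC": 30},
            "SMAC": {"Ctr": 12, "LN": 12, "LC": 12},
        },
        plate_size=48,
        lod_quantile=0.0,
        calibrant_missing_rate=0.01,
        effects=effects,
        seed=seed,
    )


def heterogeneity_spec(seed: int = 4) -> CohortSpec:
    """Single-cohort scenario with pronounced inter-individual variation.

    Used by the imputation masking experiment: correlation-based kNN can
    only outperform a group mean when samples actually differ in a
    correlated way (here: strong per-sample lipid-class and dilution
    factors against modest per-analyte noise).
    """
    return CohortSpec(
        group_sizes={"MOLTEST": {"Ctr": 30, "LN": 30, "LC": 30}},
        plate_size=96,
        lod_quantile=0.0,
        calibrant_missing_rate=0.0,
        class_factor_sd=0.8,
        sample_shift_sd=0.5,
        noise_sd_range=(0.3, 0.5),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_data():
    """(matrix, limits, truth) for the reduced scenario."""
    return generate(small_spec())


@pytest.fixture(scope="session")
def small_preprocessed(small_data):
    matrix, limits, _ = small_data
    return preprocess(matrix, limits, seed=123)


@pytest.fixture(scope="session")
def paper_like_data():
    """Full-scale study-like dataset (123/31 per group, planted effects)."""
    return generate(default_paper_like_spec(1))


def toy_matrix(values, codes, groups, plates=None, cohorts=None, registry=None):
    """Assemble a small MeasurementMatrix from raw arrays for counting tests."""
    registry = registry if registry is not None else default_panel()
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    analytes = registry.ids[:p]
    sample_ids = [f"s{i}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "cohort": cohorts if cohorts is not None else ["MOLTEST"] * n,
            "group": groups,
            "plate_id": plates if plates is not None else ["P1"] * n,
            "age": 65,
            "sex": "F",
            "pack_years": 40,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return MeasurementMatrix(
        samples=samples,
        values=pd.DataFrame(values, index=sample_ids, columns=analytes),
        codes=pd.DataFrame(np.asarray(codes), index=sample_ids, columns=analytes),
        registry=registry,
    )
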