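"""Domain types for a Biocrates-style targeted serum metabolomics panel.

The panel mirrors an Absolute IDQ p400-class kit: ten analyte classes
(amino acids, biogenic amines, acylcarnitines, di-/triglycerides,
(lyso)phosphatidylcholines, sphingolipids, cholesteryl esters, hexose),
concentrations in micromolar, plate-wise acquisition in the 96-well format.
Two distinct missingness mechanisms are tracked per cell: a failed internal
isotope-labelled calibrant (no value at all) and a concentration below the
plate's limit of detection/quantitation (exported as a literal zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Analyte classes

AMINO_ACID = "amino_acid"
BIOGENIC_AMINE = "biogenic_amine"
ACYLCARNITINE = "acylcarnitine"
LYSOPHOSPHATIDYLCHOLINE = "lysophosphatidylcholine"
PHOSPHATIDYLCHOLINE = "phosphatidylcholine"
DIGLYCERIDE = "diglyceride"
TRIGLYCERIDE = "triglyceride"
SPHINGOLIPID = "sphingolipid"
CHOLESTERYL_ESTER = "cholesteryl_ester"
HEXOSE = "hexose"

CLASS_ORDER: tuple[str, ...] = (
    AMINO_ACID,
    BIOGENIC_AMINE,
    ACYLCARNITINE,
    LYSOPHOSPHATIDYLCHOLINE,
    PHOSPHATIDYLCHOLINE,
    DIGLYCERIDE,
    TRIGLYCERIDE,
    SPHINGOLIPID,
    CHOLESTERYL_ESTER,
    HEXOSE,
)

#: classes counted as lipids in class-share accounting
LIPID_CLASSES: frozenset[str] = frozenset(
    {
        ACYLCARNITINE,
        LYSOPHOSPHATIDYLCHOLINE,
        PHOSPHATIDYLCHOLINE,
        DIGLYCERIDE,
        TRIGLYCERIDE,
        SPHINGOLIPID,
        CHOLESTERYL_ESTER,
    }
)

# Cell codes of a MeasurementMatrix.
OBSERVED = "observed"
MISSING_CALIBRANT = "missing_calibrant"
BELOW_LOD = "below_lod"
IMPUTED = "imputed"          # calibrant gap filled by kNN; counts as observed
LOD_REPLACED = "lod_replaced"  # below-LOD zero replaced by a truncated-normal draw

CODES: frozenset[str] = frozenset(
    {OBSERVED, MISSING_CALIBRANT, BELOW_LOD, IMPUTED, LOD_REPLACED}
)
#: codes whose cells carry a quantified (detected) concentration
DETECTED_CODES: frozenset[str] = frozenset({OBSERVED, IMPUTED})

COHORTS = ("MOLTEST", "SMAC")
GROUPS = ("Ctr", "LN", "LC")

META_COLUMNS = ("cohort", "group", "plate_id", "age", "sex", "pack_years")


@dataclass(frozen=True)
class AnalyteDescriptor:
    """One measured compound (or unresolved isomer group) of the panel."""

    analyte_id: str
    analyte_class: str

    def __post_init__(self) -> None:
        if self.analyte_class not in CLASS_ORDER:
            raise ValueError(f"unknown analyte class {self.analyte_class!r}")

    @property
    def is_lipid(self) -> bool:
        return self.analyte_class in LIPID_CLASSES


class PanelRegistry:
    """Ordered collection of analyte descriptors with unique identifiers."""

    def __init__(self, analytes: Iterable[AnalyteDescriptor]):
        self.analytes: tuple[AnalyteDescriptor, ...] = tuple(analytes)
        self._by_id = {a.analyte_id: a for a in self.analytes}
        if len(self._by_id) != len(self.analytes):
            raise ValueError("duplicate analyte_id in registry")

    def __len__(self) -> int:
        return len(self.analytes)

    def __contains__(self, analyte_id: str) -> bool:
        return analyte_id in self._by_id

    def __getitem__(self, analyte_id: str) -> AnalyteDescriptor:
        return self._by_id[analyte_id]

    @property
    def ids(self) -> list[str]:
        return [a.analyte_id for a in self.analytes]

    def class_of(self, analyte_id: str) -> str:
        return self._by_id[analyte_id].analyte_class

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASS_ORDER}
        for a in self.analytes:
            counts[a.analyte_class] += 1
        return counts

    def ids_of_class(self, analyte_class: str) -> list[str]:
        return [a.analyte_id for a in self.analytes if a.analyte_class == analyte_class]

    def subset(self, analyte_ids: Iterable[str]) -> "PanelRegistry":
        wanted = set(analyte_ids)
        missing = wanted - set(self._by_id)
        if missing:
            raise KeyError(f"analytes not in registry: {sorted(missing)[:5]}")
        return PanelRegistry(a for a in self.analytes if a.analyte_id in wanted)


# ---------------------------------------------------------------------------
# Default panel

_AMINO_ACIDS = (
    "Ala Arg Asn Asp Cit Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr "
    "Trp Tyr Val"
).split()

_BIOGENIC_AMINES = (
    "ADMA SDMA alpha-AAA Ac-Orn Carnosine Creatinine DOPA Dopamine Histamine "
    "Kynurenine Met-SO Orn PEA Putrescine Sarcosine Serotonin Spermidine "
    "Spermine Taurine t4-OH-Pro"
).split() + ["HArg"]


def _species(prefix: str, combos: list[tuple[int, int]]) -> list[str]:
    return [f"{prefix}({c}:{d})" for c, d in combos]


def _grid(carbons: range, bonds: range, n: int) -> list[tuple[int, int]]:
    combos = [(c, d) for c in carbons for d in bonds]
    if len(combos) < n:
        raise ValueError("grid too small")
    return combos[:n]


def default_panel() -> PanelRegistry:
    """The 408-entry default registry.

    Class totals: 21 amino acids + 21 biogenic amines, 55 acylcarnitines,
    15 diglycerides + 45 triglycerides, 24 lysophosphatidylcholines + 172
    phosphatidylcholines, 40 sphingolipids, 14 cholesteryl esters and one
    hexose.  The kit's advertised total of 407 compounds differs from the
    sum of its per-class counts by one; the per-class counts are taken as
    authoritative (see docs/methods.md).  Lipid species beyond those with
    conventional names get systematic ``CLASS(C:D)`` identifiers.
    """
    entries: list[AnalyteDescriptor] = []
    for name in _AMINO_ACIDS:
        entries.append(AnalyteDescriptor(name, AMINO_ACID))
    for name in _BIOGENIC_AMINES:
        entries.append(AnalyteDescriptor(name, BIOGENIC_AMINE))
    # 55 acylcarnitines: C2..C18 with 0-2 double bonds plus short-chain extras
    ac = _species("AC", _grid(range(2, 21), range(0, 3), 55))
    entries.extend(AnalyteDescriptor(a, ACYLCARNITINE) for a in ac)
    # 24 LPC including LPC(18:0)
    lpc = _species("LPC", _grid(range(14, 26), range(0, 2), 24))
    assert "LPC(18:0)" in lpc
    entries.extend(AnalyteDescriptor(a, LYSOPHOSPHATIDYLCHOLINE) for a in lpc)
    # 172 PC spanning 28-49 carbons; covers PC(32:3), PC(38:6), PC(40:6), PC(41:5)
    pc = _species("PC", _grid(range(28, 50), range(0, 8), 172))
    for needed in ("PC(32:3)", "PC(38:6)", "PC(40:6)", "PC(41:5)"):
        assert needed in pc
    entries.extend(AnalyteDescriptor(a, PHOSPHATIDYLCHOLINE) for a in pc)
    # 15 DG including DG(39:0); 45 TG including TG(52:4)
    dg = _species("DG", _grid(range(32, 47), range(0, 1), 15))
    assert "DG(39:0)" in dg
    entries.extend(AnalyteDescriptor(a, DIGLYCERIDE) for a in dg)
    tg = _species("TG", _grid(range(44, 59), range(0, 5), 45))
    assert "TG(52:4)" in tg
    entries.extend(AnalyteDescriptor(a, TRIGLYCERIDE) for a in tg)
    # 40 SM including SM(38:1)
    sm = _species("SM", _grid(range(30, 44), range(0, 3), 40))
    assert "SM(38:1)" in sm
    entries.extend(AnalyteDescriptor(a, SPHINGOLIPID) for a in sm)
    # 14 CE including CE(20:5)
    ce = _species("CE", [(14, 0), (16, 0), (16, 1), (18, 0), (18, 1), (18, 2),
                         (18, 3), (20, 3), (20, 4), (20, 5), (22, 4), (22, 5),
                         (22, 6), (24, 0)])
    entries.extend(AnalyteDescriptor(a, CHOLESTERYL_ESTER) for a in ce)
    entries.append(AnalyteDescriptor("Hexose", HEXOSE))
    registry = PanelRegistry(entries)
    assert len(registry) == 408
    return registry


# ---------------------------------------------------------------------------
# Measurement containers


@dataclass(frozen=True)
class PlateLimits:
    """Per (plate, analyte) limit of detection/quantitation in micromolar."""

    table: pd.DataFrame  # MultiIndex (plate_id, analyte_id) -> column 'lod'

    def __post_init__(self) -> None:
        if list(self.table.columns) != ["lod"]:
            raise ValueError("PlateLimits table must have a single 'lod' column")
        if (self.table["lod"] <= 0).any() or not np.isfinite(self.table["lod"]).all():
            raise ValueError("every LOD must be finite and > 0")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, float]]) -> "PlateLimits":
        df = pd.DataFrame(records, columns=["plate_id", "analyte_id", "lod"])
        return cls(df.set_index(["plate_id", "analyte_id"]))

    def lod(self, plate_id: str, analyte_id: str) -> float:
        try:
            return float(self.table.loc[(plate_id, analyte_id), "lod"])
        except KeyError as exc:
            raise KeyError(f"no LOD for plate {plate_id!r}, analyte {analyte_id!r}") from exc

    def as_matrix(self, plate_ids: list[str], analyte_ids: list[str]) -> pd.DataFrame:
        """Dense plate x analyte LOD table (NaN where absent)."""
        wide = self.table["lod"].unstack("analyte_id")
        return wide.reindex(index=plate_ids, columns=analyte_ids)


@dataclass
class MeasurementMatrix:
    """Samples x analytes concentrations with per-cell missingness codes.

    ``values`` holds micromolar concentrations on the ``scale`` stated
    ("linear" or "log2"); calibrant-failure cells are NaN, below-LOD cells
    are 0 until replaced.  ``samples`` is the per-sample metadata frame
    (cohort, group, plate_id, age, sex, pack_years) indexed like the rows
    of ``values``; ``codes`` mirrors ``values`` cell-for-cell.
    """

    samples: pd.DataFrame
    values: pd.DataFrame
    codes: pd.DataFrame
    registry: PanelRegistry
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.shape != self.codes.shape:
            raise ValueError("values and codes dimensions disagree")
        if not self.values.index.equals(self.codes.index) or not self.values.columns.equals(
            self.codes.columns
        ):
            raise ValueError("values and codes must share index and columns")
        if not self.values.index.equals(self.samples.index):
            raise ValueError("sample metadata index must match value rows")
        for col in ("cohort", "group", "plate_id"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks required column {col!r}")
            if self.samples[col].isna().any():
                bad = self.samples.index[self.samples[col].isna()][0]
                raise ValueError(f"sample {bad!r} lacks {col}")
        unknown = set(self.values.columns) - set(self.registry.ids)
        if unknown:
            raise ValueError(f"analytes absent from registry: {sorted(unknown)[:5]}")
        bad_codes = set(np.unique(self.codes.to_numpy())) - CODES
        if bad_codes:
            raise ValueError(f"unknown cell codes: {sorted(bad_codes)}")
        codes = self.codes.to_numpy()
        vals = self.values.to_numpy()
        cal = codes == MISSING_CALIBRANT
        if not np.isnan(vals[cal]).all():
            raise ValueError("calibrant-missing cells must carry no value")
        if np.isnan(vals[~cal]).any():
            raise ValueError("non-missing cells must be finite")
        if self.scale == "linear":
            obs = np.isin(codes, list(DETECTED_CODES | {LOD_REPLACED}))
            if (vals[obs] < 0).any():
                raise ValueError("observed concentrations must be >= 0")
            if (vals[codes == BELOW_LOD] != 0).any():
                raise ValueError("below-LOD cells must hold 0 before replacement")
        elif self.scale != "log2":
            raise ValueError(f"unknown scale {self.scale!r}")

    # -- convenience -------------------------------------------------------

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def copy(self) -> "MeasurementMatrix":
        return MeasurementMatrix(
            self.samples.copy(), self.values.copy(), self.codes.copy(),
            self.registry, self.scale,
        )

    def subset_analytes(self, analyte_ids: Iterable[str]) -> "MeasurementMatrix":
        ids = [a for a in analyte_ids]
        return MeasurementMatrix(
            self.samples.copy(), self.values[ids].copy(), self.codes[ids].copy(),
            self.registry, self.scale,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "MeasurementMatrix":
        ids = [s for s in sample_ids]
        return MeasurementMatrix(
            self.samples.loc[ids].copy(), self.values.loc[ids].copy(),
            self.codes.loc[ids].copy(), self.registry, self.scale,
        )

    def with_values(self, values: pd.DataFrame, codes: pd.DataFrame | None = None,
                    scale: str | None = None) -> "MeasurementMatrix":
        return MeasurementMatrix(
            self.samples.copy(), values,
            self.codes.copy() if codes is None else codes,
            self.registry, self.scale if scale is None else scale,
        )


# ---------------------------------------------------------------------------
# Plate-export CSV dialect
#
# header: sample_id,cohort,group,plate_id,age,sex,pack_years,<analyte>,...
# empty cell  -> calibrant-failure missing
# literal 0   -> below the plate LOD
# companion LOD CSV: plate_id,analyte_id,lod


def read_concentration_csv(
    path: str | Path,
    registry: PanelRegistry,
    lod_path: str | Path | None = None,
    scale: str = "linear",
) -> tuple[MeasurementMatrix, PlateLimits | None]:
    """Read a plate-exported wide concentration table (and optional LOD table).

    With ``scale="linear"`` (raw exports) the missingness dialect applies:
    empty cell -> calibrant failure, literal 0 -> below LOD, negatives
    rejected.  With ``scale="log2"`` (already-normalized tables) every
    non-empty cell is an observed value of any sign.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "plate_id": str})
    expected_meta = ["sample_id", *META_COLUMNS]
    if list(df.columns[: len(expected_meta)]) != expected_meta:
        raise ValueError(
            f"malformed header: expected leading columns {expected_meta}, "
            f"got {list(df.columns[:len(expected_meta)])}"
        )
    analyte_cols = list(df.columns[len(expected_meta):])
    unknown = [a for a in analyte_cols if a not in registry]
    if unknown:
        raise ValueError(f"unknown analyte columns: {unknown[:5]}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id rows")
    df = df.set_index("sample_id")
    samples = df[list(META_COLUMNS)].copy()
    for col in ("cohort", "group", "plate_id"):
        if samples[col].isna().any():
            bad = samples.index[samples[col].isna()][0]
            raise ValueError(f"sample {bad!r} lacks metadata column {col!r}")
    values = df[analyte_cols].astype(float)
    arr = values.to_numpy()
    if scale == "linear":
        if (arr[np.isfinite(arr)] < 0).any():
            raise ValueError("negative concentration encountered")
        codes = np.where(
            np.isnan(arr), MISSING_CALIBRANT, np.where(arr == 0.0, BELOW_LOD, OBSERVED)
        )
    else:
        codes = np.where(np.isnan(arr), MISSING_CALIBRANT, OBSERVED)
    matrix = MeasurementMatrix(
        samples=samples,
        values=values,
        codes=pd.DataFrame(codes, index=values.index, columns=values.columns),
        registry=registry,
        scale=scale,
    )
    limits = None
    if lod_path is not None:
        limits = read_lod_csv(lod_path)
    return matrix, limits


def read_lod_csv(path: str | Path) -> PlateLimits:
    df = pd.read_csv(path, dtype={"plate_id": str, "analyte_id": str})
    if list(df.columns) != ["plate_id", "analyte_id", "lod"]:
        raise ValueError("LOD CSV must have columns plate_id,analyte_id,lod")
    return PlateLimits(df.set_index(["plate_id", "analyte_id"]).astype(float))


def write_concentration_csv(
    matrix: MeasurementMatrix,
    path: str | Path,
    limits: PlateLimits | None = None,
    lod_path: str | Path | None = None,
) -> None:
    """Write the plate-export dialect (lossless for raw, pre-imputation data)."""
    out = matrix.samples.copy()
    out.insert(0, "sample_id", out.index)
    vals = matrix.values.copy()
    # calibrant cells are NaN already -> empty field; below-LOD cells hold 0
    out = pd.concat([out, vals], axis=1)
    out.to_csv(path, index=False)
    if limits is not None:
        if lod_path is None:
            raise ValueError("lod_path required when writing limits")
        limits.table.reset_index().to_csv(lod_path, index=False)


def write_result_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write a per-analyte result table as TSV (12 significant digits)."""
    results.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
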