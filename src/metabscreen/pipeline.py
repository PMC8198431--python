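"""End-to-end orchestration: simulate -> preprocess -> stats -> classify.

A single master seed fans out to per-stage seeds through a spawned
``numpy.random.SeedSequence`` (documented scheme: children are, in order,
simulation, LOD replacement, embedding, statistics, classifier), so a run
is reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, preprocess as pp, stats as st, synthetic
from .core import MeasurementMatrix, PlateLimits, default_panel, read_concentration_csv, write_concentration_csv, write_result_table


@dataclass
class RunConfig:
    """All pipeline parameters; defaults reproduce the study-faithful run."""

    seed: int = 0
    # input: either simulate (default) or read from CSVs
    concentration_csv: str | None = None
    lod_csv: str | None = None
    simulate_null: bool = False          # drop planted group effects
    # preprocessing
    calibrant_tol: float = 0.10
    lod_tol: float = 0.50
    knn_k: int = 3
    pooled_groups: bool = False
    batch_key: str = "plate_id"
    # statistics
    alpha: float = 0.05
    # classifier
    folds: int = 10
    per_group_test: int = 10
    mrcv_reps: int = 100
    train_frac: float = 0.70
    delta_bic: float = 2.0
    candidate_cap: int | None = 60
    mode: str = "paper"                  # paper | strict
    # embedding
    embed: bool = True
    embed_neighbors: int = 15
    embed_min_dist: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(5)
    names = ("simulate", "lod_replace", "embed", "stats", "classify")
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _load_or_simulate(
    config: RunConfig, seeds: dict[str, int]
) -> tuple[MeasurementMatrix, PlateLimits, synthetic.GroundTruth | None]:
    if config.concentration_csv is not None:
        if config.lod_csv is None:
            raise ValueError("lod_csv required with concentration_csv")
        matrix, limits = read_concentration_csv(
            config.concentration_csv, default_panel(), config.lod_csv
        )
        return matrix, limits, None
    spec = synthetic.default_paper_like_spec(seeds["simulate"])
    if config.simulate_null:
        spec.effects = []
    return synthetic.generate(spec)


def run_all(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every stage and write the artifact bundle; abort names the stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    log: dict = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "stages": [],
        "fallbacks": [],
    }
    artifacts: dict[str, Path] = {}

    def stage(name):
        log["stages"].append({"stage": name, "time": time.strftime("%Y-%m-%dT%H:%M:%S")})

    try:
        stage("input")
        matrix, limits, truth = _load_or_simulate(config, seeds)
        if truth is not None:
            truth_path = outdir / "ground_truth.tsv"
            write_result_table(truth.analytes.reset_index(), truth_path)
            artifacts["ground_truth"] = truth_path
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"stage 'input' failed: {exc}") from exc

    try:
        stage("preprocess")
        res = pp.preprocess(
            matrix, limits, seed=seeds["lod_replace"],
            calibrant_tol=config.calibrant_tol, lod_tol=config.lod_tol,
            knn_k=config.knn_k, pooled_groups=config.pooled_groups,
            batch_key=config.batch_key,
        )
        log["fallbacks"] = [list(f) for f in res.fallbacks]
        corrected = res.matrix
        mat_path = outdir / "corrected_matrix.csv"
        write_concentration_csv(corrected, mat_path)
        part_path = outdir / "partition.tsv"
        write_result_table(res.partition.as_frame(), part_path)
        artifacts["corrected_matrix"] = mat_path
        artifacts["partition"] = part_path
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc

    try:
        stage("embedding")
        if config.embed:
            coords = pp.embed_2d(
                corrected, seeds["embed"],
                n_neighbors=config.embed_neighbors, min_dist=config.embed_min_dist,
            )
            emb_path = outdir / "embedding.csv"
            coords.join(corrected.samples[["cohort", "group"]]).to_csv(emb_path)
            artifacts["embedding"] = emb_path
    except Exception as exc:
        raise RuntimeError(f"stage 'embedding' failed: {exc}") from exc

    try:
        stage("stats")
        linear_corrected = corrected.with_values(
            pd.DataFrame(
                np.exp2(corrected.values.to_numpy()),
                index=corrected.values.index, columns=corrected.values.columns,
            ),
            scale="linear",
        )
        pooled = st.run_battery(corrected, res.partition, mode="pooled",
                                alpha=config.alpha)
        per_cohort = st.run_battery(corrected, res.partition, mode="per_cohort",
                                    alpha=config.alpha)
        presence = st.presence_battery(corrected, res.partition.binary,
                                       alpha=config.alpha, seed=seeds["stats"])
        class_tests = st.class_level_tests(linear_corrected, alpha=config.alpha)
        tables = {
            "stats_pooled": pooled.pooled.reset_index(),
            "stats_combined": per_cohort.combined.reset_index(),
            "concordance": per_cohort.concordance.reset_index(),
            "stats_presence": presence.reset_index(),
            "class_aggregates": class_tests.reset_index(),
        }
        for cohort, df in per_cohort.per_cohort.items():
            tables[f"stats_{cohort}"] = df.reset_index()
        for name, df in tables.items():
            path = outdir / f"{name}.tsv"
            write_result_table(df, path)
            artifacts[name] = path
    except Exception as exc:
        raise RuntimeError(f"stage 'stats' failed: {exc}") from exc

    try:
        stage("classify")
        if config.mode == "strict":
            report = classify.outer_cv_strict(
                matrix, limits, folds=config.folds,
                per_group_test=config.per_group_test, mrcv_reps=config.mrcv_reps,
                train_frac=config.train_frac, delta=config.delta_bic,
                candidate_cap=config.candidate_cap, seed=seeds["classify"],
                preprocess_kwargs=dict(
                    calibrant_tol=config.calibrant_tol, lod_tol=config.lod_tol,
                    knn_k=config.knn_k, pooled_groups=config.pooled_groups,
                ),
            )
        else:
            samples = corrected.samples
            mol = corrected.subset_samples(samples.index[samples.cohort == "MOLTEST"])
            smac = corrected.subset_samples(samples.index[samples.cohort == "SMAC"])
            report = classify.outer_cv(
                mol, smac, res.partition.quantitative, folds=config.folds,
                per_group_test=config.per_group_test, mrcv_reps=config.mrcv_reps,
                train_frac=config.train_frac, delta=config.delta_bic,
                candidate_cap=config.candidate_cap, seed=seeds["classify"],
            )
        rep_path = outdir / "classifier_report.json"
        with open(rep_path, "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=1)
        t2_path = outdir / "table2.tsv"
        write_result_table(report.to_table2(), t2_path)
        artifacts["classifier_report"] = rep_path
        artifacts["table2"] = t2_path
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    log_path = outdir / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    artifacts["run_log"] = log_path
    return artifacts


def make_report(bundle_dir: str | Path) -> str:
    """Human-readable markdown summary of a completed bundle."""
    bundle = Path(bundle_dir)
    required = ["table2.tsv", "class_aggregates.tsv", "concordance.tsv",
                "classifier_report.json"]
    for name in required:
        if not (bundle / name).exists():
            raise FileNotFoundError(f"incomplete bundle: missing {name}")
    table2 = pd.read_csv(bundle / "table2.tsv", sep="\t")
    class_agg = pd.read_csv(bundle / "class_aggregates.tsv", sep="\t")
    conc = pd.read_csv(bundle / "concordance.tsv", sep="\t")
    with open(bundle / "classifier_report.json") as fh:
        rep = json.load(fh)

    lines = ["# Serum metabolome screening analysis — run summary", ""]
    lines += ["## Classification model indices", "",
              table2.to_markdown(index=False), ""]
    acc = rep["aggregate"]["test"]["accuracy"]["mean"] * 100
    if abs(acc - 100.0 / 3.0) < 5.0:
        lines.append(
            f"Mean held-out test accuracy {acc:.1f}% — indistinguishable from "
            "the 33.3% expected by chance in a three-class model."
        )
    else:
        lines.append(
            f"Mean held-out test accuracy {acc:.1f}% "
            "(33.3% expected by chance in a three-class model)."
        )
    lines += ["", "## Metabolite-class aggregate differences", ""]
    cols = [c for c in ("metabolite_class", "H", "p_kw", "p_kw_fdr", "significant")
            if c in class_agg.columns]
    lines += [class_agg[cols].to_markdown(index=False), ""]
    lines += ["## Cross-cohort concordance", ""]
    common = conc[conc["common"] == True]  # noqa: E712
    if len(common) == 0:
        lines.append("No analyte was significant with the same direction in "
                     "both cohorts.")
    else:
        lines.append("Analytes significant with the same direction in both "
                     "cohorts:")
        for a in common["analyte_id"]:
            lines.append(f"- {a}")
    text = "\n".join(lines) + "\n"
    (bundle / "report.md").write_text(text)
    return text
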