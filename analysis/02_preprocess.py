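#!/usr/bin/env python
"""Normalize the simulated dataset: partition, impute, replace, correct.

Reads results/data/, applies the 10%/50% missingness rules, kNN imputation
of calibrant failures, truncated-normal below-LOD replacement, log2, and
plate-wise empirical-Bayes batch correction; writes the corrected matrix,
the analyte partition, and a 2-D UMAP embedding under results/.
"""

import json
from pathlib import Path

from metabscreen import core, preprocess as pp

DATA = Path("results/data")
OUT = Path("results")
SEED = 11


def main() -> None:
    matrix, limits = core.read_concentration_csv(
        DATA / "concentrations.csv", core.default_panel(), DATA / "lod.csv"
    )
    res = pp.preprocess(matrix, limits, seed=SEED)
    part = res.partition
    print(f"analyte partition: {len(part.quantitative)} quantitative, "
          f"{len(part.binary)} presence/absence, {len(part.excluded)} excluded")
    print(f"imputation fallbacks: {len(res.fallbacks)}")

    core.write_concentration_csv(res.matrix, OUT / "corrected_matrix.csv")
    core.write_result_table(part.as_frame(), OUT / "partition.tsv")
    with open(OUT / "preprocess_log.json", "w") as fh:
        json.dump({"params": res.params,
                   "fallbacks": [list(f) for f in res.fallbacks]}, fh, indent=1)

    coords = pp.embed_2d(res.matrix, seed=SEED)
    coords.join(res.matrix.samples[["cohort", "group"]]).to_csv(OUT / "embedding.csv")
    print(f"wrote corrected matrix and embedding under {OUT}/")


if __name__ == "__main__":
    main()
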