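#!/usr/bin/env python
"""Univariate battery and cross-cohort concordance on the corrected data.

Runs Kruskal-Wallis (+ eta-squared), Conover posthoc (+ Pallant r),
Jonckheere-Terpstra trend and BH-FDR per analyte — pooled and per cohort —
combines cohorts with Lancaster weighting, tests the presence/absence
analytes, aggregates metabolite classes, and writes all tables under
results/.
"""

import numpy as np
import pandas as pd
from pathlib import Path

from metabscreen import core, stats as st
from metabscreen.preprocess import AnalytePartition

OUT = Path("results")
SEED = 21


def main() -> None:
    matrix, _ = core.read_concentration_csv(
        OUT / "corrected_matrix.csv", core.default_panel(), scale="log2"
    )
    part_df = core.read_result_table(OUT / "partition.tsv")
    groups = part_df.groupby("partition")["analyte_id"].apply(list).to_dict()
    partition = AnalytePartition(
        quantitative=groups.get("quantitative", []),
        binary=[a for a in groups.get("binary", []) if a in matrix.values.columns],
        excluded=groups.get("excluded", []),
    )

    pooled = st.run_battery(matrix, partition, mode="pooled")
    per_cohort = st.run_battery(matrix, partition, mode="per_cohort")
    # presence/absence status comes from the raw export's censoring codes
    raw, _ = core.read_concentration_csv(
        Path("results/data/concentrations.csv"), core.default_panel()
    )
    presence = st.presence_battery(raw, partition.binary, seed=SEED)

    linear = matrix.with_values(
        pd.DataFrame(np.exp2(matrix.values.to_numpy()),
                     index=matrix.values.index, columns=matrix.values.columns),
        scale="linear",
    )
    class_tests = st.class_level_tests(linear)

    core.write_result_table(pooled.pooled.reset_index(), OUT / "stats_pooled.tsv")
    for cohort, df in per_cohort.per_cohort.items():
        core.write_result_table(df.reset_index(), OUT / f"stats_{cohort}.tsv")
    core.write_result_table(per_cohort.combined.reset_index(),
                            OUT / "stats_combined.tsv")
    core.write_result_table(per_cohort.concordance.reset_index(),
                            OUT / "concordance.tsv")
    core.write_result_table(presence.reset_index(), OUT / "stats_presence.tsv")
    core.write_result_table(class_tests.reset_index(), OUT / "class_aggregates.tsv")

    n_sig = int(pooled.pooled["significant"].sum())
    common = per_cohort.concordance.query("common").index.tolist()
    print(f"pooled battery: {n_sig} / {len(pooled.pooled)} analytes "
          f"FDR-significant at 0.05")
    print(f"class aggregates significant: "
          f"{class_tests.query('significant').index.tolist()}")
    print(f"cross-cohort concordant (same direction, both significant): {common}")
    if len(presence):
        print(f"presence/absence battery: "
              f"{int(presence['significant'].sum())} / {len(presence)} significant")


if __name__ == "__main__":
    main()
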