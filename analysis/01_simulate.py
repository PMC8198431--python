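#!/usr/bin/env python
"""Generate the study-like synthetic two-cohort dataset.

Emits the plate-exported concentration CSV (462 samples x 408 analytes,
two cohorts at 123 and 31 samples per screening group), the per-plate LOD
table, and the planted ground truth, under results/data/.
"""

from pathlib import Path

from metabscreen import core, synthetic

OUT = Path("results/data")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = synthetic.default_paper_like_spec(SEED)
    matrix, limits, truth = synthetic.generate(spec)
    core.write_concentration_csv(matrix, OUT / "concentrations.csv",
                                 limits, OUT / "lod.csv")
    core.write_result_table(truth.analytes.reset_index(), OUT / "ground_truth.tsv")

    codes = matrix.codes.to_numpy()
    n_cal = (codes == core.MISSING_CALIBRANT).sum()
    n_lod = (codes == core.BELOW_LOD).sum()
    print(f"wrote {len(matrix.sample_ids)} samples x {len(matrix.analyte_ids)} "
          f"analytes to {OUT}/")
    print(f"  calibrant-failure cells: {n_cal} ({100*n_cal/codes.size:.2f}%)")
    print(f"  below-LOD cells:        {n_lod} ({100*n_lod/codes.size:.2f}%)")
    print(f"  planted differential analytes: "
          f"{int(truth.analytes['is_differential'].sum())}")


if __name__ == "__main__":
    main()
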