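import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal, truncnorm

from metabscreen import core
from metabscreen.core import PlateLimits, default_panel
from metabscreen.preprocess import (
    batch_correct_eb,
    combat_fit,
    embed_2d,
    impute_calibrant_knn,
    log2_transform,
    partition_analytes,
    preprocess,
    profile_missingness,
    replace_below_lod,
)
from metabscreen.synthetic import CohortSpec, generate

from conftest import toy_matrix

OBS = core.OBSERVED
CAL = core.MISSING_CALIBRANT
LOD = core.BELOW_LOD


class TestMissingnessProfile:
    def test_all_observed_all_zero(self):
        m = toy_matrix(np.ones((6, 3)), [[OBS] * 3] * 6, ["Ctr", "LN", "LC"] * 2)
        prof = profile_missingness(m)
        assert (prof.frac_calibrant.to_numpy() == 0).all()
        assert (prof.frac_below_lod.to_numpy() == 0).all()

    def test_single_missing_cell_fraction(self):
        values = np.ones((10, 2))
        codes = np.full((10, 2), OBS, dtype=object)
        values[0, 0] = np.nan
        codes[0, 0] = CAL
        m = toy_matrix(values, codes, ["Ctr"] * 10)
        prof = profile_missingness(m)
        analyte = m.analyte_ids[0]
        assert prof.frac_calibrant.loc[("MOLTEST", "Ctr"), analyte] == pytest.approx(0.1)

    def test_strata_recount_matches_brute_force(self, small_data):
        matrix, _, _ = small_data
        prof = profile_missingness(matrix)
        # brute-force recount of one stratum x analyte
        analyte = matrix.analyte_ids[5]
        sel = (matrix.samples.cohort == "SMAC") & (matrix.samples.group == "LC")
        codes = matrix.codes.loc[sel, analyte]
        assert prof.frac_below_lod.loc[("SMAC", "LC"), analyte] == pytest.approx(
            (codes == LOD).mean()
        )
        # pooled counts are consistent with stratum-weighted sums
        n_by = matrix.samples.groupby(["cohort", "group"]).size()
        pooled = (prof.frac_calibrant.mul(n_by, axis=0)).sum(axis=0)
        assert pooled[analyte] == pytest.approx(
            (matrix.codes[analyte] == CAL).sum()
        )


class TestPartition:
    def _profile(self, cal, lod):
        idx = pd.MultiIndex.from_tuples(
            [("MOLTEST", "Ctr"), ("MOLTEST", "LC")], names=["cohort", "group"]
        )
        from metabscreen.preprocess import MissingnessProfile

        return MissingnessProfile(
            frac_calibrant=pd.DataFrame(cal, index=idx, columns=["A", "B"]),
            frac_below_lod=pd.DataFrame(lod, index=idx, columns=["A", "B"]),
        )

    def test_clean_analyte_is_quantitative(self):
        part = partition_analytes(self._profile([[0, 0], [0, 0]], [[0, 0], [0, 0]]))
        assert part.quantitative == ["A", "B"]

    def test_calibrant_over_ten_percent_excluded(self):
        part = partition_analytes(self._profile([[0.11, 0], [0, 0]], [[0, 0], [0, 0]]))
        assert part.excluded == ["A"]
        assert part.quantitative == ["B"]

    def test_mostly_censored_goes_binary(self):
        part = partition_analytes(self._profile([[0, 0], [0, 0]], [[0.6, 0], [0, 0]]))
        assert part.binary == ["A"]

    def test_exclusion_takes_precedence_over_binary(self):
        part = partition_analytes(
            self._profile([[0.2, 0], [0, 0]], [[0.9, 0], [0, 0]])
        )
        assert part.excluded == ["A"] and part.binary == []

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ValueError, match="tolerances"):
            partition_analytes(self._profile([[0, 0], [0, 0]], [[0, 0], [0, 0]]), 1.5)


class TestKnnImputation:
    def test_mean_of_three_nearest(self):
        # donors 0-2 share the target's profile (corr 1), donor 3 is reversed
        base = np.linspace(1, 12, 12)
        values = np.vstack([
            np.r_[1.0, base], np.r_[2.0, base * 1.1], np.r_[3.0, base * 0.9],
            np.r_[100.0, base[::-1]], np.r_[np.nan, base],
        ])
        codes = np.full(values.shape, OBS, dtype=object)
        codes[4, 0] = CAL
        m = toy_matrix(values, codes, ["Ctr"] * 5)
        out = impute_calibrant_knn(m, k=3, min_shared=5)
        target_analyte = m.analyte_ids[0]
        assert out.values.loc["s4", target_analyte] == pytest.approx(2.0)
        assert out.codes.loc["s4", target_analyte] == core.IMPUTED

    def test_identical_donor_ranks_nearest(self):
        base = np.linspace(1, 12, 12)
        values = np.vstack([
            np.r_[5.0, base],                 # identical profile -> distance 0
            np.r_[1.0, base[::-1]], np.r_[2.0, base[::-1]], np.r_[3.0, base[::-1]],
            np.r_[np.nan, base],
        ])
        codes = np.full(values.shape, OBS, dtype=object)
        codes[4, 0] = CAL
        m = toy_matrix(values, codes, ["Ctr"] * 5)
        out = impute_calibrant_knn(m, k=1, min_shared=5)
        assert out.values.loc["s4", m.analyte_ids[0]] == pytest.approx(5.0)

    def test_fallback_across_plates_is_logged(self):
        base = np.linspace(1, 12, 12)
        values = np.vstack([
            np.r_[np.nan, base],
            np.r_[1.0, base], np.r_[2.0, base], np.r_[3.0, base],
        ])
        codes = np.full(values.shape, OBS, dtype=object)
        codes[0, 0] = CAL
        log = []
        m = toy_matrix(values, codes, ["Ctr"] * 4, plates=["P1", "P2", "P2", "P2"])
        out = impute_calibrant_knn(m, k=3, min_shared=5, fallback_log=log)
        assert out.values.loc["s0", m.analyte_ids[0]] == pytest.approx(2.0)
        assert log and log[0][0] == "cross_plate"

    def test_masking_experiment_beats_group_mean(self):
        """Correlation-kNN should exploit per-sample heterogeneity that a
        group mean ignores."""
        from conftest import heterogeneity_spec

        matrix, _, _ = generate(heterogeneity_spec())
        rng = np.random.default_rng(42)
        m = matrix.copy()
        codes = m.codes.to_numpy()
        vals = m.values.to_numpy()
        observed = np.argwhere(codes == OBS)
        pick = observed[rng.choice(len(observed), size=200, replace=False)]
        truth_vals = vals[pick[:, 0], pick[:, 1]].copy()
        vals[pick[:, 0], pick[:, 1]] = np.nan
        codes[pick[:, 0], pick[:, 1]] = CAL
        m.values = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
        m.codes = pd.DataFrame(codes, index=m.codes.index, columns=m.codes.columns)
        out = impute_calibrant_knn(m, k=3)
        knn_vals = out.values.to_numpy()[pick[:, 0], pick[:, 1]]
        # group-mean baseline on the masked data, log2 scale comparison
        group_mean = np.empty(len(pick))
        groups = m.samples["group"].to_numpy()
        cohorts = m.samples["cohort"].to_numpy()
        for idx, (i, j) in enumerate(pick):
            sel = (groups == groups[i]) & (cohorts == cohorts[i])
            col = np.where(sel)[0]
            donor = vals[col, j]
            ok = (codes[col, j] == OBS) & np.isfinite(donor)
            group_mean[idx] = donor[ok].mean()
        rmse_knn = np.sqrt(np.mean((np.log2(knn_vals) - np.log2(truth_vals)) ** 2))
        rmse_gm = np.sqrt(np.mean((np.log2(group_mean) - np.log2(truth_vals)) ** 2))
        assert rmse_knn < rmse_gm


class TestBelowLodReplacement:
    def _censored_matrix(self, n=100, p=100, lod=1.0):
        values = np.zeros((n, p))
        codes = np.full((n, p), LOD, dtype=object)
        m = toy_matrix(values, codes, ["Ctr"] * n)
        limits = PlateLimits.from_records(
            [("P1", a, lod) for a in m.analyte_ids]
        )
        return m, limits

    def test_support_and_moments(self):
        m, limits = self._censored_matrix()
        out = replace_below_lod(m, limits, seed=0)
        draws = out.values.to_numpy().ravel()
        assert ((draws >= 0) & (draws <= 1.0)).all()
        assert (out.codes.to_numpy() == core.LOD_REPLACED).all()
        # closed-form truncated-normal moments as the oracle
        a, b = (0 - 0.5) / 0.25, (1 - 0.5) / 0.25
        mean = truncnorm.mean(a, b, loc=0.5, scale=0.25)
        sd = truncnorm.std(a, b, loc=0.5, scale=0.25)
        assert abs(draws.mean() - mean) < 3 * sd / np.sqrt(draws.size)

    def test_reproducible_and_seed_sensitive(self):
        m, limits = self._censored_matrix(n=10, p=10)
        a = replace_below_lod(m, limits, seed=1).values
        b = replace_below_lod(m, limits, seed=1).values
        c = replace_below_lod(m, limits, seed=2).values
        assert a.equals(b) and not a.equals(c)

    def test_noop_without_censored_cells(self):
        m = toy_matrix(np.ones((4, 3)), [[OBS] * 3] * 4, ["Ctr"] * 4)
        limits = PlateLimits.from_records([("P1", a, 1.0) for a in m.analyte_ids])
        out = replace_below_lod(m, limits, seed=0)
        assert out.values.equals(m.values)

    def test_missing_lod_entry_raises(self):
        m, _ = self._censored_matrix(n=4, p=2)
        limits = PlateLimits.from_records([("P1", m.analyte_ids[0], 1.0)])
        with pytest.raises(KeyError, match="no LOD"):
            replace_below_lod(m, limits, seed=0)


class TestLog2:
    def test_examples(self):
        m = toy_matrix([[4.0, 1.0]], [[OBS, OBS]], ["Ctr"])
        out = log2_transform(m)
        assert out.values.iloc[0, 0] == 2.0
        assert out.values.iloc[0, 1] == 0.0
        assert out.scale == "log2"
        back = np.exp2(out.values.to_numpy())
        np.testing.assert_allclose(back, m.values.to_numpy(), rtol=1e-12)

    def test_nonpositive_cell_named(self):
        m = toy_matrix([[4.0, 0.0]], [[OBS, LOD]], ["Ctr"])
        with pytest.raises(ValueError, match="s0"):
            log2_transform(m)

    def test_double_transform_rejected(self):
        m = toy_matrix([[4.0]], [[OBS]], ["Ctr"])
        out = log2_transform(m)
        with pytest.raises(ValueError, match="already"):
            log2_transform(out)


class TestBatchCorrection:
    def _log2_matrix(self, X, plates):
        n, p = X.shape
        m = toy_matrix(np.exp2(X), [[OBS] * p] * n, ["Ctr"] * n, plates=plates)
        return log2_transform(m)

    def test_single_batch_identity(self):
        rng = np.random.default_rng(0)
        m = self._log2_matrix(rng.normal(5, 1, (20, 10)), ["P1"] * 20)
        out, model = batch_correct_eb(m)
        assert model is None
        np.testing.assert_allclose(
            out.values.to_numpy(), m.values.to_numpy(), atol=1e-8
        )

    def test_planted_shift_removed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(5, 0.1, (200, 100))
        X[100:] += 1.0  # pure +1 log2 shift on every analyte in batch B
        m = self._log2_matrix(X, ["A"] * 100 + ["B"] * 100)
        out, _ = batch_correct_eb(m)
        corr = out.values.to_numpy()
        diff = corr[100:].mean(axis=0) - corr[:100].mean(axis=0)
        assert np.abs(diff).max() < 0.05

    def test_planted_scale_removed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(5, 0.5, (200, 100))
        X[100:] = 5 + (X[100:] - 5) * 2.0  # x2 spread in batch B
        m = self._log2_matrix(X, ["A"] * 100 + ["B"] * 100)
        out, _ = batch_correct_eb(m)
        corr = out.values.to_numpy()
        ratio = corr[100:].var(axis=0) / corr[:100].var(axis=0)
        assert 0.9 < np.exp(np.mean(np.log(ratio))) < 1.1

    def test_matches_scanpy_reference(self):
        anndata = pytest.importorskip("anndata")
        sc = pytest.importorskip("scanpy")
        rng = np.random.default_rng(3)
        X = rng.normal(5, 1, (120, 50))
        batch = np.repeat(["A", "B", "C"], 40)
        X[batch == "B"] += rng.normal(1.0, 0.2, 50)
        X[batch == "C"] += 0.5
        vals = pd.DataFrame(X, index=[f"s{i}" for i in range(120)],
                            columns=[f"a{j}" for j in range(50)])
        model = combat_fit(vals, pd.Series(batch, index=vals.index))
        mine = model.transform(vals, pd.Series(batch, index=vals.index))
        ad = anndata.AnnData(X=X.copy(), obs=pd.DataFrame({"batch": batch},
                                                          index=vals.index))
        ref = sc.pp.combat(ad, key="batch", inplace=False)
        # small systematic gap: the reference port uses the biased variance
        # for the additive-effect prior, this implementation the unbiased one
        assert np.abs(mine.to_numpy() - ref).max() < 0.01

    def test_degenerate_batches_rejected(self):
        rng = np.random.default_rng(0)
        m = self._log2_matrix(rng.normal(5, 1, (5, 4)), ["A"] * 4 + ["B"])
        with pytest.raises(ValueError, match="fewer than 2"):
            batch_correct_eb(m)

    def test_requires_log2_scale(self):
        m = toy_matrix(np.ones((4, 2)), [[OBS] * 2] * 4, ["Ctr"] * 4)
        with pytest.raises(ValueError, match="log2"):
            batch_correct_eb(m)


class TestFullChain:
    def test_order_and_determinism(self, small_data):
        matrix, limits, _ = small_data
        a = preprocess(matrix, limits, seed=5)
        b = preprocess(matrix, limits, seed=5)
        assert a.matrix.values.equals(b.matrix.values)
        assert a.matrix.scale == "log2"
        assert set(a.matrix.analyte_ids) == set(a.partition.retained)

    def test_metadata_untouched(self, small_data, small_preprocessed):
        matrix, _, _ = small_data
        pd.testing.assert_frame_equal(
            small_preprocessed.matrix.samples, matrix.samples
        )

    def test_plate_test_calibrated_after_correction(self):
        """With plate effects planted and no group effects, a Kruskal-Wallis
        test on plate labels should reject at roughly the nominal rate after
        correction (and grossly before)."""
        reg = default_panel()
        reg = reg.subset(reg.ids[:120])
        spec = CohortSpec(
            group_sizes={"MOLTEST": {"Ctr": 64, "LN": 64, "LC": 64}},
            plate_size=48, lod_quantile=0.0, calibrant_missing_rate=0.0,
            batch_shift_sd=0.5, batch_scale_log_sd=0.1, seed=17,
        )
        matrix, limits, _ = generate(spec, reg)
        res = preprocess(matrix, limits, seed=3)
        plates = matrix.samples["plate_id"].to_numpy()

        def rejection_rate(values):
            hits = 0
            for a in values.columns:
                col = values[a].to_numpy()
                _, p = kruskal(*[col[plates == b] for b in np.unique(plates)])
                hits += p < 0.05
            return hits / values.shape[1]

        raw_logged = np.log2(matrix.values)
        assert rejection_rate(raw_logged) > 0.5
        assert rejection_rate(res.matrix.values) < 0.15

    def test_strict_transform_uses_only_fit_statistics(self, small_data):
        matrix, limits, _ = small_data
        held_ids = matrix.sample_ids[:6]
        fit_ids = matrix.sample_ids[6:]
        res = preprocess(matrix.subset_samples(fit_ids), limits, seed=5)
        out = res.transform(matrix.subset_samples(held_ids), seed=6)
        assert out.scale == "log2"
        assert list(out.values.index) == held_ids
        assert np.isfinite(out.values.to_numpy()).all()
        # refitting without the held-out samples must give identical output
        again = res.transform(matrix.subset_samples(held_ids), seed=6)
        assert out.values.equals(again.values)


class TestEmbedding:
    def test_blob_separation_and_determinism(self):
        rng = np.random.default_rng(0)
        X = np.vstack([
            rng.normal(0, 1, (40, 15)),
            rng.normal(10, 1, (40, 15)),
        ])
        labels = np.array([0] * 40 + [1] * 40)
        m = toy_matrix(np.exp2(X * 0.1 + 5), [[OBS] * 15] * 80, ["Ctr"] * 80)
        m = log2_transform(m)
        coords = embed_2d(m, seed=11, n_neighbors=10)
        assert coords.shape == (80, 2)
        again = embed_2d(m, seed=11, n_neighbors=10)
        assert coords.equals(again)
        # 1-NN on the embedding separates the blobs
        from scipy.spatial.distance import cdist

        d = cdist(coords, coords)
        np.fill_diagonal(d, np.inf)
        acc = (labels[d.argmin(axis=1)] == labels).mean()
        assert acc >= 0.95

    def test_too_few_samples(self):
        m = toy_matrix(np.ones((5, 3)), [[OBS] * 3] * 5, ["Ctr"] * 5)
        with pytest.raises(ValueError, match="neighborhood"):
            embed_2d(log2_transform(m), seed=0, n_neighbors=15)
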