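import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metabscreen import core, stats as st
from metabscreen.preprocess import preprocess
from metabscreen.synthetic import EffectSpec, generate

import oracles
from conftest import small_spec, toy_matrix

OBS = core.OBSERVED


def random_groups(rng, k=3, min_n=4, max_n=12, ties=False):
    sizes = rng.integers(min_n, max_n + 1, size=k)
    if ties:
        return [rng.integers(0, 5, size=n).astype(float) for n in sizes]
    return [rng.normal(0, 1, size=n) for n in sizes]


class TestKruskalWallis:
    def test_hand_example(self):
        h, p = st.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(192 / 42, abs=1e-10)

    def test_all_tied_defined_as_zero(self):
        h, p = st.kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert (h, p) == (0.0, 1.0)

    @pytest.mark.parametrize("ties", [False, True])
    def test_matches_brute_force_oracle(self, ties):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            groups = random_groups(rng, ties=ties)
            h, p = st.kruskal_wallis(groups)
            h0, p0 = oracles.kw_brute(groups)
            assert h == pytest.approx(h0, abs=1e-10)
            assert p == pytest.approx(p0, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2 obs"):
            st.kruskal_wallis([[1.0], [2, 3]])


class TestEtaSquared:
    def test_hand_example(self):
        assert st.eta_squared_kw(192 / 42, 3, 6) == pytest.approx(0.857142857, abs=1e-6)

    def test_null_expectation_centred(self):
        assert st.eta_squared_kw(2.0, 3, 50) == 0.0

    def test_monotone_in_h(self):
        vals = [st.eta_squared_kw(h, 3, 30) for h in (1.0, 2.0, 5.0, 10.0)]
        assert vals == sorted(vals)

    def test_requires_n_above_k(self):
        with pytest.raises(ValueError):
            st.eta_squared_kw(1.0, 3, 3)


class TestConover:
    def test_identical_groups_zero(self):
        out = st.conover_posthoc({"a": np.r_[1.0, 2, 3], "b": np.r_[1.0, 2, 3],
                                  "c": np.r_[9.0, 9, 9]})
        t, p, r = out[("a", "b")]
        assert t == pytest.approx(0.0, abs=1e-12)
        assert r == 0.0

    def test_p_matches_permutation_oracle(self):
        """Analytic t-distribution p vs a 10,000-permutation null on a 3x8
        fixture; tolerance covers Monte-Carlo error plus the t approximation."""
        rng = np.random.default_rng(7)
        groups = {g: rng.normal(mu, 1, 8) for g, mu in
                  zip(("a", "b", "c"), (0.0, 0.4, 0.9))}
        out = st.conover_posthoc(groups)
        for pair in [("a", "b"), ("a", "c"), ("b", "c")]:
            p_perm = oracles.conover_perm_p(groups, pair, n_perm=10_000, seed=3)
            assert out[pair][1] == pytest.approx(p_perm, abs=0.03)

    def test_r_uses_pair_size(self):
        rng = np.random.default_rng(0)
        groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(1, 1, 6),
                  "c": rng.normal(2, 1, 8)}
        out = st.conover_posthoc(groups)
        t, _, r = out[("a", "b")]
        assert r == pytest.approx(abs(t) / np.sqrt(16))

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(5)
        groups = {g: rng.normal(i, 1, 7) for i, g in enumerate("abc")}
        out1 = st.conover_posthoc(groups)
        out2 = st.conover_posthoc({g: np.exp(v) for g, v in groups.items()})
        for pair in out1:
            assert out1[pair] == pytest.approx(out2[pair], abs=1e-10)


class TestJonckheereTerpstra:
    def test_extremes(self):
        jt, z, p = st.jonckheere_terpstra([[1, 2], [3, 4], [5, 6]])
        assert jt == 12.0  # maximum sum(n_i * n_j)
        jt2, z2, _ = st.jonckheere_terpstra([[5, 6], [3, 4], [1, 2]])
        assert jt2 == 0.0
        assert z > 0 > z2

    def test_statistic_matches_mannwhitney_sum(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            groups = random_groups(rng, ties=bool(rng.integers(2)))
            jt, _, _ = st.jonckheere_terpstra(groups)
            assert jt == pytest.approx(oracles.jt_brute(groups), abs=1e-9)

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 2000
        for _ in range(n_sim):
            groups = [rng.normal(0, 1, 30) for _ in range(3)]
            _, _, p = st.jonckheere_terpstra(groups)
            hits += p < 0.05
        rate = hits / n_sim
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_sim) + 0.005


class TestLancaster:
    def test_reduces_to_fisher_at_weight_two(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            p = rng.uniform(1e-6, 1, size=4)
            fisher = sps.combine_pvalues(p, method="fisher").pvalue
            assert st.lancaster_combine(p, [2.0] * 4) == pytest.approx(
                fisher, abs=1e-10
            )

    def test_worked_example(self):
        assert st.lancaster_combine([0.5, 0.5], [2, 2]) == pytest.approx(
            0.5966, abs=2e-4
        )

    def test_monotone_in_each_input(self):
        base = st.lancaster_combine([0.3, 0.4], [3.0, 1.0])
        assert st.lancaster_combine([0.2, 0.4], [3.0, 1.0]) < base
        assert st.lancaster_combine([0.3, 0.5], [3.0, 1.0]) > base

    def test_zero_p_clamped_finite(self):
        p = st.lancaster_combine([0.0, 0.5], [2.0, 2.0])
        assert 0.0 <= p <= 1.0

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            st.lancaster_combine([0.5], [0.0])


class TestBhFdr:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            st.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_single_p_unchanged(self):
        assert st.bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(st.bh_fdr(p), oracles.bh_brute(p), atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=25)
        assert (st.bh_fdr(p) >= p - 1e-15).all()


class TestChiSquarePresence:
    def test_equal_proportions_uninformative(self):
        presence = np.array([True] * 30 + [False] * 30)
        groups = np.tile(["a", "b", "c"], 20)
        stat, p, _ = st.chi_square_presence(presence, groups)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_textbook_table(self):
        presence = np.r_[[True] * 20, [False] * 20, [True] * 10, [False] * 10]
        groups = np.r_[["a"] * 20, ["b"] * 20, ["c"] * 10, ["c"] * 10]
        stat, p, method = st.chi_square_presence(presence, groups)
        assert method == "chi2"
        assert stat == pytest.approx(40.0)  # expected counts all 10
        assert p == pytest.approx(sps.chi2.sf(40.0, df=2))

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(3)
        presence = rng.random(60) < 0.5
        groups = np.tile(["a", "b", "c"], 20)
        _, p1, _ = st.chi_square_presence(presence, groups)
        relabel = {"a": "z", "b": "y", "c": "x"}
        _, p2, _ = st.chi_square_presence(
            presence, np.array([relabel[g] for g in groups])
        )
        assert p1 == pytest.approx(p2)

    def test_small_expected_counts_use_exact_path(self):
        presence = np.r_[[True] * 2, [False] * 6, [True] * 6, [False] * 2]
        groups = np.r_[["a"] * 8, ["b"] * 8]
        _, p, method = st.chi_square_presence(presence, groups)
        assert method == "fisher_exact"
        assert p == pytest.approx(
            sps.fisher_exact([[2, 6], [6, 2]])[1]
        )

    def test_small_counts_three_groups_permutation(self):
        presence = np.r_[[True] * 2, [False] * 4, [True] * 5, [False] * 1,
                         [True] * 3, [False] * 3]
        groups = np.r_[["a"] * 6, ["b"] * 6, ["c"] * 6]
        _, p, method = st.chi_square_presence(presence, groups, seed=5)
        assert method == "permutation"
        assert 0.0 < p <= 1.0


class TestEffectMagnitude:
    @pytest.mark.parametrize("value,kind,label", [
        (0.05, "r", "N"), (0.15, "r", "S"), (0.35, "r", "M"), (0.6, "r", "L"),
        (0.005, "eta_sq", "N"), (0.02, "eta_sq", "S"), (0.1, "eta_sq", "M"),
        (0.2, "eta_sq", "L"),
    ])
    def test_labels(self, value, kind, label):
        assert st.effect_magnitude(value, kind) == label

    def test_monotone(self):
        order = {"N": 0, "S": 1, "M": 2, "L": 3}
        labels = [order[st.effect_magnitude(v, "r")] for v in np.linspace(0, 1, 50)]
        assert labels == sorted(labels)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            st.effect_magnitude(-0.1)


class TestAggregates:
    def test_summation_and_identities(self):
        reg = core.default_panel()
        ce_ids = reg.ids_of_class("cholesteryl_ester")[:2]
        sub = reg.subset(ce_ids + ["Ala", "TG(44:0)"])
        by_id = {"Ala": 10.0, "TG(44:0)": 5.0, ce_ids[0]: 3.0, ce_ids[1]: 4.0}
        m = toy_matrix(
            [[by_id[a] for a in sub.ids]], [[OBS] * 4], ["Ctr"], registry=sub
        )
        agg = st.aggregate_classes(m)
        assert agg.loc["s0", "cholesteryl_ester"] == 7.0
        lipid_cols = [c for c in core.CLASS_ORDER if c in core.LIPID_CLASSES]
        assert agg.loc["s0", "total_lipids"] == pytest.approx(
            agg.loc["s0", lipid_cols].sum()
        )
        shares = agg.loc["s0", lipid_cols] / agg.loc["s0", "total_lipids"]
        assert shares.sum() == pytest.approx(1.0)

    def test_requires_linear_scale(self, small_preprocessed):
        with pytest.raises(ValueError, match="linear"):
            st.aggregate_classes(small_preprocessed.matrix)


class TestBattery:
    @pytest.fixture(scope="class")
    def battery(self, small_preprocessed):
        return st.run_battery(
            small_preprocessed.matrix, small_preprocessed.partition,
            mode="per_cohort",
        )

    def test_planted_both_cohort_analytes_are_common(self, battery):
        conc = battery.concordance
        assert conc.loc["LPC(18:0)", "common"]
        assert conc.loc["CE(20:5)", "common"]

    def test_opposite_direction_analyte_not_common(self, battery):
        conc = battery.concordance
        assert not conc.loc["TG(52:4)", "common"]

    def test_lancaster_column_bounds(self, battery):
        p = battery.combined["p_lancaster"]
        assert ((0 <= p) & (p <= 1)).all()
        assert battery.combined.loc["LPC(18:0)", "p_lancaster"] < 0.05

    def test_pooled_mode_flags_planted_analytes(self, small_preprocessed):
        res = st.run_battery(
            small_preprocessed.matrix, small_preprocessed.partition, mode="pooled"
        )
        assert res.pooled.loc["LPC(18:0)", "significant"]
        assert res.pooled.loc["LPC(18:0)", "sig_ctr_lc"]
        assert res.pooled.loc["LPC(18:0)", "direction_lc"] == -1

    def test_invalid_mode(self, small_preprocessed):
        with pytest.raises(ValueError, match="invalid mode"):
            st.run_battery(small_preprocessed.matrix,
                           small_preprocessed.partition, mode="bogus")

    def test_presence_battery_well_formed(self, small_data, small_preprocessed):
        matrix, _, _ = small_data
        df = st.presence_battery(
            small_preprocessed.matrix, small_preprocessed.partition.binary
        )
        if len(df):
            assert ((df["p"] >= 0) & (df["p"] <= 1)).all()
            assert set(df["method"]).issubset(
                {"chi2", "fisher_exact", "permutation", "degenerate"}
            )

    def test_lancaster_weights_mean_two(self):
        w = st.lancaster_weights({"MOLTEST": 369, "SMAC": 93})
        assert np.mean(list(w.values())) == pytest.approx(2.0)
        assert w["MOLTEST"] / w["SMAC"] == pytest.approx(369 / 93)


class TestRankInvariance:
    """All rank statistics are invariant to strictly monotone transforms."""

    @pytest.mark.parametrize("seed", range(5))
    def test_kw_and_jt_invariant(self, seed):
        rng = np.random.default_rng(seed)
        groups = random_groups(rng)
        transformed = [np.exp(g) for g in groups]
        assert st.kruskal_wallis(groups)[0] == pytest.approx(
            st.kruskal_wallis(transformed)[0], abs=1e-10
        )
        assert st.jonckheere_terpstra(groups)[0] == pytest.approx(
            st.jonckheere_terpstra(transformed)[0], abs=1e-10
        )
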