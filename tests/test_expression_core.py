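"""Expression filtering, empirical-control normalization, differential
expression, correlation analytics and the CMS comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hypertad as ht


def frame(values, prefix="s"):
    values = np.asarray(values, float)
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"{prefix}{i}" for i in range(values.shape[1])],
    )


def two_groups(n1, n2):
    cols = [f"s{i}" for i in range(n1 + n2)]
    return pd.Series(["A"] * n1 + ["B"] * n2, index=cols)


class TestFilterExpressed:
    @staticmethod
    def counts_with_cpm(cpm_rows, libsize=10**6):
        # library of exactly 1e6 so counts == CPM
        vals = np.asarray(cpm_rows, dtype=float)
        filler = libsize - vals.sum(axis=0)
        return frame(np.vstack([vals, filler]))

    def test_expressed_in_ninety_percent_of_one_group_kept(self):
        counts = self.counts_with_cpm([[1.2] * 9 + [0.0] + [0.0] * 10])
        groups = two_groups(10, 10)
        kept = ht.filter_expressed(counts, groups)
        assert "g0" in kept

    def test_cpm_exactly_at_threshold_dropped(self):
        counts = self.counts_with_cpm([[1.0] * 20])
        kept = ht.filter_expressed(counts, two_groups(10, 10))
        assert "g0" not in kept

    def test_half_of_both_groups_dropped(self):
        row = [5.0] * 5 + [0.0] * 5 + [5.0] * 5 + [0.0] * 5
        counts = self.counts_with_cpm([row])
        kept = ht.filter_expressed(counts, two_groups(10, 10))
        assert "g0" not in kept

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        counts = frame(rng.poisson(5, size=(50, 12)))
        groups = two_groups(6, 6)
        k1 = set(ht.filter_expressed(counts, groups, cpm_threshold=1.0))
        k2 = set(ht.filter_expressed(counts, groups, cpm_threshold=10.0))
        assert k2 <= k1

    def test_zero_library_rejected(self):
        counts = frame(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="library"):
            ht.filter_expressed(counts, two_groups(2, 2))


class TestIterativeEmpiricalControls:
    def test_pure_noise_passes_through(self):
        rng = np.random.default_rng(0)
        vals = frame(rng.normal(0, 1, (800, 20)))
        groups = two_groups(10, 10)
        res = ht.iterative_empirical_controls(vals, groups)
        change = (res.adjusted - ht.median_normalize(vals)).abs()
        assert change.median(axis=None) < 0.05
        assert len(res.controls) / len(vals) >= 0.8

    def test_planted_batch_removed_group_effect_kept(self):
        rng = np.random.default_rng(1)
        n_g, n_s = 800, 20
        noise = rng.normal(0, 1, (n_g, n_s))
        batch = np.tile([1.0, -1.0], n_s // 2)  # orthogonal to groups
        loadings = rng.normal(0, 1, n_g)
        effect = np.zeros(n_g)
        true = rng.choice(n_g, 80, replace=False)
        effect[true] = 1.0
        groups = two_groups(10, 10)
        gvec = (groups == "A").to_numpy(float)
        vals = frame(noise + np.outer(loadings, batch) + np.outer(effect, gvec))
        res = ht.iterative_empirical_controls(vals, groups)
        b = batch / np.linalg.norm(batch)
        before = float(np.mean((ht.median_normalize(vals).to_numpy() @ b) ** 2))
        after = float(np.mean((res.adjusted.to_numpy() @ b) ** 2))
        assert after / before < 0.2  # >= 80% of batch variance removed
        # the loop must not erode the group effect present in its input
        # (median normalization itself shifts the absolute level slightly)
        lfc_in = ht.differential_expression(ht.median_normalize(vals),
                                            groups).table["log2fc"]
        lfc_out = ht.differential_expression(res.adjusted,
                                             groups).table["log2fc"]
        ratio = lfc_out.to_numpy()[true].mean() / lfc_in.to_numpy()[true].mean()
        assert ratio == pytest.approx(1.0, abs=0.10)

    def test_k_zero_is_identity_after_median_normalization(self):
        rng = np.random.default_rng(2)
        vals = frame(rng.normal(2, 1, (50, 12)))
        res = ht.iterative_empirical_controls(vals, two_groups(6, 6), k_factors=0)
        pd.testing.assert_frame_equal(res.adjusted, ht.median_normalize(vals))

    def test_small_group_rejected(self):
        vals = frame(np.zeros((5, 4)))
        with pytest.raises(ValueError, match="fewer than 3"):
            ht.iterative_empirical_controls(vals, two_groups(2, 2))


class TestDifferentialExpression:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        half = rng.normal(0, 1, (30, 8))
        vals = frame(np.hstack([half, half]))
        res = ht.differential_expression(vals, two_groups(8, 8))
        assert np.allclose(res.table["log2fc"], 0.0)
        assert (res.table["adj_pvalue"] > 0.9).all()

    def test_group_swap_negates_fold_changes(self):
        rng = np.random.default_rng(1)
        vals = frame(rng.normal(0, 1, (40, 16)))
        groups = two_groups(8, 8)
        r1 = ht.differential_expression(vals, groups)
        swapped = groups.map({"A": "B", "B": "A"})
        r2 = ht.differential_expression(
            vals.iloc[:, ::-1], swapped.iloc[::-1]
        )
        np.testing.assert_allclose(
            r1.table["log2fc"], -r2.table["log2fc"], atol=1e-12
        )
        np.testing.assert_allclose(
            r1.table["pvalue"], r2.table["pvalue"], atol=1e-12
        )

    def test_planted_shift_sensitivity_and_fdr(self):
        rng = np.random.default_rng(5)
        n_g = 2000
        vals = rng.normal(0, 0.5, (n_g, 20))
        true = rng.choice(n_g, 100, replace=False)
        vals[np.ix_(true, np.arange(10))] += 1.0
        res = ht.differential_expression(frame(vals), two_groups(10, 10))
        sig = res.table["adj_pvalue"].to_numpy() <= 0.05
        sensitivity = sig[true].mean()
        n_false = sig.sum() - sig[true].sum()
        fdr = n_false / max(sig.sum(), 1)
        assert sensitivity >= 0.7  # Welch-test power at these conditions
        assert fdr <= 0.1

    def test_degenerate_zero_variance_rows(self):
        vals = frame([[1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
                      [1.0, 1.0, 1.0, 2.0, 2.0, 2.0]])
        res = ht.differential_expression(vals, two_groups(3, 3))
        assert res.table.loc["g0", "pvalue"] == 1.0
        assert res.table.loc["g1", "pvalue"] < 0.2


class TestMrnaProteinCorrelation:
    def test_identical_layers_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        rna = frame(rng.normal(size=(20, 10)))
        table, summary = ht.mrna_protein_correlation(rna, rna.copy())
        assert np.allclose(table["rho"], 1.0)
        assert summary["mean_rho"] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        rna = frame(rng.normal(size=(10, 10)))
        table, _ = ht.mrna_protein_correlation(rna, np.exp(rna))
        assert np.allclose(table["rho"], 1.0)

    def test_independent_layers_are_null(self):
        rng = np.random.default_rng(2)
        rna = frame(rng.normal(size=(2000, 27)))
        prot = frame(rng.normal(size=(2000, 27)))
        _table, summary = ht.mrna_protein_correlation(rna, prot)
        assert abs(summary["mean_rho"]) < 0.02
        assert summary["fraction_significant"] <= 0.05

    def test_unmatched_genes_counted(self):
        rng = np.random.default_rng(3)
        rna = frame(rng.normal(size=(10, 8)))
        prot = frame(rng.normal(size=(10, 8)))
        prot.index = [f"g{i}" for i in range(5, 15)]
        _table, summary = ht.mrna_protein_correlation(rna, prot)
        assert summary["n_genes"] == 5
        assert summary["n_unmatched"] == 10


class TestComplexCoregulation:
    def test_planted_complex_factor_detected(self):
        rng = np.random.default_rng(0)
        n_g, n_s = 300, 20
        vals = rng.normal(0, 1, (n_g, n_s))
        factor = rng.normal(0, 1, n_s)
        members = [f"g{i}" for i in range(10)]
        for i in range(10):
            vals[i] += factor
        df = frame(vals)
        cmap = pd.Series("c1", index=members)
        res = ht.complex_coregulation(df, cmap, n_random=1000, seed=1)
        assert res["mean_within"] > res["mean_random"]
        assert res["pvalue"] < 0.01

    def test_identical_member_rows_give_unit_pairs(self):
        rng = np.random.default_rng(1)
        vals = frame(rng.normal(size=(10, 12)))
        vals.loc["g1"] = vals.loc["g0"]
        vals.loc["g2"] = vals.loc["g0"]
        cmap = pd.Series("c1", index=["g0", "g1", "g2"])
        res = ht.complex_coregulation(vals, cmap, n_random=200, seed=0)
        assert np.allclose(res["within"], 1.0)

    def test_random_map_is_null(self):
        rng = np.random.default_rng(2)
        vals = frame(rng.normal(size=(400, 24)))
        members = rng.choice(vals.index, 60, replace=False)
        cmap = pd.Series(
            [f"c{i % 12}" for i in range(60)], index=members
        )
        res = ht.complex_coregulation(vals, cmap, n_random=3000, seed=3)
        assert abs(res["mean_within"] - res["mean_random"]) < 0.05

    def test_no_qualifying_complex_rejected(self):
        vals = frame(np.zeros((5, 8)))
        cmap = pd.Series("c1", index=["absent_gene"])
        with pytest.raises(ValueError):
            ht.complex_coregulation(vals, cmap)


class TestPartialCorrelation:
    def test_simpsons_paradox_construction(self):
        rng = np.random.default_rng(0)
        subtype = np.repeat(["A", "B"], 20)
        shift = np.where(subtype == "A", 5.0, 0.0)
        x = shift + rng.normal(0, 1, 40)
        y = shift + rng.normal(0, 1, 40)
        raw = stats.spearmanr(x, y).statistic
        partial = ht.partial_correlation_by_subtype(x, y, subtype)
        assert raw > 0.6
        assert abs(partial) < 0.3

    def test_subtype_balanced_signal_preserved(self):
        rng = np.random.default_rng(1)
        subtype = np.tile(["A", "B"], 20)
        common = rng.normal(0, 1, 40)
        x = common + rng.normal(0, 0.3, 40)
        y = common + rng.normal(0, 0.3, 40)
        raw = stats.spearmanr(x, y).statistic
        partial = ht.partial_correlation_by_subtype(x, y, subtype)
        assert partial == pytest.approx(raw, abs=0.1)

    def test_independent_is_null(self):
        rng = np.random.default_rng(2)
        subtype = np.repeat(["A", "B"], 25)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        assert abs(ht.partial_correlation_by_subtype(x, y, subtype)) < 0.3

    def test_single_subtype_warns(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="single subtype"):
            ht.partial_correlation_by_subtype(
                rng.normal(size=10), rng.normal(size=10), np.repeat("A", 10)
            )


class TestStrataComparison:
    def test_two_identical_strata_not_significant(self):
        rng = np.random.default_rng(0)
        coef = rng.normal(size=200)
        strata = np.repeat(["a", "b"], 100)
        res = ht.strata_correlation_compare(coef, strata)
        assert res["test"] == "wilcoxon_rank_sum"
        assert res["pvalue"] > 0.05

    def test_shifted_stratum_detected(self):
        rng = np.random.default_rng(1)
        coef = np.concatenate(
            [rng.normal(0, 0.3, 200), rng.normal(0.2, 0.3, 200)]
        )
        strata = np.repeat(["a", "b"], 200)
        assert ht.strata_correlation_compare(coef, strata)["pvalue"] < 0.001

    def test_three_strata_use_kruskal(self):
        rng = np.random.default_rng(2)
        coef = rng.normal(size=300)
        strata = np.repeat(["a", "b", "c"], 100)
        res = ht.strata_correlation_compare(coef, strata)
        assert res["test"] == "kruskal_wallis"

    def test_tiny_stratum_dropped_with_warning(self):
        coef = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        strata = np.array(["a", "a", "b", "b", "c"])
        with pytest.warns(UserWarning, match="'c'"):
            res = ht.strata_correlation_compare(coef, strata)
        assert res["strata"] == ["a", "b"]


class TestCompareCms:
    @staticmethod
    def table(scores_by_case):
        rows = []
        for (case, group), scores in scores_by_case.items():
            for k, s in enumerate(scores):
                rows.append({"case_id": case, "group": group,
                             "metaphase_index": k, "score": s})
        return ht.CmsTable(table=pd.DataFrame(rows))

    def test_all_twos_give_exact_means(self):
        t = self.table({
            ("c1", "heh"): [2] * 5, ("c2", "heh"): [2] * 5,
            ("c3", "etv"): [2] * 5, ("c4", "etv"): [2] * 5,
        })
        res = ht.compare_cms(t)
        assert res["group_means"] == {"heh": 2.0, "etv": 2.0}
        assert res["pvalue"] >= 0.5

    def test_pooled_and_per_case_agree_on_balanced_data(self):
        t = self.table({
            ("c1", "heh"): [1, 2], ("c2", "heh"): [2, 2],
            ("c3", "etv"): [2, 3], ("c4", "etv"): [3, 3],
        })
        per_case = ht.compare_cms(t, pooled=False)
        pooled = ht.compare_cms(t, pooled=True)
        assert per_case["group_means"]["heh"] == pooled["group_means"]["heh"]

    def test_single_case_group_rejected(self):
        t = self.table({("c1", "heh"): [2], ("c2", "etv"): [2],
                        ("c3", "etv"): [2]})
        with pytest.raises(ValueError, match="fewer than 2"):
            ht.compare_cms(t)
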