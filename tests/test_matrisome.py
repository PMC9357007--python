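import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fibrarch import matrisome as mt
from fibrarch.synthetic import AbundanceSimParams, simulate_abundance


def bh_stepup_oracle(pvals):
    """Direct Benjamini-Hochberg step-up: sort, cumulative-minimum of
    p * m / rank from the largest rank down."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@pytest.fixture
def small_dataset():
    m, d, truth = simulate_abundance(
        AbundanceSimParams(n_per_cluster=10, n_null=20, n_replicates=4,
                           effect_size=2.0, noise_sd=0.4, seed=21))
    return m, d, truth


class TestFilterPresence:
    def test_threshold_boundaries(self):
        # 29 samples: 20/29 = 69.0% removed, 21/29 = 72.4% retained
        cols = [f"s{i}" for i in range(29)]
        row_lo = [1.0] * 20 + [np.nan] * 9
        row_hi = [1.0] * 21 + [np.nan] * 8
        m = pd.DataFrame([row_lo, row_hi], index=["lo", "hi"], columns=cols)
        kept = mt.filter_presence(m, 0.70)
        assert list(kept.index) == ["hi"]

    def test_zero_threshold_is_identity(self, small_dataset):
        m, _, _ = small_dataset
        assert mt.filter_presence(m, 0.0).equals(m)

    def test_empty_result_flagged(self):
        m = pd.DataFrame({"a": [np.nan], "b": [np.nan]}, index=["p"])
        with pytest.raises(ValueError):
            mt.filter_presence(m, 0.7)


class TestTransform:
    def test_equal_column_centres_to_zero(self):
        m = pd.DataFrame({"s1": [4.0, 4.0, 4.0], "s2": [8.0, 2.0, 32.0]})
        out = mt.transform(m)
        np.testing.assert_allclose(out["s1"], 0.0)

    def test_z_profiles_have_unit_moments(self, small_dataset):
        m, d, _ = small_dataset
        z = mt.zscore_profiles(mt.condition_medians(mt.transform(m), d))
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_global_scaling_removed_by_median_centring(self, small_dataset):
        m, _, _ = small_dataset
        np.testing.assert_allclose(mt.transform(m).to_numpy(),
                                   mt.transform(m * 2.0).to_numpy(),
                                   atol=1e-12, equal_nan=True)

    def test_non_positive_values_rejected(self):
        with pytest.raises(ValueError):
            mt.transform(pd.DataFrame({"s": [0.0]}))


class TestAnova:
    def test_zero_variance_protein_flagged_untestable(self, small_dataset):
        m, d, _ = small_dataset
        logm = mt.transform(m)
        logm.iloc[0] = 3.14  # identical everywhere: degenerate
        res = mt.multi_sample_anova(logm, d)
        assert not res.table.iloc[0]["testable"]
        assert not res.table.iloc[0]["significant"]

    def test_constructed_shift_matches_direct_f_formula(self):
        # two groups of equal size reduce one-way ANOVA to F = t^2
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 8), rng.normal(3, 1, 8)
        F = stats.f_oneway(a, b).statistic
        t = stats.ttest_ind(a, b, equal_var=True).statistic
        assert F == pytest.approx(t ** 2, rel=1e-12)
        # and a 3-sigma shifted protein comes out far below the FDR cut
        m, d, _ = simulate_abundance(AbundanceSimParams(
            n_per_cluster=0, n_null=50, noise_sd=0.3, seed=3))
        logm = mt.transform(m)
        tumour_late = d.index[(d["tissue"] == "tumour") & (d["stage"] == "late")]
        logm.loc[logm.index[0], tumour_late] += 3.0
        res = mt.multi_sample_anova(logm, d)
        assert res.table.iloc[0]["q"] < 1e-4

    def test_bh_matches_stepup_oracle(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(5, 200))
            np.testing.assert_allclose(mt._bh_qvalues(p), bh_stepup_oracle(p),
                                       atol=1e-12)

    def test_row_permutation_invariance(self, small_dataset):
        m, d, _ = small_dataset
        logm = mt.transform(m)
        res1 = mt.multi_sample_anova(logm, d).table
        perm = logm.sample(frac=1.0, random_state=0)
        res2 = mt.multi_sample_anova(perm, d).table
        np.testing.assert_allclose(res1.loc[perm.index, "p"], res2["p"],
                                   equal_nan=True)


class TestVolcano:
    def test_equal_groups_give_zero_fold_change(self, small_dataset):
        m, d, _ = small_dataset
        logm = mt.transform(m)
        logm.iloc[1] = list(np.tile(np.arange(4.0), 6))  # same in every group
        res = mt.two_group_volcano(logm, d, stage="late")
        assert res.iloc[1]["log2fc"] == pytest.approx(0.0, abs=1e-12)

    def test_t_statistic_matches_welch_formula(self, small_dataset):
        m, d, _ = small_dataset
        logm = mt.transform(m)
        res = mt.two_group_volcano(logm, d, stage="mid")
        h = d.index[(d["tissue"] == "healthy") & (d["stage"] == "mid")]
        t = d.index[(d["tissue"] == "tumour") & (d["stage"] == "mid")]
        i = 5
        a, b = logm.loc[logm.index[i], t], logm.loc[logm.index[i], h]
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert res.iloc[i]["t"] == pytest.approx(
            (a.mean() - b.mean()) / se, rel=1e-12)

    def test_label_swap_negates_fold_change(self, small_dataset):
        m, d, _ = small_dataset
        logm = mt.transform(m)
        res = mt.two_group_volcano(logm, d, stage="early")
        d_swapped = d.copy()
        d_swapped["tissue"] = d["tissue"].map(
            {"healthy": "tumour", "tumour": "healthy"})
        res_sw = mt.two_group_volcano(logm, d_swapped, stage="early")
        np.testing.assert_allclose(res_sw["log2fc"], -res["log2fc"],
                                   equal_nan=True)
        np.testing.assert_allclose(res_sw["p"], res["p"], equal_nan=True)


class TestTemporalCluster:
    def test_planted_clusters_recovered(self):
        m, d, truth = simulate_abundance(AbundanceSimParams(
            n_per_cluster=40, n_null=0, effect_size=2.0, noise_sd=0.5, seed=1))
        z = mt.zscore_profiles(mt.condition_medians(mt.transform(m), d))
        res = mt.temporal_cluster(z, k=4)
        # canonical relabelling should map planted labels 1:1
        joint = pd.crosstab(truth[res.labels.index], res.labels)
        assert (joint.to_numpy() > 0).sum() == 4

    def test_single_cluster_trivially_valid(self, small_dataset):
        m, d, _ = small_dataset
        z = mt.zscore_profiles(mt.condition_medians(mt.transform(m), d))
        res = mt.temporal_cluster(z, k=1)
        assert set(res.labels) == {"C1"}

    def test_duplicated_rows_cluster_together(self, small_dataset):
        m, d, _ = small_dataset
        z = mt.zscore_profiles(mt.condition_medians(mt.transform(m), d))
        z.loc["dup"] = z.iloc[0]
        res = mt.temporal_cluster(z, k=4)
        assert res.labels["dup"] == res.labels[z.index[0]]

    def test_oversized_k_rejected(self, small_dataset):
        m, d, _ = small_dataset
        z = mt.zscore_profiles(mt.condition_medians(mt.transform(m), d))
        with pytest.raises(ValueError):
            mt.temporal_cluster(z.iloc[:3], k=4)


class TestEnrichment:
    def test_balanced_table_is_not_significant(self):
        labels = pd.Series(["C1"] * 10 + ["C2"] * 10,
                           index=[f"p{i}" for i in range(20)])
        cats = ["collagens"] * 5 + ["proteoglycans"] * 5
        annot = pd.DataFrame({"category": cats * 2}, index=labels.index)
        res = mt.category_enrichment(labels, annot)
        assert (res["p"] == 1.0).all()

    def test_extreme_table_matches_hypergeometric_tail(self):
        # 10 in-cluster/in-category vs 10 out/out: p from direct
        # hypergeometric enumeration of tables at least as extreme
        labels = pd.Series(["C1"] * 10 + ["C2"] * 10,
                           index=[f"p{i}" for i in range(20)])
        annot = pd.DataFrame({"category": ["collagens"] * 10
                              + ["proteoglycans"] * 10}, index=labels.index)
        res = mt.category_enrichment(labels, annot)
        row = res[(res.cluster == "C1") & (res.category == "collagens")].iloc[0]
        rv = stats.hypergeom(20, 10, 10)
        p_exact = sum(rv.pmf(k) for k in range(11)
                      if rv.pmf(k) <= rv.pmf(10) * (1 + 1e-9))
        assert row["p"] == pytest.approx(p_exact, rel=1e-9)

    def test_unannotated_protein_rejected(self):
        labels = pd.Series(["C1", "C2"], index=["a", "b"])
        annot = pd.DataFrame({"category": ["collagens"]}, index=["a"])
        with pytest.raises(ValueError):
            mt.category_enrichment(labels, annot)


class TestPCA:
    def test_collinear_data_loads_on_first_component(self):
        t = np.linspace(0, 1, 8)
        m = pd.DataFrame([2 ** (10 + 3 * t), 2 ** (12 + 1.5 * t)],
                         index=["a", "b"],
                         columns=[f"s{i}" for i in range(8)])
        res = mt.pca_summary(np.log2(m) - np.log2(m).median(axis=0))
        assert res.variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_rotation_leaves_spectrum_unchanged(self, rng):
        X = rng.normal(size=(30, 12))
        Q, _ = np.linalg.qr(rng.normal(size=(30, 30)))
        m1 = pd.DataFrame(X, columns=[f"s{i}" for i in range(12)])
        m2 = pd.DataFrame(Q @ X, columns=m1.columns)
        r1 = mt.pca_summary(m1, n_components=5)
        r2 = mt.pca_summary(m2, n_components=5)
        np.testing.assert_allclose(r1.variance_ratio, r2.variance_ratio,
                                   atol=1e-9)

    def test_planted_factors_recovered(self, rng):
        # two orthogonal loading patterns drive the samples
        n_prot, n_samp = 60, 24
        load_true = np.zeros((n_prot, 2))
        load_true[:30, 0] = 1.0 / np.sqrt(30)
        load_true[30:, 1] = 1.0 / np.sqrt(30)
        scores = rng.normal(scale=[5.0, 2.0], size=(n_samp, 2))
        X = scores @ load_true.T + rng.normal(scale=0.05, size=(n_samp, n_prot))
        m = pd.DataFrame(X.T, index=[f"p{i}" for i in range(n_prot)],
                         columns=[f"s{i}" for i in range(n_samp)])
        res = mt.pca_summary(m)
        for pc in ("PC1", "PC2"):
            corr = max(abs(np.corrcoef(res.loadings[pc], load_true[:, 0])[0, 1]),
                       abs(np.corrcoef(res.loadings[pc], load_true[:, 1])[0, 1]))
            assert corr >= 0.95

    def test_single_sample_rejected(self):
        m = pd.DataFrame({"s": [1.0, 2.0]})
        with pytest.raises(ValueError):
            mt.pca_summary(m)


class TestPipeline:
    def test_end_to_end_on_planted_data(self):
        m, d, truth = simulate_abundance(AbundanceSimParams(
            n_per_cluster=20, n_null=40, effect_size=2.0, noise_sd=0.4,
            missing_rate=0.05, seed=8))
        annot = pd.DataFrame(
            {"division": ["core matrisome"] * len(m),
             "category": ["collagens" if i % 2 else "proteoglycans"
                          for i in range(len(m))]}, index=m.index)
        out = mt.run_matrisome_pipeline(m, d, annot)
        assert out["n_filtered"] <= out["n_input"]
        assert out["anova"].n_significant > 0
        assert "clusters" in out and "enrichment" in out
        assert len(out["pca"].variance_ratio) == 2
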