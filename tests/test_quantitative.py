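import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.cluster import KMeans

from bcellmap.cluster import root_split
from bcellmap.core_io import IdMap, IntensityMatrix, ScreenParams
from bcellmap.quantitative import (
    DifferentialTable,
    chromosome_profiles,
    differential_screen,
    drop_all_absent,
    extremal_summary,
    group_mean_profiles,
    hierarchical_heatmap_order,
    pca_scores,
    propagate_zeros,
    som_clusters,
    zscore_profiles,
)
from conftest import make_design, random_intensity_matrix


def bh_stepup_oracle(pvals):
    """Independent BH: sort, apply step-up rule, enforce monotonicity."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * n / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def two_pass_f_oracle(groups):
    """Brute-force sum-of-squares one-way ANOVA for one protein."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((g - np.mean(g)) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    return (ssb / dfb) / (ssw / dfw), dfb, dfw


class TestZeroHandling:
    def test_any_zero_replicate_zeroes_population(self):
        design = make_design(("A",), {"A": 5})
        m = IntensityMatrix(["P1"], design, np.array([[1.0, 2, 0, 4, 5]]))
        assert propagate_zeros(m).values.tolist() == [[0.0] * 5]

    def test_complete_population_unchanged(self):
        design = make_design(("A", "B"), 2)
        m = IntensityMatrix(["P1"], design, np.array([[1.0, 2, 0, 4]]))
        out = propagate_zeros(m)
        assert out.values.tolist() == [[1.0, 2.0, 0.0, 0.0]]

    def test_idempotent_on_random_matrices(self, rng):
        for _ in range(20):
            m = random_intensity_matrix(rng)
            once = propagate_zeros(m)
            twice = propagate_zeros(once)
            assert np.array_equal(once.values, twice.values)

    def test_drop_all_absent_matches_brute_force(self, rng):
        m = propagate_zeros(random_intensity_matrix(rng, zero_fraction=0.6))
        kept = drop_all_absent(m)
        expected = [pid for pid, row in zip(m.protein_ids, m.values) if (row > 0).any()]
        assert kept.protein_ids == expected


class TestDifferentialScreen:
    def test_worked_f_statistic_example(self):
        """Closed form: groups {1,2,3},{2,3,4},{3,4,5} give F=3, p=sf(F(2,6) at 3)."""
        design = make_design(("a", "b", "c"), 3)
        values = np.array([[1.0, 2, 3, 2, 3, 4, 3, 4, 5]])
        m = IntensityMatrix(["P1"], design, values)
        t = differential_screen(m, ScreenParams(), log_transform=False)
        f_oracle, dfb, dfw = two_pass_f_oracle([values[0, :3], values[0, 3:6], values[0, 6:]])
        assert f_oracle == pytest.approx(3.0)
        assert t.anova_p[0] == pytest.approx(stats.f.sf(3.0, 2, 6), abs=1e-12)
        assert t.anova_p[0] == pytest.approx(0.125, abs=0.0005)

    def test_constant_protein_flagged_untestable(self):
        design = make_design(("a", "b"), 3)
        m = IntensityMatrix(["P1"], design, np.full((1, 6), 4.0))
        t = differential_screen(m, ScreenParams())
        assert t.untestable[0]
        assert t.anova_p[0] == 1.0
        assert not t.significant[0]

    def test_f_matches_two_pass_oracle_on_random_data(self, rng):
        m = random_intensity_matrix(rng, n_proteins=40, zero_fraction=0.0)
        params = ScreenParams()
        t = differential_screen(m, params)
        y = np.log2(m.values + params.pseudo_offset)
        for i in range(m.n_proteins):
            groups = [y[i, m.design.columns_for(p)] for p in m.design.populations]
            f, dfb, dfw = two_pass_f_oracle(groups)
            assert stats.f.sf(f, dfb, dfw) == pytest.approx(t.anova_p[i], abs=1e-10)

    def test_bh_matches_stepup_oracle(self, rng):
        m = random_intensity_matrix(rng, n_proteins=80, zero_fraction=0.0)
        t = differential_screen(m, ScreenParams())
        np.testing.assert_allclose(t.bh_q, bh_stepup_oracle(t.anova_p), atol=1e-12)

    def test_max_fold_change_larger_over_smaller(self):
        design = make_design(("a", "b"), 2)
        m = IntensityMatrix(["P1", "P2"], design, np.array([[10.0, 10, 5, 5], [2.0, 2, 8, 8]]))
        t = differential_screen(m, ScreenParams())
        assert t.max_fold_change.tolist() == [2.0, 4.0]
        assert not t.mfc_undefined.any()

    def test_zero_mean_comparison_reported_infinite(self):
        design = make_design(("a", "b"), 2)
        m = IntensityMatrix(["P1"], design, np.array([[10.0, 10, 0, 0]]))
        t = differential_screen(m, ScreenParams())
        assert np.isinf(t.max_fold_change[0])
        assert t.mfc_undefined[0]

    def test_pairwise_welch_matches_scipy(self, rng):
        m = random_intensity_matrix(rng, n_proteins=10, zero_fraction=0.0)
        params = ScreenParams()
        t = differential_screen(m, params)
        y = np.log2(m.values + 1.0)
        a, b = m.design.populations[0], m.design.populations[2]
        expected = stats.ttest_ind(
            y[:, m.design.columns_for(a)], y[:, m.design.columns_for(b)], axis=1, equal_var=False
        ).pvalue
        np.testing.assert_allclose(t.pairwise_p[(a, b)], expected, atol=1e-12)


class TestZScoreAndExtremal:
    def _table(self, means, pops=None):
        means = np.asarray(means, dtype=float)
        pops = tuple(pops or [f"p{i}" for i in range(means.shape[1])])
        n = means.shape[0]
        return DifferentialTable(
            protein_ids=[f"P{i}" for i in range(n)],
            populations=pops,
            means=means,
            anova_p=np.ones(n),
            bh_q=np.ones(n),
            max_fold_change=np.ones(n),
            mfc_undefined=np.zeros(n, bool),
            pairwise_p={},
            significant=np.zeros(n, bool),
            untestable=np.zeros(n, bool),
        )

    def test_z_of_arithmetic_sequence(self):
        t = zscore_profiles(self._table([[1, 2, 3]]))
        np.testing.assert_allclose(t.z_profile, [[-1.0, 0.0, 1.0]])

    def test_constant_profile_gets_zero_z(self):
        t = zscore_profiles(self._table([[4, 4, 4, 4]]))
        np.testing.assert_array_equal(t.z_profile, [[0.0] * 4])

    def test_z_rows_have_zero_mean_unit_sd(self, rng):
        means = rng.normal(size=(30, 4)) * 5 + 10
        t = zscore_profiles(self._table(means))
        np.testing.assert_allclose(t.z_profile.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(t.z_profile.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_argmax_argmin_assignment(self):
        t = zscore_profiles(self._table([[0, 5, 3, 1]], pops=("N", "CB", "CC", "M")))
        assert t.argmax_population == ["CB"]
        assert t.argmin_population == ["N"]
        assert not t.argmax_tie[0]

    def test_tie_broken_by_population_order_and_flagged(self):
        t = zscore_profiles(self._table([[5, 5, 0, 0]], pops=("N", "CB", "CC", "M")))
        assert t.argmax_population == ["N"]
        assert t.argmax_tie[0]

    def test_extremal_counts_partition_proteins(self, rng):
        means = rng.normal(size=(50, 4))
        s = extremal_summary(zscore_profiles(self._table(means)))
        assert sum(s.argmax_counts.values()) == 50
        assert sum(s.argmin_counts.values()) == 50


class TestGroupedProfiles:
    def test_group_mean_matches_nested_brute_force(self, rng):
        m = random_intensity_matrix(rng, n_proteins=20, zero_fraction=0.0)
        grouping = {pid: f"g{i % 3}" for i, pid in enumerate(m.protein_ids)}
        out = group_mean_profiles(m, grouping)
        for g in set(grouping.values()):
            members = [i for i, pid in enumerate(m.protein_ids) if grouping[pid] == g]
            for pop in m.design.populations:
                expected = np.mean(
                    [m.population_values(pop)[i].mean() for i in members]
                )
                assert out.at[g, pop] == pytest.approx(expected)
            assert out.at[g, "group_size"] == len(members)

    def test_singleton_group_is_its_own_profile(self, rng):
        m = random_intensity_matrix(rng, n_proteins=5, zero_fraction=0.0)
        out = group_mean_profiles(m, {m.protein_ids[0]: "solo"})
        for pop in m.design.populations:
            assert out.at["solo", pop] == pytest.approx(m.population_values(pop)[0].mean())

    def test_unmatched_group_dropped_with_warning(self, rng):
        m = random_intensity_matrix(rng, n_proteins=5)
        with pytest.warns(UserWarning, match="no matched proteins"):
            out = group_mean_profiles(m, {"not_a_protein": "ghost", m.protein_ids[0]: "ok"})
        assert list(out.index) == ["ok"]


class TestChromosomeProfiles:
    def _idmap(self, mapping):
        rows = [{"protein_id": p, "gene_id": f"g_{p}_{c}", "chromosome": c, "pe_class": ""}
                for p, chroms in mapping.items() for c in chroms]
        return IdMap(records=pd.DataFrame(rows))

    def test_mean_z_per_chromosome(self, rng):
        m = random_intensity_matrix(rng, n_proteins=2, zero_fraction=0.0)
        t = differential_screen(m, ScreenParams())
        idmap = self._idmap({"P0": ["chr1"], "P1": ["chr1"]})
        prof = chromosome_profiles(t, idmap)
        np.testing.assert_allclose(
            prof.frame.loc["chr1", list(t.populations)].to_numpy(dtype=float),
            t.z_profile.mean(axis=0),
        )
        assert prof.frame.at["chr1", "protein_count"] == 2

    def test_accounting_with_unmapped_and_multimapped(self, rng):
        m = random_intensity_matrix(rng, n_proteins=4, zero_fraction=0.0)
        t = differential_screen(m, ScreenParams())
        idmap = self._idmap({"P0": ["chr1"], "P1": ["chr1", "chr2"], "P2": ["chr3"]})
        prof = chromosome_profiles(t, idmap)
        assert prof.unmapped == 1
        assert prof.multi_mapped == ["P1"]
        assert prof.frame["protein_count"].sum() + prof.unmapped == t.n_proteins + 1


class TestHeatmapOrderAndPCA:
    def test_duplicate_rows_merge_at_zero(self):
        z = pd.DataFrame([[1.0, 2], [1.0, 2], [5.0, 6]], index=["a", "b", "c"])
        d = hierarchical_heatmap_order(z, axis="rows")
        assert d.merge_heights[0] == 0.0
        assert sorted(d.leaf_order) == ["a", "b", "c"]

    def test_collinear_points_merge_nearest_first(self):
        z = pd.DataFrame([[0.0], [1.0], [10.0]], index=["x", "y", "far"])
        d = hierarchical_heatmap_order(z, axis="rows")
        left, right = root_split(d)
        assert {left, right} == {frozenset({"x", "y"}), frozenset({"far"})}

    def test_samples_on_a_line_give_one_component(self):
        x = pd.DataFrame(np.outer([0, 1, 2, 3], [1.0, 2.0, 3.0]), index=list("abcd"))
        res = pca_scores(x)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_explained_fractions_sum_to_one(self, rng):
        x = pd.DataFrame(rng.normal(size=(6, 20)))
        res = pca_scores(x)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_reconstruction_identity(self, rng):
        x = pd.DataFrame(rng.normal(size=(5, 8)))
        res = pca_scores(x)
        centered = x.to_numpy() - x.to_numpy().mean(axis=0)
        np.testing.assert_allclose(res.scores.to_numpy() @ res.loadings, centered, atol=1e-8)


class TestSOM:
    def _blobs(self, rng, n=30):
        a = rng.normal(loc=(-5, -5, -5), scale=0.3, size=(n, 3))
        b = rng.normal(loc=(5, 5, 5), scale=0.3, size=(n, 3))
        return np.vstack([a, b])

    def test_two_blobs_match_kmeans_partition(self):
        agreements = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = self._blobs(rng)
            z = pd.DataFrame(x, index=[f"P{i}" for i in range(len(x))])
            params = ScreenParams(som_rows=2, som_cols=1, som_epochs=100, seed=seed)
            som_labels = som_clusters(z, params).labels
            km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit_predict(x)
            same = (som_labels == km).mean()
            agreements.append(max(same, 1 - same))  # label permutation
        assert np.mean(agreements) >= 0.95

    def test_fixed_seed_reproducible(self, rng):
        x = pd.DataFrame(rng.normal(size=(40, 4)), index=[f"P{i}" for i in range(40)])
        params = ScreenParams(som_rows=5, som_cols=1, som_epochs=50, seed=3)
        a = som_clusters(x, params)
        b = som_clusters(x, params)
        assert np.array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.prototypes, b.prototypes)

    def test_grid_larger_than_data_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(3, 4)), index=list("abc"))
        with pytest.raises(ValueError, match="grid"):
            som_clusters(x, ScreenParams(som_rows=5, som_cols=1))

    def test_single_point_gets_finite_prototypes(self):
        from bcellmap.som import SelfOrganizingMap

        som = SelfOrganizingMap(rows=1, cols=1, epochs=5, random_state=0)
        som.fit(np.array([[1.0, 2.0]]))
        assert np.isfinite(som.prototypes_).all()
        assert som.labels_.tolist() == [0]
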