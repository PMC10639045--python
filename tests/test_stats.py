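"""Statistical layer: loads, MWU/q-values, age trends, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from adductomics.simulate import SimulationConfig, simulate_cohort
from adductomics.stats import (
    adduct_load,
    age_correlation,
    age_tests,
    cluster_profiles,
    estimate_pi0,
    largest_remainder_percents,
    q_values,
    sex_tests,
)
from conftest import make_meta


class TestAdductLoadPercentages:
    @pytest.mark.parametrize("loads,expected", [
        # rat cohort 1: brain, heart, kidney, liver
        ((3517, 1458, 3574, 3790), (28, 12, 29, 31)),
        # rat cohort 2
        ((9483, 7085, 10552, 13080), (24, 18, 26, 32)),
        # human brain / heart
        ((6142, 3584), (63, 37)),
    ])
    def test_published_tissue_percentages(self, loads, expected):
        assert tuple(largest_remainder_percents(loads)) == expected

    def test_single_tissue_is_100(self):
        assert largest_remainder_percents([123.4]) == [100]

    def test_percentages_always_sum_to_100(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vals = rng.uniform(0.1, 100, size=rng.integers(2, 8))
            assert sum(largest_remainder_percents(vals)) == 100

    def test_load_excludes_the_epigenetic_mark(self):
        meta = make_meta({"liver": ["L1", "L2"], "heart": ["H1", "H2"]})
        matrix = pd.DataFrame(
            {"L1": [1e5, 10, 20], "L2": [1e5, 12, 22],
             "H1": [1e5, 5, 8], "H2": [1e5, 7, 10]},
            index=["5-MdC", "a1", "a2"],
        )
        out = adduct_load(matrix, meta)
        assert out.loc["liver", "load"] == pytest.approx(11 + 21)
        assert out.loc["heart", "load"] == pytest.approx(6 + 9)
        assert out.loc["liver", "n_species"] == 2
        assert out.percent.sum() == 100


class TestSexTests:
    def _matrix_meta(self, f_vals, m_vals):
        meta = make_meta({"liver": ["F1", "F2", "F3", "F4", "M1", "M2", "M3", "M4"]})
        meta.loc[meta.sample_id.str.startswith("M"), "sex"] = "M"
        matrix = pd.DataFrame(
            [list(f_vals) + list(m_vals)],
            index=["sp1"], columns=["F1", "F2", "F3", "F4", "M1", "M2", "M3", "M4"],
        )
        return matrix, meta

    def test_exact_mwu_p_for_separated_groups(self):
        """F={1,2,3,4} vs M={10,11,12,13}: exact two-sided p = 2/C(8,4)
        restricted to the extreme orderings = 0.0286."""
        matrix, meta = self._matrix_meta([1, 2, 3, 4], [10, 11, 12, 13])
        res = sex_tests(matrix, meta, "liver")
        assert res.table.p_value.iloc[0] == pytest.approx(0.0286, abs=0.0001)

    def test_identical_distributions_give_p_one(self):
        matrix, meta = self._matrix_meta([5, 5, 5, 5], [5, 5, 5, 5])
        res = sex_tests(matrix, meta, "liver")
        assert res.table.p_value.iloc[0] == 1.0

    def test_insufficient_samples_rejected(self):
        meta = make_meta({"liver": ["F1", "M1"]})
        meta.loc[meta.sample_id == "M1", "sex"] = "M"
        matrix = pd.DataFrame([[1.0, 2.0]], index=["sp1"], columns=["F1", "M1"])
        with pytest.raises(ValueError):
            sex_tests(matrix, meta, "liver")


class TestQValues:
    def test_singleton_with_forced_pi0(self):
        assert q_values([0.001], pi0=1.0)[0] == pytest.approx(0.001)

    def test_monotone_in_ranked_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        q = q_values(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_pi0_near_one_for_uniform_p(self):
        """Storey oracle: uniform p-values have pi0 = 1; the smoother
        estimate should land near it."""
        rng = np.random.default_rng(42)
        p = rng.uniform(size=1000)
        assert 0.8 <= estimate_pi0(p) <= 1.0

    def test_qvalues_bounded_by_bh_when_pi0_is_one(self):
        """With pi0 = 1 Storey q-values equal Benjamini-Hochberg adjusted
        p-values (independent statsmodels oracle)."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = np.concatenate([rng.uniform(0, 0.01, 20), rng.uniform(size=180)])
        q = q_values(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, rtol=1e-10)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            q_values([0.5, 1.5])


class TestAgeTests:
    def _cohort_matrix(self, seed, fold=1.0):
        cfg = SimulationConfig(
            tissues=("liver",), ages=(1.0, 26.0), n_per_cell=4, n_unnamed=0,
            age_folds={"5-HMdC": {"liver": fold}}, sex_ratios={},
        )
        cohort = simulate_cohort(cfg, seed=seed)
        hydro = cohort.hydrolysate_ids()
        named = [k for k in cohort.abundance.index if ":" not in k]
        return cohort.abundance.loc[named, hydro], cohort.meta

    def test_null_age_effect_gives_large_p_on_average(self):
        ps = []
        for seed in range(20):
            matrix, meta = self._cohort_matrix(seed, fold=1.0)
            out = age_tests(matrix, meta, "liver")
            ps.append(out.loc["N2-CMdG", "p_value"])  # no liver fold planted here
        assert np.mean(ps) > 0.3

    def test_planted_fold_change_estimated(self):
        matrix, meta = self._cohort_matrix(0, fold=2.8)
        out = age_tests(matrix, meta, "liver")
        assert out.loc["5-HMdC", "fold_change"] == pytest.approx(2.8, rel=0.35)
        assert out.loc["5-HMdC", "p_value"] < 0.01

    def test_constant_species_reports_nan(self):
        meta = make_meta({"liver": ["a", "b", "c", "d"]})
        meta.loc[meta.sample_type == "hydrolysate", "age"] = [1.0, 1.0, 26.0, 26.0]
        matrix = pd.DataFrame([[3.0, 3.0, 3.0, 3.0]], index=["sp"],
                              columns=["a", "b", "c", "d"])
        out = age_tests(matrix, meta, "liver")
        assert np.isnan(out.loc["sp", "p_value"])

    def test_bonferroni_pairwise_adjustment(self):
        matrix, meta = self._cohort_matrix(0, fold=2.8)
        out = age_tests(matrix, meta, "liver")
        pw = out.loc["5-HMdC", "pairwise_p"]
        raw = ss.ttest_ind(
            matrix.loc["5-HMdC", meta.loc[meta.age == 1.0, "sample_id"]],
            matrix.loc["5-HMdC", meta.loc[meta.age == 26.0, "sample_id"]],
        ).pvalue
        assert pw[(1.0, 26.0)] == pytest.approx(min(1.0, raw * 1))


class TestAgeCorrelation:
    def test_perfect_linear_increase(self):
        r, p = age_correlation([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r == pytest.approx(1.0)

    def test_sign_antisymmetry(self):
        vals = [3.0, 1.0, 4.0, 1.5, 5.0]
        ages = [22, 40, 55, 63, 81]
        r1, _ = age_correlation(vals, ages)
        r2, _ = age_correlation([-v for v in vals], ages)
        assert r2 == pytest.approx(-r1)

    def test_null_values_uncorrelated_on_average(self):
        rng = np.random.default_rng(3)
        ages = np.linspace(22, 81, 19)
        rs = [abs(age_correlation(rng.lognormal(0, 0.3, 19), ages)[0])
              for _ in range(100)]
        assert np.mean(rs) < 0.25

    def test_zero_variance_gives_nan(self):
        r, p = age_correlation([2.0, 2.0, 2.0], [10, 20, 30])
        assert np.isnan(r) and np.isnan(p)


def make_clusters(n_clusters, n_per_cluster, n_features, seed, sep=6.0):
    """Well-separated Gaussian clusters in log-intensity space."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, sep, size=(n_clusters, n_features))
    cols, data = [], []
    for c in range(n_clusters):
        for i in range(n_per_cluster):
            cols.append(f"c{c}_s{i}")
            data.append(10 ** (centers[c] + rng.normal(0, 0.3, n_features)))
    return pd.DataFrame(np.array(data).T, columns=cols), np.repeat(
        np.arange(n_clusters), n_per_cluster
    )


class TestClusterProfiles:
    def test_planted_five_clusters_recovered(self):
        matrix, truth = make_clusters(5, 8, 10, seed=0)
        res = cluster_profiles(matrix, seed=0)
        assert res.n_clusters == 5
        # labels agree with truth up to permutation
        from scipy.stats import mode

        for c in range(5):
            labels_c = res.labels[truth == c]
            assert (labels_c == mode(labels_c).mode).all()

    def test_single_tight_cluster_selects_one(self):
        matrix, _ = make_clusters(1, 30, 8, seed=1)
        res = cluster_profiles(matrix, seed=1)
        assert res.n_clusters == 1

    def test_cumulative_variance_monotone_and_bounded(self):
        matrix, _ = make_clusters(3, 10, 6, seed=2)
        res = cluster_profiles(matrix, seed=2)
        assert np.all(np.diff(res.cumulative_variance) >= -1e-12)
        assert res.cumulative_variance[-1] <= 1.0 + 1e-9

    def test_full_component_reconstruction_is_exact(self):
        """PCA with all components reconstructs the data exactly."""
        from sklearn.decomposition import PCA

        matrix, _ = make_clusters(2, 10, 5, seed=3)
        X = np.log10(matrix.to_numpy().T)
        X = (X - X.mean(0)) / X.std(0)
        pca = PCA(n_components=min(X.shape))
        Z = pca.fit_transform(X)
        np.testing.assert_allclose(pca.inverse_transform(Z), X, atol=1e-8)

    def test_duplicated_dataset_gives_identical_labels(self):
        matrix, _ = make_clusters(3, 8, 6, seed=4)
        r1 = cluster_profiles(matrix, seed=4)
        r2 = cluster_profiles(matrix.copy(), seed=4)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_selected_model_maximizes_bic(self):
        matrix, _ = make_clusters(3, 8, 6, seed=5)
        res = cluster_profiles(matrix, seed=5)
        best_row = res.bic_table.loc[res.bic_table.bic.idxmax()]
        assert best_row.n_clusters == res.n_clusters
        assert best_row.covariance_type == res.covariance_type

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles(pd.DataFrame({"s1": [1.0, 2.0]}))
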