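import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from stromabalance import (
    Cohort,
    DatasetSplit,
    GeneratorParams,
    SampleRecord,
    ValidationError,
    average_pvalues,
    benjamini_hochberg,
    differential_genes,
    differential_metabolites,
    generate_cohort,
    quantile_normalize,
    split_balanced_unbalanced,
)
from stromabalance.differential import fit_variance_prior
from stromabalance.tissue_balance import draw_unstratified


def bh_stepup_oracle(p):
    """Independent brute-force BH: sort, scale by m/i, enforce monotonicity."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for i in range(m - 1, -1, -1):
        running_min = min(running_min, p[order[i]] * m / (i + 1))
        adj[order[i]] = running_min
    return np.minimum(adj, 1.0)


def two_arm_cohort(values_cancer, values_normal, n_features=1):
    """Cohort where every feature carries the same two arms of values."""
    vc = np.atleast_2d(np.asarray(values_cancer, dtype=float))
    vn = np.atleast_2d(np.asarray(values_normal, dtype=float))
    if vc.shape[0] == 1 and n_features > 1:
        vc = np.repeat(vc, n_features, axis=0)
        vn = np.repeat(vn, n_features, axis=0)
    recs = [
        SampleRecord(f"C{i}", "cancer", 0.5, 0.3, 0.2) for i in range(vc.shape[1])
    ] + [SampleRecord(f"N{i}", "normal", 0.0, 0.5, 0.5) for i in range(vn.shape[1])]
    matrix = np.hstack([vc, vn])
    ids = [f"g{i}" for i in range(vc.shape[0])]
    cohort = Cohort(
        samples=recs,
        gene_matrix=matrix,
        gene_ids=ids,
        metabolite_matrix=matrix.copy(),
        metabolite_ids=[f"m{i}" for i in range(vc.shape[0])],
    )
    split = DatasetSplit(
        name="all",
        cancer_ids=tuple(r.sample_id for r in recs if r.group == "cancer"),
        normal_ids=tuple(r.sample_id for r in recs if r.group == "normal"),
    )
    return cohort, split


class TestQuantileNormalize:
    def test_hand_computed_two_columns(self):
        # reference distribution is ((1+2)/2, (3+4)/2) = (1.5, 3.5)
        out = quantile_normalize(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(out, [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_are_fixed_point(self):
        x = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 4))
        np.testing.assert_allclose(quantile_normalize(x), x, atol=1e-12)

    def test_columns_share_sorted_values(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 7))
        out = quantile_normalize(x)
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_rank_order_preserved_per_column(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 5))
        out = quantile_normalize(x)
        for j in range(5):
            assert np.array_equal(np.argsort(x[:, j]), np.argsort(out[:, j]))

    def test_ties_get_mean_of_reference_ranks(self):
        # col0 has a two-way tie spanning reference ranks 1 and 2
        x = np.array([[1.0, 10.0], [2.0, 20.0], [2.0, 30.0], [4.0, 40.0]])
        out = quantile_normalize(x)
        ref = np.sort(x, axis=0).mean(axis=1)
        assert out[1, 0] == pytest.approx((ref[1] + ref[2]) / 2)
        assert out[2, 0] == pytest.approx((ref[1] + ref[2]) / 2)

    @given(
        arrays(
            float,
            st.tuples(st.integers(2, 25), st.integers(1, 6)),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_definitional_properties_hold(self, x):
        out = quantile_normalize(x)
        ref = np.sort(x, axis=0).mean(axis=1)
        for j in range(out.shape[1]):
            # tie-free columns carry the reference distribution exactly;
            # tied entries are averaged and only preserve weak monotonicity
            if len(np.unique(x[:, j])) == x.shape[0]:
                np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-9)
            order = np.argsort(x[:, j], kind="mergesort")
            assert np.all(np.diff(out[order, j]) >= -1e-9)
            # column mean is invariant under tie averaging
            assert out[:, j].mean() == pytest.approx(ref.mean(), abs=1e-9)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.empty((0, 0)))


class TestBenjaminiHochberg:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 80))
            np.testing.assert_allclose(
                benjamini_hochberg(p), bh_stepup_oracle(p), atol=1e-12
            )

    @given(
        arrays(
            float,
            st.integers(1, 40),
            elements=st.floats(1e-12, 1.0, allow_nan=False),
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_property(self, p):
        np.testing.assert_allclose(benjamini_hochberg(p), bh_stepup_oracle(p), atol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        adj = benjamini_hochberg(p)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestDifferentialGenes:
    def test_pooled_t_closed_form(self):
        cohort, split = two_arm_cohort([1, 2, 3], [4, 5, 6])
        (res,) = differential_genes(split, cohort, moderation=False)
        # closed-form oracle: sp2 = 1, se = sqrt(2/3)
        t_expected = -3.0 / np.sqrt(2.0 / 3.0)
        p_expected = 2 * stats.t.sf(abs(t_expected), 4)
        assert res.statistic == pytest.approx(t_expected, abs=1e-12)
        assert res.p_raw == pytest.approx(p_expected, abs=1e-12)
        assert res.p_raw == pytest.approx(0.0213, abs=5e-4)
        assert res.direction == "down_in_cancer"
        assert res.mean_diff == pytest.approx(-3.0)

    def test_moderation_prior_df_zero_equals_ordinary(self, synth):
        cohort, _ = synth
        balanced, _ = split_balanced_unbalanced(cohort.samples)
        plain = differential_genes(balanced, cohort, moderation=False)
        forced = differential_genes(balanced, cohort, moderation=True, prior_df=0)
        for a, b in zip(plain, forced):
            assert abs(a.statistic - b.statistic) < 1e-6
            assert a.p_raw == pytest.approx(b.p_raw, abs=1e-9)

    def test_moderation_shrinks_extreme_variances(self, synth):
        cohort, _ = synth
        balanced, _ = split_balanced_unbalanced(cohort.samples)
        plain = {r.feature_id: r for r in differential_genes(balanced, cohort, moderation=False)}
        mod = {r.feature_id: r for r in differential_genes(balanced, cohort, moderation=True)}
        # shrinkage changes statistics but keeps signs
        signs_match = [
            np.sign(plain[f].statistic) == np.sign(mod[f].statistic)
            for f in plain
            if abs(plain[f].statistic) > 0.5
        ]
        assert np.mean(signs_match) == 1.0

    def test_zero_variance_gives_p_one_with_warning(self, caplog):
        cohort, split = two_arm_cohort([[5, 5, 5]], [[5, 5, 5]])
        with caplog.at_level(logging.WARNING, logger="stromabalance.differential"):
            (res,) = differential_genes(split, cohort, moderation=False)
        assert res.p_raw == 1.0 and not np.isnan(res.statistic)
        assert "zero variance" in caplog.text

    def test_ranks_are_permutation(self, synth):
        cohort, _ = synth
        balanced, _ = split_balanced_unbalanced(cohort.samples)
        res = differential_genes(balanced, cohort)
        assert sorted(r.rank for r in res) == list(range(1, len(res) + 1))
        assert all(r.p_adj >= r.p_raw - 1e-15 for r in res)
        assert all(
            (r.direction == "up_in_cancer") == (r.mean_diff > 0) for r in res
        )

    def test_too_small_arm_rejected(self):
        cohort, split = two_arm_cohort([[1, 2]], [[3]])
        with pytest.raises(ValidationError, match=">=2"):
            differential_genes(split, cohort)

    def test_planted_robust_markers_rank_in_top_decile(self):
        # high-purity cancer samples, effect 1.0 log2, noise 0.5, n=40/20
        params = GeneratorParams(
            n_cancer=40,
            n_normal=20,
            n_genes=2000,
            seed=3,
            alpha_cancer=(30.0, 3.0, 3.0),
            gene_class_fractions={
                "cancer_vs_epithelium": 0.0,
                "stroma_vs_epithelium": 0.0,
                "robust_cancer": 0.05,
                "null": 0.95,
            },
        )
        cohort, truth = generate_cohort(params)
        balanced, _ = split_balanced_unbalanced(cohort.samples)
        res = differential_genes(balanced, cohort)
        ranks = {r.feature_id: r.rank for r in res}
        robust = truth.gene_truth.index[
            truth.gene_truth.marker_class == "robust_cancer"
        ]
        in_top_decile = np.mean([ranks[f] <= len(res) // 10 for f in robust])
        assert in_top_decile >= 0.95


class TestVariancePrior:
    def test_recovers_prior_from_simulated_variances(self):
        rng = np.random.default_rng(8)
        d0_true, s0_true, df = 8.0, 0.25, 10
        # s2 ~ s0^2 * F(df, d0)
        s2 = s0_true * stats.f.rvs(df, d0_true, size=20000, random_state=rng)
        d0, s0 = fit_variance_prior(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0 == pytest.approx(s0_true, rel=0.1)

    def test_homogeneous_variances_give_infinite_prior(self):
        d0, s0 = fit_variance_prior(np.full(100, 2.0), df=10)
        assert np.isinf(d0)
        assert s0 == pytest.approx(2.0, rel=0.3)


class TestDifferentialMetabolites:
    def test_identical_arms(self):
        cohort, split = two_arm_cohort([[1, 2, 3]], [[1, 2, 3]])
        (res,) = differential_metabolites(split, cohort)
        assert res.p_raw == pytest.approx(1.0)
        assert res.mean_diff == 0.0

    def test_against_textbook_formulas(self):
        x = np.array([10.0, 11, 12, 13])
        y = np.array([20.0, 22, 24, 26])
        cohort, split = two_arm_cohort([x], [y])
        # F pretest oracle
        f = x.var(ddof=1) / y.var(ddof=1)
        cdf = stats.f.cdf(f, 3, 3)
        p_var = 2 * min(cdf, 1 - cdf)
        assert p_var == pytest.approx(0.2847569798652943)
        # as_published: pretest p >= 0.05 -> Welch
        sp_w = np.sqrt(x.var(ddof=1) / 4 + y.var(ddof=1) / 4)
        t_w = (x.mean() - y.mean()) / sp_w
        df_w = sp_w**4 / (
            (x.var(ddof=1) / 4) ** 2 / 3 + (y.var(ddof=1) / 4) ** 2 / 3
        )
        p_w = 2 * stats.t.sf(abs(t_w), df_w)
        (res,) = differential_metabolites(split, cohort, variance_rule="as_published")
        assert res.statistic == pytest.approx(t_w, abs=1e-12)
        assert res.p_raw == pytest.approx(p_w, abs=1e-12)
        # conventional: pretest p >= 0.05 -> pooled
        sp2 = (3 * x.var(ddof=1) + 3 * y.var(ddof=1)) / 6
        t_p = (x.mean() - y.mean()) / np.sqrt(sp2 * 0.5)
        p_p = 2 * stats.t.sf(abs(t_p), 6)
        (res2,) = differential_metabolites(split, cohort, variance_rule="conventional")
        assert res2.statistic == pytest.approx(t_p, abs=1e-12)
        assert res2.p_raw == pytest.approx(p_p, abs=1e-12)

    def test_rules_swap_test_choice_when_pretest_significant(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 0.1, size=20)
        y = rng.normal(1, 5.0, size=20)
        cohort, split = two_arm_cohort([x], [y])
        (pub,) = differential_metabolites(split, cohort, variance_rule="as_published")
        (conv,) = differential_metabolites(split, cohort, variance_rule="conventional")
        pooled = stats.ttest_ind(x, y, equal_var=True)
        welch = stats.ttest_ind(x, y, equal_var=False)
        assert pub.p_raw == pytest.approx(pooled.pvalue, abs=1e-12)
        assert conv.p_raw == pytest.approx(welch.pvalue, abs=1e-12)

    def test_missing_metabolite_matrix(self, synth):
        cohort, _ = synth
        stripped = Cohort(
            samples=cohort.samples,
            gene_matrix=cohort.gene_matrix,
            gene_ids=cohort.gene_ids,
        )
        balanced, _ = split_balanced_unbalanced(cohort.samples)
        with pytest.raises(ValidationError, match="metabolite"):
            differential_metabolites(balanced, stripped)


class TestAveragePvalues:
    def test_single_replicate_identity(self, synth):
        cohort, _ = synth
        balanced, _ = split_balanced_unbalanced(cohort.samples)
        res = differential_genes(balanced, cohort)
        avg = average_pvalues([res])
        assert avg == res

    def test_two_replicate_arithmetic(self):
        cohort, split = two_arm_cohort([[1, 2, 3]], [[4, 5, 6]])
        r1 = differential_genes(split, cohort, moderation=False)
        cohort2, split2 = two_arm_cohort([[1, 2, 3]], [[3.3, 4, 5]])
        r2 = differential_genes(split2, cohort2, moderation=False)
        avg = average_pvalues([r1, r2])
        assert avg[0].p_raw == pytest.approx((r1[0].p_raw + r2[0].p_raw) / 2)

    def test_inconsistent_features_rejected(self, synth):
        cohort, _ = synth
        balanced, _ = split_balanced_unbalanced(cohort.samples)
        res = differential_genes(balanced, cohort)
        with pytest.raises(ValidationError, match="feature set"):
            average_pvalues([res, res[:-1]])

    def test_averaged_p_stable_across_resampling_seeds(self):
        # 47/17 draws from a 60/22 cohort: the resampling null is stable
        params = GeneratorParams(n_cancer=60, n_normal=22, n_genes=5000, seed=21)
        cohort, _ = generate_cohort(params)
        out = {}
        for seed in (100, 200):
            draws = draw_unstratified(cohort.samples, k=50, seed=seed)
            reps = [
                differential_genes(s, cohort, moderation=False) for s in draws
            ]
            avg = average_pvalues(reps)
            out[seed] = np.array([r.p_raw for r in sorted(avg, key=lambda r: r.feature_id)])
        rho = stats.spearmanr(out[100], out[200]).statistic
        assert rho > 0.95
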