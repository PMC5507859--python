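"""Diversity estimators, CSS scaling, Yue-Clayton distance and group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from skbio.diversity.alpha import chao1 as skbio_chao1

import fryflora as ff
from fryflora.metrics import (
    css_apply,
    css_fit,
    distance_matrix,
    letters,
    log_trend_fit,
    summarize_group_dissimilarity,
)
from fryflora.tables import CountTable


count_vectors = st.lists(st.integers(min_value=0, max_value=60), min_size=2,
                         max_size=30).filter(lambda v: sum(v) > 0)


def _literal_np_shannon(counts):
    x = np.asarray([c for c in counts if c > 0], dtype=float)
    n = x.sum()
    c = 1.0 - (x == 1).sum() / n
    total = 0.0
    for xi in x:
        pa = c * xi / n
        total += -(pa * np.log(pa)) / (1.0 - (1.0 - pa) ** n)
    return total


class TestAlphaEstimators:
    def test_goods_coverage_worked_example(self):
        assert ff.goods_coverage([5, 3, 1, 1]) == pytest.approx(0.8)

    def test_goods_coverage_extremes(self):
        assert ff.goods_coverage([4, 2, 3]) == 1.0
        assert ff.goods_coverage([1, 1, 1]) == 0.0

    def test_chao1_worked_examples(self):
        # S_obs=10, F1=4, F2=2 -> 12
        counts = [1, 1, 1, 1, 2, 2, 5, 5, 5, 5]
        assert ff.chao1(counts) == pytest.approx(12.0)
        # F2=0 case: S_obs + F1(F1-1)/2
        counts = [1, 1, 1, 1, 5, 5, 5, 5, 5, 5]
        assert ff.chao1(counts) == pytest.approx(10 + 6)
        assert ff.chao1([3, 4, 5]) == 3  # no singletons -> S_obs

    @given(counts=count_vectors)
    def test_chao1_at_least_observed_and_matches_skbio(self, counts):
        est = ff.chao1(counts)
        s_obs = sum(1 for c in counts if c > 0)
        assert est >= s_obs
        f1 = sum(1 for c in counts if c == 1)
        if f1 <= 1:
            assert est == pytest.approx(s_obs)
        assert est == pytest.approx(skbio_chao1(np.array(counts), bias_corrected=True))

    def test_np_shannon_single_otu_is_zero(self):
        assert ff.np_shannon([7]) == 0.0

    def test_np_shannon_literal_formula(self):
        counts = [4, 4, 2]
        assert ff.np_shannon(counts) == pytest.approx(_literal_np_shannon(counts),
                                                      abs=1e-12)

    def test_np_shannon_all_singletons_falls_back(self):
        with pytest.warns(UserWarning, match="plug-in"):
            h = ff.np_shannon([1, 1, 1, 1])
        assert h == pytest.approx(np.log(4))

    def test_np_shannon_consistency_large_sample(self):
        # with a deep sample the estimator approaches the true entropy
        rng = np.random.default_rng(7)
        p = np.array([0.4, 0.3, 0.15, 0.1, 0.05])
        truth = -(p * np.log(p)).sum()
        counts = rng.multinomial(200_000, p)
        assert ff.np_shannon(counts) == pytest.approx(truth, rel=0.01)

    def test_alpha_table_invariants(self, pipeline_products):
        qc, _, _, _ = pipeline_products
        alpha = ff.alpha_table(qc)
        assert (alpha["chao1"] >= alpha["observed_otus"]).all()
        assert alpha["goods_coverage"].between(0, 1).all()
        assert (alpha["np_shannon"] >= 0).all()


class TestCss:
    def test_hand_evaluated_factors(self):
        table = CountTable(pd.DataFrame({"s": [10, 10, 10, 10]}, index=list("abcd")))
        model = css_fit(table, percentile=0.5)
        assert model.quantiles["s"] == 10
        assert model.factors["s"] == 40
        norm = css_apply(table, model)
        assert np.allclose(norm["s"], 10 / 40 * model.scale)

    def test_identical_samples_identical_factors(self):
        df = pd.DataFrame({"a": [5, 0, 9], "b": [5, 0, 9]}, index=list("xyz"))
        model = css_fit(CountTable(df))
        assert model.factors["a"] == model.factors["b"]

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=40), min_size=3,
                        max_size=12).filter(lambda v: sum(v) > 0),
        factor=st.integers(min_value=2, max_value=7),
    )
    def test_scale_equivariance(self, counts, factor):
        # rescaling a sample's raw counts leaves its normalized column unchanged
        df = pd.DataFrame({"s": counts, "t": [c * factor for c in counts]})
        model = css_fit(df)
        norm = css_apply(df, model)
        assert np.allclose(norm["s"], norm["t"], atol=1e-9)

    def test_rank_order_preserved(self):
        df = pd.DataFrame({"s": [1, 50, 7, 0, 22]})
        norm = css_apply(df, css_fit(df))
        assert list(norm["s"].rank()) == list(df["s"].rank())

    def test_empty_sample_rejected(self):
        df = pd.DataFrame({"s": [0, 0]})
        with pytest.raises(ValueError, match="no nonzero"):
            css_fit(df)

    def test_percentile_validated(self):
        df = pd.DataFrame({"s": [1, 2]})
        with pytest.raises(ValueError, match="percentile"):
            css_fit(df, percentile=0.0)


class TestThetayc:
    def test_worked_examples(self):
        assert ff.thetayc([0.5, 0.5], [0.5, 0.5]) == 0.0
        assert ff.thetayc([1.0, 0.0], [0.0, 1.0]) == 1.0
        assert ff.thetayc([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.5)

    @given(data=st.data(), n=st.integers(min_value=2, max_value=12))
    @settings(max_examples=60)
    def test_symmetry_bounds_and_literal_formula(self, data, n):
        raw_x = data.draw(st.lists(st.floats(0.01, 10), min_size=n, max_size=n))
        raw_y = data.draw(st.lists(st.floats(0.01, 10), min_size=n, max_size=n))
        x = np.array(raw_x) / sum(raw_x)
        y = np.array(raw_y) / sum(raw_y)
        d = ff.thetayc(x, y)
        assert d == ff.thetayc(y, x)
        assert 0.0 <= d <= 1.0
        num = sum(a * b for a, b in zip(x, y))
        den = sum(a * a for a in x) + sum(b * b for b in y) - num
        assert d == pytest.approx(1.0 - num / den, abs=1e-12)

    def test_zero_iff_equal(self):
        x = np.array([0.2, 0.3, 0.5])
        assert ff.thetayc(x, x) == 0.0
        assert ff.thetayc(x, np.array([0.5, 0.3, 0.2])) > 0.0

    def test_mismatched_axes_rejected(self):
        a = pd.Series([0.5, 0.5], index=["x", "y"])
        b = pd.Series([0.5, 0.5], index=["x", "z"])
        with pytest.raises(ValueError, match="mismatched"):
            ff.thetayc(a, b)


class TestDistanceMatrix:
    def test_identical_samples_zero_matrix(self):
        rel = pd.DataFrame({"a": [0.6, 0.4], "b": [0.6, 0.4]})
        dm = distance_matrix(rel)
        assert np.allclose(dm.data, 0.0)

    def test_matches_pairwise_calls(self):
        rng = np.random.default_rng(0)
        rel = pd.DataFrame(rng.dirichlet(np.ones(6), size=4).T,
                           columns=list("abcd"))
        dm = distance_matrix(rel)
        for i in "abcd":
            for j in "abcd":
                assert dm[i, j] == pytest.approx(
                    ff.thetayc(rel[i].to_numpy(), rel[j].to_numpy()), abs=1e-12)

    def test_sample_permutation_consistent(self):
        rng = np.random.default_rng(1)
        rel = pd.DataFrame(rng.dirichlet(np.ones(5), size=3).T,
                           columns=list("abc"))
        dm1 = distance_matrix(rel)
        dm2 = distance_matrix(rel[["c", "a", "b"]])
        assert dm1["a", "c"] == pytest.approx(dm2["c", "a"])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            distance_matrix(pd.DataFrame({"a": [1.0]}))


class TestGroupSummary:
    def test_hand_stats(self):
        import skbio
        values = np.array([[0, 0.4, 0.6], [0.4, 0, 0.1], [0.6, 0.1, 0]])
        dm = skbio.DistanceMatrix(values, ids=list("xyz"))
        s = summarize_group_dissimilarity(dm, ["x"], ["y", "z"])
        assert s.mean == pytest.approx(0.5)
        assert s.std_deviation == pytest.approx(np.std([0.4, 0.6], ddof=1))
        assert s.std_error == pytest.approx(s.std_deviation / np.sqrt(2))

    def test_single_pair_degenerate(self):
        import skbio
        dm = skbio.DistanceMatrix([[0, 0.3], [0.3, 0]], ids=["a", "b"])
        s = summarize_group_dissimilarity(dm, ["a"], ["b"])
        assert s.degenerate and s.std_deviation == 0.0 and s.n_pairs == 1

    def test_overlapping_groups_rejected(self):
        import skbio
        dm = skbio.DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"])
        with pytest.raises(ValueError, match="overlap"):
            summarize_group_dissimilarity(dm, ["a"], ["a", "b"])


class TestTrendFit:
    def test_exact_log_relationship(self):
        x = np.array([0, 2, 6, 13, 20, 50])
        y = 1.5 + 0.8 * np.log(x + 1)
        fit = log_trend_fit(x, y)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(1.5)
        assert fit.slope == pytest.approx(0.8)

    def test_constant_y(self):
        fit = log_trend_fit([0, 5, 10], [2.0, 2.0, 2.0])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == 0.0

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 100, size=12)
        y = rng.normal(size=12)
        fit = log_trend_fit(x, y)
        t = np.log(x + 1.0)
        b = np.cov(t, y, ddof=1)[0, 1] / np.var(t, ddof=1)
        a = y.mean() - b * t.mean()
        assert fit.slope == pytest.approx(b)
        assert fit.intercept == pytest.approx(a)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="all x"):
            log_trend_fit([5, 5, 5], [1, 2, 3])


class TestWelch:
    def test_identical_groups(self):
        t, df, p = ff.welch_ttest([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_textbook_separation(self):
        t, df, p = ff.welch_ttest([1, 2, 3], [11, 12, 13])
        assert p < 0.01
        res = sps.ttest_ind([1, 2, 3], [11, 12, 13], equal_var=False)
        assert t == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)
        assert df == pytest.approx(res.df)

    def test_zero_variance_branches(self):
        assert ff.welch_ttest([2, 2], [2, 2])[2] == 1.0
        assert ff.welch_ttest([2, 2], [5, 5])[2] == 0.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ff.welch_ttest([1], [2, 3])

    def test_null_p_values_uniform(self):
        # KS test over 1000 simulated null pairs at alpha = 0.01
        rng = np.random.default_rng(11)
        pvals = [ff.welch_ttest(rng.normal(size=10), rng.normal(size=10))[2]
                 for _ in range(1000)]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestLetters:
    def test_one_distinct_group(self):
        rng = np.random.default_rng(5)
        groups = {
            "g1": rng.normal(0, 1, 20),
            "g2": rng.normal(0.1, 1, 20),
            "g3": rng.normal(8, 1, 20),
        }
        out = letters(groups)
        assert set(out["g1"]) & set(out["g2"])      # not significantly different
        assert not set(out["g1"]) & set(out["g3"])  # significantly different
        assert not set(out["g2"]) & set(out["g3"])

    def test_letters_reflect_pairwise_tests(self):
        rng = np.random.default_rng(6)
        groups = {f"g{i}": rng.normal(loc, 1, 15)
                  for i, loc in enumerate([0, 0.2, 5, 5.3, 12])}
        out = letters(groups, alpha=0.05)
        names = list(groups)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                _, _, p = ff.welch_ttest(groups[a], groups[b])
                share = bool(set(out[a]) & set(out[b]))
                assert share == (p >= 0.05)
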