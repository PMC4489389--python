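"""Inferential statistics: t-tests, chi-square, AUC, FDR, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from restconn.connectome import SparsityGrid
from restconn.stats import (
    MetricCurve,
    StatsError,
    SummaryStatsGroup,
    bh_fdr,
    chi_square_2x2,
    compare_groups_over_grid,
    curve_auc,
    metric_cognition_correlation,
    summary_ttest,
    two_sample_ttest,
)

from _oracles import bh_brute, pooled_t_brute, trapezoid_brute


class TestTTests:
    def test_identical_groups(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = two_sample_ttest(x, x)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        x = 0.0 + 1e-3 * rng.standard_normal(4)
        y = 1.0 + 1e-3 * rng.standard_normal(4)
        assert two_sample_ttest(x, y).p < 1e-4

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.standard_normal(rng.integers(3, 15))
            y = rng.standard_normal(rng.integers(3, 15)) + rng.normal()
            res = two_sample_ttest(x, y)
            t_o, df_o = pooled_t_brute(list(x), list(y))
            assert res.t == pytest.approx(t_o, abs=1e-10)
            assert res.df == df_o
            p_o = 2 * sps.t.sf(abs(t_o), df_o)
            assert res.p == pytest.approx(p_o, abs=1e-10)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(StatsError):
            two_sample_ttest([1.0, 1.0, 1.0], [1.0, 1.0])

    def test_summary_equals_raw_on_matching_data(self):
        """Affine-constructed raw vectors with exactly the stated summaries
        give the identical t to 1e-10."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = SummaryStatsGroup(rng.normal(), abs(rng.normal()) + 0.1, int(rng.integers(3, 30)))
            b = SummaryStatsGroup(rng.normal(), abs(rng.normal()) + 0.1, int(rng.integers(3, 30)))

            def realise(s):
                z = rng.standard_normal(s.n)
                z = (z - z.mean()) / z.std(ddof=1)
                return s.mean + s.sd * z

            raw = two_sample_ttest(realise(a), realise(b))
            summ = summary_ttest(a, b)
            assert summ.t == pytest.approx(raw.t, abs=1e-10)
            assert summ.p == pytest.approx(raw.p, abs=1e-10)

    def test_equal_summaries_give_t_zero(self):
        res = summary_ttest(SummaryStatsGroup(5, 1, 10), SummaryStatsGroup(5, 1, 12))
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "a, b, printed_p",
        [
            ((8.17, 2.44, 23), (9.55, 2.20, 20), 0.060),   # years of education
            ((24.57, 9.40, 23), (20.25, 0.72, 20), 0.047),  # daily-living score
        ],
    )
    def test_published_summary_examples(self, a, b, printed_p):
        res = summary_ttest(SummaryStatsGroup(*a), SummaryStatsGroup(*b))
        assert round(res.p, 3) == printed_p


class TestChiSquare:
    def test_balanced_table(self):
        chi2, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        chi2, p = chi_square_2x2([[10, 13], [11, 9]])
        assert chi2 == pytest.approx(0.5684, abs=1e-3)

    def test_doubling_counts_doubles_chi2(self):
        t = np.array([[10, 13], [11, 9]])
        chi2, _ = chi_square_2x2(t)
        chi2_2, _ = chi_square_2x2(2 * t)
        assert chi2_2 == pytest.approx(2 * chi2)

    def test_variants_available(self):
        t = [[10, 13], [11, 9]]
        _, p_yates = chi_square_2x2(t, method="yates")
        _, p_fisher = chi_square_2x2(t, method="fisher")
        assert p_fisher == pytest.approx(0.5467, abs=1e-3)
        assert p_yates > chi_square_2x2(t)[1]

    def test_zero_marginal_rejected(self):
        with pytest.raises(StatsError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestAUC:
    def test_constant_curve(self):
        s = np.round(np.arange(0.05, 0.401, 0.01), 10)
        assert curve_auc(s, np.full(len(s), 3.0), 0.05, 0.40) == pytest.approx(0.35 * 3.0)

    def test_linear_curve_exact(self):
        s = np.linspace(0, 1, 21)
        assert curve_auc(s, s, 0.0, 1.0) == pytest.approx(0.5)

    def test_matches_summed_trapezoid_oracle(self):
        rng = np.random.default_rng(2)
        s = np.round(np.arange(0.05, 0.401, 0.01), 10)
        v = rng.standard_normal(len(s))
        assert curve_auc(s, v, 0.08, 0.31) == pytest.approx(
            trapezoid_brute(list(s[3:27]), list(v[3:27])), abs=1e-12
        )

    def test_range_off_grid_rejected(self):
        s = np.round(np.arange(0.05, 0.401, 0.01), 10)
        with pytest.raises(StatsError):
            curve_auc(s, np.ones(len(s)), 0.055, 0.31)

    def test_metric_curve_auc_recomputable(self):
        s = np.round(np.arange(0.05, 0.401, 0.01), 10)
        rng = np.random.default_rng(3)
        curve = MetricCurve("s1", "Cp", s, rng.random(len(s)))
        assert curve.auc() == pytest.approx(np.trapezoid(curve.values, s), abs=1e-12)


class TestFDR:
    def test_bh_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_bh_matches_step_up_definition(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), bh_brute(list(p)), atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_bh_monotone_and_dominates_p(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_all_equal_p_fixed_point(self):
        p = [0.2] * 5
        assert np.allclose(bh_fdr(p), p)


def _toy_curves(rng, effect=0.0, n_per_group=6, metric_val=None):
    grid = SparsityGrid(0.1, 0.3, 0.1)
    rows = []
    groups = {}
    for g, off in (("patient", effect), ("control", 0.0)):
        for i in range(n_per_group):
            sid = f"{g}{i}"
            groups[sid] = g
            base = rng.standard_normal() * 0.1 + off
            for s in grid.values:
                rows.append(dict(subject=sid, sparsity=float(s),
                                 Cp=0.5 + base + 0.01 * rng.standard_normal(),
                                 Lp=2.0 - base + 0.01 * rng.standard_normal(),
                                 Eglob=0.5 + base, Eloc=0.5 + base))
    return pd.DataFrame(rows), pd.Series(groups), grid


def test_identical_groups_yield_no_significance():
    rng = np.random.default_rng(5)
    curves, groups, grid = _toy_curves(rng, effect=0.0)
    res = compare_groups_over_grid(curves, groups, grid)
    assert not res["significant"].any()


def test_strong_effect_detected_with_correct_signs():
    rng = np.random.default_rng(6)
    curves, groups, grid = _toy_curves(rng, effect=-1.0)  # patients lower Cp, higher Lp
    res = compare_groups_over_grid(curves, groups, grid)
    auc = res[res["scope"] == "global_auc"].set_index("metric")
    assert auc.loc["Cp", "t"] < 0 and auc.loc["Cp", "significant"]
    assert auc.loc["Lp", "t"] > 0 and auc.loc["Lp", "significant"]


def test_sign_convention_patient_minus_control():
    rng = np.random.default_rng(7)
    curves, groups, grid = _toy_curves(rng, effect=1.0)  # patients higher Cp
    res = compare_groups_over_grid(curves, groups, grid)
    auc = res[res["scope"] == "global_auc"].set_index("metric")
    assert auc.loc["Cp", "t"] > 0
    assert auc.loc["Cp", "direction"] == 1


def test_correlation_perfect_when_score_is_auc():
    rng = np.random.default_rng(8)
    curves, groups, grid = _toy_curves(rng)
    from restconn.stats import auc_table

    aucs = auc_table(curves, (0.1, 0.3), metrics=("Cp",)).set_index("subject")["auc"]
    scores = pd.DataFrame({"score": aucs})
    res = metric_cognition_correlation(curves, scores, auc_range=(0.1, 0.3))
    r_cp = res[(res["metric"] == "Cp") & (res["score"] == "score")]["r"].iloc[0]
    assert r_cp == pytest.approx(1.0)


def test_correlation_calibrated_under_permutation():
    """With scores shuffled independently of the metric, the p < 0.05 rate
    over 200 permutations stays within binomial noise of 5%."""
    rng = np.random.default_rng(9)
    curves, groups, grid = _toy_curves(rng, n_per_group=12)
    base_scores = rng.standard_normal(24)
    subjects = sorted(groups.index)
    hits = 0
    for _ in range(200):
        perm = rng.permutation(base_scores)
        scores = pd.DataFrame({"score": perm}, index=subjects)
        res = metric_cognition_correlation(curves, scores, auc_range=(0.1, 0.3))
        p = res[res["metric"] == "Cp"]["p"].iloc[0]
        hits += p < 0.05
    # Binomial(200, 0.05): central 99.9% interval is about [2, 20]
    assert 1 <= hits <= 21


def test_constant_score_rejected():
    rng = np.random.default_rng(10)
    curves, groups, grid = _toy_curves(rng)
    scores = pd.DataFrame({"score": 1.0}, index=sorted(groups.index))
    with pytest.raises(StatsError):
        metric_cognition_correlation(curves, scores, auc_range=(0.1, 0.3))
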