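"""Statistic-layer tests with enumeration and dense-grid oracles."""

import dataclasses
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from sdnam1 import (ModelParameters, binomial_preference_test, compare_groups,
                    compute_rday, fisher_2x2, half_life, roc_analysis)
from sdnam1.model import persistent_solution, transient_solution

P3 = ModelParameters(lam=600, k=3, theta=4, mu=0.08, r=0.25, N=25, x2_0=3, x3_0=15)


class TestComputeRday:
    def test_no_transient_gives_zero(self):
        p = dataclasses.replace(P3, lam=0.0)
        for h in (20, 30, 40, 50):
            assert compute_rday(p, h).r_day_n == 0.0

    def test_no_persistent_gives_hundred(self):
        p = dataclasses.replace(P3, x2_0=0.0)
        for h in (20, 30, 40, 50):
            assert compute_rday(p, h).r_day_n == 100.0

    def test_quadrature_matches_dense_trapezoid(self):
        grid = np.linspace(0, 30, 10_000)
        auc1 = np.trapezoid(transient_solution(grid, P3), grid)
        auc2 = np.trapezoid(persistent_solution(grid, P3), grid)
        rv = compute_rday(P3, 30.0)
        assert rv.auc_x1 == pytest.approx(auc1, rel=1e-4)
        assert rv.auc_x2 == pytest.approx(auc2, rel=1e-4)
        assert rv.r_day_n == pytest.approx(100 * auc1 / (auc1 + auc2), rel=1e-4)

    def test_undefined_ratio_raises(self):
        p = dataclasses.replace(P3, lam=0.0, x2_0=0.0)
        with pytest.raises(ValueError, match="undefined"):
            compute_rday(p, 30.0)

    @pytest.mark.parametrize("c", [0.1, 3.0, 42.0])
    def test_amplitude_rescaling_invariance(self, c):
        """Scaling (lam, N, x2_0, x3_0) jointly leaves R_day_n unchanged."""
        scaled = dataclasses.replace(P3, lam=c * P3.lam, N=c * P3.N,
                                     x2_0=c * P3.x2_0, x3_0=c * P3.x3_0)
        assert compute_rday(scaled, 30.0).r_day_n == pytest.approx(
            compute_rday(P3, 30.0).r_day_n, rel=1e-9)


class TestHalfLife:
    def test_ln2_rate_gives_one_day(self):
        assert half_life(math.log(2)) == pytest.approx(1.0)

    def test_cohort_scale_inverse_consistency(self):
        assert half_life(math.log(2) / 12.5) == pytest.approx(12.5)

    def test_halving_rate_doubles_half_life(self):
        assert half_life(0.05) == pytest.approx(2 * half_life(0.1))

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            half_life(0.0)


class TestCompareGroups:
    def test_identical_groups(self):
        vals = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1], bool)
        gc = compare_groups(vals, labels)
        assert gc.diff_mean == 0.0
        assert gc.p_t == pytest.approx(1.0)

    def test_strong_separation(self):
        # constant shift, negligible within-group spread
        rng = np.random.default_rng(0)
        neg = 10 + 1e-6 * rng.standard_normal(10)
        pos = 50 + 1e-6 * rng.standard_normal(10)
        gc = compare_groups(np.r_[neg, pos], np.r_[np.zeros(10), np.ones(10)] > 0)
        assert gc.p_t < 1e-30
        assert gc.ci_low > 0.0

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0, 3.0], [True, False, False])

    def test_type_one_error_calibration(self):
        """Welch p maintains ~5% size under the null (500 replicates)."""
        rng = np.random.default_rng(42)
        labels = np.r_[np.zeros(19), np.ones(48)].astype(bool)
        rejections = sum(
            compare_groups(rng.normal(50, 20, 67), labels).p_t < 0.05
            for _ in range(500)
        )
        assert 0.03 <= rejections / 500 <= 0.07


class TestBinomialPreferenceTest:
    def test_cohort_preference_values(self):
        res = binomial_preference_test(47, 67)
        assert res.p_value == pytest.approx(0.0013, abs=5e-5)
        assert 100 * res.proportion == pytest.approx(70.1, abs=0.05)
        assert 100 * res.ci_low == pytest.approx(58.0, abs=0.5)
        assert 100 * res.ci_high == pytest.approx(81.0, abs=0.5)

    def test_central_value(self):
        assert binomial_preference_test(10, 20).p_value == pytest.approx(1.0)

    def test_enumeration_oracle(self):
        """p sums the probabilities of all outcomes no likelier than observed."""
        k, n = 4, 5
        pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
        expected = sum(p for p in pmf if p <= pmf[k] * (1 + 1e-12))
        assert binomial_preference_test(k, n).p_value == pytest.approx(expected)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            binomial_preference_test(6, 5)


def _fisher_enumeration(table) -> float:
    """Brute-force two-sided Fisher p over all tables with the same margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(a_):
        return (math.comb(r1, a_) * math.comb(r2, c1 - a_)) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


class TestFisher2x2:
    def test_allele_match_table(self):
        assert fisher_2x2([[12, 7], [32, 16]]) == pytest.approx(0.78, abs=0.005)

    def test_matches_enumeration_on_small_tables(self):
        for table in itertools.product(range(4), repeat=4):
            t = [[table[0], table[1]], [table[2], table[3]]]
            margins = (sum(t[0]), sum(t[1]), t[0][0] + t[1][0], t[0][1] + t[1][1])
            if any(m == 0 for m in margins):
                continue
            assert fisher_2x2(t) == pytest.approx(_fisher_enumeration(t),
                                                  rel=1e-9), t

    def test_degenerate_margin(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert fisher_2x2([[3, 0], [5, 0]]) == 1.0


def _roc_enumeration(values, labels):
    """Exhaustive threshold scan with the >=-cutoff positive-call rule."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    best = None
    for cut in np.unique(values):
        pred = values >= cut
        tp = np.sum(pred & labels)
        tn = np.sum(~pred & ~labels)
        fp = np.sum(pred & ~labels)
        fn = np.sum(~pred & labels)
        sens, spec = tp / (tp + fn), tn / (tn + fp)
        d = math.hypot(1 - sens, 1 - spec)
        key = (d, 1 - spec, -cut)
        if best is None or key < best[0]:
            best = (key, cut, tp, tn, fp, fn)
    return best[1:]


class TestRocAnalysis:
    def test_perfect_separation(self):
        vals = np.array([1.0, 2, 3, 10, 11, 12])
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        r = roc_analysis(vals, labels)
        assert r.auc == 1.0
        assert r.sensitivity == r.specificity == r.accuracy == 1.0

    def test_toy_set_matches_enumeration(self):
        vals = np.array([1.0, 2, 3, 4, 5, 6])
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        r = roc_analysis(vals, labels)
        cut, tp, tn, fp, fn = _roc_enumeration(vals, labels)
        assert (r.cutoff, r.tp, r.tn, r.fp, r.fn) == (cut, tp, tn, fp, fn)

    @pytest.mark.parametrize("seed", range(5))
    def test_cutoff_matches_enumeration_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.round(rng.normal(size=25), 1)  # ties on purpose
        labels = rng.random(25) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        r = roc_analysis(vals, labels)
        cut, tp, tn, fp, fn = _roc_enumeration(vals, labels)
        assert (r.cutoff, r.tp, r.tn, r.fp, r.fn) == (cut, tp, tn, fp, fn)

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_mann_whitney_identity(self, seed):
        rng = np.random.default_rng(100 + seed)
        vals = np.round(rng.normal(size=40), 1)
        labels = rng.random(40) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        r = roc_analysis(vals, labels)
        u = sps.mannwhitneyu(vals[labels], vals[~labels],
                             alternative="two-sided").statistic
        assert r.auc == pytest.approx(u / (labels.sum() * (~labels).sum()))

    def test_accuracy_definition(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        labels[0] = True
        labels[1] = False
        r = roc_analysis(vals, labels)
        assert r.accuracy == (r.tp + r.tn) / (r.tp + r.tn + r.fp + r.fn)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], [True, True])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.data())
def test_auc_invariant_under_monotone_transform(data):
    """AUC depends only on ranks: strictly increasing transforms preserve it."""
    n = data.draw(st.integers(6, 30))
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    vals = rng.normal(size=n)
    labels = rng.random(n) < 0.5
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    a = roc_analysis(vals, labels).auc
    b = roc_analysis(np.exp(3 * vals) + 7, labels).auc
    assert a == pytest.approx(b, abs=1e-12)
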