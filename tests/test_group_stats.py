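import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from tussilab import group_stats as gs


def wilcoxon_enumeration(d):
    """Exact two-sided p over all 2^n sign patterns (independent oracle)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sstats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = [sum(r for r, s in zip(ranks, signs) if s)
             for signs in itertools.product([False, True], repeat=n)]
    stats = np.array(stats)
    total = stats.size
    lo = np.count_nonzero(stats <= w_obs + 1e-12) / total
    hi = np.count_nonzero(stats >= w_obs - 1e-12) / total
    return min(1.0, 2 * min(lo, hi))


def mann_whitney_enumeration(x, y):
    """Exact two-sided p over all C(n1+n2, n1) labelings (independent oracle)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    r_obs = sstats.rankdata(pooled)[:n1].sum()
    ranks = sstats.rankdata(pooled)
    sums = np.array([sum(ranks[list(idx)])
                     for idx in itertools.combinations(range(len(pooled)), n1)])
    total = sums.size
    lo = np.count_nonzero(sums <= r_obs + 1e-12) / total
    hi = np.count_nonzero(sums >= r_obs - 1e-12) / total
    return min(1.0, 2 * min(lo, hi))


class TestDescriptives:
    def test_five_number_summary(self):
        d = gs.descriptives([1, 2, 3, 4, 5])
        assert (d.minimum, d.median, d.maximum) == (1.0, 3.0, 5.0)
        assert d.q1 == 2.0 and d.q3 == 4.0

    def test_constant_data_degenerate_ci(self):
        d = gs.descriptives(np.full(20, 7.0))
        assert d.ci_low == d.ci_high == 7.0

    def test_ci_brackets_median_and_is_seeded(self, rng):
        x = rng.standard_normal(200)
        d1 = gs.descriptives(x, seed=123)
        d2 = gs.descriptives(x, seed=123)
        assert d1 == d2
        assert d1.ci_low <= d1.median <= d1.ci_high

    def test_ordering_invariant(self, rng):
        x = rng.standard_normal(57)
        d = gs.descriptives(x, seed=5)
        assert d.minimum <= d.q1 <= d.median <= d.q3 <= d.maximum

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gs.descriptives([])


class TestWilcoxon:
    def test_constant_positive_shift_extreme_p(self):
        y = np.arange(12.0)
        r = gs.wilcoxon_signed_rank(y + 3.0, y)
        assert r.statistic == 12 * 13 / 2
        assert r.p_value == pytest.approx(2 * 2.0**-12, abs=1e-15)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration_n8(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(8)
        y = x + rng.standard_normal(8)
        want = wilcoxon_enumeration(x - y)
        got = gs.wilcoxon_signed_rank(x, y)
        assert got.p_value == pytest.approx(want, abs=1e-12)

    def test_exact_matches_enumeration_with_ties(self):
        # integer-valued differences force mid-ranked ties
        x = np.array([5.0, 7, 2, 9, 4, 6, 8, 3])
        y = np.array([3.0, 7, 4, 5, 4, 2, 4, 1])
        want = wilcoxon_enumeration(x - y)
        got = gs.wilcoxon_signed_rank(x, y)
        assert got.p_value == pytest.approx(want, abs=1e-12)

    def test_agrees_with_scipy_exact_when_tie_free(self, rng):
        for _ in range(5):
            x = rng.standard_normal(15)
            y = x + rng.standard_normal(15)
            mine = gs.wilcoxon_signed_rank(x, y).p_value
            ref = sstats.wilcoxon(x, y, mode="exact").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_exact_and_approx_agree_at_boundary(self, rng):
        # n = 25 is the largest enumerated size; the normal approximation
        # with continuity correction should land within 0.01 of it
        for _ in range(5):
            x = rng.standard_normal(25)
            y = x + 0.3 * rng.standard_normal(25)
            exact = gs.wilcoxon_signed_rank(x, y, exact_max_n=25).p_value
            approx = gs.wilcoxon_signed_rank(x, y, exact_max_n=0).p_value
            assert abs(exact - approx) < 0.01

    def test_statistic_plus_complement(self, rng):
        x = rng.standard_normal(14)
        y = rng.standard_normal(14)
        w_plus = gs.wilcoxon_signed_rank(x, y).statistic
        w_minus = gs.wilcoxon_signed_rank(y, x).statistic
        assert w_plus + w_minus == 14 * 15 / 2

    def test_monotone_transform_invariance(self, rng):
        # rank test: any strictly monotone transform of the pooled paired
        # values that preserves difference signs/order keeps p identical;
        # scaling both samples is such a transform
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        p0 = gs.wilcoxon_signed_rank(x, y).p_value
        p1 = gs.wilcoxon_signed_rank(5 * x, 5 * y).p_value
        assert p0 == pytest.approx(p1, abs=1e-12)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gs.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestMannWhitney:
    def test_identical_groups_symmetric_u(self):
        x = [1.0, 2, 3, 4, 5, 6]
        r = gs.mann_whitney_u(x, x)
        assert r.statistic == 18.0  # n1*n2/2
        assert r.p_value == 1.0

    def test_complete_separation_minimal_p(self):
        x = np.arange(10.0, 16)
        y = np.arange(0.0, 6)
        r = gs.mann_whitney_u(x, y)
        assert r.statistic == 36.0  # n1*n2
        assert r.p_value == pytest.approx(2 / math.comb(12, 6), abs=1e-15)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration_6v6(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(6)
        y = rng.standard_normal(6) + 0.5
        want = mann_whitney_enumeration(x, y)
        got = gs.mann_whitney_u(x, y)
        assert got.p_value == pytest.approx(want, abs=1e-12)

    def test_agrees_with_scipy_exact(self, rng):
        for _ in range(5):
            x = rng.standard_normal(8)
            y = rng.standard_normal(9) + 0.3
            mine = gs.mann_whitney_u(x, y).p_value
            ref = sstats.mannwhitneyu(x, y, method="exact",
                                      alternative="two-sided").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_exact_and_approx_agree_at_boundary(self, rng):
        for _ in range(5):
            x = rng.standard_normal(10)
            y = rng.standard_normal(10) + 0.4
            exact = gs.mann_whitney_u(x, y, exact_max_n=20).p_value
            approx = gs.mann_whitney_u(x, y, exact_max_n=0).p_value
            assert abs(exact - approx) < 0.01

    def test_monotone_transform_invariance(self, rng):
        x = rng.uniform(0.1, 5, 10)
        y = rng.uniform(0.1, 5, 12)
        p0 = gs.mann_whitney_u(x, y).p_value
        p1 = gs.mann_whitney_u(np.log(x), np.log(y)).p_value
        assert p0 == pytest.approx(p1, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            gs.mann_whitney_u([], [1.0])


class TestCompareGroups:
    @staticmethod
    def _tables(rng, feature_values=None):
        rows, feats = [], []
        for s in range(6):
            for cls in ("voluntary_cough", "throat_clearing"):
                fid = f"s{s}_{cls}.wav"
                rows.append(dict(file_id=fid, subject=f"s{s}", maneuver=cls,
                                 microphone="free_standing", induction="none",
                                 token=0))
                val = (feature_values[cls] if feature_values
                       else rng.standard_normal())
                feats.append(dict(file_id=fid, amp_curv=val,
                                  kurt_avg=rng.standard_normal()))
        return pd.DataFrame(feats), pd.DataFrame(rows)

    def test_paired_contrast_routes_to_wilcoxon(self, rng):
        feats, cohort = self._tables(rng)
        contrast = gs.Contrast("maneuver", "voluntary_cough", "throat_clearing",
                               paired=True)
        results = gs.compare_groups(feats, cohort, contrast)
        assert {r.test for r in results} == {"wilcoxon"}
        assert {r.feature for r in results} == {"amp_curv", "kurt_avg"}

    def test_independent_contrast_routes_to_mann_whitney(self, rng):
        feats, cohort = self._tables(rng)
        contrast = gs.Contrast("maneuver", "voluntary_cough", "throat_clearing",
                               paired=False)
        results = gs.compare_groups(feats, cohort, contrast)
        assert {r.test for r in results} == {"mann_whitney"}

    def test_constant_feature_documented_p_one(self, rng):
        feats, cohort = self._tables(rng, feature_values={
            "voluntary_cough": 1.0, "throat_clearing": 1.0})
        contrast = gs.Contrast("maneuver", "voluntary_cough", "throat_clearing",
                               paired=True)
        results = gs.compare_groups(feats, cohort, contrast,
                                    feature_cols=["amp_curv"])
        assert results[0].p_value == 1.0 and not results[0].significant

    def test_unmatched_pairing_keys_listed(self, rng):
        feats, cohort = self._tables(rng)
        cohort.loc[cohort.index[-1], "token"] = 9  # orphan one clearing token
        contrast = gs.Contrast("maneuver", "voluntary_cough", "throat_clearing",
                               paired=True)
        with pytest.raises(ValueError, match="unmatched pairing"):
            gs.compare_groups(feats, cohort, contrast)

    def test_absent_level_rejected(self, rng):
        feats, cohort = self._tables(rng)
        contrast = gs.Contrast("maneuver", "voluntary_cough", "reflexive_cough",
                               paired=False)
        with pytest.raises(ValueError, match="absent"):
            gs.compare_groups(feats, cohort, contrast)
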