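"""Risk-difference confidence intervals, homogeneity, decisions, sample size."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from virosnap.stats import (
    Bound,
    DiffCI,
    CiMethod,
    SampleSizeSpec,
    StratumCounts,
    TwoByTwo,
    cmh_mn_ci,
    cmh_mn_z,
    homogeneity_test,
    mn_score_ci,
    mn_score_z,
    ni_sample_size,
    noninferiority_decision,
    round_half_away,
    wald_ci,
)

Z975 = norm.ppf(0.975)


def grid_search_mn_bounds(t: TwoByTwo, step=1e-6):
    """Independent oracle: scan delta for sign changes of |z(delta)| - z."""
    grid = np.arange(-1 + step, 1, step)
    # vectorized closed-form restricted MLE (same algebra, independent path)
    x1, n1, x2, n2 = t.x1, t.n1, t.x2, t.n2
    N = n1 + n2
    L3 = N
    L2 = (n1 + 2 * n2) * grid - N - (x1 + x2)
    L1 = (n2 * grid - N - 2 * x2) * grid + (x1 + x2)
    L0 = x2 * grid * (1 - grid)
    q = L2**3 / (27 * L3**3) - L1 * L2 / (6 * L3**2) + L0 / (2 * L3)
    pin = np.maximum(L2**2 / (9 * L3**2) - L1 / (3 * L3), 0.0)
    p_ = np.sqrt(pin)
    ratio = np.where(p_ > 0, np.clip(q / np.where(p_ > 0, p_, 1.0) ** 3, -1, 1), 0.0)
    a_ = (np.pi + np.arccos(ratio)) / 3
    p2t = np.clip(np.where(p_ > 0, 2 * p_ * np.cos(a_) - L2 / (3 * L3),
                           -L2 / (3 * L3)), 0, 1)
    p1t = np.clip(p2t + grid, 0, 1)
    var = (p1t * (1 - p1t) / n1 + p2t * (1 - p2t) / n2) * N / (N - 1)
    num = x1 / n1 - x2 / n2 - grid
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, num / np.sqrt(np.where(var > 0, var, 1.0)),
                     np.sign(num) * np.inf)
    f = np.abs(z) - Z975
    idx = np.where(np.diff(np.sign(f)) != 0)[0]
    assert len(idx) >= 2, "grid oracle found fewer than two crossings"
    return grid[idx[0]], grid[idx[-1]]


class TestMnScoreCi:
    def test_zero_events_in_one_arm(self):
        """4/255 vs 0/257: the score interval stays finite and positive on
        the left, unlike Wald."""
        ci = mn_score_ci(TwoByTwo(4, 255, 0, 257))
        assert round_half_away(ci.estimate) == 1.6
        assert 0 < ci.lower < ci.estimate < ci.upper
        assert math.isfinite(ci.lower) and math.isfinite(ci.upper)

    def test_symmetric_when_no_events(self):
        ci = mn_score_ci(TwoByTwo(0, 100, 0, 100))
        assert ci.estimate == 0.0
        assert ci.lower == pytest.approx(-ci.upper, abs=1e-6)

    def test_matches_grid_search_oracle_small_table(self):
        t = TwoByTwo(2, 10, 1, 10)
        ci = mn_score_ci(t)
        lo, hi = grid_search_mn_bounds(t)
        assert ci.lower / 100 == pytest.approx(lo, abs=5e-6)
        assert ci.upper / 100 == pytest.approx(hi, abs=5e-6)

    def test_matches_statsmodels_score_interval(self):
        from statsmodels.stats.proportion import confint_proportions_2indep
        for t in (TwoByTwo(4, 255, 0, 257), TwoByTwo(247, 255, 250, 257),
                  TwoByTwo(30, 100, 20, 100), TwoByTwo(5, 50, 3, 60)):
            ci = mn_score_ci(t)
            lo, hi = confint_proportions_2indep(
                t.x1, t.n1, t.x2, t.n2, method="score", compare="diff",
                correction=True)
            # statsmodels inverts the same statistic with a much looser
            # search (its root can sit at |z| ~ 1.92); coarse agreement only,
            # the precision anchor is the grid-search oracle above
            assert ci.lower / 100 == pytest.approx(lo, abs=3e-3)
            assert ci.upper / 100 == pytest.approx(hi, abs=3e-3)

    def test_root_accuracy(self):
        t = TwoByTwo(4, 255, 0, 257)
        ci = mn_score_ci(t)
        assert abs(mn_score_z(t, ci.lower / 100) - Z975) < 1e-8
        assert abs(mn_score_z(t, ci.upper / 100) + Z975) < 1e-8

    def test_width_non_increasing_in_n(self):
        widths = []
        for scale in (1, 4, 16):
            t = TwoByTwo(5 * scale, 50 * scale, 3 * scale, 50 * scale)
            ci = mn_score_ci(t)
            widths.append(ci.upper - ci.lower)
        assert widths[0] > widths[1] > widths[2]

    def test_agrees_with_wald_for_large_balanced_n(self):
        t = TwoByTwo(60_000, 100_000, 59_000, 100_000)
        mn = mn_score_ci(t)
        wd = wald_ci(t)
        assert mn.lower == pytest.approx(wd.lower, abs=0.1)
        assert mn.upper == pytest.approx(wd.upper, abs=0.1)

    @given(st.integers(1, 40), st.integers(1, 40), st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=60, deadline=None)
    def test_bounds_bracket_estimate(self, n1, n2, x1, x2):
        t = TwoByTwo(min(x1, n1), n1, min(x2, n2), n2)
        ci = mn_score_ci(t)
        assert ci.lower - 1e-9 <= ci.estimate <= ci.upper + 1e-9
        assert -100 <= ci.lower <= ci.upper <= 100


class TestCmhMn:
    def test_single_stratum_equals_unstratified_exactly(self):
        t = TwoByTwo(4, 255, 0, 257)
        strat = cmh_mn_ci([StratumCounts("all", t)])
        plain = mn_score_ci(t)
        assert strat.estimate == plain.estimate
        assert strat.lower == plain.lower
        assert strat.upper == plain.upper

    def test_identical_strata_keep_the_common_difference(self):
        s = StratumCounts("a", TwoByTwo(2, 128, 1, 129))
        ci = cmh_mn_ci([s, StratumCounts("b", s.counts)])
        assert ci.estimate == pytest.approx(100 * s.counts.diff)

    def test_weighted_estimate_close_to_crude_for_mild_imbalance(self):
        strata = [StratumCounts("i", TwoByTwo(240, 247, 243, 250)),
                  StratumCounts("n", TwoByTwo(7, 8, 7, 7))]
        # direct computation with CMH weights n1k n2k / (n1k + n2k)
        w = np.array([247 * 250 / 497, 8 * 7 / 15])
        d = np.array([240 / 247 - 243 / 250, 7 / 8 - 1.0])
        expected = 100 * float((w * d).sum() / w.sum())
        ci = cmh_mn_ci(strata)
        assert ci.estimate == pytest.approx(expected, abs=1e-9)
        crude = 100 * (247 / 255 - 250 / 257)
        assert abs(ci.estimate - crude) < 0.2

    def test_empty_arm_stratum_excluded_with_warning(self):
        good = StratumCounts("a", TwoByTwo(5, 50, 4, 50))
        empty = StratumCounts("b", TwoByTwo(0, 10, 0, 0))
        with pytest.warns(UserWarning, match="empty arm"):
            ci = cmh_mn_ci([good, empty])
        assert ci.estimate == mn_score_ci(good.counts).estimate
        with pytest.raises(ValueError):
            cmh_mn_ci([])

    def test_degenerate_two_by_two_rejected_unstratified(self):
        with pytest.raises(ValueError):
            mn_score_ci(TwoByTwo(0, 10, 0, 0))

    def test_stratified_root_accuracy(self):
        strata = [StratumCounts("i", TwoByTwo(223, 231, 233, 240)),
                  StratumCounts("n", TwoByTwo(24, 24, 17, 17))]
        ci = cmh_mn_ci(strata)
        assert abs(cmh_mn_z(strata, ci.lower / 100) - Z975) < 1e-8
        assert abs(cmh_mn_z(strata, ci.upper / 100) + Z975) < 1e-8


class TestWald:
    def test_grade3_adverse_event_row(self):
        ci = wald_ci(TwoByTwo(41, 255, 22, 257))
        assert (round_half_away(ci.estimate), round_half_away(ci.lower),
                round_half_away(ci.upper)) == (7.5, 1.9, 13.2)

    def test_serious_adverse_event_row(self):
        ci = wald_ci(TwoByTwo(12, 255, 9, 257))
        assert (round_half_away(ci.estimate), round_half_away(ci.lower),
                round_half_away(ci.upper)) == (1.2, -2.2, 4.6)

    def test_equal_proportions_symmetric(self):
        ci = wald_ci(TwoByTwo(10, 50, 10, 50))
        assert ci.estimate == 0.0
        assert ci.lower == pytest.approx(-ci.upper)

    def test_zero_variance_degenerates_to_estimate(self):
        ci = wald_ci(TwoByTwo(50, 50, 0, 50))
        assert ci.lower == ci.estimate == ci.upper == 100.0


class TestHomogeneity:
    def test_identical_differences_give_zero_statistic(self):
        levels = [StratumCounts("a", TwoByTwo(40, 100, 30, 100)),
                  StratumCounts("b", TwoByTwo(40, 100, 30, 100))]
        stat, p, df = homogeneity_test(levels)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_grossly_discordant_level_detected(self):
        levels = [StratumCounts("a", TwoByTwo(90, 100, 89, 100)),
                  StratumCounts("b", TwoByTwo(95, 100, 40, 100))]
        stat, p, df = homogeneity_test(levels)
        assert p < 0.05 and df == 1

    def test_needs_two_levels(self):
        with pytest.raises(ValueError):
            homogeneity_test([StratumCounts("a", TwoByTwo(5, 10, 5, 10))])


class TestDecisions:
    def test_primary_outcome_met_on_lower_bound(self):
        ci = DiffCI(-0.4, -3.1, 2.0, 0.05, CiMethod.CMH_MN_SCORE)
        assert noninferiority_decision(ci, 10, Bound.LOWER).met

    def test_failure_outcome_not_met_on_upper_bound(self):
        ci = DiffCI(1.6, 0.4, 4.2, 0.05, CiMethod.MN_SCORE)
        assert not noninferiority_decision(ci, 4, Bound.UPPER).met

    def test_boundary_is_strict(self):
        ci = DiffCI(0.0, -10.0, 2.0, 0.05, CiMethod.MN_SCORE)
        assert not noninferiority_decision(ci, 10, Bound.LOWER).met


class TestSampleSize:
    def test_design_parameters_give_119_per_group(self):
        n = ni_sample_size(SampleSizeSpec(0.94, 0.94, 0.10, 0.05, 0.90))
        assert n == 119

    def test_power_half_matches_closed_form(self):
        # z_power = 0 at 50% power: n = z_{.975}^2 * 2 p q / margin^2
        spec = SampleSizeSpec(0.94, 0.94, 0.10, 0.05, 0.50)
        expected = math.ceil(norm.ppf(0.975) ** 2 * 2 * 0.94 * 0.06 / 0.01)
        assert ni_sample_size(spec) == expected

    def test_doubling_margin_quarters_n(self):
        base = SampleSizeSpec(0.94, 0.94, 0.05, 0.05, 0.90)
        n1 = ni_sample_size(base)
        n2 = ni_sample_size(SampleSizeSpec(0.94, 0.94, 0.10, 0.05, 0.90))
        raw = (norm.ppf(0.975) + norm.ppf(0.90)) ** 2 * 2 * 0.94 * 0.06
        assert n1 == math.ceil(raw / 0.05**2)
        assert n2 == math.ceil(raw / 0.10**2)

    def test_margin_not_exceeding_drift_rejected(self):
        with pytest.raises(ValueError):
            ni_sample_size(SampleSizeSpec(0.90, 0.94, 0.03))
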