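"""ROR/CI, BCPNN-IC, p-values and the composite verdict, each checked
against an independent route (closed forms, statsmodels, hypergeometric
enumeration, Monte-Carlo posterior sampling)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tnfvigil.stats import (
    bcpnn_ic,
    classify_signal,
    expected_count,
    pvalue,
    ror_with_ci,
)

cells = st.integers(min_value=0, max_value=500)


class TestROR:
    def test_independence_gives_one_symmetric_ci(self):
        ror, lo, hi, corr = ror_with_ci(10, 10, 10, 10)
        assert ror == 1.0
        assert not corr
        assert lo * hi == pytest.approx(1.0)  # symmetric on the log scale

    def test_arithmetic_oracle(self):
        a, b, c, d = 12, 8, 50, 930
        ror, lo, hi, corr = ror_with_ci(a, b, c, d)
        assert ror == pytest.approx((12 * 930) / (8 * 50))  # 27.9
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = sps.norm.ppf(0.975)
        assert lo == pytest.approx(ror * math.exp(-z * se))
        assert hi == pytest.approx(ror * math.exp(z * se))

    def test_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for a, b, c, d in [(12, 8, 50, 930), (5, 95, 40, 860), (30, 70, 20, 80)]:
            ror, lo, hi, _ = ror_with_ci(a, b, c, d)
            t = sm.Table2x2([[a, b], [c, d]])
            assert ror == pytest.approx(t.oddsratio)
            sm_lo, sm_hi = t.oddsratio_confint()
            assert lo == pytest.approx(sm_lo)
            assert hi == pytest.approx(sm_hi)

    def test_zero_cell_haldane_correction(self):
        ror, lo, hi, corr = ror_with_ci(0, 5, 5, 90)
        assert corr
        assert ror == pytest.approx((0.5 * 90.5) / (5.5 * 5.5))
        assert 0 < lo < ror < hi

    @given(a=cells, b=cells, c=cells, d=cells, k=st.integers(2, 10))
    @settings(max_examples=100, deadline=None)
    def test_scaling_invariance_and_ci_narrowing(self, a, b, c, d, k):
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 1, b + 1, c + 1, d + 1
        r1, lo1, hi1, _ = ror_with_ci(a, b, c, d)
        r2, lo2, hi2, _ = ror_with_ci(k * a, k * b, k * c, k * d)
        assert r2 == pytest.approx(r1)
        assert lo2 >= lo1 - 1e-12
        assert hi2 <= hi1 + 1e-12

    def test_bounds_bracket_estimate(self):
        ror, lo, hi, _ = ror_with_ci(7, 3, 11, 200)
        assert lo < ror < hi


class TestIC:
    def test_zero_at_exact_independence(self):
        # a = E exactly: a=b=c=d so E=(2a)^2/4a=a; the +0.5 offsets cancel
        ic, ic_lo = bcpnn_ic(10, 10, 10, 10)
        assert ic == 0.0
        assert ic_lo < 0
        ic, _ = bcpnn_ic(99.5, 99.5, 99.5, 99.5)
        assert ic == 0.0

    def test_direct_evaluation(self):
        # a=8, a+b=100, a+c=100, N=10000 -> E=1
        a, b, c, d = 8, 92, 92, 9808
        assert expected_count(a, b, c, d) == pytest.approx(1.0)
        ic, ic_lo = bcpnn_ic(a, b, c, d)
        assert ic == pytest.approx(math.log2(8.5 / 1.5))
        assert ic_lo == pytest.approx(ic - 3.3 / math.sqrt(8.5) - 2 / 8.5**1.5)

    def test_deficit_pair_negative(self):
        # a=0 with E=5: IC = log2(0.5/5.5) < 0, and the bound sits below
        a, b, c, d = 0, 100, 500, 9400
        e = expected_count(a, b, c, d)
        assert e == pytest.approx(5.0)
        ic, ic_lo = bcpnn_ic(a, b, c, d)
        assert ic == pytest.approx(math.log2(0.5 / 5.5))
        assert ic_lo < ic < 0

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=100, deadline=None)
    def test_sign_iff_observed_exceeds_expected(self, a, b, c, d):
        if a + b + c + d == 0:
            d = 1
        e = expected_count(a, b, c, d)
        ic, ic_lo = bcpnn_ic(a, b, c, d)
        assert (ic > 0) == (a > e)
        assert ic_lo < ic

    def test_closed_form_against_gamma_posterior_mc(self):
        """The Noren IC025 approximation vs Monte-Carlo quantiles of the
        Gamma(a+0.5) posterior of the observed-count intensity."""
        rng = np.random.default_rng(12345)
        for a, b, c, d in [(8, 92, 92, 9808), (25, 500, 300, 40000), (100, 900, 400, 90000)]:
            e = expected_count(a, b, c, d)
            draws = np.log2(rng.gamma(a + 0.5, size=200_000) / (e + 0.5))
            mc_lo = np.quantile(draws, 0.025)
            _, ic_lo = bcpnn_ic(a, b, c, d, variant="noren")
            _, ic_lo_exact = bcpnn_ic(a, b, c, d, variant="gamma")
            assert ic_lo_exact == pytest.approx(mc_lo, abs=0.02)
            assert ic_lo == pytest.approx(mc_lo, abs=0.1)

    def test_bate_variant_agrees_roughly_for_large_counts(self):
        ic_n, lo_n = bcpnn_ic(100, 900, 400, 90000, variant="noren")
        ic_b, lo_b = bcpnn_ic(100, 900, 400, 90000, variant="bate")
        assert ic_b == pytest.approx(ic_n, abs=0.3)
        assert lo_b == pytest.approx(lo_n, abs=0.4)

    def test_zero_n_raises(self):
        with pytest.raises(ValueError):
            bcpnn_ic(0, 0, 0, 0)


def fisher_two_sided_enumeration(a, b, c, d):
    """Brute-force hypergeometric tail: sum P(table) over all tables with
    the observed margins whose probability <= P(observed)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    rv = sps.hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


class TestPValue:
    def test_independence_statistic_zero(self):
        assert pvalue(10, 10, 10, 10, method="chi2_yates") == 1.0

    def test_row_swap_symmetry(self):
        for meth in ("chi2_yates", "fisher_exact"):
            assert pvalue(12, 8, 50, 930, method=meth) == pytest.approx(
                pvalue(50, 930, 12, 8, method=meth)
            )

    def test_fisher_equals_enumeration_small_table(self):
        assert pvalue(5, 1, 1, 5, method="fisher_exact") == pytest.approx(
            fisher_two_sided_enumeration(5, 1, 1, 5)
        )

    def test_fisher_matches_enumeration_all_margins_le_30(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(200):
            a, b, c, d = rng.integers(0, 16, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            p = pvalue(a, b, c, d, method="fisher_exact")
            assert p == pytest.approx(
                fisher_two_sided_enumeration(a, b, c, d), rel=1e-9, abs=1e-12
            ), (a, b, c, d)
            checked += 1
        assert checked > 100

    def test_auto_falls_back_to_fisher_when_expected_small(self):
        # expected a-cell = 6*6/100 < 5 -> Fisher
        a, b, c, d = 5, 1, 1, 93
        assert pvalue(a, b, c, d) == pytest.approx(
            pvalue(a, b, c, d, method="fisher_exact")
        )

    def test_degenerate_margins_give_one(self):
        assert pvalue(0, 0, 5, 5) == 1.0


class TestClassify:
    @pytest.mark.parametrize(
        "ror_lo,a,ic_lo,expected",
        [
            (1.2, 5, 0.3, True),
            (1.2, 3, 0.3, False),  # count must be strictly > 3
            (1.2, 4, 0.3, True),
            (0.9, 100, 0.5, False),
            (1.2, 5, -0.1, False),
        ],
    )
    def test_composite_criteria(self, ror_lo, a, ic_lo, expected):
        assert bool(classify_signal(ror_lo, a, ic_lo)) is expected

    def test_significance_gate(self):
        assert bool(
            classify_signal(1.2, 5, 0.3, p_adj=0.2, require_significance=True)
        ) is False
        assert bool(
            classify_signal(1.2, 5, 0.3, p_adj=0.01, require_significance=True)
        ) is True
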