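"""Unit and property tests for the 2x2 disproportionality statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from pvsignal.stats import (
    ContingencyTable,
    SignalResult,
    build_table,
    compute_signal,
    evaluate_criteria,
    ic_point,
    ic_with_ci,
    prr_with_chi2,
    ror_with_ci,
)

cells = st.integers(min_value=1, max_value=2000)


class TestBuildTable:
    def test_set_arithmetic(self):
        universe = {f"c{i}" for i in range(1, 101)}
        event = {f"c{i}" for i in range(1, 11)}
        entity = {f"c{i}" for i in range(1, 6)} | {f"c{i}" for i in range(11, 16)}
        t = build_table(event, entity, universe)
        assert (t.a, t.b, t.c, t.d) == (5, 5, 5, 85)

    def test_entity_equals_universe_degenerate_margins(self):
        universe = {"a", "b", "c"}
        t = build_table({"a"}, universe, universe)
        assert t.c == 0 and t.d == 0 and t.n == 3

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            build_table(set(), set(), set())

    def test_margins_are_event_and_entity_totals(self):
        universe = {str(i) for i in range(50)}
        event = {str(i) for i in range(0, 20)}
        entity = {str(i) for i in range(10, 25)}
        t = build_table(event, entity, universe)
        assert t.a + t.c == len(event)
        assert t.a + t.b == len(entity)


class TestROR:
    def test_symmetric_table_is_null(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(10, 10, 10, 10))
        assert ror == pytest.approx(1.0)
        # exp(+/- 1.96 * sqrt(4/10))
        assert lo == pytest.approx(math.exp(-1.96 * math.sqrt(0.4)), rel=1e-12)
        assert hi == pytest.approx(math.exp(+1.96 * math.sqrt(0.4)), rel=1e-12)
        assert lo == pytest.approx(0.29, abs=0.005)
        assert hi == pytest.approx(3.45, abs=0.01)

    def test_hand_value(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(20, 80, 100, 9800))
        assert ror == pytest.approx(24.5)
        assert lo < ror < hi

    def test_zero_cell_continuity_correction(self):
        t = ContingencyTable(0, 50, 100, 9000)
        ror, lo, hi = ror_with_ci(t)
        assert t.has_zero_cell
        assert math.isfinite(ror) and math.isfinite(lo) and math.isfinite(hi)
        assert ror == pytest.approx((0.5 * 9000.5) / (50.5 * 100.5))


class TestPRRChi2:
    def test_independence(self):
        prr, chi2 = prr_with_chi2(ContingencyTable(10, 10, 10, 10))
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)

    def test_hand_value(self):
        prr, chi2 = prr_with_chi2(ContingencyTable(20, 80, 100, 9800))
        assert prr == pytest.approx(19.8)

    def test_chi2_matches_independent_pearson(self):
        t = ContingencyTable(20, 80, 100, 9800)
        _, chi2 = prr_with_chi2(t)
        ref = chi2_contingency([[20, 80], [100, 9800]], correction=False).statistic
        assert chi2 == pytest.approx(ref, rel=1e-6)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            prr_with_chi2(ContingencyTable(0, 0, 10, 10))

    @settings(max_examples=200, deadline=None)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_chi2_identity_property(self, a, b, c, d):
        """The closed-form chi-square equals Pearson's statistic exactly."""
        _, chi2 = prr_with_chi2(ContingencyTable(a, b, c, d))
        ref = chi2_contingency([[a, b], [c, d]], correction=False).statistic
        assert chi2 == pytest.approx(ref, rel=1e-10, abs=1e-12)


class TestIC:
    def test_large_symmetric_table(self):
        ic, lo, hi = ic_with_ci(ContingencyTable(1000, 1000, 1000, 1000), 50_000, seed=5)
        assert ic == pytest.approx(0.0, abs=1e-12)
        assert lo < 0 < hi

    def test_hand_value(self):
        ic, lo, hi = ic_with_ci(ContingencyTable(20, 80, 100, 9800), 50_000, seed=5)
        assert ic == pytest.approx(math.log2(20 * 10000 / (100 * 120)), rel=1e-12)
        assert ic == pytest.approx(4.06, abs=0.005)
        assert lo < ic < hi

    def test_seeded_determinism_and_mc_convergence(self):
        t = ContingencyTable(20, 80, 100, 9800)
        r1 = ic_with_ci(t, 50_000, seed=11)
        r2 = ic_with_ci(t, 50_000, seed=11)
        assert r1 == r2
        _, lo_half, _ = ic_with_ci(t, 50_000, seed=11)
        _, lo_full, _ = ic_with_ci(t, 100_000, seed=11)
        assert abs(lo_full - lo_half) < 0.02

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            ic_with_ci(ContingencyTable(1, 1, 1, 1), 100)

    def test_posterior_mean_approaches_point_ic_for_large_counts(self):
        """E(IC) converges to the point IC as all cells scale up."""
        small = ContingencyTable(20, 80, 100, 9800)
        big = ContingencyTable(2000, 8000, 10000, 980000)
        def e_ic(t):
            ic, lo, hi = ic_with_ci(t, 100_000, seed=3)
            return (lo + hi) / 2.0
        assert abs(e_ic(big) - ic_point(big)) < abs(e_ic(small) - ic_point(small))
        assert abs(e_ic(big) - ic_point(big)) < 0.01


class TestCriteria:
    def _result(self, t, **stats):
        r = SignalResult(entity="x", table=t)
        for k, v in stats.items():
            setattr(r, k, v)
        return evaluate_criteria(r)

    def test_rare_report_count_gates_ror_and_prr(self):
        # huge ratios cannot fire with fewer than 3 event reports
        t = ContingencyTable(2, 1, 1, 10000)
        r = self._result(t, ror=5000.0, ror_lo=100.0, prr=4000.0, chi2=900.0, ic025=-1.0)
        assert not r.flag_ror and not r.flag_prr and not r.positive

    def test_strong_table_fires_all_three(self):
        r = compute_signal("x", ContingencyTable(20, 80, 100, 9800), 50_000, seed=2)
        assert r.flag_ror and r.flag_prr and r.flag_bcpnn and r.positive

    def test_null_table_is_negative(self):
        r = compute_signal("x", ContingencyTable(10, 10, 10, 10), 50_000, seed=2)
        assert not r.positive


@settings(max_examples=200, deadline=None)
@given(a=cells, b=cells, c=cells, d=cells)
def test_sign_equivalence(a, b, c, d):
    """For all-positive cells: ror>1, prr>1 and ic>0 agree (ad vs bc)."""
    t = ContingencyTable(a, b, c, d)
    ror, _, _ = ror_with_ci(t)
    prr, _ = prr_with_chi2(t)
    ic = ic_point(t)
    if a * d > b * c:
        assert ror > 1 and prr > 1 and ic > 0
    elif a * d < b * c:
        assert ror < 1 and prr < 1 and ic < 0


@settings(max_examples=50, deadline=None)
@given(a=st.integers(1, 500), b=cells, c=cells, d=cells)
def test_ror_prr_strictly_monotone_in_a(a, b, c, d):
    """More target-drug event reports strictly strengthen ROR and PRR."""
    t1, t2 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
    assert ror_with_ci(t2)[0] > ror_with_ci(t1)[0]
    assert prr_with_chi2(t2)[0] > prr_with_chi2(t1)[0]


@settings(max_examples=50, deadline=None)
@given(a=st.integers(1, 500), b=st.integers(502, 2000), c=st.integers(502, 2000),
       d=cells)
def test_ic_monotone_in_a_when_margins_dominated(a, b, c, d):
    """IC strictly increases with a while other entities dominate both
    margins (b, c > a+1) — the usual screening regime.  Without that
    condition IC is not monotone in a, since a also inflates N and both
    margins: (1,1,1,5) -> (2,1,1,5) leaves IC at exactly 1 bit."""
    t1, t2 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
    assert ic_point(t2) > ic_point(t1)
    assert ic_point(ContingencyTable(1, 1, 1, 5)) == ic_point(ContingencyTable(2, 1, 1, 5))
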