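"""ROR/PRR/chi-squared/BCPNN statistics and the triple signal rule.

Independent oracles: scipy's chi-squared on the 2x2 (Yates-corrected),
statsmodels' Table2x2 odds ratio / risk ratio with Wald intervals, and a
term-by-term re-evaluation of the BCPNN posterior moments written directly
from their definition.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency
from statsmodels.stats.contingency_tables import Table2x2

from pvsignal import (
    BcpnnPriors,
    ContingencyTable,
    DispropResult,
    SignalCriteria,
    bcpnn,
    compute_statistics,
    evaluate_signal,
    prr_with_chi2,
    raw_ic,
    ror_with_ci,
)


def bcpnn_oracle(a, b, c, d, a1=1.0, b1=1.0, al=2.0, be=2.0, g11=1.0):
    """Posterior moments evaluated term by term, independently coded."""
    n = a + b + c + d
    row, col = a + b, a + c
    g = g11 * (n + al) / (row + a1) * (n + be) / (col + b1)
    e_ic = (math.log2(a + g11) + math.log2(n + al) + math.log2(n + be)
            - math.log2(n + g) - math.log2(row + a1) - math.log2(col + b1))
    t1 = (n - a + g - g11) / ((a + g11) * (1 + n + g))
    t2 = (n - row + al - a1) / ((row + a1) * (1 + n + al))
    t3 = (n - col + be - b1) / ((col + b1) * (1 + n + be))
    v_ic = (t1 + t2 + t3) / math.log(2) ** 2
    return e_ic, v_ic


positive_tables = st.tuples(
    st.integers(1, 500), st.integers(1, 500),
    st.integers(1, 500), st.integers(1, 500),
).map(lambda t: ContingencyTable(*t))


class TestRor:
    def test_symmetric_table_is_null(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(10, 10, 10, 10))
        assert ror == 1.0 and lo < 1.0 < hi

    def test_direct_arithmetic(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(10, 20, 30, 40))
        assert ror == pytest.approx(2 / 3, abs=1e-12)
        assert lo < ror < hi

    def test_zero_cell_is_undefined(self):
        assert ror_with_ci(ContingencyTable(0, 10, 10, 10)) == (None, None, None)

    def test_haldane_correction_defines_zero_cell(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(0, 10, 10, 10), haldane=True)
        assert ror is not None and lo is not None

    def test_against_statsmodels_wald_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 1000, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            ror, lo, hi = ror_with_ci(t)
            sm = Table2x2([[t.a, t.b], [t.c, t.d]], shift_zeros=False)
            assert ror == pytest.approx(sm.oddsratio, rel=1e-12)
            sm_lo, sm_hi = sm.oddsratio_confint(0.05)
            # z=1.96 print convention vs statsmodels' exact 97.5% quantile
            assert lo == pytest.approx(sm_lo, rel=2e-4)
            assert hi == pytest.approx(sm_hi, rel=2e-4)


class TestPrrChi2:
    def test_independence_gives_unit_prr_zero_chi2(self):
        t = ContingencyTable(25, 25, 25, 25)
        for cc in (False, True):
            prr, chi2 = prr_with_chi2(t, continuity_correction=cc)
            assert prr == 1.0 and chi2 == 0.0

    def test_direct_evaluation_without_correction(self):
        prr, chi2 = prr_with_chi2(ContingencyTable(10, 20, 30, 40),
                                  continuity_correction=False)
        assert prr == pytest.approx(7 / 9, abs=5e-5)
        assert chi2 == pytest.approx(0.7937, abs=5e-5)

    def test_direct_evaluation_with_correction(self):
        _, chi2 = prr_with_chi2(ContingencyTable(10, 20, 30, 40),
                                continuity_correction=True)
        assert chi2 == pytest.approx(0.4464, abs=5e-5)

    def test_correction_term_floors_at_zero(self):
        # |ad-bc| = 2 < N/2 = 4: corrected statistic must be 0, not negative
        _, chi2 = prr_with_chi2(ContingencyTable(2, 2, 2, 2), continuity_correction=True)
        assert chi2 == 0.0

    def test_undefined_cases(self):
        prr, _ = prr_with_chi2(ContingencyTable(5, 5, 0, 10))
        assert prr is None
        _, chi2 = prr_with_chi2(ContingencyTable(0, 0, 5, 5))
        assert chi2 is None

    def test_against_scipy_yates(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 1000, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            _, chi2 = prr_with_chi2(t, continuity_correction=True)
            ref = chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=True).statistic
            assert chi2 == pytest.approx(ref, rel=1e-10, abs=1e-10)
            prr, _ = prr_with_chi2(t)
            sm = Table2x2([[t.a, t.b], [t.c, t.d]], shift_zeros=False)
            assert prr == pytest.approx(sm.riskratio, rel=1e-12)


class TestBcpnn:
    def test_symmetric_table_expectation_exactly_zero(self):
        e_ic, v_ic, ic025 = bcpnn(ContingencyTable(25, 25, 25, 25))
        assert e_ic == pytest.approx(0.0, abs=1e-14)
        assert v_ic > 0 and ic025 < 0

    def test_zero_a_is_regularized(self):
        e_ic, v_ic, _ = bcpnn(ContingencyTable(0, 10, 10, 10))
        assert math.isfinite(e_ic) and v_ic > 0

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            bcpnn(ContingencyTable(0, 0, 0, 0))

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            BcpnnPriors(alpha1=0)

    def test_moments_match_independent_term_by_term_evaluation(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 125, size=4))
            if a + b + c + d == 0:
                continue
            t = ContingencyTable(a, b, c, d)
            e_ic, v_ic, ic025 = bcpnn(t)
            e_ref, v_ref = bcpnn_oracle(a, b, c, d)
            assert e_ic == pytest.approx(e_ref, rel=1e-10, abs=1e-10)
            assert v_ic == pytest.approx(v_ref, rel=1e-10)
            assert ic025 == pytest.approx(e_ref - 2 * math.sqrt(v_ref), rel=1e-10)

    def test_expectation_converges_to_raw_ic_under_scaling(self):
        base = (12, 300, 700, 20000)
        gaps = []
        for k in (1, 10, 100, 1000):
            t = ContingencyTable(*(x * k for x in base))
            gaps.append(abs(bcpnn(t)[0] - raw_ic(t)))
        assert all(g2 < g1 for g1, g2 in zip(gaps, gaps[1:]))
        assert gaps[-1] < 1e-4


class TestProperties:
    @settings(derandomize=True, max_examples=200)
    @given(a=st.integers(1, 200), b=st.integers(1, 200), scale=st.integers(1, 50))
    def test_exchangeable_tables_are_null(self, a, b, scale):
        """a/(a+b) = c/(c+d) forces ROR = PRR = 1, raw IC = 0, chi2 = 0."""
        t = ContingencyTable(a, b, a * scale, b * scale)
        ror, _, _ = ror_with_ci(t)
        prr, chi2 = prr_with_chi2(t, continuity_correction=False)
        assert ror == pytest.approx(1.0, abs=1e-12)
        assert prr == pytest.approx(1.0, abs=1e-12)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert raw_ic(t) == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(t=positive_tables)
    def test_ror_at_least_prr_when_disproportionate(self, t):
        ror, _, _ = ror_with_ci(t)
        prr, _ = prr_with_chi2(t)
        if prr is not None and t.a / t.drug_total > t.c / (t.c + t.d):
            assert ror >= prr - 1e-12

    @settings(derandomize=True, max_examples=100)
    @given(t=positive_tables, delta=st.integers(1, 20))
    def test_monotone_in_a_with_margins_held(self, t, delta):
        """Moving mass onto the diagonal raises ROR, PRR and raw IC."""
        if t.b <= delta or t.c <= delta:
            return
        t2 = ContingencyTable(t.a + delta, t.b - delta, t.c - delta, t.d + delta)
        assert ror_with_ci(t2)[0] > ror_with_ci(t)[0]
        assert prr_with_chi2(t2)[0] > prr_with_chi2(t)[0]
        assert raw_ic(t2) > raw_ic(t)

    @settings(derandomize=True, max_examples=200)
    @given(t=positive_tables)
    def test_result_invariants(self, t):
        r = evaluate_signal(compute_statistics("d", "p", t))
        assert r.ror_ci_low <= r.ror <= r.ror_ci_high
        assert r.ic_minus_2sd <= r.ic_expected
        assert r.combined_signal == (r.ror_positive and r.prr_positive
                                     and r.bcpnn_positive)


class TestSignalRule:
    def make_result(self, **kw) -> DispropResult:
        base = dict(drug="T", pt="E", a=100, ror=5.0, ror_ci_low=4.0,
                    ror_ci_high=6.0, prr=5.0, chi2=100.0, ic_expected=2.0,
                    ic_variance=0.01, ic_minus_2sd=1.8)
        base.update(kw)
        return DispropResult(**base)

    def test_all_methods_positive_combine(self):
        r = evaluate_signal(self.make_result())
        assert r.ror_positive and r.prr_positive and r.bcpnn_positive
        assert r.combined_signal and r.intensity == "++"

    def test_min_a_is_strict(self):
        r = evaluate_signal(self.make_result(a=3, ror_ci_low=100.0))
        assert not (r.ror_positive or r.prr_positive or r.bcpnn_positive)
        r4 = evaluate_signal(self.make_result(a=4))
        assert r4.combined_signal

    def test_negative_ic025_breaks_conjunction(self):
        r = evaluate_signal(self.make_result(ic_minus_2sd=-0.01))
        assert r.ror_positive and r.prr_positive and not r.bcpnn_positive
        assert not r.combined_signal and r.intensity == "none"

    def test_undefined_statistic_means_negative_method(self):
        r = evaluate_signal(self.make_result(prr=None, chi2=None))
        assert not r.prr_positive and not r.combined_signal

    def test_intensity_grading_cut_points(self):
        assert evaluate_signal(self.make_result(ic_expected=1.2)).intensity == "+"
        assert evaluate_signal(self.make_result(ic_expected=2.0)).intensity == "++"
        assert evaluate_signal(self.make_result(ic_expected=3.5)).intensity == "+++"

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            SignalCriteria(intensity_thresholds=(3.0, 1.5))
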