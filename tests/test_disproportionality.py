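"""ROR/PRR/χ² against independent oracles; thresholds; ranking; labels."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency
from statsmodels.stats.contingency_tables import Table2x2

from pvsignal.disproportionality import (ContingencyTable, SignalResult, analyze,
                                         build_contingency, chi_square,
                                         ci_geometric_mean, compare_to_label,
                                         count_unlisted, evaluate_signal,
                                         percent_of_events, prr, rank_signals, ror)
from pvsignal.faers import CaseReport, MedDRAMap


def _case(pid, events, target=True):
    return CaseReport(primaryid=str(pid), caseid=str(pid), fda_dt="20200101",
                      event_dt="", age_years=float("nan"), sex="", occupation="",
                      country="", outcomes=frozenset(), events=frozenset(events),
                      drugs=[], therapy_starts=[], indications=frozenset(),
                      report_year=2020)


cells = st.integers(1, 500)


class TestROR:
    def test_textbook_table(self):
        est = ror(ContingencyTable(10, 90, 100, 9900))
        assert est.value == pytest.approx(11.0)
        # Woolf CI by hand
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        assert est.low == pytest.approx(11.0 * math.exp(-1.959963984540054 * se))

    def test_symmetric_table_is_null(self):
        est = ror(ContingencyTable(5, 5, 5, 5))
        assert est.value == pytest.approx(1.0)
        assert est.low * est.high == pytest.approx(1.0)   # symmetric about 1 on log scale

    @given(cells, cells, cells, cells)
    def test_matches_statsmodels_oracle(self, a, b, c, d):
        est = ror(ContingencyTable(a, b, c, d))
        oracle = Table2x2(np.array([[a, b], [c, d]]))
        assert est.value == pytest.approx(oracle.oddsratio, rel=1e-12)
        lo, hi = oracle.oddsratio_confint(0.05)
        assert est.low == pytest.approx(lo, rel=1e-9)
        assert est.high == pytest.approx(hi, rel=1e-9)

    @given(cells, cells, cells, cells)
    def test_ci_is_log_symmetric(self, a, b, c, d):
        est = ror(ContingencyTable(a, b, c, d))
        assert ci_geometric_mean(est.low, est.high) == pytest.approx(est.value, rel=1e-9)
        p = prr(ContingencyTable(a, b, c, d))
        assert ci_geometric_mean(p.low, p.high) == pytest.approx(p.value, rel=1e-9)

    def test_zero_cell_haldane_vs_skip(self):
        t = ContingencyTable(3, 97, 0, 1000)
        assert ror(t, "haldane").defined
        assert not ror(t, "skip").defined


class TestPRR:
    def test_hand_computed_table(self):
        est = prr(ContingencyTable(20, 80, 100, 9800))
        assert est.value == pytest.approx((20 / 100) / (100 / 9900))
        assert est.value == pytest.approx(19.8)

    @pytest.mark.parametrize("table", [
        ContingencyTable(1, 99, 10, 990),     # independent proportions
        ContingencyTable(5, 5, 5, 5),
    ])
    def test_null_tables(self, table):
        assert prr(table).value == pytest.approx(1.0)

    @given(cells, cells, cells, cells)
    def test_matches_statsmodels_riskratio_oracle(self, a, b, c, d):
        est = prr(ContingencyTable(a, b, c, d))
        oracle = Table2x2(np.array([[a, b], [c, d]]))
        assert est.value == pytest.approx(oracle.riskratio, rel=1e-12)
        lo, hi = oracle.riskratio_confint(0.05)
        assert est.low == pytest.approx(lo, rel=1e-9)
        assert est.high == pytest.approx(hi, rel=1e-9)

    def test_rare_event_ror_prr_concordance(self, rng):
        """When the event is rare on both arms (a ≤ b/100, c ≤ d/100) the odds
        ratio and the proportional reporting ratio agree within 5%."""
        for _ in range(300):
            b = int(rng.integers(2000, 20_000))
            d = int(rng.integers(20_000, 200_000))
            a = int(rng.integers(1, max(2, b // 100)))
            c = int(rng.integers(1, max(2, d // 100)))
            r = ror(ContingencyTable(a, b, c, d)).value
            p = prr(ContingencyTable(a, b, c, d)).value
            assert abs(r - p) / p < 0.05


class TestChiSquare:
    def test_independent_table_is_zero(self):
        assert chi_square(ContingencyTable(10, 90, 100, 900)) == pytest.approx(0.0)

    @given(cells, cells, cells, cells)
    def test_matches_scipy_pearson(self, a, b, c, d):
        stat = chi_square(ContingencyTable(a, b, c, d))
        oracle = chi2_contingency(np.array([[a, b], [c, d]]), correction=False)
        assert stat == pytest.approx(oracle.statistic, rel=1e-9, abs=1e-9)

    @given(cells, cells, cells, cells)
    def test_invariant_under_simultaneous_row_column_swap(self, a, b, c, d):
        assert chi_square(ContingencyTable(a, b, c, d)) == \
            pytest.approx(chi_square(ContingencyTable(d, c, b, a)), rel=1e-9)

    def test_yates_matches_scipy_correction(self):
        t = ContingencyTable(12, 88, 40, 960)
        oracle = chi2_contingency(np.array([[12, 88], [40, 960]]), correction=True)
        assert chi_square(t, yates=True) == pytest.approx(oracle.statistic, rel=1e-9)

    def test_zero_margin_undefined(self):
        assert math.isnan(chi_square(ContingencyTable(0, 0, 5, 5)))


class TestSignalRule:
    @pytest.mark.parametrize("a,ror_low,prr_v,chi2,expect", [
        (3, 1.001, 1.0, 0.0, (True, False, True)),    # ROR branch, lower bound just above 1
        (2, 50.0, 50.0, 100.0, (False, False, False)),  # too few reports
        (10, 0.9, 2.0, 4.0, (False, True, True)),     # PRR branch, inclusive thresholds
        (10, 1.0, 1.99, 4.0, (False, False, False)),  # ROR bound not strict, PRR below 2
        (10, 0.5, 2.0, 3.99, (False, False, False)),  # chi2 below 4
    ])
    def test_threshold_boundaries(self, a, ror_low, prr_v, chi2, expect):
        assert evaluate_signal(a, ror_low, prr_v, chi2) == expect

    def test_undefined_statistics_never_signal(self):
        nan = float("nan")
        assert evaluate_signal(10, nan, nan, nan) == (False, False, False)


class TestContingencyConstruction:
    def test_report_unit_counts(self):
        target = [_case(i, ["EVT_A"] if i < 4 else ["EVT_B"]) for i in range(10)]
        background = [_case(100 + i, ["EVT_A"] if i < 20 else ["EVT_C"])
                      for i in range(990)]
        t = build_contingency(target, background, "EVT_A")
        assert (t.a, t.b, t.c, t.d) == (4, 6, 20, 970)

    def test_soc_level_counts_reports_not_mentions(self):
        m = MedDRAMap.from_pairs([("evt_a", "SOC_X"), ("evt_b", "SOC_X")])
        target = [_case(1, ["EVT_A", "EVT_B"])]           # both PTs, one SOC
        background = [_case(2, ["EVT_A"]), _case(3, [])]
        t = build_contingency(target, background, "SOC_X", level="SOC", mapping=m)
        assert (t.a, t.b) == (1, 0)
        assert t.c == 1

    def test_event_unit_uses_mention_totals(self):
        target = [_case(1, ["EVT_A", "EVT_B"]), _case(2, ["EVT_B"])]
        background = [_case(3, ["EVT_A", "EVT_C", "EVT_D"])]
        t = build_contingency(target, background, "EVT_A", unit="event")
        assert (t.a, t.b, t.c, t.d) == (1, 2, 1, 2)

    def test_synthetic_cohort_matches_ground_truth_tallies(self, cohort):
        target, background, truth = cohort
        for pt, g in truth.planted.items():
            t = build_contingency(target, background, pt)
            assert (t.a, t.b, t.c, t.d) == (g["a"], g["b"], g["c"], g["d"])


class TestRankingAndLabel:
    def _results(self, specs):
        out = []
        for term, a, r in specs:
            out.append(SignalResult(term=term, level="PT", a=a, ror=r, ror_low=r / 2,
                                    ror_high=r * 2, prr=r, prr_low=r / 2, prr_high=r * 2,
                                    chi2=10.0, ror_signal=True, prr_signal=True,
                                    signal=True, pct=0.0))
        return out

    def test_frequency_order_preserved(self):
        res = self._results([("anaemia", 99, 4.45), ("cardiac failure", 82, 8.88),
                             ("condition aggravated", 79, 2.39)])
        ranked = rank_signals(res, by="frequency", k=30)
        assert [r.term for r in ranked] == \
            ["anaemia", "cardiac failure", "condition aggravated"]

    def test_strength_tiebreak_on_frequency_then_term(self):
        res = self._results([("b", 5, 9.0), ("a", 5, 5.0), ("c", 9, 5.0)])
        ranked = rank_signals(res, by="strength")
        assert [r.term for r in ranked] == ["b", "c", "a"]

    def test_k_zero_and_k_beyond_available(self):
        res = self._results([("a", 5, 2.0)])
        assert rank_signals(res, k=0) == []
        assert len(rank_signals(res, k=10)) == 1

    def test_label_comparison_counts_unlisted(self):
        res = self._results([("anaemia", 9, 2.0), ("fall", 8, 2.0),
                             ("tachycardia", 7, 2.0)])
        flagged = compare_to_label(res, {"Anaemia", "TACHYCARDIA"})
        assert count_unlisted(flagged) == 1
        all_listed = compare_to_label(res, {r.term for r in res})
        assert count_unlisted(all_listed) == 0

    def test_withholding_k_terms_from_label_yields_k_unlisted(self, cohort):
        target, background, _ = cohort
        results = analyze(target, background)
        top = rank_signals(results, by="frequency", k=30)
        withheld = {r.term for r in top[:2]}
        label = {r.term for r in results} - withheld
        flagged = compare_to_label(top, label)
        assert count_unlisted(flagged) == len(withheld & {r.term for r in top})


class TestPercent:
    @pytest.mark.parametrize("a,total,expect", [
        (99, 7134, 1.39), (0, 7134, 0.0), (7134, 7134, 100.0)])
    def test_share_of_events(self, a, total, expect):
        assert percent_of_events(a, total) == pytest.approx(expect)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent_of_events(1, 0)


class TestAnalyze:
    def test_recovers_planted_signals_and_not_null(self, cohort):
        target, background, truth = cohort
        results = {r.term: r for r in analyze(target, background)}
        for pt, g in truth.planted.items():
            if g["true_ror"] > 1 and g["a"] >= 3:
                assert results[pt].signal, pt
        null = results["Headache"]               # planted true_ror = 1
        assert not null.ror_signal or null.ror_low < 1.5

    def test_min_a_monotonicity(self, cohort):
        target, background, _ = cohort
        n3 = sum(r.signal for r in analyze(target, background, min_a=3))
        n4 = sum(r.signal for r in analyze(target, background, min_a=4))
        n6 = sum(r.signal for r in analyze(target, background, min_a=6))
        assert n6 <= n4 <= n3

    def test_soc_a_never_exceeds_cohort_size(self, cohort):
        from pvsignal.synthetic import synthetic_meddra_map
        target, background, _ = cohort
        for r in analyze(target, background, level="SOC",
                         mapping=synthetic_meddra_map()):
            assert r.a <= len(target)
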