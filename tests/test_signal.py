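"""Contingency construction, ROR, Woolf CI, z-test and threshold filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rorscreen import (
    ContingencyTable,
    DegenerateTableError,
    apply_min_count_filter,
    build_contingency,
    generate,
    reference_screen_config,
    ror,
    round_half_up,
    screen,
    screen_from_counts,
    woolf_ci,
    z_p_value,
)
from rorscreen.signal import SignalResult

# Drug-level counts from a published FAERS thyroid-cancer screen
# (2004-2024Q1): (a, b) per drug plus the all-drugs totals.
TOTAL_EVENT, TOTAL_OTHER = 14370, 25925016
TIRZEPATIDE = ContingencyTable(37, 31928, TOTAL_EVENT - 37, TOTAL_OTHER - 31928)
METFORMIN = ContingencyTable(17, 53172, TOTAL_EVENT - 17, TOTAL_OTHER - 53172)
TOPIRAMATE = ContingencyTable(14, 34652, TOTAL_EVENT - 14, TOTAL_OTHER - 34652)

positive_tables = st.builds(
    ContingencyTable,
    st.integers(1, 500), st.integers(1, 100_000),
    st.integers(1, 20_000), st.integers(1, 10_000_000),
)


def brute_force_table(reports, drug, term_set, comparator="exclusive"):
    """Independent O(n*m) enumeration of the 2x2 cells."""
    a = b = c = d = 0
    composite = {t.lower() for t in term_set.composite_terms}
    for report in reports:
        has_drug = any(ingredient == drug for ingredient, _ in report.drugs)
        has_event = False
        for pt in report.events:
            if pt.lower() in composite:
                has_event = True
        if has_drug and has_event:
            a += 1
        elif has_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    if comparator == "inclusive":
        c, d = a + c, b + d
    return ContingencyTable(a, b, c, d)


class TestContingency:
    def test_toy_enumeration(self, toy_reports, term_set):
        table = build_contingency(toy_reports, "D", term_set)
        assert (table.a, table.b, table.c, table.d) == (1, 1, 1, 3)

    def test_absent_drug_gives_empty_row(self, toy_reports, term_set):
        table = build_contingency(toy_reports, "nonexistent", term_set)
        assert (table.a, table.b) == (0, 0)
        assert table.c + table.d == len(toy_reports)

    def test_matches_brute_force_on_synthetic(self, term_set):
        cfg = reference_screen_config(seed=13, n_reports=500)
        reports, _ = generate(cfg)
        for spec in cfg.drugs[:5]:
            assert build_contingency(reports, spec.name, term_set) == \
                brute_force_table(reports, spec.name, term_set)

    def test_inclusive_comparator_keeps_totals(self, toy_reports, term_set):
        table = build_contingency(toy_reports, "D", term_set, comparator="inclusive")
        assert (table.c, table.d) == (2, 4)

    def test_each_report_in_exactly_one_cell(self, toy_reports, term_set):
        table = build_contingency(toy_reports, "D", term_set)
        assert table.n == len(toy_reports)


class TestStatistics:
    def test_tirzepatide_published_values(self):
        assert round_half_up(ror(TIRZEPATIDE)) == 2.09
        low, high = woolf_ci(TIRZEPATIDE)
        assert round_half_up(high) == 2.89

    def test_metformin_published_values(self):
        assert round_half_up(ror(METFORMIN)) == 0.58
        low, high = woolf_ci(METFORMIN)
        assert (round_half_up(low), round_half_up(high)) == (0.36, 0.93)
        assert round_half_up(z_p_value(METFORMIN)) == 0.02

    def test_topiramate_published_values(self):
        assert round_half_up(ror(TOPIRAMATE)) == 0.73
        low, high = woolf_ci(TOPIRAMATE)
        assert (round_half_up(low), round_half_up(high)) == (0.43, 1.23)

    def test_balanced_table_has_unit_ror(self):
        table = ContingencyTable(5, 50, 10, 100)
        assert ror(table) == pytest.approx(1.0)
        assert z_p_value(table) == pytest.approx(1.0)

    def test_against_statsmodels(self):
        """Cross-check point estimate and CI against an independent implementation."""
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for table in (TIRZEPATIDE, METFORMIN, ContingencyTable(3, 7, 11, 13)):
            ref = sm.Table2x2(np.array([[table.a, table.b], [table.c, table.d]]))
            assert ror(table) == pytest.approx(ref.oddsratio)
            assert woolf_ci(table) == pytest.approx(ref.oddsratio_confint())

    def test_alpha_near_one_collapses_ci(self):
        low, high = woolf_ci(METFORMIN, alpha=1 - 1e-12)
        assert low == pytest.approx(ror(METFORMIN), rel=1e-5)
        assert high == pytest.approx(ror(METFORMIN), rel=1e-5)

    def test_zero_cell_raises_without_correction(self):
        table = ContingencyTable(0, 10, 5, 100)
        with pytest.raises(DegenerateTableError):
            ror(table)
        assert ror(table, correction=True) == pytest.approx(
            (0.5 * 100.5) / (10.5 * 5.5))

    @given(positive_tables)
    @settings(deadline=None)
    def test_inversion_symmetry(self, table):
        """Swapping the rows maps ROR -> 1/ROR and swaps/inverts the CI."""
        swapped = table.swap_rows()
        assert ror(swapped) == pytest.approx(1.0 / ror(table))
        low, high = woolf_ci(table)
        slow, shigh = woolf_ci(swapped)
        assert (slow, shigh) == (pytest.approx(1 / high), pytest.approx(1 / low))

    @given(positive_tables, st.sampled_from([0.01, 0.05, 0.1]))
    @settings(deadline=None)
    def test_p_value_ci_consistency(self, table, alpha):
        """p < alpha iff 1 lies outside the (1 - alpha) CI."""
        low, high = woolf_ci(table, alpha=alpha)
        p = z_p_value(table)
        assert (p < alpha) == (not low <= 1.0 <= high)

    @given(positive_tables)
    @settings(deadline=None)
    def test_monotonicity_in_a(self, table):
        bigger = ContingencyTable(table.a + 1, table.b, table.c, table.d)
        assert ror(bigger) > ror(table)

    def test_se_shrinks_with_any_cell(self):
        from rorscreen.signal import log_ror_se
        table = ContingencyTable(5, 10, 15, 20)
        for grown in (ContingencyTable(6, 10, 15, 20), ContingencyTable(5, 11, 15, 20),
                      ContingencyTable(5, 10, 16, 20), ContingencyTable(5, 10, 15, 21)):
            assert log_ror_se(grown) < log_ror_se(table)


class TestThresholdAndScreen:
    def test_min_count_boundary(self):
        results = [SignalResult(drug=f"d{a}", table=ContingencyTable(a, 10, 100, 1000))
                   for a in (4, 5, 6)]
        flagged = apply_min_count_filter(results, k=5)
        assert [r.excluded for r in flagged] == [True, False, False]
        assert flagged[0].reason == "below-min-count"
        assert flagged[0].ror is None

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            apply_min_count_filter([], k=0)

    def test_screen_order_and_exclusions(self, term_set):
        cfg = reference_screen_config(seed=3, n_reports=4000)
        reports, _ = generate(cfg)
        drugs = ["liraglutide", "orlistat", "metformin"]
        results = screen(reports, drugs, term_set)
        assert [r.drug for r in results] == drugs
        for r in results:
            assert r.excluded == (r.table.a < 5)
            if not r.excluded:
                assert r.ci_low <= r.ror <= r.ci_high

    def test_screen_empty_reports_errors(self, term_set):
        with pytest.raises(ValueError):
            screen([], ["metformin"], term_set)

    def test_zero_report_drug_excluded(self, toy_reports, term_set):
        result = screen(toy_reports, ["absent-drug"], term_set)[0]
        assert result.excluded and result.reason == "below-min-count"

    def test_embedded_signal_has_largest_ror(self, term_set):
        """With one large embedded multiplier, that drug tops the retained RORs."""
        from rorscreen.synthetic import DrugSpec, SyntheticConfig
        drugs = tuple([DrugSpec("hit", 0.02, 8.0)] +
                      [DrugSpec(f"null{i}", 0.02, 1.0) for i in range(4)])
        cfg = SyntheticConfig(seed=5, n_reports=60_000, drugs=drugs, p0=0.01,
                              duplication_rate=0.0)
        reports, _ = generate(cfg)
        results = screen(reports, [d.name for d in drugs], term_set)
        retained = {r.drug: r.ror for r in results if not r.excluded}
        assert max(retained, key=retained.get) == "hit"

    def test_from_counts_matches_direct_tables(self):
        results = screen_from_counts({"tirzepatide": (37, 31928)},
                                     TOTAL_EVENT, TOTAL_OTHER)
        assert results[0].table == TIRZEPATIDE
        assert round_half_up(results[0].ror) == 2.09


def test_round_half_up_at_exact_halves():
    assert round_half_up(2.085) == 2.09
    assert round_half_up(0.725) == 0.73
    assert round_half_up(1.0) == 1.0
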