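"""Contingency construction, stratification, Mantel-Haenszel, ranking."""
from __future__ import annotations

import numpy as np
import pytest

from pvsignals import (
    ContingencyTable,
    DrugQuery,
    EventQuery,
    NotEstimableError,
    ReportSet,
    StratumTable,
    build_table,
    flag_cases,
    mantel_haenszel_or,
    mantel_haenszel_rr,
    rank_events,
    stratify,
)
from pvsignals.signal_stats import ebgm_rrr, prr, ror

from conftest import TARGET_DRUG, TARGET_EVENT, make_report, random_report_set


def brute_force_cells(reports, drug: DrugQuery, event: EventQuery):
    """Independent oracle: classify each report one at a time."""
    a = b = c = d = 0
    for r in reports:
        exposed = bool(drug.names & r.drugs)
        has_event = bool(event.names & {x.upper() for x in r.reactions})
        if exposed and has_event:
            a += 1
        elif exposed:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return a, b, c, d


class TestContingencyTable:
    def test_margins_consistent(self):
        t = ContingencyTable(1, 2, 3, 4)
        assert t.n == 10
        assert t.drug_total == 3 and t.event_total == 4
        assert t.other_drug_total == 7 and t.other_event_total == 6

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)

    def test_frame_layout_matches_margins(self, crude_table):
        frame = crude_table.to_frame()
        assert frame.loc["Total", "Total"] == 7_524_973
        assert frame.loc["Target drug", "Total"] == 11_696


class TestFlagging:
    def test_flags_for_known_reports(self, drug_query, event_query):
        hit = make_report(1, 1, drugs=("GATTEX", "OMEPRAZOLE"), reactions=("Pancreatitis",))
        miss = make_report(2, 2, drugs=("ASPIRIN",), reactions=("Nausea",))
        flags = flag_cases([hit, miss], drug_query, event_query)
        assert flags == [(True, True), (False, False)]

    def test_event_match_is_exact_not_substring(self, drug_query):
        r = make_report(1, 1, drugs=("GATTEX",), reactions=("Pancreatitis acute",))
        q = EventQuery(["Pancreatitis"])
        assert flag_cases([r], drug_query, q) == [(True, False)]

    def test_duplicated_drug_rows_count_once(self, drug_query, event_query):
        # drugs are a set: a report listing the target twice is still one case
        r = make_report(1, 1, drugs=("GATTEX", "Gattex "), reactions=("Pancreatitis",))
        table = build_table([r], drug_query, event_query)
        assert table.cells() == (1, 0, 0, 0)


class TestBuildTable:
    def test_empty_report_set_gives_zero_table(self, drug_query, event_query):
        assert build_table(ReportSet([], []), drug_query, event_query).cells() == (0, 0, 0, 0)

    def test_six_report_toy_set_matches_enumeration(self, drug_query, event_query):
        reports = [
            make_report(1, 1, drugs=("GATTEX",), reactions=("Pancreatitis",)),
            make_report(2, 2, drugs=("GATTEX",), reactions=("Nausea",)),
            make_report(3, 3, drugs=("TEDUGLUTIDE",), reactions=("Pancreatitis", "Rash")),
            make_report(4, 4, drugs=("ASPIRIN",), reactions=("Pancreatitis",)),
            make_report(5, 5, drugs=("ASPIRIN",), reactions=("Rash",)),
            make_report(6, 6, drugs=("METFORMIN",), reactions=("Nausea",)),
        ]
        table = build_table(reports, drug_query, event_query)
        assert table.cells() == (2, 1, 1, 2)
        assert table.cells() == brute_force_cells(reports, drug_query, event_query)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_oracle_equivalence_on_random_sets(self, seed, drug_query, event_query):
        rs = random_report_set(100, seed=seed)
        table = build_table(rs, drug_query, event_query)
        assert table.cells() == brute_force_cells(rs, drug_query, event_query)
        assert table.n == len(rs)


class TestStratify:
    @pytest.mark.parametrize("axis", ["sex", "age"])
    @pytest.mark.parametrize("seed", [10, 11])
    def test_strata_partition_the_crude_table(self, axis, seed, drug_query, event_query):
        rs = random_report_set(200, seed=seed)
        strata = stratify(rs, drug_query, event_query, by=axis)
        total = ContingencyTable(0, 0, 0, 0)
        for s in strata:
            total = total + s.table
        assert total == build_table(rs, drug_query, event_query)

    def test_sex_levels_and_age_bins_are_fixed(self, drug_query, event_query):
        rs = random_report_set(50, seed=1)
        sex_labels = [s.label for s in stratify(rs, drug_query, event_query, by="sex")]
        assert sex_labels == ["Female", "Male", "Unspecified sex"]
        age_labels = [s.label for s in stratify(rs, drug_query, event_query, by="age")]
        assert age_labels == ["Less than 18", "18-24", "25-64", "65 and older", "Unspecified age"]

    def test_age_bin_edges_are_left_closed(self, drug_query, event_query):
        reports = [
            make_report(i, i, age=age, drugs=("GATTEX",), reactions=("Pancreatitis",))
            for i, age in enumerate([17.99, 18.0, 24.99, 25.0, 64.99, 65.0])
        ]
        strata = {s.label: s.table.a for s in stratify(reports, drug_query, EventQuery(["Pancreatitis"]), by="age")}
        assert strata == {
            "Less than 18": 1,
            "18-24": 2,
            "25-64": 2,
            "65 and older": 1,
            "Unspecified age": 0,
        }

    def test_single_stratum_degenerate_input(self, drug_query, event_query):
        rs = random_report_set(40, seed=2)
        all_female = ReportSet(
            [make_report(r.primaryid, r.caseid, sex="female", age=r.age_years,
                         drugs=r.drugs, reactions=r.reactions) for r in rs],
            rs.provenance,
        )
        strata = stratify(all_female, drug_query, event_query, by="sex")
        assert strata[0].table == build_table(all_female, drug_query, event_query)
        assert strata[1].table.n == 0 and strata[2].table.n == 0

    def test_unknown_axis_rejected(self, drug_query, event_query):
        with pytest.raises(ValueError):
            stratify(ReportSet([], []), drug_query, event_query, by="weight")


class TestMantelHaenszel:
    def test_golden_sex_strata(self, sex_strata):
        assert round(mantel_haenszel_or(sex_strata), 2) == 3.69
        assert round(mantel_haenszel_rr(sex_strata), 2) == 3.67

    def test_golden_age_strata(self, age_strata):
        assert round(mantel_haenszel_or(age_strata), 2) == 3.55
        assert round(mantel_haenszel_rr(age_strata), 2) == 3.53

    def test_single_stratum_collapses_to_crude(self, crude_table):
        strata = [StratumTable("all", crude_table)]
        assert mantel_haenszel_or(strata) == pytest.approx(
            ror(crude_table).value, rel=1e-12
        )
        assert mantel_haenszel_rr(strata) == pytest.approx(
            prr(crude_table).value, rel=1e-12
        )

    def test_identical_strata_preserve_homogeneous_ratio(self, crude_table):
        strata = [StratumTable("s1", crude_table), StratumTable("s2", crude_table)]
        assert mantel_haenszel_rr(strata) == pytest.approx(prr(crude_table).value, rel=1e-12)
        assert mantel_haenszel_or(strata) == pytest.approx(ror(crude_table).value, rel=1e-12)

    def test_empty_strata_skipped(self, crude_table):
        strata = [StratumTable("empty", ContingencyTable(0, 0, 0, 0)),
                  StratumTable("all", crude_table)]
        assert mantel_haenszel_or(strata) == pytest.approx(ror(crude_table).value, rel=1e-12)

    def test_zero_denominator_not_estimable(self):
        strata = [StratumTable("s", ContingencyTable(5, 0, 0, 5))]
        with pytest.raises(NotEstimableError):
            mantel_haenszel_or(strata)

    def test_matches_statsmodels_on_random_strata(self):
        # independent implementation check on dense random strata
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        rng = np.random.default_rng(42)
        for _ in range(20):
            strata = [
                StratumTable(str(i), ContingencyTable(*rng.integers(1, 50, size=4)))
                for i in range(rng.integers(2, 5))
            ]
            stacked = np.array(
                [[[s.table.a, s.table.b], [s.table.c, s.table.d]] for s in strata]
            ).transpose(1, 2, 0)
            expected = sm.StratifiedTable(stacked.astype(float)).oddsratio_pooled
            assert mantel_haenszel_or(strata) == pytest.approx(expected, rel=1e-10)


class TestRankEvents:
    def test_count_ordering(self, drug_query):
        reports = []
        pid = 0
        for _ in range(30):
            pid += 1
            reports.append(make_report(pid, pid, drugs=("GATTEX",), reactions=("X event",)))
        for _ in range(10):
            pid += 1
            reports.append(make_report(pid, pid, drugs=("GATTEX",), reactions=("Y event",)))
        ranked = rank_events(reports, drug_query, top_k=2)
        assert [(name, n) for name, n, _ in ranked] == [("X event", 30), ("Y event", 10)]

    def test_top_k_larger_than_vocabulary_returns_all(self, drug_query):
        reports = [
            make_report(1, 1, drugs=("GATTEX",), reactions=("Nausea", "Rash")),
            make_report(2, 2, drugs=("GATTEX",), reactions=("Nausea",)),
        ]
        ranked = rank_events(reports, drug_query, top_k=50)
        assert len(ranked) == 2

    def test_ties_broken_alphabetically(self, drug_query):
        reports = [
            make_report(1, 1, drugs=("GATTEX",), reactions=("Zeta", "Alpha")),
        ]
        ranked = rank_events(reports, drug_query, top_k=2)
        assert [name for name, _, _ in ranked] == ["Alpha", "Zeta"]

    @pytest.mark.parametrize("seed", [5, 6])
    def test_matches_brute_force_per_term_tables(self, seed, drug_query):
        rs = random_report_set(50, seed=seed)
        ranked = rank_events(rs, drug_query, top_k=3)
        n = len(rs)
        exposed = [bool(drug_query.names & r.drugs) for r in rs]
        n_exp = sum(exposed)
        for name, count, stats in ranked:
            a = sum(
                1
                for r, e in zip(rs, exposed)
                if e and name.upper() in {x.upper() for x in r.reactions}
            )
            c = sum(
                1
                for r, e in zip(rs, exposed)
                if not e and name.upper() in {x.upper() for x in r.reactions}
            )
            assert count == a
            expected_table = ContingencyTable(a, n_exp - a, c, n - n_exp - c)
            assert stats.ebgm == pytest.approx(ebgm_rrr(expected_table), rel=1e-12)

    def test_top_k_must_be_positive(self, drug_query):
        with pytest.raises(ValueError):
            rank_events([], drug_query, top_k=0)
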