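import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amubench.ddd_catalog import AgeCategory
from amubench.errors import JournalParseError, SchemaError, ValidationError
from amubench.journal import (
    PlausibilityRules,
    ValidationReport,
    apply_continuity_filter,
    apply_entry_lag_filter,
    apply_plausibility_filter,
    apply_window_filter,
    load_census,
    load_journal,
)

from .conftest import make_record

HEADER = "event_id,farm_id,age_category,substance,amount_mg,n_animals,n_days,application_date,entry_date\n"


def write_journal(tmp_path, rows, name="journal.csv"):
    path = tmp_path / name
    path.write_text(HEADER + "".join(r + "\n" for r in rows))
    return path


class TestLoadJournal:
    def test_one_record_per_row(self, tmp_path):
        path = write_journal(
            tmp_path,
            [
                "E1,F1,weaned_piglet,amoxicillin,5000,20,3,2019-03-01,2019-03-02",
                "E2,F1,weaned_piglet,colistin,300,10,2,2019-04-01,2019-04-03",
                "E3,F2,fattening_pig,doxycycline,9000,30,5,2019-05-01,2019-05-01",
            ],
        )
        records = load_journal(path)
        assert len(records) == 3
        assert records[0].n_animals == 20
        assert records[2].age_category is AgeCategory.FATTENING_PIG

    def test_combination_rows_merge_into_one_record(self, tmp_path):
        path = write_journal(
            tmp_path,
            [
                "E1,F1,weaned_piglet,trimethoprim,1000,10,2,2019-03-01,2019-03-02",
                "E1,F1,weaned_piglet,sulfadimidine,5000,10,2,2019-03-01,2019-03-02",
            ],
        )
        records = load_journal(path)
        assert len(records) == 1
        assert records[0].substances == (
            ("trimethoprim", 1000.0),
            ("sulfadimidine", 5000.0),
        )

    def test_zero_animals_is_row_error(self, tmp_path):
        path = write_journal(
            tmp_path, ["E1,F1,weaned_piglet,amoxicillin,5000,0,3,2019-03-01,2019-03-02"]
        )
        with pytest.raises(JournalParseError) as excinfo:
            load_journal(path)
        assert excinfo.value.row_errors[0][0] == 0

    def test_errors_collected_not_dropped(self, tmp_path):
        path = write_journal(
            tmp_path,
            [
                "E1,F1,weaned_piglet,amoxicillin,5000,20,3,2019-03-01,2019-03-02",
                "E2,F1,weaned_piglet,amoxicillin,-1,20,3,2019-03-01,2019-03-02",
                "E3,F1,weaned_piglet,amoxicillin,5000,20,3,not-a-date,2019-03-02",
            ],
        )
        records, errors = load_journal(path, collect_errors=True)
        assert len(records) == 1
        assert sorted(i for i, _ in errors) == [1, 2]

    def test_mismatched_merge_fields_is_error(self, tmp_path):
        path = write_journal(
            tmp_path,
            [
                "E1,F1,weaned_piglet,trimethoprim,1000,10,2,2019-03-01,2019-03-02",
                "E1,F1,weaned_piglet,sulfadimidine,5000,12,2,2019-03-01,2019-03-02",
            ],
        )
        with pytest.raises(JournalParseError):
            load_journal(path)

    def test_entry_before_application_is_error(self, tmp_path):
        path = write_journal(
            tmp_path, ["E1,F1,weaned_piglet,amoxicillin,5000,20,3,2019-03-05,2019-03-01"]
        )
        with pytest.raises(JournalParseError):
            load_journal(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("event_id,farm_id\nE1,F1\n")
        with pytest.raises(SchemaError):
            load_journal(path)


class TestEntryLagFilter:
    def test_lag_of_exactly_seven_days_kept(self):
        kept, report = apply_entry_lag_filter([make_record(lag_days=7)])
        assert len(kept) == 1
        assert report.n_rejected == 0

    def test_lag_of_eight_days_rejected(self):
        kept, report = apply_entry_lag_filter([make_record(lag_days=8)])
        assert kept == []
        assert report.rejected == [(0, "entry_lag")]

    def test_empty_input(self):
        kept, report = apply_entry_lag_filter([])
        assert kept == []
        assert report.n_input == 0

    def test_order_preserved(self):
        records = [make_record(event_id=f"E{i}", lag_days=i % 3) for i in range(6)]
        kept, _ = apply_entry_lag_filter(records)
        assert [r.event_id for r in kept] == [f"E{i}" for i in range(6)]


class TestWindowFilter:
    def test_out_of_window_rejected(self):
        start, end = dt.date(2018, 10, 1), dt.date(2019, 9, 30)
        inside = make_record(application_date=dt.date(2019, 1, 1))
        outside = make_record(event_id="E2", application_date=dt.date(2019, 10, 1))
        kept, report = apply_window_filter([inside, outside], start, end)
        assert [r.event_id for r in kept] == ["E1"]
        assert report.rejected == [(1, "out_of_window")]

    def test_window_bounds_inclusive(self):
        start, end = dt.date(2018, 10, 1), dt.date(2019, 9, 30)
        records = [
            make_record(event_id="A", application_date=start),
            make_record(event_id="B", application_date=end),
        ]
        kept, _ = apply_window_filter(records, start, end)
        assert len(kept) == 2


class TestPlausibilityFilter:
    def test_duration_cap(self):
        # a 400-day treatment under a 365-day cap is an entry error
        rec = make_record(n_days=400, substances=(("amoxicillin", 1e6),))
        kept, report = apply_plausibility_filter([rec])
        assert kept == []
        assert report.rejected == [(0, "duration")]

    def test_animal_cap(self):
        rec = make_record(n_animals=30_000, substances=(("amoxicillin", 1e6),))
        _, report = apply_plausibility_filter([rec])
        assert report.rejected == [(0, "animals")]

    def test_dose_exactly_at_ddd_kept(self, catalog):
        # per-day dose per animal = ddd x SW exactly: well within the x10 cap
        amount = 20.0 * 12.0 * 20 * 3
        rec = make_record(substances=(("amoxicillin", amount),))
        kept, report = apply_plausibility_filter([rec], catalog=catalog)
        assert len(kept) == 1 and report.n_rejected == 0

    def test_dose_twenty_fold_rejected(self, catalog):
        # implied per-day dose = amount / (animals x days x SW) = 20 x ddd > 10 x ddd
        amount = 20 * (20.0 * 12.0 * 20 * 3)
        rec = make_record(substances=(("amoxicillin", amount),))
        _, report = apply_plausibility_filter([rec], catalog=catalog)
        assert report.rejected == [(0, "dose")]

    def test_unknown_substance_rejected_not_crash(self, catalog):
        rec = make_record(substances=(("tylosin", 100.0),))
        kept, report = apply_plausibility_filter([rec], catalog=catalog)
        assert kept == []
        assert report.rejected == [(0, "unknown_substance")]

    def test_dose_rule_inactive_without_catalog(self):
        rec = make_record(substances=(("tylosin", 1e9),))
        kept, report = apply_plausibility_filter([rec])
        assert len(kept) == 1


class TestContinuityFilter:
    def test_uncensused_and_noncontinuous_rejected(self, census):
        census.continuous[("F2", AgeCategory.WEANED_PIGLET)] = False
        records = [
            make_record(farm_id="F1"),
            make_record(event_id="E2", farm_id="F2"),
            make_record(event_id="E3", farm_id="F9"),
        ]
        kept, report = apply_continuity_filter(records, census)
        assert [r.event_id for r in kept] == ["E1"]
        assert dict(report.rejected) == {1: "not_continuous", 2: "not_censused"}


class TestLoadCensus:
    def test_basic(self, tmp_path):
        path = tmp_path / "census.csv"
        path.write_text(
            "farm_id,age_category,animals_per_year,continuous_recording\n"
            "F1,weaned_piglet,2000,true\n"
            "F1,fattening_pig,1050,true\n"
            "F2,lactating_sow,22,false\n"
        )
        census = load_census(path)
        assert len(census) == 3
        assert census.animals_per_year("F1", AgeCategory.WEANED_PIGLET) == 2000
        assert census.animals_per_year("F2", AgeCategory.LACTATING_SOW) == 22
        assert not census.is_continuous("F2", AgeCategory.LACTATING_SOW)

    def test_duplicate_pair_rejected(self, tmp_path):
        path = tmp_path / "census.csv"
        path.write_text(
            "farm_id,age_category,animals_per_year,continuous_recording\n"
            "F1,weaned_piglet,2000,true\n"
            "F1,weaned_piglet,1800,true\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            load_census(path)

    def test_nonpositive_count_rejected(self, tmp_path):
        path = tmp_path / "census.csv"
        path.write_text(
            "farm_id,age_category,animals_per_year,continuous_recording\n"
            "F1,weaned_piglet,0,true\n"
        )
        with pytest.raises(ValidationError):
            load_census(path)


class TestReportInvariants:
    def test_report_conservation_enforced(self):
        with pytest.raises(ValidationError):
            ValidationReport(n_input=3, n_kept=1, rejected=[(0, "x")])

    @given(
        lags=st.lists(st.integers(min_value=0, max_value=30), max_size=40),
        max_lag=st.integers(min_value=0, max_value=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_lag_filter_conserves_counts(self, lags, max_lag):
        records = [make_record(event_id=f"E{i}", lag_days=lag) for i, lag in enumerate(lags)]
        kept, report = apply_entry_lag_filter(records, max_lag)
        assert report.n_input == report.n_kept + report.n_rejected == len(records)
        assert len(kept) == report.n_kept

    @given(
        lags=st.lists(st.integers(min_value=0, max_value=30), max_size=25),
        days=st.lists(st.integers(min_value=1, max_value=500), max_size=25),
    )
    @settings(max_examples=50, deadline=None)
    def test_filters_commute_on_single_violation_records(self, lags, days):
        # each record violates at most one rule: either late entry or over-long
        n = min(len(lags), len(days))
        records = []
        for i in range(n):
            if lags[i] > 7:
                records.append(make_record(event_id=f"L{i}", lag_days=lags[i], n_days=1))
            else:
                records.append(make_record(event_id=f"D{i}", lag_days=0, n_days=days[i]))
        rules = PlausibilityRules(max_days=365)
        a1, _ = apply_entry_lag_filter(records)
        a2, _ = apply_plausibility_filter(a1, rules)
        b1, _ = apply_plausibility_filter(records, rules)
        b2, _ = apply_entry_lag_filter(b1)
        assert [r.event_id for r in a2] == [r.event_id for r in b2]
        assert len(a2) <= len(records)
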