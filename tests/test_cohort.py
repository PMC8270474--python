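import numpy as np
import pandas as pd
import pytest

import diseasemap as dm
from diseasemap.cohort import (CohortInputError, DataConsistencyError, bin_period,
                               classify_subsite, drop_zero_expected)

from conftest import toy_cases, toy_pops


class TestSubsite:
    @pytest.mark.parametrize("code,expected", [
        ("C160", "cardia"),
        ("C169", "unspecified"),
        ("C163", "non_cardia"),
        ("C161", "non_cardia"),
        ("C168", "non_cardia"),
    ])
    def test_classification(self, code, expected):
        assert classify_subsite(code) == expected

    def test_invalid_code_named_in_error(self):
        with pytest.raises(CohortInputError, match="C167"):
            classify_subsite("C167")

    def test_every_valid_code_assigned_exactly_one_class(self):
        classes = [classify_subsite(c) for c in dm.TOPOGRAPHY_CODES]
        assert len(classes) == 9
        assert set(classes) == {"cardia", "non_cardia", "unspecified"}
        assert classes.count("cardia") == 1
        assert classes.count("unspecified") == 1


class TestPeriods:
    @pytest.mark.parametrize("year,label", [
        (1996, "1992-1996"), (2012, "2012-2016"), (1992, "1992-1996"),
        (2016, "2012-2016"), (2003, "2002-2006"),
    ])
    def test_default_scheme(self, year, label):
        assert bin_period(year) == label

    def test_year_outside_window_errors(self):
        with pytest.raises(CohortInputError, match="1991"):
            bin_period(1991)


class TestAggregate:
    def test_simple_counting_with_zero_region(self):
        cases = toy_cases([("A", "M", "<35", 1995, "C160")] * 3)
        table = dm.aggregate_counts(cases, ["A", "B"])
        assert list(table.Y) == [3, 0]

    def test_subsite_filter_uses_classification(self):
        cases = toy_cases([("A", "M", "<35", 1995, "C160"),
                           ("A", "M", "<35", 1995, "C160"),
                           ("A", "F", "85+", 1995, "C169")])
        table = dm.aggregate_counts(cases, ["A"], subsite="cardia")
        assert list(table.Y) == [2]

    def test_period_partition_conserves_totals(self):
        rows = [("A", "M", "<35", y, "C164") for y in (1992, 1999, 2004, 2011, 2016)]
        cases = toy_cases(rows)
        by_period = dm.aggregate_counts(cases, ["A", "B"], period_scheme=dm.DEFAULT_PERIODS)
        assert by_period.Y.shape == (2, 5)
        assert by_period.Y.sum() == 5
        flat = dm.aggregate_counts(cases, ["A", "B"])
        assert np.array_equal(by_period.Y.sum(axis=1), flat.Y)

    def test_unknown_region_errors(self):
        cases = toy_cases([("Z", "M", "<35", 1995, "C160")])
        with pytest.raises(CohortInputError, match="Z"):
            dm.aggregate_counts(cases, ["A"])


class TestExpectedCounts:
    def test_hand_computed_indirect_standardization(self):
        # two regions, one sex, two age groups; pooled rates (0.02, 0.04)
        cases = toy_cases(
            [("A", "M", "<35", 1995, "C160")] * 4
            + [("A", "M", "35-39", 1995, "C160")] * 8)
        pops = toy_pops([("A", "M", "<35", 100), ("A", "M", "35-39", 50),
                         ("B", "M", "<35", 100), ("B", "M", "35-39", 150)])
        table = dm.expected_counts(cases, pops, ["A", "B"])
        assert table.E == pytest.approx([4.0, 8.0])
        assert table.E.sum() == pytest.approx(table.Y.sum())
        rates = table.reference_rates.set_index("age_group")["rate"]
        assert rates["<35"] == pytest.approx(0.02)
        assert rates["35-39"] == pytest.approx(0.04)

    def test_equal_populations_spread_expectation_evenly(self):
        cases = toy_cases([("A", "M", "<35", 1995, "C160")] * 6)
        pops = toy_pops([(r, "M", "<35", 500) for r in ("A", "B", "C")])
        table = dm.expected_counts(cases, pops, ["A", "B", "C"])
        assert table.E == pytest.approx([2.0, 2.0, 2.0])
        assert list(table.Y) == [6, 0, 0]

    def test_zero_cases_gives_zero_expected(self):
        cases = toy_cases([])
        pops = toy_pops([("A", "M", "<35", 100)])
        table = dm.expected_counts(cases, pops, ["A"])
        assert table.E == pytest.approx([0.0])

    def test_cases_without_population_is_consistency_error(self):
        cases = toy_cases([("A", "F", "85+", 1995, "C160")])
        pops = toy_pops([("A", "M", "<35", 100)])
        with pytest.raises(DataConsistencyError):
            dm.expected_counts(cases, pops, ["A"])

    def test_conservation_on_synthetic_registry(self, small_registry):
        reg = small_registry
        ids = reg.graph.region_ids
        table = dm.expected_counts(reg.cases, reg.populations, ids)
        assert abs(table.E.sum() - table.Y.sum()) < 1e-9
        for filt in ({"sex": "M"}, {"sex": "F"}, {"subsite": "cardia"},
                     {"subsite": "non_cardia"}):
            t = dm.expected_counts(reg.cases, reg.populations, ids, **filt)
            assert abs(t.E.sum() - t.Y.sum()) < 1e-9


class TestExpectedByPeriod:
    def test_single_region_absorbs_all_expectation(self):
        rows = ([("A", "M", "<35", 1993, "C160")] * 2
                + [("A", "M", "<35", 1999, "C160")] * 4)
        pops = toy_pops([("A", "M", "<35", 1000)])
        scheme = ((1992, 1996), (1997, 2001))
        table = dm.expected_counts_by_period(toy_cases(rows), pops, ["A"], scheme)
        assert table.E[0] == pytest.approx([2.0, 4.0])

    def test_period_without_cases_has_zero_expected(self):
        rows = [("A", "M", "<35", 1993, "C160")]
        pops = toy_pops([("A", "M", "<35", 1000), ("B", "M", "<35", 1000)])
        scheme = ((1992, 1996), (1997, 2001))
        table = dm.expected_counts_by_period(toy_cases(rows), pops, ["A", "B"], scheme)
        assert table.E[:, 1] == pytest.approx([0.0, 0.0])

    def test_hand_computation_per_period(self):
        # the two-region toy split over two periods: rates recomputed per period
        rows = ([("A", "M", "<35", 1995, "C160")] * 4
                + [("A", "M", "35-39", 1995, "C160")] * 8
                + [("A", "M", "<35", 2000, "C160")] * 2)
        pops = toy_pops([("A", "M", "<35", 100), ("A", "M", "35-39", 50),
                         ("B", "M", "<35", 100), ("B", "M", "35-39", 150)])
        scheme = ((1992, 1996), (1997, 2001))
        table = dm.expected_counts_by_period(toy_cases(rows), pops, ["A", "B"], scheme)
        # period 1 identical to the unstratified toy; period 2: rate 2/200 = 0.01
        assert table.E[:, 0] == pytest.approx([4.0, 8.0])
        assert table.E[:, 1] == pytest.approx([1.0, 1.0])
        for t in range(2):
            assert table.E[:, t].sum() == pytest.approx(table.Y[:, t].sum())

    def test_per_period_conservation_on_registry(self, small_registry):
        reg = small_registry
        scheme = ((1992, 1996), (1997, 2001), (2002, 2006))
        table = dm.expected_counts_by_period(reg.cases, reg.populations,
                                             reg.graph.region_ids, scheme)
        for t in range(3):
            assert abs(table.E[:, t].sum() - table.Y[:, t].sum()) < 1e-9


class TestDropZeroExpected:
    def test_zero_e_region_dropped_with_name(self):
        table = dm.CountTable(("A", "B"), np.array([3, 0]), E=np.array([3.0, 0.0]))
        sub, dropped = drop_zero_expected(table)
        assert dropped == ["B"]
        assert sub.region_ids == ("A",)


def test_csv_round_trip(tmp_path, small_registry):
    from diseasemap.cohort import read_cases_csv, read_populations_csv
    reg = small_registry
    reg.cases.to_csv(tmp_path / "cases.csv", index=False)
    reg.populations.to_csv(tmp_path / "pops.csv", index=False)
    cases = read_cases_csv(tmp_path / "cases.csv")
    pops = read_populations_csv(tmp_path / "pops.csv")
    ids = [str(r) for r in reg.graph.region_ids]
    table = dm.expected_counts(cases.assign(region_id=cases.region_id.astype(str)),
                               pops.assign(region_id=pops.region_id.astype(str)), ids)
    assert table.Y.sum() == len(reg.cases)
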