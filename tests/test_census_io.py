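"""Record filtering, monthly carcass rates, period labels and the market
summary table."""

import numpy as np
import pandas as pd
import pytest

from bushmarket import census_io as ci


def make_records(entries):
    """entries: list of (date, species) or full dict rows."""
    rows = []
    for e in entries:
        if isinstance(e, dict):
            rows.append(e)
        else:
            date, species = e
            rows.append(
                {"date": date, "species": species, "group": "rodent",
                 "method": "trap", "origin": "island", "condition": "fresh",
                 "price_fcfa": 1000.0}
            )
    return pd.DataFrame(rows)


def make_calendar(start="2000-01", n=6, days=20):
    months = pd.period_range(start, periods=n, freq="M")
    return pd.DataFrame(
        {"year": months.year, "month": months.month,
         "market_days": np.full(n, days, dtype=int)}
    )


class TestFilterRare:
    @pytest.mark.parametrize("count,kept", [(74, False), (75, True), (76, True)])
    def test_threshold_is_strict_less_than(self, count, kept):
        records = make_records([("2000-01-05", "sp_a")] * count + [("2000-01-06", "sp_b")] * 100)
        out = ci.filter_rare(records)
        assert ("sp_a" in out["species"].to_numpy()) is kept
        assert (out["species"] == "sp_b").sum() == 100

    def test_empty_table(self):
        records = make_records([]).reindex(columns=ci.RECORD_COLUMNS)
        assert ci.filter_rare(records).empty


class TestMonthlyRates:
    def test_simple_ratio(self):
        records = make_records([("2000-01-10", "sp")] * 30)
        series = ci.monthly_rates(records, make_calendar(days=30))
        assert series.values[0] == 1.0
        assert np.all(series.values[1:] == 0.0)

    def test_zero_carcasses_zero_rate(self):
        records = make_records([("2000-02-01", "sp")])
        series = ci.monthly_rates(records, make_calendar(days=20), species="other_sp")
        assert np.all(series.values == 0.0)

    def test_matches_brute_force_tally(self, rng):
        """Randomized table: every selector combination equals a
        record-by-record brute-force count divided by market days."""
        months = pd.period_range("2000-01", periods=6, freq="M")
        n = 400
        records = pd.DataFrame(
            {
                "date": [
                    str((m := months[rng.integers(6)]).start_time.date() + pd.Timedelta(days=int(rng.integers(27))))
                    for _ in range(n)
                ],
                "species": rng.choice(["a", "b"], n),
                "group": rng.choice(["rodent", "primate"], n),
                "method": rng.choice(["trap", "shotgun"], n),
                "origin": rng.choice(["island", "import"], n),
                "condition": "fresh",
                "price_fcfa": 1.0,
            }
        )
        calendar = make_calendar(days=22)
        for sel in [{}, {"group": "primate"}, {"method": "trap", "origin": "island"}]:
            series = ci.monthly_rates(records, calendar, **sel)
            for i, m in enumerate(months):
                expected = 0
                for _, row in records.iterrows():
                    if pd.Period(row["date"], "M") != m:
                        continue
                    if all(row[k] == v for k, v in sel.items()):
                        expected += 1
                assert series.values[i] == pytest.approx(expected / 22)

    def test_zero_survey_days_with_records_errors(self):
        records = make_records([("2000-03-01", "sp")])
        calendar = make_calendar()
        calendar.loc[2, "market_days"] = 0
        with pytest.raises(ValueError, match="2000-03"):
            ci.monthly_rates(records, calendar)

    def test_record_outside_calendar_errors(self):
        records = make_records([("2001-01-01", "sp")])
        with pytest.raises(ValueError, match="not covered"):
            ci.monthly_rates(records, make_calendar())


class TestImputeGap:
    def make_series(self, values):
        months = pd.period_range("2001-01", periods=len(values), freq="M")
        return ci.MonthlySeries(months, np.asarray(values, float), np.full(len(values), 20))

    def test_mean_of_neighbors(self):
        series = self.make_series([2.0, np.nan, 4.0])
        out = ci.impute_gap(series, "2001-02")
        assert out.values[1] == 3.0
        assert out.values[0] == 2.0 and out.values[2] == 4.0

    def test_equal_neighbors(self):
        out = ci.impute_gap(self.make_series([5.0, 0.0, 5.0]), "2001-02")
        assert out.values[1] == 5.0

    def test_missing_neighbor_refused(self):
        series = self.make_series([np.nan, np.nan, 4.0, 1.0])
        with pytest.raises(ValueError, match="chained"):
            ci.impute_gap(series, "2001-02")

    def test_study_calendar_fire_gap(self, study_months):
        """A fire-style single-month loss in Feb-2001 leaves a gap-free
        Oct-1997..Sep-2010 series after imputation."""
        values = np.ones(len(study_months))
        values[study_months.get_loc(pd.Period("2001-02", "M"))] = np.nan
        series = ci.MonthlySeries(study_months, values, np.full(len(study_months), 25))
        out = ci.impute_gap(series, "2001-02")
        assert not np.isnan(out.values).any()
        assert len(out) == 156


class TestAssignPeriods:
    @pytest.mark.parametrize(
        "month,label",
        [
            ("1997-10", "Early"),
            ("2003-03", "Early"),
            ("2003-04", "Pre-ban"),
            ("2007-10", "Pre-ban"),
            ("2007-11", "Post-ban"),
            ("2010-09", "Post-ban"),
        ],
    )
    def test_breakpoints_open_periods(self, study_months, month, label):
        labels = ci.assign_periods(study_months)
        assert labels[pd.Period(month, "M")] == label

    def test_breakpoint_outside_range_errors(self):
        months = pd.period_range("2005-01", periods=24, freq="M")
        with pytest.raises(ValueError, match="outside"):
            ci.assign_periods(months, ci.PeriodPartition())

    def test_unordered_breakpoints_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            ci.PeriodPartition(breakpoints=("2007-11", "2003-04"))


class TestMarketSummary:
    def test_single_species_full_share(self):
        reference = pd.DataFrame(
            {"species": ["solo"], "group": ["rodent"], "mass_kg": [2.0]}
        )
        records = make_records([("2000-01-01", "solo")] * 10)
        out = ci.market_summary(records, reference)
        assert ci.summary_value(out, "solo", "count_share_pct") == 100.0
        assert ci.summary_value(out, "solo", "biomass_kg") == 20.0

    def test_unknown_species_listed(self):
        reference = pd.DataFrame({"species": ["known"], "group": ["rodent"], "mass_kg": [1.0]})
        records = make_records([("2000-01-01", "mystery")])
        with pytest.raises(ValueError, match="mystery"):
            ci.market_summary(records, reference)

    def test_name_matching_normalizes_case_and_whitespace(self):
        reference = pd.DataFrame({"species": ["Cricetomys emini"], "group": ["rodent"], "mass_kg": [1.14]})
        records = make_records([("2000-01-01", "  cricetomys   EMINI ")] * 3)
        out = ci.market_summary(records, reference)
        assert ci.summary_value(out, "Cricetomys emini", "n") == 3

    def test_group_totals_are_sums_and_shares_sum_to_100(self):
        """Internal consistency of the published-count summary: groups sum
        to their members, the overall row sums the groups, and count
        shares add to 100 within rounding."""
        summary = ci.reference_summary(ci.load_species_reference())
        species = summary[summary["level"] == "species"]
        groups = summary[summary["level"] == "group"]
        total = summary[summary["level"] == "total"].iloc[0]
        for _, g in groups.iterrows():
            members = species[species["group"] == g["label"]]
            assert g["n"] == members["n"].sum()
            assert g["biomass_kg"] == pytest.approx(members["biomass_kg"].sum(), abs=0.02)
        assert total["n"] == groups["n"].sum() == 196_892
        assert total["biomass_kg"] == pytest.approx(groups["biomass_kg"].sum(), abs=0.02)
        assert groups["count_share_pct"].sum() == pytest.approx(100.0, abs=0.05)

    def test_printed_per_row_biomass_consistent_with_printed_total(self):
        """The transcribed per-row biomass column sums to the published
        overall total within 0.02 kg (the published table itself carries a
        0.01 rounding discrepancy)."""
        ref = ci.load_species_reference()
        assert ref["biomass_printed"].sum() == pytest.approx(873_993.28, abs=0.02)


def test_reference_rejects_duplicates(tmp_path):
    ref = ci.load_species_reference()
    bad = pd.concat([ref, ref.iloc[[0]]], ignore_index=True)
    path = tmp_path / "ref.csv"
    bad.to_csv(path, index=False)
    with pytest.raises(ValueError, match="duplicate"):
        ci.load_species_reference(path)
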