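"""Clearance-time metric: fiscal calendar, weekly rates, census, categories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipwait.demand_metric import (CATEGORIES, assess_demand, categorize,
                                   clearance_time, fiscal_quarter,
                                   hospital_quarter_rates, max_weekly_rate,
                                   preop_census, quarter_start)


def _cohort(rows):
    df = pd.DataFrame(rows)
    for c in ("admit_date", "discharge_date", "surgery_date"):
        if c in df:
            df[c] = pd.to_datetime(df[c])
    return df


class TestFiscalCalendar:
    @pytest.mark.parametrize("date,label", [
        ("2004-04-01", "FY2004Q1"),
        ("2004-06-30", "FY2004Q1"),
        ("2004-07-01", "FY2004Q2"),
        ("2004-12-31", "FY2004Q3"),
        ("2005-01-01", "FY2004Q4"),
        ("2005-03-31", "FY2004Q4"),
    ])
    def test_labels(self, date, label):
        assert fiscal_quarter([date]).iloc[0] == label

    def test_quarter_start_roundtrip(self):
        for label, start in [("FY2004Q1", "2004-04-01"), ("FY2004Q4", "2005-01-01")]:
            assert quarter_start(label) == pd.Timestamp(start)
            assert fiscal_quarter([start]).iloc[0] == label


class TestMaxWeeklyRate:
    def test_max_over_weeks(self):
        # weekly surgery counts 3, 5, 4 inside one quarter -> S = 5
        days = []
        for week, count in enumerate([3, 5, 4]):
            days += [pd.Timestamp("2004-04-01") + pd.Timedelta(days=7 * week + i)
                     for i in range(count)]
        cohort = _cohort({
            "index_hospital_id": "H0",
            "admit_date": days,
            "discharge_date": days,
            "surgery_date": days,
        })
        assert max_weekly_rate(cohort, "H0", "FY2004Q1") == 5

    def test_constant_weekly_rate(self):
        days = pd.date_range("2004-04-01", "2004-06-24", freq="D")
        cohort = _cohort({"index_hospital_id": "H0", "admit_date": days,
                          "discharge_date": days, "surgery_date": days})
        assert max_weekly_rate(cohort, "H0", "FY2004Q1") == 7

    def test_undefined_rate_raises(self):
        cohort = _cohort({"index_hospital_id": ["H0"],
                          "admit_date": ["2004-04-02"],
                          "discharge_date": ["2004-04-09"],
                          "surgery_date": ["2004-04-05"]})
        with pytest.raises(ValueError, match="undefined"):
            max_weekly_rate(cohort, "H0", "FY2004Q2")


class TestCensus:
    def test_sole_patient_counts_themself(self):
        cohort = _cohort({"index_hospital_id": ["H0"],
                          "admit_date": ["2004-05-01"],
                          "discharge_date": ["2004-05-10"],
                          "surgery_date": ["2004-05-03"]})
        assert preop_census(cohort, "H0", "2004-05-01") == 1
        assert preop_census(cohort, "H0", "2004-05-01", include_index=False) == 0

    def test_earlier_waiting_patients_counted(self):
        rows = {
            "index_hospital_id": ["H0"] * 4,
            "admit_date": ["2004-05-01", "2004-05-02", "2004-05-03", "2004-05-04"],
            "discharge_date": ["2004-05-20"] * 4,
            "surgery_date": ["2004-05-06", "2004-05-05", "2004-05-07", "2004-05-08"],
        }
        cohort = _cohort(rows)
        # on 2004-05-04 all four are admitted and none operated yet
        assert preop_census(cohort, "H0", "2004-05-04") == 4

    def test_operated_patients_drop_out(self):
        rows = {
            "index_hospital_id": ["H0"] * 2,
            "admit_date": ["2004-05-01", "2004-05-05"],
            "discharge_date": ["2004-05-20"] * 2,
            "surgery_date": ["2004-05-02", "2004-05-06"],
        }
        cohort = _cohort(rows)
        assert preop_census(cohort, "H0", "2004-05-05") == 1


class TestClearanceTime:
    @pytest.mark.parametrize("q,s,c,cat", [
        (2, 7, 2.0, "benchmark"),
        (0, 3, 0.0, "benchmark"),
        (7, 7, 7.0, "excessive"),
        (4, 7, 4.0, "medium"),
        (6, 7, 6.0, "high"),
        (3, 10, 2.1, "medium"),
    ])
    def test_examples(self, q, s, c, cat):
        cc, got = clearance_time(q, s)
        assert cc == pytest.approx(c)
        assert got == cat

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            clearance_time(3, 0)

    @given(q=st.integers(0, 100), s=st.integers(1, 40))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_census_and_rate(self, q, s):
        c, _ = clearance_time(q, s)
        c_more, _ = clearance_time(q + 1, s)
        c_faster, _ = clearance_time(q + 1, s + 1)
        assert c_more > c
        assert c_faster < c_more

    def test_categories_partition_and_are_monotone(self):
        cs = np.linspace(0, 12, 500)
        cats = categorize(cs)
        order = {c: i for i, c in enumerate(CATEGORIES)}
        ranks = np.array([order[c] for c in cats])
        assert np.all(np.diff(ranks) >= 0)
        assert set(cats) == set(CATEGORIES)


class TestAssessDemand:
    def test_rate_from_admission_quarter_and_hospital(self):
        # surgeries concentrated so that S differs between quarters
        q1 = [f"2004-04-{d:02d}" for d in range(1, 8)]      # 7 in one week
        q2 = ["2004-07-05", "2004-07-20"]                   # max 1 per week
        cohort = _cohort({
            "index_hospital_id": "H0",
            "admit_date": q1 + q2,
            "discharge_date": q1 + q2,
            "surgery_date": q1 + q2,
        })
        dem = assess_demand(cohort)
        assert (dem.loc[:6, "max_weekly_rate"] == 7).all()
        assert (dem.loc[7:, "max_weekly_rate"] == 1).all()

    def test_undefined_quarter_flagged(self):
        cohort = _cohort({
            "index_hospital_id": ["H0", "H0"],
            # admitted in Q4 but operated in the next quarter: no Q4 surgery
            "admit_date": ["2004-03-30", "2004-04-02"],
            "discharge_date": ["2004-04-10", "2004-04-10"],
            "surgery_date": ["2004-04-02", "2004-04-03"],
        })
        dem = assess_demand(cohort)
        assert dem["demand_category"].isna().iloc[0]
        assert dem["demand_category"].notna().iloc[1]

    def test_census_matches_scalar_definition(self, tiny_cohort):
        sub = tiny_cohort.sample(25, random_state=0)
        for _, row in sub.iterrows():
            assert row["census_q"] == preop_census(
                tiny_cohort, row["index_hospital_id"], row["admit_date"])


class TestGeneratorAgreement:
    def test_realized_rate_caps_at_known_capacity(self):
        """With saturating arrivals, the realized max weekly rate equals the
        known nominal capacity and never exceeds it."""
        from hipwait import SimulationConfig, simulate_admissions_and_surgery

        cfg = SimulationConfig(
            n_hospitals=3, start="2004-01-01", end="2004-12-31",
            arrival_rate_per_hospital_day=3.0, base_capacity_per_week=10,
            capacity_quarter_multipliers=(1, 1, 1, 1), seed=5)
        traj = simulate_admissions_and_surgery(cfg)
        cohort = traj[traj["surgery_date"].notna()].rename(
            columns={"hospital_id": "index_hospital_id"})
        rates = hospital_quarter_rates(cohort)
        assert rates["max_weekly_rate"].max() == 10
        # saturated in (nearly) every full quarter
        assert (rates["max_weekly_rate"] == 10).mean() > 0.8

    def test_excessive_share_rises_with_arrivals(self):
        from hipwait import SimulationConfig, simulate_admissions_and_surgery

        shares = []
        for rate in (0.4, 1.0, 2.0):
            cfg = SimulationConfig(
                n_hospitals=4, start="2004-01-01", end="2004-12-31",
                arrival_rate_per_hospital_day=rate, base_capacity_per_week=7,
                capacity_quarter_multipliers=(1, 1, 1, 1), seed=7)
            traj = simulate_admissions_and_surgery(cfg)
            shares.append((traj["demand_category"] == "excessive").mean())
        assert shares[0] <= shares[1] <= shares[2]
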