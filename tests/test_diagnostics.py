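"""Diagnostics against hand computations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from cohortdx import diagnostics as dx
from cohortdx.cohorts import CohortDefinition

from conftest import incidence_oracle, make_entries, make_store, oracle_rows, random_small_store


class TestCohortCounts:
    def test_empty(self):
        empty = make_entries([]).iloc[0:0]
        out = dx.cohort_counts(empty)
        assert len(out) == 0

    def test_three_entries_two_subjects(self):
        e = make_entries([(1, "2010-01-01", "2010-02-01"), (1, "2010-06-01", "2010-07-01"),
                          (2, "2010-01-01", "2010-02-01")])
        out = dx.cohort_counts(e)
        assert (out["entry_count"].iloc[0], out["subject_count"].iloc[0]) == (3, 2)

    def test_matches_set_cardinality(self):
        rng = np.random.default_rng(5)
        subjects = rng.integers(1, 20, size=40)
        rows = [(int(s), "2010-01-01", "2010-02-01") for s in subjects]
        out = dx.cohort_counts(make_entries(rows))
        assert out["subject_count"].iloc[0] == len(set(subjects))
        assert out["entry_count"].iloc[0] == 40


class TestIncidenceRates:
    def test_marginal_rate_two_cases(self):
        # person 1 observed 4 calendar years (incl leap 2012 -> 1461 days),
        # person 2 enters the cohort once
        store = make_store(
            [(1, "FEMALE", 1980), (2, "MALE", 1970)],
            [(1, "2010-01-01", "2013-12-31"), (2, "2010-01-01", "2010-12-31")],
            [],
        )
        e = make_entries([(2, "2010-03-01", "2010-12-31")])
        out = dx.incidence_rates(e, store, by_age=False, by_sex=False, by_year=False)
        row = out.iloc[0]
        # oracle by per-day enumeration
        pt, cases = incidence_oracle(e, store)
        days = sum(pt.values())
        assert days == 1461 + ((pd.Timestamp("2010-03-01") - pd.Timestamp("2010-01-01")).days + 1)
        assert row["cases"] == sum(cases.values()) == 1
        assert row["person_years"] == pytest.approx(days / 365.25, abs=1e-12)

    def test_zero_cases_positive_person_time(self):
        store = make_store([(1, "FEMALE", 1980)], [(1, "2010-01-01", "2010-12-31")], [])
        empty = make_entries([]).iloc[0:0]
        out = dx.incidence_rates(empty, store, by_age=False, by_sex=False, by_year=False,
                                 cohort_ids=[1])
        assert out["cases"].iloc[0] == 0
        assert out["rate_per_1000"].iloc[0] == 0.0
        assert out["person_years"].iloc[0] > 0

    def test_entry_on_first_observed_day(self):
        store = make_store([(1, "FEMALE", 1980)], [(1, "2010-01-01", "2012-12-31")], [])
        e = make_entries([(1, "2010-01-01", "2012-12-31")])
        out = dx.incidence_rates(e, store, by_age=False, by_sex=False, by_year=False)
        assert out["cases"].iloc[0] == 1
        assert out["person_years"].iloc[0] == pytest.approx(1 / 365.25)

    def test_case_sums_and_person_time_sums_across_strata(self):
        rng = np.random.default_rng(17)
        store, entries = random_small_store(rng)
        out = dx.incidence_rates(entries, store, by_sex=True, by_year=True, by_age=False)
        marg = out[out["sex"].isna() & out["calendar_year"].isna()]
        by_year = out[out["sex"].isna() & out["calendar_year"].notna()]
        assert by_year["cases"].sum() == marg["cases"].iloc[0]
        assert by_year["person_years"].sum() == pytest.approx(marg["person_years"].iloc[0], abs=1e-9)

    def test_age_requested_without_birth_years_errors(self):
        store = make_store([(1, "FEMALE", None)], [(1, "2010-01-01", "2010-12-31")], [])
        with pytest.raises(ValueError, match="year_of_birth"):
            dx.incidence_rates(make_entries([]).iloc[0:0], store, by_age=True,
                               by_sex=False, by_year=False, cohort_ids=[1])

    def test_washout_trims_person_time(self):
        store = make_store([(1, "FEMALE", 1980)], [(1, "2010-01-01", "2010-12-31")], [])
        e = make_entries([]).iloc[0:0]
        out = dx.incidence_rates(e, store, by_age=False, by_sex=False, by_year=False,
                                 washout_days=100, cohort_ids=[1])
        assert out["person_years"].iloc[0] == pytest.approx((365 - 100) / 365.25)


class TestTimeDistributions:
    def test_worked_example(self):
        store = make_store([(1, "FEMALE", 1980)], [(1, "2010-01-01", "2012-12-31")], [])
        e = make_entries([(1, "2011-01-01", "2011-06-30")])
        out = dx.time_distributions(e, store).set_index("measure")
        assert out.loc["obs_start_to_index", "mean"] == 365
        assert out.loc["index_to_cohort_end", "mean"] == 180
        assert out.loc["index_to_obs_end", "mean"] == 730

    def test_entry_on_observation_start(self):
        store = make_store([(1, "FEMALE", 1980)], [(1, "2010-01-01", "2012-12-31")], [])
        e = make_entries([(1, "2010-01-01", "2010-06-01")])
        out = dx.time_distributions(e, store).set_index("measure")
        assert out.loc["obs_start_to_index", "min"] == 0

    def test_single_value_stats_degenerate(self):
        store = make_store([(1, "FEMALE", 1980)], [(1, "2010-01-01", "2012-12-31")], [])
        e = make_entries([(1, "2011-01-01", "2011-06-30")])
        out = dx.time_distributions(e, store)
        row = out[out["measure"] == "obs_start_to_index"].iloc[0]
        for col in ("mean", "min", "p10", "p25", "median", "p75", "p90", "max"):
            assert row[col] == 365
        assert row["sd"] == 0

    def test_entry_outside_observation_excluded(self):
        store = make_store([(1, "FEMALE", 1980)], [(1, "2010-01-01", "2010-12-31")], [])
        e = make_entries([(1, "2015-01-01", "2015-06-30")])
        assert len(dx.time_distributions(e, store)) == 0


def breakdown_definition():
    return CohortDefinition(
        cohort_id=1, name="b",
        concept_sets=[
            {"concept_set_id": 1, "name": "dx", "items": [{"concept_id": 1001}, {"concept_id": 1002}]},
            {"concept_set_id": 2, "name": "rx", "items": [{"concept_id": 2001}]},
        ],
        entry_events=[{"domain": "condition", "concept_set_id": 1},
                      {"domain": "drug", "concept_set_id": 2}],
    )


class TestIndexEventBreakdown:
    def test_multi_attribution(self):
        store = make_store([(1, "FEMALE", 1980)], [(1, "2010-01-01", "2012-12-31")],
                           [(1, 1001, "condition", "2011-01-01"), (1, 1002, "condition", "2011-01-01")])
        e = make_entries([(1, "2011-01-01", "2012-12-31")])
        out = dx.index_event_breakdown(e, breakdown_definition(), store)
        assert set(out["concept_id"]) == {1001, 1002}
        assert (out["entry_count"] == 1).all()

    def test_only_index_dated_concept_counted(self):
        store = make_store([(1, "FEMALE", 1980)], [(1, "2010-01-01", "2012-12-31")],
                           [(1, 1001, "condition", "2010-12-31"), (1, 2001, "drug", "2011-01-01")])
        e = make_entries([(1, "2011-01-01", "2012-12-31")])
        out = dx.index_event_breakdown(e, breakdown_definition(), store)
        assert set(out["concept_id"]) == {2001}

    def test_matches_nested_loop_join(self):
        rng = np.random.default_rng(23)
        persons = [(p, "FEMALE", 1980) for p in range(1, 11)]
        periods = [(p, "2010-01-01", "2014-12-31") for p in range(1, 11)]
        events, entry_rows = [], []
        for p in range(1, 11):
            for _ in range(int(rng.integers(0, 6))):
                c = int(rng.choice([1001, 1002, 2001, 5000]))
                domain = "drug" if c == 2001 else "condition"
                events.append((p, c, domain,
                               pd.Timestamp("2010-01-01") + pd.Timedelta(days=int(rng.integers(0, 1500)))))
            if rng.random() < 0.7:
                d = pd.Timestamp("2010-01-01") + pd.Timedelta(days=int(rng.integers(0, 1500)))
                entry_rows.append((p, d, d + pd.Timedelta(days=100)))
        store = make_store(persons, periods, events)
        entries = pd.DataFrame(entry_rows, columns=["subject_id", "cohort_start_date", "cohort_end_date"])
        entries.insert(0, "cohort_id", 1)
        out = dx.index_event_breakdown(entries, breakdown_definition(), store)
        # oracle: nested loops over entries x events, filtered to resolved sets
        resolved = {("condition", 1001), ("condition", 1002), ("drug", 2001)}
        want: dict[int, set] = {}
        for _, entry in entries.iterrows():
            for ev in events:
                if ev[0] == entry["subject_id"] and ev[3] == entry["cohort_start_date"] \
                        and (ev[2], ev[1]) in resolved:
                    want.setdefault(ev[1], set()).add((entry["subject_id"], entry["cohort_start_date"]))
        got = {int(r["concept_id"]): int(r["entry_count"]) for _, r in out.iterrows()}
        assert got == {c: len(v) for c, v in want.items()}


class TestVisitContext:
    def make(self, visit):
        store = make_store([(1, "FEMALE", 1980)], [(1, "2009-01-01", "2012-12-31")], [],
                           visits=[visit])
        e = make_entries([(1, "2011-01-01", "2012-12-31")])
        return dx.visit_context(e, store)

    @pytest.mark.parametrize("visit,context", [
        ((1, "outpatient", "2010-11-22", "2010-12-22"), "before"),   # ends index-10
        ((1, "outpatient", "2010-12-27", "2011-01-03"), "during"),
        ((1, "inpatient", "2011-01-01", "2011-01-04"), "simultaneous"),
        ((1, "emergency", "2011-01-05", "2011-01-05"), "after"),
        ((1, "outpatient", "2010-01-01", "2010-02-01"), None),       # far before
        ((1, "outpatient", "2011-03-01", "2011-03-02"), None),       # >30d after
    ])
    def test_window_classification(self, visit, context):
        out = self.make(visit)
        if context is None:
            assert len(out) == 0
        else:
            assert list(out["context"]) == [context]

    def test_contexts_partition(self):
        rng = np.random.default_rng(31)
        visits = []
        for _ in range(60):
            s = int(rng.integers(-60, 61))
            visits.append((1, "outpatient", pd.Timestamp("2011-01-01") + pd.Timedelta(days=s),
                           pd.Timestamp("2011-01-01") + pd.Timedelta(days=s + int(rng.integers(0, 20)))))
        store = make_store([(1, "FEMALE", 1980)], [(1, "2009-01-01", "2012-12-31")], [], visits=visits)
        e = make_entries([(1, "2011-01-01", "2012-12-31")])
        m = e.merge(store.visits.rename(columns={"person_id": "subject_id"}), on="subject_id")
        # each visit satisfies at most one context per the stated windows
        for _, v in m.iterrows():
            so = (v["start_date"] - v["cohort_start_date"]).days
            eo = (v["end_date"] - v["cohort_start_date"]).days
            n_ctx = sum([so == 0, (so < 0) and (eo >= 0), -30 <= eo <= -1, 1 <= so <= 30])
            assert n_ctx <= 1


class TestOverlap:
    def test_identical(self):
        e = make_entries([(i, "2010-01-01", "2010-02-01") for i in range(1, 6)])
        out = dx.cohort_overlap(e, e.assign(cohort_id=2)).iloc[0]
        assert (out["n_both"], out["n_only_a"], out["n_only_b"]) == (5, 0, 0)

    def test_disjoint(self):
        a = make_entries([(i, "2010-01-01", "2010-02-01") for i in range(1, 4)], cohort_id=1)
        b = make_entries([(i, "2010-01-01", "2010-02-01") for i in range(10, 15)], cohort_id=2)
        out = dx.cohort_overlap(a, b).iloc[0]
        assert (out["n_both"], out["n_only_a"], out["n_only_b"]) == (0, 3, 5)

    def test_random_sets_and_conservation(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            sa = set(int(x) for x in rng.choice(50, size=rng.integers(0, 30), replace=False))
            sb = set(int(x) for x in rng.choice(50, size=rng.integers(0, 30), replace=False))
            a = make_entries([(s, "2010-01-01", "2010-02-01") for s in sa], cohort_id=1) \
                if sa else make_entries([]).iloc[0:0]
            b = make_entries([(s, "2010-01-01", "2010-02-01") for s in sb], cohort_id=2) \
                if sb else make_entries([]).iloc[0:0]
            out = dx.cohort_overlap(a, b).iloc[0]
            assert out["n_both"] == len(sa & sb)
            assert out["n_only_a"] == len(sa - sb)
            assert out["n_only_b"] == len(sb - sa)
            assert out["n_both"] + out["n_only_a"] + out["n_only_b"] == len(sa | sb)


class TestCharacterize:
    def test_boundary_event_at_minus_31(self):
        store = make_store([(1, "FEMALE", 1980)], [(1, "2009-01-01", "2012-12-31")],
                           [(1, 5000, "condition", pd.Timestamp("2011-01-01") - pd.Timedelta(days=31))])
        e = make_entries([(1, "2011-01-01", "2012-12-31")])
        out = dx.characterize(e, store)
        hit = out[out["concept_id"] == 5000]
        assert set(zip(hit["window_start"], hit["window_end"])) == {(-365, -31)}

    def test_proportion_quarter(self):
        store = make_store([(p, "FEMALE", 1980) for p in range(1, 5)],
                           [(p, "2009-01-01", "2012-12-31") for p in range(1, 5)],
                           [(1, 5000, "condition", "2011-01-05")])
        e = make_entries([(p, "2011-01-01", "2012-12-31") for p in range(1, 5)])
        out = dx.characterize(e, store)
        row = out[(out["concept_id"] == 5000) & (out["window_start"] == 1)].iloc[0]
        assert row["proportion"] == 0.25

    def test_duplicate_events_do_not_inflate(self):
        store = make_store([(1, "FEMALE", 1980)], [(1, "2009-01-01", "2012-12-31")],
                           [(1, 5000, "condition", "2011-01-05"), (1, 5000, "condition", "2011-01-06")])
        e = make_entries([(1, "2011-01-01", "2012-12-31")])
        out = dx.characterize(e, store)
        row = out[(out["concept_id"] == 5000) & (out["window_start"] == 1)]
        assert list(row["n_subjects"]) == [1]

    def test_demographics_under_index_window(self):
        store = make_store([(1, "FEMALE", 1980), (2, "MALE", 1955)],
                           [(1, "2009-01-01", "2012-12-31"), (2, "2009-01-01", "2012-12-31")], [])
        e = make_entries([(1, "2011-01-01", "2012-12-31"), (2, "2011-06-01", "2012-12-31")])
        out = dx.characterize(e, store)
        demo = out[out["covariate_name"].notna()]
        assert set(demo["covariate_name"]) == {"sex=FEMALE", "sex=MALE", "age_group=30-39", "age_group=50-59"}
        assert (demo["window_start"] == 0).all()

    def test_rollup_reports_group_rows(self):
        store = make_store([(1, "FEMALE", 1980), (2, "MALE", 1985)],
                           [(1, "2009-01-01", "2012-12-31"), (2, "2009-01-01", "2012-12-31")],
                           [(1, 1001, "condition", "2011-01-01"), (2, 1002, "condition", "2011-01-01")])
        e = make_entries([(1, "2011-01-01", "2012-12-31"), (2, "2011-01-01", "2012-12-31")])
        out = dx.characterize(e, store, rollup=True)
        grp = out[out["is_group"] & (out["window_start"] == 0)]
        assert list(grp["concept_id"]) == [1000]   # both codes roll up to the disease group
        assert list(grp["n_subjects"]) == [2]
        raw = out[~out["is_group"] & (out["window_start"] == 0) & (out["concept_id"] > 0)]
        assert set(raw["concept_id"]) == {1001, 1002}

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(41)
        persons = [(p, "FEMALE", 1980) for p in range(1, 9)]
        periods = [(p, "2008-01-01", "2014-12-31") for p in range(1, 9)]
        events = []
        for p in range(1, 9):
            for _ in range(int(rng.integers(0, 10))):
                events.append((p, int(rng.choice([5000, 5001, 5002])), "condition",
                               pd.Timestamp("2010-06-01") + pd.Timedelta(days=int(rng.integers(-400, 400)))))
        store = make_store(persons, periods, events)
        e = make_entries([(p, "2010-06-01", "2012-12-31") for p in range(1, 9)])
        out = dx.characterize(e, store)
        for lo, hi in dx.DEFAULT_WINDOWS:
            for concept in (5000, 5001, 5002):
                want = sum(
                    any(ev[0] == p and ev[1] == concept
                        and lo <= (ev[3] - pd.Timestamp("2010-06-01")).days <= hi
                        for ev in events)
                    for p in range(1, 9)
                )
                row = out[(out["window_start"] == lo) & (out["window_end"] == hi)
                          & (out["concept_id"] == concept)]
                got = int(row["n_subjects"].iloc[0]) if len(row) else 0
                assert got == want, (lo, hi, concept)


class TestBalance:
    def test_zero_at_equality(self):
        assert dx.binary_smd(0.3, 0.3) == 0.0

    def test_known_value(self):
        assert dx.binary_smd(0.5, 0.2) == pytest.approx(0.3 / np.sqrt((0.25 + 0.16) / 2), abs=1e-15)

    def test_degenerate_null(self):
        assert dx.binary_smd(0.0, 0.0) is None
        assert dx.binary_smd(1.0, 1.0) is None

    def test_swap_negates(self, tiny_store):
        e1 = make_entries([(1, "2011-02-01", "2012-12-31")], cohort_id=1)
        e2 = make_entries([(2, "2012-03-15", "2014-12-31")], cohort_id=2)
        c1 = dx.characterize(e1, tiny_store)
        c2 = dx.characterize(e2, tiny_store)
        fwd = dx.compare_characterizations(c1, c2)
        rev = dx.compare_characterizations(c2, c1)
        merged = fwd.merge(rev, on=["window_start", "window_end", "concept_id", "is_group"],
                           suffixes=("_f", "_r"))
        for _, r in merged.iterrows():
            if r["smd_f"] is None or pd.isna(r["smd_f"]):
                assert r["smd_r"] is None or pd.isna(r["smd_r"])
            else:
                assert r["smd_f"] == pytest.approx(-r["smd_r"], abs=1e-15)

    def test_absent_covariate_treated_as_zero(self):
        t = pd.DataFrame([(1, 0, 0, 5000, None, False, 3, 0.5)],
                         columns=["cohort_id", "window_start", "window_end", "concept_id",
                                  "covariate_name", "is_group", "n_subjects", "proportion"])
        c = t.iloc[0:0]
        out = dx.compare_characterizations(t, c)
        assert out["p_comparator"].iloc[0] == 0.0
        assert out["smd"].iloc[0] > 0

    def test_mismatched_windows_error(self):
        t = pd.DataFrame([(1, 0, 0, 5000, None, False, 3, 0.5)],
                         columns=["cohort_id", "window_start", "window_end", "concept_id",
                                  "covariate_name", "is_group", "n_subjects", "proportion"])
        c = t.assign(window_start=-30, window_end=-1, cohort_id=2)
        with pytest.raises(ValueError, match="window"):
            dx.compare_characterizations(t, c)


class TestRelativeDifference:
    @pytest.mark.parametrize("simple,restrictive,expected", [
        (38413, 24073, 37.3),
        (3804, 718, 81.1),
        (100, 100, 0.0),
    ])
    def test_values(self, simple, restrictive, expected):
        assert dx.relative_difference(simple, restrictive) == expected

    def test_zero_simple_count_undefined(self):
        with pytest.raises(ValueError):
            dx.relative_difference(0, 5)
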