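"""Shared fixtures: tiny hand-built stores, random small stores, and the
independent per-day incidence oracle used to cross-check stratified rates."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cohortdx import cdm
from cohortdx.cohorts import collapse_eras

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def make_store(persons, periods, events, visits=None, source_name="test") -> cdm.CdmStore:
    """Build a store from plain tuples.

    persons: (person_id, sex, year_of_birth|None)
    periods: (person_id, start, end) ISO strings
    events:  (person_id, concept_id, domain, date[, end_date])
    visits:  (person_id, category, start, end)
    """
    p = pd.DataFrame(persons, columns=["person_id", "sex", "year_of_birth"])
    op = pd.DataFrame(periods, columns=["person_id", "start_date", "end_date"])
    ev_rows = [(e[0], e[1], e[2], e[3], e[4] if len(e) > 4 else None) for e in events]
    ev = pd.DataFrame(ev_rows, columns=["person_id", "concept_id", "domain", "event_date", "end_date"])
    vis = (pd.DataFrame(visits, columns=["person_id", "visit_category", "start_date", "end_date"])
           if visits else None)
    return cdm.from_frames(p, op, ev, visits=vis, source_name=source_name)


def make_entries(rows, cohort_id=1) -> pd.DataFrame:
    """rows: (subject_id, start, end) ISO strings."""
    df = pd.DataFrame(rows, columns=["subject_id", "cohort_start_date", "cohort_end_date"])
    df.insert(0, "cohort_id", cohort_id)
    df["cohort_start_date"] = pd.to_datetime(df["cohort_start_date"])
    df["cohort_end_date"] = pd.to_datetime(df["cohort_end_date"])
    return df


def random_small_store(rng: np.random.Generator, max_persons: int = 50):
    """Random store (<= 50 persons, <= 10-year span) plus a random cohort.

    Raw observation periods may overlap or abut; a fraction of persons lack
    year_of_birth; cohort entries are random dates, era-collapsed, and may
    fall outside observation (both code paths must ignore them alike).
    """
    n = int(rng.integers(1, max_persons + 1))
    span_start = pd.Timestamp(2010, 1, 1)
    span_days = int(rng.integers(200, 3653))
    persons, periods, entry_rows = [], [], []
    for pid in range(1, n + 1):
        yob = None if rng.random() < 0.1 else int(rng.integers(1930, 2009))
        sex = "FEMALE" if rng.random() < 0.5 else "MALE"
        persons.append((pid, sex, yob))
        for _ in range(int(rng.integers(1, 4))):
            a = int(rng.integers(0, span_days))
            b = min(span_days - 1, a + int(rng.integers(0, span_days // 2 + 1)))
            periods.append((pid, span_start + pd.Timedelta(days=a), span_start + pd.Timedelta(days=b)))
        for _ in range(int(rng.integers(0, 3))):
            d = int(rng.integers(0, span_days))
            entry_rows.append((1, pid, span_start + pd.Timedelta(days=d),
                               span_start + pd.Timedelta(days=min(span_days - 1, d + int(rng.integers(0, 400))))))
    p = pd.DataFrame(persons, columns=["person_id", "sex", "year_of_birth"])
    op = pd.DataFrame(periods, columns=["person_id", "start_date", "end_date"])
    ev = pd.DataFrame(columns=["person_id", "concept_id", "domain", "event_date"])
    store = cdm.from_frames(p, op, ev)
    entries = pd.DataFrame(entry_rows, columns=["cohort_id", "subject_id",
                                                "cohort_start_date", "cohort_end_date"])
    entries = collapse_eras(entries, gap_days=0) if len(entries) else entries
    return store, entries


def incidence_oracle(entries: pd.DataFrame, store: cdm.CdmStore, washout_days: int = 0):
    """Per-day risk-set enumeration: (age_band|None, sex, year) -> (days, cases).

    Enumerates every observed calendar day of every person (numpy day
    arrays), independent of the implementation's interval arithmetic.
    """
    first_entry = entries.groupby("subject_id")["cohort_start_date"].min() if len(entries) else pd.Series(dtype="datetime64[ns]")
    pt: dict[tuple, int] = {}
    cases: dict[tuple, int] = {}
    for pid, sex, yob in store.persons[["person_id", "sex", "year_of_birth"]].itertuples(index=False):
        pid = int(pid)
        yob_i = None if pd.isna(yob) else int(yob)
        entry = first_entry.get(pid)
        sub = store.observation_periods[store.observation_periods["person_id"] == pid]
        case_counted = False
        for s, e in zip(sub["start_date"], sub["end_date"]):
            days = np.arange(np.datetime64(s, "D"), np.datetime64(e, "D") + 1)
            days = days[days >= np.datetime64(s, "D") + washout_days]
            if entry is not None and not pd.isna(entry):
                days = days[days <= np.datetime64(entry, "D")]
            if not len(days):
                continue
            years = days.astype("datetime64[Y]").astype(int) + 1970
            for y, c in zip(*np.unique(years, return_counts=True)):
                band = None if yob_i is None else (int(y) - yob_i) // 10
                key = (band, sex, int(y))
                pt[key] = pt.get(key, 0) + int(c)
            if entry is not None and not pd.isna(entry) and not case_counted:
                if np.datetime64(entry, "D") in days:
                    y = int(entry.year)
                    band = None if yob_i is None else (y - yob_i) // 10
                    key = (band, sex, y)
                    cases[key] = cases.get(key, 0) + 1
                    case_counted = True
    return pt, cases


def oracle_rows(pt: dict, cases: dict, use_age: bool, use_sex: bool, use_year: bool):
    """Aggregate oracle cells to one strata subset, mirroring nothing of the
    implementation beyond the published row keying."""
    agg_pt: dict[tuple, int] = {}
    agg_cases: dict[tuple, int] = {}
    for (band, sex, year), d in pt.items():
        if use_age and band is None:
            continue
        key = (band if use_age else None, sex if use_sex else None, year if use_year else None)
        agg_pt[key] = agg_pt.get(key, 0) + d
    for (band, sex, year), c in cases.items():
        if use_age and band is None:
            continue
        key = (band if use_age else None, sex if use_sex else None, year if use_year else None)
        agg_cases[key] = agg_cases.get(key, 0) + c
    return agg_pt, agg_cases


@pytest.fixture
def tiny_store():
    """Three persons, simple events, used across diagnostic unit tests."""
    return make_store(
        persons=[(1, "FEMALE", 1980), (2, "MALE", 1970), (3, "FEMALE", 1990)],
        periods=[(1, "2010-01-01", "2012-12-31"),
                 (2, "2010-01-01", "2014-12-31"),
                 (3, "2011-06-01", "2013-05-31")],
        events=[(1, 1001, "condition", "2011-01-01"),
                (1, 2001, "drug", "2011-02-01"),
                (2, 1002, "condition", "2012-03-15"),
                (3, 5000, "condition", "2012-01-01")],
        visits=[(1, "outpatient", "2011-01-01", "2011-01-01"),
                (2, "inpatient", "2012-03-10", "2012-03-20")],
    )
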