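"""Population-level diagnostics over instantiated cohorts.

Each function consumes a cohort table (cohort_id, subject_id,
cohort_start_date, cohort_end_date) plus the :class:`~cohortdx.cdm.CdmStore`
it was instantiated against, and returns a tidy DataFrame in the results
model schema.  Conventions shared across diagnostics:

* person-years use a 365.25-day year; day counts over intervals are
  inclusive (end - start + 1);
* age band = floor((calendar_year - year_of_birth) / 10), labeled
  "0-9", "10-19", ...; persons lacking year_of_birth are excluded from
  age-stratified rows only;
* incidence denominators cover every person with observation time, with
  each person's at-risk time right-censored at their first cohort entry
  (the entry day itself is still at risk) and left-trimmed by the washout;
* characterization windows are closed day intervals relative to the index
  date (day 0 = index, negative = before), anchored on each subject's
  first entry.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .cdm import CdmStore
from .cohorts import CohortDefinition
from .vocabulary import rollup_concepts

logger = logging.getLogger(__name__)

__all__ = [
    "cohort_counts",
    "incidence_rates",
    "time_distributions",
    "index_event_breakdown",
    "visit_context",
    "cohort_overlap",
    "characterize",
    "compare_characterizations",
    "relative_difference",
    "DEFAULT_WINDOWS",
]

DEFAULT_WINDOWS: list[tuple[int, int]] = [(-365, -31), (-30, -1), (0, 0), (1, 30), (31, 365)]

DAYS_PER_YEAR = 365.25

TIME_MEASURES = ("obs_start_to_index", "index_to_cohort_end", "index_to_obs_end")

VISIT_CONTEXTS = ("simultaneous", "during", "before", "after")  # precedence order


def cohort_counts(entries: pd.DataFrame) -> pd.DataFrame:
    """Entry and distinct-subject counts per cohort.

    A subject-to-entry ratio below one flags definitions that admit a
    person at multiple distinct temporal periods.
    """
    if not len(entries):
        return pd.DataFrame(columns=["cohort_id", "entry_count", "subject_count"])
    out = entries.groupby("cohort_id").agg(
        entry_count=("subject_id", "size"), subject_count=("subject_id", "nunique")
    ).reset_index()
    return out


def _age_band_label(band: int) -> str:
    return f"{10 * band}-{10 * band + 9}"


def incidence_rates(
    entries: pd.DataFrame,
    store: CdmStore,
    by_age: bool = True,
    by_sex: bool = True,
    by_year: bool = True,
    washout_days: int = 0,
    censor_at_first_entry: bool = True,
    cohort_ids: list[int] | None = None,
) -> pd.DataFrame:
    """Incidence of cohort entry per 1000 person-years, stratified.

    Rows cover every combination of the *requested* strata dimensions,
    including all marginal combinations (a row where a dimension is absent
    carries NA in that column); strata with zero person-time are omitted.

    Cases are first-ever cohort entries (per subject) assigned to strata by
    the subject's age band and sex at cohort_start_date and by the entry's
    calendar year.  Person-time splits observation periods at calendar-year
    boundaries; with ``censor_at_first_entry`` (default) time stops at the
    first entry date (inclusive) and repeat entries never count.  Setting it
    False counts every entry as a case against uncensored person-time.
    """
    persons = store.persons
    if by_age and len(persons) and persons["year_of_birth"].isna().all():
        raise ValueError("age stratification requested but no person has year_of_birth")

    if cohort_ids is None:
        cohort_ids = sorted(entries["cohort_id"].unique()) if len(entries) else []
    rows = []
    for cohort_id in cohort_ids:
        sub = entries[entries["cohort_id"] == cohort_id] if len(entries) else entries
        pt, cases = _person_time_and_cases(sub, store, washout_days, censor_at_first_entry)
        rows.extend(_stratify(cohort_id, pt, cases, by_age, by_sex, by_year))
    out = pd.DataFrame(rows, columns=[
        "cohort_id", "age_group", "sex", "calendar_year", "cases", "person_years", "rate_per_1000",
    ])
    out["calendar_year"] = out["calendar_year"].astype("Int64")
    return out


def _person_time_and_cases(
    entries: pd.DataFrame, store: CdmStore, washout_days: int, censor: bool
) -> tuple[dict, dict]:
    """Accumulate (age_band|None, sex, year) -> at-risk days and case counts."""
    if censor:
        first_entry = entries.groupby("subject_id")["cohort_start_date"].min().to_dict()
        case_dates: dict[int, list[pd.Timestamp]] = {s: [d] for s, d in first_entry.items()}
    else:
        first_entry = {}
        case_dates = {
            s: list(g["cohort_start_date"]) for s, g in entries.groupby("subject_id")
        }

    periods_by_person: dict[int, list[tuple[pd.Timestamp, pd.Timestamp]]] = {}
    for pid, s, e in store.observation_periods[["person_id", "start_date", "end_date"]].itertuples(index=False):
        periods_by_person.setdefault(int(pid), []).append((s, e))

    pt: dict[tuple, float] = {}
    cases: dict[tuple, int] = {}
    for pid, sex, yob in store.persons[["person_id", "sex", "year_of_birth"]].itertuples(index=False):
        pid = int(pid)
        yob_i = None if pd.isna(yob) else int(yob)
        censor_date = first_entry.get(pid) if censor else None
        for p_start, p_end in periods_by_person.get(pid, []):
            risk_start = p_start + pd.Timedelta(days=washout_days)
            risk_end = p_end if censor_date is None else min(p_end, censor_date)
            if risk_start > risk_end:
                continue
            for year in range(risk_start.year, risk_end.year + 1):
                seg_start = max(risk_start, pd.Timestamp(year, 1, 1))
                seg_end = min(risk_end, pd.Timestamp(year, 12, 31))
                if seg_start > seg_end:
                    continue
                band = None if yob_i is None else (year - yob_i) // 10
                key = (band, sex, year)
                pt[key] = pt.get(key, 0) + (seg_end - seg_start).days + 1
            for d in case_dates.get(pid, []):
                if risk_start <= d <= risk_end:
                    band = None if yob_i is None else (d.year - yob_i) // 10
                    key = (band, sex, d.year)
                    cases[key] = cases.get(key, 0) + 1
    return pt, cases


def _stratify(cohort_id, pt: dict, cases: dict, by_age: bool, by_sex: bool, by_year: bool) -> list[tuple]:
    dims_enabled = [by_age, by_sex, by_year]
    rows = []
    # every subset of the enabled dimensions, marginal (empty subset) included
    for mask in range(8):
        use = [bool(mask & (1 << i)) for i in range(3)]
        if any(u and not e for u, e in zip(use, dims_enabled)):
            continue
        agg_pt: dict[tuple, float] = {}
        agg_cases: dict[tuple, int] = {}
        for (band, sex, year), days in pt.items():
            if use[0] and band is None:
                continue
            key = (band if use[0] else None, sex if use[1] else None, year if use[2] else None)
            agg_pt[key] = agg_pt.get(key, 0) + days
        for (band, sex, year), n in cases.items():
            if use[0] and band is None:
                continue
            key = (band if use[0] else None, sex if use[1] else None, year if use[2] else None)
            agg_cases[key] = agg_cases.get(key, 0) + n
        for key in sorted(agg_pt, key=lambda k: tuple((v is None, v) for v in k)):
            band, sex, year = key
            days = agg_pt[key]
            n_cases = agg_cases.get(key, 0)
            py = days / DAYS_PER_YEAR
            rows.append((
                cohort_id,
                None if band is None else _age_band_label(band),
                sex, year, n_cases, py,
                (n_cases / py) * 1000.0 if py > 0 else np.nan,
            ))
    return rows


def time_distributions(entries: pd.DataFrame, store: CdmStore) -> pd.DataFrame:
    """Distributions (days) of observation-start->index, index->cohort-end,
    index->observation-end, per cohort.

    Entries not enclosed by any observation period are excluded with a
    logged count.  sd of a single-entry cohort is reported as 0.
    """
    if not len(entries):
        return pd.DataFrame(columns=["cohort_id", "measure", "n", "mean", "sd", "min",
                                     "p10", "p25", "median", "p75", "p90", "max"])
    merged = entries.merge(
        store.observation_periods.rename(columns={"person_id": "subject_id"}),
        on="subject_id", how="left",
    )
    inside = (merged["cohort_start_date"] >= merged["start_date"]) & (
        merged["cohort_start_date"] <= merged["end_date"]
    )
    merged = merged[inside.fillna(False)]
    n_excluded = len(entries) - len(merged.drop_duplicates(subset=["cohort_id", "subject_id", "cohort_start_date"]))
    if n_excluded > 0:
        logger.warning("time_distributions: excluded %d entr(ies) outside any observation period", n_excluded)

    rows = []
    for cohort_id, grp in merged.groupby("cohort_id"):
        values = {
            "obs_start_to_index": (grp["cohort_start_date"] - grp["start_date"]).dt.days,
            "index_to_cohort_end": (grp["cohort_end_date"] - grp["cohort_start_date"]).dt.days,
            "index_to_obs_end": (grp["end_date"] - grp["cohort_start_date"]).dt.days,
        }
        for measure in TIME_MEASURES:
            v = values[measure].to_numpy(dtype=float)
            sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            q = np.percentile(v, [10, 25, 50, 75, 90])
            rows.append((cohort_id, measure, len(v), float(np.mean(v)), sd, float(v.min()),
                         *map(float, q), float(v.max())))
    return pd.DataFrame(rows, columns=["cohort_id", "measure", "n", "mean", "sd", "min",
                                       "p10", "p25", "median", "p75", "p90", "max"])


def index_event_breakdown(
    entries: pd.DataFrame, defn: CohortDefinition, store: CdmStore
) -> pd.DataFrame:
    """Entry-event concepts coinciding with the index date.

    For every concept in the resolved union of the definition's entry-event
    concept sets, counts cohort entries having at least one event of that
    concept dated exactly cohort_start_date; an entry with k coinciding
    distinct concepts contributes to k rows.  Zero-count concepts are
    omitted.
    """
    union = defn.entry_concept_union(store)
    hits = []
    for domain, concepts in union.items():
        ev = store.clinical_events
        ev = ev[(ev["domain"] == domain) & (ev["concept_id"].isin(concepts))]
        m = entries.merge(
            ev[["person_id", "concept_id", "event_date"]],
            left_on=["subject_id", "cohort_start_date"],
            right_on=["person_id", "event_date"],
        )
        hits.append(m[["cohort_id", "subject_id", "cohort_start_date", "concept_id"]])
    if not hits:
        return pd.DataFrame(columns=["cohort_id", "concept_id", "entry_count", "subject_count"])
    joined = pd.concat(hits, ignore_index=True).drop_duplicates()
    out = joined.groupby(["cohort_id", "concept_id"]).agg(
        entry_count=("cohort_start_date", "size"), subject_count=("subject_id", "nunique")
    ).reset_index()
    return out.sort_values(["cohort_id", "entry_count"], ascending=[True, False]).reset_index(drop=True)


def visit_context(entries: pd.DataFrame, store: CdmStore) -> pd.DataFrame:
    """Distinct subjects by visit category and context around the index.

    before: visit concluded within [index-30, index-1];
    during: visit began before the index and extended to or past it;
    simultaneous: visit began on the index date;
    after: visit began within [index+1, index+30].
    Each (entry, visit) pair maps to at most one context, by precedence
    simultaneous > during > before > after.
    """
    if not len(entries) or not len(store.visits):
        return pd.DataFrame(columns=["cohort_id", "visit_category", "context", "subject_count"])
    m = entries.merge(store.visits.rename(columns={"person_id": "subject_id"}), on="subject_id")
    idx = m["cohort_start_date"]
    start_off = (m["start_date"] - idx).dt.days
    end_off = (m["end_date"] - idx).dt.days
    context = pd.Series(pd.NA, index=m.index, dtype=object)
    context[start_off.between(1, 30)] = "after"
    context[end_off.between(-30, -1)] = "before"
    context[(start_off < 0) & (end_off >= 0)] = "during"
    context[start_off == 0] = "simultaneous"
    m = m.assign(context=context).dropna(subset=["context"])
    out = m.groupby(["cohort_id", "visit_category", "context"]).agg(
        subject_count=("subject_id", "nunique")
    ).reset_index()
    return out


def cohort_overlap(entries_a: pd.DataFrame, entries_b: pd.DataFrame) -> pd.DataFrame:
    """Subject-level overlap between two cohorts (set algebra on ids)."""
    a = set(entries_a["subject_id"]) if len(entries_a) else set()
    b = set(entries_b["subject_id"]) if len(entries_b) else set()
    cid_a = int(entries_a["cohort_id"].iloc[0]) if len(entries_a) else -1
    cid_b = int(entries_b["cohort_id"].iloc[0]) if len(entries_b) else -1
    return pd.DataFrame([{
        "cohort_id_a": cid_a,
        "cohort_id_b": cid_b,
        "n_both": len(a & b),
        "n_only_a": len(a - b),
        "n_only_b": len(b - a),
    }])


def characterize(
    entries: pd.DataFrame,
    store: CdmStore,
    windows: list[tuple[int, int]] | None = None,
    rollup: bool = False,
    designated_groups: set[int] | None = None,
) -> pd.DataFrame:
    """Prevalence of observed clinical events around the index date.

    Anchored on each subject's first cohort entry; for each closed window
    (in days relative to index) and each concept, counts subjects with at
    least one event of that concept in the window (per-subject dedup).
    With ``rollup``, each observed concept is additionally reported under
    its hierarchy group (``is_group`` rows); ``designated_groups`` defaults
    to all concepts that are proper ancestors in the store's hierarchy.
    Demographics (age band at index, sex) are emitted under the index-date
    window (0, 0) with ``concept_id`` 0 and a ``covariate_name``.
    """
    windows = DEFAULT_WINDOWS if windows is None else windows
    cols = ["cohort_id", "window_start", "window_end", "concept_id", "covariate_name",
            "is_group", "n_subjects", "proportion"]
    if not len(entries):
        return pd.DataFrame(columns=cols)

    anchors = entries.sort_values("cohort_start_date").drop_duplicates(subset=["cohort_id", "subject_id"])
    rows = []
    for cohort_id, grp in anchors.groupby("cohort_id"):
        n_total = len(grp)
        m = grp[["subject_id", "cohort_start_date"]].merge(
            store.clinical_events.rename(columns={"person_id": "subject_id"}), on="subject_id"
        )
        offset = (m["event_date"] - m["cohort_start_date"]).dt.days
        for lo, hi in windows:
            in_w = m[(offset >= lo) & (offset <= hi)][["subject_id", "concept_id"]].drop_duplicates()
            counts = in_w.groupby("concept_id")["subject_id"].nunique()
            for concept_id, n in counts.items():
                rows.append((cohort_id, lo, hi, int(concept_id), None, False, int(n), n / n_total))
            if rollup and len(in_w):
                groups = designated_groups
                if groups is None:
                    anc = store.concept_ancestors
                    groups = set(
                        anc.loc[anc["ancestor_concept_id"] != anc["descendant_concept_id"],
                                "ancestor_concept_id"].astype(int)
                    )
                mapping = rollup_concepts(set(in_w["concept_id"].astype(int)), store.concept_ancestors, groups)
                grouped = in_w.assign(group=in_w["concept_id"].map(mapping))
                grouped = grouped[grouped["group"] != grouped["concept_id"]]
                gcounts = grouped.drop_duplicates(subset=["subject_id", "group"]).groupby("group")[
                    "subject_id"].nunique()
                for gid, n in gcounts.items():
                    rows.append((cohort_id, lo, hi, int(gid), None, True, int(n), n / n_total))
        # demographics under the index-date window
        sexes = grp.merge(store.persons, left_on="subject_id", right_on="person_id")
        for sex, n in sexes["sex"].value_counts().items():
            rows.append((cohort_id, 0, 0, 0, f"sex={sex}", False, int(n), n / n_total))
        with_yob = sexes.dropna(subset=["year_of_birth"])
        if len(with_yob):
            band = (
                with_yob["cohort_start_date"].dt.year - with_yob["year_of_birth"].astype(int)
            ) // 10
            for b, n in band.value_counts().items():
                rows.append((cohort_id, 0, 0, 0, f"age_group={_age_band_label(int(b))}",
                             False, int(n), n / n_total))
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["cohort_id", "window_start", "window_end", "is_group", "concept_id",
                            "covariate_name"], na_position="first").reset_index(drop=True)


def compare_characterizations(rows_target: pd.DataFrame, rows_comparator: pd.DataFrame) -> pd.DataFrame:
    """Covariate balance between two characterized cohorts.

    For binary prevalence covariates,
    ``smd = (p_t - p_c) / sqrt((p_t(1-p_t) + p_c(1-p_c)) / 2)`` (signed).
    Covariates absent from one side are treated as prevalence 0 there; smd
    is null when both proportions are equal and sit at 0 or 1 (degenerate
    pooled variance), and exactly 0 whenever the proportions are equal
    otherwise.
    """
    w_t = set(map(tuple, rows_target[["window_start", "window_end"]].drop_duplicates().to_numpy())) \
        if len(rows_target) else set()
    w_c = set(map(tuple, rows_comparator[["window_start", "window_end"]].drop_duplicates().to_numpy())) \
        if len(rows_comparator) else set()
    # an empty window on one side just means no events landed there, so only
    # flag genuinely disjoint configurations
    if w_t and w_c and not (w_t <= w_c or w_c <= w_t):
        raise ValueError(f"mismatched window sets: {sorted(w_t)} vs {sorted(w_c)}")

    key = ["window_start", "window_end", "concept_id", "covariate_name", "is_group"]
    t = rows_target[key + ["proportion"]].rename(columns={"proportion": "p_target"})
    c = rows_comparator[key + ["proportion"]].rename(columns={"proportion": "p_comparator"})
    merged = t.merge(c, on=key, how="outer")
    merged["p_target"] = merged["p_target"].fillna(0.0)
    merged["p_comparator"] = merged["p_comparator"].fillna(0.0)
    merged["cohort_id_target"] = rows_target["cohort_id"].iloc[0] if len(rows_target) else -1
    merged["cohort_id_comparator"] = rows_comparator["cohort_id"].iloc[0] if len(rows_comparator) else -1
    merged["smd"] = [
        binary_smd(pt, pc) for pt, pc in zip(merged["p_target"], merged["p_comparator"])
    ]
    cols = ["cohort_id_target", "cohort_id_comparator", "window_start", "window_end",
            "concept_id", "covariate_name", "is_group", "p_target", "p_comparator", "smd"]
    return merged[cols].sort_values(key, na_position="first").reset_index(drop=True)


def binary_smd(p_t: float, p_c: float) -> float | None:
    """Signed standardized difference of two prevalences.

    None (null) when the pooled binomial variance is zero — both
    proportions at 0 or 1 — where the statistic is undefined.
    """
    if p_t == p_c:
        if p_t in (0.0, 1.0):
            return None
        return 0.0
    pooled = (p_t * (1.0 - p_t) + p_c * (1.0 - p_c)) / 2.0
    if pooled == 0.0:
        return None
    return (p_t - p_c) / np.sqrt(pooled)


def relative_difference(count_simple: int, count_restrictive: int) -> float:
    """Percent reduction of a restrictive algorithm's count vs a simple one.

    ``(1 - restrictive/simple) * 100`` rounded half-up to one decimal.
    """
    if count_simple <= 0:
        raise ValueError("count_simple must be positive")
    value = (Decimal(1) - Decimal(count_restrictive) / Decimal(count_simple)) * Decimal(100)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
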