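"""Declarative phenotype algorithms and their instantiation.

A cohort definition is a simplified, JSON-serializable phenotype algorithm:
concept sets, entry events (earliest qualifying event becomes the index
date), a prior continuous-observation requirement (washout), an ordered
list of inclusion rules evaluated in windows relative to the index date,
and an exit strategy.  Instantiating it against a :class:`~cohortdx.cdm.CdmStore`
yields the cohort table (cohort_id, subject_id, cohort_start_date,
cohort_end_date) plus the attrition of entries/subjects across rules.

Conventions
-----------
* "Continuous observation prior to index" means the enclosing normalized
  observation period starts at least ``prior_observation_days`` before the
  index date.
* Inclusion-rule windows are closed intervals in days relative to index;
  day 0 is the index date; a ``null`` offset bound means unbounded.
* Exclusion criteria are inclusion rules with comparator ``at_most 0``.
* Instantiation is fully deterministic.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .cdm import CdmStore
from .vocabulary import ConceptSet, ConceptSetItem, resolve_concept_set

__all__ = [
    "EntryEvent",
    "InclusionRule",
    "CohortDefinition",
    "instantiate_cohort",
    "collapse_eras",
    "union_cohorts",
    "ATTRITION_COLUMNS",
]

ENTRY_COLUMNS = ["cohort_id", "subject_id", "cohort_start_date", "cohort_end_date"]
ATTRITION_COLUMNS = ["cohort_id", "rule_sequence", "rule_name", "remaining_entries", "remaining_subjects"]

Domain = Literal["condition", "drug", "procedure", "measurement", "observation"]


class ConceptSetItemModel(BaseModel):
    concept_id: int
    include_descendants: bool = False
    is_excluded: bool = False


class ConceptSetModel(BaseModel):
    concept_set_id: int
    name: str
    items: list[ConceptSetItemModel]

    def to_concept_set(self) -> ConceptSet:
        return ConceptSet(
            concept_set_id=self.concept_set_id,
            name=self.name,
            items=[ConceptSetItem(i.concept_id, i.include_descendants, i.is_excluded) for i in self.items],
        )


class EntryEvent(BaseModel):
    domain: Domain
    concept_set_id: int
    occurrence: Literal["first_ever", "all"] = "all"


class InclusionRule(BaseModel):
    name: str
    domain: Domain
    concept_set_id: int
    window: tuple[Optional[int], Optional[int]]  # closed [start, end] day offsets; None = unbounded
    comparator: Literal["at_least", "at_most", "exactly"] = "at_least"
    n: int = Field(default=1, ge=0)

    @model_validator(mode="after")
    def _window_ordered(self) -> "InclusionRule":
        lo, hi = self.window
        if lo is not None and hi is not None and lo > hi:
            raise ValueError(f"rule {self.name!r}: window start offset {lo} > end offset {hi}")
        return self


class ExitStrategy(BaseModel):
    kind: Literal["end_of_observation", "fixed_offset"] = "end_of_observation"
    offset_days: int = Field(default=0, ge=0)


class CohortDefinition(BaseModel):
    """Simplified declarative phenotype algorithm."""

    cohort_id: int
    name: str
    concept_sets: list[ConceptSetModel]
    entry_events: list[EntryEvent]
    prior_observation_days: int = Field(default=0, ge=0)
    inclusion_rules: list[InclusionRule] = Field(default_factory=list)
    exit: ExitStrategy = Field(default_factory=ExitStrategy)
    era_gap_days: int = Field(default=0, ge=0)

    @field_validator("entry_events")
    @classmethod
    def _nonempty_entry(cls, v: list[EntryEvent]) -> list[EntryEvent]:
        if not v:
            raise ValueError("cohort definition needs at least one entry event")
        return v

    @model_validator(mode="after")
    def _concept_sets_defined(self) -> "CohortDefinition":
        defined = {cs.concept_set_id for cs in self.concept_sets}
        for ev in self.entry_events:
            if ev.concept_set_id not in defined:
                raise ValueError(f"entry event references undefined concept set {ev.concept_set_id}")
        for rule in self.inclusion_rules:
            if rule.concept_set_id not in defined:
                raise ValueError(f"rule {rule.name!r} references undefined concept set {rule.concept_set_id}")
        return self

    def resolved_sets(self, store: CdmStore) -> dict[int, set[int]]:
        """Resolve every concept set against the store's hierarchy."""
        return {
            cs.concept_set_id: resolve_concept_set(
                cs.to_concept_set(), store.concept_ancestors, known_concepts=store.concept_ids
            )
            for cs in self.concept_sets
        }

    def entry_concept_union(self, store: CdmStore) -> dict[str, set[int]]:
        """Resolved entry concepts grouped by domain (for index breakdown)."""
        resolved = self.resolved_sets(store)
        out: dict[str, set[int]] = {}
        for ev in self.entry_events:
            out.setdefault(ev.domain, set()).update(resolved[ev.concept_set_id])
        return out


def _matching_events(store: CdmStore, domain: str, concepts: set[int]) -> pd.DataFrame:
    ev = store.clinical_events
    return ev[(ev["domain"] == domain) & (ev["concept_id"].isin(concepts))]


def instantiate_cohort(
    defn: CohortDefinition, store: CdmStore
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run a phenotype algorithm against a store.

    Returns ``(entries, attrition)``.  Entry candidates are qualifying
    events (per entry event, ``first_ever`` restricted to the subject's
    earliest event of that concept set in the whole store, before washout
    filtering); each candidate must sit inside a normalized observation
    period starting at least ``prior_observation_days`` earlier, and the
    earliest surviving candidate per subject becomes the index.  Inclusion
    rules then filter indexes sequentially (attrition row per rule,
    sequence 0 = entry events) — a subject whose index fails a rule is out,
    with no fallback to a later candidate.  Survivors get an exit date and
    are era-collapsed.
    If the collapse changes counts, a final "era collapse" attrition row is
    appended so the last row always equals the emitted cohort's counts.
    """
    resolved = defn.resolved_sets(store)
    periods = store.observation_periods

    cand_frames = []
    for ev in defn.entry_events:
        events = _matching_events(store, ev.domain, resolved[ev.concept_set_id])
        if ev.occurrence == "first_ever" and len(events):
            first = events.groupby("person_id")["event_date"].min().rename("event_date").reset_index()
            events = first
        cand_frames.append(events[["person_id", "event_date"]])
    candidates = (
        pd.concat(cand_frames, ignore_index=True).drop_duplicates()
        if cand_frames else pd.DataFrame(columns=["person_id", "event_date"])
    )

    # washout: candidate must fall inside a period starting >= prior_days before it
    if len(candidates):
        merged = candidates.merge(periods, on="person_id", how="inner")
        ok = (
            (merged["event_date"] >= merged["start_date"] + pd.Timedelta(days=defn.prior_observation_days))
            & (merged["event_date"] <= merged["end_date"])
        )
        merged = merged[ok]
        entries = merged.rename(columns={
            "person_id": "subject_id", "event_date": "cohort_start_date",
            "start_date": "period_start", "end_date": "period_end",
        }).drop_duplicates(subset=["subject_id", "cohort_start_date"])
        # the earliest qualifying event IS the index: a subject whose index
        # fails an inclusion rule drops out, with no fallback to later events
        entries = entries.sort_values(["subject_id", "cohort_start_date"]).groupby(
            "subject_id", as_index=False).first()
    else:
        entries = pd.DataFrame(columns=["subject_id", "cohort_start_date", "period_start", "period_end"])

    attrition_rows = [(defn.cohort_id, 0, "entry events", len(entries), entries["subject_id"].nunique())]

    for seq, rule in enumerate(defn.inclusion_rules, start=1):
        entries = _apply_rule(entries, rule, resolved[rule.concept_set_id], store)
        attrition_rows.append(
            (defn.cohort_id, seq, rule.name, len(entries), entries["subject_id"].nunique())
        )

    if len(entries):
        if defn.exit.kind == "end_of_observation":
            end = entries["period_end"]
        else:
            end = (entries["cohort_start_date"] + pd.Timedelta(days=defn.exit.offset_days)).clip(
                upper=entries["period_end"]
            )
        out = pd.DataFrame({
            "cohort_id": defn.cohort_id,
            "subject_id": entries["subject_id"].astype(int).to_numpy(),
            "cohort_start_date": entries["cohort_start_date"].to_numpy(),
            "cohort_end_date": pd.to_datetime(end.to_numpy()),
        }).sort_values(["subject_id", "cohort_start_date"]).reset_index(drop=True)
    else:
        out = _empty_entries()
    collapsed = collapse_eras(out, gap_days=defn.era_gap_days)
    if len(collapsed) != len(out):
        attrition_rows.append((
            defn.cohort_id, len(defn.inclusion_rules) + 1, "era collapse",
            len(collapsed), collapsed["subject_id"].nunique(),
        ))
    attrition = pd.DataFrame(attrition_rows, columns=ATTRITION_COLUMNS)
    return collapsed, attrition


def _apply_rule(entries: pd.DataFrame, rule: InclusionRule, concepts: set[int], store: CdmStore) -> pd.DataFrame:
    if not len(entries):
        return entries
    events = _matching_events(store, rule.domain, concepts)[["person_id", "event_date"]]
    merged = entries.reset_index().merge(events, left_on="subject_id", right_on="person_id", how="left")
    delta = (merged["event_date"] - merged["cohort_start_date"]).dt.days
    lo, hi = rule.window
    in_window = merged["event_date"].notna()
    if lo is not None:
        in_window &= delta >= lo
    if hi is not None:
        in_window &= delta <= hi
    counts = merged.assign(_hit=in_window).groupby("index")["_hit"].sum()
    counts = counts.reindex(np.arange(len(entries)), fill_value=0)
    if rule.comparator == "at_least":
        keep = counts >= rule.n
    elif rule.comparator == "at_most":
        keep = counts <= rule.n
    else:
        keep = counts == rule.n
    return entries.reset_index(drop=True)[keep.to_numpy()]


def _empty_entries() -> pd.DataFrame:
    return pd.DataFrame({
        "cohort_id": pd.Series(dtype=int),
        "subject_id": pd.Series(dtype=int),
        "cohort_start_date": pd.Series(dtype="datetime64[ns]"),
        "cohort_end_date": pd.Series(dtype="datetime64[ns]"),
    })


def collapse_eras(entries: pd.DataFrame, gap_days: int = 0) -> pd.DataFrame:
    """Merge a subject's entries whose gap is <= ``gap_days``.

    Two entries with a gap of g days have g days strictly between them:
    (s1,e1) and (s2,e2) with s2 > e1 merge when (s2 - e1 - 1) <= gap_days.
    Overlapping entries always merge.  Output is sorted and non-overlapping
    per (cohort_id, subject_id).
    """
    if gap_days < 0:
        raise ValueError(f"gap_days must be >= 0, got {gap_days}")
    if not len(entries):
        return entries.copy()
    out = []
    sorted_e = entries.sort_values(["cohort_id", "subject_id", "cohort_start_date", "cohort_end_date"])
    for (cid, sid), grp in sorted_e.groupby(["cohort_id", "subject_id"], sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["cohort_start_date"], grp["cohort_end_date"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif (s - cur_e).days - 1 <= gap_days:
                cur_e = max(cur_e, e)
            else:
                out.append((cid, sid, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((cid, sid, cur_s, cur_e))
    return pd.DataFrame(out, columns=ENTRY_COLUMNS)


def union_cohorts(entry_frames: list[pd.DataFrame], cohort_id: int, gap_days: int = 0) -> pd.DataFrame:
    """Union the entries of several definitions into one cohort.

    Used to express disjunctive entry arms (e.g. "AD diagnosis with
    confirmation" OR "dementia followed by two AD prescriptions") as
    separate simple definitions combined afterwards.  Earliest start wins
    where entries overlap, via era-collapse.
    """
    if not entry_frames:
        return _empty_entries()
    merged = pd.concat(entry_frames, ignore_index=True)
    merged["cohort_id"] = cohort_id
    merged = merged.drop_duplicates(subset=["subject_id", "cohort_start_date", "cohort_end_date"])
    return collapse_eras(merged, gap_days=gap_days)
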