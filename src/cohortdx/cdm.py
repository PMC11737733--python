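"""Load, validate and index OMOP-CDM-shaped patient-level tables.

The store holds the person, observation-period, visit and vocabulary
tables plus a single unified *clinical event* view merging the domain
event tables (condition, drug, procedure, measurement, observation) with
their domain labels preserved.  All dates are whole calendar days
(datetime64 normalized to midnight); arithmetic downstream is in integer
days.

Observation periods that overlap or abut (next start <= previous end + 1
day) are merged at load into a canonical non-overlapping interval set —
"continuous observation" semantics need one — while the raw rows are kept
for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CdmStore",
    "CdmLoadError",
    "ReferentialIntegrityError",
    "Finding",
    "load_cdm",
    "observed_interval",
    "validate_cdm",
]

SEXES = ("FEMALE", "MALE", "OTHER")
EVENT_DOMAINS = ("condition", "drug", "procedure", "measurement", "observation")
VISIT_CATEGORIES = ("inpatient", "outpatient", "emergency", "other")

# OMOP v5.3 column conventions per domain table: (concept col, start col, end col)
DOMAIN_TABLES: dict[str, tuple[str, str, str, str | None]] = {
    "condition_occurrence": ("condition", "condition_concept_id", "condition_start_date", "condition_end_date"),
    "drug_exposure": ("drug", "drug_concept_id", "drug_exposure_start_date", "drug_exposure_end_date"),
    "procedure_occurrence": ("procedure", "procedure_concept_id", "procedure_date", None),
    "measurement": ("measurement", "measurement_concept_id", "measurement_date", None),
    "observation": ("observation", "observation_concept_id", "observation_date", None),
}

# Standard OMOP visit concept ids -> category
VISIT_CONCEPT_CATEGORY = {9201: "inpatient", 9202: "outpatient", 9203: "emergency"}

_GENDER_CONCEPT_SEX = {8532: "FEMALE", 8507: "MALE"}


class CdmLoadError(Exception):
    """Fatal problem while loading CDM tables."""


class ReferentialIntegrityError(CdmLoadError):
    """A table references person/concept ids that do not exist."""


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    table: str
    message: str


@dataclass
class CdmStore:
    """Validated in-memory collection of OMOP-shaped tables."""

    persons: pd.DataFrame            # person_id, sex, year_of_birth (nullable)
    observation_periods: pd.DataFrame  # normalized: person_id, start_date, end_date
    clinical_events: pd.DataFrame    # event_id, person_id, concept_id, domain, event_date, end_date
    visits: pd.DataFrame             # person_id, visit_category, start_date, end_date
    concepts: pd.DataFrame           # concept_id, concept_name, domain_id, vocabulary_id
    concept_ancestors: pd.DataFrame  # ancestor_concept_id, descendant_concept_id
    source_name: str = "source"
    raw_observation_periods: pd.DataFrame | None = None
    load_log: list[str] = field(default_factory=list)

    @property
    def concept_ids(self) -> set[int]:
        return set(int(c) for c in self.concepts["concept_id"])

    def events_in_domain(self, domain: str) -> pd.DataFrame:
        return self.clinical_events[self.clinical_events["domain"] == domain]

    def save(self, directory: str | Path) -> None:
        """Write the store back out in the CSV layout ``load_cdm`` reads.

        Events are split back into their OMOP domain tables; a store that
        was built in memory with interleaved domains is re-serialized in
        canonical domain order.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        persons = self.persons.copy()
        persons["gender_concept_id"] = persons["sex"].map(
            {v: k for k, v in _GENDER_CONCEPT_SEX.items()}
        ).astype("Int64")
        persons[["person_id", "gender_concept_id", "year_of_birth"]].to_csv(
            directory / "person.csv", index=False
        )
        raw = self.raw_observation_periods if self.raw_observation_periods is not None else self.observation_periods
        _write_dates(raw.rename(columns={"start_date": "observation_period_start_date",
                                         "end_date": "observation_period_end_date"}),
                     directory / "observation_period.csv")
        for table, (domain, concept_col, start_col, end_col) in DOMAIN_TABLES.items():
            sub = self.clinical_events[self.clinical_events["domain"] == domain]
            out = pd.DataFrame({
                "person_id": sub["person_id"].to_numpy(),
                concept_col: sub["concept_id"].to_numpy(),
                start_col: sub["event_date"].to_numpy(),
            })
            if end_col is not None:
                out[end_col] = sub["end_date"].to_numpy()
            _write_dates(out, directory / f"{table}.csv")
        visits = pd.DataFrame({
            "person_id": self.visits["person_id"].to_numpy(),
            "visit_concept_id": self.visits["visit_category"].map(
                {v: k for k, v in VISIT_CONCEPT_CATEGORY.items()}
            ).fillna(0).astype(int).to_numpy(),
            "visit_start_date": self.visits["start_date"].to_numpy(),
            "visit_end_date": self.visits["end_date"].to_numpy(),
        })
        _write_dates(visits, directory / "visit_occurrence.csv")
        self.concepts.to_csv(directory / "concept.csv", index=False)
        self.concept_ancestors.to_csv(directory / "concept_ancestor.csv", index=False)
        with open(directory / "source_name.txt", "w") as fh:
            fh.write(self.source_name)


def _write_dates(df: pd.DataFrame, path: Path) -> None:
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_datetime64_any_dtype(df[col]):
            df[col] = df[col].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def _read_table(directory: Path, name: str, column_map: dict[str, dict[str, str]]) -> pd.DataFrame | None:
    for suffix, reader in ((".csv", pd.read_csv), (".parquet", pd.read_parquet)):
        path = directory / f"{name}{suffix}"
        if path.exists():
            df = reader(path)
            renames = column_map.get(name, {})
            if renames:
                df = df.rename(columns={v: k for k, v in renames.items()})
            return df
    return None


def _parse_dates(df: pd.DataFrame, table: str, cols: list[str], required: bool = True) -> pd.DataFrame:
    df = df.copy()
    for col in cols:
        if col not in df.columns:
            if required:
                raise CdmLoadError(f"table {table!r} is missing column {col!r}")
            continue
        raw = df[col]
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & raw.notna()
        if bad.any():
            rows = list(df.index[bad][:5])
            raise CdmLoadError(
                f"table {table!r}, column {col!r}: unparseable date(s) at row(s) {rows} "
                f"(e.g. {raw[bad].iloc[0]!r}); expected ISO-8601 YYYY-MM-DD"
            )
        df[col] = parsed.dt.normalize()
    return df


def normalize_periods(periods: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or abutting (gap <= 0 days) periods per person."""
    out = []
    for pid, grp in periods.sort_values(["person_id", "start_date", "end_date"]).groupby("person_id", sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["start_date"], grp["end_date"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + pd.Timedelta(days=1):
                cur_e = max(cur_e, e)
            else:
                out.append((pid, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((pid, cur_s, cur_e))
    return pd.DataFrame(out, columns=["person_id", "start_date", "end_date"])


def load_cdm(
    path_spec: str | Path,
    source_name: str | None = None,
    column_map: dict[str, dict[str, str]] | None = None,
) -> CdmStore:
    """Load a directory of OMOP-shaped CSV/Parquet tables into a ``CdmStore``.

    Mandatory tables: ``person``, ``observation_period``, at least one event
    domain table, and ``concept``.  ``column_map`` maps canonical column
    names to the names used in the files, per table
    (``{"person": {"person_id": "subject"}}``).
    """
    directory = Path(path_spec)
    if not directory.is_dir():
        raise CdmLoadError(f"CDM path {directory} is not a directory")
    column_map = column_map or {}
    log: list[str] = []

    person_raw = _read_table(directory, "person", column_map)
    if person_raw is None:
        raise CdmLoadError("mandatory table 'person' not found")
    if "person_id" not in person_raw.columns:
        raise CdmLoadError("table 'person' is missing column 'person_id'")
    if person_raw["person_id"].duplicated().any():
        dupes = sorted(person_raw.loc[person_raw["person_id"].duplicated(), "person_id"].unique()[:5])
        raise CdmLoadError(f"table 'person': duplicate person_id values {dupes}")
    if "sex" in person_raw.columns:
        sex = person_raw["sex"].where(person_raw["sex"].isin(SEXES), "OTHER")
    elif "gender_concept_id" in person_raw.columns:
        sex = person_raw["gender_concept_id"].map(_GENDER_CONCEPT_SEX).fillna("OTHER")
    else:
        sex = pd.Series("OTHER", index=person_raw.index)
    persons = pd.DataFrame({
        "person_id": person_raw["person_id"].astype(int),
        "sex": sex.to_numpy(),
        "year_of_birth": person_raw.get("year_of_birth", pd.Series(pd.NA, index=person_raw.index)),
    })
    persons["year_of_birth"] = persons["year_of_birth"].astype("Int64")
    n_no_yob = int(persons["year_of_birth"].isna().sum())
    if n_no_yob:
        log.append(f"{n_no_yob} person(s) lack year_of_birth; excluded from age-stratified outputs only")
    known_persons = set(persons["person_id"])

    op_raw = _read_table(directory, "observation_period", column_map)
    if op_raw is None:
        raise CdmLoadError("mandatory table 'observation_period' not found")
    op_raw = op_raw.rename(columns={
        "observation_period_start_date": "start_date",
        "observation_period_end_date": "end_date",
    })
    op_raw = _parse_dates(op_raw, "observation_period", ["start_date", "end_date"])
    _check_persons(op_raw, "observation_period", known_persons)
    raw_periods = op_raw[["person_id", "start_date", "end_date"]].reset_index(drop=True)
    bad = raw_periods["end_date"] < raw_periods["start_date"]
    if bad.any():
        raise CdmLoadError(
            f"table 'observation_period': end_date before start_date at row(s) {list(raw_periods.index[bad][:5])}"
        )
    periods = normalize_periods(raw_periods)

    event_frames = []
    n_domain_tables = 0
    for table, (domain, concept_col, start_col, end_col) in DOMAIN_TABLES.items():
        df = _read_table(directory, table, column_map)
        if df is None:
            continue
        n_domain_tables += 1
        cols = [start_col] + ([end_col] if end_col else [])
        df = _parse_dates(df, table, [c for c in cols if c in df.columns] or [start_col])
        if concept_col not in df.columns or start_col not in df.columns:
            raise CdmLoadError(f"table {table!r} is missing {concept_col!r} or {start_col!r}")
        rejected = df[concept_col].isna() | df[start_col].isna()
        if rejected.any():
            log.append(f"table {table!r}: rejected {int(rejected.sum())} row(s) with missing concept or date")
            df = df[~rejected]
        _check_persons(df, table, known_persons)
        frame = pd.DataFrame({
            "person_id": df["person_id"].astype(int).to_numpy(),
            "concept_id": df[concept_col].astype(int).to_numpy(),
            "domain": domain,
            "event_date": df[start_col].to_numpy(),
            "end_date": df[end_col].to_numpy() if end_col and end_col in df.columns else pd.NaT,
        })
        event_frames.append(frame)
    if n_domain_tables == 0:
        raise CdmLoadError("no event domain table found (need at least one of "
                           + ", ".join(DOMAIN_TABLES))
    events = pd.concat(event_frames, ignore_index=True) if event_frames else _empty_events()
    events.insert(0, "event_id", np.arange(len(events), dtype=np.int64))
    events["end_date"] = pd.to_datetime(events["end_date"])

    visits_raw = _read_table(directory, "visit_occurrence", column_map)
    if visits_raw is not None:
        visits_raw = _parse_dates(visits_raw, "visit_occurrence", ["visit_start_date", "visit_end_date"])
        _check_persons(visits_raw, "visit_occurrence", known_persons)
        if "visit_category" in visits_raw.columns:
            cat = visits_raw["visit_category"].where(visits_raw["visit_category"].isin(VISIT_CATEGORIES), "other")
        else:
            cat = visits_raw["visit_concept_id"].map(VISIT_CONCEPT_CATEGORY).fillna("other")
        visits = pd.DataFrame({
            "person_id": visits_raw["person_id"].astype(int).to_numpy(),
            "visit_category": cat.to_numpy(),
            "start_date": visits_raw["visit_start_date"].to_numpy(),
            "end_date": visits_raw["visit_end_date"].to_numpy(),
        })
    else:
        visits = pd.DataFrame(columns=["person_id", "visit_category", "start_date", "end_date"])

    concepts = _read_table(directory, "concept", column_map)
    if concepts is None:
        raise CdmLoadError("mandatory table 'concept' not found")
    if concepts["concept_id"].duplicated().any():
        raise CdmLoadError("table 'concept': duplicate concept_id values")
    ancestors = _read_table(directory, "concept_ancestor", column_map)
    if ancestors is None:
        ancestors = pd.DataFrame({
            "ancestor_concept_id": concepts["concept_id"].to_numpy(),
            "descendant_concept_id": concepts["concept_id"].to_numpy(),
        })

    if source_name is None:
        name_file = directory / "source_name.txt"
        source_name = name_file.read_text().strip() if name_file.exists() else directory.name

    for line in log:
        logger.info("%s: %s", source_name, line)
    return CdmStore(
        persons=persons,
        observation_periods=periods,
        clinical_events=events,
        visits=visits,
        concepts=concepts,
        concept_ancestors=ancestors,
        source_name=source_name,
        raw_observation_periods=raw_periods,
        load_log=log,
    )


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({
        "person_id": pd.Series(dtype=int),
        "concept_id": pd.Series(dtype=int),
        "domain": pd.Series(dtype=object),
        "event_date": pd.Series(dtype="datetime64[ns]"),
        "end_date": pd.Series(dtype="datetime64[ns]"),
    })


def _check_persons(df: pd.DataFrame, table: str, known: set[int]) -> None:
    if "person_id" not in df.columns:
        raise CdmLoadError(f"table {table!r} is missing column 'person_id'")
    missing = set(df["person_id"].astype(int)) - known
    if missing:
        raise ReferentialIntegrityError(
            f"table {table!r} references person_id(s) absent from person table: {sorted(missing)[:10]}"
        )


def from_frames(
    persons: pd.DataFrame,
    observation_periods: pd.DataFrame,
    clinical_events: pd.DataFrame,
    visits: pd.DataFrame | None = None,
    concepts: pd.DataFrame | None = None,
    concept_ancestors: pd.DataFrame | None = None,
    source_name: str = "source",
) -> CdmStore:
    """Assemble a store from in-memory frames (tests and the generator).

    Periods are normalized; events get surrogate ids in append order.
    """
    from .vocabulary import build_synthetic_vocabulary

    if concepts is None or concept_ancestors is None:
        syn_c, syn_a = build_synthetic_vocabulary()
        concepts = concepts if concepts is not None else syn_c
        concept_ancestors = concept_ancestors if concept_ancestors is not None else syn_a
    persons = persons.copy()
    persons["year_of_birth"] = persons["year_of_birth"].astype("Int64")
    events = clinical_events.copy().reset_index(drop=True)
    if "end_date" not in events.columns:
        events["end_date"] = pd.NaT
    if "event_id" not in events.columns:
        events.insert(0, "event_id", np.arange(len(events), dtype=np.int64))
    events["event_date"] = pd.to_datetime(events["event_date"])
    events["end_date"] = pd.to_datetime(events["end_date"])
    raw = observation_periods.copy()
    raw["start_date"] = pd.to_datetime(raw["start_date"])
    raw["end_date"] = pd.to_datetime(raw["end_date"])
    if visits is None:
        visits = pd.DataFrame(columns=["person_id", "visit_category", "start_date", "end_date"])
    visits = visits.copy()
    visits["start_date"] = pd.to_datetime(visits["start_date"])
    visits["end_date"] = pd.to_datetime(visits["end_date"])
    return CdmStore(
        persons=persons,
        observation_periods=normalize_periods(raw),
        clinical_events=events,
        visits=visits,
        concepts=concepts,
        concept_ancestors=concept_ancestors,
        source_name=source_name,
        raw_observation_periods=raw.reset_index(drop=True),
    )


def observed_interval(store: CdmStore, person_id: int) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Normalized, sorted, non-overlapping observation intervals of a person."""
    if person_id not in set(store.persons["person_id"]):
        raise KeyError(f"person {person_id} not found in store {store.source_name!r}")
    sub = store.observation_periods[store.observation_periods["person_id"] == person_id]
    sub = sub.sort_values("start_date")
    return [(s, e) for s, e in zip(sub["start_date"], sub["end_date"])]


def validate_cdm(store: CdmStore) -> list[Finding]:
    """Enumerate invariant violations; empty list iff the store is consistent.

    Findings are data, not exceptions: error-level findings are genuine
    invariant violations, warning-level ones are plausibility flags (e.g.
    events dated outside all of their person's observation periods).
    """
    findings: list[Finding] = []
    persons = store.persons
    if persons["person_id"].duplicated().any():
        findings.append(Finding("error", "person", "duplicate person_id values"))
    if len(store.observation_periods):
        latest_year = int(store.observation_periods["end_date"].dt.year.max())
        yob = persons["year_of_birth"].dropna()
        bad = yob[yob > latest_year]
        if len(bad):
            findings.append(Finding(
                "error", "person",
                f"{len(bad)} person(s) born after latest observation year {latest_year}"))

    op = store.observation_periods
    bad = op[op["end_date"] < op["start_date"]]
    if len(bad):
        findings.append(Finding("error", "observation_period",
                                f"{len(bad)} period(s) with end before start"))
    known = set(persons["person_id"])
    for table, df, datecol in (
        ("observation_period", op, None),
        ("clinical_event", store.clinical_events, "event_date"),
        ("visit", store.visits, "start_date"),
    ):
        missing = set(df["person_id"].astype(int)) - known if len(df) else set()
        if missing:
            findings.append(Finding("error", table,
                                    f"person_id(s) not in person table: {sorted(missing)[:10]}"))

    ev = store.clinical_events
    if len(ev):
        bad = ev[ev["end_date"].notna() & (ev["end_date"] < ev["event_date"])]
        if len(bad):
            findings.append(Finding("error", "clinical_event",
                                    f"{len(bad)} event(s) with end_date before event_date"))
        merged = ev.merge(op, on="person_id", how="left")
        inside = (merged["event_date"] >= merged["start_date"]) & (merged["event_date"] <= merged["end_date_y"]) \
            if "end_date_y" in merged.columns else \
            (merged["event_date"] >= merged["start_date"]) & (merged["event_date"] <= merged["end_date"])
        covered = merged.assign(_in=inside.fillna(False)).groupby("event_id")["_in"].any()
        n_out = int((~covered).sum())
        if n_out:
            findings.append(Finding("warning", "clinical_event",
                                    f"{n_out} event(s) dated outside all observation periods of their person"))
    vis = store.visits
    if len(vis):
        bad = vis[vis["end_date"] < vis["start_date"]]
        if len(bad):
            findings.append(Finding("error", "visit", f"{len(bad)} visit(s) with end before start"))
    return findings
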