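"""Synthetic OMOP-shaped data with known ground truth.

The generator emits one disease per scenario.  Each person gets an
observation period inside the calendar span; true disease onset follows an
exponential waiting time at the configured rate per 1000 person-years
(optionally modulated by sex and age band) within observed time, so the
first-onset process is Poisson and the empirical onset rate is an unbiased
estimate of the configured one.  The diagnosis code is emitted at
onset + coding lag; with probability ``p_treatment_before_code`` a
treatment code appears at the true onset — i.e. strictly before the
diagnosis code whenever the lag is positive — injecting exactly the
index-date misclassification a treatment-OR-diagnosis phenotype algorithm
will surface in its index event breakdown.  Symptom codes, background
noise codes and visits are layered on top.

Ground truth (true onset dates, per-event provenance) is returned
separately and is never read by the diagnostics path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import cdm
from .vocabulary import (
    DIAGNOSIS_CODES,
    N_NOISE,
    NOISE_BASE,
    SYMPTOM_CODES,
    TREATMENT_CODES,
    build_synthetic_vocabulary,
)

__all__ = ["ScenarioConfig", "GroundTruth", "generate_source", "truth_incidence",
           "sle_like", "ad_like"]


class LagSpec(BaseModel):
    """Coding-lag distribution from true onset to first diagnosis code."""

    kind: Literal["constant", "geometric"] = "constant"
    days: float = Field(default=0, ge=0)  # constant value, or mean of the geometric


class SymptomSpec(BaseModel):
    concept_id: int
    probability: float = Field(ge=0, le=1)
    window: tuple[int, int] = (-60, 0)  # day offsets relative to true onset

    @field_validator("window")
    @classmethod
    def _ordered(cls, v: tuple[int, int]) -> tuple[int, int]:
        if v[0] > v[1]:
            raise ValueError(f"symptom window {v} has start after end")
        return v


class ScenarioConfig(BaseModel):
    """Stated world of one synthetic source."""

    n_persons: int = Field(ge=1)
    calendar_span: tuple[int, int] = (2010, 2019)
    sex_ratio_female: float = Field(default=0.5, ge=0, le=1)
    age_distribution: dict[str, float] = Field(
        default_factory=lambda: {"20-29": 0.2, "30-39": 0.2, "40-49": 0.2, "50-59": 0.2, "60-69": 0.2}
    )
    onset_rate_per_1000py: float = Field(default=2.0, ge=0)
    sex_rate_multipliers: dict[str, float] = Field(default_factory=dict)
    age_rate_multipliers: dict[str, float] = Field(default_factory=dict)
    coding_lag: LagSpec = Field(default_factory=LagSpec)
    p_treatment_before_code: float = Field(default=0.0, ge=0, le=1)
    treatment_after_days: int = Field(default=30, ge=0)
    symptom_emission: list[SymptomSpec] = Field(default_factory=list)
    background_code_rate: float = Field(default=2.0, ge=0)  # noise events per person-year
    visit_model: dict[str, float] = Field(
        default_factory=lambda: {"outpatient": 0.8, "inpatient": 0.1, "emergency": 0.1}
    )
    seed: int = 0

    @field_validator("calendar_span")
    @classmethod
    def _span(cls, v: tuple[int, int]) -> tuple[int, int]:
        if v[1] < v[0]:
            raise ValueError(f"calendar span {v} ends before it starts")
        return v

    @field_validator("age_distribution")
    @classmethod
    def _bands(cls, v: dict[str, float]) -> dict[str, float]:
        if not v or any(w < 0 for w in v.values()) or sum(v.values()) <= 0:
            raise ValueError("age_distribution needs non-negative weights summing > 0")
        for label in v:
            lo, _, hi = label.partition("-")
            if not (lo.isdigit() and hi.isdigit()):
                raise ValueError(f"age band label {label!r} is not of the form 'lo-hi'")
        return v

    @field_validator("visit_model")
    @classmethod
    def _visits(cls, v: dict[str, float]) -> dict[str, float]:
        bad = set(v) - set(cdm.VISIT_CATEGORIES)
        if bad or sum(v.values()) <= 0:
            raise ValueError(f"visit_model has unknown categories {sorted(bad)} or zero mass")
        return v


@dataclass
class GroundTruth:
    """True onsets and per-event provenance for one generated source."""

    source_name: str
    onsets: pd.DataFrame       # person_id, onset_date
    provenance: pd.DataFrame   # event_id, tag in {diagnosis, treatment, symptom, noise}


def _band_bounds(label: str) -> tuple[int, int]:
    lo, _, hi = label.partition("-")
    return int(lo), int(hi)


def _draw_lag(rng: np.random.Generator, spec: LagSpec, n: int) -> np.ndarray:
    if spec.kind == "constant":
        return np.full(n, int(round(spec.days)), dtype=np.int64)
    if spec.days <= 0:
        return np.zeros(n, dtype=np.int64)
    # geometric on {0, 1, ...} with mean `days`
    p = 1.0 / (spec.days + 1.0)
    return rng.geometric(p, size=n).astype(np.int64) - 1


def generate_source(
    config: ScenarioConfig, source_name: str = "synthetic"
) -> tuple[cdm.CdmStore, GroundTruth]:
    """Generate a CDM store plus ground truth; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    start_year, end_year = config.calendar_span
    span_start = pd.Timestamp(start_year, 1, 1)
    span_days = (pd.Timestamp(end_year, 12, 31) - span_start).days + 1

    person_id = np.arange(1, n + 1, dtype=np.int64)
    sex = np.where(rng.random(n) < config.sex_ratio_female, "FEMALE", "MALE")
    bands = list(config.age_distribution)
    weights = np.array([config.age_distribution[b] for b in bands], dtype=float)
    band_idx = rng.choice(len(bands), size=n, p=weights / weights.sum())
    ages = np.empty(n, dtype=np.int64)
    for i, b in enumerate(bands):
        lo, hi = _band_bounds(b)
        mask = band_idx == i
        ages[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    yob = start_year - ages

    # observation periods: at least ~one year each, random in/out within the span
    min_len = min(365, span_days)
    obs_start = rng.integers(0, max(span_days - min_len, 1), size=n)
    obs_end = obs_start + min_len + (rng.random(n) * (span_days - obs_start - min_len)).astype(np.int64)
    obs_end = np.minimum(obs_end, span_days - 1)

    # true onset: exponential waiting time within observed days
    rate = np.full(n, config.onset_rate_per_1000py, dtype=float)
    for s, mult in config.sex_rate_multipliers.items():
        rate[sex == s] *= mult
    for b, mult in config.age_rate_multipliers.items():
        lo, hi = _band_bounds(b)
        rate[(ages >= lo) & (ages <= hi)] *= mult
    daily = rate / 1000.0 / 365.25
    with np.errstate(divide="ignore"):
        wait = np.where(daily > 0, rng.exponential(1.0, size=n) / np.where(daily > 0, daily, 1.0), np.inf)
    onset_day = obs_start + np.floor(wait).astype(np.float64)
    has_onset = onset_day <= obs_end
    onset_day = np.where(has_onset, onset_day, -1).astype(np.int64)

    events: list[tuple[int, int, str, int, str]] = []  # person, concept, domain, day, tag

    onset_pids = person_id[has_onset]
    onset_days = onset_day[has_onset]
    n_onset = len(onset_pids)
    person_end = dict(zip(person_id, obs_end))

    lag = _draw_lag(rng, config.coding_lag, n_onset)
    diag_day = onset_days + lag
    diag_concept = rng.choice(DIAGNOSIS_CODES, size=n_onset)
    treat_before = rng.random(n_onset) < config.p_treatment_before_code
    treat_concept = rng.choice(TREATMENT_CODES, size=n_onset)
    for i in range(n_onset):
        pid = int(onset_pids[i])
        end = person_end[pid]
        if diag_day[i] <= end:
            events.append((pid, int(diag_concept[i]), "condition", int(diag_day[i]), "diagnosis"))
        t_day = onset_days[i] if treat_before[i] else diag_day[i] + config.treatment_after_days
        if t_day <= end:
            events.append((pid, int(treat_concept[i]), "drug", int(t_day), "treatment"))
        for spec in config.symptom_emission:
            if rng.random() < spec.probability:
                s_day = onset_days[i] + int(rng.integers(spec.window[0], spec.window[1] + 1))
                if obs_start[pid - 1] <= s_day <= end:  # person_id is 1..n positional
                    events.append((pid, spec.concept_id, "condition", int(s_day), "symptom"))

    # background noise codes over observed time
    obs_years = (obs_end - obs_start + 1) / 365.25
    n_noise = rng.poisson(config.background_code_rate * obs_years)
    for i in np.nonzero(n_noise)[0]:
        days = rng.integers(obs_start[i], obs_end[i] + 1, size=int(n_noise[i]))
        concepts = NOISE_BASE + rng.integers(0, N_NOISE, size=int(n_noise[i]))
        for d, c in zip(days, concepts):
            events.append((int(person_id[i]), int(c), "condition", int(d), "noise"))

    ev = pd.DataFrame(events, columns=["person_id", "concept_id", "domain", "day", "tag"])
    ev = ev.sort_values(["person_id", "day", "concept_id"], kind="stable").reset_index(drop=True)
    ev["event_date"] = span_start + pd.to_timedelta(ev["day"], unit="D")
    ev["event_id"] = np.arange(len(ev), dtype=np.int64)

    # one visit per clinical event, category per the visit model
    cats = list(config.visit_model)
    probs = np.array([config.visit_model[c] for c in cats], dtype=float)
    if len(ev):
        vcat = np.array(cats, dtype=object)[rng.choice(len(cats), size=len(ev), p=probs / probs.sum())]
        v_extra = np.where(vcat == "inpatient", rng.integers(1, 8, size=len(ev)), 0)
        visits = pd.DataFrame({
            "person_id": ev["person_id"].to_numpy(),
            "visit_category": vcat,
            "start_date": ev["event_date"].to_numpy(),
            "end_date": (ev["event_date"] + pd.to_timedelta(v_extra, unit="D")).to_numpy(),
        })
        # clip visit ends to the person's observation end
        end_map = {int(p): span_start + pd.Timedelta(days=int(e)) for p, e in zip(person_id, obs_end)}
        cap = pd.to_datetime(visits["person_id"].map(end_map))
        visits["end_date"] = pd.to_datetime(visits["end_date"]).where(
            pd.to_datetime(visits["end_date"]) <= cap, cap
        )
    else:
        visits = None

    persons = pd.DataFrame({"person_id": person_id, "sex": sex, "year_of_birth": yob})
    periods = pd.DataFrame({
        "person_id": person_id,
        "start_date": span_start + pd.to_timedelta(obs_start, unit="D"),
        "end_date": span_start + pd.to_timedelta(obs_end, unit="D"),
    })
    concept, ancestor = build_synthetic_vocabulary()
    store = cdm.from_frames(
        persons=persons,
        observation_periods=periods,
        clinical_events=ev[["event_id", "person_id", "concept_id", "domain", "event_date"]],
        visits=visits,
        concepts=concept,
        concept_ancestors=ancestor,
        source_name=source_name,
    )
    truth = GroundTruth(
        source_name=source_name,
        onsets=pd.DataFrame({
            "person_id": onset_pids,
            "onset_date": span_start + pd.to_timedelta(onset_days, unit="D"),
        }),
        provenance=ev[["event_id", "tag"]].copy(),
    )
    return store, truth


def truth_incidence(truth: GroundTruth, store: cdm.CdmStore) -> float:
    """Gold-standard onset rate per 1000 person-years.

    Uses the same person-time conventions as
    :func:`cohortdx.diagnostics.incidence_rates` (365.25-day years,
    inclusive day counts, censoring at the true onset date), so it is
    directly comparable with a phenotype algorithm's estimated rate.
    """
    from .diagnostics import incidence_rates

    if truth.source_name != store.source_name:
        raise ValueError(
            f"ground truth is for source {truth.source_name!r}, store is {store.source_name!r}")
    pseudo = pd.DataFrame({
        "cohort_id": 0,
        "subject_id": truth.onsets["person_id"].to_numpy(),
        "cohort_start_date": truth.onsets["onset_date"].to_numpy(),
        "cohort_end_date": truth.onsets["onset_date"].to_numpy(),
    })
    rows = incidence_rates(pseudo, store, by_age=False, by_sex=False, by_year=False,
                           cohort_ids=[0])
    if not len(rows):
        return 0.0
    marginal = rows.iloc[0]
    return 0.0 if marginal["person_years"] == 0 else float(marginal["rate_per_1000"])


def sle_like(n_persons: int = 20_000, seed: int = 0) -> ScenarioConfig:
    """Female-skewed autoimmune-disease scenario with heavy
    treatment-before-coding mass, emulating index-date misclassification."""
    return ScenarioConfig(
        n_persons=n_persons,
        calendar_span=(2010, 2019),
        sex_ratio_female=0.55,
        age_distribution={"10-19": 0.15, "20-29": 0.25, "30-39": 0.25, "40-49": 0.2, "50-59": 0.15},
        onset_rate_per_1000py=1.0,
        sex_rate_multipliers={"FEMALE": 5.0, "MALE": 1.0},
        coding_lag=LagSpec(kind="geometric", days=45),
        p_treatment_before_code=0.4,
        symptom_emission=[SymptomSpec(concept_id=c, probability=0.3, window=(-90, 0))
                          for c in SYMPTOM_CODES],
        background_code_rate=2.0,
        seed=seed,
    )


def ad_like(n_persons: int = 20_000, seed: int = 0) -> ScenarioConfig:
    """Elderly-onset dementia scenario for comparing a simple vs a
    restrictive phenotype algorithm."""
    return ScenarioConfig(
        n_persons=n_persons,
        calendar_span=(2010, 2019),
        sex_ratio_female=0.6,
        age_distribution={"60-69": 0.3, "70-79": 0.4, "80-89": 0.3},
        onset_rate_per_1000py=8.0,
        age_rate_multipliers={"60-69": 0.5, "70-79": 1.0, "80-89": 2.0},
        coding_lag=LagSpec(kind="geometric", days=60),
        p_treatment_before_code=0.1,
        treatment_after_days=14,
        background_code_rate=4.0,
        seed=seed,
    )
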