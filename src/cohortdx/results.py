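"""File-based results model: censoring, export, import, multi-source merge.

A :class:`DiagnosticsBundle` is the set of named result tables one
diagnostics run produces for one data source, plus run metadata.  Before
leaving a site the bundle is censored: every person/entry count ``c`` with
``0 < c < min_cell_count`` is replaced by the sentinel ``-min_cell_count``
(so consumers can distinguish "censored" from "zero" and recover the
policy) and any quantity derived from a censored count (a proportion, a
rate, distribution statistics) is nulled rather than recomputed, which
would allow back-calculation.  Zero counts pass through.

Export writes one headered CSV per table with stable column order plus a
JSON manifest (file names, row counts, SHA-256 digest per file); the run
timestamp lives in the metadata record but is excluded from the digests so
identical runs yield digest-equal manifests.  No exported table carries a
person-level identifier column.  Merging bundles from several sources is
row-wise concatenation keyed by source name — never cross-source
aggregation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import SCHEMA_VERSION

__all__ = [
    "CensoringPolicy",
    "DiagnosticsBundle",
    "TABLE_SCHEMAS",
    "censor",
    "export_bundle",
    "load_bundle",
    "merge_bundles",
]


@dataclass(frozen=True)
class CensoringPolicy:
    """Minimum-cell-count rule; ``min_cell_count = 0`` disables censoring."""

    min_cell_count: int = 5

    def __post_init__(self) -> None:
        if self.min_cell_count < 0:
            raise ValueError("min_cell_count must be >= 0")


# table -> (ordered columns, count columns, {count column: derived columns nulled with it})
TABLE_SCHEMAS: dict[str, tuple[list[str], list[str], dict[str, list[str]]]] = {
    "cohort": (["cohort_id", "cohort_name"], [], {}),
    "cohort_count": (["cohort_id", "entry_count", "subject_count"],
                     ["entry_count", "subject_count"], {}),
    "attrition": (["cohort_id", "rule_sequence", "rule_name", "remaining_entries", "remaining_subjects"],
                  ["remaining_entries", "remaining_subjects"], {}),
    "incidence_rate": (["cohort_id", "age_group", "sex", "calendar_year", "cases",
                        "person_years", "rate_per_1000"],
                       ["cases"], {"cases": ["rate_per_1000"]}),
    "time_distribution": (["cohort_id", "measure", "n", "mean", "sd", "min", "p10", "p25",
                           "median", "p75", "p90", "max"],
                          ["n"], {"n": ["mean", "sd", "min", "p10", "p25", "median", "p75", "p90", "max"]}),
    "index_event_breakdown": (["cohort_id", "concept_id", "entry_count", "subject_count"],
                              ["entry_count", "subject_count"], {}),
    "visit_context": (["cohort_id", "visit_category", "context", "subject_count"],
                      ["subject_count"], {}),
    "cohort_overlap": (["cohort_id_a", "cohort_id_b", "n_both", "n_only_a", "n_only_b"],
                       ["n_both", "n_only_a", "n_only_b"], {}),
    "characterization": (["cohort_id", "window_start", "window_end", "concept_id", "covariate_name",
                          "is_group", "n_subjects", "proportion"],
                         ["n_subjects"], {"n_subjects": ["proportion"]}),
    "balance": (["cohort_id_target", "cohort_id_comparator", "window_start", "window_end",
                 "concept_id", "covariate_name", "is_group", "p_target", "p_comparator", "smd"],
                [], {}),
}

_FORBIDDEN_COLUMNS = {"subject_id", "person_id"}

_ROUND_COLUMNS = {"person_years", "rate_per_1000", "proportion", "p_target", "p_comparator",
                  "smd", "mean", "sd"}


@dataclass
class DiagnosticsBundle:
    source_name: str
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION
    tool_version: str = ""
    run_timestamp: str = ""
    policy: CensoringPolicy | None = None
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.tool_version:
            from . import __version__
            self.tool_version = __version__
        if not self.run_timestamp:
            self.run_timestamp = datetime.now(timezone.utc).isoformat()
        for name, df in self.tables.items():
            if name not in TABLE_SCHEMAS:
                raise ValueError(f"unknown results table {name!r}")
            cols, _, _ = TABLE_SCHEMAS[name]
            extra = [c for c in df.columns if c not in cols and c != "source_name"]
            bad = set(df.columns) & _FORBIDDEN_COLUMNS
            if bad:
                raise ValueError(f"table {name!r} carries person-level identifier column(s) {sorted(bad)}")
            if extra:
                raise ValueError(f"table {name!r} has columns outside its schema: {extra}")

    def table(self, name: str) -> pd.DataFrame:
        cols, _, _ = TABLE_SCHEMAS[name]
        if name in self.tables:
            return self.tables[name]
        return pd.DataFrame(columns=cols)


def censor(bundle: DiagnosticsBundle, policy: CensoringPolicy) -> DiagnosticsBundle:
    """Apply the minimum-cell-count rule; idempotent."""
    k = policy.min_cell_count
    new_tables: dict[str, pd.DataFrame] = {}
    for name, df in bundle.tables.items():
        _, count_cols, derived = TABLE_SCHEMAS[name]
        df = df.copy()
        if k > 0:
            for col in count_cols:
                if col not in df.columns or not len(df):
                    continue
                mask = (df[col] > 0) & (df[col] < k)
                if mask.any():
                    for dcol in derived.get(col, []):
                        if dcol in df.columns:
                            df[dcol] = df[dcol].astype(object)
                            df.loc[mask, dcol] = None
                    df[col] = df[col].where(~mask, -k)
        new_tables[name] = df
    return replace(bundle, tables=new_tables, policy=policy, censored=True)


def _serialize_table(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        if col not in out.columns:
            out[col] = pd.NA
    cols = list(columns) + (["source_name"] if "source_name" in out.columns else [])
    out = out[cols]
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
        elif col in _ROUND_COLUMNS:
            out[col] = out[col].map(
                lambda v: float(f"{v:.5g}") if isinstance(v, float) and v == v else v
            )
    return out


def export_bundle(bundle: DiagnosticsBundle, directory: str | Path) -> dict:
    """Write one CSV per table plus ``manifest.json``; returns the manifest.

    Refuses to export an uncensored bundle: the censoring pass must run
    first (a zero-threshold policy counts — the pass is what certifies the
    bundle for release).
    """
    if not bundle.censored:
        raise ValueError("refusing to export an uncensored bundle; run censor() first")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for name in TABLE_SCHEMAS:
        cols, _, _ = TABLE_SCHEMAS[name]
        df = _serialize_table(bundle.table(name), cols)
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        files[f"{name}.csv"] = {"rows": int(len(df)), "sha256": digest}
    manifest = {
        "schema_version": bundle.schema_version,
        "source_name": bundle.source_name,
        "min_cell_count": bundle.policy.min_cell_count if bundle.policy else 0,
        "files": files,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    metadata = {
        "tool_version": bundle.tool_version,
        "run_timestamp": bundle.run_timestamp,
        "schema_version": bundle.schema_version,
        "source_name": bundle.source_name,
    }
    with open(directory / "metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
    return manifest


def load_bundle(directory: str | Path) -> DiagnosticsBundle:
    """Read an exported bundle directory back into memory."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    meta_path = directory / "metadata.json"
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    tables = {}
    for name in TABLE_SCHEMAS:
        path = directory / f"{name}.csv"
        if path.exists():
            tables[name] = pd.read_csv(path)
    return DiagnosticsBundle(
        source_name=manifest["source_name"],
        tables=tables,
        schema_version=manifest["schema_version"],
        tool_version=metadata.get("tool_version", ""),
        run_timestamp=metadata.get("run_timestamp", ""),
        policy=CensoringPolicy(manifest.get("min_cell_count", 0)),
        censored=True,
    )


def merge_bundles(bundles: list[DiagnosticsBundle]) -> DiagnosticsBundle:
    """Concatenate bundles from distinct sources into one for joint review."""
    if not bundles:
        raise ValueError("nothing to merge")
    versions = {b.schema_version for b in bundles}
    if len(versions) > 1:
        raise ValueError(f"schema version mismatch across bundles: {sorted(versions)}")
    names = [b.source_name for b in bundles]
    if len(names) != len(set(names)):
        raise ValueError(f"duplicate source_name(s) in merge: {sorted(names)}")
    tables: dict[str, pd.DataFrame] = {}
    for name in TABLE_SCHEMAS:
        parts = []
        for b in bundles:
            df = b.table(name).copy()
            if "source_name" not in df.columns:
                df["source_name"] = b.source_name
            parts.append(df)
        merged = pd.concat(parts, ignore_index=True)
        if len(merged):
            tables[name] = merged
    return DiagnosticsBundle(
        source_name="+".join(names),
        tables=tables,
        schema_version=bundles[0].schema_version,
        policy=bundles[0].policy,
        censored=all(b.censored for b in bundles),
    )
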