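"""Concept sets and hierarchy operations.

A concept set is a declarative list of vocabulary concepts, each optionally
expanded to its descendants and optionally excluded; resolving it against
the concept-ancestor closure yields the flat set of codes a phenotype
algorithm actually matches. The same closure supports rolling raw codes up
to designated group ancestors for characterization output.

Exclusion semantics follow the OHDSI convention: all inclusions are
expanded first, then all exclusions are expanded and subtracted, so an item
that is both included and excluded resolves to excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ConceptSetItem",
    "ConceptSet",
    "resolve_concept_set",
    "rollup_concepts",
    "descendants_of",
    "build_synthetic_vocabulary",
]


@dataclass(frozen=True)
class ConceptSetItem:
    concept_id: int
    include_descendants: bool = False
    is_excluded: bool = False


@dataclass
class ConceptSet:
    concept_set_id: int
    name: str
    items: list[ConceptSetItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [it.concept_id for it in self.items]
        if len(ids) != len(set(ids)):
            raise ValueError(f"concept set {self.concept_set_id!r}: duplicate item concept_ids")
        if not any(not it.is_excluded for it in self.items):
            raise ValueError(f"concept set {self.concept_set_id!r}: needs at least one non-excluded item")


def _descendant_map(ancestors: pd.DataFrame) -> dict[int, set[int]]:
    """ancestor_concept_id -> set of descendant ids (from the closure table)."""
    out: dict[int, set[int]] = {}
    for anc, desc in zip(
        ancestors["ancestor_concept_id"].to_numpy(), ancestors["descendant_concept_id"].to_numpy()
    ):
        out.setdefault(int(anc), set()).add(int(desc))
    return out


def descendants_of(concept_id: int, ancestors: pd.DataFrame) -> set[int]:
    """Descendants of ``concept_id`` per the closure table, including itself."""
    sub = ancestors.loc[ancestors["ancestor_concept_id"] == concept_id, "descendant_concept_id"]
    return set(int(c) for c in sub) | {int(concept_id)}


def resolve_concept_set(
    cs: ConceptSet,
    ancestors: pd.DataFrame,
    known_concepts: set[int] | None = None,
) -> set[int]:
    """Resolve a concept set to the flat set of matched concept ids.

    Parameters
    ----------
    cs
        The concept set expression.
    ancestors
        Concept-ancestor closure table with columns ``ancestor_concept_id``
        and ``descendant_concept_id`` (transitive and reflexive).
    known_concepts
        When given, every referenced concept id must be a member; unknown
        ids raise ``KeyError`` naming the offender.
    """
    if known_concepts is not None:
        unknown = [it.concept_id for it in cs.items if it.concept_id not in known_concepts]
        if unknown:
            raise KeyError(f"concept set {cs.concept_set_id!r} references unknown concept ids {unknown}")

    def expand(item: ConceptSetItem) -> set[int]:
        if item.include_descendants:
            return descendants_of(item.concept_id, ancestors)
        return {item.concept_id}

    included: set[int] = set()
    for it in cs.items:
        if not it.is_excluded:
            included |= expand(it)
    for it in cs.items:
        if it.is_excluded:
            included -= expand(it)
    return included


def rollup_concepts(
    concept_ids: set[int],
    ancestors: pd.DataFrame,
    designated_groups: set[int],
) -> dict[int, int]:
    """Map each concept to its nearest designated group ancestor.

    The roll-up policy is "nearest designated ancestor": among the
    designated group concepts that are ancestors of ``c`` (including ``c``
    itself), the one with the fewest descendants wins — fewest descendants
    is the most specific group.  Ties break on the smaller concept id so the
    mapping is deterministic.  A concept with no designated ancestor maps to
    itself.
    """
    desc_map = _descendant_map(ancestors)
    group_size = {g: len(desc_map.get(g, {g})) for g in designated_groups}
    out: dict[int, int] = {}
    for c in concept_ids:
        candidates = [g for g in designated_groups if c in desc_map.get(g, set()) or g == c]
        if not candidates:
            out[c] = c
        else:
            out[c] = min(candidates, key=lambda g: (group_size[g], g))
    return out


# ---------------------------------------------------------------------------
# Synthetic miniature vocabulary
# ---------------------------------------------------------------------------

# Concept-id layout of the shipped three-level synthetic vocabulary.
DISEASE_ROOT = 1000          # disease of interest (group level)
DIAGNOSIS_CODES = [1001, 1002, 1003]          # leaf diagnosis codes
TREATMENT_ROOT = 2000        # drug class
TREATMENT_CODES = [2001, 2002, 2003, 2004]    # individual drugs
SYMPTOM_ROOT = 3000          # sign/symptom group
SYMPTOM_CODES = [3001, 3002, 3003]
VISIT_CONCEPTS = {9201: "Inpatient Visit", 9202: "Outpatient Visit", 9203: "Emergency Room Visit"}
NOISE_BASE = 5000            # 5000..5149: unrelated background condition codes
N_NOISE = 150


def build_synthetic_vocabulary() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the ~200-concept, three-level synthetic vocabulary.

    Returns ``(concept, concept_ancestor)`` tables in OMOP column naming.
    The ancestor table is a reflexive, transitive closure: the hierarchy is
    only two edges deep (root -> leaf), so the closure is the edge list plus
    reflexive pairs.
    """
    rows = [(DISEASE_ROOT, "Synthetic disease", "condition", "SNOMED")]
    rows += [(c, f"Synthetic disease diagnosis {i+1}", "condition", "ICD") for i, c in enumerate(DIAGNOSIS_CODES)]
    rows += [(TREATMENT_ROOT, "Synthetic treatment class", "drug", "ATC")]
    rows += [(c, f"Synthetic treatment {i+1}", "drug", "RxNorm") for i, c in enumerate(TREATMENT_CODES)]
    rows += [(SYMPTOM_ROOT, "Synthetic symptom group", "condition", "SNOMED")]
    rows += [(c, f"Synthetic symptom {i+1}", "condition", "SNOMED") for i, c in enumerate(SYMPTOM_CODES)]
    rows += [(c, name, "visit", "Visit") for c, name in VISIT_CONCEPTS.items()]
    rows += [
        (NOISE_BASE + i, f"Background condition {i+1}", "condition", "SNOMED")
        for i in range(N_NOISE)
    ]
    concept = pd.DataFrame(rows, columns=["concept_id", "concept_name", "domain_id", "vocabulary_id"])

    pairs = [(DISEASE_ROOT, c) for c in DIAGNOSIS_CODES]
    pairs += [(TREATMENT_ROOT, c) for c in TREATMENT_CODES]
    pairs += [(SYMPTOM_ROOT, c) for c in SYMPTOM_CODES]
    pairs += [(c, c) for c in concept["concept_id"]]
    ancestor = pd.DataFrame(pairs, columns=["ancestor_concept_id", "descendant_concept_id"])
    return concept, ancestor
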