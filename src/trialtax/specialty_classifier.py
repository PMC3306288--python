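"""Rule-based assignment of studies to clinical specialties.

For each specialty every study falls into exactly one of five groups, read
off the summarized tags of its condition terms:

  Group 1  any term summarized Y            -> label Y
  Group 2  else, any term summarized A      -> label Ambiguous
  Group 3  else, >= 1 term and every term N -> label N
  Group 4  else, any term N                 -> label N  (some terms untagged)
  Group 5  otherwise                        -> label Unclassified

Groups 3 and 4 are pooled as the negative class; a study may be Y for
several specialties at once. Terms come from the submitted ``condition``
field, the NLM-generated ``condition_browse`` field, or their union.
Pediatrics and genomics use dedicated selectors instead of term tags.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from ._text import normalize_term
from .registry_etl import INTERVENTIONAL, StudyRecord

SOURCES = ("both", "condition_only", "condition_browse_only")

GROUP_LABELS = {1: "Y", 2: "Ambiguous", 3: "N", 4: "N", 5: "Unclassified"}

#: summary-tag lookup shape produced by annotation.build_term_summaries
TermSummaries = Mapping[str, Mapping[str, str]]


@dataclass(frozen=True)
class CohortFilter:
    """Cohort restriction applied before classification (default: the FDAAA
    window — interventional studies registered after September 27, 2007)."""

    study_type: str = INTERVENTIONAL
    registered_after: _dt.date = _dt.date(2007, 9, 27)

    def admits(self, study: StudyRecord) -> bool:
        if self.study_type is not None and study.study_type != self.study_type:
            return False
        if self.registered_after is not None:
            if study.registration_date is None:
                return False
            if study.registration_date <= self.registered_after:
                return False
        return True


@dataclass(frozen=True)
class SpecialtyAssignment:
    study_id: str
    specialty: str
    group: int
    label: str
    source: str

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(f"group must be 1..5, got {self.group}")
        if self.label != GROUP_LABELS[self.group]:
            raise ValueError(
                f"label {self.label!r} inconsistent with group {self.group}"
            )


def study_term_tags(
    study: StudyRecord,
    summaries: TermSummaries,
    specialty: str,
    source: str = "both",
) -> tuple[list[str], int]:
    """Resolve a study's terms to summary tags for one specialty.

    Returns the list of resolved tags (multiset — duplicates kept, so the
    union source is exactly the concatenation of the two single sources)
    and the count of terms with no annotation at all.
    """
    if source not in SOURCES:
        raise ValueError(f"source must be one of {SOURCES}, got {source!r}")
    lookup = summaries.get(specialty, {})
    terms: list[str] = []
    if source in ("both", "condition_only"):
        terms.extend(study.conditions)
    if source in ("both", "condition_browse_only"):
        terms.extend(study.condition_browse_terms)
    tags: list[str] = []
    unannotated = 0
    for term in terms:
        tag = lookup.get(normalize_term(term))
        if tag is None:
            unannotated += 1
        else:
            tags.append(tag)
    return tags, unannotated


def assign_group(tags: Sequence[str], n_unannotated: int = 0) -> int:
    """Apply the five-group rules to a study's resolved tags.

    "All terms N" (Group 3) requires at least one term and zero unannotated
    terms; a study with nothing annotated but some N evidence is Group 4,
    and a study with no evidence at all is Group 5.
    """
    tagset = set(tags)
    if not tagset <= {"Y", "N", "A"}:
        raise ValueError(f"tags must be Y/N/A, got {sorted(tagset)}")
    if "Y" in tagset:
        return 1
    if "A" in tagset:
        return 2
    if tags and n_unannotated == 0:  # every term annotated, all N
        return 3
    if "N" in tagset:
        return 4
    return 5


def classify_study(
    study: StudyRecord,
    summaries: TermSummaries,
    specialty: str,
    source: str = "both",
) -> SpecialtyAssignment:
    tags, unannotated = study_term_tags(study, summaries, specialty, source)
    group = assign_group(tags, unannotated)
    return SpecialtyAssignment(
        study_id=study.study_id,
        specialty=specialty,
        group=group,
        label=GROUP_LABELS[group],
        source=source,
    )


def classify_cohort(
    studies: Iterable[StudyRecord],
    summaries: TermSummaries,
    specialty: str,
    cohort_filter: CohortFilter | None = CohortFilter(),
    source: str = "both",
    exclusion: Callable[[StudyRecord], bool] | None = None,
) -> list[SpecialtyAssignment]:
    """Classify every study surviving the cohort filter for one specialty.

    ``exclusion`` is a hook for investigation-specific inclusion/exclusion
    criteria (a predicate returning True to drop a study); no default.
    """
    if specialty not in summaries:
        raise ValueError(
            f"unknown specialty {specialty!r}; annotated specialties: "
            f"{sorted(summaries)}"
        )
    out = []
    for study in studies:
        if cohort_filter is not None and not cohort_filter.admits(study):
            continue
        if exclusion is not None and exclusion(study):
            continue
        out.append(classify_study(study, summaries, specialty, source))
    return out


# ---------------------------------------------------------------------------
# special-case selectors

PEDIATRIC_MAX_AGE_YEARS = 18.0

DEFAULT_GENOMICS_KEYWORDS = ("gene", "genomic", "DNA")


def pediatric_selector(study: StudyRecord) -> bool:
    """Enrollment restricted to a pediatric population (max age <= 18 years).

    A missing maximum age evidences no restriction and is not pediatric.
    """
    return (
        study.max_age_years is not None
        and study.max_age_years <= PEDIATRIC_MAX_AGE_YEARS
    )


def genomics_selector(
    study: StudyRecord,
    keywords: Sequence[str] = DEFAULT_GENOMICS_KEYWORDS,
) -> bool:
    """Keyword search over conditions, interventions, keywords, and title.

    Matching is case-insensitive on word boundaries ("gene" does not match
    "generalized"). Observational studies are eligible, so no cohort filter
    is applied here.
    """
    pattern = re.compile(
        r"\b(?:" + "|".join(re.escape(k) for k in keywords) + r")\b",
        re.IGNORECASE,
    )
    fields: list[str] = [
        *study.conditions,
        *study.intervention_browse_terms,
        *study.keywords,
        study.brief_title,
    ]
    return any(pattern.search(text) for text in fields if text)


# ---------------------------------------------------------------------------
# export


def write_assignments(
    assignments: Sequence[SpecialtyAssignment], path: str | Path
) -> None:
    """Assignments CSV: study_id, specialty, group, label, source."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "study_id": a.study_id,
                "specialty": a.specialty,
                "group": a.group,
                "label": a.label,
                "source": a.source,
            }
            for a in assignments
        ],
        columns=["study_id", "specialty", "group", "label", "source"],
    ).to_csv(path, index=False)


def specialty_dataset(
    assignments: Iterable[SpecialtyAssignment], pooled: bool = True
) -> list[str]:
    """Study ids forming the specialty dataset: Group 1, or Groups 1 and 2
    pooled (the investigation-facing dataset)."""
    groups = {1, 2} if pooled else {1}
    return sorted(a.study_id for a in assignments if a.group in groups)
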