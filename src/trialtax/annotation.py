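"""Specialty annotations over MeSH tree numbers and free-text terms.

Each (tree number, specialty) pair carries a Y or N tag from a clinical
reviewer. Because one term may hold several tree numbers, per-term tags are
summarized: all-Y -> Y, all-N -> N, mixed -> A (ambiguous). Annotated
hierarchies are validated for parent/child consistency — selecting or
negating a parent node should match all annotated descendants — and
inconsistencies are flagged for specialist review, never auto-corrected.

Untagged terms are a distinct state from N: they drive the Group 4 / Group 5
split downstream and must never default to N.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Collection, Iterable, Mapping

from ._text import normalize_term
from .mesh_thesaurus import MeshThesaurus
from .registry_etl import INTERVENTIONAL, StudyRecord

logger = logging.getLogger(__name__)

TAGS = ("Y", "N")
SUMMARY_TAGS = ("Y", "N", "A")
KEY_TYPES = ("mesh_id", "term")

REVIEW_LABELS = ("yes", "no", "unknown")


@dataclass(frozen=True)
class TermAnnotation:
    """One reviewer tag: key is a tree number (mesh_id) or a normalized term."""

    key: str
    specialty: str
    tag: str
    key_type: str = "mesh_id"

    def __post_init__(self) -> None:
        if self.tag not in TAGS:
            raise ValueError(f"tag must be Y or N, got {self.tag!r}")
        if self.key_type not in KEY_TYPES:
            raise ValueError(f"key_type must be one of {KEY_TYPES}")


def summarize_term_tags(tags: Collection[str]) -> str:
    """Summarize the per-tree-number tags of one term: Y / N / A.

    All tags Y -> "Y"; all N -> "N"; a mix -> "A". An empty collection is an
    error — untagged terms must be routed to the "no annotation" state by the
    caller, not summarized.
    """
    tagset = set(tags)
    if not tagset:
        raise ValueError("cannot summarize an empty tag set")
    if not tagset <= set(TAGS):
        raise ValueError(f"tags must be Y or N, got {sorted(tagset)}")
    if tagset == {"Y"}:
        return "Y"
    if tagset == {"N"}:
        return "N"
    return "A"


def build_term_summaries(
    annotations: Iterable[TermAnnotation],
    thesaurus: MeshThesaurus,
) -> dict[str, dict[str, str]]:
    """Per-(specialty, term) summary lookup used by the classifier.

    mesh_id annotations contribute through the thesaurus (all tags on a
    term's tree numbers are pooled); term-keyed annotations contribute their
    tag directly. Returns ``{specialty: {normalized term: Y|N|A}}``. Tree
    numbers absent from the thesaurus are logged and skipped.
    """
    pooled: dict[str, dict[str, set[str]]] = {}
    for ann in annotations:
        if ann.key_type == "mesh_id":
            if ann.key not in thesaurus:
                logger.warning("annotation on unknown tree number %s skipped", ann.key)
                continue
            term = thesaurus.term_for_id(ann.key)
        else:
            term = normalize_term(ann.key)
        pooled.setdefault(ann.specialty, {}).setdefault(term, set()).add(ann.tag)
    return {
        specialty: {term: summarize_term_tags(tags) for term, tags in terms.items()}
        for specialty, terms in pooled.items()
    }


# ---------------------------------------------------------------------------
# hierarchy consistency


@dataclass
class ConsistencyReport:
    """Parents whose tag disagrees with at least one annotated descendant.

    ``n_flagged_parents / n_parents_checked`` is the headline rate; a parent
    means any annotated id with >= 1 annotated descendant, so leaves are
    never flagged. ``orphans`` lists annotated ids absent from the thesaurus.
    """

    specialty: str
    flagged: list[tuple[str, str]] = field(default_factory=list)
    n_flagged_parents: int = 0
    n_parents_checked: int = 0
    orphans: list[str] = field(default_factory=list)
    accepted: list[str] = field(default_factory=list)

    @property
    def flagged_parents(self) -> list[str]:
        return sorted({parent for parent, _ in self.flagged})

    def rate(self) -> float | None:
        if self.n_parents_checked == 0:
            return None
        return self.n_flagged_parents / self.n_parents_checked


def check_hierarchy_consistency(
    annotations: Mapping[str, str],
    specialty: str,
    thesaurus: MeshThesaurus,
    accept: Collection[str] = (),
) -> ConsistencyReport:
    """Flag annotated parents whose tag mismatches any annotated descendant.

    ``annotations`` maps tree numbers to Y/N for one specialty. Parents on
    the ``accept`` list (previously reviewed and confirmed) are counted but
    not re-flagged. Annotations on ids missing from the thesaurus go to the
    orphan list rather than failing.
    """
    report = ConsistencyReport(specialty=specialty)
    accepted = set(accept)
    in_tree = {}
    for tree_number, tag in annotations.items():
        if tag not in TAGS:
            raise ValueError(f"tag must be Y or N, got {tag!r} on {tree_number}")
        if tree_number in thesaurus:
            in_tree[tree_number] = tag
        else:
            report.orphans.append(tree_number)
    report.orphans.sort()

    for tree_number in sorted(in_tree):
        annotated_desc = thesaurus.descendants_of(tree_number) & in_tree.keys()
        if not annotated_desc:
            continue  # a leaf within the annotated set; never a parent
        report.n_parents_checked += 1
        mismatches = sorted(
            d for d in annotated_desc if in_tree[d] != in_tree[tree_number]
        )
        if not mismatches:
            continue
        if tree_number in accepted:
            report.accepted.append(tree_number)
            continue
        report.n_flagged_parents += 1
        report.flagged.extend((tree_number, child) for child in mismatches)
    return report


def find_conflicting_terms(
    annotations: Mapping[str, str],
    thesaurus: MeshThesaurus,
    specialty: str | None = None,
) -> list[str]:
    """Terms whose tree numbers carry mixed Y/N tags (would summarize to A).

    These are the multi-tree terms queued for specialist adjudication.
    Returns display forms, sorted.
    """
    tags_by_term: dict[str, set[str]] = {}
    for tree_number, tag in annotations.items():
        if tree_number not in thesaurus:
            continue
        tags_by_term.setdefault(thesaurus.term_for_id(tree_number), set()).add(tag)
    return sorted(
        thesaurus.display_term(term)
        for term, tags in tags_by_term.items()
        if summarize_term_tags(tags) == "A"
    )


# ---------------------------------------------------------------------------
# free-text term eligibility

FDAAA_CUTOFF = _dt.date(2007, 9, 27)


def eligible_free_text_terms(
    studies: Iterable[StudyRecord],
    cutoff_date: _dt.date = FDAAA_CUTOFF,
    min_count: int = 5,
    exclude_terms: Collection[str] | None = None,
) -> dict[str, int]:
    """Submitted condition terms frequent enough to warrant specialist review.

    Counts distinct qualifying studies per normalized term over
    interventional studies registered strictly after ``cutoff_date``; terms
    reaching ``min_count`` are returned with their counts (descending count,
    then term). ``exclude_terms`` removes terms already covered elsewhere
    (e.g. thesaurus headings).
    """
    excluded = {normalize_term(t) for t in exclude_terms} if exclude_terms else set()
    counts: dict[str, int] = {}
    for study in studies:
        if study.study_type != INTERVENTIONAL:
            continue
        if study.registration_date is None or study.registration_date <= cutoff_date:
            continue
        for term in {normalize_term(c) for c in study.conditions}:
            if term and term not in excluded:
                counts[term] = counts.get(term, 0) + 1
    return {
        term: count
        for term, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if count >= min_count
    }


# ---------------------------------------------------------------------------
# dual review and adjudication


@dataclass
class ReviewRecord:
    """Two independent reviews of one item, with third-party adjudication."""

    item: str
    reviewer_a: str
    reviewer_b: str
    adjudicated: str | None = None

    def __post_init__(self) -> None:
        for label in (self.reviewer_a, self.reviewer_b):
            if label not in REVIEW_LABELS:
                raise ValueError(f"review label must be one of {REVIEW_LABELS}")
        if self.adjudicated is not None and self.adjudicated not in REVIEW_LABELS:
            raise ValueError(f"adjudicated label must be one of {REVIEW_LABELS}")

    @property
    def disagreement(self) -> bool:
        return self.reviewer_a != self.reviewer_b


def adjudicate(review: ReviewRecord) -> str:
    """Final label: the common label on agreement, else the adjudicated one.

    A disagreement without an adjudicated label is an error naming the item.
    """
    if not review.disagreement:
        return review.reviewer_a
    if review.adjudicated is None:
        raise ValueError(
            f"item {review.item!r}: reviewers disagree "
            f"({review.reviewer_a} vs {review.reviewer_b}) and no adjudication given"
        )
    return review.adjudicated


# ---------------------------------------------------------------------------
# file formats


def load_annotations(path: str | Path) -> list[TermAnnotation]:
    """Read the annotation CSV (columns key_type, key, specialty, tag)."""
    out = []
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            out.append(
                TermAnnotation(
                    key=row["key"],
                    specialty=row["specialty"],
                    tag=row["tag"],
                    key_type=row["key_type"],
                )
            )
    return out


def save_annotations(annotations: Iterable[TermAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["key_type", "key", "specialty", "tag"])
        for ann in sorted(
            annotations, key=lambda a: (a.specialty, a.key_type, a.key)
        ):
            writer.writerow([ann.key_type, ann.key, ann.specialty, ann.tag])


def load_accept_list(path: str | Path) -> set[str]:
    """Plain-text file of accepted parent ids, one per line; '#' comments."""
    out = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out
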