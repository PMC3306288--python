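"""Seeded generators for miniature thesauri, registry cohorts with planted
specialty truth, annotation sets with controlled inconsistency, and dual
reviews with controlled error.

Everything is a pure function of :class:`SynthConfig` (the seed fully
determines all output), so every other module can be exercised — and its
error estimators calibrated against known planted rates — without any
external download.

Key structural choice: each top-level tree node is planted as Y for *at most
one* specialty, so specialty subtrees are disjoint and a study's true
specialty memberships follow exactly from the terms embedded in it. Free-text
noise terms come from a fixed nonsense lexicon guaranteed not to collide with
generated thesaurus headings.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from ._text import normalize_term
from .annotation import ReviewRecord, TermAnnotation
from .mesh_thesaurus import MAX_DEPTH, MeshThesaurus, depth_of
from .registry_etl import (
    EXPANDED_ACCESS,
    INTERVENTIONAL,
    MISSING,
    OBSERVATIONAL,
    StudyRecord,
    parse_study_design,
    serialize_study_record,
)

import datetime as _dt


# nonsense free-text conditions/keywords; the "zz" token keeps them out of
# any generated thesaurus heading
NOISE_TERMS = tuple(
    f"{adj} {noun} zz"
    for adj in ("chronic", "acute", "recurrent", "idiopathic", "familial")
    for noun in ("malaise", "fatigue", "syndrome", "episode", "condition", "disorder")
)

_SYLLABLES = (
    "car", "neo", "derm", "gastr", "nephr", "neur", "onc", "pulm", "rheum",
    "hep", "oste", "myel", "angi", "cephal", "entero", "fibro", "glyco",
)
_SUFFIXES = ("itis", "osis", "emia", "oma", "pathy", "algia")

_CATEGORY_LETTERS = "CEFGABDH" + "".join(
    c for c in string.ascii_uppercase if c not in "CEFGABDH"
)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic world.

    Defaults describe a small but structurally faithful registry: an
    FDAAA-era year span, ~82% interventional studies, three annotated
    specialties at ~10% prevalence each, a four-category thesaurus with
    occasional multi-tree terms, and the validation study's planted error
    scales (2% false positive, 20% false negative, 10% reviewer flips).
    """

    seed: int = 0
    n_studies: int = 500
    year_range: tuple[int, int] = (2003, 2010)
    #: element name -> {year: probability the element is present}
    completeness_schedule: dict[str, dict[int, float]] = field(default_factory=dict)
    specialties: tuple[str, ...] = ("cardiology", "oncology", "mental health")
    prevalence: float = 0.1
    thesaurus_depth: int = 3
    branching: int = 3
    n_top_categories: int = 4
    multi_tree_fraction: float = 0.1
    planted_tag_rates: float = 0.25
    annotation_inconsistency_rate: float = 0.0
    reviewer_flip_prob: float = 0.1
    fp_rate: float = 0.02
    fn_rate: float = 0.2
    p_interventional: float = 0.82
    p_no_conditions: float = 0.05
    p_noise_condition: float = 0.5
    p_genomics: float = 0.05
    common_term_quantile: float = 0.99

    def __post_init__(self) -> None:
        probs = (
            self.prevalence, self.multi_tree_fraction, self.planted_tag_rates,
            self.annotation_inconsistency_rate, self.reviewer_flip_prob,
            self.fp_rate, self.fn_rate, self.p_interventional,
            self.p_no_conditions, self.p_noise_condition, self.p_genomics,
            self.common_term_quantile,
        )
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not 1 <= self.thesaurus_depth <= MAX_DEPTH:
            raise ValueError(f"thesaurus_depth must be within 1..{MAX_DEPTH}")
        if self.branching < 1 or self.n_top_categories < 1:
            raise ValueError("branching and n_top_categories must be >= 1")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range start must not exceed end")

    def _rng(self, stream: str) -> random.Random:
        # string seeds hash deterministically (SHA-512 path of random.seed)
        return random.Random(f"{self.seed}/{stream}")


# ---------------------------------------------------------------------------
# thesaurus


def _make_term_name(rng: random.Random, used: set[str]) -> str:
    for _ in range(8):
        name = (
            "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(2, 3)))
            + rng.choice(_SUFFIXES)
        ).capitalize()
        if normalize_term(name) not in used:
            used.add(normalize_term(name))
            return name
    k = 2
    base = name
    while normalize_term(f"{base} type {k}") in used:
        k += 1
    name = f"{base} type {k}"
    used.add(normalize_term(name))
    return name


def generate_thesaurus(config: SynthConfig) -> MeshThesaurus:
    """A prefix forest of ``n_top_categories`` categories, ``branching``
    nodes per level, ``thesaurus_depth`` levels; ``multi_tree_fraction`` of
    terms span 2–3 tree numbers in different top categories."""
    rng = config._rng("thesaurus")
    ids_by_category: dict[str, list[str]] = {}
    for c in range(config.n_top_categories):
        letter = _CATEGORY_LETTERS[c % len(_CATEGORY_LETTERS)]
        category_ids: list[str] = []
        frontier = [f"{letter}{t + 1:02d}" for t in range(config.branching)]
        category_ids.extend(frontier)
        for _ in range(config.thesaurus_depth - 1):
            frontier = [
                f"{node}.{100 * (j + 1):03d}"
                for node in frontier
                for j in range(config.branching)
            ]
            category_ids.extend(frontier)
        ids_by_category[letter] = category_ids

    all_ids = [i for ids in ids_by_category.values() for i in ids]
    used_names: set[str] = set()
    term_of = {tree_number: _make_term_name(rng, used_names) for tree_number in all_ids}

    if config.multi_tree_fraction > 0 and len(ids_by_category) > 1:
        n_merges = int(round(config.multi_tree_fraction * len(all_ids) / 2))
        categories = sorted(ids_by_category)
        merged: set[str] = set()
        for _ in range(n_merges):
            cat_a, cat_b = rng.sample(categories, 2)
            pool_a = [i for i in ids_by_category[cat_a] if i not in merged]
            pool_b = [i for i in ids_by_category[cat_b] if i not in merged]
            if not pool_a or not pool_b:
                continue
            primary = rng.choice(pool_a)
            secondary = rng.choice(pool_b)
            term_of[secondary] = term_of[primary]
            merged.update((primary, secondary))
            if rng.random() < 0.3 and len(categories) > 2:
                cat_c = rng.choice([c for c in categories if c not in (cat_a, cat_b)])
                pool_c = [i for i in ids_by_category[cat_c] if i not in merged]
                if pool_c:
                    tertiary = rng.choice(pool_c)
                    term_of[tertiary] = term_of[primary]
                    merged.add(tertiary)

    thesaurus = MeshThesaurus()
    for tree_number in sorted(term_of):
        thesaurus.add(term_of[tree_number], tree_number)
    return thesaurus


# ---------------------------------------------------------------------------
# planted specialty structure


def generate_specialty_tags(
    config: SynthConfig, thesaurus: MeshThesaurus
) -> dict[str, dict[str, str]]:
    """Subtree-consistent base tags: ``{specialty: {tree_number: Y|N}}``.

    Each top node is drawn Y for at most one specialty (probability
    ``planted_tag_rates`` per specialty, first hit wins), every id inherits
    its top node's tag, and deterministic fixups guarantee each specialty
    owns at least one subtree and at least one subtree stays neutral.
    """
    rng = config._rng("tags")
    top_nodes = sorted({tn.split(".", 1)[0] for tn in thesaurus.id_to_term})
    if len(top_nodes) <= len(config.specialties):
        raise ValueError(
            "need more top nodes than specialties to plant disjoint subtrees"
        )
    owner: dict[str, str | None] = {}
    for node in top_nodes:
        owner[node] = None
        for specialty in config.specialties:
            if rng.random() < config.planted_tag_rates:
                owner[node] = specialty
                break

    owned_by = lambda s: [n for n, o in owner.items() if o == s]
    for specialty in config.specialties:
        if not owned_by(specialty):
            free = [n for n in top_nodes if owner[n] is None]
            if free:
                owner[free[0]] = specialty
            else:
                richest = max(config.specialties, key=lambda s: len(owned_by(s)))
                owner[owned_by(richest)[-1]] = specialty
    if not any(o is None for o in owner.values()):
        richest = max(config.specialties, key=lambda s: len(owned_by(s)))
        owner[owned_by(richest)[-1]] = None

    tags: dict[str, dict[str, str]] = {}
    for specialty in config.specialties:
        tags[specialty] = {
            tree_number: "Y" if owner[tree_number.split(".", 1)[0]] == specialty else "N"
            for tree_number in thesaurus.id_to_term
        }
    return tags


def y_terms_by_specialty(
    thesaurus: MeshThesaurus, specialty_tags: Mapping[str, Mapping[str, str]]
) -> dict[str, list[str]]:
    """Display terms whose every tree number is planted Y for the specialty
    (these summarize to Y, never A)."""
    out: dict[str, list[str]] = {}
    for specialty, tags in specialty_tags.items():
        terms = [
            thesaurus.display_term(term)
            for term, ids in sorted(thesaurus.term_to_ids.items())
            if all(tags[i] == "Y" for i in ids)
        ]
        if not terms:
            raise ValueError(f"no unambiguous Y term for specialty {specialty!r}")
        out[specialty] = terms
    return out


def neutral_terms(
    thesaurus: MeshThesaurus, specialty_tags: Mapping[str, Mapping[str, str]]
) -> list[str]:
    """Display terms planted N for every specialty on every tree number."""
    return [
        thesaurus.display_term(term)
        for term, ids in sorted(thesaurus.term_to_ids.items())
        if all(tags[i] == "N" for tags in specialty_tags.values() for i in ids)
    ]


# ---------------------------------------------------------------------------
# annotations


def generate_annotations(
    config: SynthConfig,
    thesaurus: MeshThesaurus,
    specialty_tags: Mapping[str, Mapping[str, str]],
) -> list[TermAnnotation]:
    """Per-(tree number, specialty) Y/N tags: the planted subtree tag, with
    each non-top id flipped independently with probability
    ``annotation_inconsistency_rate``."""
    rng = config._rng("annotations")
    out: list[TermAnnotation] = []
    for specialty in config.specialties:
        base = specialty_tags[specialty]
        for tree_number in sorted(base):
            tag = base[tree_number]
            if (
                depth_of(tree_number) > 1
                and rng.random() < config.annotation_inconsistency_rate
            ):
                tag = "N" if tag == "Y" else "Y"
            out.append(TermAnnotation(tree_number, specialty, tag, "mesh_id"))
    return out


# ---------------------------------------------------------------------------
# cohort

_ALLOCATIONS = ("Randomized", "Non-Randomized")
_MODELS = ("Parallel Assignment", "Crossover Assignment", "Single Group Assignment")
_PURPOSES = ("Treatment", "Prevention", "Diagnostic")
_MASKINGS = (
    "Open Label",
    "Single Blind (Participant)",
    "Double Blind (Participant, Investigator)",
    "Single; Double-Blind (Participant, Outcome Assessor)",
)

#: presence probability when no completeness schedule is given
_DEFAULT_PRESENCE = {
    "design_raw": 0.95,
    "max_age_years": 0.8,
    "brief_description": 0.9,
    "keywords": 0.7,
}


def _element_present(
    config: SynthConfig, element: str, year: int, rng: random.Random
) -> bool:
    schedule = config.completeness_schedule.get(element)
    if schedule is not None:
        prob = schedule.get(year, 1.0)
    else:
        prob = _DEFAULT_PRESENCE.get(element, 1.0)
    return rng.random() < prob


def _interventional_design(rng: random.Random) -> str:
    return (
        f"Allocation: {rng.choice(_ALLOCATIONS)}, "
        f"Intervention Model: {rng.choice(_MODELS)}, "
        f"Masking: {rng.choice(_MASKINGS)}, "
        f"Primary Purpose: {rng.choice(_PURPOSES)}"
    )


def generate_cohort(
    config: SynthConfig,
    thesaurus: MeshThesaurus,
    specialty_tags: Mapping[str, Mapping[str, str]] | None = None,
):
    """Registry cohort with planted per-study ground truth.

    Members of a specialty embed 1–2 of its unambiguous Y terms in their
    submitted conditions; non-members draw only specialty-neutral terms, so
    the truth table is exact. The ``condition_browse`` field is produced by
    a simplified indexer: condition text matched against thesaurus headings,
    with headings above the ``common_term_quantile`` document-frequency
    quantile excluded (common terms are not indexed).

    Returns ``(studies, truth)`` where truth is a DataFrame with one boolean
    column per specialty plus ``genomics`` and ``pediatric``.
    """
    import pandas as pd

    if specialty_tags is None:
        specialty_tags = generate_specialty_tags(config, thesaurus)
    rng = config._rng("cohort")
    y_terms = y_terms_by_specialty(thesaurus, specialty_tags)
    neutral = neutral_terms(thesaurus, specialty_tags)
    if not neutral:
        raise ValueError("no specialty-neutral terms available")

    studies: list[StudyRecord] = []
    truth_rows: list[dict] = []
    for i in range(config.n_studies):
        study_id = f"NCT{i:08d}"
        roll = rng.random()
        if roll < config.p_interventional:
            study_type = INTERVENTIONAL
        elif roll < config.p_interventional + 0.97 * (1 - config.p_interventional):
            study_type = OBSERVATIONAL
        elif roll < config.p_interventional + 0.99 * (1 - config.p_interventional):
            study_type = EXPANDED_ACCESS
        else:
            study_type = MISSING
        year = rng.randint(*config.year_range)
        date = _dt.date(year, rng.randint(1, 12), rng.randint(1, 28))

        members = [s for s in config.specialties if rng.random() < config.prevalence]
        conditions: list[str] = []
        if members:
            for specialty in members:
                pool = y_terms[specialty]
                conditions.extend(
                    rng.sample(pool, min(len(pool), rng.randint(1, 2)))
                )
            if rng.random() < config.p_noise_condition:
                conditions.append(rng.choice(NOISE_TERMS))
        elif rng.random() >= config.p_no_conditions:
            conditions.extend(
                rng.sample(neutral, min(len(neutral), rng.randint(1, 3)))
            )
            if rng.random() < 0.3 * config.p_noise_condition:
                conditions.append(rng.choice(NOISE_TERMS))

        keywords: list[str] = []
        if _element_present(config, "keywords", year, rng):
            keywords.extend(
                rng.sample(NOISE_TERMS, rng.randint(0, 2))
            )
        is_genomics = rng.random() < config.p_genomics
        if is_genomics:
            keywords.append(rng.choice(("gene therapy", "genomic profiling", "DNA repair")))
        elif rng.random() < 0.05:
            keywords.append("generalized wellness")  # decoy: no word-boundary hit

        design_raw = None
        if study_type == INTERVENTIONAL and _element_present(
            config, "design_raw", year, rng
        ):
            design_raw = _interventional_design(rng)
        elif study_type == OBSERVATIONAL and _element_present(
            config, "design_raw", year, rng
        ):
            design_raw = "Observational Model: Cohort, Time Perspective: Prospective"

        max_age = None
        if _element_present(config, "max_age_years", year, rng):
            max_age = float(
                rng.randint(1, 18) if rng.random() < 0.3 else rng.randint(19, 90)
            )

        title_seed = conditions[0] if conditions else "an Unspecified Condition"
        brief_title = f"A Study of {title_seed}"
        brief_description = ""
        if _element_present(config, "brief_description", year, rng):
            brief_description = (
                f"Evaluation of outcomes in participants with {title_seed.lower()}."
            )

        studies.append(
            StudyRecord(
                study_id=study_id,
                study_type=study_type,
                registration_date=date,
                conditions=conditions,
                condition_browse_terms=[],  # filled by the indexer pass below
                intervention_browse_terms=[],
                keywords=keywords,
                design_raw=design_raw,
                design_components=parse_study_design(design_raw).components,
                max_age_years=max_age,
                brief_title=brief_title,
                brief_description=brief_description,
            )
        )
        truth_rows.append(
            {
                "study_id": study_id,
                **{s: (s in members) for s in config.specialties},
                "genomics": is_genomics,
                "pediatric": max_age is not None and max_age <= 18,
            }
        )

    _apply_browse_indexer(config, thesaurus, studies)
    columns = ["study_id", *config.specialties, "genomics", "pediatric"]
    truth = pd.DataFrame(truth_rows, columns=columns).set_index("study_id")
    return studies, truth


def _apply_browse_indexer(
    config: SynthConfig, thesaurus: MeshThesaurus, studies: list[StudyRecord]
) -> None:
    """Simplified NLM-style indexer: exact (normalized) heading matches on the
    submitted conditions, minus headings above the document-frequency cutoff."""
    matched: dict[str, list[str]] = {}
    doc_freq: dict[str, int] = {}
    for study in studies:
        hits = sorted(
            {
                normalize_term(c)
                for c in study.conditions
                if normalize_term(c) in thesaurus.term_to_ids
            }
        )
        matched[study.study_id] = hits
        for term in hits:
            doc_freq[term] = doc_freq.get(term, 0) + 1
    if doc_freq and config.common_term_quantile < 1.0:
        counts = sorted(doc_freq.values())
        rank = min(len(counts) - 1, int(config.common_term_quantile * (len(counts) - 1)))
        cutoff = counts[rank]
        excluded = {t for t, c in doc_freq.items() if c > cutoff}
    else:
        excluded = set()
    for study in studies:
        study.condition_browse_terms = [
            thesaurus.display_term(t)
            for t in matched[study.study_id]
            if t not in excluded
        ]


# ---------------------------------------------------------------------------
# reviews and planted algorithm error


def generate_reviews(
    truth: Mapping[str, bool], config: SynthConfig
) -> tuple[list[ReviewRecord], dict[str, str]]:
    """Dual reviews plus planted-error algorithm labels for one specialty.

    ``truth`` maps item id to true membership. Each reviewer reports the
    truth flipped with ``reviewer_flip_prob``; the adjudicator always
    returns the truth. Algorithm labels flip truth with ``fn_rate`` (member
    -> N) or ``fp_rate`` (non-member -> Y), so feeding the output into
    :mod:`trialtax.validation_stats` recovers the planted rates.
    """
    rng = config._rng("reviews")
    reviews: list[ReviewRecord] = []
    algo_labels: dict[str, str] = {}
    for item, is_member in truth.items():
        true_label = "yes" if is_member else "no"
        flipped = {"yes": "no", "no": "yes"}
        a = flipped[true_label] if rng.random() < config.reviewer_flip_prob else true_label
        b = flipped[true_label] if rng.random() < config.reviewer_flip_prob else true_label
        reviews.append(
            ReviewRecord(
                item=item,
                reviewer_a=a,
                reviewer_b=b,
                adjudicated=true_label if a != b else None,
            )
        )
        if is_member:
            algo_labels[item] = "N" if rng.random() < config.fn_rate else "Y"
        else:
            algo_labels[item] = "Y" if rng.random() < config.fp_rate else "N"
    return reviews, algo_labels


# ---------------------------------------------------------------------------
# file output


def write_cohort_xml(studies, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for study in studies:
        path = out / f"{study.study_id}.xml"
        path.write_text(serialize_study_record(study), encoding="utf-8")
        paths.append(path)
    return paths


def write_reviews(reviews, algo_labels, path: str | Path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["item", "reviewer_a", "reviewer_b", "adjudicated", "algorithm"])
        for review in reviews:
            writer.writerow(
                [
                    review.item,
                    review.reviewer_a,
                    review.reviewer_b,
                    review.adjudicated or "",
                    algo_labels.get(review.item, ""),
                ]
            )
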