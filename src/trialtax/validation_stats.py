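"""Misclassification statistics: manual review vs algorithmic classification.

The contingency layout crosses adjudicated manual labels {Y, N, Unknown}
with algorithm labels {Y, N, Ambiguous, Unclassified}:

                    algorithm
                Y    N    Amb  Uncl
    manual Y    A    B    G    H
           N    C    D    I    J
           Unk  E    F    K    L

Cell C holds false positives (algorithm Y, truth N) and cell B false
negatives (algorithm N, truth Y). Rates are reported against both margins:
the manual margin (how much of the true class is missed / contaminated) and
the algorithm margin (how reliable an algorithmic label is). Percentages
where the algorithm margin is the denominator exclude the ambiguous and
unclassified columns. Manual-Unknown studies never enter an error numerator
or a Y/N margin; they contribute only to the grand total.

Rounding to one decimal happens only at presentation; internal values are
exact ratios.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, fields as _dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .registry_etl import StudyRecord
from .specialty_classifier import (
    CohortFilter,
    SOURCES,
    TermSummaries,
    classify_cohort,
)

MANUAL_LABELS = ("Y", "N", "Unknown")
ALGORITHM_LABELS = ("Y", "N", "Ambiguous", "Unclassified")

#: (manual, algorithm) -> cell name, the canonical lettering
CELL_OF = {
    ("Y", "Y"): "A",
    ("Y", "N"): "B",
    ("Y", "Ambiguous"): "G",
    ("Y", "Unclassified"): "H",
    ("N", "Y"): "C",
    ("N", "N"): "D",
    ("N", "Ambiguous"): "I",
    ("N", "Unclassified"): "J",
    ("Unknown", "Y"): "E",
    ("Unknown", "N"): "F",
    ("Unknown", "Ambiguous"): "K",
    ("Unknown", "Unclassified"): "L",
}

_MANUAL_ALIASES = {
    "y": "Y", "yes": "Y",
    "n": "N", "no": "N",
    "unknown": "Unknown", "u": "Unknown",
}


def normalize_manual_label(label: str) -> str:
    try:
        return _MANUAL_ALIASES[label.strip().lower()]
    except KeyError:
        raise ValueError(
            f"manual label must be one of {MANUAL_LABELS} (or yes/no/unknown), "
            f"got {label!r}"
        ) from None


@dataclass
class ConfusionTable:
    A: int = 0
    B: int = 0
    C: int = 0
    D: int = 0
    E: int = 0
    F: int = 0
    G: int = 0
    H: int = 0
    I: int = 0
    J: int = 0
    K: int = 0
    L: int = 0

    def __post_init__(self) -> None:
        for f in _dc_fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"cell {f.name} is negative")

    @property
    def T(self) -> int:
        return sum(getattr(self, f.name) for f in _dc_fields(self))

    @property
    def n_ambiguous(self) -> int:
        return self.G + self.I + self.K

    @property
    def n_unclassified(self) -> int:
        return self.H + self.J + self.L

    def cell(self, manual: str, algorithm: str) -> int:
        return getattr(self, CELL_OF[(manual, algorithm)])

    def to_frame(self):
        """The contingency table with margins, rows manual x columns algorithm."""
        import pandas as pd

        data = {
            alg: [self.cell(man, alg) for man in MANUAL_LABELS]
            for alg in ALGORITHM_LABELS
        }
        frame = pd.DataFrame(data, index=list(MANUAL_LABELS))
        frame["Total"] = frame.sum(axis=1)
        frame.loc["Total"] = frame.sum(axis=0)
        return frame


def build_confusion(pairs: Iterable[tuple[str, str]]) -> ConfusionTable:
    """Tally (manual, algorithm) label pairs into the contingency table."""
    table = ConfusionTable()
    for manual, algorithm in pairs:
        if (manual, algorithm) not in CELL_OF:
            raise ValueError(f"invalid label pair ({manual!r}, {algorithm!r})")
        cell = CELL_OF[(manual, algorithm)]
        setattr(table, cell, getattr(table, cell) + 1)
    return table


# ---------------------------------------------------------------------------
# metrics

METRIC_NAMES = (
    "pct_specialty_manual",
    "pct_specialty_algorithm",
    "fp_among_manual_N",
    "fp_among_algo_Y",
    "fn_among_manual_Y",
    "fn_among_algo_N",
    "overall_incorrect",
    "overall_ambiguous",
    "overall_unclassified",
)


@dataclass
class MetricsReport:
    """The nine summary percentages; None marks an undefined ratio (zero
    denominator). Values are exact; use :meth:`rounded` for display."""

    pct_specialty_manual: float | None
    pct_specialty_algorithm: float | None
    fp_among_manual_N: float | None
    fp_among_algo_Y: float | None
    fn_among_manual_Y: float | None
    fn_among_algo_N: float | None
    overall_incorrect: float | None
    overall_ambiguous: float | None
    overall_unclassified: float | None

    def rounded(self, ndigits: int = 1) -> dict[str, float | None]:
        return {
            name: None if value is None else round(value, ndigits)
            for name, value in self.as_dict().items()
        }

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _pct(numerator: int, denominator: int) -> float | None:
    if denominator == 0:
        return None
    return 100.0 * numerator / denominator


def misclassification_metrics(t: ConfusionTable) -> MetricsReport:
    """Error rates from the contingency table.

    Denominators: manual-margin rates use the full manual row totals;
    algorithm-margin rates (and the algorithm prevalence and overall error)
    exclude the ambiguous and unclassified columns; the ambiguous and
    unclassified fractions are over the grand total.
    """
    if t.T == 0:
        raise ValueError("empty contingency table")
    classified = t.T - t.n_ambiguous - t.n_unclassified
    return MetricsReport(
        pct_specialty_manual=_pct(t.A + t.B + t.G + t.H, t.T),
        pct_specialty_algorithm=_pct(t.A + t.C + t.E, classified),
        fp_among_manual_N=_pct(t.C, t.C + t.D + t.I + t.J),
        fp_among_algo_Y=_pct(t.C, t.A + t.C + t.E),
        fn_among_manual_Y=_pct(t.B, t.A + t.B + t.G + t.H),
        fn_among_algo_N=_pct(t.B, t.B + t.D + t.F),
        overall_incorrect=_pct(t.B + t.C, classified),
        overall_ambiguous=_pct(t.n_ambiguous, t.T),
        overall_unclassified=_pct(t.n_unclassified, t.T),
    )


# ---------------------------------------------------------------------------
# reviewer disagreement


@dataclass(frozen=True)
class BatchDisagreement:
    reviewer_pair: str
    n_disagreements: int
    n_reviewed: int

    def __post_init__(self) -> None:
        if self.n_disagreements > self.n_reviewed:
            raise ValueError(
                f"batch {self.reviewer_pair!r}: disagreements "
                f"({self.n_disagreements}) exceed reviews ({self.n_reviewed})"
            )

    @property
    def rate(self) -> float:
        return self.n_disagreements / self.n_reviewed if self.n_reviewed else 0.0

    def formatted(self) -> str:
        return f"{self.n_disagreements}/{self.n_reviewed:,} ({100 * self.rate:.1f}%)"


@dataclass
class DisagreementSummary:
    batches: list[BatchDisagreement]
    pooled_n: int
    pooled_total: int

    @property
    def pooled_rate(self) -> float:
        return self.pooled_n / self.pooled_total if self.pooled_total else 0.0

    def formatted_pooled(self) -> str:
        return f"{self.pooled_n}/{self.pooled_total:,} ({100 * self.pooled_rate:.1f}%)"


def disagreement_summary(
    batches: Iterable[tuple[str, int, int]]
) -> DisagreementSummary:
    """Per-batch and pooled reviewer disagreement rates.

    A disagreement is any difference in classification of a study by its two
    reviewers; the pooled rate is total disagreements over total reviews
    (the N-weighted mean of the batch rates).
    """
    parsed = [BatchDisagreement(pair, n, total) for pair, n, total in batches]
    return DisagreementSummary(
        batches=parsed,
        pooled_n=sum(b.n_disagreements for b in parsed),
        pooled_total=sum(b.n_reviewed for b in parsed),
    )


# ---------------------------------------------------------------------------
# review sampling

REGISTRY_LINK_TEMPLATE = "https://clinicaltrials.gov/ct2/show/{study_id}"


def sample_for_review(
    studies: Sequence[StudyRecord],
    n: int = 1000,
    batch_size: int = 200,
    seed: int = 0,
) -> list[list[dict]]:
    """Draw a seeded random sample without replacement, split into batches of
    review packets (brief title, brief description, keywords, conditions,
    registry link). The last batch may be short when batch_size does not
    divide n."""
    if len(studies) < n:
        raise ValueError(f"need at least {n} studies, have {len(studies)}")
    rng = random.Random(seed)
    sampled = rng.sample(list(studies), n)
    packets = [
        {
            "study_id": s.study_id,
            "brief_title": s.brief_title,
            "brief_description": s.brief_description,
            "keywords": list(s.keywords),
            "conditions": list(s.conditions),
            "registry_link": REGISTRY_LINK_TEMPLATE.format(study_id=s.study_id),
        }
        for s in sampled
    ]
    return [packets[i : i + batch_size] for i in range(0, n, batch_size)]


# ---------------------------------------------------------------------------
# source comparison


@dataclass
class SourceComparison:
    """Per-source metric reports plus the browse-vs-condition differences."""

    specialty: str
    reports: dict[str, MetricsReport]
    tables: dict[str, ConfusionTable]

    def differences(self) -> dict[str, float | None]:
        """Absolute per-metric difference, condition_browse_only vs
        condition_only; None where either side is undefined."""
        browse = self.reports["condition_browse_only"].as_dict()
        condition = self.reports["condition_only"].as_dict()
        return {
            name: (
                None
                if browse[name] is None or condition[name] is None
                else abs(browse[name] - condition[name])
            )
            for name in METRIC_NAMES
        }

    def to_frame(self):
        """Metrics rows x (source columns), one-decimal display values."""
        import pandas as pd

        return pd.DataFrame(
            {src: self.reports[src].rounded() for src in self.reports},
            index=list(METRIC_NAMES),
        )


def compare_sources(
    studies: Sequence[StudyRecord],
    summaries: TermSummaries,
    specialty: str,
    manual_labels: Mapping[str, str],
    cohort_filter: CohortFilter | None = CohortFilter(),
) -> SourceComparison:
    """Re-run classification under each term source and score each against
    the same manual labels.

    ``manual_labels`` maps study_id to an adjudicated Y/N/Unknown (or
    yes/no/unknown) label; only studies with a manual label and surviving
    the cohort filter enter the tables.
    """
    manual = {sid: normalize_manual_label(lbl) for sid, lbl in manual_labels.items()}
    reports: dict[str, MetricsReport] = {}
    tables: dict[str, ConfusionTable] = {}
    for source in SOURCES:
        assignments = classify_cohort(
            studies, summaries, specialty, cohort_filter, source
        )
        pairs = [
            (manual[a.study_id], a.label)
            for a in assignments
            if a.study_id in manual
        ]
        table = build_confusion(pairs)
        tables[source] = table
        reports[source] = misclassification_metrics(table)
    return SourceComparison(specialty=specialty, reports=reports, tables=tables)


# ---------------------------------------------------------------------------
# export


def write_confusion(table: ConfusionTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index_label="manual_review")


def write_metrics(report: MetricsReport, path: str | Path) -> None:
    import pandas as pd

    rounded = report.rounded()
    pd.DataFrame(
        {"metric": list(METRIC_NAMES), "percent": [rounded[m] for m in METRIC_NAMES]}
    ).to_csv(path, index=False)


def write_disagreements(summary: DisagreementSummary, path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "reviewer_pair": b.reviewer_pair,
            "n_disagreements": b.n_disagreements,
            "n_reviewed": b.n_reviewed,
            "formatted": b.formatted(),
        }
        for b in summary.batches
    ]
    rows.append(
        {
            "reviewer_pair": "Overall",
            "n_disagreements": summary.pooled_n,
            "n_reviewed": summary.pooled_total,
            "formatted": summary.formatted_pooled(),
        }
    )
    pd.DataFrame(rows).to_csv(path, index=False)
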