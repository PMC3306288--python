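"""Contingency tables, misclassification metrics, disagreement, sampling."""

import datetime
import random
from collections import Counter

import pytest

from trialtax.annotation import build_term_summaries
from trialtax.registry_etl import INTERVENTIONAL, StudyRecord
from trialtax.specialty_classifier import classify_cohort
from trialtax.synthetic_data import generate_annotations
from trialtax.validation_stats import (
    ALGORITHM_LABELS,
    CELL_OF,
    ConfusionTable,
    MANUAL_LABELS,
    build_confusion,
    compare_sources,
    disagreement_summary,
    misclassification_metrics,
    normalize_manual_label,
    sample_for_review,
)

# the published cardiology validation counts, used as a worked example
CARDIOLOGY = dict(A=72, B=21, G=0, H=2, C=18, D=836, I=1, J=49, E=0, F=1, K=0, L=0)


def _pairs_from_counts(counts, seed=0):
    pairs = [
        pair
        for pair, cell in CELL_OF.items()
        for _ in range(counts.get(cell, 0))
    ]
    random.Random(seed).shuffle(pairs)
    return pairs


class TestBuildConfusion:
    def test_planted_cell_counts_recovered(self):
        rng = random.Random(42)
        counts = {cell: rng.randint(0, 120) for cell in CELL_OF.values()}
        table = build_confusion(_pairs_from_counts(counts, seed=1))
        for cell, expected in counts.items():
            assert getattr(table, cell) == expected
        assert table.T == sum(counts.values())

    def test_empty_input_is_all_zero(self):
        table = build_confusion([])
        assert table.T == 0

    def test_cardiology_validation_counts(self):
        table = build_confusion(_pairs_from_counts(CARDIOLOGY))
        assert table == ConfusionTable(**CARDIOLOGY)
        assert table.T == 1000

    def test_invalid_label_pair_named_in_error(self):
        with pytest.raises(ValueError, match="Maybe"):
            build_confusion([("Y", "Maybe")])

    def test_margins_in_frame_layout(self):
        frame = ConfusionTable(**CARDIOLOGY).to_frame()
        assert frame.loc["Y", "Total"] == 95
        assert frame.loc["N", "Total"] == 904
        assert frame.loc["Total", "Y"] == 90
        assert frame.loc["Total", "Total"] == 1000


class TestMetrics:
    def test_cardiology_printed_row(self):
        report = misclassification_metrics(ConfusionTable(**CARDIOLOGY))
        assert report.rounded() == {
            "pct_specialty_manual": 9.5,
            "pct_specialty_algorithm": 9.5,
            "fp_among_manual_N": 2.0,
            "fp_among_algo_Y": 20.0,
            "fn_among_manual_Y": 22.1,
            "fn_among_algo_N": 2.4,
            "overall_incorrect": 4.1,
            "overall_ambiguous": 0.1,
            "overall_unclassified": 5.1,
        }

    def test_diagonal_table_has_zero_error(self):
        report = misclassification_metrics(ConfusionTable(A=100, D=900))
        assert report.fp_among_manual_N == 0.0
        assert report.fp_among_algo_Y == 0.0
        assert report.fn_among_manual_Y == 0.0
        assert report.fn_among_algo_N == 0.0
        assert report.overall_incorrect == 0.0

    def test_zero_denominators_marked_undefined_not_crash(self):
        # only Unknown-row mass: every Y/N-margin metric is undefined
        report = misclassification_metrics(ConfusionTable(E=3, F=2))
        assert report.fp_among_manual_N is None
        assert report.fn_among_manual_Y is None
        assert report.pct_specialty_manual == 0.0

    def test_metrics_agree_with_independent_tally_over_raw_pairs(self):
        rng = random.Random(9)
        pairs = [
            (rng.choice(MANUAL_LABELS), rng.choice(ALGORITHM_LABELS))
            for _ in range(3000)
        ]
        report = misclassification_metrics(build_confusion(pairs))
        tally = Counter(pairs)

        def total(manual=None, algorithm=None):
            return sum(
                count
                for (man, alg), count in tally.items()
                if (manual is None or man == manual)
                and (algorithm is None or alg == algorithm)
            )

        n = len(pairs)
        classified = n - total(algorithm="Ambiguous") - total(algorithm="Unclassified")
        fp = tally[("N", "Y")]
        fn = tally[("Y", "N")]
        assert report.pct_specialty_manual == pytest.approx(100 * total("Y") / n)
        assert report.fp_among_manual_N == pytest.approx(100 * fp / total("N"))
        assert report.fp_among_algo_Y == pytest.approx(
            100 * fp / (total(algorithm="Y"))
        )
        assert report.fn_among_manual_Y == pytest.approx(100 * fn / total("Y"))
        assert report.fn_among_algo_N == pytest.approx(100 * fn / total(algorithm="N"))
        assert report.overall_incorrect == pytest.approx(100 * (fp + fn) / classified)


class TestDisagreement:
    def test_published_batches_pool_correctly(self):
        summary = disagreement_summary(
            [("1&2", 12, 200), ("1&3", 20, 400), ("4&5", 18, 200), ("6&7", 18, 200)]
        )
        assert summary.pooled_n == 68
        assert summary.pooled_total == 1000
        assert summary.formatted_pooled() == "68/1,000 (6.8%)"
        assert summary.batches[0].formatted() == "12/200 (6.0%)"

    def test_zero_disagreement_batch(self):
        summary = disagreement_summary([("a", 0, 200)])
        assert summary.pooled_rate == 0.0

    def test_pooled_rate_is_size_weighted_mean(self):
        rng = random.Random(5)
        batches = []
        for i in range(8):
            total = rng.randint(50, 400)
            batches.append((f"pair{i}", rng.randint(0, total), total))
        summary = disagreement_summary(batches)
        weighted = sum(n for _, n, _ in batches) / sum(t for _, _, t in batches)
        assert summary.pooled_rate == pytest.approx(weighted)

    def test_more_disagreements_than_reviews_rejected(self):
        with pytest.raises(ValueError):
            disagreement_summary([("bad", 5, 4)])


def _dummy_studies(n):
    return [
        StudyRecord(
            study_id=f"NCT{i:05d}",
            study_type=INTERVENTIONAL,
            registration_date=datetime.date(2009, 1, 1),
            conditions=["X"],
            keywords=["k"],
            brief_title=f"Study {i}",
            brief_description="d",
        )
        for i in range(n)
    ]


class TestSampling:
    def test_batch_shape_1000_by_200(self):
        batches = sample_for_review(_dummy_studies(1500), n=1000, batch_size=200,
                                    seed=4)
        assert [len(b) for b in batches] == [200] * 5
        ids = [p["study_id"] for b in batches for p in b]
        assert len(set(ids)) == 1000  # without replacement

    def test_same_seed_identical_sample(self):
        studies = _dummy_studies(300)
        first = sample_for_review(studies, n=100, batch_size=40, seed=11)
        second = sample_for_review(studies, n=100, batch_size=40, seed=11)
        assert first == second
        different = sample_for_review(studies, n=100, batch_size=40, seed=12)
        assert first != different

    def test_short_final_batch_and_exhaustive_draw(self):
        batches = sample_for_review(_dummy_studies(10), n=10, batch_size=4, seed=0)
        assert [len(b) for b in batches] == [4, 4, 2]
        whole = sample_for_review(_dummy_studies(10), n=10, batch_size=200, seed=0)
        assert [len(b) for b in whole] == [10]

    def test_too_few_studies_rejected(self):
        with pytest.raises(ValueError):
            sample_for_review(_dummy_studies(5), n=10)

    def test_packet_contains_review_fields_and_link(self):
        packet = sample_for_review(_dummy_studies(10), n=1, batch_size=1, seed=0)[0][0]
        assert set(packet) == {
            "study_id", "brief_title", "brief_description", "keywords",
            "conditions", "registry_link",
        }
        assert packet["study_id"] in packet["registry_link"]


class TestCompareSources:
    def test_identical_sources_have_zero_differences(
        self, config, thesaurus, specialty_tags, cohort
    ):
        studies, truth = cohort
        # force browse == condition by copying submitted terms across
        mirrored = []
        for s in studies:
            copy = StudyRecord(
                study_id=s.study_id,
                study_type=s.study_type,
                registration_date=s.registration_date,
                conditions=list(s.conditions),
                condition_browse_terms=list(s.conditions),
            )
            mirrored.append(copy)
        summaries = build_term_summaries(
            generate_annotations(config, thesaurus, specialty_tags), thesaurus
        )
        specialty = config.specialties[0]
        manual = {
            sid: ("Y" if truth.loc[sid, specialty] else "N") for sid in truth.index
        }
        comparison = compare_sources(
            mirrored, summaries, specialty, manual, cohort_filter=None
        )
        for value in comparison.differences().values():
            assert value == 0.0

    def test_browse_subset_never_lowers_unclassified(
        self, config, thesaurus, specialty_tags, cohort
    ):
        studies, _ = cohort  # generator browse terms are a subset of conditions
        summaries = build_term_summaries(
            generate_annotations(config, thesaurus, specialty_tags), thesaurus
        )
        specialty = config.specialties[0]
        by_source = {}
        for source in ("condition_only", "condition_browse_only"):
            assignments = classify_cohort(
                studies, summaries, specialty, cohort_filter=None, source=source
            )
            by_source[source] = sum(a.group == 5 for a in assignments) / len(
                assignments
            )
        assert by_source["condition_browse_only"] >= by_source["condition_only"]

    def test_report_has_three_sources_and_all_metric_rows(
        self, config, thesaurus, specialty_tags, cohort
    ):
        studies, truth = cohort
        summaries = build_term_summaries(
            generate_annotations(config, thesaurus, specialty_tags), thesaurus
        )
        specialty = config.specialties[0]
        manual = {
            sid: ("yes" if truth.loc[sid, specialty] else "no")
            for sid in truth.index
        }
        comparison = compare_sources(
            studies, summaries, specialty, manual, cohort_filter=None
        )
        frame = comparison.to_frame()
        assert list(frame.columns) == [
            "both", "condition_only", "condition_browse_only"
        ]
        assert len(frame) == 9


def test_manual_label_normalization():
    assert normalize_manual_label("yes") == "Y"
    assert normalize_manual_label(" NO ") == "N"
    assert normalize_manual_label("Unknown") == "Unknown"
    with pytest.raises(ValueError):
        normalize_manual_label("perhaps")
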