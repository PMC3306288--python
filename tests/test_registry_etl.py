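"""Registry ingestion: escaping, design parsing, record mapping, completeness."""

import datetime

import pytest
from hypothesis import given, settings, strategies as st

from trialtax.registry_etl import (
    INTERVENTIONAL,
    MISSING,
    MissingStudyIdError,
    RegistryParseError,
    StudyRecord,
    completeness_by_year,
    normalize_study_type,
    parse_age_years,
    parse_study_design,
    parse_study_record,
    sanitize_text,
    serialize_study_record,
)
from trialtax.synthetic_data import SynthConfig, generate_cohort, generate_thesaurus


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("AT&T", "AT&amp;T"),
        ("plain text", "plain text"),
        ("dose <5 mg", "dose &lt;5 mg"),
        ('say "hi"', "say &quot;hi&quot;"),
        ("it's >10", "it&apos;s &gt;10"),
        ("", ""),
    ],
)
def test_sanitize_text_examples(raw, expected):
    assert sanitize_text(raw) == expected


@given(st.text(max_size=200))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_sanitize_leaves_no_bare_reserved_characters(raw):
    out = sanitize_text(raw)
    for ref in ("&amp;", "&lt;", "&gt;", "&quot;", "&apos;"):
        out = out.replace(ref, "")
    assert not set(out) & set("&<>\"'")


class TestDesignParsing:
    def test_three_components_with_masked_roles(self):
        parsed = parse_study_design(
            "Allocation: Randomized, Masking: Double Blind (Participant, "
            "Investigator), Primary Purpose: Treatment"
        )
        assert [c.name for c in parsed.components] == [
            "allocation",
            "masking",
            "primary_purpose",
        ]
        masking = parsed.components[1]
        assert masking.value == "Double Blind"
        assert masking.masked_roles == {"Participant", "Investigator"}
        assert not parsed.flagged_segments

    def test_compound_masking_levels_split(self):
        parsed = parse_study_design("Masking: Single; Double-Blind")
        assert [(c.name, c.value) for c in parsed.components] == [
            ("masking", "Single"),
            ("masking", "Double-Blind"),
        ]

    def test_empty_string_yields_empty(self):
        assert parse_study_design("").components == []
        assert parse_study_design(None).components == []

    def test_unrecognized_name_preserved_with_flag(self):
        parsed = parse_study_design("Allocation: Randomized, Novel Axis: Foo")
        assert parsed.components[1].name == "Novel Axis"
        assert parsed.components[1].recognized is False

    def test_segment_without_colon_flagged_and_skipped(self):
        parsed = parse_study_design("Allocation: Randomized, gibberish segment")
        # "gibberish segment" has no Name: header so it stays glued to the
        # allocation value; a leading colon-free segment is flagged instead
        parsed2 = parse_study_design("gibberish, Allocation: Randomized")
        assert parsed2.flagged_segments == ["gibberish"]
        assert [c.name for c in parsed2.components] == ["allocation"]
        assert [c.name for c in parsed.components] == ["allocation"]

    def test_no_recognized_component_dropped(self):
        raw = (
            "Allocation: Non-Randomized, Intervention Model: Crossover Assignment, "
            "Masking: Open Label, Primary Purpose: Prevention, "
            "Time Perspective: Prospective, Endpoint Classification: Safety Study"
        )
        parsed = parse_study_design(raw)
        emitted = {c.name for c in parsed.components}
        assert emitted == {
            "allocation",
            "interventional_model",
            "masking",
            "primary_purpose",
            "time_perspective",
            "endpoint_classification",
        }
        assert raw.count(":") == len(parsed.components) + len(parsed.flagged_segments)


@pytest.mark.parametrize(
    "raw, years",
    [
        ("18 Years", 18.0),
        ("1 Year", 1.0),
        ("6 Months", 0.5),
        ("26 Weeks", 0.5),
        ("N/A", None),
        ("", None),
        ("365 Days", 1.0),
    ],
)
def test_age_normalization(raw, years):
    if years is None:
        assert parse_age_years(raw) is None
    else:
        assert parse_age_years(raw) == pytest.approx(years)


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("Interventional", "interventional"),
        ("OBSERVATIONAL", "observational"),
        ("Observational [Patient Registry]", "observational"),
        ("Expanded Access", "expanded_access"),
        ("something else", MISSING),
        (None, MISSING),
    ],
)
def test_study_type_normalization(raw, expected):
    assert normalize_study_type(raw) == expected


SAMPLE_XML = """\
<clinical_study>
  <id_info><nct_id>NCT01234567</nct_id></id_info>
  <brief_title>A Trial of Something</brief_title>
  <study_type>Interventional</study_type>
  <firstreceived_date>September 28, 2008</firstreceived_date>
  <study_design>Allocation: Randomized, Primary Purpose: Treatment</study_design>
  <condition>Heart Failure</condition>
  <condition>Hypertension</condition>
  <eligibility><maximum_age>18 Years</maximum_age></eligibility>
</clinical_study>
"""


class TestParseStudyRecord:
    def test_direct_field_mapping(self):
        record = parse_study_record(SAMPLE_XML)
        assert record.study_id == "NCT01234567"
        assert record.study_type == INTERVENTIONAL
        assert record.registration_date == datetime.date(2008, 9, 28)
        assert record.conditions == ["Heart Failure", "Hypertension"]
        assert record.max_age_years == 18.0
        assert [c.name for c in record.design_components] == [
            "allocation",
            "primary_purpose",
        ]

    def test_missing_blocks_map_to_empty(self):
        record = parse_study_record(SAMPLE_XML)
        assert record.condition_browse_terms == []
        assert record.intervention_browse_terms == []
        assert record.keywords == []

    def test_malformed_xml_raises_parse_error(self):
        with pytest.raises(RegistryParseError):
            parse_study_record("<clinical_study><unclosed>")

    def test_missing_study_id_rejected(self):
        with pytest.raises(MissingStudyIdError):
            parse_study_record("<clinical_study><study_type>Interventional</study_type></clinical_study>")

    def test_roundtrip_on_synthetic_cohort(self, cohort):
        studies, _ = cohort
        for study in studies:
            assert parse_study_record(serialize_study_record(study)) == study


def _study(year, design=None, sid="NCTx"):
    return StudyRecord(
        study_id=sid,
        study_type=INTERVENTIONAL,
        registration_date=datetime.date(year, 6, 1),
        design_raw=design,
    )


class TestCompleteness:
    def test_full_and_zero_completeness(self):
        full = [_study(2008, "Allocation: Randomized", f"N{i}") for i in range(4)]
        assert completeness_by_year(full, "design_raw").per_year == {2008: 1.0}
        empty = [_study(2008, None, f"N{i}") for i in range(4)]
        assert completeness_by_year(empty, "design_raw").per_year == {2008: 0.0}

    def test_unknown_element_lists_queryable_fields(self):
        with pytest.raises(ValueError, match="design_raw"):
            completeness_by_year([], "no_such_element")

    def test_permutation_invariance(self):
        studies = [
            _study(2008, "x: y", "a"),
            _study(2008, None, "b"),
            _study(2009, "x: y", "c"),
        ]
        forward = completeness_by_year(studies, "design_raw").per_year
        backward = completeness_by_year(list(reversed(studies)), "design_raw").per_year
        assert forward == backward == {2008: 0.5, 2009: 1.0}

    def test_planted_step_schedule_recovered_exactly(self):
        config = SynthConfig(
            seed=11,
            n_studies=250,
            year_range=(2004, 2009),
            completeness_schedule={
                "design_raw": {2004: 0.0, 2005: 0.0, 2006: 0.0, 2007: 1.0, 2008: 1.0, 2009: 1.0}
            },
        )
        studies, _ = generate_cohort(config, generate_thesaurus(config))
        interventional = [s for s in studies if s.study_type == INTERVENTIONAL]
        report = completeness_by_year(interventional, "design_raw")
        for year, fraction in report.per_year.items():
            assert fraction == (0.0 if year <= 2006 else 1.0)
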