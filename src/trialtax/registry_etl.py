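"""Registry XML ingestion: normalized study records, design-string parsing,
escape sanitization, and per-year field-completeness metrics.

The input dialect is the ClinicalTrials.gov public XML (one ``<clinical_study>``
document per file). Element paths are configurable through a YAML mapping so
that dialect drift (e.g. the name of the first-received date element) does not
require code changes.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from xml.etree import ElementTree as ET

from lxml import etree

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# study type

INTERVENTIONAL = "interventional"
OBSERVATIONAL = "observational"
EXPANDED_ACCESS = "expanded_access"
MISSING = "missing"

STUDY_TYPES = (INTERVENTIONAL, OBSERVATIONAL, EXPANDED_ACCESS, MISSING)

_STUDY_TYPE_PREFIXES = {
    "interventional": INTERVENTIONAL,
    "observational": OBSERVATIONAL,
    "expanded access": EXPANDED_ACCESS,
}


def normalize_study_type(raw: str | None) -> str:
    """Map a raw study-type string onto the closed enum; unknown -> missing."""
    if raw is None:
        return MISSING
    text = " ".join(raw.split()).lower()
    for prefix, value in _STUDY_TYPE_PREFIXES.items():
        if text.startswith(prefix):
            return value
    return MISSING


# ---------------------------------------------------------------------------
# escape sanitization


def sanitize_text(raw: str) -> str:
    """Replace the five XML-reserved characters with character references.

    The ampersand is replaced first, so the function is total and its output
    contains no bare reserved character. It is deliberately *not* idempotent:
    an already-escaped ``&amp;`` becomes ``&amp;amp;`` — sanitize exactly once,
    before the text is embedded in XML.
    """
    return (
        raw.replace("&", "&amp;")
        .replace("<", "&lt;")
        .replace(">", "&gt;")
        .replace('"', "&quot;")
        .replace("'", "&apos;")
    )


# ---------------------------------------------------------------------------
# study design parsing

#: canonical design-component names, keyed by the spellings seen in the
#: concatenated Study Design string (case-insensitive)
_COMPONENT_ALIASES = {
    "primary purpose": "primary_purpose",
    "intervention model": "interventional_model",
    "interventional model": "interventional_model",
    "observational model": "observational_model",
    "allocation": "allocation",
    "endpoint classification": "endpoint_classification",
    "time perspective": "time_perspective",
    "masking": "masking",
}

DESIGN_COMPONENT_NAMES = tuple(sorted(set(_COMPONENT_ALIASES.values())))

MASKED_ROLES = ("Participant", "Investigator", "Outcome Assessor", "Caregiver")

_ROLE_ALIASES = {
    "participant": "Participant",
    "subject": "Participant",
    "investigator": "Investigator",
    "outcome assessor": "Outcome Assessor",
    "outcomes assessor": "Outcome Assessor",
    "caregiver": "Caregiver",
}

# split on ", " only when the next token looks like a "Name:" header
_SEGMENT_SPLIT = re.compile(r",\s+(?=[A-Za-z][A-Za-z /-]*?:)")
_TRAILING_PARENS = re.compile(r"\(([^()]*)\)\s*$")


@dataclass(frozen=True)
class DesignComponent:
    """One parsed component of the concatenated Study Design string."""

    name: str
    value: str
    masked_roles: frozenset[str] = frozenset()
    recognized: bool = True

    def __post_init__(self) -> None:
        if self.masked_roles and self.name != "masking":
            raise ValueError("masked_roles only apply to the masking component")


@dataclass
class ParsedDesign:
    """Parse result: recognized/unrecognized components plus skipped segments."""

    components: list[DesignComponent] = field(default_factory=list)
    flagged_segments: list[str] = field(default_factory=list)


def _parse_masking(value: str) -> list[DesignComponent]:
    roles: frozenset[str] = frozenset()
    m = _TRAILING_PARENS.search(value)
    if m:
        parsed = []
        for chunk in m.group(1).split(","):
            key = chunk.strip().lower()
            if key in _ROLE_ALIASES:
                parsed.append(_ROLE_ALIASES[key])
            elif key:
                logger.warning("unrecognized masking role %r ignored", chunk.strip())
        roles = frozenset(parsed)
        value = value[: m.start()].strip()
    # compound masking levels, e.g. "Single; Double-Blind"
    levels = [lvl.strip() for lvl in value.split(";") if lvl.strip()]
    if not levels:
        levels = [value.strip()]
    return [DesignComponent("masking", lvl, roles) for lvl in levels]


def parse_study_design(design_raw: str | None) -> ParsedDesign:
    """Decompose a Study Design string into named components.

    Segments are ``Name: Value`` pairs separated by ``", "``; masking values
    may carry a parenthesized role list and multiple levels separated by ";".
    Unrecognized names are preserved verbatim with ``recognized=False``;
    segments without a colon are flagged and skipped.
    """
    result = ParsedDesign()
    if not design_raw or not design_raw.strip():
        return result
    for segment in _SEGMENT_SPLIT.split(design_raw.strip()):
        segment = segment.strip().rstrip(",")
        if not segment:
            continue
        if ":" not in segment:
            logger.warning("design segment without colon skipped: %r", segment)
            result.flagged_segments.append(segment)
            continue
        name_raw, value = (part.strip() for part in segment.split(":", 1))
        canonical = _COMPONENT_ALIASES.get(name_raw.lower())
        if canonical is None:
            result.components.append(
                DesignComponent(name_raw, value, recognized=False)
            )
        elif canonical == "masking":
            result.components.extend(_parse_masking(value))
        else:
            result.components.append(DesignComponent(canonical, value))
    return result


# ---------------------------------------------------------------------------
# age and date parsing

_AGE_UNITS = {
    "year": 1.0,
    "month": 12.0,
    "week": 52.0,
    "day": 365.0,
    "hour": 365.0 * 24,
    "minute": 365.0 * 24 * 60,
}
_AGE_RE = re.compile(r"^(\d+(?:\.\d+)?)\s*([a-z]+?)s?$")
_NA_VALUES = {"", "n/a", "na", "none"}


def parse_age_years(text: str | None) -> float | None:
    """Normalize an eligibility age string ("18 Years", "6 Months", "N/A") to years."""
    if text is None:
        return None
    cleaned = " ".join(text.split()).lower()
    if cleaned in _NA_VALUES:
        return None
    m = _AGE_RE.match(cleaned)
    if m is None or m.group(2) not in _AGE_UNITS:
        logger.warning("unparseable age value %r treated as missing", text)
        return None
    return float(m.group(1)) / _AGE_UNITS[m.group(2)]


_DATE_FORMATS = ("%B %d, %Y", "%Y-%m-%d")


def parse_registry_date(text: str | None) -> _dt.date | None:
    if text is None:
        return None
    cleaned = " ".join(text.split())
    for fmt in _DATE_FORMATS:
        try:
            return _dt.datetime.strptime(cleaned, fmt).date()
        except ValueError:
            continue
    logger.warning("unparseable date %r treated as missing", text)
    return None


def format_registry_date(date: _dt.date) -> str:
    # %-d is not portable; strip the leading zero by hand
    return f"{date.strftime('%B')} {date.day}, {date.year}"


# ---------------------------------------------------------------------------
# study records


@dataclass
class StudyRecord:
    """One normalized registry entry."""

    study_id: str
    study_type: str = MISSING
    registration_date: _dt.date | None = None
    conditions: list[str] = field(default_factory=list)
    condition_browse_terms: list[str] = field(default_factory=list)
    intervention_browse_terms: list[str] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)
    design_raw: str | None = None
    design_components: list[DesignComponent] = field(default_factory=list)
    max_age_years: float | None = None
    brief_title: str = ""
    brief_description: str = ""

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be nonempty")
        if self.max_age_years is not None and self.max_age_years < 0:
            raise ValueError("max_age_years must be non-negative")

    @property
    def registration_year(self) -> int | None:
        return None if self.registration_date is None else self.registration_date.year


class RegistryParseError(ValueError):
    """Malformed registry XML; message carries the parser's position."""


class MissingStudyIdError(ValueError):
    """Record rejected: no study identifier element."""


#: default element paths for the ClinicalTrials.gov public dialect;
#: override any entry via the YAML config
DEFAULT_FIELD_MAP: dict[str, str] = {
    "study_id": "id_info/nct_id",
    "study_type": "study_type",
    "registration_date": "firstreceived_date",
    "condition": "condition",
    "condition_browse": "condition_browse/mesh_term",
    "intervention_browse": "intervention_browse/mesh_term",
    "keyword": "keyword",
    "study_design": "study_design",
    "maximum_age": "eligibility/maximum_age",
    "brief_title": "brief_title",
    "brief_description": "brief_summary/textblock",
}


def load_field_map(path: str | Path | None) -> dict[str, str]:
    """Merge a YAML ``fields:`` mapping over the default element paths."""
    field_map = dict(DEFAULT_FIELD_MAP)
    if path is not None:
        import yaml

        with open(path) as handle:
            config = yaml.safe_load(handle) or {}
        overrides = config.get("fields", config)
        unknown = set(overrides) - set(field_map)
        if unknown:
            raise ValueError(f"unknown field-map keys: {sorted(unknown)}")
        field_map.update(overrides)
    return field_map


def _text_of(root: etree._Element, path: str) -> str | None:
    node = root.find(path)
    if node is None or node.text is None:
        return None
    stripped = node.text.strip()
    return stripped or None


def _texts_of(root: etree._Element, path: str) -> list[str]:
    out = []
    for node in root.findall(path):
        if node.text and node.text.strip():
            out.append(" ".join(node.text.split()))
    return out


def parse_study_record(
    xml_document: str | bytes, field_map: Mapping[str, str] | None = None
) -> StudyRecord:
    """Parse one registry XML document into a :class:`StudyRecord`.

    Missing elements map to missing/empty values; only malformed XML or a
    missing study identifier rejects the record.
    """
    fm = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fm.update(field_map)
    data = xml_document.encode() if isinstance(xml_document, str) else xml_document
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise RegistryParseError(f"malformed registry XML: {exc}") from exc

    study_id = _text_of(root, fm["study_id"])
    if study_id is None:
        raise MissingStudyIdError(
            f"record rejected: no study id at {fm['study_id']!r}"
        )

    design_raw = _text_of(root, fm["study_design"])
    return StudyRecord(
        study_id=study_id,
        study_type=normalize_study_type(_text_of(root, fm["study_type"])),
        registration_date=parse_registry_date(_text_of(root, fm["registration_date"])),
        conditions=_texts_of(root, fm["condition"]),
        condition_browse_terms=_texts_of(root, fm["condition_browse"]),
        intervention_browse_terms=_texts_of(root, fm["intervention_browse"]),
        keywords=_texts_of(root, fm["keyword"]),
        design_raw=design_raw,
        design_components=parse_study_design(design_raw).components,
        max_age_years=parse_age_years(_text_of(root, fm["maximum_age"])),
        brief_title=_text_of(root, fm["brief_title"]) or "",
        brief_description=_text_of(root, fm["brief_description"]) or "",
    )


def _format_age(age: float | None) -> str:
    if age is None:
        return "N/A"
    if float(age).is_integer():
        return f"{int(age)} Years"
    months = age * 12.0
    if months.is_integer():
        return f"{int(months)} Months"
    return f"{age} Years"


def serialize_study_record(study: StudyRecord) -> str:
    """Render a record back to the registry XML dialect (round-trip inverse
    of :func:`parse_study_record` for records produced by the generator)."""
    root = ET.Element("clinical_study")
    id_info = ET.SubElement(root, "id_info")
    ET.SubElement(id_info, "nct_id").text = study.study_id
    if study.brief_title:
        ET.SubElement(root, "brief_title").text = study.brief_title
    if study.brief_description:
        summary = ET.SubElement(root, "brief_summary")
        ET.SubElement(summary, "textblock").text = study.brief_description
    if study.study_type != MISSING:
        label = {
            INTERVENTIONAL: "Interventional",
            OBSERVATIONAL: "Observational",
            EXPANDED_ACCESS: "Expanded Access",
        }[study.study_type]
        ET.SubElement(root, "study_type").text = label
    if study.registration_date is not None:
        ET.SubElement(root, "firstreceived_date").text = format_registry_date(
            study.registration_date
        )
    if study.design_raw is not None:
        ET.SubElement(root, "study_design").text = study.design_raw
    for condition in study.conditions:
        ET.SubElement(root, "condition").text = condition
    if study.condition_browse_terms:
        browse = ET.SubElement(root, "condition_browse")
        for term in study.condition_browse_terms:
            ET.SubElement(browse, "mesh_term").text = term
    if study.intervention_browse_terms:
        browse = ET.SubElement(root, "intervention_browse")
        for term in study.intervention_browse_terms:
            ET.SubElement(browse, "mesh_term").text = term
    for keyword in study.keywords:
        ET.SubElement(root, "keyword").text = keyword
    if study.max_age_years is not None:
        eligibility = ET.SubElement(root, "eligibility")
        ET.SubElement(eligibility, "maximum_age").text = _format_age(
            study.max_age_years
        )
    ET.indent(root)
    return ET.tostring(root, encoding="unicode") + "\n"


def ingest_directory(
    xml_dir: str | Path, field_map: Mapping[str, str] | None = None
) -> list[StudyRecord]:
    """Parse every ``*.xml`` file under ``xml_dir``; rejected records are
    logged and skipped, never fatal."""
    records = []
    for path in sorted(Path(xml_dir).glob("*.xml")):
        try:
            records.append(parse_study_record(path.read_bytes(), field_map))
        except (RegistryParseError, MissingStudyIdError) as exc:
            logger.error("skipping %s: %s", path.name, exc)
    return records


# ---------------------------------------------------------------------------
# completeness


@dataclass
class CompletenessReport:
    element_name: str
    per_year: dict[int, float]


#: queryable elements -> predicate "value present" on a StudyRecord
QUERYABLE_ELEMENTS = {
    "study_type": lambda s: s.study_type != MISSING,
    "conditions": lambda s: bool(s.conditions),
    "condition_browse_terms": lambda s: bool(s.condition_browse_terms),
    "intervention_browse_terms": lambda s: bool(s.intervention_browse_terms),
    "keywords": lambda s: bool(s.keywords),
    "design_raw": lambda s: s.design_raw is not None,
    "max_age_years": lambda s: s.max_age_years is not None,
    "brief_title": lambda s: bool(s.brief_title),
    "brief_description": lambda s: bool(s.brief_description),
}


def completeness_by_year(
    studies: Iterable[StudyRecord], element_name: str
) -> CompletenessReport:
    """Fraction of studies with a non-null element, per registration year.

    Studies without a registration date are excluded; years with zero dated
    studies do not appear.
    """
    if element_name not in QUERYABLE_ELEMENTS:
        raise ValueError(
            f"unknown element {element_name!r}; queryable elements: "
            f"{sorted(QUERYABLE_ELEMENTS)}"
        )
    predicate = QUERYABLE_ELEMENTS[element_name]
    totals: dict[int, int] = {}
    present: dict[int, int] = {}
    for study in studies:
        year = study.registration_year
        if year is None:
            continue
        totals[year] = totals.get(year, 0) + 1
        if predicate(study):
            present[year] = present.get(year, 0) + 1
    per_year = {
        year: present.get(year, 0) / totals[year] for year in sorted(totals)
    }
    return CompletenessReport(element_name, per_year)


# ---------------------------------------------------------------------------
# normalized table export


def write_tables(studies: Sequence[StudyRecord], out_dir: str | Path) -> None:
    """Write the normalized STUDIES/CONDITIONS/BROWSE/DESIGNS tables as CSV."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        {
            "study_id": [s.study_id for s in studies],
            "study_type": [s.study_type for s in studies],
            "registration_date": [
                s.registration_date.isoformat() if s.registration_date else ""
                for s in studies
            ],
            "max_age_years": [s.max_age_years for s in studies],
            "brief_title": [s.brief_title for s in studies],
        }
    ).to_csv(out / "studies.csv", index=False)

    def _long(attr: str, colname: str, extra: dict | None = None) -> "pd.DataFrame":
        rows = [
            {"study_id": s.study_id, colname: value, **(extra or {})}
            for s in studies
            for value in getattr(s, attr)
        ]
        return pd.DataFrame(rows, columns=["study_id", colname, *(extra or {})])

    _long("conditions", "condition").to_csv(out / "conditions.csv", index=False)
    pd.concat(
        [
            _long("condition_browse_terms", "mesh_term", {"source": "condition"}),
            _long("intervention_browse_terms", "mesh_term", {"source": "intervention"}),
        ],
        ignore_index=True,
    ).to_csv(out / "browse_terms.csv", index=False)
    _long("keywords", "keyword").to_csv(out / "keywords.csv", index=False)

    design_rows = [
        {
            "study_id": s.study_id,
            "design_name": c.name,
            "design_value": c.value,
            "masked_roles": ";".join(sorted(c.masked_roles)),
            "recognized": c.recognized,
        }
        for s in studies
        for c in s.design_components
    ]
    pd.DataFrame(
        design_rows,
        columns=["study_id", "design_name", "design_value", "masked_roles", "recognized"],
    ).to_csv(out / "designs.csv", index=False)
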