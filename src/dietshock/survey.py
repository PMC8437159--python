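"""Household survey data model, validation, and delimited-text IO.

Missing values are a first-class state: ``None`` in memory, the empty string
in files.  Unparseable cells are flagged in a validation report and set
missing rather than dropped, because the downstream tables report per-field
non-missing denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable

import pandas as pd

from .codebook import Codebook, load_codebook

# -- controlled vocabularies ----------------------------------------------

COUNTRIES = ("BurkinaFaso", "Ethiopia", "Nigeria")

#: site -> (country, locality)
SITES: dict[str, tuple[str, str]] = {
    "Nouna": ("BurkinaFaso", "rural"),
    "Ouagadougou": ("BurkinaFaso", "urban"),
    "Kersa": ("Ethiopia", "rural"),
    "AddisAbaba": ("Ethiopia", "urban"),
    "Ibadan": ("Nigeria", "rural"),
    "Lagos": ("Nigeria", "urban"),
}

PRICE_CATEGORIES = ("staples", "pulses", "fruits", "vegetables", "animal_source_foods")
PRICE_LEVELS = ("unchanged", "decreased", "increased")

SEX_LEVELS = ("female", "male")
AGE_BANDS = ("20-29", "30-39", "40+")
EDUCATION_LEVELS = (
    "none_or_incomplete_primary",
    "primary_or_incomplete_secondary",
    "secondary_or_higher",
)
OCCUPATION_LEVELS = (
    "unemployed",
    "farmer_or_casual_labor",
    "employed",
    "student_self_employed_other",
)
CROP_LEVELS = ("unchanged", "decreased", "increased", "does_not_farm")
ASSISTANCE_TYPES = ("cash", "food", "school_meals", "other")

PERIODS = ("before", "during")

MISSING = ""  # file sentinel


class SchemaError(ValueError):
    """Survey file header does not match the codebook column schema."""


@dataclass
class FoodFrequencyRecord:
    """Days consumed (0-7) per survey food group for one recall period."""

    period: str  # "before" | "during"
    days_by_group: dict[str, int | None]

    def copy(self) -> "FoodFrequencyRecord":
        return FoodFrequencyRecord(self.period, dict(self.days_by_group))


@dataclass
class HouseholdRecord:
    household_id: str
    country: str
    site: str
    locality: str
    respondent_sex: str | None
    age_band: str | None
    education: str | None
    head_of_household: bool | None
    household_size: int | None
    occupation: str | None
    price_changes: dict[str, str | None]  # category -> level or None
    worried_food: bool | None
    skipped_meal: bool | None
    whole_day_no_food: bool | None
    social_assistance: bool | None
    assistance_type: str | None
    crop_production: str | None
    food_freq_before: FoodFrequencyRecord
    food_freq_during: FoodFrequencyRecord

    def copy(self) -> "HouseholdRecord":
        return replace(
            self,
            price_changes=dict(self.price_changes),
            food_freq_before=self.food_freq_before.copy(),
            food_freq_during=self.food_freq_during.copy(),
        )


@dataclass
class Issue:
    household_id: str
    field: str
    problem: str


@dataclass
class ValidationReport:
    """Accumulated content problems; never raised for data issues."""

    issues: list[Issue] = field(default_factory=list)
    missing_counts: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, household_id: str, field_name: str, problem: str) -> None:
        self.issues.append(Issue(household_id, field_name, problem))

    def note_missing(self, field_name: str) -> None:
        self.missing_counts[field_name] = self.missing_counts.get(field_name, 0) + 1

    def summary(self) -> str:
        lines = [f"issues: {len(self.issues)}"]
        for iss in self.issues[:50]:
            lines.append(f"  {iss.household_id}: {iss.field}: {iss.problem}")
        if self.missing_counts:
            lines.append("missing counts:")
            for k, v in sorted(self.missing_counts.items()):
                lines.append(f"  {k}: {v}")
        return "\n".join(lines)


# -- validation ------------------------------------------------------------


def validate_record(record: HouseholdRecord, codebook: Codebook) -> ValidationReport:
    """Report every invariant violation; empty report iff the record is valid.

    Total: never raises for content problems.
    """
    rep = ValidationReport()
    rid = str(record.household_id)

    if record.site not in SITES:
        rep.add(rid, "site", f"unknown site {record.site!r}")
    else:
        country, locality = SITES[record.site]
        if record.country != country:
            rep.add(
                rid,
                "country",
                f"site {record.site} belongs to {country}, not {record.country}",
            )
        if record.locality != locality:
            rep.add(
                rid,
                "locality",
                f"site {record.site} is {locality}, not {record.locality}",
            )

    def check_enum(name: str, value: Any, levels: Iterable[Any]) -> None:
        if value is not None and value not in tuple(levels):
            rep.add(rid, name, f"invalid level {value!r}")

    check_enum("respondent_sex", record.respondent_sex, SEX_LEVELS)
    check_enum("age_band", record.age_band, AGE_BANDS)
    check_enum("education", record.education, EDUCATION_LEVELS)
    check_enum("occupation", record.occupation, OCCUPATION_LEVELS)
    check_enum("crop_production", record.crop_production, CROP_LEVELS)
    check_enum("assistance_type", record.assistance_type, ASSISTANCE_TYPES)

    if record.household_size is not None and record.household_size < 0:
        rep.add(rid, "household_size", f"negative size {record.household_size}")

    if set(record.price_changes) != set(PRICE_CATEGORIES):
        rep.add(rid, "price_changes", "price categories do not match schema")
    for cat, level in record.price_changes.items():
        if level is not None and level not in PRICE_LEVELS:
            rep.add(rid, f"price_{cat}", f"invalid level {level!r}")

    expected = set(codebook.survey_group_ids)
    for freq in (record.food_freq_before, record.food_freq_during):
        suffix = freq.period
        if set(freq.days_by_group) != expected:
            rep.add(rid, f"food_freq_{suffix}", "food groups do not match codebook")
        for gid, days in freq.days_by_group.items():
            if days is not None and not (0 <= days <= 7):
                rep.add(rid, f"ff_{gid}_{suffix}", f"days {days} outside [0, 7]")
    return rep


# -- delimited text IO -----------------------------------------------------

_BASE_COLUMNS = (
    "household_id",
    "country",
    "site",
    "locality",
    "respondent_sex",
    "age_band",
    "education",
    "head_of_household",
    "household_size",
    "occupation",
    *(f"price_{cat}" for cat in PRICE_CATEGORIES),
    "worried_food",
    "skipped_meal",
    "whole_day_no_food",
    "social_assistance",
    "assistance_type",
    "crop_production",
)


def table_columns(codebook: Codebook) -> tuple[str, ...]:
    ff = tuple(
        f"ff_{gid}_{period}"
        for period in PERIODS
        for gid in codebook.survey_group_ids
    )
    return _BASE_COLUMNS + ff


def _fmt_bool(v: bool | None) -> str:
    if v is None:
        return MISSING
    return "yes" if v else "no"


def _fmt(v: Any) -> str:
    return MISSING if v is None else str(v)


def record_to_row(record: HouseholdRecord, codebook: Codebook) -> dict[str, str]:
    row: dict[str, str] = {
        "household_id": str(record.household_id),
        "country": _fmt(record.country),
        "site": _fmt(record.site),
        "locality": _fmt(record.locality),
        "respondent_sex": _fmt(record.respondent_sex),
        "age_band": _fmt(record.age_band),
        "education": _fmt(record.education),
        "head_of_household": _fmt_bool(record.head_of_household),
        "household_size": _fmt(record.household_size),
        "occupation": _fmt(record.occupation),
        "worried_food": _fmt_bool(record.worried_food),
        "skipped_meal": _fmt_bool(record.skipped_meal),
        "whole_day_no_food": _fmt_bool(record.whole_day_no_food),
        "social_assistance": _fmt_bool(record.social_assistance),
        "assistance_type": _fmt(record.assistance_type),
        "crop_production": _fmt(record.crop_production),
    }
    for cat in PRICE_CATEGORIES:
        row[f"price_{cat}"] = _fmt(record.price_changes.get(cat))
    for freq in (record.food_freq_before, record.food_freq_during):
        for gid, days in freq.days_by_group.items():
            row[f"ff_{gid}_{freq.period}"] = _fmt(days)
    return row


def write_survey_table(
    records: Iterable[HouseholdRecord],
    path: str | Path,
    codebook: Codebook | None = None,
) -> None:
    """Write records as UTF-8 comma-delimited text; missing -> empty cell."""
    codebook = codebook or load_codebook()
    cols = table_columns(codebook)
    rows = [record_to_row(r, codebook) for r in records]
    df = pd.DataFrame(rows, columns=cols, dtype=str)
    df.to_csv(path, index=False, encoding="utf-8")


def _parse_bool(raw: str, rid: str, col: str, rep: ValidationReport) -> bool | None:
    if raw == MISSING:
        rep.note_missing(col)
        return None
    if raw in ("yes", "1", "True", "true"):
        return True
    if raw in ("no", "0", "False", "false"):
        return False
    rep.add(rid, col, f"unparseable boolean {raw!r}")
    return None


def _parse_enum(
    raw: str, levels: tuple[str, ...], rid: str, col: str, rep: ValidationReport
) -> str | None:
    if raw == MISSING:
        rep.note_missing(col)
        return None
    if raw not in levels:
        rep.add(rid, col, f"invalid level {raw!r}")
        return None
    return raw


def _parse_int(
    raw: str, rid: str, col: str, rep: ValidationReport, lo: int, hi: int | None
) -> int | None:
    if raw == MISSING:
        rep.note_missing(col)
        return None
    try:
        v = int(raw)
    except ValueError:
        rep.add(rid, col, f"unparseable integer {raw!r}")
        return None
    if v < lo or (hi is not None and v > hi):
        rep.add(rid, col, f"value {v} outside range")
        return None
    return v


def read_survey_table(
    path: str | Path, codebook: Codebook | None = None
) -> tuple[list[HouseholdRecord], ValidationReport]:
    """Read a survey CSV; returns (records, validation report).

    Content problems are flagged missing and reported, never dropped.
    A header/schema mismatch raises :class:`SchemaError` naming the column.
    """
    codebook = codebook or load_codebook()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")

    expected = table_columns(codebook)
    got = tuple(df.columns)
    unknown = [c for c in got if c not in expected]
    if unknown:
        raise SchemaError(f"unknown column(s): {unknown}")
    absent = [c for c in expected if c not in got]
    if absent:
        raise SchemaError(f"missing column(s): {absent}")

    rep = ValidationReport()
    records: list[HouseholdRecord] = []
    for _, row in df.iterrows():
        rid = row["household_id"]
        site = row["site"] or None
        country = row["country"] or None
        locality = row["locality"] or None
        price = {
            cat: _parse_enum(row[f"price_{cat}"], PRICE_LEVELS, rid, f"price_{cat}", rep)
            for cat in PRICE_CATEGORIES
        }
        freqs = {}
        for period in PERIODS:
            days = {
                gid: _parse_int(
                    row[f"ff_{gid}_{period}"], rid, f"ff_{gid}_{period}", rep, 0, 7
                )
                for gid in codebook.survey_group_ids
            }
            freqs[period] = FoodFrequencyRecord(period, days)
        rec = HouseholdRecord(
            household_id=rid,
            country=country,
            site=site,
            locality=locality,
            respondent_sex=_parse_enum(
                row["respondent_sex"], SEX_LEVELS, rid, "respondent_sex", rep
            ),
            age_band=_parse_enum(row["age_band"], AGE_BANDS, rid, "age_band", rep),
            education=_parse_enum(
                row["education"], EDUCATION_LEVELS, rid, "education", rep
            ),
            head_of_household=_parse_bool(
                row["head_of_household"], rid, "head_of_household", rep
            ),
            household_size=_parse_int(
                row["household_size"], rid, "household_size", rep, 0, None
            ),
            occupation=_parse_enum(
                row["occupation"], OCCUPATION_LEVELS, rid, "occupation", rep
            ),
            price_changes=price,
            worried_food=_parse_bool(row["worried_food"], rid, "worried_food", rep),
            skipped_meal=_parse_bool(row["skipped_meal"], rid, "skipped_meal", rep),
            whole_day_no_food=_parse_bool(
                row["whole_day_no_food"], rid, "whole_day_no_food", rep
            ),
            social_assistance=_parse_bool(
                row["social_assistance"], rid, "social_assistance", rep
            ),
            assistance_type=_parse_enum(
                row["assistance_type"], ASSISTANCE_TYPES, rid, "assistance_type", rep
            ),
            crop_production=_parse_enum(
                row["crop_production"], CROP_LEVELS, rid, "crop_production", rep
            ),
            food_freq_before=freqs["before"],
            food_freq_during=freqs["during"],
        )
        records.append(rec)
        consistency = validate_record(rec, codebook)
        for iss in consistency.issues:
            # range/enum problems were already flagged at parse time
            if iss.field in ("site", "country", "locality"):
                rep.issues.append(iss)
    return records, rep
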