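"""Descriptive tables: household characteristics, price/food-security
frequencies, consumption-change summaries, and before/during score summaries.

Percentages always use the per-variable non-missing denominator and are
rounded half-up to one decimal, so every emitted percentage recomputes from
its own count and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import pct
from .codebook import Codebook, load_codebook
from .scoring import ScoringOptions, classify_consumption_change, score_records
from .survey import (
    AGE_BANDS,
    CROP_LEVELS,
    EDUCATION_LEVELS,
    HouseholdRecord,
    OCCUPATION_LEVELS,
    PRICE_CATEGORIES,
    PRICE_LEVELS,
    SEX_LEVELS,
    SITES,
)

OVERALL = "Overall"

FOODSEC_LABELS = {
    "worried_food": "Worried you would run out of food (past month)",
    "skipped_meal": "Skipped a meal (past month)",
    "whole_day_no_food": "Went without eating for a whole day (past month)",
}


@dataclass
class FrequencyTable:
    """Long-format count/percentage table.

    Columns: variable, category, stratum, count, denominator, percentage.
    Percentage is None when the denominator is zero.
    """

    data: pd.DataFrame

    def cell(self, variable: str, category: str, stratum: str = OVERALL) -> dict:
        d = self.data
        row = d[
            (d["variable"] == variable)
            & (d["category"] == str(category))
            & (d["stratum"] == stratum)
        ]
        if row.empty:
            raise KeyError((variable, category, stratum))
        return row.iloc[0].to_dict()

    def percentage(self, variable: str, category: str, stratum: str = OVERALL):
        return self.cell(variable, category, stratum)["percentage"]


def _strata(records: list[HouseholdRecord]) -> dict[str, list[HouseholdRecord]]:
    out: dict[str, list[HouseholdRecord]] = {OVERALL: list(records)}
    for site in SITES:
        out[site] = [r for r in records if r.site == site]
    return out


def _freq_rows(
    variable: str,
    categories: tuple,
    values_by_stratum: dict[str, list],
) -> list[dict]:
    rows = []
    for stratum, values in values_by_stratum.items():
        observed = [v for v in values if v is not None]
        denom = len(observed)
        for cat in categories:
            count = sum(1 for v in observed if v == cat)
            rows.append(
                {
                    "variable": variable,
                    "category": str(cat),
                    "stratum": stratum,
                    "count": count,
                    "denominator": denom,
                    "percentage": pct(count, denom),
                }
            )
        rows.append(
            {
                "variable": variable,
                "category": "missing",
                "stratum": stratum,
                "count": len(values) - denom,
                "denominator": len(values),
                "percentage": pct(len(values) - denom, len(values)),
            }
        )
    return rows


def characteristics_table(
    records: list[HouseholdRecord],
) -> tuple[FrequencyTable, pd.DataFrame]:
    """Demographic characteristics by site and overall.

    Returns (frequency table, continuous summaries).  Continuous summaries
    cover household size (mean +/- SD); respondent age is collected banded,
    so no continuous age summary is available.
    """
    if not records:
        raise ValueError("need at least one record")
    strata = _strata(records)
    rows: list[dict] = []
    spec = [
        ("respondent_sex", SEX_LEVELS, lambda r: r.respondent_sex),
        ("age_band", AGE_BANDS, lambda r: r.age_band),
        ("education", EDUCATION_LEVELS, lambda r: r.education),
        ("head_of_household", (True, False), lambda r: r.head_of_household),
        ("occupation", OCCUPATION_LEVELS, lambda r: r.occupation),
        ("locality", ("rural", "urban"), lambda r: r.locality),
    ]
    for variable, categories, getter in spec:
        values = {s: [getter(r) for r in recs] for s, recs in strata.items()}
        rows.extend(_freq_rows(variable, categories, values))

    cont_rows = []
    for stratum, recs in strata.items():
        sizes = [r.household_size for r in recs if r.household_size is not None]
        arr = np.asarray(sizes, dtype=float)
        cont_rows.append(
            {
                "variable": "household_size",
                "stratum": stratum,
                "n": len(sizes),
                "mean": float(arr.mean()) if len(sizes) else None,
                "sd": float(arr.std(ddof=1)) if len(sizes) > 1 else None,
            }
        )
    return FrequencyTable(pd.DataFrame(rows)), pd.DataFrame(cont_rows)


def price_change_table(records: list[HouseholdRecord]) -> FrequencyTable:
    """Price-change and food-security frequencies by site and overall
    (non-missing denominators per variable)."""
    strata = _strata(records)
    rows: list[dict] = []
    for cat in PRICE_CATEGORIES:
        values = {
            s: [r.price_changes.get(cat) for r in recs] for s, recs in strata.items()
        }
        rows.extend(_freq_rows(f"price_{cat}", PRICE_LEVELS, values))
    for item in FOODSEC_LABELS:
        values = {s: [getattr(r, item) for r in recs] for s, recs in strata.items()}
        rows.extend(_freq_rows(item, (True, False), values))
    values = {s: [r.social_assistance for r in recs] for s, recs in strata.items()}
    rows.extend(_freq_rows("social_assistance", (True, False), values))
    # crop production among farming households only
    values = {
        s: [
            r.crop_production
            for r in recs
            if r.crop_production not in (None, "does_not_farm")
        ]
        for s, recs in strata.items()
    }
    rows.extend(_freq_rows("crop_production", CROP_LEVELS[:3], values))
    return FrequencyTable(pd.DataFrame(rows))


@dataclass
class ChangeSummary:
    """Percent decreased/unchanged/increased per group x stratum among
    households with both periods observed for the group."""

    data: pd.DataFrame

    def cell(self, group: str, stratum: str = OVERALL) -> dict:
        d = self.data
        row = d[(d["group"] == group) & (d["stratum"] == stratum)]
        if row.empty:
            raise KeyError((group, stratum))
        return row.iloc[0].to_dict()


def consumption_change_summary(
    records: list[HouseholdRecord],
    grouping: str = "MDD-W",
    codebook: Codebook | None = None,
    options: ScoringOptions = ScoringOptions(),
) -> ChangeSummary:
    codebook = codebook or load_codebook()
    per_record = []
    for r in records:
        mask = (
            codebook.mask_for_site(r.site) if options.apply_site_masks else frozenset()
        )
        per_record.append(
            classify_consumption_change(
                r.food_freq_before,
                r.food_freq_during,
                grouping,
                codebook,
                options.aggregator,
                mask,
            )
        )
    strata = _strata(records)
    idx_by_id = {id(r): c for r, c in zip(records, per_record)}
    rows = []
    groups = list(per_record[0]) if per_record else []
    for stratum, recs in strata.items():
        for group in groups:
            statuses = [idx_by_id[id(r)][group] for r in recs]
            observed = [s for s in statuses if s != "indeterminate"]
            denom = len(observed)
            row = {"group": group, "stratum": stratum, "n": denom}
            for status in ("decreased", "unchanged", "increased"):
                count = sum(1 for s in observed if s == status)
                row[f"n_{status}"] = count
                row[f"pct_{status}"] = pct(count, denom)
            rows.append(row)
    return ChangeSummary(pd.DataFrame(rows))


def mean_scores_before_during(
    records: list[HouseholdRecord],
    codebook: Codebook | None = None,
    options: ScoringOptions = ScoringOptions(),
    scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-site and overall DDS mean +/- SD and PDQS median (IQR), both
    periods, among records complete for the period."""
    codebook = codebook or load_codebook()
    if scores is None:
        scores = score_records(records, codebook, options)
    rows = []
    strata = {OVERALL: scores} | {
        site: scores[scores["site"] == site] for site in SITES
    }
    for stratum, df in strata.items():
        for period in ("before", "during"):
            sub = df[df[f"complete_{period}"]]
            dds = sub[f"dds_{period}"].to_numpy(dtype=float)
            pdqs = sub[f"pdqs_{period}"].to_numpy(dtype=float)
            rows.append(
                {
                    "stratum": stratum,
                    "period": period,
                    "n": len(sub),
                    "dds_mean": float(dds.mean()) if len(dds) else None,
                    "dds_sd": float(dds.std(ddof=1)) if len(dds) > 1 else None,
                    "pdqs_median": float(np.median(pdqs)) if len(pdqs) else None,
                    "pdqs_q1": float(np.percentile(pdqs, 25)) if len(pdqs) else None,
                    "pdqs_q3": float(np.percentile(pdqs, 75)) if len(pdqs) else None,
                }
            )
    return pd.DataFrame(rows)
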