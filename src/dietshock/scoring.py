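"""Dietary diversity (DDS, 0-10) and diet quality (PDQS, 0-40) scoring.

Both scores are computed from 7-day food-group recall.  A dietary-diversity
group contributes one point only when it was eaten at least once each day of
the week (weekly days / 7 >= 1, i.e. 7 of 7 days); the threshold is exposed
for sensitivity analyses.  Diet-quality points use weekly frequency bands:
healthy groups 0-1 -> 0, 2-3 -> 1, >=4 -> 2; unhealthy groups reversed.
Weekly servings are proxied by days consumed (the recall collects days).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .codebook import Codebook, CodebookError, MDDW_GROUPS, load_codebook
from .survey import FoodFrequencyRecord, HouseholdRecord

AGGREGATORS = ("max", "sum_capped")

DDS_MAX = 10
PDQS_MAX = 40


@dataclass(frozen=True)
class ScoringOptions:
    """Configurable scoring rules.

    dds_min_days: weekly days needed for a group to count toward the DDS
        (7 = eaten every day, the default rule; 1 = any-consumption variant).
    aggregator: how multiple survey groups collapse into one score group
        ("max" counts a day once however many constituents were eaten;
        "sum_capped" sums days and caps at 7).
    apply_site_masks: honor per-site food-list exclusions from the codebook.
    """

    dds_min_days: int = 7
    aggregator: str = "max"
    apply_site_masks: bool = True

    def __post_init__(self) -> None:
        if self.aggregator not in AGGREGATORS:
            raise ValueError(f"unknown aggregator {self.aggregator!r}")
        if not 1 <= self.dds_min_days <= 7:
            raise ValueError("dds_min_days must be in [1, 7]")


@dataclass
class MddwProfile:
    """Days consumed per MDD-W group; masked groups flagged, not deleted."""

    days_by_group: dict[str, int | None]  # None = missing
    excluded: frozenset[str] = frozenset()


@dataclass
class PdqsProfile:
    """Weekly servings (proxied by days) per PDQS group with healthy flags."""

    servings_by_group: dict[str, int | None]
    healthy: dict[str, bool]
    excluded: frozenset[str] = frozenset()


@dataclass
class DietScores:
    period: str
    dds: int
    pdqs: int
    dds_contributions: dict[str, int] = field(default_factory=dict)
    pdqs_points: dict[str, int] = field(default_factory=dict)
    mask: frozenset[str] = frozenset()
    complete: bool = True  # no missing group-days in the period


def _aggregate(days: list[int], aggregator: str) -> int:
    if aggregator == "max":
        return max(days)
    return min(7, sum(days))


def map_to_mddw_groups(
    freq: FoodFrequencyRecord,
    codebook: Codebook | None = None,
    aggregator: str = "max",
    mask: frozenset[str] = frozenset(),
) -> MddwProfile:
    """Collapse survey groups into the 10 MDD-W groups.

    *mask* contains excluded **survey** group ids; an MDD-W group is excluded
    when every constituent is masked.  A group with any missing constituent
    day (among unmasked constituents) is missing.
    """
    codebook = codebook or load_codebook()
    constituents = codebook.mddw_constituents()
    for gid in freq.days_by_group:
        codebook.group(gid)  # raises KeyError for unknown survey groups
    days_out: dict[str, int | None] = {}
    excluded = set()
    for mddw_id in MDDW_GROUPS:
        cons = [c for c in constituents[mddw_id] if c not in mask]
        if not cons:
            excluded.add(mddw_id)
            days_out[mddw_id] = None
            continue
        vals = [freq.days_by_group.get(c) for c in cons]
        if any(v is None for v in vals):
            days_out[mddw_id] = None
        else:
            days_out[mddw_id] = _aggregate(vals, aggregator)  # type: ignore[arg-type]
    return MddwProfile(days_by_group=days_out, excluded=frozenset(excluded))


def compute_dds(
    profile: MddwProfile,
    mask: frozenset[str] = frozenset(),
    min_days: int = 7,
    period: str = "during",
) -> DietScores:
    """Count MDD-W groups meeting the daily-consumption rule.

    *mask* here holds excluded **MDD-W** group ids (merged with the profile's
    own exclusions).  Masked groups contribute 0; the score is not rescaled.
    """
    excluded = profile.excluded | mask
    contributions: dict[str, int] = {}
    complete = True
    for gid, days in profile.days_by_group.items():
        if gid in excluded:
            contributions[gid] = 0
            continue
        if days is None:
            contributions[gid] = 0
            complete = False
            continue
        contributions[gid] = 1 if days >= min_days else 0
    dds = sum(contributions.values())
    return DietScores(
        period=period,
        dds=dds,
        pdqs=0,
        dds_contributions=contributions,
        mask=frozenset(excluded),
        complete=complete,
    )


def map_to_pdqs_groups(
    freq: FoodFrequencyRecord,
    codebook: Codebook | None = None,
    aggregator: str = "max",
    mask: frozenset[str] = frozenset(),
) -> PdqsProfile:
    """Survey groups coincide with PDQS groups in the shipped codebook, but
    aggregation is kept general for codebooks with several survey groups per
    PDQS group (constituency = identity here)."""
    codebook = codebook or load_codebook()
    servings: dict[str, int | None] = {}
    healthy: dict[str, bool] = {}
    excluded = set()
    for g in codebook.groups:
        healthy[g.id] = g.healthy
        if g.id not in freq.days_by_group:
            raise CodebookError(f"survey group {g.id!r} absent from record")
        if g.id in mask:
            excluded.add(g.id)
            servings[g.id] = None
            continue
        servings[g.id] = freq.days_by_group[g.id]
    return PdqsProfile(
        servings_by_group=servings, healthy=healthy, excluded=frozenset(excluded)
    )


def _pdqs_points(servings: int, healthy: bool) -> int:
    if healthy:
        if servings <= 1:
            return 0
        if servings <= 3:
            return 1
        return 2
    if servings <= 1:
        return 2
    if servings <= 3:
        return 1
    return 0


def compute_pdqs(
    profile: PdqsProfile,
    mask: frozenset[str] = frozenset(),
    period: str = "during",
) -> DietScores:
    """Sum the 0/1/2 frequency-band points; masked groups contribute 0."""
    excluded = profile.excluded | mask
    points: dict[str, int] = {}
    complete = True
    for gid, servings in profile.servings_by_group.items():
        if gid in excluded:
            points[gid] = 0
            continue
        if servings is None:
            points[gid] = 0
            complete = False
            continue
        points[gid] = _pdqs_points(servings, profile.healthy[gid])
    return DietScores(
        period=period,
        dds=0,
        pdqs=sum(points.values()),
        pdqs_points=points,
        mask=frozenset(excluded),
        complete=complete,
    )


def classify_consumption_change(
    before: FoodFrequencyRecord,
    during: FoodFrequencyRecord,
    grouping: str = "MDD-W",
    codebook: Codebook | None = None,
    aggregator: str = "max",
    mask: frozenset[str] = frozenset(),
) -> dict[str, str]:
    """Per mapped group: decreased / unchanged / increased / indeterminate."""
    codebook = codebook or load_codebook()
    if grouping == "MDD-W":
        b = map_to_mddw_groups(before, codebook, aggregator, mask).days_by_group
        d = map_to_mddw_groups(during, codebook, aggregator, mask).days_by_group
    elif grouping == "PDQS":
        b = map_to_pdqs_groups(before, codebook, aggregator, mask).servings_by_group
        d = map_to_pdqs_groups(during, codebook, aggregator, mask).servings_by_group
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    out: dict[str, str] = {}
    for gid in b:
        vb, vd = b[gid], d[gid]
        if vb is None or vd is None:
            out[gid] = "indeterminate"
        elif vd < vb:
            out[gid] = "decreased"
        elif vd > vb:
            out[gid] = "increased"
        else:
            out[gid] = "unchanged"
    return out


# -- household/batch scoring ----------------------------------------------


def score_household(
    record: HouseholdRecord,
    codebook: Codebook | None = None,
    options: ScoringOptions = ScoringOptions(),
) -> dict[str, DietScores]:
    """Score both periods for one household, applying its site mask."""
    codebook = codebook or load_codebook()
    mask = (
        codebook.mask_for_site(record.site)
        if options.apply_site_masks
        else frozenset()
    )
    out: dict[str, DietScores] = {}
    for freq in (record.food_freq_before, record.food_freq_during):
        mddw = map_to_mddw_groups(freq, codebook, options.aggregator, mask)
        dds = compute_dds(mddw, min_days=options.dds_min_days, period=freq.period)
        pdqs_profile = map_to_pdqs_groups(freq, codebook, options.aggregator, mask)
        pdqs = compute_pdqs(pdqs_profile, period=freq.period)
        out[freq.period] = DietScores(
            period=freq.period,
            dds=dds.dds,
            pdqs=pdqs.pdqs,
            dds_contributions=dds.dds_contributions,
            pdqs_points=pdqs.pdqs_points,
            mask=dds.mask | pdqs.mask,
            complete=dds.complete and pdqs.complete,
        )
    return out


def score_records(
    records: list[HouseholdRecord],
    codebook: Codebook | None = None,
    options: ScoringOptions = ScoringOptions(),
) -> pd.DataFrame:
    """Score a batch; one row per household with per-period scores and
    completeness flags (scores of incomplete records are computed over the
    observed groups and should be filtered on the flag downstream)."""
    codebook = codebook or load_codebook()
    rows = []
    for rec in records:
        scored = score_household(rec, codebook, options)
        rows.append(
            {
                "household_id": rec.household_id,
                "site": rec.site,
                "country": rec.country,
                "dds_before": scored["before"].dds,
                "dds_during": scored["during"].dds,
                "pdqs_before": scored["before"].pdqs,
                "pdqs_during": scored["during"].pdqs,
                "complete_before": scored["before"].complete,
                "complete_during": scored["during"].complete,
            }
        )
    return pd.DataFrame(rows)
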