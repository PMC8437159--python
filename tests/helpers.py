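"""Independent brute-force re-implementations used as test oracles.

These deliberately re-derive the scores with explicit loops over the printed
point rules, sharing no code with the production scorer beyond the codebook
*data* (group ids, mappings, masks).
"""

from __future__ import annotations


def brute_dds(days_by_survey_group: dict[str, int], codebook,
              masked_survey_groups=frozenset(), min_days: int = 7,
              aggregator: str = "max") -> int:
    """Explicit-loop dietary diversity score (0-10)."""
    score = 0
    for mddw_id, constituents in codebook.mddw_constituents().items():
        usable = [c for c in constituents if c not in masked_survey_groups]
        if not usable:
            continue
        if aggregator == "max":
            days = 0
            for c in usable:
                if days_by_survey_group[c] > days:
                    days = days_by_survey_group[c]
        else:
            days = 0
            for c in usable:
                days += days_by_survey_group[c]
            if days > 7:
                days = 7
        if days >= min_days:
            score += 1
    return score


def brute_pdqs(days_by_survey_group: dict[str, int], codebook,
               masked_survey_groups=frozenset()) -> int:
    """Explicit-loop diet quality score (0-40).

    Healthy groups: 0-1 serving/week -> 0, 2-3 -> 1, >= 4 -> 2 points.
    Unhealthy groups: 0-1 -> 2, 2-3 -> 1, >= 4 -> 0 points.
    """
    total = 0
    for g in codebook.groups:
        if g.id in masked_survey_groups:
            continue
        servings = days_by_survey_group[g.id]
        if g.healthy:
            if servings in (0, 1):
                points = 0
            elif servings in (2, 3):
                points = 1
            else:
                points = 2
        else:
            if servings in (0, 1):
                points = 2
            elif servings in (2, 3):
                points = 1
            else:
                points = 0
        total += points
    return total
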