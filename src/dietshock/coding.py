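"""Exposure/confounder coding and missing-indicator design-matrix assembly.

Price-change responses are dichotomized (increased = 1; unchanged or
decreased = 0).  Missing confounder values are retained via the missing
indicator method: categorical terms gain an explicit missing level,
continuous terms are mean-imputed with a companion 0/1 indicator.  Rows with
a missing outcome are dropped (outcomes are never imputed) and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codebook import Codebook, load_codebook
from .scoring import ScoringOptions, score_records
from .survey import (
    AGE_BANDS,
    CROP_LEVELS,
    EDUCATION_LEVELS,
    HouseholdRecord,
    OCCUPATION_LEVELS,
    PRICE_CATEGORIES,
    SEX_LEVELS,
)

OUTCOMES = ("DDS", "PDQS")


class CodingError(ValueError):
    pass


# -- elementary coders -----------------------------------------------------


def code_price_change(level: str | None) -> int | None:
    """increased -> 1; unchanged or decreased -> 0; missing stays missing."""
    if level is None:
        return None
    if level == "increased":
        return 1
    if level in ("unchanged", "decreased"):
        return 0
    raise CodingError(f"unknown price-change level {level!r}")


def code_food_security(record: HouseholdRecord) -> tuple[int | None, int | None, int | None]:
    """(worried, skipped meal, whole day without food) as 1/0/missing."""

    def b(v: bool | None) -> int | None:
        return None if v is None else int(v)

    return b(record.worried_food), b(record.skipped_meal), b(record.whole_day_no_food)


def code_crop_production(record: HouseholdRecord) -> str | None:
    """4-level factor with 'unchanged' as reference; missing preserved."""
    v = record.crop_production
    if v is None:
        return None
    if v not in CROP_LEVELS:
        raise CodingError(f"unknown crop-production level {v!r}")
    return v


# -- term specification ----------------------------------------------------


@dataclass(frozen=True)
class TermSpec:
    """One model term: how to extract and encode it.

    kind: "binary" (0/1), "categorical" (reference-coded), or "continuous".
    For categorical terms *levels* lists all levels and *ref* the reference.
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()
    ref: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "continuous"):
            raise CodingError(f"unknown term kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels or self.ref not in self.levels:
                raise CodingError(f"categorical term {self.name!r} needs levels + ref")


def price_term(category: str) -> TermSpec:
    if category not in PRICE_CATEGORIES:
        raise CodingError(f"unknown price category {category!r}")
    return TermSpec(name=f"price_{category}_increase", kind="binary")


def default_exposure_terms() -> list[TermSpec]:
    return [price_term(cat) for cat in PRICE_CATEGORIES]


def default_candidate_terms() -> list[TermSpec]:
    """Screen candidates, with the reference levels used in the tables."""
    return [
        TermSpec("worried_food", "binary"),
        TermSpec("skipped_meal", "binary"),
        TermSpec("whole_day_no_food", "binary"),
        TermSpec("age_band", "categorical", AGE_BANDS, "20-29"),
        TermSpec("respondent_sex", "categorical", SEX_LEVELS, "female"),
        TermSpec(
            "education", "categorical", EDUCATION_LEVELS, "primary_or_incomplete_secondary"
        ),
        TermSpec("head_of_household", "binary"),
        TermSpec(
            "occupation", "categorical", OCCUPATION_LEVELS, "employed"
        ),
        TermSpec("locality", "categorical", ("urban", "rural"), "urban"),
    ]


def default_forced_terms() -> list[TermSpec]:
    """Always kept in the multivariate model regardless of the screen."""
    return [
        TermSpec("crop_production", "categorical", CROP_LEVELS, "unchanged"),
        TermSpec("household_size", "continuous"),
    ]


def extract_term(record: HouseholdRecord, name: str):
    """Raw term value for one household (None = missing)."""
    if name.startswith("price_") and name.endswith("_increase"):
        cat = name[len("price_") : -len("_increase")]
        return code_price_change(record.price_changes.get(cat))
    if name == "worried_food":
        return None if record.worried_food is None else int(record.worried_food)
    if name == "skipped_meal":
        return None if record.skipped_meal is None else int(record.skipped_meal)
    if name == "whole_day_no_food":
        return None if record.whole_day_no_food is None else int(record.whole_day_no_food)
    if name == "head_of_household":
        return None if record.head_of_household is None else int(record.head_of_household)
    if name == "age_band":
        return record.age_band
    if name == "respondent_sex":
        return record.respondent_sex
    if name == "education":
        return record.education
    if name == "occupation":
        return record.occupation
    if name == "locality":
        return record.locality
    if name == "crop_production":
        return code_crop_production(record)
    if name == "household_size":
        return record.household_size
    raise CodingError(f"term references unknown field {name!r}")


# -- design matrix ---------------------------------------------------------


@dataclass
class DesignMatrix:
    outcome: str
    y: np.ndarray
    X: pd.DataFrame  # includes an "intercept" column
    clusters: np.ndarray
    term_columns: dict[str, list[str]] = field(default_factory=dict)
    n_dropped_outcome: int = 0

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.clusters))


def _encode_term(
    term: TermSpec, values: list, X: dict[str, np.ndarray]
) -> list[str]:
    """Append the term's columns to X; returns the column names added."""
    cols: list[str] = []
    n = len(values)
    missing = np.array([v is None for v in values])
    if term.kind == "binary":
        col = term.name
        X[col] = np.array([0.0 if v is None else float(v) for v in values])
        cols.append(col)
    elif term.kind == "continuous":
        observed = np.array([float(v) for v in values if v is not None])
        if observed.size == 0:
            raise CodingError(f"term {term.name!r} has no observed values")
        mean = float(observed.mean())
        X[term.name] = np.array(
            [mean if v is None else float(v) for v in values]
        )
        cols.append(term.name)
    else:  # categorical, reference-coded
        for level in term.levels:
            if level == term.ref:
                continue
            col = f"{term.name}_{level}"
            X[col] = np.array([1.0 if v == level else 0.0 for v in values])
            cols.append(col)
    if missing.any():
        ind = f"{term.name}_missing"
        X[ind] = missing.astype(float)
        cols.append(ind)
    assert len(next(iter(X.values()))) == n
    return cols


def encode_with_missing_indicators(
    records: list[HouseholdRecord],
    terms: list[TermSpec],
    outcome: str,
    codebook: Codebook | None = None,
    options: ScoringOptions = ScoringOptions(),
    period: str = "during",
    scores: pd.DataFrame | None = None,
    cluster: str = "site",
) -> DesignMatrix:
    """Assemble outcome, encoded covariates, and cluster ids.

    Rows whose outcome score is incomplete (missing group-days in *period*)
    are dropped and counted in ``n_dropped_outcome``; no missing values
    remain in the design after encoding.
    """
    if outcome not in OUTCOMES:
        raise CodingError(f"unknown outcome {outcome!r}")
    codebook = codebook or load_codebook()
    if scores is None:
        scores = score_records(records, codebook, options)
    score_col = f"{outcome.lower()}_{period}"
    complete_col = f"complete_{period}"
    keep = scores[complete_col].to_numpy(dtype=bool)
    n_dropped = int((~keep).sum())

    kept = [r for r, k in zip(records, keep) if k]
    y = scores.loc[keep, score_col].to_numpy(dtype=float)
    clusters = np.array([getattr(r, cluster) for r in kept])

    X: dict[str, np.ndarray] = {"intercept": np.ones(len(kept))}
    term_columns: dict[str, list[str]] = {}
    for term in terms:
        values = [extract_term(r, term.name) for r in kept]
        term_columns[term.name] = _encode_term(term, values, X)
    Xdf = pd.DataFrame(X)
    return DesignMatrix(
        outcome=outcome,
        y=y,
        X=Xdf,
        clusters=clusters,
        term_columns=term_columns,
        n_dropped_outcome=n_dropped,
    )
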