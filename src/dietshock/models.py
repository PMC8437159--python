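"""Exchangeable-correlation GEE models with univariate screening.

Model-building rules: each of the five price-change exposures is always
retained; candidate confounders enter the multivariate model when their
joint Wald p-value in a single-covariate (univariate) GEE is below 0.20;
crop production and household size are forced in regardless.  Estimation is
a linear marginal mean with an exchangeable working correlation clustered by
site and cluster-robust (sandwich) standard errors; Wald 95% CIs use the
1.96 normal quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .codebook import Codebook, load_codebook
from .coding import (
    DesignMatrix,
    TermSpec,
    default_candidate_terms,
    default_exposure_terms,
    default_forced_terms,
    encode_with_missing_indicators,
)
from .scoring import ScoringOptions, score_records
from .survey import COUNTRIES, HouseholdRecord

Z_95 = 1.96
SCREEN_ALPHA = 0.20


class ModelError(ValueError):
    pass


class SingleClusterError(ModelError):
    """Raised when < 2 clusters are present; refit with independence
    working correlation on unclustered data instead."""


@dataclass
class GeeResult:
    """Tidy per-column estimates plus fit metadata."""

    outcome: str
    table: pd.DataFrame  # column, estimate, se, ci_low, ci_high, p
    term_pvalues: dict[str, float]  # joint Wald p per term
    n_obs: int
    n_clusters: int
    n_dropped_outcome: int
    working_correlation: str = "exchangeable"
    cov_type: str = "robust"
    dep_param: float = float("nan")  # estimated common correlation
    converged: bool = True
    scope: str = "combined"
    model: str = "multivariate"

    def estimate(self, column: str) -> float:
        return float(self.table.set_index("column").loc[column, "estimate"])

    def row(self, column: str) -> pd.Series:
        return self.table.set_index("column").loc[column]


def fit_gee_linear(
    design: DesignMatrix, maxiter: int = 100, cov_type: str = "robust"
) -> GeeResult:
    """Fit the linear exchangeable-GEE contract on an encoded design.

    cov_type "robust" is the plain cluster sandwich (default, matching the
    source analysis); "bias_reduced" applies the Mancl-DeRouen small-sample
    correction, config-gated because 6-cluster sandwich SEs are
    anticonservative.
    """
    if cov_type not in ("robust", "bias_reduced"):
        raise ModelError(f"unknown cov_type {cov_type!r}")
    if design.n_clusters < 2:
        raise SingleClusterError(
            "exchangeable correlation needs >= 2 clusters; "
            "use an independence fit for single-cluster data"
        )
    X = design.X
    for col in X.columns:
        if col != "intercept" and float(np.asarray(X[col]).std()) == 0.0:
            raise ModelError(f"zero-variance column: {col}")

    model = sm.GEE(
        design.y,
        X,
        groups=design.clusters,
        family=sm.families.Gaussian(),
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(maxiter=maxiter, cov_type=cov_type)
        except Exception as exc:
            raise ModelError(f"GEE estimation failed: {exc}") from exc
    # non-convergence is flagged on the result, never silent
    if any("convergence" in str(w.message).lower() for w in caught):
        converged = False
    if getattr(res, "converged", True) is False:
        converged = False

    params = np.asarray(res.params)
    se = np.asarray(res.standard_errors(cov_type=cov_type))
    z = np.divide(params, se, out=np.zeros_like(params), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "column": list(X.columns),
            "estimate": params,
            "se": se,
            "ci_low": params - Z_95 * se,
            "ci_high": params + Z_95 * se,
            "p": p,
        }
    )

    term_pvalues: dict[str, float] = {}
    cols = list(X.columns)
    for term, term_cols in design.term_columns.items():
        test_cols = [c for c in term_cols if not c.endswith("_missing")]
        if not test_cols:
            continue
        L = np.zeros((len(test_cols), len(cols)))
        for i, c in enumerate(test_cols):
            L[i, cols.index(c)] = 1.0
        wald = res.wald_test(L, scalar=True)
        term_pvalues[term] = float(wald.pvalue)

    dep = model.cov_struct.dep_params
    return GeeResult(
        outcome=design.outcome,
        table=table,
        term_pvalues=term_pvalues,
        n_obs=design.n_obs,
        n_clusters=design.n_clusters,
        n_dropped_outcome=design.n_dropped_outcome,
        cov_type=cov_type,
        dep_param=float(np.asarray(dep).ravel()[0]),
        converged=converged,
    )


# -- model specification ----------------------------------------------------


@dataclass
class ModelSpec:
    outcome: str = "DDS"
    exposures: list[TermSpec] = field(default_factory=default_exposure_terms)
    candidates: list[TermSpec] = field(default_factory=default_candidate_terms)
    forced: list[TermSpec] = field(default_factory=default_forced_terms)
    cluster: str = "site"
    scope: str = "combined"  # "combined" | "per_country"
    alpha: float = SCREEN_ALPHA
    cov_type: str = "robust"

    def __post_init__(self) -> None:
        if self.scope not in ("combined", "per_country"):
            raise ModelError(f"unknown scope {self.scope!r}")


@dataclass
class ScreenResult:
    pvalues: dict[str, float]
    selected: list[TermSpec]
    excluded_all_missing: list[str] = field(default_factory=list)


def univariate_screen(
    records: list[HouseholdRecord],
    outcome: str,
    candidates: list[TermSpec],
    alpha: float = SCREEN_ALPHA,
    codebook: Codebook | None = None,
    options: ScoringOptions = ScoringOptions(),
    cluster: str = "site",
    scores: pd.DataFrame | None = None,
) -> ScreenResult:
    """Fit each candidate alone; keep it iff its joint Wald p < alpha."""
    codebook = codebook or load_codebook()
    if scores is None:
        scores = score_records(records, codebook, options)
    pvalues: dict[str, float] = {}
    selected: list[TermSpec] = []
    excluded: list[str] = []
    for cand in candidates:
        design = encode_with_missing_indicators(
            records, [cand], outcome, codebook, options, scores=scores, cluster=cluster
        )
        substantive = [
            c for c in design.term_columns[cand.name] if not c.endswith("_missing")
        ]
        if not substantive or all(
            float(np.asarray(design.X[c]).std()) == 0.0 for c in substantive
        ):
            warnings.warn(
                f"candidate {cand.name!r} has no observed variation; excluded"
            )
            excluded.append(cand.name)
            continue
        result = fit_gee_linear(design)
        p = result.term_pvalues[cand.name]
        pvalues[cand.name] = p
        if p < alpha:
            selected.append(cand)
    return ScreenResult(pvalues=pvalues, selected=selected, excluded_all_missing=excluded)


@dataclass
class ModelFit:
    scope_label: str  # "combined" or the country name
    screen: ScreenResult
    multivariate: GeeResult
    univariate: list[GeeResult] = field(default_factory=list)


def build_and_fit(
    records: list[HouseholdRecord],
    spec: ModelSpec,
    codebook: Codebook | None = None,
    options: ScoringOptions = ScoringOptions(),
    include_univariate: bool = True,
) -> list[ModelFit]:
    """Run the screen, assemble the multivariate model, and fit.

    Returns one :class:`ModelFit` for combined scope, or one per country for
    per-country scope (each country requires both of its sites present).
    The screen is re-run within each scope.
    """
    codebook = codebook or load_codebook()
    if spec.scope == "per_country":
        fits = []
        for country in COUNTRIES:
            subset = [r for r in records if r.country == country]
            n_sites = len({r.site for r in subset})
            if n_sites < 2:
                raise ModelError(
                    f"country model for {country} requires both sites present "
                    f"(found {n_sites})"
                )
            sub_spec = ModelSpec(
                outcome=spec.outcome,
                exposures=spec.exposures,
                candidates=spec.candidates,
                forced=spec.forced,
                cluster=spec.cluster,
                scope="combined",
                alpha=spec.alpha,
                cov_type=spec.cov_type,
            )
            fit = build_and_fit(subset, sub_spec, codebook, options, include_univariate)[0]
            fit.scope_label = country
            fits.append(fit)
        return fits

    scores = score_records(records, codebook, options)
    screen = univariate_screen(
        records,
        spec.outcome,
        spec.candidates,
        spec.alpha,
        codebook,
        options,
        spec.cluster,
        scores=scores,
    )
    terms = list(spec.exposures) + screen.selected + [
        t for t in spec.forced if t.name not in {s.name for s in screen.selected}
    ]
    design = encode_with_missing_indicators(
        records, terms, spec.outcome, codebook, options, scores=scores,
        cluster=spec.cluster,
    )
    mv = fit_gee_linear(design, cov_type=spec.cov_type)
    mv.model = "multivariate"

    univariate: list[GeeResult] = []
    if include_univariate:
        for term in list(spec.exposures) + spec.candidates + spec.forced:
            d = encode_with_missing_indicators(
                records, [term], spec.outcome, codebook, options, scores=scores,
                cluster=spec.cluster,
            )
            try:
                r = fit_gee_linear(d, cov_type=spec.cov_type)
            except ModelError:
                continue
            r.model = "univariate"
            univariate.append(r)
    return [ModelFit(scope_label="combined", screen=screen, multivariate=mv,
                     univariate=univariate)]


# -- reporting --------------------------------------------------------------


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def format_estimate(estimate: float, ci_low: float, ci_high: float, p: float) -> str:
    return f"{estimate:.2f} ({ci_low:.2f} to {ci_high:.2f}){_stars(p)}"


def tidy_results(
    fits: list[ModelFit],
    outcome: str,
    terms: list[TermSpec] | None = None,
) -> pd.DataFrame:
    """Long results table across scopes and models.

    When *terms* is given, a ``display = "ref"`` row is emitted for the
    reference level of every categorical term present in a model.
    """
    cols_by_ref: dict[str, list[str]] = {}
    for t in terms or []:
        if t.kind == "categorical":
            ref_col = f"{t.name}_{t.ref}"
            level_cols = [f"{t.name}_{lv}" for lv in t.levels if lv != t.ref]
            cols_by_ref[ref_col] = level_cols
    rows = []
    for fit in fits:
        for res in [fit.multivariate] + fit.univariate:
            present = set(res.table["column"])
            for ref_col, level_cols in cols_by_ref.items():
                if any(c in present for c in level_cols):
                    rows.append(
                        {
                            "outcome": outcome,
                            "scope": fit.scope_label,
                            "model": res.model,
                            "column": ref_col,
                            "estimate": np.nan,
                            "se": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "p": np.nan,
                            "display": "ref",
                        }
                    )
            for _, r in res.table.iterrows():
                rows.append(
                    {
                        "outcome": outcome,
                        "scope": fit.scope_label,
                        "model": res.model,
                        "column": r["column"],
                        "estimate": r["estimate"],
                        "se": r["se"],
                        "ci_low": r["ci_low"],
                        "ci_high": r["ci_high"],
                        "p": r["p"],
                        "display": format_estimate(
                            r["estimate"], r["ci_low"], r["ci_high"], r["p"]
                        ),
                    }
                )
    return pd.DataFrame(rows)


def results_report(fits: list[ModelFit], outcome: str) -> str:
    """Plain-text report mirroring the estimate (95% CI) star convention."""
    lines = [f"Outcome: {outcome}", ""]
    for fit in fits:
        mv = fit.multivariate
        lines.append(f"[{fit.scope_label}] multivariate exchangeable GEE")
        lines.append(
            f"  n={mv.n_obs} clusters={mv.n_clusters} "
            f"dropped_outcome={mv.n_dropped_outcome} "
            f"corr={mv.dep_param:.3f} converged={mv.converged}"
        )
        if fit.screen.pvalues:
            kept = {t.name for t in fit.screen.selected}
            lines.append("  screen (P < 0.20):")
            for name, p in fit.screen.pvalues.items():
                status = "kept" if name in kept else "dropped"
                lines.append(f"    {name}: p={p:.3f} -> {status}")
        lines.append("  terms:")
        for _, r in mv.table.iterrows():
            if r["column"] == "intercept":
                continue
            lines.append(
                "    "
                + f"{r['column']}: "
                + format_estimate(r["estimate"], r["ci_low"], r["ci_high"], r["p"])
            )
        lines.append("")
    return "\n".join(lines)
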