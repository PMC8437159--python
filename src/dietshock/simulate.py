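"""Synthetic six-site household survey generator and effect oracle.

Households are generated with the statistical structure the analysis
assumes: site clustering via a shared per-site normal effect on the logit
scale, configurable exposure prevalences and covariate mixes, and per-group
weekly consumption drawn as Binomial(7, p) with

    logit(p) = baseline(group) + site effect + sum of active effect shifts.

The "before" period uses baseline + site effect only; the "during" period
adds the configured shifts for each household's active exposures and
covariates.  Score-level true effects are never injected directly — they are
obtained by Monte Carlo through :func:`implied_effect_oracle`, which uses the
scoring module as its only score implementation.

Effect keys
-----------
``during`` (always active in the during period),
``price_increase:<category>``, ``foodsec:<item>``, ``crop:<level>``,
``occupation:<level>``, ``education:<level>``, ``sex:<level>``,
``age:<band>``, ``locality:rural``, ``head_of_household``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from .codebook import Codebook, load_codebook
from .scoring import (
    ScoringOptions,
    compute_dds,
    compute_pdqs,
    map_to_mddw_groups,
    map_to_pdqs_groups,
)
from .survey import (
    AGE_BANDS,
    ASSISTANCE_TYPES,
    CROP_LEVELS,
    EDUCATION_LEVELS,
    FoodFrequencyRecord,
    HouseholdRecord,
    OCCUPATION_LEVELS,
    PRICE_CATEGORIES,
    SITES,
)

FOODSEC_ITEMS = ("worried_food", "skipped_meal", "whole_day_no_food")

#: confounder fields eligible for missingness injection (outcome food
#: frequencies are deliberately not missable).
MISSABLE_FIELDS = (
    "respondent_sex",
    "age_band",
    "education",
    "head_of_household",
    "household_size",
    "occupation",
    "worried_food",
    "skipped_meal",
    "whole_day_no_food",
    "social_assistance",
    "assistance_type",
    "crop_production",
    *(f"price_{cat}" for cat in PRICE_CATEGORIES),
)


class ConfigError(ValueError):
    pass


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SyntheticConfig:
    """Everything needed to generate one deterministic synthetic survey."""

    site_sizes: dict[str, int]
    price_increase: dict[str, dict[str, float]]  # site -> category -> P(increase)
    decrease_share: float  # of the non-increase mass that is "decreased"
    sex_female: dict[str, float]
    age_probs: dict[str, tuple[float, float, float]]
    education_probs: dict[str, tuple[float, float, float]]
    occupation_probs: dict[str, tuple[float, float, float, float]]
    head_prob: dict[str, float]
    household_size_mean: dict[str, float]  # Poisson mean (shifted, min 1)
    foodsec: dict[str, dict[str, float]]
    assistance_prob: dict[str, float]
    assistance_type_probs: tuple[float, float, float, float]
    crop_probs: dict[str, tuple[float, float, float, float]]
    baseline_logit: dict[str, float]  # survey group -> before-period logit
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    site_sd: float = 0.25
    missingness: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self, codebook: Codebook | None = None) -> None:
        codebook = codebook or load_codebook()
        sites = tuple(SITES)
        for site in sites:
            if self.site_sizes.get(site, 0) <= 0:
                raise ConfigError(f"site size for {site} must be positive")
        for mapping, name in (
            (self.sex_female, "sex_female"),
            (self.head_prob, "head_prob"),
            (self.assistance_prob, "assistance_prob"),
        ):
            for site, p in mapping.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{name}[{site}] outside [0, 1]")
        for site, cats in self.price_increase.items():
            for cat, p in cats.items():
                if cat not in PRICE_CATEGORIES:
                    raise ConfigError(f"unknown price category {cat!r}")
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"price_increase[{site}][{cat}] outside [0, 1]")
        if not 0.0 <= self.decrease_share <= 1.0:
            raise ConfigError("decrease_share outside [0, 1]")
        if self.site_sd < 0:
            raise ConfigError("site_sd must be non-negative")
        for gid in self.baseline_logit:
            codebook.group(gid)
        for key, shifts in self.effects.items():
            _check_effect_key(key)
            for gid in shifts:
                codebook.group(gid)
        for fname, rate in self.missingness.items():
            if fname not in MISSABLE_FIELDS:
                raise ConfigError(f"field {fname!r} is not missable")
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"missingness rate for {fname!r} outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthRecord:
    """Realized generator state: enough to rerun the oracle."""

    config: dict
    site_effects: dict[str, float]
    effects: dict[str, dict[str, float]]


def _check_effect_key(key: str) -> None:
    if key in ("during", "head_of_household", "locality:rural"):
        return
    prefix, _, value = key.partition(":")
    valid = {
        "price_increase": PRICE_CATEGORIES,
        "foodsec": FOODSEC_ITEMS,
        "crop": CROP_LEVELS,
        "occupation": OCCUPATION_LEVELS,
        "education": EDUCATION_LEVELS,
        "sex": ("female", "male"),
        "age": AGE_BANDS,
    }
    if prefix not in valid or value not in valid[prefix]:
        raise KeyError(f"unknown effect/exposure key {key!r}")


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Default calibration: descriptives loosely resemble the study's
    magnitudes (price-increase prevalences 0.6-0.98, rural sites farming,
    low dietary diversity).  It makes no claim of replicating the source
    survey."""
    sites = tuple(SITES)
    rural = {s for s, (_, loc) in SITES.items() if loc == "rural"}
    price_increase = {
        "Nouna": dict(staples=0.71, pulses=0.70, fruits=0.60, vegetables=0.61,
                      animal_source_foods=0.61),
        "Ouagadougou": dict(staples=0.88, pulses=0.80, fruits=0.76, vegetables=0.82,
                            animal_source_foods=0.80),
        "Kersa": dict(staples=0.98, pulses=0.98, fruits=0.96, vegetables=0.96,
                      animal_source_foods=0.96),
        "AddisAbaba": dict(staples=0.93, pulses=0.91, fruits=0.60, vegetables=0.76,
                           animal_source_foods=0.78),
        "Ibadan": dict(staples=0.91, pulses=0.92, fruits=0.91, vegetables=0.91,
                       animal_source_foods=0.92),
        "Lagos": dict(staples=0.98, pulses=0.98, fruits=0.97, vegetables=0.98,
                      animal_source_foods=0.98),
    }
    baseline = {
        "dark_green_leafy_vegetables": 1.3,
        "other_vitamin_a_fruits_vegetables": -0.4,
        "cruciferous_vegetables": -0.6,
        "other_vegetables": 1.7,
        "citrus_fruits": -0.5,
        "other_fruits": -0.2,
        "fish": 0.6,
        "eggs": -0.9,
        "poultry": -1.0,
        "legumes": 1.2,
        "nuts_seeds": -0.8,
        "dairy": -0.7,
        "whole_grains": 0.8,
        "liquid_vegetable_oils": 1.5,
        "red_meat": -1.2,
        "processed_meats": -1.8,
        "refined_grains": 2.0,
        "sugar_sweetened_beverages": -0.3,
        "desserts_ice_cream": -1.5,
        "roots_tubers": 0.9,
    }
    effects = {
        "during": {g: -0.25 for g in ("legumes", "other_vegetables", "other_fruits",
                                      "fish", "red_meat", "whole_grains")},
        "price_increase:pulses": {"legumes": -0.3},
        "price_increase:animal_source_foods": {"fish": -0.2, "red_meat": -0.2,
                                               "poultry": -0.2},
        "crop:decreased": {g: -0.2 for g in ("legumes", "other_vegetables",
                                             "whole_grains", "roots_tubers")},
    }
    cfg = SyntheticConfig(
        site_sizes={s: 300 for s in sites},
        price_increase=price_increase,
        decrease_share=0.15,
        sex_female={"Nouna": 0.12, "Ouagadougou": 0.32, "Kersa": 0.22,
                    "AddisAbaba": 0.65, "Ibadan": 0.51, "Lagos": 0.38},
        age_probs={s: (0.14, 0.29, 0.57) for s in sites},
        education_probs={
            "Nouna": (0.77, 0.20, 0.03), "Ouagadougou": (0.71, 0.27, 0.02),
            "Kersa": (0.74, 0.21, 0.05), "AddisAbaba": (0.36, 0.25, 0.39),
            "Ibadan": (0.04, 0.28, 0.68), "Lagos": (0.01, 0.07, 0.92),
        },
        occupation_probs={
            "Nouna": (0.02, 0.79, 0.05, 0.14), "Ouagadougou": (0.19, 0.17, 0.17, 0.47),
            "Kersa": (0.09, 0.86, 0.01, 0.04), "AddisAbaba": (0.44, 0.0, 0.14, 0.42),
            "Ibadan": (0.01, 0.06, 0.27, 0.66), "Lagos": (0.03, 0.03, 0.42, 0.52),
        },
        head_prob={s: 0.75 for s in sites},
        household_size_mean={"Nouna": 9.9, "Ouagadougou": 7.3, "Kersa": 7.0,
                             "AddisAbaba": 4.2, "Ibadan": 5.3, "Lagos": 4.9},
        foodsec={
            s: dict(worried_food=0.68, skipped_meal=0.34, whole_day_no_food=0.15)
            for s in sites
        },
        assistance_prob={s: 0.12 for s in sites},
        assistance_type_probs=(0.2, 0.6, 0.02, 0.18),
        crop_probs={
            s: ((0.35, 0.30, 0.15, 0.20) if s in rural else (0.1, 0.05, 0.03, 0.82))
            for s in sites
        },
        baseline_logit=baseline,
        effects=effects,
        site_sd=0.25,
        missingness={},
        seed=seed,
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Default config with every effect shift removed (null generator)."""
    return default_config(seed=seed, effects={}, **overrides)


# -- generation ------------------------------------------------------------


def _site_effects(config: SyntheticConfig) -> dict[str, float]:
    rng = np.random.default_rng([config.seed, 97])
    draws = rng.normal(0.0, config.site_sd, len(SITES))
    return {site: float(d) for site, d in zip(SITES, draws)}


def _draw_site_attrs(config: SyntheticConfig, site: str, n: int,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Vectorized covariate/exposure draws for one site."""
    attrs: dict[str, np.ndarray] = {}
    attrs["respondent_sex"] = np.where(
        rng.random(n) < config.sex_female[site], "female", "male"
    )
    attrs["age_band"] = rng.choice(AGE_BANDS, n, p=np.asarray(config.age_probs[site]))
    attrs["education"] = rng.choice(
        EDUCATION_LEVELS, n, p=np.asarray(config.education_probs[site])
    )
    attrs["occupation"] = rng.choice(
        OCCUPATION_LEVELS, n, p=np.asarray(config.occupation_probs[site])
    )
    attrs["head_of_household"] = rng.random(n) < config.head_prob[site]
    attrs["household_size"] = 1 + rng.poisson(
        max(config.household_size_mean[site] - 1.0, 0.0), n
    )
    for cat in PRICE_CATEGORIES:
        p_inc = config.price_increase[site][cat]
        u = rng.random(n)
        level = np.where(
            u < p_inc,
            "increased",
            np.where(rng.random(n) < config.decrease_share, "decreased", "unchanged"),
        )
        attrs[f"price_{cat}"] = level
    for item in FOODSEC_ITEMS:
        attrs[item] = rng.random(n) < config.foodsec[site][item]
    attrs["social_assistance"] = rng.random(n) < config.assistance_prob[site]
    atype = rng.choice(ASSISTANCE_TYPES, n, p=np.asarray(config.assistance_type_probs))
    attrs["assistance_type"] = atype
    attrs["crop_production"] = rng.choice(
        CROP_LEVELS, n, p=np.asarray(config.crop_probs[site])
    )
    return attrs


def _indicator(key: str, attrs: dict[str, np.ndarray], site: str, n: int) -> np.ndarray:
    if key == "during":
        return np.ones(n)
    if key == "head_of_household":
        return attrs["head_of_household"].astype(float)
    if key == "locality:rural":
        return np.full(n, 1.0 if SITES[site][1] == "rural" else 0.0)
    prefix, _, value = key.partition(":")
    if prefix == "price_increase":
        return (attrs[f"price_{value}"] == "increased").astype(float)
    if prefix == "foodsec":
        return attrs[value].astype(float)
    if prefix == "crop":
        return (attrs["crop_production"] == value).astype(float)
    if prefix == "occupation":
        return (attrs["occupation"] == value).astype(float)
    if prefix == "education":
        return (attrs["education"] == value).astype(float)
    if prefix == "sex":
        return (attrs["respondent_sex"] == value).astype(float)
    if prefix == "age":
        return (attrs["age_band"] == value).astype(float)
    raise KeyError(key)


def _during_logits(
    config: SyntheticConfig,
    codebook: Codebook,
    attrs: dict[str, np.ndarray],
    site: str,
    site_effect: float | np.ndarray,
    n: int,
) -> np.ndarray:
    gids = codebook.survey_group_ids
    base = np.array([config.baseline_logit.get(g, 0.0) for g in gids])
    logits = np.tile(base, (n, 1)) + np.asarray(site_effect).reshape(-1, 1)
    for key, shifts in config.effects.items():
        ind = _indicator(key, attrs, site, n)
        row = np.array([shifts.get(g, 0.0) for g in gids])
        logits += ind[:, None] * row
    return logits


def generate_survey(
    config: SyntheticConfig, codebook: Codebook | None = None
) -> tuple[list[HouseholdRecord], TruthRecord]:
    """Generate one deterministic survey (records pass validation)."""
    codebook = codebook or load_codebook()
    config.validate(codebook)
    gids = codebook.survey_group_ids
    site_effects = _site_effects(config)

    records: list[HouseholdRecord] = []
    for site_idx, site in enumerate(SITES):
        n = config.site_sizes[site]
        rng = np.random.default_rng([config.seed, site_idx])
        country, locality = SITES[site]
        attrs = _draw_site_attrs(config, site, n, rng)
        eff = site_effects[site]

        base = np.array([config.baseline_logit.get(g, 0.0) for g in gids])
        p_before = _sigmoid(base[None, :] + eff)
        days_before = rng.binomial(7, np.broadcast_to(p_before, (n, len(gids))))
        p_during = _sigmoid(_during_logits(config, codebook, attrs, site, eff, n))
        days_during = rng.binomial(7, p_during)

        for i in range(n):
            ff_before = FoodFrequencyRecord(
                "before", {g: int(days_before[i, j]) for j, g in enumerate(gids)}
            )
            ff_during = FoodFrequencyRecord(
                "during", {g: int(days_during[i, j]) for j, g in enumerate(gids)}
            )
            assisted = bool(attrs["social_assistance"][i])
            records.append(
                HouseholdRecord(
                    household_id=f"{site}-{i:04d}",
                    country=country,
                    site=site,
                    locality=locality,
                    respondent_sex=str(attrs["respondent_sex"][i]),
                    age_band=str(attrs["age_band"][i]),
                    education=str(attrs["education"][i]),
                    head_of_household=bool(attrs["head_of_household"][i]),
                    household_size=int(attrs["household_size"][i]),
                    occupation=str(attrs["occupation"][i]),
                    price_changes={
                        cat: str(attrs[f"price_{cat}"][i]) for cat in PRICE_CATEGORIES
                    },
                    worried_food=bool(attrs["worried_food"][i]),
                    skipped_meal=bool(attrs["skipped_meal"][i]),
                    whole_day_no_food=bool(attrs["whole_day_no_food"][i]),
                    social_assistance=assisted,
                    assistance_type=str(attrs["assistance_type"][i]) if assisted else None,
                    crop_production=str(attrs["crop_production"][i]),
                    food_freq_before=ff_before,
                    food_freq_during=ff_during,
                )
            )

    if any(rate > 0 for rate in config.missingness.values()):
        records = inject_missingness(records, config.missingness, seed=config.seed)

    truth = TruthRecord(
        config=config.to_dict(),
        site_effects=site_effects,
        effects=copy.deepcopy(config.effects),
    )
    return records, truth


# -- missingness -----------------------------------------------------------


def inject_missingness(
    records: list[HouseholdRecord],
    rates: dict[str, float],
    seed: int,
) -> list[HouseholdRecord]:
    """Independently blank each targeted confounder field with its rate.

    Outcome food-frequency fields are never blanked.
    """
    for fname, rate in rates.items():
        if fname not in MISSABLE_FIELDS:
            raise ConfigError(f"field {fname!r} is not missable")
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"rate for {fname!r} outside [0, 1]")
    rng = np.random.default_rng([seed, 31])
    out = [r.copy() for r in records]
    for fname, rate in sorted(rates.items()):
        if rate == 0:
            continue
        hits = rng.random(len(out)) < rate
        for rec, hit in zip(out, hits):
            if not hit:
                continue
            if fname.startswith("price_"):
                rec.price_changes[fname[len("price_"):]] = None
            else:
                setattr(rec, fname, None)
    return out


# -- Monte-Carlo oracle ----------------------------------------------------


def implied_effect_oracle(
    config: SyntheticConfig,
    exposure: str,
    score: str,
    n_mc: int = 50_000,
    codebook: Codebook | None = None,
    options: ScoringOptions = ScoringOptions(),
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo mean score difference (exposed minus unexposed).

    All other inputs — site, site effect, covariates, the other exposures —
    are marginalized by fresh draws from the config.  Scores are computed
    exclusively through the scoring module.  Returns (effect, MC standard
    error).
    """
    if n_mc < 1000:
        raise ConfigError("n_mc must be >= 1000")
    if score not in ("DDS", "PDQS"):
        raise ConfigError(f"unknown score {score!r}")
    _check_effect_key(exposure)  # KeyError for unknown exposure ids
    codebook = codebook or load_codebook()
    config.validate(codebook)
    gids = codebook.survey_group_ids
    rng = np.random.default_rng([seed if seed is not None else config.seed, 777])

    sites = list(SITES)
    sizes = np.array([config.site_sizes[s] for s in sites], dtype=float)
    site_idx = rng.choice(len(sites), n_mc, p=sizes / sizes.sum())
    site_eff = rng.normal(0.0, config.site_sd, n_mc)

    arm_scores: list[np.ndarray] = []
    for arm in (0.0, 1.0):
        vals = np.empty(n_mc)
        for s_i, site in enumerate(sites):
            sel = np.flatnonzero(site_idx == s_i)
            if sel.size == 0:
                continue
            n = sel.size
            attrs = _draw_site_attrs(config, site, n, rng)
            logits = _during_logits(config, codebook, attrs, site, site_eff[sel], n)
            # force the target exposure indicator to the arm value
            shifts = config.effects.get(exposure, {})
            if shifts:
                row = np.array([shifts.get(g, 0.0) for g in gids])
                ind = _indicator(exposure, attrs, site, n)
                logits += (arm - ind)[:, None] * row
            days = rng.binomial(7, _sigmoid(logits))
            mask = (
                codebook.mask_for_site(site)
                if options.apply_site_masks
                else frozenset()
            )
            for k in range(n):
                freq = FoodFrequencyRecord(
                    "during", {g: int(days[k, j]) for j, g in enumerate(gids)}
                )
                if score == "DDS":
                    prof = map_to_mddw_groups(freq, codebook, options.aggregator, mask)
                    vals[sel[k]] = compute_dds(
                        prof, min_days=options.dds_min_days
                    ).dds
                else:
                    prof = map_to_pdqs_groups(freq, codebook, options.aggregator, mask)
                    vals[sel[k]] = compute_pdqs(prof).pdqs
        arm_scores.append(vals)
    unexposed, exposed = arm_scores
    effect = float(exposed.mean() - unexposed.mean())
    se = float(
        np.sqrt(exposed.var(ddof=1) / n_mc + unexposed.var(ddof=1) / n_mc)
    )
    return effect, se
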