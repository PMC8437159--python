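# dietshock

A tested pipeline for analyzing how food-price shocks and food insecurity
relate to household dietary diversity and quality in multi-site surveys.

It scores 7-day food-group recall (20 survey groups, two recall periods)
into:

- **DDS** — a 10-group dietary diversity score (adapted MDD-W). A group
  counts only if eaten every day of the week (days/7 ≥ 1); the threshold is
  configurable for sensitivity analyses.
- **PDQS** — a 20-group Prime Diet Quality Score (range 0–40): healthy
  groups score 0/1/2 points at 0–1 / 2–3 / ≥4 weekly servings, unhealthy
  groups the reverse; weekly servings are proxied by days consumed.

Around the scores it provides:

- a **survey data model** with CSV readers/writers, first-class missingness
  and validation reports, driven by a packaged, editable YAML **codebook**
  (group ids, MDD-W/PDQS mappings, per-site food-list masks);
- **exposure coding** (price increases dichotomized, three food-insecurity
  items, crop production) and missing-indicator design-matrix assembly;
- **descriptive tables**: characteristics, price/food-security frequencies
  (non-missing denominators, half-up rounding), per-group consumption-change
  summaries, and before/during score summaries (DDS mean ± SD, PDQS median
  and IQR);
- **association models**: linear GEE with exchangeable working correlation
  clustered by site, cluster-robust (sandwich) SEs, a P < 0.20 univariate
  screen with forced covariates (crop production, household size), combined
  and per-country scopes, and an optional bias-reduced small-sample
  covariance;
- a **synthetic six-site generator** (site clustering via logit-scale random
  effects, configurable prevalences, effects injected on food-group
  propensities, missingness injection) with a **Monte-Carlo oracle** for the
  implied score-level effect of any exposure.

## CLI

```sh
dietshock simulate --seed 1 --out survey.csv          # synthetic survey
dietshock score   --in survey.csv --out scored.csv    # DDS/PDQS per period
dietshock describe --in survey.csv --out tables/      # descriptive tables
dietshock model   --in survey.csv --out results/ --outcome DDS
dietshock run-all --config demo.yaml --out bundle/    # full pipeline
```

A pipeline config is YAML, e.g.:

```yaml
seed: 1
synthetic: {}            # or: input_path: survey.csv
outcomes: [DDS, PDQS]
scope: combined          # or per_country
scoring:
  dds_min_days: 7
  aggregator: max
  apply_site_masks: true
```

`run-all` writes a deterministic bundle (survey, scores, descriptive tables,
tidy model results, text report, manifest); identical config + seed gives
byte-identical outputs.

## Library use

```python
import dietshock as ds

cfg = ds.default_config(seed=1)
records, truth = ds.generate_survey(cfg)
scores = ds.score_records(records)

from dietshock.models import ModelSpec, build_and_fit, results_report
fits = build_and_fit(records, ModelSpec(outcome="DDS"))
print(results_report(fits, "DDS"))
```
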