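"""End-to-end orchestration: simulate/ingest -> score -> describe -> model.

Every output bundle is deterministic under a fixed config + seed; a run
manifest records the config, seed, and package versions.  Record-level data
are never written to the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codebook import Codebook, load_codebook
from .descriptives import (
    characteristics_table,
    consumption_change_summary,
    mean_scores_before_during,
    price_change_table,
)
from .models import ModelSpec, build_and_fit, results_report, tidy_results
from .scoring import ScoringOptions, score_records
from .simulate import SyntheticConfig, default_config, generate_survey
from .survey import read_survey_table, write_survey_table

logger = logging.getLogger("dietshock")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int = 0
    input_path: str | None = None  # exactly one of input_path / synthetic
    synthetic: dict | None = None  # overrides for default_config (may be {})
    codebook_path: str | None = None
    scoring: dict = field(default_factory=dict)  # ScoringOptions kwargs
    outcomes: tuple[str, ...] = ("DDS", "PDQS")
    scope: str = "combined"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise PipelineError(
                "config", "exactly one of input_path / synthetic must be set"
            )
        for oc in self.outcomes:
            if oc not in ("DDS", "PDQS"):
                raise PipelineError("config", f"unknown outcome {oc!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        if "outcomes" in raw:
            raw["outcomes"] = tuple(raw["outcomes"])
        return cls(**raw)

    def scoring_options(self) -> ScoringOptions:
        return ScoringOptions(**self.scoring)


def _synthetic_config(config: PipelineConfig) -> SyntheticConfig:
    overrides = dict(config.synthetic or {})
    overrides.pop("seed", None)
    return default_config(seed=config.seed, **overrides)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline; returns the bundle directory.

    Any stage failure raises :class:`PipelineError` naming the stage; partial
    outputs are retained alongside a FAILED marker file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    codebook = load_codebook(config.codebook_path)
    options = config.scoring_options()
    try:
        # -- simulate / ingest ------------------------------------------
        stage = "ingest"
        if config.synthetic is not None:
            stage = "simulate"
            syn = _synthetic_config(config)
            records, truth = generate_survey(syn, codebook)
            write_survey_table(records, out / "survey.csv", codebook)
            (out / "truth.json").write_text(
                json.dumps(
                    {
                        "site_effects": truth.site_effects,
                        "effects": truth.effects,
                        "config": truth.config,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            logger.info("simulated %d households", len(records))
        else:
            records, report = read_survey_table(config.input_path, codebook)
            (out / "ingest_report.txt").write_text(report.summary())
            logger.info(
                "read %d households (%d issues)", len(records), len(report.issues)
            )

        # -- score -------------------------------------------------------
        stage = "score"
        scores = score_records(records, codebook, options)
        scores.to_csv(out / "scored.csv", index=False)
        n_incomplete = int((~scores["complete_during"]).sum())
        logger.info("scored %d households (%d incomplete)", len(scores), n_incomplete)

        # -- describe ----------------------------------------------------
        stage = "describe"
        freq, cont = characteristics_table(records)
        freq.data.to_csv(out / "characteristics.csv", index=False)
        cont.to_csv(out / "characteristics_continuous.csv", index=False)
        price_change_table(records).data.to_csv(out / "food_security.csv", index=False)
        consumption_change_summary(records, "MDD-W", codebook, options).data.to_csv(
            out / "consumption_change_mddw.csv", index=False
        )
        consumption_change_summary(records, "PDQS", codebook, options).data.to_csv(
            out / "consumption_change_pdqs.csv", index=False
        )
        mean_scores_before_during(records, codebook, options, scores=scores).to_csv(
            out / "score_summaries.csv", index=False
        )

        # -- model -------------------------------------------------------
        stage = "model"
        all_tidy = []
        report_parts = []
        for outcome in config.outcomes:
            spec = ModelSpec(outcome=outcome, scope=config.scope)
            fits = build_and_fit(records, spec, codebook, options)
            terms = spec.exposures + spec.candidates + spec.forced
            all_tidy.append(tidy_results(fits, outcome, terms))
            report_parts.append(results_report(fits, outcome))
        pd.concat(all_tidy, ignore_index=True).to_csv(
            out / "model_results.csv", index=False, float_format="%.10g"
        )
        (out / "model_report.txt").write_text("\n".join(report_parts))

        # -- manifest ----------------------------------------------------
        stage = "manifest"
        manifest = {
            "package": "dietshock",
            "version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "n_records": len(records),
            "n_incomplete_during": n_incomplete,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    return out
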