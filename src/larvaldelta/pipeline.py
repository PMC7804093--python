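"""End-to-end analysis pipeline and its configuration.

The response modelled throughout is the *frequency of parasitized fish
larvae*: the count of parasitized larvae per area × season × survey ×
species cell.  Covariates are the cell's species, season, area, and
``abundance`` = log1p(larvae collected).  Cells where no larvae of a species
were collected cannot carry parasitized larvae and are excluded from the
model frame (they still count in descriptive totals).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .delta_model import fit_delta, predict_cells
from .descriptive import summarize_dataset
from .glm_core import ModelSpec, analysis_of_deviance
from .inference import compare_families, forward_select, pairwise_contrasts
from .survey_data import Dataset, read_survey_table
from .synthetic import SimConfig, generate_dataset, paper_like_scenario

logger = logging.getLogger("larvaldelta")

#: Candidate terms in the order the study's model formula lists them.
DEFAULT_CANDIDATE_TERMS = ("abundance", "season", "species", "area", "species:area")
#: Competing explanatory variables resolved by AIC in selection step (ii).
DEFAULT_COMPETING_GROUPS = (("season", "abundance"),)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    input_csv: Optional[str] = None  # mutually exclusive with simulate
    simulate: Optional[SimConfig] = None
    candidate_terms: Tuple[str, ...] = DEFAULT_CANDIDATE_TERMS
    competing_groups: Tuple[Tuple[str, ...], ...] = DEFAULT_COMPETING_GROUPS
    alpha: float = 0.05
    positive_family: str = "gamma_log"
    contrast_factor: str = "species"
    contrast_method: str = "single_step"
    mc_seed: int = 20210112
    mc_draws: int = 100_000
    deviance_terms: Tuple[str, ...] = DEFAULT_CANDIDATE_TERMS
    outdir: str = "larvaldelta_out"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if sim is not None:
            if sim == "paper_like":
                cfg.simulate = paper_like_scenario()
            else:
                cfg.simulate = SimConfig(**{
                    k: tuple(v) if isinstance(v, list) and k in
                    ("areas", "seasons", "species") else v
                    for k, v in sim.items()
                })
        if cfg.input_csv is None and cfg.simulate is None:
            raise PipelineError("config: provide input_csv or simulate")
        return cfg


def build_model_frame(dataset: Dataset) -> pd.DataFrame:
    """Tidy modelling rows: one per cell with larvae collected."""
    frame = dataset.to_frame()
    frame = frame[frame["n_collected"] >= 1].reset_index(drop=True)
    frame["abundance"] = np.log1p(frame["n_collected"].astype(float))
    frame["response"] = frame["n_parasitized"].astype(float)
    return frame


def prediction_grid(frame: pd.DataFrame) -> pd.DataFrame:
    """One cell per species × area × season, abundance at the stratum mean."""
    strat_mean = frame.groupby(["area", "season"])["abundance"].mean()
    rows = []
    for area in sorted(frame["area"].unique()):
        for season in sorted(frame["season"].unique()):
            for species in sorted(frame["species"].unique()):
                rows.append({
                    "area": area, "season": season, "species": species,
                    "abundance": float(strat_mean.loc[(area, season)]),
                })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """describe → compare_families → forward_select → fit_delta →
    analysis_of_deviance → pairwise_contrasts → predict_cells.

    Writes one artifact per stage into ``config.outdir`` and a MANIFEST
    noting completion (or the failing stage, with partial outputs kept).
    Returns the artifact path map.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    manifest = {"complete": False, "stages": [], "version": _version,
                "mc_seed": config.mc_seed, "alpha": config.alpha}
    stage = "load"
    try:
        if config.simulate is not None:
            dataset, truth = generate_dataset(config.simulate)
            (outdir / "true_parameters.json").write_text(json.dumps(truth, indent=2))
            artifacts["true_parameters"] = str(outdir / "true_parameters.json")
        else:
            dataset = read_survey_table(config.input_csv)
        manifest["stages"].append(stage)

        stage = "describe"
        summary = summarize_dataset(dataset)
        summary.cells.to_csv(outdir / "cells.csv", index=False)
        summary.strata.to_csv(outdir / "strata.csv", index=False)
        artifacts["cells"] = str(outdir / "cells.csv")
        artifacts["strata"] = str(outdir / "strata.csv")
        manifest["stages"].append(stage)

        frame = build_model_frame(dataset)
        full_terms = tuple(config.candidate_terms)
        mains = tuple(t for t in full_terms if ":" not in t)

        stage = "compare_families"
        fam_table = compare_families(
            frame, frame["response"],
            ModelSpec("response", mains, "binomial_logit"),
            ModelSpec("response", mains, "gamma_log"),
        )
        fam_table.to_csv(outdir / "aic_table.csv", index=False)
        artifacts["aic_table"] = str(outdir / "aic_table.csv")
        manifest["stages"].append(stage)

        stage = "forward_select"
        trace = forward_select(
            frame, frame["response"], list(config.candidate_terms),
            alpha=config.alpha, competing_groups=config.competing_groups,
            positive_family=config.positive_family,
        )
        (outdir / "selection_trace.json").write_text(
            json.dumps({"alpha": trace.alpha,
                        "steps": trace.to_records(),
                        "final_terms": list(trace.presence_spec.terms)}, indent=2)
        )
        artifacts["selection_trace"] = str(outdir / "selection_trace.json")
        manifest["stages"].append(stage)

        stage = "fit_delta"
        sel_terms = trace.presence_spec.terms or mains
        model = fit_delta(
            frame, frame["response"],
            ModelSpec("response", sel_terms, "binomial_logit"),
            ModelSpec("response", sel_terms, config.positive_family),
        )
        model.presence_fit.coef_table().to_csv(outdir / "presence_coefficients.csv", index=False)
        model.positive_fit.coef_table().to_csv(outdir / "positive_coefficients.csv", index=False)
        artifacts["presence_coefficients"] = str(outdir / "presence_coefficients.csv")
        artifacts["positive_coefficients"] = str(outdir / "positive_coefficients.csv")
        manifest["stages"].append(stage)

        stage = "analysis_of_deviance"
        dev_terms = tuple(config.deviance_terms)
        presence_dev = analysis_of_deviance(
            frame.assign(response=(frame["response"] > 0).astype(float)),
            ModelSpec("response", dev_terms, "binomial_logit"),
        )
        pos_frame = frame[frame["response"] > 0].reset_index(drop=True)
        positive_dev = analysis_of_deviance(
            pos_frame, ModelSpec("response", dev_terms, config.positive_family)
        )
        presence_dev.to_csv(outdir / "deviance_presence.csv", index=False)
        positive_dev.to_csv(outdir / "deviance_positive.csv", index=False)
        artifacts["deviance_presence"] = str(outdir / "deviance_presence.csv")
        artifacts["deviance_positive"] = str(outdir / "deviance_positive.csv")
        manifest["stages"].append(stage)

        stage = "pairwise_contrasts"
        full_model = model
        if config.contrast_factor in sel_terms:
            contrasts = pairwise_contrasts(
                full_model.positive_fit, config.contrast_factor,
                method=config.contrast_method, seed=config.mc_seed,
                ndraws=config.mc_draws,
            )
        else:  # factor dropped in selection: contrast on the main-effects fit
            aux = fit_delta(
                frame, frame["response"],
                ModelSpec("response", mains, "binomial_logit"),
                ModelSpec("response", mains, config.positive_family),
            )
            contrasts = pairwise_contrasts(
                aux.positive_fit, config.contrast_factor,
                method=config.contrast_method, seed=config.mc_seed,
                ndraws=config.mc_draws,
            )
        contrasts.to_csv(outdir / "contrasts.csv", index=False)
        artifacts["contrasts"] = str(outdir / "contrasts.csv")
        manifest["stages"].append(stage)

        stage = "predict_cells"
        grid = prediction_grid(frame)
        preds = predict_cells(model, grid)
        preds.to_csv(outdir / "predictions.csv", index=False)
        artifacts["predictions"] = str(outdir / "predictions.csv")
        manifest["stages"].append(stage)

        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = str(outdir / "MANIFEST.json")
    return artifacts
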