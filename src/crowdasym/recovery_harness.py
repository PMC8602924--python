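"""End-to-end ground-truth recovery: generator -> staircases -> exclusion ->
model -> asymmetry analysis, with a machine-readable pass/fail report.

The harness answers the question every stage-level test cannot: when the
whole pipeline runs on a cohort whose in-out asymmetry is known exactly, do
the posterior summaries recover it?
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bayes_model import ModelSpec, build_design_matrix, fit
from .design_core import DESIGNS, LOCATIONS, StudyDesign, ConditionCell
from .observer_sim import PopulationConfig, sample_population
from .posterior_analysis import AnalysisConfig, exceedance, hdi, ioa_draws
from .preprocess import ExclusionRule, apply_exclusion, cohort_counts
from .quest_engine import QuestConfig, simulate_cohort

__all__ = ["RecoveryScenario", "run_pipeline", "run_scenario", "load_scenario"]


@dataclass
class RecoveryScenario:
    """Everything one recovery experiment needs, seeds included."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    study: StudyDesign = field(default_factory=StudyDesign)
    quest: QuestConfig = field(default_factory=QuestConfig)
    exclusion: ExclusionRule = field(default_factory=ExclusionRule)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    mcmc: str | dict = "smoke"
    seeds: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if len(self.seeds) == 0:
            raise ValueError("need at least one seed")


def run_pipeline(
    population: PopulationConfig,
    study: StudyDesign,
    quest: QuestConfig,
    exclusion: ExclusionRule,
    analysis: AnalysisConfig,
    mcmc: str | dict,
    seed: int,
) -> dict:
    """One seeded end-to-end run.  Returns the per-cell recovery record plus
    aggregate staircase and posterior summaries."""
    observers = sample_population(population, rng_seed=seed)
    _, thresholds = simulate_cohort(observers, study, quest, rng_seed=seed)
    thresholds = apply_exclusion(thresholds, exclusion)
    counts = cohort_counts(thresholds)

    # staircase accuracy against ground truth, in log10 units
    truth = {
        (o.participant, c): t
        for o in observers
        for c, t in o.true_threshold_deg.items()
    }
    errors = []
    for r in thresholds.itertuples(index=False):
        if r.excluded:
            continue
        cell = ConditionCell(r.design, r.location, r.flanker)
        errors.append(
            np.log10(r.threshold_deg) - np.log10(truth[(r.participant, cell)])
        )
    errors = np.asarray(errors)

    data = build_design_matrix(thresholds, ModelSpec())
    draws = fit(data, ModelSpec(), mcmc=mcmc, seed=seed)

    cells = []
    for design in DESIGNS:
        for location in LOCATIONS:
            s = ioa_draws(draws, design, location)
            lo, hi = hdi(s, 0.97)
            true_ioa = population.true_ioa(design, location)
            cells.append(
                {
                    "design": design,
                    "location": location,
                    "true_ioa": true_ioa,
                    "posterior_median_ioa": float(np.median(s)),
                    "hdi97_lo": lo,
                    "hdi97_hi": hi,
                    "covered": bool(lo <= true_ioa <= hi),
                    "p_gt_1": exceedance(s, 1.0),
                    "p_gt_1_5": exceedance(s, 1.5),
                }
            )
    return {
        "seed": seed,
        "counts": counts,
        "staircase": {
            "bias_log10": float(errors.mean()),
            "mae_log10": float(np.abs(errors).mean()),
            "n": int(errors.size),
        },
        "max_rhat": draws.max_rhat(),
        "cells": cells,
        "n_covered": int(sum(c["covered"] for c in cells)),
        "min_p_gt_1": float(min(c["p_gt_1"] for c in cells)),
        "median_p_gt_1_5": float(np.median([c["p_gt_1_5"] for c in cells])),
        "_draws": draws,
        "_thresholds": thresholds,
    }


def run_scenario(scenario: RecoveryScenario, keep_draws: bool = False) -> dict:
    """Run every seed of a scenario and aggregate coverage.  The report is a
    plain JSON-serialisable dict; identical inputs give identical reports."""
    per_seed = []
    for seed in scenario.seeds:
        result = run_pipeline(
            scenario.population,
            scenario.study,
            scenario.quest,
            scenario.exclusion,
            scenario.analysis,
            scenario.mcmc,
            seed,
        )
        if not keep_draws:
            result.pop("_draws")
            result.pop("_thresholds")
        per_seed.append(result)
    n_cells = len(per_seed[0]["cells"])
    return {
        "seeds": list(scenario.seeds),
        "n_cells": n_cells,
        "runs": per_seed,
        "aggregate": {
            "coverage_rate": float(
                sum(r["n_covered"] for r in per_seed) / (n_cells * len(per_seed))
            ),
            "min_p_gt_1": float(min(r["min_p_gt_1"] for r in per_seed)),
            "median_p_gt_1_5": float(
                np.median([r["median_p_gt_1_5"] for r in per_seed])
            ),
            "staircase_mae_log10": float(
                np.mean([r["staircase"]["mae_log10"] for r in per_seed])
            ),
        },
    }


def load_scenario(path: str | Path) -> RecoveryScenario:
    """Read a scenario from a YAML file.  Only scalar convenience fields are
    supported: population (uniform-truth keyword arguments), study and quest
    overrides, mcmc preset, seeds."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    population = PopulationConfig.uniform(**payload.get("population", {}))
    study = StudyDesign(**payload.get("study", {}))
    quest = QuestConfig(**payload.get("quest", {}))
    return RecoveryScenario(
        population=population,
        study=study,
        quest=quest,
        mcmc=payload.get("mcmc", "smoke"),
        seeds=tuple(payload.get("seeds", (1,))),
    )
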