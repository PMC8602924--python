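"""QUEST Bayesian adaptive staircase.

Maintains a gridded posterior over log10 threshold.  Each trial multiplies
the posterior by the Weibull likelihood of the observed response at the shown
letter size; the next size is placed at the posterior mean of log10 threshold
(the standard recommendation), clamped to the displayable range.  A condition
cell is measured in two fresh-prior adaptive runs of 40 trials whose pooled
80 (size, correct) pairs are then re-evaluated through the same Bayesian
update from the fresh prior — a pure re-analysis, no adaptation — to yield
the cell's single threshold estimate and its posterior SD in log10 units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design_core import (
    THRESHOLD_TABLE_COLUMNS,
    TRIAL_TABLE_COLUMNS,
    ConditionCell,
    ConfigurationError,
    StudyDesign,
    enumerate_cells,
)
from .observer_sim import ObserverTruth, PsychometricParams, simulate_trial, weibull_p

__all__ = [
    "QuestConfig",
    "QuestState",
    "ThresholdEstimate",
    "quest_init",
    "quest_update",
    "recommend_size",
    "quest_estimate",
    "run_adaptive_run",
    "reevaluate",
    "run_cell",
    "simulate_cohort",
    "write_threshold_table",
    "read_threshold_table",
]


@dataclass(frozen=True)
class QuestConfig:
    """Staircase configuration.

    Defaults follow the original protocol: initial threshold guess 1.1 deg
    with prior SD 3 log10 units, sizes clamped to [0.1, 3.0] deg.  The grid
    defaults to the prior mean +/- 5 prior SDs in steps of 0.005 log10 units,
    wide enough that the Gaussian prior is represented essentially
    untruncated.
    """

    initial_guess_deg: float = 1.1
    guess_sd_log10: float = 3.0
    grid_lo_log10: float | None = None
    grid_hi_log10: float | None = None
    grid_step_log10: float = 0.005
    psychometric: PsychometricParams = field(default_factory=PsychometricParams)
    size_min_deg: float = 0.1
    size_max_deg: float = 3.0

    def __post_init__(self) -> None:
        if self.initial_guess_deg <= 0 or self.guess_sd_log10 <= 0:
            raise ConfigurationError("initial guess and its SD must be positive")
        if self.grid_step_log10 <= 0:
            raise ConfigurationError("grid_step_log10 must be positive")
        if not (0 < self.size_min_deg < self.size_max_deg):
            raise ConfigurationError("need 0 < size_min_deg < size_max_deg")
        lo, hi = self.grid_bounds()
        centre = math.log10(self.initial_guess_deg)
        if lo > centre - 3 * self.guess_sd_log10 or hi < centre + 3 * self.guess_sd_log10:
            raise ConfigurationError(
                "grid must span the initial guess +/- 3 prior SDs in log10 space"
            )

    def grid_bounds(self) -> tuple[float, float]:
        centre = math.log10(self.initial_guess_deg)
        lo = self.grid_lo_log10
        hi = self.grid_hi_log10
        if lo is None:
            lo = centre - 5.0 * self.guess_sd_log10
        if hi is None:
            hi = centre + 5.0 * self.guess_sd_log10
        return float(lo), float(hi)

    def grid(self) -> np.ndarray:
        lo, hi = self.grid_bounds()
        n = int(math.floor((hi - lo) / self.grid_step_log10)) + 1
        return lo + self.grid_step_log10 * np.arange(n)


@dataclass(frozen=True)
class QuestState:
    """Whole staircase state: config, grid, unnormalised log posterior over
    log10 threshold, and the trials absorbed so far."""

    config: QuestConfig
    grid: np.ndarray
    log_posterior: np.ndarray
    trials_seen: tuple[tuple[float, bool], ...] = ()

    def posterior(self) -> np.ndarray:
        """Normalised posterior mass over the grid."""
        w = np.exp(self.log_posterior - self.log_posterior.max())
        return w / w.sum()


def quest_init(config: QuestConfig | None = None) -> QuestState:
    """Fresh state: Gaussian prior on log10 threshold centred at the initial
    guess."""
    config = config or QuestConfig()
    grid = config.grid()
    centre = math.log10(config.initial_guess_deg)
    log_prior = -0.5 * ((grid - centre) / config.guess_sd_log10) ** 2
    return QuestState(config=config, grid=grid, log_posterior=log_prior)


def quest_update(state: QuestState, size_deg: float, correct: bool) -> QuestState:
    """Absorb one trial.  The likelihood is evaluated at the size actually
    shown; sizes outside the displayable range are a domain error."""
    cfg = state.config
    if not (cfg.size_min_deg - 1e-9 <= size_deg <= cfg.size_max_deg + 1e-9):
        raise ValueError(
            f"size {size_deg} deg outside displayable range "
            f"[{cfg.size_min_deg}, {cfg.size_max_deg}]"
        )
    p = weibull_p(math.log10(size_deg) - state.grid, cfg.psychometric)
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    log_lik = np.log(p) if correct else np.log1p(-p)
    return QuestState(
        config=cfg,
        grid=state.grid,
        log_posterior=state.log_posterior + log_lik,
        trials_seen=state.trials_seen + ((float(size_deg), bool(correct)),),
    )


def recommend_size(state: QuestState) -> float:
    """Next letter size: posterior mean of log10 threshold, exponentiated and
    clamped to the displayable range."""
    w = state.posterior()
    mean_log10 = float(w @ state.grid)
    return float(
        np.clip(10.0 ** mean_log10, state.config.size_min_deg, state.config.size_max_deg)
    )


def quest_estimate(state: QuestState) -> tuple[float, float]:
    """(threshold in deg, posterior SD of log10 threshold)."""
    w = state.posterior()
    mean = float(w @ state.grid)
    var = float(w @ (state.grid - mean) ** 2)
    return 10.0 ** mean, math.sqrt(max(var, 0.0))


@dataclass(frozen=True)
class ThresholdEstimate:
    """Per participant per cell: pooled threshold estimate and its
    reliability."""

    participant: str
    cell: ConditionCell
    threshold_deg: float
    sd_log10: float
    n_trials: int
    excluded: bool = False


def run_adaptive_run(
    observer: ObserverTruth,
    cell: ConditionCell,
    config: QuestConfig,
    n_trials: int,
    rng: np.random.Generator,
) -> list[tuple[float, bool]]:
    """One adaptive run from a fresh prior; returns the (size, correct)
    pairs in presentation order."""
    state = quest_init(config)
    trials: list[tuple[float, bool]] = []
    for _ in range(n_trials):
        size = recommend_size(state)
        correct = simulate_trial(observer, cell, size, rng)
        state = quest_update(state, size, correct)
        trials.append((size, correct))
    return trials


def reevaluate(
    config: QuestConfig, trials: list[tuple[float, bool]]
) -> QuestState:
    """Re-subject a pooled trial list to the Bayesian update from the fresh
    prior.  Pure re-analysis: the result is order-invariant because the
    per-trial likelihoods commute."""
    state = quest_init(config)
    for size, correct in trials:
        state = quest_update(state, size, correct)
    return state


def run_cell(
    observer: ObserverTruth,
    cell: ConditionCell,
    design: StudyDesign,
    config: QuestConfig,
    rng: np.random.Generator,
) -> tuple[list[dict], ThresholdEstimate]:
    """Measure one cell: independent fresh-prior adaptive runs, then the
    pooled re-evaluation that produces the cell's single estimate."""
    records: list[dict] = []
    pooled: list[tuple[float, bool]] = []
    for run in range(1, design.runs_per_cell + 1):
        trials = run_adaptive_run(observer, cell, config, design.trials_per_run, rng)
        pooled.extend(trials)
        for t, (size, correct) in enumerate(trials, start=1):
            records.append(
                {
                    "participant": observer.participant,
                    "design": cell.design,
                    "location": cell.location,
                    "flanker": cell.flanker,
                    "run": run,
                    "trial": t,
                    "size_deg": size,
                    "correct": int(correct),
                }
            )
    threshold, sd = quest_estimate(reevaluate(config, pooled))
    estimate = ThresholdEstimate(
        participant=observer.participant,
        cell=cell,
        threshold_deg=threshold,
        sd_log10=sd,
        n_trials=len(pooled),
    )
    return records, estimate


def simulate_cohort(
    observers: list[ObserverTruth],
    design: StudyDesign,
    config: QuestConfig,
    rng_seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full staircase protocol for a cohort.

    Staircase state lives per cell, so estimates are independent of how trial
    slots interleave across blocks; cells are therefore simulated cell by
    cell with an independent, seed-derived random stream per (observer, cell).
    Returns (trial table, threshold table).
    """
    design.validate()
    cells = enumerate_cells()
    trial_rows: list[dict] = []
    thr_rows: list[dict] = []
    for pi, observer in enumerate(observers):
        for ci, cell in enumerate(cells):
            rng = np.random.default_rng([rng_seed, pi, ci])
            records, est = run_cell(observer, cell, design, config, rng)
            trial_rows.extend(records)
            thr_rows.append(
                {
                    "participant": est.participant,
                    "design": cell.design,
                    "location": cell.location,
                    "flanker": cell.flanker,
                    "threshold_deg": est.threshold_deg,
                    "sd_log10": est.sd_log10,
                    "n_trials": est.n_trials,
                    "excluded": False,
                }
            )
    trials = pd.DataFrame(trial_rows)[TRIAL_TABLE_COLUMNS]
    thresholds = pd.DataFrame(thr_rows)[THRESHOLD_TABLE_COLUMNS]
    return trials, thresholds


def write_threshold_table(frame: pd.DataFrame, path: str | Path) -> None:
    out = frame[THRESHOLD_TABLE_COLUMNS].copy()
    out["excluded"] = out["excluded"].astype(int)
    out.to_csv(path, index=False, float_format="%.8g")


def read_threshold_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(THRESHOLD_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"threshold table missing columns: {sorted(missing)}")
    frame["excluded"] = frame["excluded"].astype(bool)
    return frame[THRESHOLD_TABLE_COLUMNS]
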