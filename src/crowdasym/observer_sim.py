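"""Synthetic observers for 9AFC letter identification.

The generator produces observers with known ground-truth size thresholds for
every condition cell and simulates trial outcomes from a Weibull psychometric
function.  Truth is parameterised the way the analysis interrogates it —
unflanked acuity, inward crowding factor, and in-out asymmetry (IOA) — so the
quantity the pipeline estimates is explicit and recoverable.

The psychometric function is the Watson-Pelli form used by the QUEST family::

    Psi(x) = delta*gamma + (1 - delta) * (1 - (1 - gamma) * exp(-10**(beta*(x - t) + eps)))

with ``x`` and ``t`` the log10 letter size and log10 threshold, ``gamma`` the
9AFC guess rate, ``delta`` the lapse rate and ``beta`` the slope.  ``eps`` is
fixed in closed form so that ``Psi(t) = threshold_criterion`` exactly; lapse
trials still succeed at chance (the ``delta*gamma`` term).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design_core import (
    DESIGNS,
    LOCATIONS,
    RANDOM_EFFECTS,
    ConditionCell,
    enumerate_cells,
    random_effect_row,
)

__all__ = [
    "PsychometricParams",
    "PopulationConfig",
    "ObserverTruth",
    "p_correct",
    "weibull_p",
    "sample_population",
    "simulate_trial",
    "truth_table",
    "truth_threshold_table",
]


@dataclass(frozen=True)
class PsychometricParams:
    """Weibull psychometric parameters for 9AFC letter identification.

    Defaults: guess rate 1/9 (one of nine letters), slope 3.5, lapse 0.05,
    threshold criterion 0.5 — the staircase's standard configuration for this
    task.
    """

    guess_rate: float = 1.0 / 9.0
    slope_beta: float = 3.5
    lapse_rate: float = 0.05
    threshold_criterion: float = 0.5

    def __post_init__(self) -> None:
        g, d, c = self.guess_rate, self.lapse_rate, self.threshold_criterion
        upper = 1.0 - d * (1.0 - g)
        if not (0.0 < g < c < upper):
            raise ValueError(
                "need 0 < guess_rate < threshold_criterion < "
                "1 - lapse_rate*(1 - guess_rate); got "
                f"guess={g}, criterion={c}, upper asymptote={upper}"
            )
        if self.slope_beta <= 0:
            raise ValueError("slope_beta must be positive")

    @property
    def offset_epsilon(self) -> float:
        """Log10 offset making Psi(threshold) equal the criterion exactly.

        Solving Psi(t) = c for the exponent gives
        ``10**eps = -ln[(1 - (c - delta*gamma)/(1 - delta)) / (1 - gamma)]``.
        """
        g, d, c = self.guess_rate, self.lapse_rate, self.threshold_criterion
        inner = (1.0 - (c - d * g) / (1.0 - d)) / (1.0 - g)
        return math.log10(-math.log(inner))

    @property
    def upper_asymptote(self) -> float:
        return self.lapse_rate * self.guess_rate + (1.0 - self.lapse_rate)

    @property
    def lower_asymptote(self) -> float:
        return self.guess_rate


def weibull_p(x_minus_t_log10, params: PsychometricParams):
    """Probability correct as a function of log10(size) - log10(threshold).

    Vectorised over the first argument; this is the kernel both the trial
    simulator and the staircase likelihood evaluate.
    """
    g, d, b = params.guess_rate, params.lapse_rate, params.slope_beta
    k = b * np.asarray(x_minus_t_log10, dtype=float) + params.offset_epsilon
    k = np.clip(k, -300.0, 300.0)
    return d * g + (1.0 - d) * (1.0 - (1.0 - g) * np.exp(-np.power(10.0, k)))


def p_correct(size_deg, true_threshold_deg, params: PsychometricParams):
    """Probability of a correct 9AFC report at ``size_deg`` for an observer
    whose true threshold is ``true_threshold_deg``.

    Depends on size and threshold only through log10(size) - log10(threshold),
    so joint rescaling leaves it unchanged.
    """
    size = np.asarray(size_deg, dtype=float)
    thr = np.asarray(true_threshold_deg, dtype=float)
    if np.any(size <= 0) or np.any(thr <= 0):
        raise ValueError("size_deg and true_threshold_deg must be positive")
    return weibull_p(np.log10(size) - np.log10(thr), params)


# ---------------------------------------------------------------------------
# Population generator


def _default_unflanked() -> dict[str, float]:
    return {loc: 0.6 for loc in LOCATIONS}


def _default_cf() -> dict[tuple[str, str], float]:
    return {(d, l): 2.0 for d in DESIGNS for l in LOCATIONS}


def _default_ioa() -> dict[tuple[str, str], float]:
    return {(d, l): 2.5 for d in DESIGNS for l in LOCATIONS}


def _default_between_sd() -> dict[str, float]:
    sd = {name: 0.05 for name in RANDOM_EFFECTS}
    sd["intercept"] = 0.1
    return sd


@dataclass
class PopulationConfig:
    """Ground-truth population model for the synthetic cohort.

    Population-median log10 thresholds follow the same factorial structure the
    regression assumes; observers deviate from the medians through centred
    normal offsets on the varying effects (``between_observer_sd``, log10
    units).  Per cell: unflanked median, inward = unflanked x cf_inward,
    outward = unflanked x cf_inward x ioa, so ``ioa`` is exactly the
    outward/inward threshold ratio being estimated downstream.
    """

    n_participants: int = 38
    median_unflanked_deg: dict[str, float] = field(default_factory=_default_unflanked)
    cf_inward: dict[tuple[str, str], float] = field(default_factory=_default_cf)
    ioa: dict[tuple[str, str], float] = field(default_factory=_default_ioa)
    between_observer_sd: dict[str, float] = field(default_factory=_default_between_sd)
    psychometric: PsychometricParams = field(default_factory=PsychometricParams)

    @classmethod
    def uniform(
        cls,
        n_participants: int = 38,
        unflanked_deg: float = 0.6,
        cf_inward: float = 2.0,
        ioa: float = 2.5,
        intercept_sd: float = 0.1,
        effect_sd: float = 0.05,
    ) -> "PopulationConfig":
        """Homogeneous truth: the same crowding factor and IOA in every cell."""
        sd = {name: effect_sd for name in RANDOM_EFFECTS}
        sd["intercept"] = intercept_sd
        return cls(
            n_participants=n_participants,
            median_unflanked_deg={loc: unflanked_deg for loc in LOCATIONS},
            cf_inward={(d, l): cf_inward for d in DESIGNS for l in LOCATIONS},
            ioa={(d, l): ioa for d in DESIGNS for l in LOCATIONS},
            between_observer_sd=sd,
        )

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for loc, v in self.median_unflanked_deg.items():
            if v <= 0:
                raise ValueError(f"unflanked median for {loc} must be positive")
        for key, v in self.cf_inward.items():
            if v < 1:
                raise ValueError(f"cf_inward{key} must be >= 1")
        for key, v in self.ioa.items():
            if v <= 0:
                raise ValueError(f"ioa{key} must be positive")
        for name, v in self.between_observer_sd.items():
            if name not in RANDOM_EFFECTS:
                raise ValueError(f"unknown varying effect {name!r}")
            if v < 0:
                raise ValueError(f"between_observer_sd[{name!r}] must be >= 0")

    def cell_median_deg(self, cell: ConditionCell) -> float:
        """Population-median threshold (deg) for a cell."""
        base = self.median_unflanked_deg[cell.location]
        if cell.flanker == "none":
            return base
        cf = self.cf_inward[(cell.design, cell.location)]
        if cell.flanker == "inward":
            return base * cf
        return base * cf * self.ioa[(cell.design, cell.location)]

    def true_ioa(self, design: str, location: str) -> float:
        return self.ioa[(design, location)]


@dataclass
class ObserverTruth:
    """One synthetic observer: true threshold per cell plus psychometric
    parameters."""

    participant: str
    true_threshold_deg: dict[ConditionCell, float]
    psychometric: PsychometricParams = field(default_factory=PsychometricParams)

    def __post_init__(self) -> None:
        if len(self.true_threshold_deg) != 36:
            raise ValueError("an observer needs a threshold for all 36 cells")
        if any(v <= 0 for v in self.true_threshold_deg.values()):
            raise ValueError("true thresholds must be strictly positive")


def sample_population(
    config: PopulationConfig, rng_seed: int
) -> list[ObserverTruth]:
    """Draw a cohort of synthetic observers.

    Each observer's log10 thresholds are the population cell medians plus the
    cell's varying-effect row dotted with a vector of centred normal offsets,
    one per varying effect, with the configured SDs.  Deterministic given the
    seed.
    """
    config.validate()
    rng = np.random.default_rng(rng_seed)
    sd = np.array([config.between_observer_sd[name] for name in RANDOM_EFFECTS])
    cells = enumerate_cells()
    z = np.stack([random_effect_row(c) for c in cells])  # (36, n_effects)
    log_medians = np.array([math.log10(config.cell_median_deg(c)) for c in cells])

    observers = []
    for i in range(config.n_participants):
        offsets = rng.standard_normal(len(RANDOM_EFFECTS)) * sd
        log_thr = log_medians + z @ offsets
        observers.append(
            ObserverTruth(
                participant=f"p{i + 1:02d}",
                true_threshold_deg={
                    c: float(10.0 ** t) for c, t in zip(cells, log_thr)
                },
                psychometric=config.psychometric,
            )
        )
    return observers


def simulate_trial(
    observer: ObserverTruth,
    cell: ConditionCell,
    size_deg: float,
    rng: np.random.Generator,
) -> bool:
    """Bernoulli draw: was the target letter identified at this size?"""
    p = float(
        p_correct(size_deg, observer.true_threshold_deg[cell], observer.psychometric)
    )
    return bool(rng.random() < p)


def truth_table(observers: list[ObserverTruth]) -> pd.DataFrame:
    """Ground-truth table, one row per observer per cell
    (``participant,design,location,flanker,true_threshold_deg``)."""
    rows = [
        {
            "participant": o.participant,
            "design": c.design,
            "location": c.location,
            "flanker": c.flanker,
            "true_threshold_deg": thr,
        }
        for o in observers
        for c, thr in o.true_threshold_deg.items()
    ]
    return pd.DataFrame(rows)


def truth_threshold_table(
    observers: list[ObserverTruth], sd_log10: float = 0.05
) -> pd.DataFrame:
    """Cohort threshold table populated directly from ground truth.

    Shaped exactly like the staircase output table (noise-free thresholds, a
    constant nominal posterior SD); useful for exercising the assembly,
    exclusion and modelling stages without running staircases.
    """
    frame = truth_table(observers).rename(
        columns={"true_threshold_deg": "threshold_deg"}
    )
    frame["sd_log10"] = sd_log10
    frame["n_trials"] = 0
    frame["excluded"] = False
    return frame
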