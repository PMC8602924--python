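"""Derived quantities from the fitted model.

Everything the analysis reports is a deterministic function of the posterior
draws: per-cell thresholds for the average observer (fixed effects only),
crowding factors (flanked/unflanked threshold ratios), the in-out asymmetry
ratio IOA = threshold_out / threshold_in (identically cf_out / cf_in per
draw), highest-density intervals, exceedance probabilities, visual-field and
design contrasts, and a simulated population of new observers drawn from the
fitted varying-effect distribution.
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
from .bayes_model import PosteriorDraws, _CELL_ROWS

__all__ = [
    "AnalysisConfig",
    "hdi",
    "exceedance",
    "cell_threshold_draws",
    "crowding_factor",
    "ioa_draws",
    "ioa_table",
    "contrast_ratio",
    "meridian_contrast",
    "simulate_population",
]


@dataclass
class AnalysisConfig:
    """Summary settings: HDI masses (53%/97% for the headline table, 75% for
    prior checks), IOA exceedance criteria, and the size of the simulated
    population of new observers."""

    hdi_masses: tuple[float, ...] = (0.53, 0.75, 0.97)
    ioa_criteria: tuple[float, ...] = (1.0, 1.5)
    n_simulated_participants: int = 1000
    rng_seed: int = 0
    pool: str = "geometric"  # how meridian IOAs are pooled across locations

    def __post_init__(self) -> None:
        if not all(0.0 < m < 1.0 for m in self.hdi_masses):
            raise ValueError("HDI masses must lie in (0, 1)")
        if not all(c > 0 for c in self.ioa_criteria):
            raise ValueError("IOA criteria must be positive")
        if self.pool not in ("geometric", "arithmetic"):
            raise ValueError("pool must be 'geometric' or 'arithmetic'")


def hdi(samples, mass: float) -> tuple[float, float]:
    """Highest-density interval: the shortest contiguous interval of the
    sorted samples containing ceil(mass * n) points.  Ties resolve to the
    lowest such window."""
    s = np.sort(np.asarray(samples, dtype=float).ravel())
    n = s.size
    if n < 1:
        raise ValueError("hdi needs at least one sample")
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie in (0, 1)")
    m = int(math.ceil(mass * n))
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m - 1:] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def exceedance(samples, criterion: float) -> float:
    """Fraction of draws strictly greater than the criterion."""
    s = np.asarray(samples, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("exceedance needs at least one sample")
    return float(np.mean(s > criterion))


def cell_threshold_draws(draws: PosteriorDraws, cell: ConditionCell) -> np.ndarray:
    """Per-draw predicted threshold (deg) for the average observer in a cell:
    exp of the sum of the cell's active fixed coefficients."""
    x = _CELL_ROWS[cell]
    return np.exp(draws.flat_beta() @ x)


def crowding_factor(
    draws: PosteriorDraws, design: str, location: str, flanker: str
) -> np.ndarray:
    """Per-draw crowding factor: flanked / unflanked threshold ratio."""
    if flanker not in ("inward", "outward"):
        raise ValueError("crowding factor is defined for inward or outward flankers")
    flanked = cell_threshold_draws(draws, ConditionCell(design, location, flanker))
    unflanked = cell_threshold_draws(draws, ConditionCell(design, location, "none"))
    return flanked / unflanked


def ioa_draws(draws: PosteriorDraws, design: str, location: str) -> np.ndarray:
    """Per-draw in-out asymmetry ratio: outward / inward threshold.

    Per draw this equals cf_out / cf_in exactly (the unflanked threshold
    cancels)."""
    out = cell_threshold_draws(draws, ConditionCell(design, location, "outward"))
    inw = cell_threshold_draws(draws, ConditionCell(design, location, "inward"))
    return out / inw


def ioa_table(
    draws: PosteriorDraws, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Headline IOA summary per (design, location): exceedance probability
    for the conservative criterion, 97% and 53% HDIs and the median."""
    config = config or AnalysisConfig()
    rows = []
    for design in DESIGNS:
        for location in LOCATIONS:
            s = ioa_draws(draws, design, location)
            lo97, hi97 = hdi(s, 0.97)
            lo53, hi53 = hdi(s, 0.53)
            rows.append(
                {
                    "design": design,
                    "location": location,
                    "p_gt_1": exceedance(s, 1.0),
                    "p_gt_1_5": exceedance(s, 1.5),
                    "hdi97_lo": lo97,
                    "hdi53_lo": lo53,
                    "median": float(np.median(s)),
                    "hdi53_hi": hi53,
                    "hdi97_hi": hi97,
                }
            )
    return pd.DataFrame(rows)


def _pool(stacked: np.ndarray, how: str) -> np.ndarray:
    """Pool per-draw IOA samples across locations (axis 0)."""
    if how == "geometric":
        return np.exp(np.mean(np.log(stacked), axis=0))
    return np.mean(stacked, axis=0)


def contrast_ratio(
    draws: PosteriorDraws,
    numerator: list[tuple[str, str]],
    denominator: list[tuple[str, str]],
    pool: str = "geometric",
) -> dict:
    """Per-draw ratio of (pooled) IOA between two sets of (design, location)
    cells, with its exceedance probability.

    Ratios are multiplicative, so pooling defaults to the geometric mean of
    the member cells' per-draw IOA values.
    """
    if set(numerator) & set(denominator):
        raise ValueError("numerator and denominator pools must not overlap")
    num = _pool(np.stack([ioa_draws(draws, d, l) for d, l in numerator]), pool)
    den = _pool(np.stack([ioa_draws(draws, d, l) for d, l in denominator]), pool)
    ratio = num / den
    return {
        "samples": ratio,
        "median": float(np.median(ratio)),
        "p_gt_1": exceedance(ratio, 1.0),
        "hdi97": hdi(ratio, 0.97),
    }


def meridian_contrast(draws: PosteriorDraws, design: str, pool: str = "geometric") -> dict:
    """Horizontal-meridian (left+right) vs vertical-meridian (up+down) IOA
    within one design."""
    return contrast_ratio(
        draws,
        numerator=[(design, "left"), (design, "right")],
        denominator=[(design, "up"), (design, "down")],
        pool=pool,
    )


def simulate_population(
    draws: PosteriorDraws, config: AnalysisConfig | None = None
) -> dict:
    """Simulate new observers from the fitted model and summarise how many
    exhibit the asymmetry.

    Each simulated participant takes one posterior draw (propagating
    posterior uncertainty), samples a fresh varying-effect vector from that
    draw's Normal(0, diag(tau**2)) distribution, and gets per-cell thresholds
    and per-(design, location) IOA values.  Reported per cell: the proportion
    of simulated participants whose IOA exceeds each criterion, plus the
    median and spread of the simulated IOA distribution.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(config.rng_seed)
    beta = draws.flat_beta()
    tau = draws.flat_tau()
    n_total = beta.shape[0]
    n_sim = config.n_simulated_participants

    which = rng.integers(0, n_total, size=n_sim)
    offsets = rng.standard_normal((n_sim, len(RANDOM_EFFECTS))) * tau[which]

    cells = enumerate_cells()
    X36 = np.stack([_CELL_ROWS[c] for c in cells])
    Z36 = np.stack([random_effect_row(c) for c in cells])
    log_thr = beta[which] @ X36.T + offsets @ Z36.T  # (n_sim, 36)

    col = {c: i for i, c in enumerate(cells)}
    per_cell = {}
    for design in DESIGNS:
        for location in LOCATIONS:
            i_out = col[ConditionCell(design, location, "outward")]
            i_in = col[ConditionCell(design, location, "inward")]
            ioa = np.exp(log_thr[:, i_out] - log_thr[:, i_in])
            entry = {
                "median": float(np.median(ioa)),
                "var_log": float(np.var(np.log(ioa))),
            }
            for crit in config.ioa_criteria:
                entry[f"prop_gt_{crit:g}"] = float(np.mean(ioa > crit))
            per_cell[f"{design}/{location}"] = entry
    overall = {
        f"prop_gt_{crit:g}": float(
            np.mean([v[f"prop_gt_{crit:g}"] for v in per_cell.values()])
        )
        for crit in config.ioa_criteria
    }
    return {
        "n_simulated_participants": n_sim,
        "per_cell": per_cell,
        "overall": overall,
    }
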