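"""Factorial structure of the crowding experiment and its canonical schemas.

The experiment crosses three *designs* (how target location uncertainty and
attention are manipulated: blocked location, exogenous pre-cue, fully random),
four *target locations* on the meridians at fixed eccentricity, and three
*flanker* conditions (no flanker, a single flanker inward of the target, or
outward of it).  Every other module speaks in terms of the 36 condition cells
and the tabular schemas defined here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DESIGNS",
    "LOCATIONS",
    "FLANKERS",
    "RANDOM_EFFECTS",
    "ConditionCell",
    "ConfigurationError",
    "StudyDesign",
    "ScheduleSlot",
    "enumerate_cells",
    "cell_index",
    "build_schedule",
    "schedule_to_frame",
    "frame_to_schedule",
    "random_effect_row",
    "write_study_config",
    "read_study_config",
]

# Reference orderings.  The first level of each factor is the dummy-coding
# reference (flanker=none, design=blocked); location enters the model as four
# cell intercepts but uses "up" as reference inside interaction terms.
DESIGNS: tuple[str, ...] = ("blocked", "precued", "random")
LOCATIONS: tuple[str, ...] = ("up", "down", "left", "right")
FLANKERS: tuple[str, ...] = ("none", "inward", "outward")

TRIAL_TABLE_COLUMNS = [
    "participant", "design", "location", "flanker",
    "run", "trial", "size_deg", "correct",
]
THRESHOLD_TABLE_COLUMNS = [
    "participant", "design", "location", "flanker",
    "threshold_deg", "sd_log10", "n_trials", "excluded",
]


class ConfigurationError(ValueError):
    """An experiment configuration violates the design arithmetic."""


@dataclass(frozen=True, order=True)
class ConditionCell:
    """One design x location x flanker combination; the unit at which
    a threshold exists."""

    design: str
    location: str
    flanker: str

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.flanker not in FLANKERS:
            raise ValueError(f"unknown flanker {self.flanker!r}")

    @property
    def key(self) -> str:
        return f"{self.design}/{self.location}/{self.flanker}"

    @classmethod
    def from_key(cls, key: str) -> "ConditionCell":
        design, location, flanker = key.split("/")
        return cls(design, location, flanker)


def enumerate_cells() -> list[ConditionCell]:
    """All 36 cells in the canonical order: design-major, then location,
    then flanker."""
    return [
        ConditionCell(d, l, f)
        for d in DESIGNS
        for l in LOCATIONS
        for f in FLANKERS
    ]


_CELL_INDEX = {c: i for i, c in enumerate(enumerate_cells())}


def cell_index(cell: ConditionCell) -> int:
    """Position of ``cell`` in the canonical :func:`enumerate_cells` order."""
    return _CELL_INDEX[cell]


# ---------------------------------------------------------------------------
# Observer-level varying effects share one coding between the synthetic
# population generator and the regression model: an intercept plus dummies for
# the non-reference level(s) of each factor.

RANDOM_EFFECTS: tuple[str, ...] = (
    "intercept",
    "loc_down", "loc_left", "loc_right",
    "fl_inward", "fl_outward",
    "des_precued", "des_random",
)


def random_effect_row(cell: ConditionCell) -> np.ndarray:
    """Indicator row of the observer-level (varying) effects for ``cell``."""
    return np.array(
        [
            1.0,
            float(cell.location == "down"),
            float(cell.location == "left"),
            float(cell.location == "right"),
            float(cell.flanker == "inward"),
            float(cell.flanker == "outward"),
            float(cell.design == "precued"),
            float(cell.design == "random"),
        ]
    )


# ---------------------------------------------------------------------------


@dataclass
class StudyDesign:
    """Counts and geometry of the study.

    Defaults reproduce the original protocol: 38 observers, 8 blocks of 120
    trials per design (2880 trials per observer), each of the 36 cells
    measured in two 40-trial adaptive runs, targets at 7.5 deg eccentricity,
    centre-to-centre spacing 1.1 x letter size, letter size clamped to
    [0.1, 3.0] deg.
    """

    n_participants: int = 38
    blocks_per_design: int = 8
    trials_per_block: int = 120
    runs_per_cell: int = 2
    trials_per_run: int = 40
    eccentricity_deg: float = 7.5
    spacing_factor: float = 1.1
    size_min_deg: float = 0.1
    size_max_deg: float = 3.0
    # Session structure is metadata only; it plays no computational role.
    sessions: int = 4
    blocks_per_session: int = 6

    @property
    def trials_per_participant(self) -> int:
        return self.blocks_per_design * self.trials_per_block * len(DESIGNS)

    @property
    def trials_per_cell(self) -> int:
        return self.runs_per_cell * self.trials_per_run

    def validate(self) -> None:
        n_cells = len(DESIGNS) * len(LOCATIONS) * len(FLANKERS)
        if self.trials_per_participant != self.trials_per_cell * n_cells:
            raise ConfigurationError(
                "block arithmetic does not tile the factorial design: "
                f"{self.trials_per_participant} block trials vs "
                f"{self.trials_per_cell * n_cells} cell trials"
            )
        if self.trials_per_block % len(FLANKERS) != 0:
            raise ConfigurationError(
                "trials_per_block must divide evenly across flanker conditions"
            )
        if self.blocks_per_design % len(LOCATIONS) != 0:
            raise ConfigurationError(
                "blocks_per_design must divide evenly across target locations"
            )
        if not (0 < self.size_min_deg < self.size_max_deg):
            raise ConfigurationError("need 0 < size_min_deg < size_max_deg")
        if self.spacing_factor <= 1:
            raise ConfigurationError("spacing_factor must exceed 1")
        for name in ("n_participants", "blocks_per_design", "trials_per_block",
                     "runs_per_cell", "trials_per_run"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")


@dataclass(frozen=True)
class ScheduleSlot:
    """One trial slot: which cell it probes and where it sits in that cell's
    run structure.  Sizes are filled in later by the staircase."""

    block: int
    cell: ConditionCell
    run: int
    trial: int


def build_schedule(
    design: StudyDesign, participant: str | int, rng_seed: int
) -> list[ScheduleSlot]:
    """Build one participant's trial schedule.

    Physically faithful interleaving: blocked-design blocks keep a single
    location for the whole block (each location twice across the 8 blocks);
    pre-cued and random blocks mix locations trial by trial.  Flanker
    conditions are exactly balanced within every block.  Block order across
    the 24 blocks is randomised.  Per-cell totals are invariant to the seed:
    each cell always receives runs_per_cell x trials_per_run slots, assigned
    to runs in temporal order.
    """
    design.validate()
    del participant  # identity does not influence the schedule beyond the seed
    rng = np.random.default_rng(rng_seed)
    per_flanker = design.trials_per_block // len(FLANKERS)

    blocks: list[tuple[str, list[tuple[str, str]]]] = []
    for dname in DESIGNS:
        if dname == "blocked":
            locs = list(LOCATIONS) * (design.blocks_per_design // len(LOCATIONS))
            rng.shuffle(locs)
            for loc in locs:
                trials = [(loc, f) for f in FLANKERS for _ in range(per_flanker)]
                rng.shuffle(trials)
                blocks.append((dname, trials))
        else:
            per_loc = design.blocks_per_design * per_flanker // len(LOCATIONS)
            pools = {}
            for f in FLANKERS:
                pool = [loc for loc in LOCATIONS for _ in range(per_loc)]
                rng.shuffle(pool)
                pools[f] = pool
            for b in range(design.blocks_per_design):
                trials = [
                    (loc, f)
                    for f in FLANKERS
                    for loc in pools[f][b * per_flanker:(b + 1) * per_flanker]
                ]
                rng.shuffle(trials)
                blocks.append((dname, trials))

    order = rng.permutation(len(blocks))
    slots: list[ScheduleSlot] = []
    seen: Counter[ConditionCell] = Counter()
    for block_pos, bi in enumerate(order, start=1):
        dname, trials = blocks[bi]
        for loc, flk in trials:
            cell = ConditionCell(dname, loc, flk)
            seen[cell] += 1
            k = seen[cell] - 1
            slots.append(
                ScheduleSlot(
                    block=block_pos,
                    cell=cell,
                    run=k // design.trials_per_run + 1,
                    trial=k % design.trials_per_run + 1,
                )
            )
    return slots


def schedule_to_frame(slots: list[ScheduleSlot]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "block": [s.block for s in slots],
            "design": [s.cell.design for s in slots],
            "location": [s.cell.location for s in slots],
            "flanker": [s.cell.flanker for s in slots],
            "run": [s.run for s in slots],
            "trial": [s.trial for s in slots],
        }
    )


def frame_to_schedule(frame: pd.DataFrame) -> list[ScheduleSlot]:
    return [
        ScheduleSlot(
            block=int(r.block),
            cell=ConditionCell(r.design, r.location, r.flanker),
            run=int(r.run),
            trial=int(r.trial),
        )
        for r in frame.itertuples(index=False)
    ]


# -- config I/O -------------------------------------------------------------


def write_study_config(design: StudyDesign, path: str | Path) -> None:
    payload = {f.name: getattr(design, f.name) for f in fields(design)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_study_config(path: str | Path) -> StudyDesign:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(StudyDesign)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigurationError(f"unknown study-config keys: {sorted(unknown)}")
    design = StudyDesign(**payload)
    design.validate()
    return design
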