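"""Cohort threshold-table assembly, reliability exclusion, bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ExclusionRule", "apply_exclusion", "cohort_counts", "validate_threshold_table"]


@dataclass(frozen=True)
class ExclusionRule:
    """Discard thresholds whose staircase posterior SD exceeds the cutoff
    (default 0.2 log10 units) — strictly greater, not >=."""

    sd_cutoff_log10: float = 0.2

    def __post_init__(self) -> None:
        if self.sd_cutoff_log10 <= 0:
            raise ValueError("sd_cutoff_log10 must be positive")


def validate_threshold_table(frame: pd.DataFrame) -> None:
    """At most one row per (participant, cell); SDs present."""
    keys = ["participant", "design", "location", "flanker"]
    if frame.duplicated(subset=keys).any():
        dupes = frame[frame.duplicated(subset=keys, keep=False)]
        raise ValueError(
            f"duplicate (participant, cell) rows in threshold table:\n{dupes[keys]}"
        )
    if "sd_log10" not in frame.columns or frame["sd_log10"].isna().any():
        raise ValueError("every threshold row needs an sd_log10 value")


def apply_exclusion(
    frame: pd.DataFrame, rule: ExclusionRule | None = None
) -> pd.DataFrame:
    """Flag unreliable thresholds.  Rows are never dropped, only flagged, so
    the bookkeeping counts stay auditable; the modelling stage filters on the
    flag.  Idempotent."""
    rule = rule or ExclusionRule()
    validate_threshold_table(frame)
    out = frame.copy()
    out["excluded"] = out["sd_log10"].to_numpy() > rule.sd_cutoff_log10
    return out


def cohort_counts(frame: pd.DataFrame) -> dict:
    """Summary counts: rows, exclusions, percentage (nearest integer)."""
    n_rows = int(len(frame))
    if n_rows == 0:
        return {"n_rows": 0, "n_excluded": 0, "pct_excluded": 0}
    n_excluded = int(frame["excluded"].sum()) if "excluded" in frame.columns else 0
    return {
        "n_rows": n_rows,
        "n_excluded": n_excluded,
        "pct_excluded": int(round(100.0 * n_excluded / n_rows)),
    }
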