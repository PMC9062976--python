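"""Raw per-specificity MFI observations -> gated, scaled, daily tDSA series.

Per case the individual donor-specific-antibody MFI values measured on the
same day are summed into a total-DSA (tDSA) level; the resulting irregular
series is linearly interpolated onto an integer daily grid within the 50-day
post-transplant window (no extrapolation past the last observation).  Cases
whose post-transplant maximum never reaches 1500 MFI are gated into the
"no response" group 0 and excluded from scaling/clustering; the rest are
max-scaled to [0, 1] and split by follow-up length into full 50-day series
(clustered directly) and shorter 20-50-day series (classified afterwards).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessConfig",
    "TdsaTrajectory",
    "InclusionError",
    "aggregate_tdsa",
    "interpolate_daily",
    "gate_no_response",
    "scale_by_max",
    "split_by_length",
    "preprocess_case",
    "preprocess_cohort",
]


class InclusionError(ValueError):
    """Case fails the minimum-monitoring inclusion rule."""


@dataclass(frozen=True)
class PreprocessConfig:
    threshold: float = 1500.0  # responder gate, MFI
    horizon: int = 50  # last day of the clustering window
    min_last_day: int = 20  # inclusion: last observed day >= 20 (21-day span)


@dataclass
class TdsaTrajectory:
    """Daily-grid total-DSA trajectory for one case."""

    case_id: str
    days: np.ndarray  # integer grid, first..last observed day (<= horizon)
    tdsa: np.ndarray
    scaled: np.ndarray | None = None
    pre_treatment_tdsa: float | None = None
    length_class: str | None = None  # "full_50" | "short_20_50"
    gate: str | None = None  # "no_response" | "responder"
    observed_days: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def aggregate_tdsa(records: pd.DataFrame) -> pd.Series:
    """Sum per-specificity MFI into tDSA at each observed day.

    ``records`` needs columns ``specificity, day, mfi`` for a single case.
    A day counts as observed if any specificity has a record on it.
    Raises on negative MFI and on duplicate (specificity, day) pairs.
    """
    if (records["mfi"] < 0).any():
        bad = records.loc[records["mfi"] < 0].iloc[0]
        raise ValueError(f"negative MFI at specificity {bad['specificity']} day {bad['day']}")
    dup = records.duplicated(subset=["specificity", "day"])
    if dup.any():
        bad = records.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate record for specificity {bad['specificity']} day {bad['day']}"
        )
    return records.groupby("day")["mfi"].sum().sort_index()


def interpolate_daily(tdsa: pd.Series, horizon: int = 50, min_last_day: int = 20) -> pd.Series:
    """Linear interpolation onto integer days between first and last observation.

    Observed values are kept exactly; nothing is extrapolated beyond the last
    observed day, and the grid is capped at ``horizon``.  Cases whose last
    post-transplant observation lands before ``min_last_day`` are rejected.
    """
    tdsa = tdsa[tdsa.index >= 0]
    if len(tdsa) < 2:
        raise ValueError("need at least two post-transplant observations")
    days = tdsa.index.to_numpy(dtype=np.int64)
    last = min(int(days.max()), horizon)
    if last < min_last_day:
        raise InclusionError(
            f"last observed day {days.max()} precedes inclusion day {min_last_day}"
        )
    grid = np.arange(int(days.min()), last + 1)
    values = np.interp(grid, days, tdsa.to_numpy(dtype=np.float64))
    return pd.Series(values, index=grid)


def gate_no_response(trajectory: TdsaTrajectory, threshold: float = 1500.0) -> str:
    """Label "no_response" iff the post-transplant maximum is strictly below
    the gate (1500 MFI); gated cases form group 0 and skip clustering."""
    post = trajectory.tdsa[trajectory.days >= 0]
    if post.size == 0:
        raise ValueError("empty trajectory")
    label = "no_response" if post.max() < threshold else "responder"
    trajectory.gate = label
    return label


def scale_by_max(trajectory: TdsaTrajectory) -> np.ndarray:
    """Scale a responder trajectory by its own maximum (max-scaled to 1)."""
    m = trajectory.tdsa.max()
    if m <= 0:
        raise ValueError("cannot scale an all-zero trajectory")
    trajectory.scaled = trajectory.tdsa / m
    return trajectory.scaled


def split_by_length(
    trajectories: list[TdsaTrajectory], horizon: int = 50
) -> tuple[list[TdsaTrajectory], list[TdsaTrajectory]]:
    """Split responders into full 50-day series and shorter 20-50-day series."""
    full, short = [], []
    for tr in trajectories:
        if tr.days[-1] >= horizon:
            tr.length_class = "full_50"
            full.append(tr)
        else:
            tr.length_class = "short_20_50"
            short.append(tr)
    return full, short


def preprocess_case(
    case_id: str, records: pd.DataFrame, config: PreprocessConfig | None = None
) -> TdsaTrajectory:
    """Aggregate, interpolate and gate a single case.

    Pre-transplant records (day < 0) contribute only the pre-treatment tDSA
    level (sum at the earliest pre-transplant sample), never the grid.
    """
    config = config or PreprocessConfig()
    tdsa = aggregate_tdsa(records)
    pre = tdsa[tdsa.index < 0]
    pre_level = float(pre.iloc[np.argmin(pre.index)]) if len(pre) else None
    daily = interpolate_daily(tdsa, config.horizon, config.min_last_day)
    tr = TdsaTrajectory(
        case_id=case_id,
        days=daily.index.to_numpy(),
        tdsa=daily.to_numpy(),
        pre_treatment_tdsa=pre_level,
        observed_days=tdsa.index.to_numpy()[tdsa.index >= 0],
    )
    gate_no_response(tr, config.threshold)
    if tr.gate == "responder":
        scale_by_max(tr)
    return tr


def preprocess_cohort(
    mfi: pd.DataFrame, config: PreprocessConfig | None = None
) -> dict:
    """Run Stage 1-2 over a long-format cohort table.

    Returns a dict with keys ``gated`` (group-0 trajectories), ``full_50``,
    ``short_20_50`` (scaled responder trajectories) and ``excluded``
    (case_id -> reason).  The four sets partition the input cohort.
    """
    config = config or PreprocessConfig()
    gated, responders, excluded = [], [], {}
    for case_id, records in mfi.groupby("case_id", sort=True):
        try:
            tr = preprocess_case(str(case_id), records, config)
        except InclusionError as err:
            excluded[str(case_id)] = str(err)
            continue
        (gated if tr.gate == "no_response" else responders).append(tr)
    full, short = split_by_length(responders, config.horizon)
    return {
        "gated": gated,
        "full_50": full,
        "short_20_50": short,
        "excluded": excluded,
    }
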